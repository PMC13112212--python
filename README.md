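# dotconn

Resting-state functional connectivity graph analysis for high-density
diffuse optical tomography (HD-DOT).

## The problem

HD-DOT records near-infrared light intensities from a dense array of
source–detector pairs over the scalp. After quality control, the channel
measurements are mapped — through a sensitivity (Jacobian) matrix relating
channels to cortical mesh nodes — into parcel-level ΔHbO time series, whose
pairwise temporal correlations define a functional connectivity graph per
subject. Graph theory then summarises each subject's network: how dense and
strong it is, how efficiently information can flow, how clustered and
modular it is, which parcels act as hubs. Comparing these summaries between
healthy controls (HC), mild cognitive impairment (MCI) and Alzheimer's
disease (AD) probes how prefrontal network organisation changes along the
disease course — in particular the hyperconnectivity (denser, stronger,
shorter-path networks) reported in MCI that normalises in AD.

`dotconn` implements that analysis chain as a tested, reusable Python
library, plus a synthetic cohort generator so every stage can be exercised
and validated without access to recorded human data.

## The pipeline

1. **Channel QC** — prune channels with coefficient of variation > 8.3 %,
   mean intensity above threshold, separation > 100 mm, or no detectable
   cardiac peak (spectral argmax outside 0.5–2 Hz); convert intensities to
   ΔOD = −ln(|I|/mean|I|); quantify motion burden (windowed ΔOD excursions,
   amplitude 0.5 / SD 10, dilated ±1 s — quantified, never corrected);
   zero-phase 3rd-order Butterworth bandpass 0.01–0.1 Hz; regress the
   nearest short-separation channel (< 12 mm) out of each long channel.
2. **Parcel extraction** — nodes are *sensitive* where any kept channel's
   normalised Jacobian exceeds 5 % of its channel-wise maximum; parcels are
   included when > 50 % of their nodes are sensitive; channel ΔOD is
   projected to nodes, inverted to (ΔHbO, ΔHbR) via the modified
   Beer–Lambert law, averaged over each parcel's sensitive nodes, and the
   global mean signal is regressed out (its coupling is reported).
3. **Graph construction** — Pearson r between parcel series, Fisher
   z-transform, absolute threshold |r| ≥ 0.2, weights |z|/2.65 ∈ [0, 1);
   sparsity = 1 − 2E/(V(V−1)).
4. **Graph metrics** — degree, strength, Onnela clustering, nodal/global
   efficiency (Dijkstra on 1/w lengths), normalised betweenness,
   eigenvector centrality, Louvain modularity (best of 100 seeded
   restarts), degree-based participation coefficients averaged per
   resting-state network.
5. **Motifs & hubs** — induced-subgraph census of triangles, open triads,
   squares, chains, stars and cliques, normalised by C(V,3)/C(V,4); hub
   frequencies (top-10 % parcels per metric per subject) filtered at
   15 %/20 % with an overall-centrality median.
6. **Group statistics** — Shapiro–Wilk-routed parametric/non-parametric
   comparisons, Hedges' g, Benjamini–Hochberg FDR, two-way and
   Aligned-Rank-Transform ANOVA, (partial) correlations, chi-squared, and
   the QC–FC motion diagnostic.

## Worked example

```bash
python examples/05_group_statistics.py
```

runs the full pipeline on a small synthetic cohort (5 subjects per group,
3 minutes each) and prints, among other lines:

```
  mean_clustering     HC vs MCI: g=-3.56, p_fdr=0.0020 (welch-t)
home-testing chi-squared: chi2=3.41, df=2, p=0.18 (no group difference)
```

The negative Hedges' g says healthy controls have lower clustering than the
synthetic MCI group — the generator programs MCI hyperconnectivity
(within-network ρ 0.45 vs 0.30) and the pipeline recovers it; the
chi-squared line reproduces a categorical group comparison built from
printed group proportions. The other examples walk through simulation
(`01`), channel QC (`02`), parcel extraction (`03`) and graph metrics
(`04`) one stage at a time.

A thin CLI wraps the same library:

```bash
dotconn run-all --out report/ --seed 1 --groups 5,5,5
dotconn qc --input subject.snirf --report qc.json
```

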