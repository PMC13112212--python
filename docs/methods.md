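# Methods

This note documents the models, conventions and numerical choices behind
`dotconn`, and what the synthetic cohort does and does not establish about
real recordings.

## Signal model of the synthetic cohort

Each subject's neural state is a zero-mean Gaussian process over P parcels
with unit variances and a block correlation structure: ρ_w between parcels
of the same resting-state network, ρ_b between networks. Group profiles are
HC (0.30, 0.05), MCI (0.45, 0.15) and AD (0.30, 0.05) — the single
mechanism programmed into the cohort is MCI hyperconnectivity, the
direction the recovery tests look for. Default cohort: 22/22/21 subjects,
5 minutes at 12.5 Hz.

Series are produced by filtering white Gaussian noise into the 0.01–0.1 Hz
band and imposing the block covariance through its Cholesky factor, which
preserves the target correlation exactly in expectation. The band filter is
a *single causal* 3rd-order Butterworth pass: a zero-phase (forward–
backward) filter here would square the magnitude response, and stacked with
the analysis pipeline's own zero-phase bandpass would leave only ~20
effective samples per 5-minute record — an artefact of double-sharpening,
not a property of real broadband haemodynamics. Even with the single pass,
a band-limited 300 s record carries only ≈ 50 effective degrees of freedom,
so per-pair sample correlations scatter around their targets with SD ≈ 0.1;
this is the dominant within-group variance in the cohort and is why null
off-diagonal |r| averages ≈ 0.10 rather than the ≈ 0.016 an i.i.d. record
of 3750 samples would give.

Channel intensities are composed as
`I = I₀ · exp(−[neural + physiology + noise + motion])` where the neural
ΔOD of a long channel is the row-normalised Gaussian-kernel sensitivity mix
of node-level absorption changes (HbO plus a proportional HbR component,
ratio −0.3, through a 2×2 extinction matrix), and short channels (< 12 mm)
carry *no* neural projection by construction. Physiology is three shared
sinusoids — Mayer waves 0.1 Hz (amplitude 0.003 ΔOD), respiration 0.3 Hz
(0.004), cardiac 1.1 Hz (0.012) — with per-channel gains (SD 15 %);
the cardiac amplitude is the largest, as in real optical recordings, so the
spectral heart-rate check passes on clean channels. Measurement noise is
white (SD 0.005 ΔOD); motion is a Poisson stream of subject-level boxcar
events (0.5/min, 0.24 s, amplitude 0.1) hitting all channels. The
amplitudes are free parameters chosen once for plausibility — the study the
pipeline models does not characterise its subjects' spectral content.

What the synthetic cohort does **not** emulate: haemodynamic response
functions, photon transport (the Jacobian is a geometric kernel, not a
forward-model solution), 1/f background spectra, inter-subject anatomical
variability, or disease-related vascular changes. Passing the recovery
tests therefore shows the *pipeline* is correct and sensitive under the
stated covariance contrast; it does not validate the biological claims on
real data.

## Preprocessing conventions

* ΔOD uses the natural-log convention, −ln(|I|/mean|I|), per channel and
  wavelength; all-zero channels are flagged not-computable, not fatal.
* Channel pruning uses strict "above threshold" semantics (CoV > 8.3 %,
  mean intensity > 1e11, separation > 100 mm); the intensity and separation
  cut-offs are treated as opaque configurable values. Cardiac detection
  linearly detrends and excludes the DC bin before taking the spectral
  argmax — without detrending, drift dominates and every channel would
  fail, contradicting usable data.
* Motion: per channel, a sliding window of 0.5 s flags its *start sample*
  when the windowed range exceeds 0.5 (amplitude) or 10× the channel SD;
  flags are unioned over channels and dilated ±1 s. The start-sample
  convention makes a single step artefact flag exactly
  (t_motion + 2·t_mask) seconds, so the burden of an isolated event is
  interpretable in closed form. No motion correction is applied.
* Short-channel regression fits each kept long channel on its nearest
  (midpoint-distance) kept short channel at the same wavelength by OLS with
  intercept. If no short channel survives, the stage raises and asks the
  caller to skip it explicitly rather than silently passing data through.

## Parcel extraction

The tomographic reconstruction of the real instrument is out of scope; the
package consumes a channels×nodes sensitivity matrix and replaces image
reconstruction with normalised-sensitivity weighting of channel ΔOD into
node space. Sensitivity masking (node sensitive iff any kept channel at
either wavelength exceeds 5 % of its channel-wise row maximum, strictly)
and parcel inclusion (> 50 % sensitive nodes, strictly) are monotone in the
kept-channel set and anti-monotone in the threshold. Only ΔHbO propagates
downstream; ΔHbR is returned for completeness. Global-signal regression is
plain OLS against the across-parcel mean; residuals are exactly orthogonal
to the global component, and the pre-regression parcel–global coupling is
reported per subject as the systemic-contamination index.

## Graph construction and metrics

Edges require |r| ≥ 0.2 (inclusive — "spurious" means strictly below);
weights are |Fisher z|/2.65, guaranteed < 1 for |r| ≲ 0.99, above which the
constructor raises rather than clips. Edge signs are stored per edge so the
magnitude convention stays auditable while all metrics operate on
non-negative weights.

Metric conventions are the Brain Connectivity Toolbox's: Onnela clustering
(cube-root cycle products over the weights themselves — no per-graph max
normalisation, which would make the coefficient incomparable across
subjects with different peak weights), path lengths 1/w with Dijkstra,
betweenness normalised by (V−1)(V−2)/2, eigenvector centrality as the
max-normalised leading eigenvector, disconnected pairs contributing zero to
efficiency. Louvain is seeded and run with 100 restarts, keeping the
best-Q partition, so results are deterministic. The participation
coefficient uses binary degree shares, P_i = 1 − Σ_s (k_is/k_i)², matching
the "proportion of its degree" definition; strength shares are available
behind a flag. "Degree density" is reported as edge density 2E/(V(V−1)),
with mean degree also emitted, since the phrase is ambiguous between the
two.

## Motifs and hubs

Motifs are counted on the binarised graph with induced-subgraph semantics,
so the classes are disjoint and normalisation by C(V,3)/C(V,4) is
well-defined: triangle and open triad at 3 nodes; chordless square, chain
(P4), star (K1,3) and clique (K4) at 4 nodes; 4-subsets matching none
(diamond, paw, sparse subsets) are reported as `unclassified`. The
triangle/open-triad ratio is flagged undefined when no open triads exist.

Hub frequencies take each subject's top ⌈0.10·N⌉ parcels per metric (ties
broken by value, then smallest parcel id — deterministic), with the
frequency denominator being the subjects that actually include the parcel.
The two-stage filter removes parcels under 15 % frequency on every metric,
then retains parcels that are hubs in ≥ 20 % of subjects. Six metrics are
profiled (participation, degree, betweenness, eigenvector, clustering,
nodal efficiency) but *overall centrality* is the median of the three
centrality frequencies (degree, betweenness, eigenvector) only — the
source analysis lists four hub metrics yet defines the aggregate as a
median "of the three"; participation is therefore profiled and reported
separately rather than folded into the aggregate.

## Statistics

The routing layer applies Shapiro–Wilk per group at α = 0.05; all-pass
routes to one-way ANOVA (Welch t for two groups), any-fail to
Kruskal–Wallis (Mann–Whitney). Post-hoc pairwise tests use the same route,
are BH-FDR corrected *within one metric's family of pairwise comparisons*
(not across metrics), and carry Hedges' g with the small-sample correction
J = 1 − 3/(4N−9); g is the interpretation adopted for the unspecified
effect-size symbol. A zero-variance group forces the non-parametric route
with a warning.

The ART-ANOVA aligns each effect by subtracting the full cell mean and
adding back the effect's unweighted cell-mean estimate, ranks the aligned
responses, and runs a factorial ANOVA on the ranks, keeping only the
aligned effect's row; balanced designs use a closed-form decomposition,
unbalanced ones a statsmodels type-II fit. Calibration: each effect's
type-I error lies in [0.03, 0.07] at α = 0.05 over 500 null simulations
(2×2, n = 20/cell).

The group connectome retains edges present (post-threshold) in > 20 % of a
group's subjects whose Fisher z differs from zero by a one-sample t-test at
uncorrected p < 0.05 (the edge-level test is unnamed in the source; the
one-sample t on z is the choice and is recorded in the output). QC–FC
correlates each edge's z with subjects' motion burden (edges seen in ≥ 4
subjects), paired with inter-centroid distance; constant burdens yield an
empty table with a warning.

## Problem sizes and determinism

The synthetic atlas defaults to 60 parcels in 10 networks (5 nodes each),
one long channel per parcel plus 15 short channels — large enough for
block structure, modularity and hub profiles to be non-trivial while a full
65-subject cohort run completes in about a minute. All randomness flows
from a single master seed through per-subject seeds, so cohorts are
bit-reproducible; Louvain restarts and tie-breaks are seeded/deterministic.

## Known limitations

* The node projection is a smoothing operator, not an inverse model; absolute
  ΔHbO amplitudes are arbitrary units and only correlation structure is
  meaningful downstream.
* With 5-minute band-limited records, per-subject graph estimates are noisy
  by construction (≈ 50 effective DOF); analyses relying on individual
  edges rather than group aggregates would need longer records.
* The ART alignment uses unweighted cell means; severely unbalanced designs
  with empty cells are rejected rather than approximated.
* Negative-correlation edges enter metrics by magnitude (sign stored); any
  analysis for which anticorrelation is qualitatively different should
  consume the sign matrix.
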