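"""End-to-end orchestration: subject-level and cohort-level runs.

``run_subject`` composes the whole per-subject chain — channel pruning, OD
conversion, motion quantification, bandpass, short-channel regression,
sensitivity masking, parcel extraction, global-signal handling, graph
construction, metrics, modularity/participation, motif census — from one
configuration object.  ``run_cohort`` runs every subject and assembles the
group layer: metric comparisons with effect sizes and FDR, participation
ANOVAs, motif ART-ANOVA, hub profiles, group connectomes and the QC–FC
diagnostic.  Every threshold used is serialised into the report for
provenance, together with a configuration hash.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import graph as graph_mod
from . import io as io_mod
from . import metrics as metrics_mod
from . import motifs as motifs_mod
from . import parcel as parcel_mod
from . import qc as qc_mod
from . import stats as stats_mod
from .atlas import SyntheticAtlas
from .synth import Subject

__all__ = ["PipelineConfig", "SubjectBundle", "CohortReport", "run_subject", "run_cohort"]

GLOBAL_METRIC_PANEL = (
    "total_strength",
    "density",
    "global_efficiency",
    "mean_betweenness",
    "mean_clustering",
    "mean_eigenvector",
)


@dataclass
class PipelineConfig:
    """All pipeline thresholds, with the analysis defaults."""

    cov_max: float = 8.3  # % coefficient of variation
    intensity_max: float = 1e11
    separation_max: float = 100.0  # mm
    short_max: float = 12.0  # mm, short-channel bound
    band_low: float = 0.01  # Hz
    band_high: float = 0.1  # Hz
    band_order: int = 3
    motion_amp: float = 0.5
    motion_std: float = 10.0
    t_motion: float = 0.5  # s
    t_mask: float = 1.0  # s
    sensitivity_threshold: float = 0.05
    parcel_min_fraction: float = 0.5
    r_thresh: float = 0.2
    z_scale: float = 2.65
    top_fraction: float = 0.10
    hub_remove_below: float = 0.15
    hub_retain_at: float = 0.20
    presence_min: float = 0.20
    alpha: float = 0.05
    gamma: float = 1.0
    louvain_restarts: int = 100
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = io_mod.read_yaml(path) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @property
    def hash(self) -> str:
        return io_mod.config_hash(self.to_dict())


@dataclass
class SubjectBundle:
    """Every per-subject artefact the pipeline produces."""

    subject_id: str
    group: str
    mask: qc_mod.ChannelMask
    motion: qc_mod.MotionReport
    pts: parcel_mod.ParcelTimeSeries  # post global-signal regression
    global_coupling: float
    cm: graph_mod.ConnectivityMatrix
    graph: graph_mod.BrainGraph
    sparsity: float
    nodal: metrics_mod.NodalMetrics
    global_: metrics_mod.GlobalMetrics
    partition: metrics_mod.Partition
    participation: metrics_mod.ParticipationResult
    census: motifs_mod.MotifCensus
    provenance: dict = field(default_factory=dict)

    def nodal_frame(self) -> pd.DataFrame:
        df = self.nodal.to_frame(self.pts.parcel_ids)
        df.insert(0, "subject", self.subject_id)
        df.insert(1, "group", self.group)
        df["participation"] = self.participation.p
        df["network"] = self.pts.network_labels
        return df


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and subject id."""

    def __init__(self, stage: str, subject_id: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed for subject {subject_id}: {cause}")
        self.stage = stage
        self.subject_id = subject_id


def run_subject(
    config: PipelineConfig,
    recording: qc_mod.ChannelRecording,
    sensitivity: parcel_mod.SensitivityMatrix,
    atlas: SyntheticAtlas,
    subject_id: str = "subject",
    group: str = "",
) -> SubjectBundle:
    """Run the full per-subject chain; deterministic given config + inputs."""

    def _stage(name, fn):
        try:
            return fn()
        except StageError:
            raise
        except Exception as exc:  # noqa: BLE001 - re-raise with context
            raise StageError(name, subject_id, exc) from exc

    mask = _stage("prune", lambda: qc_mod.prune_channels(
        recording, config.cov_max, config.intensity_max, config.separation_max))
    od = _stage("od", lambda: qc_mod.intensity_to_od(recording))
    motion = _stage("motion", lambda: qc_mod.detect_motion(
        od, config.motion_amp, config.motion_std, config.t_motion, config.t_mask, mask))
    od_f = _stage("bandpass", lambda: qc_mod.bandpass(
        od, config.band_low, config.band_high, config.band_order))
    od_r = _stage("short-regress", lambda: qc_mod.short_channel_regress(
        od_f, mask, config.short_max))

    def _parcels():
        node_mask = parcel_mod.sensitive_nodes(sensitivity, mask, config.sensitivity_threshold)
        included = parcel_mod.include_parcels(node_mask, atlas, config.parcel_min_fraction)
        if included.size == 0:
            raise ValueError("no parcel passed the sensitivity-coverage criterion")
        node_mua = parcel_mod.channel_to_nodes(od_r, sensitivity, mask)
        hbo, _hbr = parcel_mod.mbll_invert(node_mua)
        return parcel_mod.parcel_average(hbo, node_mask, included, atlas, od_r.fs)

    pts_raw = _stage("parcels", _parcels)

    def _gsr():
        resid, g = parcel_mod.global_signal_regress(pts_raw)
        coupling = parcel_mod.global_coupling(pts_raw, g)
        return resid, coupling

    pts, coupling = _stage("global-signal", _gsr)

    cm = _stage("correlation", lambda: graph_mod.correlation_matrix(pts))
    g = _stage("graph", lambda: graph_mod.build_graph(cm, config.r_thresh, config.z_scale))
    spars = graph_mod.sparsity(g)
    nodal = _stage("nodal-metrics", lambda: metrics_mod.nodal_metrics(g))
    glob = _stage("global-metrics", lambda: metrics_mod.global_metrics(g, nodal))
    part = _stage("louvain", lambda: metrics_mod.louvain_partition(
        g, config.gamma, config.seed, config.louvain_restarts))
    pc = _stage("participation", lambda: metrics_mod.participation(g, part))
    census = _stage("motifs", lambda: motifs_mod.motif_census(g))

    return SubjectBundle(
        subject_id=subject_id,
        group=group,
        mask=mask,
        motion=motion,
        pts=pts,
        global_coupling=coupling,
        cm=cm,
        graph=g,
        sparsity=spars,
        nodal=nodal,
        global_=glob,
        partition=part,
        participation=pc,
        census=census,
        provenance={"config": config.to_dict(), "config_hash": config.hash},
    )


@dataclass
class CohortReport:
    """All cohort-level tables and summaries of one run."""

    global_table: pd.DataFrame  # one row per subject
    global_stats: pd.DataFrame  # pairwise comparisons per metric panel
    omnibus: pd.DataFrame  # omnibus test per metric
    participation_table: pd.DataFrame
    participation_anova: pd.DataFrame
    participation_art: dict
    participation_tukey: pd.DataFrame
    motif_table: pd.DataFrame
    motif_art: dict
    hub_profiles: dict[str, motifs_mod.HubProfile]
    hub_summaries: dict[str, dict]
    group_connectomes: dict[str, graph_mod.GroupConnectome]
    qcfc: pd.DataFrame
    provenance: dict

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.global_table.to_csv(out / "global_metrics.csv", index=False)
        self.global_stats.to_csv(out / "global_stats.csv", index=False)
        self.omnibus.to_csv(out / "global_omnibus.csv", index=False)
        self.participation_table.to_csv(out / "participation.csv", index=False)
        self.participation_anova.to_csv(out / "participation_anova.csv", index=False)
        self.participation_tukey.to_csv(out / "participation_tukey.csv", index=False)
        self.motif_table.to_csv(out / "motifs.csv", index=False)
        self.qcfc.to_csv(out / "qcfc.csv", index=False)
        for grp, prof in self.hub_profiles.items():
            prof.frequencies.to_csv(out / f"hubs_{grp}.csv")
        for grp, gc in self.group_connectomes.items():
            gc.edges.to_csv(out / f"group_connectome_{grp}.csv", index=False)
        io_mod.write_json(
            out / "report.json",
            {
                "provenance": self.provenance,
                "hub_summaries": self.hub_summaries,
                "participation_art": {
                    k: {"F": v.statistic, "df": v.df, "p": v.p}
                    for k, v in self.participation_art.items()
                },
                "motif_art": {
                    k: {"F": v.statistic, "df": v.df, "p": v.p}
                    for k, v in self.motif_art.items()
                },
            },
        )


def run_cohort(
    config: PipelineConfig,
    subjects: list[Subject],
    sensitivity: parcel_mod.SensitivityMatrix,
    atlas: SyntheticAtlas,
    out_dir: str | Path | None = None,
) -> CohortReport:
    """Run every subject and assemble the group-level analysis."""
    groups = sorted({s.group for s in subjects})
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    for grp in groups:
        if sum(s.group == grp for s in subjects) < 3:
            raise ValueError(f"group {grp!r} has fewer than three subjects")

    bundles: list[SubjectBundle] = []
    for s in subjects:
        bundles.append(
            run_subject(config, s.recording, sensitivity, atlas, s.subject_id, s.group)
        )

    rows = []
    for b in bundles:
        rows.append(
            {
                "subject": b.subject_id,
                "group": b.group,
                "n_parcels": b.pts.n_parcels,
                "n_channels_kept": b.mask.n_kept,
                "motion_burden": b.motion.burden,
                "global_coupling": b.global_coupling,
                "sparsity": b.sparsity,
                "density": b.global_.density,
                "mean_degree": b.global_.mean_degree,
                "total_strength": b.global_.total_strength,
                "global_efficiency": b.global_.global_efficiency,
                "mean_clustering": b.global_.mean_clustering,
                "mean_betweenness": b.global_.mean_betweenness,
                "mean_eigenvector": b.global_.mean_eigenvector,
                "modularity": b.partition.q,
            }
        )
    gtab = pd.DataFrame(rows)

    # group comparisons for the six-panel global metrics + sparsity + coupling
    stat_rows, omni_rows = [], []
    for metric in GLOBAL_METRIC_PANEL + ("sparsity", "global_coupling"):
        by_group = {grp: gtab.loc[gtab["group"] == grp, metric].to_numpy() for grp in groups}
        res = stats_mod.auto_compare_groups(by_group)
        omni_rows.append(
            {
                "metric": metric,
                "test": res.omnibus.test,
                "statistic": res.omnibus.statistic,
                "p": res.omnibus.p,
                "parametric": res.parametric,
            }
        )
        pw = res.pairwise.copy()
        pw.insert(0, "metric", metric)
        stat_rows.append(pw)
    global_stats = pd.concat(stat_rows, ignore_index=True)
    omnibus = pd.DataFrame(omni_rows)

    # participation per network (two-way group × network)
    subj_tables = [b.nodal_frame()[["subject", "group", "network", "participation"]] for b in bundles]
    ptable = metrics_mod.network_participation(subj_tables, config.presence_min)
    try:
        panova, ptukey = stats_mod.two_way_anova(
            ptable["participation"].to_numpy(),
            ptable["group"].to_numpy(),
            ptable["network"].to_numpy(),
        )
        part_art = stats_mod.art_anova(
            ptable["participation"].to_numpy(),
            ptable["group"].to_numpy(),
            ptable["network"].to_numpy(),
        )
    except ValueError:
        panova, ptukey, part_art = pd.DataFrame(), pd.DataFrame(), {}

    # motif counts (group × motif type)
    mrows = []
    for b in bundles:
        for motif, count in b.census.counts.items():
            if motif == "unclassified4":
                continue
            mrows.append(
                {
                    "subject": b.subject_id,
                    "group": b.group,
                    "motif": motif,
                    "count": count,
                    "frequency": b.census.frequencies[motif],
                    "triangle_open_ratio": b.census.triangle_open_ratio,
                }
            )
    mtable = pd.DataFrame(mrows)
    try:
        motif_art = stats_mod.art_anova(
            mtable["count"].to_numpy(dtype=float),
            mtable["group"].to_numpy(),
            mtable["motif"].to_numpy(),
        )
    except ValueError:
        motif_art = {}

    # hub profiles per group
    hub_profiles, hub_summaries = {}, {}
    nodal_all = pd.concat([b.nodal_frame() for b in bundles], ignore_index=True)
    for grp in groups:
        prof = motifs_mod.hub_frequencies(
            nodal_all[nodal_all["group"] == grp], config.top_fraction
        )
        retained, summary = motifs_mod.filter_hubs(
            prof, config.hub_remove_below, config.hub_retain_at
        )
        hub_profiles[grp] = retained
        hub_summaries[grp] = summary

    # group connectomes
    group_connectomes = {
        grp: graph_mod.group_connectome(
            [b.cm for b in bundles if b.group == grp],
            config.presence_min,
            config.alpha,
            config.r_thresh,
        )
        for grp in groups
    }

    # QC-FC diagnostic over the whole cohort
    centroids = {int(p): atlas.centroids[k] for k, p in enumerate(atlas.parcel_ids)}
    qcfc = stats_mod.qc_fc(
        [b.cm for b in bundles], [b.motion.burden for b in bundles], centroids
    )

    report = CohortReport(
        global_table=gtab,
        global_stats=global_stats,
        omnibus=omnibus,
        participation_table=ptable,
        participation_anova=panova,
        participation_art=part_art,
        participation_tukey=ptukey,
        motif_table=mtable,
        motif_art=motif_art,
        hub_profiles=hub_profiles,
        hub_summaries=hub_summaries,
        group_connectomes=group_connectomes,
        qcfc=qcfc,
        provenance={
            "config": config.to_dict(),
            "config_hash": config.hash,
            "n_subjects": len(subjects),
            "groups": {grp: int(sum(s.group == grp for s in subjects)) for grp in groups},
        },
    )
    if out_dir is not None:
        report.write(out_dir)
    return report
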