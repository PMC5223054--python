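"""End-to-end orchestration: simulate -> score -> spectra -> statistics.

A run is a pure function of a :class:`RunConfig`: the synthetic cohort,
every permutation seed and all statistics parameters derive from it, so
re-running a configuration reproduces the report byte for byte.  Stage
artifacts (cohort container, event tables, cluster JSON, the run report)
are written to the output directory as they are produced.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import cluster as cl
from . import contrasts as con
from . import io as oio
from . import tfr
from .beamformer import lcmv_filters, sensor_covariance, virtual_electrode
from .cohort import CELLS, Cohort, CohortConfig, EffectSpec, generate_cohort
from .recall import RecallLog, score_recall
from .sliding import SlidingGeometry, coherence_filter, sliding_map

__all__ = ["RunConfig", "validate_config", "run_pipeline",
           "subject_cell_maps", "sensor_cluster_test", "ve_cluster_test"]

logger = logging.getLogger("oscmem")


@dataclass
class RunConfig:
    """Everything a pipeline run depends on; fully JSON-serializable."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    seed: int = 0
    # spectral analysis
    foi_band: tuple[float, float] = (2.0, 10.0)  # theta-centred band of interest
    foi_step: float = 1.0
    broad_band: tuple[float, float] = (2.0, 30.0)  # sliding-statistic band
    broad_step: float = 0.5
    n_cycles: float = 5.0
    frame_rate: float = 50.0
    work_srate: float = 100.0
    fwhm_time: float = 0.2
    fwhm_freq: float = 2.0
    stats_window: tuple[float, float] = (-1.0, 3.0)
    # statistics
    n_perm: int = 1000
    sliding_n_perm: int = 200
    alpha: float = 0.05
    min_extent: tuple[int, int] = (3, 4)
    # source analysis
    lcmv_lambda: float = 0.05
    ve_rois: tuple[str, ...] = ("mtl_left", "mtl_right")
    # stage switches
    do_sliding: bool = True
    do_source: bool = True
    save_cohort: bool = False
    min_cell_trials: int = 15

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["cohort"] = self.cohort.to_dict()
        return d


def validate_config(config: RunConfig) -> list[dict]:
    """Static consistency checks; returns [{level, message}, ...]."""
    diags: list[dict] = []

    def err(msg):
        diags.append({"level": "error", "message": msg})

    def warn(msg):
        diags.append({"level": "warning", "message": msg})

    nyq = min(config.cohort.srate, config.work_srate) / 2
    for name, band in (("foi_band", config.foi_band),
                       ("broad_band", config.broad_band)):
        if band[1] >= nyq:
            err(f"{name} upper edge {band[1]} Hz at or above Nyquist {nyq} Hz")
        if band[0] >= band[1]:
            err(f"{name} has empty extent")
    w0, w1 = config.stats_window
    e0, e1 = config.cohort.epoch
    if w0 < e0 or w1 > e1:
        err("statistics window extends outside the epoch")
    if config.min_cell_trials < 15:
        err("minimum per-cell trial count below the exclusion rule of 15 trials")
    if not config.cohort.effects:
        warn("null run: no effects injected")
    if config.n_perm < 100:
        err("n_perm below 100 gives unusable p resolution")
    return diags


# ---------------------------------------------------------------------------
# Stage helpers
# ---------------------------------------------------------------------------


def subject_cell_maps(cohort: Cohort, freqs, config: RunConfig,
                      smooth: bool = True) -> list[dict[str, tfr.TimeFrequencyMap]]:
    """Per-subject smoothed first-level cell averages on a frequency grid."""
    out = []
    for subj in cohort.subjects:
        power = tfr.morlet_power(subj, freqs, n_cycles=config.n_cycles,
                                 frame_rate=config.frame_rate,
                                 work_srate=config.work_srate)
        z = tfr.zscore_power(power)
        cells = tfr.average_cells(z, subj.cell_labels)
        if smooth:
            cells = {c: tfr.smooth_tf(m, config.fwhm_time, config.fwhm_freq)
                     for c, m in cells.items()}
        out.append(cells)
    return out


def _contrast_stack(cell_maps, contrast, config):
    """(n_subj, ch, F, T) contrast stack cropped to the statistics window."""
    maps = []
    for cells in cell_maps:
        cropped = {c: tfr.crop_map(m, *config.stats_window) for c, m in cells.items()}
        maps.append(con.build_contrast(cropped, contrast))
    ref = maps[0]
    arr = np.stack([m.values for m in maps])
    return arr, ref.freqs, ref.times, ref.valid


def sensor_cluster_test(cell_maps, contrast: str, sensor_adjacency,
                        config: RunConfig, seed_offset: int = 0) -> cl.ClusterResult:
    """3D (electrode x frequency x time) cluster permutation test."""
    arr, freqs, times, valid = _contrast_stack(cell_maps, contrast, config)
    adj = cl.build_adjacency(arr.shape[1:], ("space", "freq", "time"),
                             sensor_adjacency)
    full_valid = np.broadcast_to(valid[None], arr.shape[1:])
    return cl.permutation_test(
        arr, adj, dims=("space", "freq", "time"), n_perm=config.n_perm,
        seed=[config.seed, 101, seed_offset], valid=full_valid)


def ve_cluster_test(ve_cells, contrast: str, config: RunConfig,
                    seed_offset: int = 0) -> cl.ClusterResult:
    """2D (frequency x time) cluster test on virtual-electrode cell maps."""
    maps = []
    for cells in ve_cells:
        cropped = {c: tfr.crop_map(m, *config.stats_window) for c, m in cells.items()}
        maps.append(con.build_contrast(cropped, contrast))
    arr = np.stack([m.values[0] for m in maps])  # single virtual channel
    ref = maps[0]
    adj = cl.build_adjacency(arr.shape[1:], ("freq", "time"))
    valid = np.broadcast_to(ref.valid, arr.shape[1:])
    return cl.permutation_test(
        arr, adj, dims=("freq", "time"), n_perm=config.n_perm,
        seed=[config.seed, 202, seed_offset], valid=valid)


def _cluster_report(result: cl.ClusterResult, freqs, times, alpha,
                    manifest_effects=None, contrast=None) -> dict:
    """Serialize a cluster result; flag overlap with injected effects."""
    sig = result.significant(alpha)
    entry = {
        "n_clusters": len(result.clusters),
        "min_p": result.min_p(),
        "threshold": result.threshold,
        "n_perm": result.n_perm,
        "significant": [
            {"polarity": c.polarity, "t_sum": c.t_sum, "p_corr": c.p_corr,
             "n_bins": int(c.members.size)}
            for c in sig
        ],
    }
    if manifest_effects and contrast is not None and len(result.shape) >= 2:
        overlaps = []
        for eff in manifest_effects:
            hit = False
            sign = "neg" if eff["amplitude_delta"] < 0 else "pos"
            for c in sig:
                if c.polarity != sign:
                    continue
                idx = np.array(np.unravel_index(c.members, result.shape))
                f_ax, t_ax = idx[-2], idx[-1]
                in_band = (freqs[f_ax] >= eff["band"][0] - 1e-9) & \
                          (freqs[f_ax] <= eff["band"][1] + 1e-9)
                in_win = (times[t_ax] >= eff["window"][0] - 1e-9) & \
                         (times[t_ax] <= eff["window"][1] + 1e-9)
                if np.any(in_band & in_win):
                    hit = True
            overlaps.append({"effect": eff["name"], "recovered": hit})
        entry["recovery"] = overlaps
    return entry


def _score_recall_stage(cohort: Cohort) -> dict:
    """Score the cohort's synthetic recall transcripts per condition."""
    summary = {}
    n_items = cohort.manifest["config"].get("n_items", 20)
    for sid, logs in cohort.recall_logs.items():
        per_cond = {}
        for cond, sequences in logs.items():
            counts = {"remembered": 0, "out_of_sequence": 0, "forgotten": 0}
            for seq in sequences:
                score = score_recall(RecallLog(n_items, tuple(seq)))
                for k, v in score.counts.items():
                    counts[k] += v
            per_cond[cond] = counts
        summary[sid] = per_cond
    return summary


# ---------------------------------------------------------------------------
# Full run
# ---------------------------------------------------------------------------


def run_pipeline(config: RunConfig, outdir: str | Path | None = None) -> dict:
    """Execute all configured stages and return the run report."""
    t_start = time.time()
    outdir = Path(outdir) if outdir is not None else None
    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)

    diags = validate_config(config)
    if any(d["level"] == "error" for d in diags):
        raise ValueError("invalid configuration: "
                         + "; ".join(d["message"] for d in diags
                                     if d["level"] == "error"))

    report: dict = {"config": config.to_dict(), "diagnostics": diags,
                    "seed": config.seed}

    logger.info("simulate: %d subjects", config.cohort.n_subjects)
    cohort = generate_cohort(config=config.cohort, master_seed=config.seed)
    report["manifest"] = cohort.manifest
    if outdir is not None and config.save_cohort:
        oio.save_cohort(cohort, outdir / "cohort")

    logger.info("score-recall")
    recall_summary = _score_recall_stage(cohort)
    rem_rates = {
        cond: float(np.mean([recall_summary[s][cond]["remembered"]
                             for s in recall_summary]))
        for cond in ("spatial", "nonspatial")
    }
    report["recall"] = {"per_subject": recall_summary,
                       "mean_remembered": rem_rates}

    logger.info("tfr: frequency band %s", config.foi_band)
    foi_freqs = np.arange(config.foi_band[0], config.foi_band[1] + 1e-9,
                          config.foi_step)
    cell_maps = subject_cell_maps(cohort, foi_freqs, config)

    manifest_effects = [e for e in cohort.manifest["effects"]]
    theta_effects = [e for e in manifest_effects
                     if e["band"][1] <= config.foi_band[1]]

    logger.info("sensor cluster tests")
    sensor_stats = {}
    effects_for = {"main_condition": [e for e in theta_effects
                                      if "spatial/forgotten" in e["cells_affected"]],
                   "main_memory": [e for e in theta_effects
                                   if "nonspatial/remembered" in e["cells_affected"]],
                   "interaction": [], "simple_remembered": theta_effects}
    arr_ref = None
    for k, contrast in enumerate(("main_condition", "main_memory", "interaction")):
        res = sensor_cluster_test(cell_maps, contrast, cohort.sensors.adjacency,
                                  config, seed_offset=k)
        arr, freqs, times, _ = _contrast_stack(cell_maps, contrast, config)
        arr_ref = (freqs, times)
        sensor_stats[contrast] = _cluster_report(
            res, freqs, times, config.alpha,
            manifest_effects=effects_for[contrast], contrast=contrast)
        if outdir is not None:
            res.save_json(outdir / f"sensor_{contrast}_clusters.json")
    report["sensor"] = sensor_stats

    if config.do_sliding:
        logger.info("sliding cluster statistic")
        broad_freqs = np.arange(config.broad_band[0], config.broad_band[1] + 1e-9,
                                config.broad_step)
        broad_cells = subject_cell_maps(cohort, broad_freqs, config)
        sliding_stats = {}
        for k, contrast in enumerate(("main_condition", "main_memory",
                                      "interaction")):
            arr, freqs, times, valid = _contrast_stack(broad_cells, contrast, config)
            pmap = sliding_map(arr, freqs, times, cohort.sensors.adjacency,
                               SlidingGeometry(), n_perm=config.sliding_n_perm,
                               seed=config.seed * 1000 + k, valid=valid)
            masks = {pol: coherence_filter(p, config.alpha, config.min_extent)
                     for pol, p in (("pos", pmap.p_pos), ("neg", pmap.p_neg))}
            sliding_stats[contrast] = {
                "n_tiles": int(pmap.p_pos.size),
                "coherent_pos_tiles": int(masks["pos"].sum()),
                "coherent_neg_tiles": int(masks["neg"].sum()),
            }
        report["sliding"] = sliding_stats

    if config.do_source:
        logger.info("virtual-electrode source analysis")
        source_stats = {}
        ve_effects = {
            "mtl_left": [e for e in theta_effects
                         if e["source"] in ("mtl_left", "mtl_bilateral")],
            "mtl_right": [e for e in theta_effects
                          if e["source"] in ("mtl_right", "mtl_bilateral")],
        }
        for ri, roi in enumerate(config.ve_rois):
            ve_cells = []
            for subj in cohort.subjects:
                cov = sensor_covariance(subj)
                filters = lcmv_filters(cohort.model, cov, config.lcmv_lambda)
                ve = virtual_electrode(filters, subj, cohort.model, roi)
                power = tfr.morlet_power(ve.as_epochs(), foi_freqs,
                                         n_cycles=config.n_cycles,
                                         frame_rate=config.frame_rate,
                                         work_srate=config.work_srate,
                                         space_names=(roi,))
                cells = tfr.average_cells(tfr.zscore_power(power),
                                          subj.cell_labels)
                cells = {c: tfr.smooth_tf(m, config.fwhm_time, config.fwhm_freq)
                         for c, m in cells.items()}
                ve_cells.append(cells)
            roi_stats = {}
            for k, contrast in enumerate(("main_condition", "main_memory")):
                res = ve_cluster_test(ve_cells, contrast, config,
                                      seed_offset=100 * ri + k)
                ref = next(iter(ve_cells[0].values()))
                roi_stats[contrast] = _cluster_report(
                    res, ref.freqs, ref.times, config.alpha,
                    manifest_effects=[e for e in ve_effects.get(roi, [])
                                      if (contrast == "main_condition")
                                      == ("spatial/forgotten" in e["cells_affected"])],
                    contrast=contrast)
            source_stats[roi] = roi_stats
        report["source"] = source_stats

    report["runtime_s"] = round(time.time() - t_start, 2)
    if outdir is not None:
        (outdir / "report.json").write_text(json.dumps(report, indent=1))
        (outdir / "run.log").write_text(
            f"oscmem run seed={config.seed} runtime={report['runtime_s']}s\n")
    return report
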