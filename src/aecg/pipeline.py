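"""End-to-end orchestration: per-record feature extraction and cohort study.

``run_features`` turns a directory of ECG files into one feature row per
record (failures are logged and skipped); ``run_study`` joins features with
per-patient metadata and emits the full report bundle: univariate screen,
ROC analyses for the primary and heart-failure outcomes, Kaplan-Meier
tables dichotomised at the angle cutoff, Cox models, full-cohort and
non-event correlation networks with rewiring scores, the patient
self-similarity matrix, and a summary JSON of headline numbers.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import network as net
from .beats import average_beats, detect_beats, locate_fiducials
from .complexity import compute_svd_features
from .exceptions import AecgError, PipelineError
from .io import CohortTable, read_cohort, read_ecg, write_features
from .scores import LvsdScoreCoefficients, lvsd_score
from .stats import cox_fit, km_curve, roc_analysis, univariate_screen
from .vcg import compute_vcg_features, load_kors_matrix

log = logging.getLogger("aecg")


@dataclass
class PipelineConfig:
    """Thresholds and file paths for the end-to-end analysis.

    Defaults are the study's operating points: edge threshold r > 0.45,
    significance support n > 82 at p < 1.2e-6, screening alpha 0.05,
    spatial QRS-T angle cutoff 110 deg (147 deg for heart-failure
    admission), DSI cutoff 0.64, beat-correlation threshold 0.97.
    """

    kors_matrix_path: str | None = None
    lvsd_coefficients_path: str | None = None
    corr_threshold: float = 0.97
    r_threshold: float = 0.45
    n_min: int = 82
    alpha: float = 0.05
    angle_cutoff: float = 110.0
    hf_angle_cutoff: float = 147.0
    dsi_cutoff: float = 0.64
    p_threshold: float = 1.2e-6
    sampling_rate: float = 500.0
    seed: int = 0

    @classmethod
    def from_toml(cls, path) -> "PipelineConfig":
        import tomllib
        with open(path, "rb") as fh:
            payload = tomllib.load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(payload) - known
        if unknown:
            raise PipelineError(f"unknown config keys: {sorted(unknown)}")
        return cls(**payload)


def extract_features(path, config: PipelineConfig) -> dict[str, float]:
    """Full single-record feature extraction: averaging, VCG, SVD, score."""
    kors = load_kors_matrix(config.kors_matrix_path)
    record = read_ecg(path, sampling_rate=config.sampling_rate)
    beats = detect_beats(record, kors_matrix=kors)
    beat = average_beats(record, beats, corr_threshold=config.corr_threshold)
    fiducials = locate_fiducials(beat, kors_matrix=kors)
    features = compute_vcg_features(beat, kors, fiducials).as_dict()
    features.update(compute_svd_features(beat, fiducials).as_dict())
    features["n_beats_averaged"] = beat.n_beats_averaged
    features["n_beats_detected"] = beats.n_beats
    if config.lvsd_coefficients_path is not None:
        coeffs = LvsdScoreCoefficients.from_file(config.lvsd_coefficients_path)
        lp, prob = lvsd_score(features, coeffs)
        features["lvsd_score"] = lp
        features["lvsd_probability"] = prob
    log.info("extracted %s: %d/%d beats averaged", Path(path).name,
             beat.n_beats_averaged, beats.n_beats)
    return features


def run_features(ecg_dir, out_table, config: PipelineConfig | None = None) -> CohortTable:
    """One feature row per readable ECG in ``ecg_dir``; failures logged and skipped."""
    config = config or PipelineConfig()
    paths = sorted(p for p in Path(ecg_dir).glob("*.csv")
                   if not p.name.endswith(".truth.json"))
    rows = {}
    for path in paths:
        try:
            rows[path.stem] = extract_features(path, config)
        except (AecgError, OSError, ValueError) as exc:
            log.warning("skipping %s: %s", path.name, exc)
    if not rows:
        raise PipelineError(f"no ECG in {ecg_dir} could be processed")
    frame = pd.DataFrame.from_dict(rows, orient="index")
    frame.index.name = "subject_id"
    table = CohortTable(frame)
    if out_table is not None:
        write_features(table, out_table)
    return table


def run_study(features_table, metadata_table, out_dir,
              config: PipelineConfig | None = None) -> dict:
    """Whole-study analysis over a joined feature+outcome table.

    ``features_table``/``metadata_table`` may be paths or
    :class:`CohortTable` objects; ``metadata_table`` may be None when the
    features table already carries outcomes. Returns the summary dict (also
    written to ``out_dir/summary.json``).
    """
    config = config or PipelineConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    features = (features_table if isinstance(features_table, CohortTable)
                else read_cohort(features_table))
    if metadata_table is None:
        joined = features.data.copy()
        excluded = dict(features.excluded)
    else:
        metadata = (metadata_table if isinstance(metadata_table, CohortTable)
                    else read_cohort(metadata_table))
        joined = features.data.join(metadata.data, how="inner", rsuffix="_meta")
        excluded = {**features.excluded, **metadata.excluded}
        if len(joined) == 0:
            raise PipelineError("feature/metadata join produced 0 rows")
    table = CohortTable(joined, excluded)
    frame = table.data
    for required in ("event", "time_days", "spatial_mean_qrst_angle"):
        if required not in frame.columns:
            raise PipelineError(f"study table lacks required column {required!r}")

    summary: dict = {"n_patients": int(len(frame)),
                     "n_events": int(frame["event"].sum())}

    # 1. univariate screen with Bonferroni control
    screen = univariate_screen(table, "event", alpha=config.alpha)
    screen.to_csv(out / "screen.csv")
    summary["n_nominal_significant"] = int(screen["nominal_significant"].sum())
    summary["n_bonferroni_significant"] = int(screen["bonferroni_significant"].sum())
    summary["bonferroni_threshold"] = float(screen.attrs["bonferroni_threshold"])

    # 2. ROC of the angle for the primary and HF outcomes
    angle = frame["spatial_mean_qrst_angle"].to_numpy()
    roc_primary = roc_analysis(angle, frame["event"].to_numpy())
    summary["roc_primary"] = dataclasses.asdict(roc_primary)
    (out / "roc_primary.json").write_text(json.dumps(summary["roc_primary"], indent=1))
    if "hf_event" in frame.columns and frame["hf_event"].sum() > 0:
        roc_hf = roc_analysis(angle, frame["hf_event"].to_numpy())
        summary["roc_hf"] = dataclasses.asdict(roc_hf)
        (out / "roc_hf.json").write_text(json.dumps(summary["roc_hf"], indent=1))

    # 3. Kaplan-Meier dichotomised at the angle cutoff
    above = (angle > config.angle_cutoff).astype(int)
    frame = frame.assign(angle_above_cutoff=above)
    km = km_curve(frame["time_days"], frame["event"], above)
    km_rows = []
    for label, curve in km.groups.items():
        curve = curve.assign(group=label)
        km_rows.append(curve)
    pd.concat(km_rows).to_csv(out / "km_primary.csv", index=False)
    summary["km_logrank_p"] = km.logrank_p

    # 4. Cox models (primary: cutoff + diabetes + LVEF; HF: cutoff + diabetes + age)
    cox_frames = {}
    primary_covs = [c for c in ("angle_above_cutoff", "type2_diabetes", "lvef")
                    if c in frame.columns]
    cox_primary = cox_fit(frame, primary_covs, "time_days", "event")
    cox_primary.summary.to_csv(out / "cox_primary.csv")
    cox_frames["primary"] = cox_primary
    summary["cox_primary_hr_angle"] = cox_primary.hazard_ratio("angle_above_cutoff")
    if "hf_event" in frame.columns and frame["hf_event"].sum() > 0:
        hf_covs = [c for c in ("angle_above_cutoff", "type2_diabetes", "age")
                   if c in frame.columns]
        cox_hf = cox_fit(frame, hf_covs, "hf_time_days", "hf_event")
        cox_hf.summary.to_csv(out / "cox_hf.csv")
        summary["cox_hf_hr_angle"] = cox_hf.hazard_ratio("angle_above_cutoff")

    # 5. correlation networks: full cohort and the non-event subset
    feature_cols = [c for c in table.numeric_columns()
                    if c not in ("event", "hf_event", "time_days", "hf_time_days",
                                 "angle_above_cutoff")]
    net_full = net.correlation_network(frame[feature_cols],
                                       r_threshold=config.r_threshold,
                                       n_min=config.n_min,
                                       p_threshold=config.p_threshold)
    non_event = frame.loc[frame["event"] == 0, feature_cols]
    net_no_event = net.correlation_network(non_event,
                                           r_threshold=config.r_threshold,
                                           n_min=config.n_min,
                                           p_threshold=config.p_threshold)
    net.export_graphml(net_full, out / "network_full.graphml")
    net.export_edge_csv(net_full, out / "network_full_edges.csv")
    net.export_graphml(net_no_event, out / "network_nonevent.graphml")
    net.export_edge_csv(net_no_event, out / "network_nonevent_edges.csv")
    net.export_force_layout_json(net_full, out / "network_full.json")
    rewiring = net.rewiring_scores(net_no_event, net_full)
    pd.Series(rewiring, name="rewiring_score").to_csv(
        out / "rewiring.csv", index_label="variable")
    metrics_full = net.network_metrics(net_full)
    metrics_no_event = net.network_metrics(net_no_event)
    summary["network"] = {
        "n_edges_full": net_full.n_edges,
        "n_edges_nonevent": net_no_event.n_edges,
        "mean_shortest_path_full": metrics_full.mean_shortest_path(),
        "mean_shortest_path_nonevent": metrics_no_event.mean_shortest_path(),
        "certainty_index": net.certainty_index(net_full, len(feature_cols)),
        "max_rewiring_score": max(rewiring.values()) if rewiring else None,
    }

    # 6. patient self-similarity
    sim = net.patient_similarity(frame[feature_cols + ["event"]], "event",
                                 rng=config.seed)
    sim.similarity.matrix.to_csv(out / "similarity.csv")
    summary["similarity"] = {
        "median_within_event": sim.median_within_event,
        "median_between": sim.median_between,
        "permutation_p": sim.permutation_p,
    }

    def _jsonable(obj):
        if isinstance(obj, dict):
            return {k: _jsonable(v) for k, v in obj.items()}
        if isinstance(obj, float) and not np.isfinite(obj):
            return None
        return obj

    (out / "summary.json").write_text(
        json.dumps(_jsonable(summary), indent=1, sort_keys=True))
    return summary
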