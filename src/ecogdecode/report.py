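"""End-to-end pipeline orchestration and result export.

:func:`run_pipeline` drives the whole analysis from one
:class:`RunConfig`: synthesize (or load) per-participant recordings,
preprocess, extract binned band-envelope features, map electrodes to
ROIs, run buffered-CV LDA for every (ROI, band), pool fold points
across participants, and apply the group-level statistics.  Everything
is deterministic given the configuration seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .containers import BandTable, DEFAULT_BANDS, FeatureTable
from .decode import (FoldOutcome, evaluate_feature, evaluate_multiclass,
                     incremental_roi_curve, make_folds)
from .features import (ArtifactRule, artifact_mask, attach_labels,
                       extract_features, segment_mask_to_bins)
from .preprocess import PreprocessConfig, preprocess
from .roimap import (DEFAULT_SIGMA_MM, DEFAULT_THRESHOLD, assign_rois,
                     projection_matrix)
from .stats import (AnovaResult, ChanceSpec, FeatureResult,
                    anova_roi_band, finite_chance_level, joint_significance,
                    ttest_accuracy, ttest_meandiff)
from .synth import (DEFAULT_ROI_CENTROIDS, EffectMap, NoiseSpec,
                    inject_artifacts, make_labels, make_layout,
                    synthesize_recording)

__all__ = ["RunConfig", "ResultBundle", "run_pipeline", "export_bundle",
           "build_feature_table"]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of a full synthetic-study run.

    Defaults describe the reference study conditions: five
    participants, two-minute behavioral blocks over three naturalistic
    states, five analysis bands, eight ROIs with at least three
    electrodes each, 7-fold buffered cross-validation, and FDR at
    alpha = 0.01.
    """

    # synthetic cohort
    n_participants: int = 5
    n_blocks: int = 60
    states: tuple[str, ...] = ("Talking", "WatchingTV", "UsingElectronics")
    class_pair: tuple[str, str] = ("Talking", "WatchingTV")
    persistence: float = 0.7
    block_duration_s: float = 120.0
    fs: float = 500.0
    n_per_roi: int = 3
    jitter_sd_mm: float = 4.0
    roi_centroids: dict = field(default_factory=lambda: dict(DEFAULT_ROI_CENTROIDS))
    effects: EffectMap = field(default_factory=EffectMap)
    base_amplitude: float = 5.0
    pink_exponent: float = 1.0
    noise_sd: float = 5.0
    drift_amplitude: float = 10.0
    drift_period_s: float = 600.0
    am_cv: float = 0.25
    am_timescale_s: float = 30.0
    artifact_segments: tuple = ()
    # features
    bands: BandTable = field(default_factory=lambda: DEFAULT_BANDS)
    bin_s: float = 10.0
    artifact_rule: ArtifactRule = field(default_factory=ArtifactRule)
    envelope_method: str = "spectral"
    # ROI mapping
    sigma_mm: float = DEFAULT_SIGMA_MM
    roi_threshold: float = DEFAULT_THRESHOLD
    min_density: int = 3
    # decoding
    n_folds: int = 7
    buffer_folds: int = 1
    ridge: float = 1e-3
    # statistics
    conf_alpha: float = 0.05
    fdr_alpha: float = 0.01
    # extras
    run_multiclass: bool = False
    additivity_bands: tuple[str, ...] = ()
    run_anova: bool = True
    seed: int = 0
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)

    def validate(self) -> None:
        if self.n_participants < 1 or self.n_blocks < 1:
            raise ValueError("need >= 1 participant and >= 1 block")
        for c in self.class_pair:
            if c not in self.states:
                raise ValueError(f"class {c!r} not in declared states")
        band_names = set(self.bands.names)
        for roi, band, state in self.effects.entries:
            if roi not in self.roi_centroids:
                raise ValueError(f"effect references unknown ROI {roi!r}")
            if band not in band_names:
                raise ValueError(f"effect references unknown band {band!r}")
            if state not in self.states:
                raise ValueError(f"effect references unknown state {state!r}")
        self.bands.validate_against_fs(self.fs)
        if self.block_duration_s % self.bin_s != 0:
            raise ValueError("block duration must be a multiple of bin_s")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = dict(doc)
        if "effects" in kwargs:
            kwargs["effects"] = EffectMap({
                (e["roi"], e["band"], e["state"]): float(e["multiplier"])
                for e in kwargs["effects"]})
        if "bands" in kwargs:
            kwargs["bands"] = BandTable.from_pairs(
                [(b["name"], b["low"], b["high"]) for b in kwargs["bands"]])
        if "artifact_rule" in kwargs:
            kwargs["artifact_rule"] = ArtifactRule(**kwargs["artifact_rule"])
        if "preprocess" in kwargs:
            kwargs["preprocess"] = PreprocessConfig(**kwargs["preprocess"])
        for key in ("states", "class_pair", "additivity_bands",
                    "artifact_segments"):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs)

    def to_yaml_dict(self) -> dict:
        doc = asdict(self)
        doc["effects"] = [
            {"roi": r, "band": b, "state": s, "multiplier": float(m)}
            for (r, b, s), m in self.effects.entries.items()]
        doc["bands"] = [{"name": b.name, "low": b.low, "high": b.high}
                        for b in self.bands]
        doc["artifact_rule"] = asdict(self.artifact_rule)
        doc["preprocess"] = asdict(self.preprocess)
        for key in ("states", "class_pair", "additivity_bands",
                    "artifact_segments"):
            doc[key] = list(doc[key])
        doc["roi_centroids"] = {k: [float(x) for x in v]
                                for k, v in self.roi_centroids.items()}
        return doc


@dataclass
class ResultBundle:
    """Everything a run produces, with provenance."""

    feature_results: list[FeatureResult]
    participant_accuracy: pd.DataFrame
    participant_meandiff: pd.DataFrame
    anova: AnovaResult | None
    chance_level: float
    multiclass: pd.DataFrame | None
    additivity: pd.DataFrame | None
    fold_records: pd.DataFrame
    provenance: dict

    def features_frame(self) -> pd.DataFrame:
        from scipy import stats as sps
        rows = []
        for r in self.feature_results:
            acc = np.asarray(r.accuracies, dtype=float)
            n = acc.size
            if n > 1 and acc.std(ddof=1) > 0:
                half = float(sps.t.ppf(0.975, n - 1) * acc.std(ddof=1) / np.sqrt(n))
            else:
                half = 0.0
            rows.append({
                "roi": r.roi, "band": r.band, "n_points": n,
                "mean_acc": r.mean_accuracy,
                "ci95_lo": r.mean_accuracy - half,
                "ci95_hi": r.mean_accuracy + half,
                "p_acc": r.p_acc, "mean_diff": r.mean_diff,
                "p_diff": r.p_diff, "sig_acc": r.sig_acc,
                "sig_diff": r.sig_diff, "sig_joint": r.sig_joint,
            })
        return pd.DataFrame(rows)


def _participant_seeds(seed: int, n: int) -> list[int]:
    state = np.random.SeedSequence(seed).generate_state(n, dtype=np.uint32)
    return [int(s) & 0x7FFFFFFF for s in state]


def build_feature_table(config: RunConfig, participant_seed: int
                        ) -> tuple[FeatureTable, "np.ndarray", object]:
    """Synthesize and featurize one participant.

    Returns the labeled feature table, the ROI assignment, and the
    block labels.
    """
    ss = np.random.SeedSequence(participant_seed)
    s_layout, s_labels, s_noise, s_art = [
        int(x) & 0x7FFFFFFF for x in ss.generate_state(4, dtype=np.uint32)]
    layout = make_layout(config.n_per_roi, config.roi_centroids,
                         config.jitter_sd_mm, seed=s_layout)
    labels = make_labels(config.n_blocks, config.states, config.persistence,
                         seed=s_labels, block_duration=config.block_duration_s)
    noise = NoiseSpec(pink_exponent=config.pink_exponent,
                      noise_sd=config.noise_sd,
                      drift_amplitude=config.drift_amplitude,
                      drift_period=config.drift_period_s,
                      am_cv=config.am_cv,
                      am_timescale_s=config.am_timescale_s, seed=s_noise)
    rec = synthesize_recording(layout, labels, config.bands, config.effects,
                               noise, fs=config.fs,
                               base_amplitude=config.base_amplitude)
    if config.artifact_segments:
        rec = inject_artifacts(rec, list(config.artifact_segments), seed=s_art)
    clean = preprocess(rec, config.preprocess)
    seg_keep = artifact_mask(clean, config.artifact_rule)
    table = extract_features(clean, config.bands, config.bin_s,
                             method=config.envelope_method)
    table.keep_mask &= segment_mask_to_bins(
        seg_keep, table.n_bins, config.bin_s, config.artifact_rule.segment_s)
    table = attach_labels(table, labels, states_of_interest=config.states)
    proj = projection_matrix(layout, config.sigma_mm)
    assignment = assign_rois(proj, config.roi_threshold, config.min_density)
    logger.info("participant: %d/%d bins kept, %d/%d ROIs retained",
                int(table.keep_mask.sum()), table.n_bins,
                len(assignment.retained_rois), len(layout.roi_names))
    return table, assignment, labels


def run_pipeline(config: RunConfig) -> ResultBundle:
    """Execute the full analysis for a synthetic cohort."""
    config.validate()
    seeds = _participant_seeds(config.seed, config.n_participants)
    band_names = config.bands.names
    acc_pool: dict[tuple[str, str], list[float]] = {}
    diff_pool: dict[tuple[str, str], list[float]] = {}
    fold_rows = []
    part_acc_rows = []
    part_diff_rows = []
    multiclass_rows = []
    additivity_rows = []
    n_tests: list[int] = []

    for p, pseed in enumerate(seeds, start=1):
        table, assignment, labels = build_feature_table(config, pseed)
        kept_labels = set(table.labels[table.keep_mask].tolist())
        for c in config.class_pair:
            if c not in kept_labels:
                raise ValueError(
                    f"participant {p}: no kept bins labeled {c!r}; increase "
                    "n_blocks or check the state set / artifact rule")
        scheme = make_folds(int(table.keep_mask.sum()), config.n_folds,
                            config.buffer_folds)
        for roi in assignment.retained_rois:
            for band in band_names:
                outcomes = evaluate_feature(
                    table, assignment, roi, band, scheme, config.class_pair,
                    seed=pseed, ridge=config.ridge)
                for o in outcomes:
                    acc_pool.setdefault((roi, band), []).append(o.accuracy)
                    diff_pool.setdefault((roi, band), []).append(
                        o.mean_diff_scalar)
                    n_tests.append(o.n_test)
                    fold_rows.append({
                        "participant": p, "roi": roi, "band": band,
                        "fold": o.fold, "accuracy": o.accuracy,
                        "mean_diff": o.mean_diff_scalar, "n_test": o.n_test})
                part_acc_rows.append({
                    "participant": p, "roi": roi, "band": band,
                    "accuracy": float(np.mean([o.accuracy for o in outcomes]))
                    if outcomes else np.nan})
                part_diff_rows.append({
                    "participant": p, "roi": roi, "band": band,
                    "mean_diff": float(np.mean([o.mean_diff_scalar
                                                for o in outcomes]))
                    if outcomes else np.nan})
        if config.run_multiclass and len(config.states) >= 3:
            mc = evaluate_multiclass(table, assignment, config.bands, scheme,
                                     config.states, seed=pseed,
                                     ridge=config.ridge)
            for band, outcomes in mc.items():
                for o in outcomes:
                    multiclass_rows.append({
                        "participant": p, "band": band, "fold": o.fold,
                        "accuracy": o.accuracy, "n_test": o.n_test})
        for band in config.additivity_bands:
            curve = incremental_roi_curve(table, assignment, band, scheme,
                                          config.class_pair, seed=pseed,
                                          ridge=config.ridge)
            for size, acc in curve:
                additivity_rows.append({
                    "participant": p, "band": band, "n_rois": size,
                    "accuracy": acc})

    chance = finite_chance_level(ChanceSpec(
        n_test=int(np.median(n_tests)) if n_tests else 1,
        n_classes=2, conf_alpha=config.conf_alpha))

    results: list[FeatureResult] = []
    for (roi, band), accs in acc_pool.items():
        diffs = diff_pool[(roi, band)]
        r = FeatureResult(roi=roi, band=band,
                          accuracies=np.asarray(accs, dtype=float),
                          mean_diffs=np.asarray(diffs, dtype=float))
        r.p_acc = ttest_accuracy(r.accuracies, chance) \
            if r.accuracies.size >= 2 else np.nan
        r.p_diff = ttest_meandiff(r.mean_diffs) \
            if r.mean_diffs.size >= 2 else np.nan
        results.append(r)
    joint_significance(results, alpha=config.fdr_alpha, chance=chance)

    fold_records = pd.DataFrame(fold_rows)
    anova = None
    if config.run_anova and len(fold_rows) > 0:
        try:
            anova = anova_roi_band(fold_records)
        except ValueError as exc:
            logger.warning("ANOVA skipped: %s", exc)

    provenance = {
        "seed": config.seed,
        "participant_seeds": seeds,
        "version": __version__,
        "config": config.to_yaml_dict(),
    }
    provenance["config_hash"] = hashlib.sha256(
        yaml.safe_dump(provenance["config"], sort_keys=True).encode()
    ).hexdigest()

    return ResultBundle(
        feature_results=results,
        participant_accuracy=pd.DataFrame(part_acc_rows),
        participant_meandiff=pd.DataFrame(part_diff_rows),
        anova=anova,
        chance_level=chance,
        multiclass=pd.DataFrame(multiclass_rows) if multiclass_rows else None,
        additivity=pd.DataFrame(additivity_rows) if additivity_rows else None,
        fold_records=fold_records,
        provenance=provenance,
    )


def export_bundle(bundle: ResultBundle, outdir) -> dict:
    """Write the bundle as CSV/JSON/YAML files; returns a manifest of
    paths and SHA-256 checksums."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: dict[str, str] = {}

    def _write_df(name: str, df: pd.DataFrame | None) -> None:
        if df is None or len(df) == 0:
            return
        path = outdir / name
        df.to_csv(path, index=False, float_format="%.10g")
        written[name] = hashlib.sha256(path.read_bytes()).hexdigest()

    _write_df("features.csv", bundle.features_frame())
    _write_df("participant_accuracy.csv", bundle.participant_accuracy)
    _write_df("participant_meandiff.csv", bundle.participant_meandiff)
    _write_df("fold_records.csv", bundle.fold_records)
    _write_df("multiclass.csv", bundle.multiclass)
    _write_df("additivity.csv", bundle.additivity)

    if bundle.anova is not None:
        path = outdir / "anova.json"
        path.write_text(json.dumps({
            "f_roi": bundle.anova.f_roi, "f_band": bundle.anova.f_band,
            "f_interaction": bundle.anova.f_interaction,
            "p_roi": bundle.anova.p_roi, "p_band": bundle.anova.p_band,
            "p_interaction": bundle.anova.p_interaction,
            "df": list(bundle.anova.df),
        }, indent=2))
        written["anova.json"] = hashlib.sha256(path.read_bytes()).hexdigest()

    cfg_path = outdir / "config.yaml"
    cfg_path.write_text(yaml.safe_dump(bundle.provenance["config"],
                                       sort_keys=False))
    written["config.yaml"] = hashlib.sha256(cfg_path.read_bytes()).hexdigest()

    log_path = outdir / "run.json"
    log_path.write_text(json.dumps({
        "chance_level": bundle.chance_level,
        "seed": bundle.provenance["seed"],
        "participant_seeds": bundle.provenance["participant_seeds"],
        "config_hash": bundle.provenance["config_hash"],
        "version": bundle.provenance["version"],
    }, indent=2))
    written["run.json"] = hashlib.sha256(log_path.read_bytes()).hexdigest()

    manifest = {"files": written}
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
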