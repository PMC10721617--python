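"""End-to-end orchestration: simulate -> degrade -> score -> shift ->
evaluate, plus the self-contained replay of the published summary
statistics.

``run_pipeline`` renders a synthetic cohort whose per-class nuclear
morphology drives the device score, optionally degrades each sequence
with one of the ablation methods, scores sites, quantifies the feature
shift introduced by the degradation, and computes the diagnostic
statistics.  Every random draw descends from one master seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import degrade as deg
from .acquisition import AcquisitionParams, TrajectorySpec
from .cohort import (CohortSpec, SiteRecord, agreement_table_from_cohort,
                     cohort_to_dataframe, generate_site_cohort)
from .evaluate import (AgreementTable, diagnostics_from_table, mcnemar_exact,
                       printed_agreement_fixture, qc_failure_fraction,
                       roc_analysis)
from .phantom import generate_phantom, render_sequence
from .score import MorphometryClassifier, score_frame
from .shift import FeatureSet, estimate_kl, extract_features

__all__ = [
    "SEVERITY_RENDER_PARAMS",
    "RunConfig",
    "render_site_sequence",
    "score_synthetic_cohort",
    "run_pipeline",
    "ablation_sweep",
    "replay_printed_results",
    "truncate2",
]


#: Per-severity nuclear morphology driving the renderer: higher grades
#: show denser, larger, brighter nuclei (nuclear crowding and enlargement).
SEVERITY_RENDER_PARAMS = {
    "benign": dict(density=150.0, radius_range=(2.5, 3.5),
                   intensity_range=(0.45, 0.70)),
    "AIN1": dict(density=300.0, radius_range=(3.0, 4.5),
                 intensity_range=(0.55, 0.80)),
    "AIN2+": dict(density=650.0, radius_range=(4.0, 6.5),
                  intensity_range=(0.70, 0.95)),
}


@dataclass
class RunConfig:
    """Resolved parameters for one pipeline run."""

    master_seed: int = 0
    output_dir: str | None = None
    fov_um: float = 198.4          # 160 px at 1.24 um/px; desk-scale field
    probe_speed_mm_s: float = 2.0
    n_frames: int = 5
    degrade_method: int | None = None  # 1..6 or None (no degradation)
    cutoff: float = 0.4
    kl_estimator: str = "gaussian-per-dim"
    ci_level: float = 0.95
    class_counts: dict[str, int] = field(
        default_factory=lambda: {"benign": 11, "AIN1": 71, "AIN2+": 22})
    acquisition: dict = field(default_factory=dict)
    degradation: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.degrade_method is not None and self.degrade_method not in range(1, 7):
            raise ValueError("degrade_method must be 1..6 or None")
        if not 0 <= self.cutoff <= 1:
            raise ValueError("cutoff must be in [0, 1]")

    def acquisition_params(self) -> AcquisitionParams:
        kw = dict(fov_diameter=self.fov_um, gamma_exponent=0.7,
                  noise_sigma=0.01)
        kw.update(self.acquisition)
        return AcquisitionParams(**kw)

    def degradation_config(self) -> deg.DegradationConfig:
        base = deg.DegradationConfig(n_average=self.n_frames,
                                     **self.degradation)
        if self.degrade_method is None:
            return base
        return deg.method_config(self.degrade_method, base)

    @classmethod
    def from_toml(cls, path) -> "RunConfig":
        import tomllib

        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        return cls(**data)


def _site_seed(master_seed: int, index: int) -> int:
    """Deterministic per-site substream seed (documented derivation)."""
    return (master_seed * 100_003 + index) % (2**31 - 1)


def render_site_sequence(record: SiteRecord, params: AcquisitionParams,
                         config: RunConfig, seed: int):
    """Render one site's frame sequence from its severity class."""
    rp = SEVERITY_RENDER_PARAMS[record.severity_class]
    fov = params.fov_diameter
    margin = 2 * config.probe_speed_mm_s * config.n_frames / params.frame_rate * 1000 + 20
    extent = (fov + margin, fov + margin)
    phantom = generate_phantom(
        extent=extent,
        nucleus_density=rp["density"],
        nucleus_radius_range=rp["radius_range"],
        intensity_range=rp["intensity_range"],
        seed=seed,
    )
    traj = TrajectorySpec(speed=config.probe_speed_mm_s, direction=(0.0, 1.0),
                          duration=config.n_frames / params.frame_rate)
    return render_sequence(phantom, traj, params, n_frames=config.n_frames,
                           seed=seed, start_offset_um=(margin / 2, 10.0))


def score_synthetic_cohort(records: list[SiteRecord], config: RunConfig,
                           collect_features: bool = True):
    """Render and score each site; optionally collect quadrant features.

    Returns (scored records, feature sets dict).  When a degradation
    method is configured, both the native and degraded frames are scored
    and embedded so the feature shift between them can be measured; the
    degraded score becomes the site's device score.
    """
    params = config.acquisition_params()
    clf = MorphometryClassifier()
    native_feats, degraded_feats = [], []
    scored: list[SiteRecord] = []
    deg_cfg = config.degradation_config() if config.degrade_method else None

    for i, rec in enumerate(records):
        seed = _site_seed(config.master_seed, i)
        seq = render_site_sequence(rec, params, config, seed)
        frame = seq.selected
        native = score_frame(frame, clf, cutoff=config.cutoff,
                             site_id=rec.site_id)
        score = native.score
        if deg_cfg is not None:
            composite = deg.apply_method(
                seq, dataclasses.replace(
                    deg_cfg, seed=seed,
                    source_gamma=params.gamma_exponent,
                    target_gamma=params.gamma_exponent))
            degraded = score_frame(composite, clf, cutoff=config.cutoff,
                                   site_id=rec.site_id)
            score = degraded.score
            if collect_features:
                degraded_feats.extend(_frame_features(
                    composite, rec.site_id, "degraded", config))
        if collect_features:
            native_feats.extend(_frame_features(
                frame, rec.site_id, "native", config))
        scored.append(dataclasses.replace(rec, device_score=score))

    feature_sets = {}
    if collect_features and native_feats:
        feature_sets["native"] = FeatureSet(native_feats, label="native")
    if collect_features and degraded_feats:
        feature_sets["degraded"] = FeatureSet(degraded_feats, label="degraded")
    return scored, feature_sets


def _frame_features(frame, site_id, label, config):
    from .score import detect_probe_region, resample_to_reference, split_quadrants

    work = resample_to_reference(frame, frame.params.pixel_pitch, 0.78)
    region = detect_probe_region(work)
    quads = split_quadrants(work, region)
    return [
        extract_features(q, source=f"{site_id}/q{j}", dataset_label=label)
        for j, q in enumerate(quads.quadrants)
    ]


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full synthetic study and return the run manifest."""
    cohort = generate_site_cohort(
        CohortSpec(class_counts=dict(config.class_counts)),
        seed=config.master_seed)
    scored, feats = score_synthetic_cohort(cohort, config)

    labels = [r.severity_class == "AIN2+" for r in scored]
    scores = [r.device_score for r in scored]
    table = agreement_table_from_cohort(scored, cutoff=config.cutoff)
    summary = diagnostics_from_table(table, ci_level=config.ci_level)
    roc = roc_analysis(scores, labels) if any(labels) and not all(labels) else None

    manifest: dict = {
        "config": dataclasses.asdict(config),
        "n_sites": len(scored),
        "diagnostics": {
            "device_sensitivity": summary.device_sensitivity,
            "device_specificity": summary.device_specificity,
            "kappa": summary.kappa,
            "agreement_fraction": summary.agreement_fraction,
            "prevalence": summary.prevalence,
        },
        "roc": {"auc": roc.auc, "pr_auc": roc.pr_auc} if roc else None,
        "mean_score_by_class": {
            cls: float(np.mean([r.device_score for r in scored
                                if r.severity_class == cls]))
            for cls in config.class_counts
            if any(r.severity_class == cls for r in scored)
        },
    }
    if "native" in feats and "degraded" in feats:
        est = estimate_kl(feats["degraded"], feats["native"],
                          estimator=config.kl_estimator)
        manifest["feature_shift_kl"] = est.value

    if config.output_dir:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        cohort_to_dataframe(scored).to_csv(out / "scored_cohort.csv",
                                           index=False)
        for label, fs in feats.items():
            fs.to_dataframe().to_csv(out / f"features_{label}.csv",
                                     index=False)
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, default=float)
    return manifest


def ablation_sweep(config: RunConfig, methods=range(1, 7)) -> dict[int, float]:
    """Feature-shift KL for each ablation method on the same cohort.

    Mirrors the shape of a method-ablation table: one average K-L
    divergence per method, measured between degraded and native
    synthetic features.  Values are properties of the synthetic study,
    not of any clinical dataset.
    """
    results = {}
    for m in methods:
        cfg = dataclasses.replace(config, degrade_method=m, output_dir=None)
        cohort = generate_site_cohort(
            CohortSpec(class_counts=dict(cfg.class_counts)),
            seed=cfg.master_seed)
        _, feats = score_synthetic_cohort(cohort, cfg)
        est = estimate_kl(feats["degraded"], feats["native"],
                          estimator=cfg.kl_estimator)
        results[m] = est.value
    return results


def truncate2(x: float) -> float:
    """Truncate toward zero to 2 decimals (how the printed CIs round)."""
    return np.trunc(x * 100) / 100


def replay_printed_results(table: AgreementTable | None = None) -> dict:
    """Recompute every printed-table-derived statistic and check it.

    Fully self-contained: starts from the published 2x2x3 agreement
    counts, the QC accounting (109 imaged / 104 analyzed) and the
    acquisition constants, and verifies each derived statistic against
    its printed value.  Returns a report dict with a ``passed`` flag per
    check and overall.  A substitute ``table`` may be injected to check
    the replay's sensitivity to perturbed counts.
    """
    table = table or printed_agreement_fixture()
    s = diagnostics_from_table(table)
    checks: dict[str, dict] = {}

    def check(name, computed, printed, tol=0.0):
        ok = abs(computed - printed) <= tol
        checks[name] = {"computed": computed, "printed": printed,
                        "passed": bool(ok)}

    check("device_sensitivity", round(s.device_sensitivity, 2), 0.91)
    check("device_specificity", round(s.device_specificity, 2), 0.87)
    check("hra_sensitivity", round(s.hra_sensitivity, 2), 0.91)
    check("agreement_count", s.agreement_count, 68)
    check("n_sites", s.n_sites, 104)
    check("agreement_percent", round(100 * s.agreement_fraction), 65)
    check("kappa", round(s.kappa, 2), 0.34)
    check("prevalence_percent", round(100 * s.prevalence), 21)
    check("discordant_ain1_percent",
          round(100 * s.discordant_ain1_fraction), 78)

    lo, hi = s.device_sensitivity_ci
    check("sensitivity_ci_low", truncate2(lo), 0.72)
    check("sensitivity_ci_high", truncate2(hi), 0.97)
    lo, hi = s.device_specificity_ci
    check("specificity_ci_low", truncate2(lo), 0.77)
    check("specificity_ci_high", truncate2(hi), 0.92)

    # paired McNemar on the discordant counts implied by the table
    c = table.counts
    sens_b, sens_c = int(c[0, 1, 2]), int(c[1, 0, 2])
    spec_b = int(c[0, 1, :2].sum())
    spec_c = int(c[1, 0, :2].sum())
    check("mcnemar_sensitivity_p", mcnemar_exact(sens_b, sens_c), 1.0)
    p_spec = mcnemar_exact(spec_b, spec_c)
    checks["mcnemar_specificity_p"] = {
        "computed": p_spec, "printed": "< 0.0001", "passed": p_spec < 0.0001}

    # degradation-design arithmetic identities
    check("equivalent_frame_rate_fps", 70.0 / 5, 14.0)
    check("composite_exposure_ms", 5 * 1.4, 7.0)
    check("resample_factor", round(1.24 / 0.78, 1), 1.6)
    check("qc_failure_percent", qc_failure_fraction(109, 104), 4.6)

    return {
        "checks": checks,
        "passed": all(v["passed"] for v in checks.values()),
    }
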