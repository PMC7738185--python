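"""End-to-end cohort analysis: simulate -> quantify -> compare -> report.

The pipeline generates (or receives) a two-group cohort, measures every
subject (leaflet morphology, thickness profile with region means, J-curve
mechanics when biaxial records are present, depth-third fiber concentration
summaries), runs each cross-group comparison through the normality-gated
dispatcher, and optionally appends the proteomics DE table.  The subject is
the statistical unit throughout: per-region values are averaged within a
subject before any group test.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from valvescale import assays, biax, microstructure, morphometry, stats, synthetic

__all__ = ["PipelineConfig", "CohortReport", "run_pipeline", "validate_suite"]


@dataclass
class PipelineConfig:
    """Fully serializable pipeline configuration; hashed into the manifest."""

    seed: int = 0
    n_ctl: int = 10
    n_tic: int = 10
    between_subject_sd: float = 0.10
    thickness_ratio: float = 1.0  # TIC over CTL effect factors
    area_ratio: float = 1.0
    kappa_d1_ratio: float = 1.0
    include_biax: bool = False
    include_omics: bool = False
    n_stations: int = 60
    n_fiber_slices: int = 12
    n_fibers_per_slice: int = 1500
    n_section_points: int = 120
    alpha: float = 0.05
    out_dir: str | None = None

    def config_hash(self) -> str:
        payload = yaml.safe_dump(asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class CohortReport:
    comparisons: pd.DataFrame  # measure, group means, chosen test, p
    subject_table: pd.DataFrame  # per-subject measured values
    de_table: pd.DataFrame | None
    manifest: dict = field(default_factory=dict)

    def significant(self, measure: str, alpha: float = 0.05) -> bool:
        row = self.comparisons.loc[self.comparisons.measure == measure]
        return bool((row.p_value < alpha).item())


def _measure_subject(
    sub: synthetic.Subject, config: PipelineConfig
) -> dict[str, float]:
    out: dict[str, float] = {}
    morph = morphometry.leaflet_morphology(sub.outline)
    out.update(morph)
    prof = morphometry.thickness_profile(sub.section, n_stations=config.n_stations)
    out["thickness_pooled_mm"] = prof.pooled_mean_mm
    for name, v in prof.region_means_mm.items():
        out[f"thickness_{name}_mm"] = v
    sub.fiber_profile.fit_all()
    for name, v in microstructure.depth_region_summary(sub.fiber_profile).items():
        out[f"kappa_{name}"] = v
    if sub.record is not None:
        curves = biax.extract_downstroke(sub.record)
        metrics = biax.jcurve_metrics(curves["circ"], curves["rad"], toe_window="auto")
        for d in ("circ", "rad"):
            out[f"toe_stiffness_{d}"] = metrics[d].toe_stiffness
            out[f"calf_stiffness_{d}"] = metrics[d].calf_stiffness
            out[f"transition_stretch_{d}"] = metrics[d].transition_stretch
        out["anisotropy_index"] = metrics["anisotropy_index"]
    return out


def run_pipeline(
    config: PipelineConfig, cohort: synthetic.Cohort | None = None
) -> CohortReport:
    """Execute the cohort analysis; simulate the cohort unless one is given."""
    if cohort is None:
        truth_ctl = synthetic.default_truth(seed=config.seed)
        truth_tic = truth_ctl.scaled(
            thickness=config.thickness_ratio,
            area=config.area_ratio,
            kappa_d1=config.kappa_d1_ratio,
        )
        if config.include_omics:
            truth_tic.de_log2fc = {f"P{i:04d}": 2.0 * (1 if i % 2 else -1) for i in range(10)}
        cohort = synthetic.gen_cohort(
            truth_ctl,
            truth_tic,
            n_ctl=config.n_ctl,
            n_tic=config.n_tic,
            between_subject_sd=config.between_subject_sd,
            n_section_points=config.n_section_points,
            n_fiber_slices=config.n_fiber_slices,
            n_fibers_per_slice=config.n_fibers_per_slice,
            include_biax=config.include_biax,
            include_omics=config.include_omics,
            seed=config.seed,
        )
    rows = []
    for sub in cohort.subjects:
        try:
            vals = _measure_subject(sub, config)
        except Exception as exc:  # isolate per-subject failures
            vals = {"error": str(exc)}
        rows.append({"subject_id": sub.subject_id, "group": sub.group, **vals})
    subject_table = pd.DataFrame(rows).set_index("subject_id")

    comps = []
    measures = [c for c in subject_table.columns if c not in ("group", "error")]
    ctl = subject_table[subject_table.group == "CTL"]
    tic = subject_table[subject_table.group == "TIC"]
    for m in measures:
        a = tic[m].dropna().to_numpy(float)
        b = ctl[m].dropna().to_numpy(float)
        if a.size < 3 or b.size < 3:
            continue
        res = stats.dispatch_compare(a, b, alpha=config.alpha)
        comps.append(
            {
                "measure": m,
                "mean_tic": float(np.mean(a)),
                "mean_ctl": float(np.mean(b)),
                "direction": "up" if np.mean(a) > np.mean(b) else "down",
                "chosen_test": res.chosen_test,
                "p_value": res.p_value,
            }
        )
    comparisons = pd.DataFrame(comps)

    de_table = None
    if cohort.intensity_matrix is not None:
        de_table = assays.de_filter(cohort.intensity_matrix, test_mode="fold_change_only")

    manifest = {
        "config": asdict(config),
        "config_hash": config.config_hash(),
        "n_subjects": len(cohort.subjects),
    }
    report = CohortReport(
        comparisons=comparisons,
        subject_table=subject_table,
        de_table=de_table,
        manifest=manifest,
    )
    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        comparisons.to_csv(out / "comparisons.csv", index=False)
        subject_table.to_csv(out / "subjects.csv")
        if de_table is not None:
            de_table.to_csv(out / "de_table.tsv", sep="\t")
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return report


def validate_suite(seed: int = 0) -> dict[str, bool]:
    """Quick machine-readable pass/fail battery over the module oracles."""
    rng = np.random.default_rng(seed)
    checks: dict[str, bool] = {}

    # deformation gradient vs closed-form least squares on random markers
    ok = True
    for _ in range(100):
        ref = rng.uniform(-2, 2, (4, 2))
        if abs(np.linalg.det((ref - ref.mean(0)).T @ (ref - ref.mean(0)))) < 1e-3:
            continue
        F_true = np.eye(2) + rng.uniform(-0.3, 0.3, (2, 2))
        if np.linalg.det(F_true) <= 0:
            continue
        defm = (ref - ref.mean(0)) @ F_true.T + ref.mean(0) + rng.uniform(1, 2, 2)
        st = biax.estimate_deformation(ref, defm)
        ok &= bool(np.allclose(st.F, F_true, atol=1e-9))
    checks["deformation_oracle"] = ok

    # thickness on a wedge
    truth = synthetic.default_truth(seed)
    sec = synthetic.gen_section_geometry(truth, base="line")
    prof = morphometry.thickness_profile(sec, n_stations=100)
    expect = truth.thickness_profile(np.array([1 / 6, 1 / 2, 5 / 6]))
    got = np.array([prof.region_means_mm[r] for r in ("near_annulus", "belly", "free_edge")])
    checks["thickness_wedge"] = bool(np.all(np.abs(got - expect) / expect < 0.01))

    # von Mises recovery at kappa 3
    prof_f = synthetic.gen_fiber_stack(truth, n_slices=3, n_fibers_per_slice=10_000, rng=rng)
    prof_f.fit_all()
    checks["von_mises_recovery"] = bool(
        np.all(np.abs(prof_f.vm_kappa - prof_f.truth["kappa"]) / prof_f.truth["kappa"] < 0.1)
    )

    # dispatcher type-I calibration (small battery)
    rate = stats.type_error_calibration(n_reps=400, seed=seed)
    checks["dispatcher_calibration"] = bool(0.02 <= rate <= 0.09)
    return checks
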