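"""End-to-end study replica: cohort → phantoms → metrics → fit → regimen.

The pipeline mirrors a list-mode dose-reduction study: a weight-stratified
cohort is dosed at a fixed MBq/kg, each subject's full-time acquisition is
simulated as a count-domain phantom, the counts are binomially thinned to
shorter acquisitions, the liver-VOI SNR is measured per reconstruction and
normalized by √DTP, the per-patient mean SNRnorm is fitted against body
mass with the power model a·m^(−d), and the fit is inverted into a
dose–time-product regimen at the target SNR.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import cohort as cohort_mod
from .cohort import CohortDesign, PatientRecord, default_design
from .fitting import PowerFit, power_fit
from .metrics import region_snr, sphere_voi, suv_metrics
from .phantom import (
    AcquisitionMeta,
    LesionSpec,
    PhantomGeometry,
    counts_to_suv,
    generate_phantom,
    thin_counts,
)
from .regimen import (
    DoseRegimen,
    activity_for_mass,
    crossover_mass,
    dtp_for_mass,
    regimen_table,
)

__all__ = [
    "StudyConfig",
    "StudyResult",
    "simulate_and_measure",
    "fit_study",
    "run_replica",
    "run_study",
]

logger = logging.getLogger("petdose")

#: One abdominal lesion outside the liver, SUVmean ≈ 30.
DEFAULT_LESIONS: tuple[LesionSpec, ...] = (
    LesionSpec(center=(143.0, 203.0, 88.5), diameter=22.0, suv_mean_target=30.0),
)


@dataclass(frozen=True)
class StudyConfig:
    """Every knob of the study replica, with the study's own defaults."""

    seed: int = 0
    strata: tuple[tuple[float, float, int], ...] = cohort_mod.DEFAULT_STRATA
    model: tuple[float, float] = (19.6, 0.95)  # generating (a, d)
    liver_suv: float = 5.8
    dose_rate: float = 1.5  # MBq per kg body mass
    mbp_list: tuple[float, ...] = (1, 2, 3, 4, 5, 6)
    reference_mbp: float = 6.0
    target_snr: float = 6.2
    voi_diameter: float = 30.0  # mm
    lesions: tuple[LesionSpec, ...] = DEFAULT_LESIONS
    geometry: PhantomGeometry = field(default_factory=PhantomGeometry)

    def design(self) -> CohortDesign:
        return CohortDesign(strata=self.strata, seed=self.seed)


@dataclass
class StudyResult:
    cohort: list[PatientRecord]
    metrics: pd.DataFrame
    fit: PowerFit
    regimen: DoseRegimen


def _measure_patient(
    patient: PatientRecord,
    config: StudyConfig,
    rng: np.random.Generator,
) -> list[dict]:
    """Simulate one subject's parent scan, thin to each mbp and measure."""
    meta = AcquisitionMeta(
        activity=config.dose_rate * patient.body_mass, mbp=config.reference_mbp
    )
    parent = generate_phantom(
        patient,
        meta,
        model=config.model,
        liver_suv=config.liver_suv,
        lesions=config.lesions,
        seed=rng,
        geometry=config.geometry,
    )
    liver_center = config.geometry.liver_voi_center
    rows = []
    for mbp in sorted(config.mbp_list):
        fraction = mbp / config.reference_mbp
        scan = thin_counts(parent, fraction, seed=rng)
        suv = counts_to_suv(scan)
        voi = sphere_voi(suv, liver_center, config.voi_diameter)
        snr = region_snr(suv, voi)
        row = {
            "patient_id": patient.id,
            "body_mass_kg": patient.body_mass,
            "mbp_min": float(mbp),
            "activity_mbq": scan.meta.activity,
            "dtp": scan.meta.dtp,
            "liver_suv_mean": snr.suv_mean,
            "liver_sd": snr.sd,
            "snr": snr.snr,
            "snr_norm": snr.snr_norm,
        }
        for lesion in config.lesions[:1]:
            lesion_voi = sphere_voi(
                suv,
                lesion.center,
                max(30.0, 1.5 * lesion.diameter),
                liver_margin_mm=0.0,
            )
            res = suv_metrics(suv, lesion_voi)
            row.update(
                suv_max=res.suv_max,
                suv_peak=res.suv_peak,
                suv_mean_50=res.suv_mean_50,
            )
        rows.append(row)
    return rows


def simulate_and_measure(config: StudyConfig) -> tuple[list[PatientRecord], pd.DataFrame]:
    """Sample the cohort and produce the per-scan metrics table."""
    seeds = np.random.SeedSequence(config.seed)
    cohort_rng = np.random.default_rng(seeds.spawn(1)[0])
    patients = cohort_mod.sample_cohort(config.design(), rng=cohort_rng)
    logger.info("cohort sampled: %d subjects", len(patients))
    rows: list[dict] = []
    for patient, child in zip(patients, seeds.spawn(len(patients))):
        rows.extend(_measure_patient(patient, config, np.random.default_rng(child)))
        logger.debug("measured %s (%.1f kg)", patient.id, patient.body_mass)
    return patients, pd.DataFrame(rows)


def fit_study(metrics: pd.DataFrame, config: StudyConfig) -> tuple[PowerFit, DoseRegimen]:
    """Average SNRnorm per patient, fit the power law, derive the regimen."""
    per_patient = metrics.groupby("patient_id").agg(
        body_mass_kg=("body_mass_kg", "first"),
        mean_snr_norm=("snr_norm", "mean"),
    )
    fit = power_fit(
        per_patient["body_mass_kg"].to_numpy(),
        per_patient["mean_snr_norm"].to_numpy(),
    )
    return fit, DoseRegimen(target_snr=config.target_snr, a=fit.a, d=fit.d)


def run_replica(config: StudyConfig) -> StudyResult:
    """The full in-memory pipeline (no file output)."""
    patients, metrics = simulate_and_measure(config)
    fit, reg = fit_study(metrics, config)
    logger.info(
        "power fit: a=%.3f d=%.3f R²=%.3f; regimen coefficient %.4f",
        fit.a, fit.d, fit.r2, reg.coefficient,
    )
    return StudyResult(cohort=patients, metrics=metrics, fit=fit, regimen=reg)


def _config_hash(config: StudyConfig) -> str:
    payload = json.dumps(asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run_study(config: StudyConfig, out_dir: str | Path) -> StudyResult:
    """Run the replica and write the report bundle to ``out_dir``.

    Outputs: ``cohort.csv``, ``metrics.csv``, ``fit.json``,
    ``regimen.csv``, ``summary.json`` and a run ``manifest.json``.
    Byte-reproducible for a fixed config.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result = run_replica(config)
    cohort_mod.write_cohort_csv(result.cohort, out / "cohort.csv")
    result.metrics.to_csv(out / "metrics.csv", index=False)

    fit = result.fit
    (out / "fit.json").write_text(
        json.dumps(
            {
                "parameter_name": "body_mass",
                "a": fit.a,
                "d": fit.d,
                "r2": fit.r2,
                "d_ci95": list(fit.d_ci95),
                "n": fit.n,
                "residual_sd_pct": fit.residual_sd_pct,
            },
            indent=2,
        )
    )
    reg = result.regimen
    masses = list(range(*cohort_mod.STUDY_MASS_RANGE)) + [cohort_mod.STUDY_MASS_RANGE[1]]
    regimen_table(reg, masses, list(config.mbp_list)).to_csv(
        out / "regimen.csv", index=False
    )
    reference = result.metrics[result.metrics.mbp_min == config.reference_mbp]
    cross_lo = crossover_mass(reg, 100.0, 3.0)
    cross_hi = crossover_mass(reg, 200.0, 3.0)
    summary = {
        "n_patients": len(result.cohort),
        "fit": {"a": fit.a, "d": fit.d, "r2": fit.r2},
        "regimen": {
            "target_snr": reg.target_snr,
            "coefficient": reg.coefficient,
            "exponent2d": reg.exponent2d,
        },
        "mean_liver_suv_reference": float(reference.liver_suv_mean.mean()),
        "activity_range_3mbp": [
            activity_for_mass(reg, cohort_mod.STUDY_MASS_RANGE[0], 3.0),
            activity_for_mass(reg, cohort_mod.STUDY_MASS_RANGE[1], 3.0),
        ],
        "guideline_crossovers_kg": {"100_mbq": cross_lo.mass, "200_mbq": cross_hi.mass},
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=2))
    (out / "manifest.json").write_text(
        json.dumps(
            {
                "config": asdict(config),
                "config_hash": _config_hash(config),
                "outputs": [
                    "cohort.csv",
                    "metrics.csv",
                    "fit.json",
                    "regimen.csv",
                    "summary.json",
                ],
            },
            indent=2,
            default=str,
        )
    )
    logger.info("report bundle written to %s", out)
    return result
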