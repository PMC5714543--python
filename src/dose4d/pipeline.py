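"""End-to-end cohort evaluation: phantom -> plans -> accumulate -> metrics.

For every synthetic patient the pipeline builds the 4D phantom, constructs
the two planning target volumes (tracking PTV = GTV + uniform 5 mm;
fixed-geometry PTV = mid-ventilation GTV + van Herk margin), paints the
per-phase dose for both techniques, accumulates with equal weights onto
the end-exhale reference, and scores static (3D) and accumulated (4D)
metrics.  A comparison report then runs the paired statistics.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field

from .accumulate import accumulate_equal_weight, select_midv_phase
from .grids import BinaryMask, ScalarVolume, StructureSet, expand_mask, shift_mask, volume_cc
from .metrics import (
    DeliveryModel,
    MarginParams,
    MetricsRecord,
    beam_on_time,
    dvh,
    nci,
    normal_tissue_shells,
    ntd2_volume,
    van_herk_margin,
    volume_at_dose,
)
from .phantom import (
    CohortSpec,
    PatientCase,
    Phase4DSet,
    PlanSpec,
    paint_dose_fixed,
    paint_dose_tracking,
    sample_cohort,
)
from .stats import (
    PairedSample,
    motion_vs_difference_correlation,
    summarize,
    wilcoxon_signed_rank,
)

log = logging.getLogger("dose4d")

__all__ = ["RunConfig", "PipelineResult", "evaluate_patient", "run_pipeline", "compare_cohort"]

TRACKING_PTV_MARGIN_MM = 5.0  # uniform GTV-to-PTV safety margin for tracking plans

#: metrics entered into the paired tracking-vs-fixed comparison
PAIRED_METRICS = (
    "nci",
    "gtv_mean_pct",
    "gtv_d99_pct",
    "ptv_v_presc_pct",
    "lung_v20_ntd2_pct",
    "cord_d1_gy",
    "esophagus_d1_gy",
    "trachea_d1_gy",
    "nt_v80_cc",
    "nt_v50_cc",
    "nt_v30_cc",
    "nt_v10_cc",
    "mu_per_gy",
    "beam_on_min",
)


class RunConfig(BaseModel):
    """Serializable description of a full cohort run.

    A run is reproducible from its config alone: the seed drives every
    random choice, and per-patient substreams are keyed by patient index.
    """

    n_patients: int = 14
    seed: int = 0
    margin_sigma_sys_mm: float = 2.0
    margin_sigma_rand_mm: float = 2.0
    margin_sigma_penumbra_mm: float = 3.2
    margin_breathing_coeff: float = 0.36
    lung_v20_excludes: str = Field(default="PTV", pattern="^(PTV|GTV|none)$")

    def cohort_spec(self) -> CohortSpec:
        return CohortSpec(n_patients=self.n_patients, seed=self.seed)

    def margin_params(self) -> MarginParams:
        s = self.margin_sigma_sys_mm
        r = self.margin_sigma_rand_mm
        return MarginParams(
            sigma_sys_mm=(s, s, s),
            sigma_rand_mm=(r, r, r),
            sigma_penumbra_mm=self.margin_sigma_penumbra_mm,
            breathing_coeff=self.margin_breathing_coeff,
        )

    def config_hash(self) -> str:
        payload = json.dumps(self.model_dump(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.model_validate(yaml.safe_load(Path(path).read_text()) or {})

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.model_dump(), sort_keys=True))


def _score_plan(
    dose: ScalarVolume,
    structures: StructureSet,
    plan: PlanSpec,
    gtv: BinaryMask,
    ptv: BinaryMask,
    lung_v20_excludes: str = "PTV",
) -> Dict[str, float]:
    presc = plan.prescription_gy
    body = structures["BODY"]
    gtv_curve = dvh(dose, gtv, "GTV")
    ptv_curve = dvh(dose, ptv, "PTV")

    lung = structures["LUNGS"].values.copy()
    if lung_v20_excludes == "PTV":
        lung &= ~ptv.values
    elif lung_v20_excludes == "GTV":
        lung &= ~gtv.values
    lung_mask = BinaryMask(structures.geometry, lung)
    lung_curve = dvh(ntd2_volume(dose, plan.fractions), lung_mask, "LUNGS")

    def d1(name: str) -> float:
        mask = structures[name]
        if not mask.values.any():
            return float("nan")
        return dvh(dose, mask, name).dose_at_volume(1.0)

    shells = normal_tissue_shells(dose, body, ptv, presc)
    return {
        "nci": nci(dose, ptv, presc, body=body),
        "gtv_mean_pct": gtv_curve.mean_gy / presc * 100.0,
        "gtv_d99_pct": gtv_curve.dose_at_volume(99.0) / presc * 100.0,
        "ptv_v_presc_pct": volume_at_dose(ptv_curve, presc),
        "lung_v20_ntd2_pct": volume_at_dose(lung_curve, 20.0),
        "cord_d1_gy": d1("CORD"),
        "esophagus_d1_gy": d1("ESOPHAGUS"),
        "trachea_d1_gy": d1("TRACHEA"),
        "nt_v80_cc": shells["V80%"],
        "nt_v50_cc": shells["V50%"],
        "nt_v30_cc": shells["V30%"],
        "nt_v10_cc": shells["V10%"],
    }


def evaluate_patient(
    case: PatientCase,
    margin_params: Optional[MarginParams] = None,
    lung_v20_excludes: str = "PTV",
) -> List[MetricsRecord]:
    """Run the full 4D evaluation for one patient.

    Returns four records: (tracking, fixed) x (3D, 4D).  The 3D evaluation
    of the tracking plan is its reference-phase dose; for the fixed plan it
    is the static mid-ventilation cloud scored against the mid-ventilation
    GTV, as planned.  Both 4D evaluations score the accumulated dose
    against the end-exhale structures.
    """
    margin_params = margin_params or MarginParams()
    from .phantom import make_phase_set  # local import to avoid cycle noise

    phases, structures = make_phase_set(case.phantom, case.trajectory)
    gtv = structures["GTV"]

    ptv_ck = expand_mask(gtv, TRACKING_PTV_MARGIN_MM)
    structures = structures.with_structure("PTV_CK", ptv_ck)

    midv = select_midv_phase(case.trajectory)
    off_midv = case.trajectory.offsets_mm[midv]
    margins = van_herk_margin(margin_params, case.trajectory.amplitudes_mm)
    gtv_midv = shift_mask(gtv, off_midv)
    ptv_vmat = expand_mask(gtv_midv, margins)
    structures = structures.with_structure("PTV_VMAT", ptv_vmat)

    log.info(
        "patient %d: MidV phase %d, van Herk margin LR/AP/SI = %s mm, "
        "isodose tracking %.1f%% fixed %.1f%%",
        case.patient_id, midv, np.round(margins, 2).tolist(),
        case.plans["tracking"].isodose_pct, case.plans["fixed"].isodose_pct,
    )

    doses_track = paint_dose_tracking(phases, structures, case.plans["tracking"])
    doses_fixed = paint_dose_fixed(phases, structures, case.plans["fixed"], midv)
    acc_track = accumulate_equal_weight(doses_track, phases.fields, technique="4DCK-like")
    acc_fixed = accumulate_equal_weight(doses_fixed, phases.fields, technique="4DVMAT-like")

    meta = {
        "patient_id": case.patient_id,
        "gtv_cc": volume_cc(gtv),
        "motion_3d_mm": case.trajectory.motion_3d_mm,
        "si_amplitude_mm": case.trajectory.amplitudes_mm[2],
        "posterior": case.phantom.posterior,
    }
    records: List[MetricsRecord] = []
    for technique, plan, ptv, evals in (
        ("tracking", case.plans["tracking"], ptv_ck,
         (("3D", doses_track[0], gtv), ("4D", acc_track.volume, gtv))),
        ("fixed", case.plans["fixed"], ptv_vmat,
         (("3D", doses_fixed[midv], gtv_midv), ("4D", acc_fixed.volume, gtv))),
    ):
        model = DeliveryModel(
            mu_per_gy=plan.mu_per_gy,
            dose_rate_mu_per_min=plan.dose_rate_mu_per_min,
            prescription_gy=plan.prescription_gy,
            fractions=plan.fractions,
        )
        for evaluation, dose, gtv_eval in evals:
            scores = _score_plan(dose, structures, plan, gtv_eval, ptv, lung_v20_excludes)
            records.append(
                MetricsRecord(
                    technique=technique,
                    evaluation=evaluation,
                    prescription_gy=plan.prescription_gy,
                    fractions=plan.fractions,
                    mu_per_gy=plan.mu_per_gy,
                    beam_on_min=beam_on_time(model),
                    ptv_cc=volume_cc(ptv),
                    **meta,
                    **scores,
                )
            )
    return records


@dataclass
class PipelineResult:
    records: pd.DataFrame
    comparison: Dict[str, object]
    config: RunConfig


def compare_cohort(records: pd.DataFrame) -> Dict[str, object]:
    """Paired statistics over a cohort metrics table.

    Runs the two-sided exact Wilcoxon signed-rank test tracking-4D vs
    fixed-4D on every paired metric, the fixed 3D-vs-4D coverage/conformity
    contrast, and the Spearman correlation between 3D motion and the
    per-patient (tracking - fixed) normal-tissue shell differences.
    """
    t4 = records.query("technique == 'tracking' and evaluation == '4D'").set_index("patient_id")
    f4 = records.query("technique == 'fixed' and evaluation == '4D'").set_index("patient_id")
    f3 = records.query("technique == 'fixed' and evaluation == '3D'").set_index("patient_id")
    ids = sorted(set(t4.index) & set(f4.index))

    wilcoxon = {}
    for metric in PAIRED_METRICS:
        res = wilcoxon_signed_rank(
            PairedSample(metric, t4.loc[ids, metric].values, f4.loc[ids, metric].values, ids)
        )
        wilcoxon[metric] = {
            "W": res.statistic, "p": res.p_value, "n": res.n, "method": res.method,
        }

    fixed_3d_vs_4d = {}
    for metric in ("nci", "ptv_v_presc_pct"):
        res = wilcoxon_signed_rank(
            PairedSample(metric, f3.loc[ids, metric].values, f4.loc[ids, metric].values, ids)
        )
        fixed_3d_vs_4d[metric] = {
            "W": res.statistic, "p": res.p_value, "n": res.n, "method": res.method,
            "mean_3d": float(f3.loc[ids, metric].mean()),
            "mean_4d": float(f4.loc[ids, metric].mean()),
        }

    motion = t4.loc[ids, "motion_3d_mm"].values
    shell_diffs = {
        shell: (t4.loc[ids, col].values - f4.loc[ids, col].values)
        for shell, col in (
            ("V80%", "nt_v80_cc"), ("V50%", "nt_v50_cc"),
            ("V30%", "nt_v30_cc"), ("V10%", "nt_v10_cc"),
        )
    }
    try:
        corr = motion_vs_difference_correlation(motion, shell_diffs)
        spearman_out = {
            k: {"rho": r.statistic, "p": r.p_value, "n": r.n} for k, r in corr.items()
        }
    except ValueError as exc:  # constant differences (e.g. identical plans)
        spearman_out = {"error": str(exc)}

    summaries = {}
    groups = [
        f"{int(d)}Gy/{int(f)}fx"
        for d, f in zip(t4.loc[ids, "prescription_gy"], t4.loc[ids, "fractions"])
    ]
    for metric in ("nci", "ptv_v_presc_pct", "gtv_mean_pct", "mu_per_gy", "beam_on_min"):
        for label, frame in (("tracking_4d", t4), ("fixed_4d", f4)):
            for g, s in summarize(frame.loc[ids, metric].values, groups, metric).items():
                summaries[f"{metric}.{label}.{g}"] = {
                    "n": s.n, "mean": s.mean, "sd": s.sd, "min": s.minimum, "max": s.maximum,
                }

    return {
        "n_patients": len(ids),
        "wilcoxon_tracking4d_vs_fixed4d": wilcoxon,
        "fixed_3d_vs_4d": fixed_3d_vs_4d,
        "spearman_motion_vs_shell_difference": spearman_out,
        "summaries": summaries,
    }


#: fixed column order of the cohort CSV (report diffs stay meaningful)
_COLUMNS = [
    "patient_id", "technique", "evaluation", "prescription_gy", "fractions",
    "gtv_cc", "ptv_cc", "motion_3d_mm", "si_amplitude_mm", "posterior",
    "nci", "gtv_mean_pct", "gtv_d99_pct", "ptv_v_presc_pct", "lung_v20_ntd2_pct",
    "cord_d1_gy", "esophagus_d1_gy", "trachea_d1_gy",
    "nt_v80_cc", "nt_v50_cc", "nt_v30_cc", "nt_v10_cc",
    "mu_per_gy", "beam_on_min",
]


def run_pipeline(
    config: RunConfig, out_dir: Optional[str | Path] = None
) -> PipelineResult:
    """Evaluate the whole synthetic cohort and run the paired comparison.

    A failing patient is logged and skipped; the comparison runs on the
    survivors.  With ``out_dir`` the cohort table (CSV, fixed column order,
    '%.6g' floats), the comparison report (JSON, embedding the config
    hash) and the config (YAML) are written.
    """
    cases = sample_cohort(config.cohort_spec())
    margin_params = config.margin_params()
    rows = []
    failures = []
    for case in cases:
        try:
            for rec in evaluate_patient(case, margin_params, config.lung_v20_excludes):
                rows.append(rec.as_dict())
        except Exception as exc:  # noqa: BLE001 - per-patient isolation
            log.error("patient %d failed: %s", case.patient_id, exc)
            failures.append({"patient_id": case.patient_id, "error": str(exc)})
    if not rows:
        raise RuntimeError("every patient failed; nothing to compare")
    records = pd.DataFrame(rows)[_COLUMNS]
    comparison = compare_cohort(records)
    comparison["config_hash"] = config.config_hash()
    comparison["failures"] = failures

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        records.to_csv(out / "cohort.csv", index=False, float_format="%.6g")
        (out / "comparison.json").write_text(json.dumps(comparison, indent=2, sort_keys=True))
        config.to_yaml(out / "config.yaml")
    return PipelineResult(records=records, comparison=comparison, config=config)
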