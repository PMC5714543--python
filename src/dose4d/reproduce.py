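"""Recompute the reference-cohort summary numbers from the packaged tables.

Everything here is arithmetic over the transcribed per-patient tables
(tumor characteristics and delivery efficiency): fractionation-group means
and ranges of MU efficiency and beam-on time, the mean PTV size difference
between the two techniques, the central-lesion OAR dose reductions, and
the beam-on-time relation itself.
"""

from __future__ import annotations

from typing import Dict

import numpy as np
import pandas as pd

from .metrics import DeliveryModel, beam_on_time
from .stats import (
    PairedSample,
    load_patient10_oar_d1,
    load_table1,
    load_table4,
    summarize,
    wilcoxon_signed_rank,
)

__all__ = ["reproduce_tables"]


def reproduce_tables() -> Dict[str, float]:
    """Summary statistics of the packaged reference tables.

    Returns a flat name -> value mapping; percentages are on the 0-100
    scale, MU and beam-on values in their table units (MU/Gy/fraction,
    minutes), volumes in cc.
    """
    t1 = load_table1()
    t4 = load_table4()
    out: Dict[str, float] = {}

    groups = np.where(t4["prescription_gy"] == 60, "60Gy", "48Gy")
    for col, name in (
        ("ck_mu_per_gy", "ck_mu_per_gy"),
        ("vmat_mu_per_gy", "vmat_mu_per_gy"),
        ("ck_beam_on_min", "ck_beam_on_min"),
        ("vmat_beam_on_min", "vmat_beam_on_min"),
    ):
        for g, s in summarize(t4[col].values, groups, name).items():
            out[f"{name}_mean_{g.lower()}"] = s.mean
            if g == "60Gy":
                out[f"{name}_sd_{g.lower()}"] = s.sd

    sixty = t4[t4["prescription_gy"] == 60]
    out["ck_mu_per_gy_min_60gy"] = float(sixty["ck_mu_per_gy"].min())
    out["ck_mu_per_gy_max_60gy"] = float(sixty["ck_mu_per_gy"].max())
    out["vmat_mu_per_gy_min_60gy"] = float(sixty["vmat_mu_per_gy"].min())
    out["vmat_mu_per_gy_max_60gy"] = float(sixty["vmat_mu_per_gy"].max())

    out["ptv_vmat_minus_ck_mean_cc"] = float(
        (t1["ptv_vmat_cc"] - t1["ptv_ck_cc"]).mean()
    )

    p10 = load_patient10_oar_d1().set_index("organ")
    for organ in ("cord", "esophagus"):
        ck = p10.loc[organ, "ck_d1_gy"]
        vmat = p10.loc[organ, "vmat_d1_gy"]
        out[f"patient10_{organ}_d1_reduction_pct"] = float((vmat - ck) / ck * 100.0)

    # the delivery model reproduces the per-patient printed times
    for pid, rate in ((1, 600.0), (12, 600.0)):
        row = t4.set_index("patient")
        model = DeliveryModel(
            mu_per_gy=float(row.loc[pid, "ck_mu_per_gy"]),
            dose_rate_mu_per_min=rate,
            prescription_gy=float(row.loc[pid, "prescription_gy"]),
            fractions=int(row.loc[pid, "fractions"]),
        )
        out[f"ck_beam_on_model_patient{pid}_min"] = beam_on_time(model)

    res = wilcoxon_signed_rank(
        PairedSample("mu_per_gy", t4["ck_mu_per_gy"].values, t4["vmat_mu_per_gy"].values)
    )
    out["mu_ck_vs_vmat_wilcoxon_p"] = res.p_value
    return out
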