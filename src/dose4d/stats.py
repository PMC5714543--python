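"""Paired cohort statistics: exact Wilcoxon signed-rank, Spearman, summaries.

The signed-rank test is exact (full sign-assignment null distribution) up
to n = 20 pairs — the study cohorts of interest are n <= 14, where
borderline p-values around 0.05 make exactness material — and falls back
to the tie- and continuity-corrected normal approximation above that.
The exact distribution is computed by a dynamic program over doubled
signed ranks (average-rank ties yield half-integer ranks), which is
equivalent to enumerating all 2^n sign patterns.

Also packaged here: the reference cohort tables (tumor characteristics
and delivery efficiency) used as inputs by the reproduction entry points.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from itertools import permutations
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "PairedSample",
    "TestResult",
    "CohortSummary",
    "wilcoxon_signed_rank",
    "spearman",
    "summarize",
    "motion_vs_difference_correlation",
    "load_table1",
    "load_table4",
    "load_patient10_oar_d1",
]

EXACT_N_MAX = 20


@dataclass
class PairedSample:
    """Matched measurements of one metric under two conditions."""

    metric: str
    a: np.ndarray
    b: np.ndarray
    patient_ids: Optional[Sequence[int]] = None

    def __post_init__(self) -> None:
        self.a = np.asarray(self.a, dtype=float)
        self.b = np.asarray(self.b, dtype=float)
        if self.a.shape != self.b.shape or self.a.ndim != 1 or self.a.size < 1:
            raise ValueError("paired sample requires equal-length 1D arrays, n >= 1")


@dataclass
class TestResult:
    statistic: float
    p_value: float
    n: int
    method: str

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")


@dataclass
class CohortSummary:
    metric: str
    group: str
    n: int
    mean: float
    sd: float
    minimum: float
    maximum: float
    degenerate: bool = False  # single-value group: SD reported as 0


def _exact_signed_rank_p(ranks: np.ndarray, w_plus: float) -> float:
    """Two-sided exact p for W+ given the |difference| ranks.

    Dynamic program over doubled ranks (integers even with average-rank
    ties): f(w) = number of sign assignments with doubled W+ equal to w.
    Equivalent to, and cross-checked in tests against, brute-force
    enumeration of all 2^n sign patterns.
    """
    r2 = np.rint(2.0 * ranks).astype(int)
    total = int(r2.sum())
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in r2:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: total + 1 - r]
        counts = counts + shifted
    counts /= counts.sum()
    w2 = int(np.rint(2.0 * w_plus))
    p_le = counts[: w2 + 1].sum()
    p_ge = counts[w2:].sum()
    return float(min(1.0, 2.0 * min(p_le, p_ge)))


def wilcoxon_signed_rank(
    sample: PairedSample, zero_method: str = "wilcox"
) -> TestResult:
    """Two-sided Wilcoxon matched-pairs signed-rank test.

    Exact null distribution for n <= 20 after zero handling; normal
    approximation with tie and continuity corrections beyond.  Zero
    differences are dropped (``wilcox``, default; the count is reported in
    the method note) or kept with Pratt's rank adjustment (``pratt``).
    All differences zero returns p = 1.0 with n = 0.
    """
    if zero_method not in ("wilcox", "pratt"):
        raise ValueError(f"unknown zero_method {zero_method!r}")
    d = sample.a - sample.b
    n_zero = int((d == 0).sum())
    if zero_method == "wilcox":
        d_used = d[d != 0]
        if d_used.size == 0:
            return TestResult(0.0, 1.0, 0, f"degenerate; all {n_zero} differences zero")
        ranks = sps.rankdata(np.abs(d_used))
    else:
        if np.all(d == 0):
            return TestResult(0.0, 1.0, 0, f"degenerate; all {n_zero} differences zero")
        ranks_all = sps.rankdata(np.abs(d))
        d_used = d[d != 0]
        ranks = ranks_all[d != 0]
    n = d_used.size
    w_plus = float(ranks[d_used > 0].sum())

    if n <= EXACT_N_MAX:
        p = _exact_signed_rank_p(ranks, w_plus)
        method = f"exact; {n_zero} zero differences dropped"
        if zero_method == "pratt":
            method = f"exact (pratt); {n_zero} zeros ranked"
    else:
        mean = ranks.sum() / 2.0
        # variance with tie correction on the (possibly pratt-adjusted) ranks
        var = (ranks**2).sum() / 4.0
        z = (abs(w_plus - mean) - 0.5) / np.sqrt(var)
        p = float(min(1.0, 2.0 * sps.norm.sf(z)))
        method = f"normal approximation; {n_zero} zeros ({zero_method})"
    return TestResult(w_plus, p, n, method)


def spearman(
    x: Sequence[float], y: Sequence[float], exact_permutation: bool = False
) -> TestResult:
    """Spearman rank correlation with two-sided p.

    rho uses the average-rank ties convention; p comes from the
    t-approximation with n - 2 degrees of freedom.  For n <= 8 an exact
    permutation p is available via ``exact_permutation``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise ValueError("need equal-length 1D samples with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("Spearman rho undefined for a constant sample")
    n = x.size
    rho, p = sps.spearmanr(x, y)
    method = "t-approximation, n-2 df"
    if exact_permutation:
        if n > 8:
            raise ValueError("exact permutation p supported for n <= 8 only")
        rx = sps.rankdata(x)
        ry = sps.rankdata(y)
        obs = abs(np.corrcoef(rx, ry)[0, 1])
        hits = 0
        count = 0
        for perm in permutations(ry):
            count += 1
            if abs(np.corrcoef(rx, np.asarray(perm))[0, 1]) >= obs - 1e-12:
                hits += 1
        p = hits / count
        method = "exact permutation"
    return TestResult(float(rho), float(p), n, method)


def summarize(
    values: Sequence[float],
    groups: Optional[Sequence[str]] = None,
    metric: str = "",
) -> Dict[str, CohortSummary]:
    """Per-group mean, sample SD (n-1), min and max.

    Rounding happens only at the presentation layer; a single-value group
    has an undefined sample SD, reported as 0 with the ``degenerate`` flag.
    Empty groups are skipped.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("no values to summarize")
    if groups is None:
        groups = ["all"] * values.size
    groups = np.asarray(groups)
    out: Dict[str, CohortSummary] = {}
    for g in dict.fromkeys(groups.tolist()):  # preserve first-seen order
        v = values[groups == g]
        if v.size == 0:
            continue
        degenerate = v.size == 1
        out[g] = CohortSummary(
            metric=metric,
            group=str(g),
            n=int(v.size),
            mean=float(v.mean()),
            sd=0.0 if degenerate else float(v.std(ddof=1)),
            minimum=float(v.min()),
            maximum=float(v.max()),
            degenerate=degenerate,
        )
    return out


def motion_vs_difference_correlation(
    motion_3d_mm: Sequence[float],
    shell_differences: Dict[str, Sequence[float]],
) -> Dict[str, TestResult]:
    """Spearman rho between 3D motion and per-shell dose-volume differences.

    ``shell_differences`` maps a shell label (e.g. ``V50%``) to the
    per-patient (tracking - fixed) normal-tissue volume difference.
    """
    motion = np.asarray(motion_3d_mm, dtype=float)
    if motion.size < 3:
        raise ValueError("need at least 3 patients")
    return {name: spearman(motion, diffs) for name, diffs in shell_differences.items()}


def _load_csv(name: str) -> pd.DataFrame:
    with resources.files("dose4d.data").joinpath(name).open("r") as fh:
        return pd.read_csv(fh)


def load_table1() -> pd.DataFrame:
    """Reference cohort tumor characteristics (volumes, motion, schedule)."""
    return _load_csv("table1_tumors.csv")


def load_table4() -> pd.DataFrame:
    """Reference per-patient delivery efficiency (MU/Gy and beam-on time)."""
    return _load_csv("table4_delivery.csv")


def load_patient10_oar_d1() -> pd.DataFrame:
    """Reported near-maximum OAR doses of the central-lesion reference case."""
    return _load_csv("patient10_oar_d1.csv")
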