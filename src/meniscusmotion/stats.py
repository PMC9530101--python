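"""Cohort aggregation and paired nonparametric testing.

Per-subject segment motions (tidy rows: subject, laterality, condition,
meniscus, segment, avg_mm, ml_mm, ap_mm) are aggregated into mean +/- SD
summary tables, and differences between rotation conditions and between
menisci are tested with the Wilcoxon signed-rank test (two-sided,
classic treatment: zero differences discarded, mid-ranks for ties, exact
null distribution for small samples).  No multiplicity adjustment is
applied; the grid of tests is exploratory.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import InsufficientDataError, PairingError, UndefinedTestError

__all__ = [
    "TestResult",
    "MEASURES",
    "SEGMENTS",
    "summarize",
    "wilcoxon_signed_rank",
    "compare_conditions",
]

MEASURES = ("avg", "ml", "ap")
SEGMENTS = ("whole", "AH", "IH", "PH")


@dataclass
class TestResult:
    """One paired comparison: W+ statistic, two-sided p, effective n."""

    label: str
    statistic: float
    p_value: float
    n_effective: int
    method: Literal["exact", "normal_approx"]

    def __post_init__(self):
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value out of range: {self.p_value}")


def summarize(records: pd.DataFrame) -> pd.DataFrame:
    """Mean and sample SD per (condition, meniscus, segment, measure).

    ``records`` is the tidy per-subject table; the sample SD uses the
    n - 1 denominator.  At least two subjects are required.
    """
    df = _as_frame(records)
    if df["subject"].nunique() < 2:
        raise InsufficientDataError("summary needs at least 2 subjects")
    long = df.melt(
        id_vars=["subject", "condition", "meniscus", "segment"],
        value_vars=[f"{m}_mm" for m in MEASURES],
        var_name="measure",
        value_name="value",
    )
    long["measure"] = long["measure"].str.replace("_mm", "", regex=False)
    out = (
        long.groupby(["condition", "meniscus", "segment", "measure"], sort=True)["value"]
        .agg(mean="mean", sd=lambda v: v.std(ddof=1), n="count")
        .reset_index()
    )
    out["sd"] = out["sd"].fillna(0.0)
    return out


def _as_frame(records) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        return records.copy()
    return pd.DataFrame(list(records))


def _exact_sf_cdf(ranks: np.ndarray, w_plus: float):
    """P(W+ <= w) and P(W+ >= w) under the exact signed-rank null.

    Mid-ranks may be half-integers; doubling makes every rank integral,
    so the null distribution of 2*W+ is computed by dynamic programming
    over the 2^n equiprobable sign assignments.
    """
    r2 = np.rint(2.0 * ranks).astype(np.int64)
    total = int(r2.sum())
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in r2:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: total + 1 - r]
        counts = counts + shifted
    counts /= counts.sum()
    w2 = int(np.rint(2.0 * w_plus))
    cdf = float(counts[: w2 + 1].sum())
    sf = float(counts[w2:].sum())
    return cdf, sf


def wilcoxon_signed_rank(
    a: Iterable[float],
    b: Iterable[float],
    mode: Literal["auto", "exact", "normal_approx"] = "auto",
    label: str = "",
) -> TestResult:
    """Two-sided Wilcoxon signed-rank test for paired samples.

    Zero differences are discarded and tied absolute differences receive
    mid-ranks.  ``auto`` uses the exact null for n_effective <= 25 when
    there are no ties, otherwise a normal approximation with continuity
    and tie correction.
    """
    a = np.asarray(list(a), dtype=float)
    b = np.asarray(list(b), dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError(f"paired samples must be equal-length 1D, got {a.shape}/{b.shape}")
    if a.size < 1:
        raise ValueError("empty samples")
    d = a - b
    d = d[d != 0.0]
    n = d.size
    if n == 0:
        raise UndefinedTestError("all paired differences are zero")
    ranks = sps.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    has_ties = np.unique(np.abs(d)).size < n

    if mode == "auto":
        method = "exact" if (n <= 25 and not has_ties) else "normal_approx"
    elif mode in ("exact", "normal_approx"):
        method = mode
    else:
        raise ValueError(f"unknown mode {mode!r}")

    if method == "exact":
        cdf, sf = _exact_sf_cdf(ranks, w_plus)
        p = min(1.0, 2.0 * min(cdf, sf))
    else:
        mu = n * (n + 1) / 4.0
        var = n * (n + 1) * (2 * n + 1) / 24.0
        _, tie_counts = np.unique(ranks, return_counts=True)
        var -= float(np.sum(tie_counts ** 3 - tie_counts)) / 48.0
        if var <= 0:
            raise UndefinedTestError("zero variance (all differences tied at one rank)")
        dev = w_plus - mu
        z = (dev - 0.5 * np.sign(dev)) / np.sqrt(var)
        p = float(2.0 * sps.norm.sf(abs(z)))
        p = min(1.0, p)
    return TestResult(label=label, statistic=w_plus, p_value=p,
                      n_effective=n, method=method)


def _paired_values(df: pd.DataFrame, key_a: dict, key_b: dict, value_col: str):
    """Aligned per-subject value pairs for two strata; errors on missing pairs."""
    qa = df
    for k, v in key_a.items():
        qa = qa[qa[k] == v]
    qb = df
    for k, v in key_b.items():
        qb = qb[qb[k] == v]
    sa = qa.set_index("subject")[value_col]
    sb = qb.set_index("subject")[value_col]
    if sa.index.duplicated().any() or sb.index.duplicated().any():
        raise PairingError("duplicate subject rows in a stratum")
    missing = sorted(set(sa.index) ^ set(sb.index))
    if missing:
        raise PairingError(f"incomplete pairs for subjects: {missing}")
    subjects = sorted(sa.index)
    return sa.loc[subjects].to_numpy(), sb.loc[subjects].to_numpy()


def compare_conditions(records) -> pd.DataFrame:
    """The full grid of paired comparisons.

    Family ``internal_vs_external``: per meniscus x segment x measure,
    paired over subjects across rotation conditions.  Family
    ``MM_vs_LM``: per condition x segment x measure, paired over
    subjects across menisci.  Returns a tidy DataFrame with the W+
    statistic, two-sided p-value, effective n and method per cell.
    """
    df = _as_frame(records)
    if df["subject"].nunique() < 2:
        raise InsufficientDataError("paired testing needs at least 2 subjects")
    conditions = sorted(df["condition"].unique())
    if len(conditions) != 2:
        raise PairingError(f"need exactly 2 conditions, found {conditions}")
    ca, cb = "internal", "external"
    if set(conditions) != {ca, cb}:
        ca, cb = conditions

    rows = []
    for meniscus in ("MM", "LM"):
        for segment in SEGMENTS:
            for measure in MEASURES:
                col = f"{measure}_mm"
                a, b = _paired_values(
                    df,
                    {"condition": ca, "meniscus": meniscus, "segment": segment},
                    {"condition": cb, "meniscus": meniscus, "segment": segment},
                    col,
                )
                res = _safe_test(a, b, f"{meniscus} {segment} {measure}: {ca} vs {cb}")
                rows.append(dict(family="internal_vs_external", condition=f"{ca}_vs_{cb}",
                                 meniscus=meniscus, segment=segment, measure=measure,
                                 **_result_cols(res)))
    for condition in (ca, cb):
        for segment in SEGMENTS:
            for measure in MEASURES:
                col = f"{measure}_mm"
                a, b = _paired_values(
                    df,
                    {"condition": condition, "meniscus": "MM", "segment": segment},
                    {"condition": condition, "meniscus": "LM", "segment": segment},
                    col,
                )
                res = _safe_test(a, b, f"MM vs LM {segment} {measure} ({condition})")
                rows.append(dict(family="MM_vs_LM", condition=condition,
                                 meniscus="MM_vs_LM", segment=segment, measure=measure,
                                 **_result_cols(res)))
    return pd.DataFrame(rows)


def _safe_test(a, b, label):
    return wilcoxon_signed_rank(a, b, mode="auto", label=label)


def _result_cols(res: TestResult) -> dict:
    return dict(statistic=res.statistic, p_value=res.p_value,
                n_effective=res.n_effective, method=res.method)
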