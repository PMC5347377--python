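"""Descriptive statistics of a sequencing cohort.

Per-subject SNV counts (total and per chromosome), group means and
standard deviations, five-number boxplot summaries per chromosome, and a
two-sample t-test between group burdens.  The reference use case is a
25-subject whole-genome cohort in which one population carries roughly
twice the total-SNV burden of the other, so the t-test variant must cope
with grossly unequal variances: Welch's test is the default, with the
pooled-variance (Student) variant available for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
import json
import math

import numpy as np
import pandas as pd
from scipy import stats

from .variant_io import CohortManifest, SnvSetCollection


@dataclass
class CountTable:
    """Per-subject SNV counts joined with manifest labels.

    ``table`` columns: id, group, population, sex, age, total, then one
    column per chromosome.  ``total`` always equals the row sum of the
    chromosome columns.
    """

    table: pd.DataFrame
    chromosomes: list[str]


def count_snvs(
    collection: SnvSetCollection, manifest: CohortManifest
) -> CountTable:
    """Exact per-chromosome SNV cardinalities and their totals."""
    chroms = collection.chromosomes()
    rows = []
    for subject in collection.subjects:
        per = collection.sets.get(subject, {})
        counts = {c: len(per.get(c, ())) for c in chroms}
        rows.append({"id": subject, "total": sum(counts.values()), **counts})
    counts_df = pd.DataFrame(rows)
    merged = manifest.table.merge(counts_df, on="id", how="right")
    return CountTable(merged, chroms)


@dataclass
class GroupComparison:
    """Two-sample t-test result between group means."""

    group_a: str
    group_b: str
    n_a: int
    n_b: int
    mean_a: float
    mean_b: float
    sd_a: float
    sd_b: float
    t: float
    df: float
    p_value: float
    log10_p: float
    variant: str  # "welch" or "pooled"

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(asdict(self), indent=indent)


def welch_t_test(
    values_a, values_b, labels: tuple[str, str] = ("A", "B"), pooled: bool = False
) -> GroupComparison:
    """Two-sided two-sample t-test on group means.

    Default is Welch's unequal-variance statistic
    ``t = (m_a - m_b) / sqrt(s_a^2/n_a + s_b^2/n_b)`` with
    Welch-Satterthwaite degrees of freedom; ``pooled=True`` gives the
    classical equal-variance (Student) variant instead.  Both groups need
    at least two finite observations.  ``log10_p`` is reported alongside
    ``p_value`` so that vanishingly small p-values survive underflow.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 observations")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValueError("non-finite values in input")
    na, nb = len(a), len(b)
    ma, mb = a.mean(), b.mean()
    va, vb = a.var(ddof=1), b.var(ddof=1)

    if va == 0.0 and vb == 0.0:
        # degenerate: no within-group variation at all
        t = 0.0 if ma == mb else math.copysign(math.inf, ma - mb)
        p = 1.0 if ma == mb else 0.0
        df = float(na + nb - 2)
        log10_p = 0.0 if ma == mb else -math.inf
        return GroupComparison(
            labels[0], labels[1], na, nb, ma, mb, 0.0, 0.0,
            t, df, p, log10_p, "pooled" if pooled else "welch",
        )

    if pooled:
        sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
        se = math.sqrt(sp2 * (1.0 / na + 1.0 / nb))
        df = float(na + nb - 2)
    else:
        sea2, seb2 = va / na, vb / nb
        se = math.sqrt(sea2 + seb2)
        df = (sea2 + seb2) ** 2 / (
            sea2**2 / (na - 1) + seb2**2 / (nb - 1)
        )
    t = (ma - mb) / se
    p = 2.0 * stats.t.sf(abs(t), df)
    log10_p = (math.log(2.0) + stats.t.logsf(abs(t), df)) / math.log(10.0)
    return GroupComparison(
        labels[0], labels[1], na, nb, float(ma), float(mb),
        float(math.sqrt(va)), float(math.sqrt(vb)),
        float(t), float(df), float(p), float(log10_p),
        "pooled" if pooled else "welch",
    )


@dataclass
class GroupSummary:
    label: str
    n: int
    mean: float
    sd_population: float  # divisor n
    sd_sample: float  # divisor n-1


def group_summary(
    values: pd.Series | np.ndarray,
    groups: pd.Series | np.ndarray,
) -> dict[str, GroupSummary]:
    """Arithmetic mean and both standard deviations per group.

    The population SD (divisor n) is reported first — it is the
    descriptive convention used for the cohort's printed age summaries —
    with the sample SD (divisor n-1) alongside.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    out: dict[str, GroupSummary] = {}
    for label in pd.unique(groups):
        sel = values[groups == label]
        if len(sel) == 0:
            raise ValueError(f"empty group {label!r}")
        out[str(label)] = GroupSummary(
            str(label),
            len(sel),
            float(sel.mean()),
            float(sel.std(ddof=0)),
            float(sel.std(ddof=1)) if len(sel) > 1 else 0.0,
        )
    return out


def tukey_five_number(values) -> dict[str, float]:
    """Min, lower hinge, median, upper hinge, max (Tukey hinges).

    Hinges are medians of the lower and upper halves of the sorted data,
    including the middle observation in both halves when n is odd — the
    classical boxplot convention.
    """
    x = np.sort(np.asarray(values, dtype=float))
    if len(x) == 0:
        raise ValueError("empty input")
    n = len(x)
    half = (n + 1) // 2
    return {
        "min": float(x[0]),
        "q1": float(np.median(x[:half])),
        "median": float(np.median(x)),
        "q3": float(np.median(x[n - half:])),
        "max": float(x[-1]),
    }


def boxplot_stats(table: CountTable, by: str = "group") -> pd.DataFrame:
    """Five-number summaries of per-chromosome SNV counts, one row per
    (chromosome, group-label) cell."""
    rows = []
    for label, sub in table.table.groupby(by, sort=True):
        for chrom in table.chromosomes:
            summary = tukey_five_number(sub[chrom])
            rows.append({by: label, "chrom": chrom, "n": len(sub), **summary})
    return pd.DataFrame(rows)
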