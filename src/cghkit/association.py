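"""Selecting pathology-associated regions via 2x3 contingency tests.

For each minimal common region and each pathology, the ternary calls are
cross-tabulated into a 2x3 table (pathology vs not-pathology rows; gain /
normal / loss columns).  The chi-squared test of independence is used when
its asymptotic requirements hold; otherwise the table is tested exactly by
the Freeman-Halton extension of Fisher's exact test.  The switching rule is
the classical expected-frequency one: the chi-squared approximation is
trusted only when at least 80% of the expected cell frequencies exceed 5.

The Freeman-Halton test enumerates every 2x3 table with the observed
margins; each has multivariate hypergeometric probability

    P(T) = (prod row_i!) (prod col_j!) / (n! prod cell_ij!)

and the p-value is the total probability of tables no more probable than
the observed one.  No installed library offers an r x c exact test, so the
enumeration is implemented here (in log-gamma space, with a 1e-12 tolerance
for floating-point probability ties).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.stats import chi2 as chi2_dist
from statsmodels.stats.multitest import multipletests

from .core import GroupLabels, Segment, SegmentMatrix

__all__ = [
    "ContingencyTable2x3",
    "AssociationResult",
    "DegenerateTableError",
    "contingency_2x3",
    "expected_counts",
    "chi2_test",
    "fisher_rule",
    "fisher_exact_2x3",
    "adjust_pvalues",
    "select_segments",
]

COLUMNS = ("gain", "normal", "loss")


class DegenerateTableError(ValueError):
    """The table does not support the requested test."""


@dataclass(frozen=True)
class ContingencyTable2x3:
    """Counts of ternary calls, pathology row first; columns gain/normal/loss."""

    counts: tuple[tuple[int, int, int], tuple[int, int, int]]

    def __post_init__(self) -> None:
        arr = np.asarray(self.counts)
        if arr.shape != (2, 3):
            raise ValueError("counts must be 2x3")
        if np.any(arr < 0) or not np.issubdtype(arr.dtype, np.integer):
            raise ValueError("counts must be non-negative integers")
        object.__setattr__(
            self, "counts", tuple(tuple(int(c) for c in row) for row in self.counts)
        )

    @property
    def array(self) -> np.ndarray:
        return np.asarray(self.counts, dtype=int)

    @property
    def row_totals(self) -> np.ndarray:
        return self.array.sum(axis=1)

    @property
    def col_totals(self) -> np.ndarray:
        return self.array.sum(axis=0)

    @property
    def total(self) -> int:
        return int(self.array.sum())


def contingency_2x3(
    calls_row: np.ndarray,
    samples: Sequence[str],
    labels: GroupLabels,
    target: str,
) -> ContingencyTable2x3:
    """Cross-tabulate one region's ternary calls for a one-vs-rest pathology.

    ``calls_row`` holds values in {-1, 0, +1} with NaN for missing; missing
    calls are excluded from the counts.
    """
    calls_row = np.asarray(calls_row, dtype=float)
    if len(calls_row) != len(samples):
        raise ValueError("calls_row length must match samples")
    labels.validate_against(samples)
    in_target = np.array([labels[s] == target for s in samples])
    if not in_target.any() or in_target.all():
        raise ValueError(f"target group {target!r} must be a proper subset of samples")
    counts = np.zeros((2, 3), dtype=int)
    for value, col in ((1.0, 0), (0.0, 1), (-1.0, 2)):
        hit = calls_row == value
        counts[0, col] = int(np.sum(hit & in_target))
        counts[1, col] = int(np.sum(hit & ~in_target))
    if counts.sum() == 0:
        raise DegenerateTableError("all calls missing for this region")
    return ContingencyTable2x3(tuple(tuple(row) for row in counts))


def expected_counts(t: ContingencyTable2x3) -> np.ndarray:
    """Independence-model expected frequencies E_rc = row_r * col_c / n."""
    n = t.total
    if n == 0:
        raise DegenerateTableError("empty table")
    return np.outer(t.row_totals, t.col_totals) / n


def chi2_test(t: ContingencyTable2x3) -> tuple[float, int, float]:
    """Pearson chi-squared test of independence on the 2x3 table.

    Columns with a zero margin are dropped (their expected counts are 0)
    and the degrees of freedom reduced to (2-1)(k-1) for the k retained
    columns.  No continuity correction.  Returns (statistic, df, p).
    """
    obs = t.array
    keep = t.col_totals > 0
    obs = obs[:, keep]
    if obs.shape[1] < 2:
        raise DegenerateTableError("fewer than 2 non-empty columns: test undefined")
    if np.any(t.row_totals == 0):
        raise DegenerateTableError("empty row: test undefined")
    n = t.total
    expected = np.outer(t.row_totals, t.col_totals[keep]) / n
    stat = float(np.sum((obs - expected) ** 2 / expected))
    df = obs.shape[1] - 1
    p = float(chi2_dist.sf(stat, df))
    return stat, df, p


def fisher_rule(t: ContingencyTable2x3) -> bool:
    """True if the exact test should replace chi-squared.

    Chi-squared requires that at least 80% of the expected frequencies
    exceed 5; for 6 cells that means at least 5 of them.  Returns True
    (use Fisher) when fewer than 5 of the 6 expected counts are > 5.
    """
    e = expected_counts(t)
    return int(np.sum(e > 5)) < 5


def fisher_exact_2x3(t: ContingencyTable2x3, cap: int = 500) -> float:
    """Freeman-Halton exact p-value for a 2x3 table.

    Enumerates all tables with the observed margins; p is the total
    multivariate-hypergeometric probability of tables whose probability
    does not exceed the observed one (ties included to 1e-12).
    """
    n = t.total
    if n == 0:
        raise DegenerateTableError("empty table")
    if n > cap:
        raise ValueError(
            f"table total {n} exceeds exact-enumeration cap {cap}; use chi2_test"
        )
    r1, r2 = (int(x) for x in t.row_totals)
    c1, c2, c3 = (int(x) for x in t.col_totals)
    lg = math.lgamma
    log_margin = (
        lg(r1 + 1) + lg(r2 + 1) + lg(c1 + 1) + lg(c2 + 1) + lg(c3 + 1) - lg(n + 1)
    )

    def prob(a: int, b: int, c: int) -> float:
        cells = (a, b, c, c1 - a, c2 - b, c3 - c)
        return math.exp(log_margin - sum(lg(x + 1) for x in cells))

    (oa, ob, oc), _ = t.counts
    p_obs = prob(oa, ob, oc)
    eps = 1e-12
    p = 0.0
    for a in range(max(0, r1 - c2 - c3), min(r1, c1) + 1):
        b_lo = max(0, r1 - a - c3)
        b_hi = min(r1 - a, c2)
        for b in range(b_lo, b_hi + 1):
            c = r1 - a - b
            pt = prob(a, b, c)
            if pt <= p_obs + eps:
                p += pt
    return min(p, 1.0)


def adjust_pvalues(pvals: Sequence[float], method: str = "bh") -> list[float]:
    """Multiple-testing adjustment: 'none' (identity) or 'bh' (Benjamini-Hochberg)."""
    pvals = list(pvals)
    if method == "none":
        return pvals
    if method == "bh":
        if not pvals:
            return []
        _, adj, _, _ = multipletests(pvals, method="fdr_bh")
        return [float(p) for p in adj]
    raise ValueError(f"unknown correction {method!r} (expected 'none' or 'bh')")


@dataclass
class AssociationResult:
    """Outcome of one region x pathology association test."""

    region: Segment
    pathology: str
    table: ContingencyTable2x3
    statistic: float | None
    p_value: float
    test_used: str  # 'chi2' | 'fisher' | 'none' (test undefined)
    p_adjusted: float = 1.0
    selected: bool = False
    cnv_masked: bool = False
    cnv_overlaps: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "chrom": self.region.chrom,
            "start": self.region.start,
            "end": self.region.end,
            "pathology": self.pathology,
            "f11": self.table.counts[0][0],
            "f12": self.table.counts[0][1],
            "f13": self.table.counts[0][2],
            "f21": self.table.counts[1][0],
            "f22": self.table.counts[1][1],
            "f23": self.table.counts[1][2],
            "statistic": self.statistic,
            "p_value": self.p_value,
            "test_used": self.test_used,
            "p_adjusted": self.p_adjusted,
            "selected": self.selected,
            "cnv_masked": self.cnv_masked,
        }


def select_segments(
    calls: SegmentMatrix,
    labels: GroupLabels,
    alpha: float = 0.05,
    correction: str = "bh",
    force_test: str = "auto",
    fisher_cap: int = 500,
) -> list[AssociationResult]:
    """Test every region against every pathology (one-vs-rest) and select.

    For each pathology the procedure is applied to all regions: build the
    2x3 table, pick chi-squared or the exact test by the expected-frequency
    rule (or ``force_test``), adjust p-values within the pathology by
    ``correction``, and mark regions with adjusted p <= alpha as selected.
    Regions whose table does not support a test get p = 1 and are never
    selected.
    """
    if not (0 < alpha < 1):
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    if force_test not in ("auto", "chi2", "fisher"):
        raise ValueError(f"unknown force_test {force_test!r}")
    labels.validate_against(calls.samples)
    groups = sorted(set(labels[s] for s in calls.samples))
    if len(groups) < 2:
        raise ValueError("need at least 2 pathology groups among the samples")
    results: list[AssociationResult] = []
    for pathology in groups:
        group_results: list[AssociationResult] = []
        for i, region in enumerate(calls.segments):
            row = np.where(calls.missing[i], np.nan, calls.values[i])
            statistic: float | None = None
            try:
                table = contingency_2x3(row, calls.samples, labels, pathology)
            except DegenerateTableError:
                table = ContingencyTable2x3(((0, 0, 0), (0, 0, 0)))
                group_results.append(
                    AssociationResult(region, pathology, table, None, 1.0, "none")
                )
                continue
            try:
                if force_test == "auto":
                    use_fisher = fisher_rule(table) and table.total <= fisher_cap
                else:
                    use_fisher = force_test == "fisher"
                if use_fisher:
                    p = fisher_exact_2x3(table, cap=fisher_cap)
                    test_used = "fisher"
                else:
                    statistic, _, p = chi2_test(table)
                    test_used = "chi2"
            except DegenerateTableError:
                p, test_used, statistic = 1.0, "none", None
            group_results.append(
                AssociationResult(region, pathology, table, statistic, p, test_used)
            )
        adjusted = adjust_pvalues([r.p_value for r in group_results], correction)
        for res, p_adj in zip(group_results, adjusted):
            res.p_adjusted = float(p_adj)
            res.selected = res.test_used != "none" and res.p_adjusted <= alpha
        results.extend(group_results)
    return results
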