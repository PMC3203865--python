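"""Multinomial cohort statistics and the exact contingency-table test.

Each experimental condition yields counts ``(n_g, n_l, n_n)`` of global,
local, and non-responsive cells out of ``N``.  Treating the classification
as a multinomial draw, the class probabilities are estimated as
``p_k = n_k / N`` with marginal-binomial standard deviations
``sd_k = sqrt(p_k (1 - p_k) / N)``.

Independence between a treatment and the control is tested with Fisher's
exact conditional test, in the Freeman–Halton extension for r x c tables:
all tables sharing the observed margins are enumerated, and the p-value is
the total multivariate-hypergeometric probability of tables whose
probability does not exceed that of the observed table (two-sided
"as-or-less-probable" convention, reducing to the classic two-sided Fisher
test for 2 x 2).  Enumeration is exhaustive — at cohort scale (N of order
hundreds) the table space is small.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import gammaln

__all__ = [
    "ResponseCounts",
    "ProportionEstimate",
    "ContingencyTable",
    "estimate_proportions",
    "fisher_exact",
    "compare_conditions",
    "cohort_report",
    "CohortReport",
]

CLASS_LABELS = ("global", "local", "none")

# relative slack when comparing table probabilities, so the enumeration is
# deterministic across platforms despite floating-point rounding
_PROB_TIE_REL = 1e-12
_LOG_TIE = np.log1p(_PROB_TIE_REL)


class StatsError(ValueError):
    """Raised for invalid counts or degenerate tables."""


@dataclass(frozen=True)
class ResponseCounts:
    """Per-condition counts of global / local / non-responsive cells."""

    n_g: int
    n_l: int
    n_n: int

    def __post_init__(self) -> None:
        for v in (self.n_g, self.n_l, self.n_n):
            if v < 0 or v != int(v):
                raise StatsError("counts must be non-negative integers")
        if self.N < 1:
            raise StatsError("total count N must be >= 1")

    @property
    def N(self) -> int:
        return self.n_g + self.n_l + self.n_n

    def as_row(self) -> list[int]:
        return [self.n_g, self.n_l, self.n_n]

    @classmethod
    def from_classes(cls, classes: list[str]) -> "ResponseCounts":
        return cls(
            n_g=sum(c == "global" for c in classes),
            n_l=sum(c == "local" for c in classes),
            n_n=sum(c == "none" for c in classes),
        )


@dataclass(frozen=True)
class ProportionEstimate:
    """Estimated class probabilities with standard deviations."""

    p_g: float
    p_l: float
    p_n: float
    sd_g: float
    sd_l: float
    sd_n: float

    def __post_init__(self) -> None:
        if abs(self.p_g + self.p_l + self.p_n - 1.0) > 1e-12:
            raise StatsError("probabilities must sum to 1")
        if min(self.sd_g, self.sd_l, self.sd_n) < 0:
            raise StatsError("standard deviations must be non-negative")

    def as_dict(self) -> dict[str, float]:
        return {
            "p_global": self.p_g, "p_local": self.p_l, "p_none": self.p_n,
            "sd_global": self.sd_g, "sd_local": self.sd_l, "sd_none": self.sd_n,
        }


@dataclass
class ContingencyTable:
    """Conditions x response-classes count table for exact testing."""

    counts: np.ndarray
    rows: tuple[str, ...] = ()
    cols: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 2:
            raise StatsError("contingency table must be 2-dimensional")
        if (self.counts < 0).any():
            raise StatsError("contingency table counts must be non-negative")
        if not self.rows:
            self.rows = tuple(f"row{i}" for i in range(self.counts.shape[0]))
        if not self.cols:
            self.cols = tuple(f"col{j}" for j in range(self.counts.shape[1]))


def estimate_proportions(counts: ResponseCounts) -> ProportionEstimate:
    """Multinomial probability estimates ``p_k = n_k / N`` with SDs.

    The standard deviation of each component uses the marginal binomial
    form ``sqrt(p_k (1 - p_k) / N)``.
    """
    N = counts.N
    ps = [counts.n_g / N, counts.n_l / N, counts.n_n / N]
    sds = [float(np.sqrt(p * (1.0 - p) / N)) for p in ps]
    return ProportionEstimate(*ps, *sds)


def _log_table_prob(table: np.ndarray, row_m: np.ndarray, col_m: np.ndarray) -> float:
    N = int(row_m.sum())
    return float(
        gammaln(row_m + 1).sum()
        + gammaln(col_m + 1).sum()
        - gammaln(N + 1)
        - gammaln(np.asarray(table) + 1).sum()
    )


# log-factorial lookup keeps the hot path fast and guarantees identical
# floating-point values for the enumeration and the observed table
_LOG_FACT = gammaln(np.arange(2049, dtype=float) + 1.0)


def _log_fact(n: np.ndarray | int) -> np.ndarray | float:
    try:
        return _LOG_FACT[n]
    except IndexError:
        return gammaln(np.asarray(n, dtype=float) + 1.0)


def _two_row_logp(first_rows: np.ndarray, row_m: np.ndarray, col_m: np.ndarray) -> np.ndarray:
    """Log-probabilities of 2-row tables given by their first rows (n, c).

    Used for both the enumeration and the observed table so the arithmetic
    (and hence floating-point rounding) is identical on both sides of the
    tie comparison.
    """
    second = col_m[None, :] - first_rows
    logp = (
        _log_fact(col_m)[None, :]
        - _log_fact(first_rows)
        - _log_fact(second)
    ).sum(axis=1)
    N = int(row_m.sum())
    r0 = int(row_m[0])
    return logp - (_log_fact(N) - _log_fact(r0) - _log_fact(N - r0))


def _two_row_log_probs(row_m: np.ndarray, col_m: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """All tables with 2 rows and the given margins, plus their log-probabilities.

    Returns ``(first_rows, log_probs)`` where ``first_rows`` is (n_tables, c):
    the second row is determined by the column margins.
    """
    r0 = int(row_m[0])
    c = len(col_m)
    ranges = [np.arange(min(r0, int(m)) + 1) for m in col_m[:-1]]
    if c == 1:
        first = np.array([[r0]])
    else:
        grids = np.meshgrid(*ranges, indexing="ij")
        partial = sum(grids)
        last = r0 - partial
        valid = (last >= 0) & (last <= int(col_m[-1]))
        first = np.stack([g[valid] for g in grids] + [last[valid]], axis=1)
    return first, _two_row_logp(first, row_m, col_m)


@lru_cache(maxsize=1 << 17)
def _two_row_class(row_m: tuple[int, ...], col_m: tuple[int, ...]):
    """Sorted log-probabilities and probability prefix sums for a margin class."""
    _, logp = _two_row_log_probs(np.asarray(row_m), np.asarray(col_m))
    logp_sorted = np.sort(logp)
    return logp_sorted, np.cumsum(np.exp(logp_sorted))


def _enumerate_tables(row_m: np.ndarray, col_m: np.ndarray):
    """Yield every non-negative integer table with the given margins."""
    r = len(row_m)
    if r == 1:
        yield col_m[None, :].copy()
        return

    def compositions(total: int, caps: list[int]):
        if len(caps) == 1:
            if total <= caps[0]:
                yield (total,)
            return
        for v in range(min(total, caps[0]) + 1):
            for rest in compositions(total - v, caps[1:]):
                yield (v, *rest)

    caps = [int(m) for m in col_m]
    for first in compositions(int(row_m[0]), caps):
        rest_cols = col_m - np.asarray(first)
        for sub in _enumerate_tables(row_m[1:], rest_cols):
            yield np.vstack([np.asarray(first)[None, :], sub])


def fisher_exact(table: ContingencyTable | np.ndarray) -> float:
    """Exact conditional p-value for independence in an r x c table.

    Enumerates all tables with the observed margins and sums the
    multivariate-hypergeometric probabilities of those as-or-less-probable
    than the observed table (with ``1e-12`` relative slack on the
    comparison).  All-zero rows or columns are dropped with a warning; a
    margin set admitting a single table gives p = 1.
    """
    if isinstance(table, ContingencyTable):
        counts = table.counts
    else:
        counts = np.asarray(table, dtype=np.int64)
        if counts.ndim != 2:
            raise StatsError("contingency table must be 2-dimensional")
        if (counts < 0).any():
            raise StatsError("contingency table counts must be non-negative")
    row_sums = counts.sum(axis=1)
    col_sums = counts.sum(axis=0)
    if (row_sums == 0).any() or (col_sums == 0).any():
        warnings.warn("dropping all-zero rows/columns from the contingency table",
                      stacklevel=2)
        counts = counts[np.ix_(row_sums > 0, col_sums > 0)]
    if counts.size == 0 or counts.shape[0] < 1 or counts.shape[1] < 1:
        raise StatsError("contingency table has no positive margins")
    if counts.shape[0] == 1 or counts.shape[1] == 1:
        return 1.0  # margins fully determine the table

    if counts.shape[0] != 2 and counts.shape[1] == 2:
        counts = counts.T  # fast path prefers 2 rows

    if counts.shape[0] == 2 and counts.sum() < len(_LOG_FACT):
        rows = counts.tolist()
        first, second = rows
        col_m = tuple(a + b for a, b in zip(first, second))
        r0, r1 = sum(first), sum(second)
        N = r0 + r1
        lf = _LOG_FACT
        logp_obs = 0.0
        for a, c in zip(first, col_m):
            logp_obs += lf[c] - lf[a] - lf[c - a]
        logp_obs -= lf[N] - lf[r0] - lf[N - r0]
        logp_sorted, csum = _two_row_class((r0, r1), col_m)
        idx = int(np.searchsorted(logp_sorted, logp_obs + _LOG_TIE, side="right"))
        return float(min(csum[idx - 1], 1.0)) if idx else 0.0

    row_m = counts.sum(axis=1)
    col_m = counts.sum(axis=0)
    logp_obs = _log_table_prob(counts, row_m, col_m)
    total = 0.0
    for t in _enumerate_tables(row_m, col_m):
        lp = _log_table_prob(t, row_m, col_m)
        if lp <= logp_obs + _LOG_TIE:
            total += float(np.exp(lp))
    return min(total, 1.0)


@dataclass
class ComparisonResult:
    """Exact-test report for one treated condition against the control."""

    p_value: float
    control: ProportionEstimate
    treated: ProportionEstimate
    table: ContingencyTable
    significant: bool

    def as_dict(self) -> dict:
        return {
            "p_value": self.p_value,
            "significant": self.significant,
            "control": self.control.as_dict(),
            "treated": self.treated.as_dict(),
            "table": self.table.counts.tolist(),
        }


def compare_conditions(
    control: ResponseCounts,
    treated: ResponseCounts,
    alpha: float = 0.05,
) -> ComparisonResult:
    """Exact test of independence between control and one treatment.

    Builds the 2 x 3 conditions-by-classes table (classes with zero counts
    in both rows are dropped inside the test) and flags significance at
    ``p < alpha`` (0.05 by default).
    """
    table = ContingencyTable(
        counts=np.array([control.as_row(), treated.as_row()]),
        rows=("control", "treated"),
        cols=CLASS_LABELS,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        p = fisher_exact(table)
    return ComparisonResult(
        p_value=p,
        control=estimate_proportions(control),
        treated=estimate_proportions(treated),
        table=table,
        significant=p < alpha,
    )


@dataclass
class CohortReport:
    """Per-condition proportion estimates and exact tests against control."""

    counts: dict[str, ResponseCounts]
    proportions: dict[str, ProportionEstimate]
    p_values: dict[str, float]
    alpha: float = 0.05

    def to_frame(self) -> pd.DataFrame:
        records = []
        for cond, cnt in self.counts.items():
            est = self.proportions[cond]
            rec = {
                "condition": cond,
                "n_global": cnt.n_g, "n_local": cnt.n_l, "n_none": cnt.n_n,
                "N": cnt.N,
                **est.as_dict(),
            }
            if cond in self.p_values:
                rec["p_value_vs_control"] = self.p_values[cond]
                rec["significant"] = self.p_values[cond] < self.alpha
            records.append(rec)
        return pd.DataFrame(records)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    def plot(self, path: str | Path) -> None:
        """Grouped bar chart of class percentages with SD error bars.

        One group per condition, one bar per response class, significance
        of the exact test vs control marked with an asterisk.
        """
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        conditions = list(self.counts)
        x = np.arange(len(conditions))
        width = 0.25
        fig, ax = plt.subplots(figsize=(1.5 + 1.2 * len(conditions), 4))
        for k, (label, attr) in enumerate(
            [("global", "g"), ("local", "l"), ("none", "n")]
        ):
            vals = [100 * getattr(self.proportions[c], f"p_{attr}") for c in conditions]
            errs = [100 * getattr(self.proportions[c], f"sd_{attr}") for c in conditions]
            ax.bar(x + (k - 1) * width, vals, width, yerr=errs, capsize=3, label=label)
        labels = [
            c + (" *" if self.p_values.get(c, 1.0) < self.alpha else "")
            for c in conditions
        ]
        ax.set_xticks(x, labels)
        ax.set_ylabel("cells (%)")
        ax.legend(title="response")
        fig.tight_layout()
        fig.savefig(path, dpi=150)
        plt.close(fig)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "alpha": self.alpha,
            "conditions": {
                cond: {
                    "counts": cnt.as_row(),
                    "N": cnt.N,
                    **self.proportions[cond].as_dict(),
                    **(
                        {"p_value_vs_control": self.p_values[cond]}
                        if cond in self.p_values else {}
                    ),
                }
                for cond, cnt in self.counts.items()
            },
        }
        Path(path).write_text(json.dumps(payload, indent=2))


def cohort_report(
    records_by_condition: dict[str, list],
    control: str = "control",
    alpha: float = 0.05,
) -> CohortReport:
    """Tally classified cells per condition and test each against control.

    ``records_by_condition`` maps a condition label to a list of class
    strings (or objects with a ``cls`` attribute, e.g.
    :class:`~vibracal.response.ResponseRecord`).  With a single condition no
    tests are run; otherwise a condition named ``control`` must be present.
    """
    if not records_by_condition:
        raise StatsError("no conditions given")
    counts: dict[str, ResponseCounts] = {}
    for cond, records in records_by_condition.items():
        classes = [r if isinstance(r, str) else r.cls for r in records]
        bad = [c for c in classes if c not in CLASS_LABELS]
        if bad:
            raise StatsError(f"unknown response class {bad[0]!r} in condition {cond!r}")
        counts[cond] = ResponseCounts.from_classes(classes)

    proportions = {cond: estimate_proportions(c) for cond, c in counts.items()}
    p_values: dict[str, float] = {}
    if len(counts) > 1:
        if control not in counts:
            raise StatsError(f"no condition named {control!r} to test against")
        for cond in counts:
            if cond == control:
                continue
            p_values[cond] = compare_conditions(
                counts[control], counts[cond], alpha=alpha
            ).p_value
    return CohortReport(
        counts=counts, proportions=proportions, p_values=p_values, alpha=alpha
    )
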