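"""Drug–event 2×2 contingency tables for disproportionality analysis.

A spontaneous-report database is summarised, for one drug–event pair, by
the classic 2×2 table

    =============  ============  ================
                   target event  all other events
    target drug         a               b
    other drugs         c               d
    =============  ============  ================

where the counting unit is the drug–event *pair*: each distinct
(report, preferred term) occurrence contributes one count, so a report
listing three reactions contributes three pairs.  ``a + b`` is the
drug's total pair count and ``n = a + b + c + d`` the whole database's.

Besides building tables from a cleaned report store, this module can
*invert* published statistics: given the printed ROR and EBGM of a pair
together with ``a`` and ``a + b``, it recovers the integer background
cells ``(c, d)`` — useful for reconstructing a table from a published
signal table when the raw database is unavailable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ContingencyTable",
    "build_table",
    "pair_counts",
    "reconstruct_table_from_stats",
    "reconstruct_table_joint",
]


@dataclass(frozen=True)
class ContingencyTable:
    """Counts ``a, b, c, d`` of one drug–event pair against the background."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "d"):
            v = getattr(self, name)
            if v < 0 or int(v) != v:
                raise ValueError(f"cell {name} must be a non-negative integer, got {v!r}")

    @property
    def n(self) -> int:
        """Total number of drug–event pairs in the database."""
        return self.a + self.b + self.c + self.d

    @property
    def expected(self) -> float:
        """Expected value of ``a`` under row/column independence."""
        return (self.a + self.b) * (self.a + self.c) / self.n

    def as_tuple(self) -> tuple[int, int, int, int]:
        return (self.a, self.b, self.c, self.d)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"ContingencyTable(a={self.a}, b={self.b}, c={self.c}, d={self.d})"


def pair_counts(store, level: str = "pt") -> pd.DataFrame:
    """Unique (report, event) pairs of a cleaned store.

    Parameters
    ----------
    store : ReportStore
        Cleaned store (deduplicated, deletions applied).
    level : ``"pt"`` or ``"soc"``
        Event granularity.  At SOC level each (report, PT) occurrence still
        counts once, so a report with two PTs in one SOC contributes two
        pairs — the convention under which per-SOC pair counts sum to the
        database total.

    Returns
    -------
    DataFrame with columns ``caseid`` and ``event`` (one row per pair).
    """
    reac = store.reac
    if level not in ("pt", "soc"):
        raise ValueError(f"level must be 'pt' or 'soc', got {level!r}")
    pt_col = "pt_current" if "pt_current" in reac.columns else "pt"
    pairs = reac[["caseid", pt_col]].rename(columns={pt_col: "pt"})
    # one count per distinct (report, PT)
    pairs = pairs.drop_duplicates()
    if level == "soc":
        soc = reac[["caseid", pt_col, "soc"]].rename(columns={pt_col: "pt"}) \
            if "soc" in reac.columns else pairs.assign(soc="UNMAPPED-SOC")
        pairs = pairs.merge(soc.drop_duplicates(), on=["caseid", "pt"], how="left")
        pairs["event"] = pairs["soc"].fillna("UNMAPPED-SOC")
        pairs = pairs[["caseid", "pt", "event"]]
    else:
        pairs = pairs.assign(event=pairs["pt"])
    return pairs


def build_table(store, drug: str, event: str, level: str = "pt",
                synonyms: tuple[str, ...] = ()) -> ContingencyTable:
    """Build the 2×2 pair-count table for one drug–event combination.

    ``a`` counts pairs (target-drug report, target event); ``a + b`` all
    pairs of target-drug reports; ``a + c`` all pairs with the target
    event; ``n`` every pair in the store.  A drug or event absent from
    the store yields ``a = 0`` rather than an error.
    """
    from .faers_io import match_drug_cases

    target_cases = match_drug_cases(store.drug, drug, synonyms=synonyms)
    pairs = pair_counts(store, level=level)
    is_target_drug = pairs["caseid"].isin(target_cases)
    is_event = pairs["event"].str.casefold() == event.strip().casefold()
    a = int((is_target_drug & is_event).sum())
    b = int((is_target_drug & ~is_event).sum())
    c = int((~is_target_drug & is_event).sum())
    d = int((~is_target_drug & ~is_event).sum())
    return ContingencyTable(a, b, c, d)


def _forward(a: np.ndarray, b: np.ndarray, c: np.ndarray, d: np.ndarray):
    """Vectorised ROR and EBGM from cell arrays (float64)."""
    n = a + b + c + d
    ror = (a * d) / (b * c)
    ebgm = a * n / ((a + c) * (a + b))
    return ror, ebgm


def reconstruct_table_from_stats(a: int, ab_total: int, ror: float, ebgm: float,
                                 search_range: tuple[int, int] | None = None,
                                 ) -> ContingencyTable:
    """Recover integer background cells (c, d) from printed ROR and EBGM.

    For each candidate ``c``, ``d`` is fixed by the ROR relation
    ``d = round(ror * b * c / a)``; the returned table minimises the sum
    of squared relative errors of the recomputed (ROR, EBGM) against the
    inputs.  Deterministic; ties resolve to the smallest ``c``.

    Parameters
    ----------
    a : observed pair count of the target drug–event combination (≥ 1).
    ab_total : the drug's total pair count ``a + b`` (> a).
    ror, ebgm : the published point estimates (> 0).
    search_range : inclusive (low, high) bounds for ``c``; default
        ``(max(1, a), 10**6)``.
    """
    if a < 1:
        raise ValueError("a must be >= 1")
    if ab_total <= a:
        raise ValueError("ab_total must exceed a")
    if ror <= 0 or ebgm <= 0:
        raise ValueError("ror and ebgm must be positive")
    if search_range is None:
        search_range = (max(1, a), 10**6)
    lo, hi = search_range
    if hi < lo:
        raise ValueError(f"empty search range {search_range}")

    b = ab_total - a
    c = np.arange(lo, hi + 1, dtype=np.float64)
    d = np.round(ror * b * c / a)
    ok = d >= 1
    if not ok.any():
        raise ValueError("no candidate table in search range")
    c, d = c[ok], d[ok]
    ror_hat, ebgm_hat = _forward(np.float64(a), np.float64(b), c, d)
    err = ((ror_hat - ror) / ror) ** 2 + ((ebgm_hat - ebgm) / ebgm) ** 2
    best = int(np.argmin(err))  # argmin takes the first (smallest c) on ties
    ties = int((err == err[best]).sum())
    if ties > 1:
        logger.info("reconstruct_table_from_stats: %d tied minimisers, keeping smallest c", ties)
    return ContingencyTable(int(a), int(b), int(c[best]), int(d[best]))


def reconstruct_table_joint(ab_total: int, ror: float, ci_high: float, ebgm: float,
                            a_range: tuple[int, int] = (1, 200),
                            c_range: tuple[int, int] = (1, 20000),
                            ) -> ContingencyTable:
    """Recover (a, c, d) jointly when ``a`` itself is unknown.

    Uses three published anchors: the ROR point estimate, its 95% upper
    bound — which pins the log-scale standard error
    ``se = ln(ci_high / ror) / 1.96 = sqrt(1/a + 1/b + 1/c + 1/d)`` —
    and the EBGM.  Scans the integer grid ``a_range × c_range`` with
    ``d`` fixed by the ROR relation and minimises the summed squared
    relative error of (ROR, se, EBGM).
    """
    se_target = np.log(ci_high / ror) / 1.96
    if se_target <= 0:
        raise ValueError("ci_high must exceed ror")
    a_lo, a_hi = a_range
    c_lo, c_hi = c_range
    best: tuple[float, ContingencyTable] | None = None
    c = np.arange(c_lo, c_hi + 1, dtype=np.float64)
    for a in range(a_lo, a_hi + 1):
        b = ab_total - a
        if b <= 0:
            break
        d = np.round(ror * b * c / a)
        ok = d >= 1
        if not ok.any():
            continue
        cc, dd = c[ok], d[ok]
        ror_hat, ebgm_hat = _forward(np.float64(a), np.float64(b), cc, dd)
        se_hat = np.sqrt(1 / a + 1 / b + 1 / cc + 1 / dd)
        err = (((ror_hat - ror) / ror) ** 2
               + ((ebgm_hat - ebgm) / ebgm) ** 2
               + ((se_hat - se_target) / se_target) ** 2)
        j = int(np.argmin(err))
        if best is None or err[j] < best[0]:
            best = (float(err[j]), ContingencyTable(a, int(b), int(cc[j]), int(dd[j])))
    if best is None:
        raise ValueError("no candidate table in search ranges")
    return best[1]
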