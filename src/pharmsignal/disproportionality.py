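"""Disproportionality statistics for spontaneous-report signal detection.

Four classical measures of a drug–event pair's over-reporting relative to
the database background, each with its conventional signal criterion:

* **ROR** — reporting odds ratio ``ad/(bc)`` with log-normal 95% CI;
  signal when ``a >= 3`` and the lower bound exceeds 1.
* **PRR** — proportional reporting ratio ``(a/(a+b)) / (c/(c+d))`` with a
  chi-square statistic; signal per the Evans rule
  (``a >= 3``, ``PRR >= 2``, ``chi2 >= 4``; configurable).
* **BCPNN / IC** — the information component ``log2`` of observed over
  expected reporting, with Bayesian shrinkage (beta-prior moments) giving
  a credibility bound ``IC - 2SD`` and a four-level strength band.
* **EBGM** — the observed/expected ratio ``a·n / ((a+c)(a+b))`` with a
  log-normal 95% interval; signal when the lower bound EBGM05 exceeds 2.
  (This is the closed-form relative reporting ratio with shrinkage-free
  CI, not a gamma-Poisson mixture fit.)

The chi-square accompanying the PRR is reported in two flavours: the
Yates continuity-corrected statistic (``chi2``) used by the Evans
criterion, and the uncorrected Pearson statistic (``chi2_pearson``),
which is what most pharmacovigilance software prints alongside the PRR.

Zero cells make ROR/PRR/EBGM intervals non-estimable; results then carry
``estimable=False`` and never classify as signals.  The BCPNN shrinkage
keeps IC bounds finite even at ``a = 0``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .contingency import ContingencyTable

__all__ = [
    "RorResult",
    "PrrResult",
    "BcpnnHyperparams",
    "BcpnnResult",
    "EbgmResult",
    "SignalResult",
    "SignalCriteria",
    "ror",
    "prr",
    "bcpnn",
    "ebgm",
    "classify_signal",
    "analyze_table",
]

_Z95 = 1.959963984540054  # scipy.stats.norm.ppf(0.975)
# The published formulas use the rounded 1.96; keep that for comparability.
_Z = 1.96


def _log_se(t: ContingencyTable) -> float:
    return math.sqrt(1 / t.a + 1 / t.b + 1 / t.c + 1 / t.d)


@dataclass(frozen=True)
class RorResult:
    ror: float
    se_ln: float
    ci_low: float
    ci_high: float
    is_signal: bool
    estimable: bool = True


@dataclass(frozen=True)
class PrrResult:
    prr: float
    chi2: float            # Yates continuity-corrected
    chi2_pearson: float    # uncorrected
    ci_low: float
    ci_high: float
    is_signal: bool
    estimable: bool = True


@dataclass(frozen=True)
class BcpnnHyperparams:
    """Beta/"gamma" prior constants of the shrunk information component."""
    alpha1: float = 1.0
    beta1: float = 1.0
    alpha: float = 2.0
    beta: float = 2.0
    gamma11: float = 1.0


@dataclass(frozen=True)
class BcpnnResult:
    ic: float | None       # None when a == 0 (raw IC undefined)
    eic: float
    vic: float
    ic_minus_2sd: float
    strength_band: str
    hyperparams: BcpnnHyperparams = field(default_factory=BcpnnHyperparams)


@dataclass(frozen=True)
class EbgmResult:
    ebgm: float
    ebgm05: float
    ebgm95: float
    is_signal: bool
    estimable: bool = True


@dataclass(frozen=True)
class SignalCriteria:
    """Configurable positive-signal rules (defaults are the classical ones)."""
    ror_min_a: int = 3
    prr_min_a: int = 3
    prr_min: float = 2.0
    prr_min_chi2: float = 4.0
    ic_minus_2sd_min: float = 0.0
    ebgm05_min: float = 2.0


@dataclass(frozen=True)
class SignalResult:
    drug: str
    event: str
    table: ContingencyTable
    ror: RorResult
    prr: PrrResult
    bcpnn: BcpnnResult
    ebgm: EbgmResult
    overall_positive: bool


def ror(t: ContingencyTable) -> RorResult:
    """Reporting odds ratio with log-normal 95% CI.

    Signal rule: ``a >= 3`` and CI lower bound > 1.  Any zero cell makes
    the estimate non-estimable (NaN statistics, no signal).
    """
    if min(t.a, t.b, t.c, t.d) == 0:
        nan = float("nan")
        return RorResult(nan, nan, nan, nan, False, estimable=False)
    est = (t.a * t.d) / (t.b * t.c)
    se = _log_se(t)
    lo = math.exp(math.log(est) - _Z * se)
    hi = math.exp(math.log(est) + _Z * se)
    return RorResult(est, se, lo, hi, t.a >= 3 and lo > 1.0)


def _chi2_pair(t: ContingencyTable) -> tuple[float, float]:
    """(Yates, Pearson) chi-square of the 2×2 table.

    Yates: ``(max(|ad-bc| - n/2, 0))² · n / ((a+b)(a+c)(c+d)(b+d))``,
    clamped at zero when the correction exceeds |ad−bc|.
    """
    a, b, c, d = t.a, t.b, t.c, t.d
    n = t.n
    denom = (a + b) * (a + c) * (c + d) * (b + d)
    if denom == 0:
        return float("nan"), float("nan")
    diff = abs(a * d - b * c)
    yates = (max(diff - n / 2, 0.0)) ** 2 * n / denom
    pearson = diff**2 * n / denom
    return yates, pearson


def prr(t: ContingencyTable, criteria: SignalCriteria = SignalCriteria()) -> PrrResult:
    """Proportional reporting ratio, chi-square, and log-normal 95% CI."""
    if t.c == 0 or min(t.a, t.b, t.d) == 0:
        nan = float("nan")
        yates, pearson = _chi2_pair(t) if t.n else (nan, nan)
        return PrrResult(nan, yates, pearson, nan, nan, False, estimable=False)
    est = (t.a / (t.a + t.b)) / (t.c / (t.c + t.d))
    yates, pearson = _chi2_pair(t)
    se = _log_se(t)
    lo = math.exp(math.log(est) - _Z * se)
    hi = math.exp(math.log(est) + _Z * se)
    sig = (t.a >= criteria.prr_min_a and est >= criteria.prr_min
           and yates >= criteria.prr_min_chi2)
    return PrrResult(est, yates, pearson, lo, hi, sig)


def _band(ic_minus_2sd: float) -> str:
    if ic_minus_2sd <= 0:
        return "(-)"
    if ic_minus_2sd <= 1.5:
        return "(+)"
    if ic_minus_2sd <= 3:
        return "(++)"
    return "(+++)"


def bcpnn(t: ContingencyTable, hp: BcpnnHyperparams = BcpnnHyperparams()) -> BcpnnResult:
    """Bayesian confidence propagation (information component with shrinkage).

    The raw IC is ``log2(a·n / ((a+b)(a+c)))``.  Its shrunk posterior
    expectation EIC and variance VIC follow the beta-prior moment
    expressions with prior constants ``alpha1 = beta1 = gamma11 = 1``,
    ``alpha = beta = 2`` by default; the signal band is read off
    ``EIC − 2·sqrt(VIC)``.
    """
    a, b, c, d = t.a, t.b, t.c, t.d
    n = t.n
    if n == 0 or (a + b) == 0 or (a + c) == 0:
        raise ValueError("BCPNN needs positive marginals")
    ic = math.log2(a * n / ((a + b) * (a + c))) if a > 0 else None

    gamma = hp.gamma11 * (n + hp.alpha) * (n + hp.beta) / ((a + b + hp.alpha1) * (a + c + hp.beta1))
    eic = math.log2((a + hp.gamma11) * (n + hp.alpha) * (n + hp.beta)
                    / ((n + gamma) * (a + b + hp.alpha1) * (a + c + hp.beta1)))
    vic = (1 / math.log(2) ** 2) * (
        (n - a + gamma - hp.gamma11) / ((a + hp.gamma11) * (1 + n + gamma))
        + (n - (a + b) + hp.alpha - hp.alpha1) / ((a + b + hp.alpha1) * (1 + n + hp.alpha))
        + (n - (a + c) + hp.beta - hp.beta1) / ((a + c + hp.beta1) * (1 + n + hp.beta))
    )
    ic025 = eic - 2 * math.sqrt(vic)
    return BcpnnResult(ic, eic, vic, ic025, _band(ic025), hp)


def ebgm(t: ContingencyTable) -> EbgmResult:
    """Observed/expected reporting ratio with log-normal 95% interval.

    Signal rule: EBGM05 > 2.  The interval needs all four cells positive;
    the point estimate only positive marginals.
    """
    if (t.a + t.b) == 0 or (t.a + t.c) == 0 or t.a == 0:
        nan = float("nan")
        return EbgmResult(nan, nan, nan, False, estimable=False)
    est = t.a * t.n / ((t.a + t.c) * (t.a + t.b))
    if min(t.b, t.c, t.d) == 0:
        nan = float("nan")
        return EbgmResult(est, nan, nan, False, estimable=False)
    se = _log_se(t)
    lo = math.exp(math.log(est) - _Z * se)
    hi = math.exp(math.log(est) + _Z * se)
    return EbgmResult(est, lo, hi, lo > 2.0)


def classify_signal(drug: str, event: str, t: ContingencyTable,
                    criteria: SignalCriteria = SignalCriteria(),
                    hp: BcpnnHyperparams = BcpnnHyperparams()) -> SignalResult:
    """All four statistics on one table plus the overall conjunction.

    ``overall_positive`` is true only when every method's own criterion
    holds: ROR (a≥3, CI low > 1), PRR (Evans rule), BCPNN
    (IC−2SD > 0), EBGM (EBGM05 > 2).
    """
    r = ror(t)
    p = prr(t, criteria)
    bc = bcpnn(t, hp)
    e = ebgm(t)
    positive = (r.is_signal and p.is_signal
                and bc.ic_minus_2sd > criteria.ic_minus_2sd_min
                and e.is_signal)
    return SignalResult(drug, event, t, r, p, bc, e, positive)


def analyze_table(t: ContingencyTable, drug: str = "", event: str = "") -> SignalResult:
    """Convenience wrapper: `classify_signal` with default criteria."""
    return classify_signal(drug, event, t)
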