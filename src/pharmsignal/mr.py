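"""Two-sample Mendelian randomization from GWAS summary statistics.

Given per-variant association estimates with an exposure (here, a binary
medication-use trait, so betas are log-odds) and with an outcome, each
variant's Wald ratio ``beta_y / beta_x`` estimates the causal effect of
the exposure on the outcome under the instrumental-variable assumptions
(relevance, independence, exclusion restriction).  The module provides:

* instrument selection (p-value threshold + distance pruning),
* allele harmonization of the two summary tables (swaps, strand flips,
  palindromic-variant removal),
* five estimators — IVW, MR-Egger, weighted median, simple and weighted
  mode — each returning a causal beta, SE, p-value and odds ratio,
* Cochran's Q heterogeneity for IVW and Egger fits, the Egger-intercept
  test of directional pleiotropy, leave-one-out sensitivity estimates,
  and scatter/funnel plot data.

Wald-ratio standard errors use the first-order delta approximation
``se_y / |beta_x|`` by default.  IVW defaults to multiplicative random
effects whenever Q/df > 1 (the common software behaviour), with
``model="fixed"`` available.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "MRResult",
    "HeterogeneityResult",
    "PleiotropyResult",
    "read_gwas",
    "select_instruments",
    "harmonize",
    "ivw",
    "mr_egger",
    "weighted_median",
    "mode_estimators",
    "cochran_q",
    "leave_one_out",
    "funnel_scatter_data",
    "run_all_estimators",
]

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

HARMONIZED_COLUMNS = ["snp", "beta_x", "se_x", "beta_y", "se_y",
                      "wald_ratio", "ratio_se"]


@dataclass(frozen=True)
class MRResult:
    method: str
    beta: float
    se: float
    pval: float
    n_snps: int

    @property
    def or_(self) -> float:
        """Odds ratio exp(beta) (outcome binary, betas on the log-odds scale)."""
        return float(np.exp(self.beta))

    @property
    def ci_low(self) -> float:
        return float(self.beta - 1.96 * self.se)

    @property
    def ci_high(self) -> float:
        return float(self.beta + 1.96 * self.se)


@dataclass(frozen=True)
class HeterogeneityResult:
    method: str  # "ivw" or "egger"
    q: float
    q_df: int
    q_pval: float


@dataclass(frozen=True)
class PleiotropyResult:
    intercept: float
    se: float
    pval: float


def read_gwas(path: str | Path) -> pd.DataFrame:
    """Read a whitespace/tab-separated GWAS summary-statistics table.

    Required columns: snp, effect_allele, other_allele, beta, se, pval.
    Optional: eaf, chr, pos.
    """
    df = pd.read_csv(path, sep=r"\s+")
    df.columns = [c.strip().lower() for c in df.columns]
    required = ["snp", "effect_allele", "other_allele", "beta", "se", "pval"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    if (df["se"] <= 0).any():
        raise ValueError(f"{path}: non-positive standard errors")
    return df


def select_instruments(exposure: pd.DataFrame, p_threshold: float = 5e-8,
                       prune_window_kb: float = 1000.0) -> pd.DataFrame:
    """Genome-wide-significant variants, distance-pruned when positions exist.

    Keeps rows with ``pval < p_threshold``; when ``chr``/``pos`` columns
    are present, greedily keeps the smallest-p variant per window of
    ``prune_window_kb`` kilobases (a proxy for LD clumping when no
    reference panel is available).  Deterministic: ties in p resolve by
    snp id.
    """
    hits = exposure[exposure["pval"] < p_threshold].copy()
    if hits.empty:
        raise ValueError(
            f"no instruments at p < {p_threshold}; relax the threshold")
    if not {"chr", "pos"}.issubset(hits.columns) or hits["pos"].isna().any():
        logger.warning("no chr/pos columns: instruments not distance-pruned")
        return hits.sort_values(["pval", "snp"]).reset_index(drop=True)
    hits = hits.sort_values(["pval", "snp"], kind="mergesort")
    kept = []
    window = prune_window_kb * 1000.0
    for _, row in hits.iterrows():
        if all(row["chr"] != k["chr"] or abs(row["pos"] - k["pos"]) > window
               for k in kept):
            kept.append(row)
    return pd.DataFrame(kept).reset_index(drop=True)


def _norm_alleles(s: pd.Series) -> pd.Series:
    return s.astype(str).str.strip().str.upper()


def _complement(s: pd.Series) -> pd.Series:
    return s.map(lambda a: "".join(_COMPLEMENT.get(ch, "N") for ch in a))


def harmonize(exposure: pd.DataFrame, outcome: pd.DataFrame,
              drop_palindromic: bool = True,
              second_order_se: bool = False) -> pd.DataFrame:
    """Align two summary tables to the same effect allele per variant.

    Outcome rows whose alleles are swapped relative to the exposure have
    their beta sign flipped; strand-complement matches are accepted;
    palindromic variants (A/T, C/G) are dropped by default because their
    strand cannot be resolved without allele frequencies; anything else
    is dropped with a warning.  Finally each instrument is oriented so
    that ``beta_x > 0`` (the exposure-increasing allele is the effect
    allele), flipping ``beta_y`` in step.

    Returns a DataFrame with columns snp, beta_x, se_x, beta_y, se_y,
    wald_ratio, ratio_se.
    """
    m = exposure.merge(outcome, on="snp", suffixes=("_x", "_y"))
    if m.empty:
        raise ValueError("no shared variants between exposure and outcome")
    ea_x = _norm_alleles(m["effect_allele_x"])
    oa_x = _norm_alleles(m["other_allele_x"])
    ea_y = _norm_alleles(m["effect_allele_y"])
    oa_y = _norm_alleles(m["other_allele_y"])

    palindromic = ea_x == _complement(oa_x)
    same = (ea_y == ea_x) & (oa_y == oa_x)
    swapped = (ea_y == oa_x) & (oa_y == ea_x)
    comp_same = (ea_y == _complement(ea_x)) & (oa_y == _complement(oa_x))
    comp_swapped = (ea_y == _complement(oa_x)) & (oa_y == _complement(ea_x))

    flip = (swapped | (comp_swapped & ~palindromic)) & ~same
    ok = same | swapped | comp_same | comp_swapped
    if drop_palindromic:
        ok &= ~palindromic
        n_pal = int(palindromic.sum())
        if n_pal:
            logger.info("harmonize: dropped %d palindromic variant(s)", n_pal)
    n_bad = int((~(same | swapped | comp_same | comp_swapped)).sum())
    if n_bad:
        logger.warning("harmonize: dropped %d variant(s) with irreconcilable alleles", n_bad)

    out = pd.DataFrame({
        "snp": m["snp"],
        "beta_x": m["beta_x"].astype(float),
        "se_x": m["se_x"].astype(float),
        "beta_y": np.where(flip, -m["beta_y"].astype(float), m["beta_y"].astype(float)),
        "se_y": m["se_y"].astype(float),
    })[ok.to_numpy()].reset_index(drop=True)

    # orient the exposure-increasing allele as the effect allele
    neg = out["beta_x"] < 0
    out.loc[neg, ["beta_x", "beta_y"]] *= -1.0

    out["wald_ratio"] = out["beta_y"] / out["beta_x"]
    if second_order_se:
        out["ratio_se"] = np.sqrt(out["se_y"] ** 2 / out["beta_x"] ** 2
                                  + out["beta_y"] ** 2 * out["se_x"] ** 2
                                  / out["beta_x"] ** 4)
    else:
        out["ratio_se"] = out["se_y"] / out["beta_x"].abs()
    return out


def _ratios_weights(instr: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    instr = instr[instr["beta_x"] != 0]
    r = instr["wald_ratio"].to_numpy(float)
    w = 1.0 / instr["ratio_se"].to_numpy(float) ** 2
    return r, w


def ivw(instr: pd.DataFrame, model: str = "auto") -> MRResult:
    """Inverse-variance-weighted meta-analysis of the Wald ratios.

    ``model``: "fixed" (se = sqrt(1/Σw)), "random" (multiplicative
    random effects: fixed SE inflated by sqrt(Q/df)), or "auto"
    (random-effects inflation only when Q/df > 1; the default).
    Instruments with ``beta_x == 0`` are dropped.
    """
    r, w = _ratios_weights(instr)
    n = len(r)
    if n < 1:
        raise ValueError("ivw needs at least one instrument")
    beta = float(np.sum(w * r) / np.sum(w))
    se = float(np.sqrt(1.0 / np.sum(w)))
    if n > 1 and model in ("auto", "random"):
        q = float(np.sum(w * (r - beta) ** 2))
        phi = q / (n - 1)
        if model == "random" or phi > 1.0:
            se *= np.sqrt(max(phi, 1.0) if model == "auto" else phi)
    pval = float(2 * stats.norm.sf(abs(beta / se)))
    return MRResult("ivw", beta, se, pval, n)


def mr_egger(instr: pd.DataFrame) -> tuple[MRResult, PleiotropyResult]:
    """Egger regression: weighted LS of beta_y on beta_x with intercept.

    Weights 1/se_y²; the slope is the causal estimate and the intercept
    its directional-pleiotropy test.  Residual variance below 1 is not
    allowed to shrink the standard errors (multiplicative random
    effects floored at 1); p-values use t with n − 2 df.
    """
    import statsmodels.api as sm

    instr = instr[instr["beta_x"] != 0]
    n = len(instr)
    if n < 3:
        raise ValueError(f"mr_egger needs at least 3 instruments, got {n}")
    x = instr["beta_x"].to_numpy(float)
    y = instr["beta_y"].to_numpy(float)
    w = 1.0 / instr["se_y"].to_numpy(float) ** 2
    fit = sm.WLS(y, sm.add_constant(x), weights=w).fit()
    sigma = np.sqrt(fit.scale)
    infl = 1.0 / min(1.0, sigma)  # floor the residual scale at 1
    se_int, se_slope = fit.bse * infl
    b_int, b_slope = fit.params
    df = n - 2
    p_slope = float(2 * stats.t.sf(abs(b_slope / se_slope), df))
    p_int = float(2 * stats.t.sf(abs(b_int / se_int), df))
    return (MRResult("egger", float(b_slope), float(se_slope), p_slope, n),
            PleiotropyResult(float(b_int), float(se_int), p_int))


def _weighted_median_point(r: np.ndarray, w: np.ndarray) -> float:
    order = np.argsort(r)
    r, w = r[order], w[order] / w.sum()
    cum = np.cumsum(w) - w / 2  # cumulative midpoint quantile positions
    if cum[0] >= 0.5:
        return float(r[0])
    if cum[-1] <= 0.5:
        return float(r[-1])
    k = int(np.searchsorted(cum, 0.5) - 1)
    return float(r[k] + (r[k + 1] - r[k]) * (0.5 - cum[k]) / (cum[k + 1] - cum[k]))


def weighted_median(instr: pd.DataFrame, n_boot: int = 5000,
                    seed: int | None = 0) -> MRResult:
    """Weighted-median estimator: the 50th percentile of the Wald ratios
    under cumulative IVW weights, consistent when instruments carrying
    at least half the weight are valid.

    SE by parametric bootstrap: per resample, beta_x and beta_y are
    perturbed by their standard errors and the weighted median
    recomputed.
    """
    instr = instr[instr["beta_x"] != 0]
    n = len(instr)
    if n < 3:
        raise ValueError(f"weighted_median needs at least 3 instruments, got {n}")
    r, w = _ratios_weights(instr)
    beta = _weighted_median_point(r, w)
    se = _bootstrap_se(instr, _weighted_median_point, weighting="ivw",
                       n_boot=n_boot, seed=seed)
    pval = float(2 * stats.norm.sf(abs(beta / se))) if se > 0 else 0.0
    return MRResult("weighted_median", beta, float(se), pval, n)


def _mode_point(r: np.ndarray, w: np.ndarray, phi: float = 1.0,
                n_grid: int = 2048) -> float:
    """Mode of the normal-kernel-smoothed weighted density of ratios."""
    h = phi * _mode_bandwidth(r)
    if h <= 0:
        raise ValueError("degenerate bandwidth 0 (identical ratios?)")
    grid = np.linspace(r.min() - 3 * h, r.max() + 3 * h, n_grid)
    dens = (w[:, None] * stats.norm.pdf((grid[None, :] - r[:, None]) / h)).sum(axis=0)
    return float(grid[np.argmax(dens)])


def _mode_bandwidth(r: np.ndarray) -> float:
    """Modified Silverman rule: 0.9·min(sd, mad/0.6745)·n^(−1/5)."""
    s = np.std(r, ddof=1)
    mad = np.median(np.abs(r - np.median(r))) / 0.6745
    spread = min(s, mad) if mad > 0 else s
    return 0.9 * spread * len(r) ** (-1 / 5)


def mode_estimators(instr: pd.DataFrame, bandwidth_phi: float = 1.0,
                    n_boot: int = 5000, seed: int | None = 0,
                    ) -> tuple[MRResult, MRResult]:
    """Simple and weighted mode estimators (kernel-smoothed ratio density).

    The causal estimate is the mode of the normal-kernel density of the
    Wald ratios — unweighted for the simple mode, IVW-weighted for the
    weighted mode — with bandwidth ``phi`` times the modified Silverman
    rule.  Consistent when the largest group of instruments sharing one
    ratio value is valid.  SEs by parametric bootstrap; p-values from t
    with n − 1 df.
    """
    instr = instr[instr["beta_x"] != 0]
    n = len(instr)
    if n < 3:
        raise ValueError(f"mode_estimators need at least 3 instruments, got {n}")
    r, w = _ratios_weights(instr)
    eq = np.ones_like(r)

    def simple_fn(rr, ww):
        return _mode_point(rr, np.ones_like(rr), phi=bandwidth_phi)

    def weighted_fn(rr, ww):
        return _mode_point(rr, ww / ww.sum(), phi=bandwidth_phi)

    b_simple = simple_fn(r, eq)
    b_weighted = weighted_fn(r, w)
    se_simple = _bootstrap_se(instr, simple_fn, weighting="ivw",
                              n_boot=n_boot, seed=seed)
    se_weighted = _bootstrap_se(instr, weighted_fn, weighting="ivw",
                                n_boot=n_boot, seed=None if seed is None else seed + 1)
    df = n - 1

    def pt(b, s):
        return float(2 * stats.t.sf(abs(b / s), df)) if s > 0 else 0.0

    return (MRResult("simple_mode", b_simple, float(se_simple), pt(b_simple, se_simple), n),
            MRResult("weighted_mode", b_weighted, float(se_weighted), pt(b_weighted, se_weighted), n))


def _bootstrap_se(instr: pd.DataFrame, point_fn, weighting: str,
                  n_boot: int, seed: int | None) -> float:
    """Parametric bootstrap SE: resample betas from their normal errors."""
    rng = np.random.default_rng(seed)
    bx = instr["beta_x"].to_numpy(float)
    by = instr["beta_y"].to_numpy(float)
    sx = instr["se_x"].to_numpy(float)
    sy = instr["se_y"].to_numpy(float)
    est = np.empty(n_boot)
    for i in range(n_boot):
        bx_i = rng.normal(bx, sx)
        by_i = rng.normal(by, sy)
        bx_i[bx_i == 0] = np.finfo(float).tiny
        r = by_i / bx_i
        w = bx_i**2 / sy**2  # 1/ratio_se² with first-order delta SE
        est[i] = point_fn(r, w)
    return float(np.std(est, ddof=1))


def cochran_q(instr: pd.DataFrame, method: str = "ivw") -> HeterogeneityResult:
    """Cochran's Q heterogeneity of the Wald ratios about the model fit.

    IVW: Q = Σ wⱼ(rⱼ − β̂)², df = n − 1.  Egger (Rücker's Q'): weighted
    residual sum of squares about the fitted line, df = n − 2.  The
    p-value is the upper chi-square tail.
    """
    instr = instr[instr["beta_x"] != 0]
    n = len(instr)
    if method == "ivw":
        r, w = _ratios_weights(instr)
        df = n - 1
        if df <= 0:
            return HeterogeneityResult("ivw", float("nan"), df, float("nan"))
        beta = np.sum(w * r) / np.sum(w)
        q = float(np.sum(w * (r - beta) ** 2))
    elif method == "egger":
        df = n - 2
        if df <= 0:
            return HeterogeneityResult("egger", float("nan"), df, float("nan"))
        est, pleio = mr_egger(instr)
        x = instr["beta_x"].to_numpy(float)
        y = instr["beta_y"].to_numpy(float)
        w = 1.0 / instr["se_y"].to_numpy(float) ** 2
        resid = y - (pleio.intercept + est.beta * x)
        q = float(np.sum(w * resid**2))
    else:
        raise ValueError(f"unknown method {method!r}")
    return HeterogeneityResult(method, q, df, float(stats.chi2.sf(q, df)))


def leave_one_out(instr: pd.DataFrame, model: str = "auto") -> pd.DataFrame:
    """IVW estimates dropping one instrument at a time.

    Flags instruments whose removal flips the sign of the estimate or
    its 0.05 significance relative to the all-instrument fit.
    """
    instr = instr[instr["beta_x"] != 0].reset_index(drop=True)
    n = len(instr)
    if n < 2:
        raise ValueError("leave_one_out needs at least 2 instruments")
    full = ivw(instr, model=model)
    rows = []
    for j in range(n):
        sub = instr.drop(index=j)
        est = ivw(sub, model=model)
        rows.append({
            "snp": instr.loc[j, "snp"],
            "beta": est.beta, "se": est.se, "pval": est.pval,
            "flips_sign": np.sign(est.beta) != np.sign(full.beta),
            "flips_significance": (est.pval < 0.05) != (full.pval < 0.05),
        })
    return pd.DataFrame(rows)


def funnel_scatter_data(instr: pd.DataFrame,
                        fits: dict[str, MRResult],
                        egger_intercept: float | None = None,
                        ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Plot-ready tables: scatter points, fitted lines, and funnel points.

    Scatter: per-instrument (beta_x, beta_y) with SE bars.  Lines: one
    (intercept, slope) per fitted method — zero intercept except Egger.
    Funnel: wald_ratio against precision 1/ratio_se, with the IVW
    estimate as the vertical reference.
    """
    scatter = instr[["snp", "beta_x", "se_x", "beta_y", "se_y"]].copy()
    lines = pd.DataFrame([
        {"method": m, "intercept": (egger_intercept if m == "egger" and
                                    egger_intercept is not None else 0.0),
         "slope": fit.beta}
        for m, fit in fits.items()
    ])
    funnel = instr[["snp", "wald_ratio"]].copy()
    funnel["precision"] = 1.0 / instr["ratio_se"]
    if "ivw" in fits:
        funnel["ivw_beta"] = fits["ivw"].beta
    return scatter, lines, funnel


def run_all_estimators(instr: pd.DataFrame, n_boot: int = 5000,
                       seed: int | None = 0, model: str = "auto") -> dict:
    """Fit all five estimators plus diagnostics; returns a result bundle."""
    est_ivw = ivw(instr, model=model)
    est_egger, pleio = mr_egger(instr)
    est_med = weighted_median(instr, n_boot=n_boot, seed=seed)
    est_sm, est_wm = mode_estimators(instr, n_boot=n_boot,
                                     seed=None if seed is None else seed + 2)
    return {
        "estimates": {e.method: e for e in (est_ivw, est_egger, est_med, est_sm, est_wm)},
        "pleiotropy": pleio,
        "heterogeneity": {m: cochran_q(instr, m) for m in ("ivw", "egger")},
        "leave_one_out": leave_one_out(instr, model=model),
    }
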