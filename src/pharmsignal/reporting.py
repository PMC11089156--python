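"""Descriptive report profiling, SOC summaries, and the pipeline driver.

Mirrors the descriptive outputs that accompany a disproportionality
study: a demographic/outcome profile of the reports behind one
drug–event pair (age bins, reporter type, top countries, outcome-code
combinations, seriousness, yearly report series, time-to-onset bins), a
per-SOC rollup of signal counts, and a ``run_pipeline`` entry point that
chains cleaning → contingency → signals → profile for the report arm and
instruments → harmonization → estimators → diagnostics for the MR arm.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .contingency import build_table, pair_counts
from .disproportionality import SignalCriteria, classify_signal
from .faers_io import match_drug_cases

logger = logging.getLogger(__name__)

__all__ = ["ProfileSummary", "soc_summary", "profile_reports", "signal_screen",
           "run_pipeline", "AGE_BIN_EDGES", "ONSET_BIN_EDGES"]

#: left-closed age bin edges; ages land in [lo, hi)
AGE_BIN_EDGES = (18, 45, 65, 75)
AGE_BIN_LABELS = ("<18", "18-45", "45-65", "65-75", ">=75")

#: onset-day bins (inclusive ranges)
ONSET_BIN_EDGES = ((0, 30), (31, 60), (61, 90), (91, 180), (181, 360),
                   (361, None))

_REPORTER_NAMES = {"CN": "Consumer", "MD": "Physician", "PH": "Pharmacist",
                   "OT": "Other health-professional", "LW": "Lawyer",
                   "": "Not Specified"}


def _pct(counts: pd.Series) -> pd.DataFrame:
    total = counts.sum()
    pct = counts / total * 100 if total else counts * 0.0
    return pd.DataFrame({"count": counts, "percent": pct.round(2)})


@dataclass
class ProfileSummary:
    """Descriptive profile of the reports behind one drug–event pair."""
    n_reports: int
    age_bins: pd.DataFrame          # count + percent per age category
    age_stats: dict                 # mean/sd/median/q1/q3/min/max of known ages
    reporter_counts: pd.DataFrame
    country_counts: pd.DataFrame    # top-k + OTHER
    outcome_counts: pd.DataFrame    # sorted semicolon-joined combinations
    serious_counts: pd.DataFrame
    yearly_counts: pd.Series        # reports per receive-year
    onset_bins: pd.DataFrame
    n_negative_onset: int = 0


def _age_category(age: float) -> str:
    if pd.isna(age):
        return "Not Specified"
    for lo, hi, label in zip((0,) + AGE_BIN_EDGES, AGE_BIN_EDGES + (np.inf,),
                             AGE_BIN_LABELS):
        if lo <= age < hi:
            return label
    return "Not Specified"  # pragma: no cover


def _onset_label(days: float) -> str:
    for lo, hi in ONSET_BIN_EDGES:
        if hi is None:
            if days >= lo:
                return f">{lo - 1}"
        elif lo <= days <= hi:
            return f"{lo}-{hi}"
    return "unbinned"  # pragma: no cover


def profile_reports(store, drug: str, event: str,
                    synonyms: tuple[str, ...] = (), top_k_countries: int = 5,
                    ) -> ProfileSummary:
    """Profile of all cleaned reports mentioning both the drug and the event.

    Age bins are left-closed at 18/45/65/75 (a 45-year-old falls in
    45–65).  Time to onset is the report receive date minus the earliest
    therapy start date for the drug; negative onsets are excluded from
    the bins and counted separately.
    """
    target = match_drug_cases(store.drug, drug, synonyms=synonyms)
    pt_col = "pt_current" if "pt_current" in store.reac.columns else "pt"
    ev_cases = set(store.reac.loc[
        store.reac[pt_col].str.casefold() == event.strip().casefold(), "caseid"])
    cases = target & ev_cases
    demo = store.demo[store.demo["caseid"].isin(cases)]
    n = len(demo)
    if n == 0:
        empty = _pct(pd.Series(dtype=int))
        return ProfileSummary(0, empty, {}, empty, empty, empty, empty,
                              pd.Series(dtype=int), empty)

    age_cat = demo["age"].map(_age_category)
    order = [*AGE_BIN_LABELS, "Not Specified"]
    age_bins = _pct(age_cat.value_counts().reindex(order, fill_value=0))
    known = demo["age"].dropna()
    age_stats = {} if known.empty else {
        "mean": float(known.mean()), "sd": float(known.std(ddof=1)),
        "median": float(known.median()),
        "q1": float(known.quantile(0.25)), "q3": float(known.quantile(0.75)),
        "min": float(known.min()), "max": float(known.max()),
    }

    reporter = demo["occp_cod"].fillna("").map(
        lambda c: _REPORTER_NAMES.get(str(c).strip(), str(c).strip() or "Not Specified"))
    reporter_counts = _pct(reporter.value_counts())

    country = demo["reporter_country"].fillna("Not Specified").astype(str)
    top = country.value_counts()
    if len(top) > top_k_countries:
        head = top.iloc[:top_k_countries]
        head["OTHER"] = top.iloc[top_k_countries:].sum()
        top = head
    country_counts = _pct(top)

    outc = store.outc[store.outc["caseid"].isin(cases)]
    combos = (outc.groupby("caseid")["outc_cod"]
              .apply(lambda s: ";".join(sorted(set(s.astype(str))))))
    combos = combos.reindex(list(cases)).fillna("NOT SPECIFIED")
    outcome_counts = _pct(combos.value_counts())

    serious = demo["serious"].map(
        lambda v: "Serious" if str(v).strip().upper() in ("Y", "1", "TRUE")
        else ("Non-Serious" if str(v).strip().upper() in ("N", "0", "FALSE")
              else "Not Specified"))
    serious_counts = _pct(serious.value_counts())

    years = (demo["fda_dt"].dropna().astype(int) // 10000)
    yearly = years.value_counts().sort_index()

    # earliest therapy start for the target drug, per case
    drug_rows = store.drug[store.drug["caseid"].isin(cases)]
    tgt = drug_rows[drug_rows["caseid"].isin(
        match_drug_cases(drug_rows, drug, synonyms=synonyms))]
    ther = store.ther.merge(
        tgt[["primaryid", "drug_seq"]].rename(columns={"drug_seq": "dsg_drug_seq"}),
        on=["primaryid", "dsg_drug_seq"], how="inner") \
        if "dsg_drug_seq" in store.ther.columns else store.ther
    ther = ther[ther["caseid"].isin(cases)].dropna(subset=["start_dt"])
    starts = ther.groupby("caseid")["start_dt"].min()
    recv = demo.set_index("caseid")["fda_dt"]
    both = pd.DataFrame({"start": starts, "recv": recv}).dropna()
    onset_days = (pd.to_datetime(both["recv"].astype(int).astype(str), format="%Y%m%d")
                  - pd.to_datetime(both["start"].astype(int).astype(str), format="%Y%m%d")
                  ).dt.days
    neg = int((onset_days < 0).sum())
    if neg:
        logger.warning("profile: %d negative onset interval(s) excluded", neg)
    labels = [f"{lo}-{hi}" if hi is not None else f">{lo - 1}"
              for lo, hi in ONSET_BIN_EDGES]
    binned = onset_days[onset_days >= 0].map(_onset_label)
    onset_bins = _pct(binned.value_counts().reindex(labels, fill_value=0))

    return ProfileSummary(n, age_bins, age_stats, reporter_counts,
                          country_counts, outcome_counts, serious_counts,
                          yearly, onset_bins, neg)


def signal_screen(store, drug: str, level: str = "pt",
                  synonyms: tuple[str, ...] = (),
                  criteria: SignalCriteria = SignalCriteria(),
                  min_a: int = 1) -> pd.DataFrame:
    """All four statistics for every event the drug was reported with.

    One row per event at the requested level, mirroring a published
    signal table: counts, ROR/PRR with CIs, chi-square, IC with its
    credibility bound and strength band, EBGM with EBGM05, and the
    per-method plus overall signal flags.
    """
    target = match_drug_cases(store.drug, drug, synonyms=synonyms)
    pairs = pair_counts(store, level=level)
    events = sorted(pairs.loc[pairs["caseid"].isin(target), "event"].unique())
    rows = []
    for ev in events:
        t = build_table(store, drug, ev, level=level, synonyms=synonyms)
        if t.a < min_a:
            continue
        res = classify_signal(drug, ev, t, criteria)
        rows.append({
            "event": ev, "a": t.a, "b": t.b, "c": t.c, "d": t.d,
            "ror": res.ror.ror, "ror_ci_low": res.ror.ci_low,
            "ror_ci_high": res.ror.ci_high,
            "prr": res.prr.prr, "prr_ci_low": res.prr.ci_low,
            "prr_ci_high": res.prr.ci_high,
            "chi2": res.prr.chi2, "chi2_pearson": res.prr.chi2_pearson,
            "ic": res.bcpnn.ic, "ic025": res.bcpnn.ic_minus_2sd,
            "band": res.bcpnn.strength_band,
            "ebgm": res.ebgm.ebgm, "ebgm05": res.ebgm.ebgm05,
            "signal_ror": res.ror.is_signal, "signal_prr": res.prr.is_signal,
            "signal_ebgm": res.ebgm.is_signal,
            "overall_positive": res.overall_positive,
        })
    return pd.DataFrame(rows)


def soc_summary(store, drug: str, signal_table: pd.DataFrame,
                synonyms: tuple[str, ...] = ()) -> pd.DataFrame:
    """Per-SOC rollup: positive-signal PT count, pair count, percentage.

    ``signal_table`` is a PT-level :func:`signal_screen` result.  The
    percentage base is the drug's grand pair total, so the column sums
    to 100.  PTs lacking a SOC group under ``"UNMAPPED-SOC"``.
    """
    target = match_drug_cases(store.drug, drug, synonyms=synonyms)
    pairs = pair_counts(store, level="soc")
    mine = pairs[pairs["caseid"].isin(target)]
    pair_tot = mine.groupby("event").size()

    pt_col = "pt_current" if "pt_current" in store.reac.columns else "pt"
    if "soc" in store.reac.columns:
        pt2soc = (store.reac[[pt_col, "soc"]].drop_duplicates()
                  .set_index(pt_col)["soc"].to_dict())
    else:
        pt2soc = {}
    sig = signal_table[signal_table["overall_positive"]] if len(signal_table) else signal_table
    pos_per_soc = (pd.Series([pt2soc.get(e, "UNMAPPED-SOC") for e in sig["event"]])
                   .value_counts() if len(sig) else pd.Series(dtype=int))

    out = pd.DataFrame({
        "soc": pair_tot.index,
        "positive_pts": [int(pos_per_soc.get(s, 0)) for s in pair_tot.index],
        "pair_count": pair_tot.values,
    })
    total = out["pair_count"].sum()
    out["percent"] = (out["pair_count"] / total * 100).round(2)
    return out.sort_values("pair_count", ascending=False).reset_index(drop=True)


# ---------------------------------------------------------------------------
# pipeline driver


def _meta_header(config: dict, seed) -> str:
    digest = hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()[:12]
    return (f"# pharmsignal {__version__} | seed={seed} | config_sha={digest}\n")


def _write(df: pd.DataFrame, path: Path, header: str) -> None:
    with open(path, "w") as fh:
        fh.write(header)
        df.to_csv(fh, sep="\t", index=False)


def run_pipeline(config: dict, out_dir: str | Path) -> Path:
    """Run whichever analysis arms the config describes; write TSV outputs.

    Config keys (all optional except at least one arm):

    * ``signal``: ``quarters`` (list of packet dirs), ``deleted`` (list
      of deletion-list files), ``remap`` (PT remap TSV), ``drug``,
      ``event``, ``synonyms``.
    * ``mr``: ``exposure``/``outcome`` (summary TSV paths),
      ``p_threshold``, ``prune_window_kb``, ``n_boot``.
    * ``seed``: propagated to every stochastic step.

    Every output carries a metadata header line (version, seed, config
    hash), so identical config + seed reproduces identical bytes.
    """
    from . import faers_io, mr as mrmod

    unknown = set(config) - {"signal", "mr", "seed"}
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if not ({"signal", "mr"} & set(config)):
        raise ValueError("config must define a 'signal' and/or 'mr' arm")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = config.get("seed", 0)
    header = _meta_header(config, seed)

    if "signal" in config:
        sc = dict(config["signal"])
        store = faers_io.read_quarters(sc["quarters"])
        deleted: set[str] = set()
        for f in sc.get("deleted", []):
            deleted |= faers_io.read_deletion_list(f)
        remap = faers_io.read_pt_remap(sc["remap"]) if sc.get("remap") else None
        store = faers_io.clean_store(store, deleted, remap)
        drug = sc["drug"]
        synonyms = tuple(sc.get("synonyms", ()))
        screen = signal_screen(store, drug, level="pt", synonyms=synonyms)
        _write(screen, out / "signals_pt.tsv", header)
        _write(soc_summary(store, drug, screen, synonyms=synonyms),
               out / "soc_summary.tsv", header)
        if sc.get("event"):
            prof = profile_reports(store, drug, sc["event"], synonyms=synonyms)
            _write(prof.age_bins.rename_axis("age_bin").reset_index(),
                   out / "profile_age.tsv", header)
            _write(prof.reporter_counts.rename_axis("reporter").reset_index(),
                   out / "profile_reporter.tsv", header)
            _write(prof.country_counts.rename_axis("country").reset_index(),
                   out / "profile_country.tsv", header)
            _write(prof.outcome_counts.rename_axis("outcome").reset_index(),
                   out / "profile_outcome.tsv", header)
            _write(prof.serious_counts.rename_axis("serious").reset_index(),
                   out / "profile_serious.tsv", header)
            _write(prof.yearly_counts.rename_axis("year").reset_index(name="count"),
                   out / "profile_yearly.tsv", header)
            _write(prof.onset_bins.rename_axis("onset_days").reset_index(),
                   out / "profile_onset.tsv", header)

    if "mr" in config:
        mc = dict(config["mr"])
        exposure = mrmod.read_gwas(mc["exposure"])
        outcome = mrmod.read_gwas(mc["outcome"])
        instruments = mrmod.select_instruments(
            exposure, p_threshold=mc.get("p_threshold", 5e-8),
            prune_window_kb=mc.get("prune_window_kb", 1000.0))
        instr = mrmod.harmonize(instruments, outcome)
        bundle = mrmod.run_all_estimators(instr, n_boot=mc.get("n_boot", 5000),
                                          seed=seed)
        est = pd.DataFrame([
            {"method": e.method, "beta": e.beta, "se": e.se, "or": e.or_,
             "pval": e.pval, "n_snps": e.n_snps}
            for e in bundle["estimates"].values()
        ])
        _write(est, out / "mr_estimates.tsv", header)
        het = pd.DataFrame([
            {"method": h.method, "q": h.q, "q_df": h.q_df, "q_pval": h.q_pval}
            for h in bundle["heterogeneity"].values()
        ])
        _write(het, out / "mr_heterogeneity.tsv", header)
        pl = bundle["pleiotropy"]
        _write(pd.DataFrame([{"intercept": pl.intercept, "se": pl.se,
                              "pval": pl.pval}]),
               out / "mr_pleiotropy.tsv", header)
        _write(bundle["leave_one_out"], out / "mr_leave_one_out.tsv", header)
        scatter, lines, funnel = mrmod.funnel_scatter_data(
            instr, bundle["estimates"], egger_intercept=pl.intercept)
        _write(scatter, out / "mr_scatter.tsv", header)
        _write(lines, out / "mr_fit_lines.tsv", header)
        _write(funnel, out / "mr_funnel.tsv", header)

    return out
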