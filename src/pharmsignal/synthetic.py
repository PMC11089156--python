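"""Synthetic spontaneous-report and GWAS summary-statistic generators.

Real inputs to the two analysis arms — a spontaneous-report database and
pairs of GWAS summary-statistic tables — are access-restricted, so this
module fabricates both under fully known ground truth:

* :func:`simulate_reports` emits a FAERS-style quarterly packet (DEMO,
  DRUG, REAC, THER, OUTC, '$'-delimited, plus a deletion list and a PT
  remap table) with implanted drug–event disproportionality signals,
  planted duplicate report versions, legacy PT spellings, and
  demographics drawn from report-profile distributions typical of a
  statin adverse-event population.
* :func:`simulate_gwas_pair` emits exposure and outcome summary tables
  under the linear instrumental-variable model
  ``beta_y = true_beta * gamma_j + alpha_j + noise`` with configurable
  pleiotropy (``alpha``), heterogeneity, and deliberate allele swaps to
  exercise harmonization.

Every run returns a *truth record* (JSON-serialisable) holding the
expected contingency tables, duplicate groups, deletion lists, per-SNP
effects — whatever downstream checks need.  All randomness flows from
the single ``seed`` in the config; regeneration with the same config is
byte-identical.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .faers_io import ReportStore

__all__ = [
    "ReportSimConfig",
    "GwasSimConfig",
    "simulate_reports",
    "simulate_gwas_pair",
    "expected_table",
    "write_report_files",
    "write_gwas_files",
    "DEFAULT_EVENT_CATALOG",
    "DEFAULT_DRUG_CATALOG",
]

# (PT, SOC, marginal probability per report)
DEFAULT_EVENT_CATALOG: tuple[tuple[str, str, float], ...] = (
    ("Erectile dysfunction", "Reproductive system and breast disorders", 0.010),
    ("Haematospermia", "Reproductive system and breast disorders", 0.002),
    ("Myalgia", "Musculoskeletal and connective tissue disorders", 0.080),
    ("Arthralgia", "Musculoskeletal and connective tissue disorders", 0.050),
    ("Fatigue", "General disorders and administration site conditions", 0.100),
    ("Nausea", "Gastrointestinal disorders", 0.090),
    ("Diarrhoea", "Gastrointestinal disorders", 0.060),
    ("Headache", "Nervous system disorders", 0.090),
    ("Dizziness", "Nervous system disorders", 0.060),
    ("Rash", "Skin and subcutaneous tissue disorders", 0.050),
    ("Insomnia", "Psychiatric disorders", 0.040),
    ("Blood glucose increased", "Investigations", 0.030),
    ("Alanine aminotransferase increased", "Investigations", 0.020),
    ("Renal impairment", "Renal and urinary disorders", 0.020),
    ("Cough", "Respiratory, thoracic and mediastinal disorders", 0.030),
)

#: one drug per report, categorical marginals
DEFAULT_DRUG_CATALOG: tuple[tuple[str, float], ...] = (
    ("ATORVASTATIN", 0.10), ("LISINOPRIL", 0.12), ("METFORMIN", 0.12),
    ("OMEPRAZOLE", 0.11), ("SERTRALINE", 0.11), ("IBUPROFEN", 0.11),
    ("AMLODIPINE", 0.11), ("SIMVASTATIN", 0.11), ("WARFARIN", 0.11),
)

#: legacy PT spellings emitted at `legacy_spelling_rate` and listed in the
#: generated remap table (old spelling -> current PT)
LEGACY_SPELLINGS: dict[str, str] = {
    "Erectile dysfunction": "Erection increased",
    "Diarrhoea": "Diarrhea",
    "Myalgia": "Muscle pain",
    "Haematospermia": "Hematospermia",
    "Renal impairment": "Renal function impaired",
    "Blood glucose increased": "Hyperglycaemia NOS",
    "Alanine aminotransferase increased": "ALT increased",
    "Fatigue": "Tiredness",
    "Dizziness": "Dizziness NOS",
    "Rash": "Rash NOS",
}

_AGE_BINS = ((18.0, 45.0, 0.0783), (45.0, 65.0, 0.3449), (65.0, 75.0, 0.1420),
             (75.0, 85.0, 0.0638))  # remaining mass -> age Not Specified
_REPORTERS = (("CN", 0.3594), ("LW", 0.0058), ("", 0.0783), ("OT", 0.1333),
              ("PH", 0.1130), ("MD", 0.3101))
_COUNTRIES = (("US", 0.3072), ("GB", 0.2029), ("NL", 0.0609), ("ES", 0.0493),
              ("DE", 0.0377), ("OTHER", 0.3420))
_OUTCOME_CODES = (("OT", 0.70), ("DS", 0.08), ("HO;OT", 0.06), ("DS;OT", 0.03),
                  ("HO", 0.02), ("", 0.11))  # given a serious report


@dataclass
class ReportSimConfig:
    """Study conditions for the synthetic spontaneous-report database."""
    n_reports: int = 10_000
    drug_catalog: tuple[tuple[str, float], ...] = DEFAULT_DRUG_CATALOG
    event_catalog: tuple[tuple[str, str, float], ...] = DEFAULT_EVENT_CATALOG
    implanted_signals: tuple[tuple[str, str, float], ...] = (
        ("ATORVASTATIN", "Erectile dysfunction", 4.0),
    )
    duplicate_rate: float = 0.05
    deletion_rate: float = 0.02
    legacy_spelling_rate: float = 0.30
    serious_prob: float = 0.8551
    year_range: tuple[int, int] = (2004, 2023)
    #: onset-day mixture: (low, high, weight) uniform components
    onset_mixture: tuple[tuple[int, int, float], ...] = (
        (0, 30, 0.50), (31, 180, 0.20), (181, 360, 0.20), (361, 720, 0.10),
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_reports < 1:
            raise ValueError("n_reports must be positive")
        for drug, event, rr in self.implanted_signals:
            if rr <= 0:
                raise ValueError(f"relative risk must be > 0 for {(drug, event)}")
            p = dict((pt, pr) for pt, _, pr in self.event_catalog).get(event)
            if p is None:
                raise ValueError(f"implanted event {event!r} not in catalog")
            if p * rr > 1:
                raise ValueError(
                    f"RR={rr} forces P({event!r}|{drug!r}) = {p * rr:.3f} > 1")


@dataclass
class GwasSimConfig:
    """Causal model for paired exposure/outcome summary statistics."""
    n_snps: int = 30
    true_beta: float = 0.5
    gamma_mean: float = 0.2     # exposure effect-size distribution (normal)
    gamma_sd: float = 0.05
    se_x: float = 0.01
    se_y: float = 0.05
    pleiotropy_mean: float = 0.0
    pleiotropy_sd: float = 0.0
    het_sd: float = 0.0         # extra outcome noise not in the reported SE
    maf_range: tuple[float, float] = (0.05, 0.5)
    swap_fraction: float = 0.2  # outcome rows emitted with alleles swapped
    palindromic_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_snps < 3:
            raise ValueError("n_snps must be at least 3")
        for name in ("gamma_sd", "se_x", "se_y", "pleiotropy_sd", "het_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


# ---------------------------------------------------------------------------
# spontaneous reports


def _event_probs(cfg: ReportSimConfig, drug: str) -> np.ndarray:
    """Per-PT inclusion probability for a report of the given drug."""
    rr = {(d, e): r for d, e, r in cfg.implanted_signals}
    return np.array([min(1.0, p * rr.get((drug, pt), 1.0))
                     for pt, _, p in cfg.event_catalog])


def _expected_from_counts(cfg: ReportSimConfig, n_by_drug: dict[str, float],
                          drug: str, event: str):
    """Expected pair-count table given per-drug report counts.

    Follows the exact sampling scheme of :func:`simulate_reports`
    (independent Bernoulli events with a forced draw for empty reports),
    so the observed table is a multinomial perturbation of this one.
    """
    from .contingency import ContingencyTable

    names = [pt for pt, _, _ in cfg.event_catalog]
    j = names.index(event)
    a = b = c = d = 0.0
    for dg, _ in cfg.drug_catalog:
        probs = _event_probs(cfg, dg)
        p0 = float(np.prod(1 - probs))       # P(no event drawn)
        q = probs / probs.sum()              # forced-draw distribution
        e_event = probs[j] + p0 * q[j]       # expected pairs with the event
        e_total = probs.sum() + p0           # expected pairs per report
        n_d = n_by_drug.get(dg, 0.0)
        if dg == drug:
            a += n_d * e_event
            b += n_d * (e_total - e_event)
        else:
            c += n_d * e_event
            d += n_d * (e_total - e_event)
    return ContingencyTable(round(a), round(b), round(c), round(d))


def expected_table(cfg: ReportSimConfig, drug: str, event: str):
    """A-priori expected 2×2 table (before duplicate/deletion artefacts)."""
    n_by_drug = {dg: cfg.n_reports * p for dg, p in cfg.drug_catalog}
    return _expected_from_counts(cfg, n_by_drug, drug, event)


def _sample_onset(rng: np.random.Generator, cfg: ReportSimConfig, size: int) -> np.ndarray:
    lows, highs, weights = zip(*cfg.onset_mixture)
    w = np.asarray(weights, float)
    comp = rng.choice(len(w), size=size, p=w / w.sum())
    lo = np.asarray(lows)[comp]
    hi = np.asarray(highs)[comp]
    return rng.integers(lo, hi + 1)


def _dates_from_days(days: np.ndarray) -> np.ndarray:
    base = np.datetime64("2004-01-01")
    dt = base + days.astype("timedelta64[D]")
    s = np.datetime_as_string(dt, unit="D")
    return np.char.replace(s, "-", "").astype(np.int64)


def simulate_reports(cfg: ReportSimConfig = ReportSimConfig(),
                     out_dir: str | Path | None = None,
                     ) -> tuple[ReportStore, dict]:
    """Generate a raw report store (with planted artefacts) and its truth.

    The store contains duplicate report versions (same caseid, older
    FDA_DT, distinct primaryid) at ``duplicate_rate``, cases flagged for
    deletion at ``deletion_rate``, and reaction PTs written in legacy
    spellings at ``legacy_spelling_rate``.  The truth record holds the
    deletion list, duplicate case groups, the PT remap table, and the
    expected contingency table of every implanted signal *after perfect
    cleaning*.  When ``out_dir`` is given the packet is also written as
    '$'-delimited ASCII plus ``deleted_cases.txt``, ``pt_remap.tsv`` and
    ``truth.json``.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_reports
    drugs, dprobs = zip(*cfg.drug_catalog)
    dprobs = np.asarray(dprobs, float)
    dprobs = dprobs / dprobs.sum()
    pts = [pt for pt, _, _ in cfg.event_catalog]
    soc_map = {pt: soc for pt, soc, _ in cfg.event_catalog}

    drug_idx = rng.choice(len(drugs), size=n, p=dprobs)
    probs_by_drug = {i: _event_probs(cfg, drugs[i]) for i in range(len(drugs))}

    # demographics
    u = rng.random(n)
    age = np.full(n, np.nan)
    edges = np.cumsum([w for _, _, w in _AGE_BINS])
    bin_of = np.searchsorted(edges, u)
    for k, (lo, hi, _) in enumerate(_AGE_BINS):
        m = bin_of == k
        age[m] = np.floor(rng.uniform(lo, hi, m.sum()))
    sex = rng.choice(["M", "F"], size=n, p=[0.55, 0.45])
    rep_codes, rep_p = zip(*_REPORTERS)
    reporter = rng.choice(rep_codes, size=n, p=np.asarray(rep_p) / sum(rep_p))
    c_codes, c_p = zip(*_COUNTRIES)
    country = rng.choice(c_codes, size=n, p=np.asarray(c_p) / sum(c_p))
    serious = rng.random(n) < cfg.serious_prob
    o_codes, o_p = zip(*_OUTCOME_CODES)
    outcome = np.where(serious,
                       rng.choice(o_codes, size=n, p=np.asarray(o_p) / sum(o_p)),
                       "")

    y0, y1 = cfg.year_range
    span_days = (np.datetime64(f"{y1}-12-31") - np.datetime64(f"{y0}-01-01")).astype(int)
    recv_offset = rng.integers(0, span_days + 1, size=n)
    fda_dt = _dates_from_days(recv_offset)
    onset = _sample_onset(rng, cfg, n)
    start_dt = _dates_from_days(np.maximum(recv_offset - onset, 0))

    demo_rows, drug_rows, reac_rows, ther_rows, outc_rows = [], [], [], [], []
    dup_groups: dict[str, list[str]] = {}
    next_pid = 1

    for i in range(n):
        caseid = f"C{i + 1:07d}"
        dg = drugs[drug_idx[i]]
        probs = probs_by_drug[drug_idx[i]]
        hit = rng.random(len(pts)) < probs
        if not hit.any():
            hit[rng.choice(len(pts), p=probs / probs.sum())] = True
        events = [pts[k] for k in np.flatnonzero(hit)]
        written = [LEGACY_SPELLINGS[e]
                   if e in LEGACY_SPELLINGS and rng.random() < cfg.legacy_spelling_rate
                   else e
                   for e in events]

        versions = [(f"P{next_pid:08d}", int(fda_dt[i]))]
        next_pid += 1
        if rng.random() < cfg.duplicate_rate:
            # superseded version: earlier receive date, its own primaryid
            old_dt = _dates_from_days(np.array([max(recv_offset[i] - int(rng.integers(1, 90)), 0)]))[0]
            versions.insert(0, (f"P{next_pid:08d}", int(old_dt)))
            next_pid += 1
            dup_groups[caseid] = [v[0] for v in versions]

        for pid, dt in versions:
            demo_rows.append((pid, caseid, dt,
                              "" if np.isnan(age[i]) else int(age[i]),
                              sex[i], reporter[i], country[i],
                              "Y" if serious[i] else "N"))
            drug_rows.append((pid, caseid, 1, "PS", dg))
            ther_rows.append((pid, caseid, 1, int(start_dt[i])))
            for ev in written:
                reac_rows.append((pid, caseid, ev))
            if outcome[i]:
                for code in outcome[i].split(";"):
                    outc_rows.append((pid, caseid, code))

    demo = pd.DataFrame(demo_rows, columns=["primaryid", "caseid", "fda_dt", "age",
                                            "sex", "occp_cod", "reporter_country",
                                            "serious"])
    demo["age"] = pd.to_numeric(demo["age"], errors="coerce")
    demo["fda_dt"] = demo["fda_dt"].astype("Int64")
    store = ReportStore(
        demo=demo,
        drug=pd.DataFrame(drug_rows, columns=["primaryid", "caseid", "drug_seq",
                                              "role_cod", "drugname"]),
        reac=pd.DataFrame(reac_rows, columns=["primaryid", "caseid", "pt"]),
        ther=pd.DataFrame(ther_rows, columns=["primaryid", "caseid",
                                              "dsg_drug_seq", "start_dt"]),
        outc=pd.DataFrame(outc_rows, columns=["primaryid", "caseid", "outc_cod"]),
    )

    all_cases = [f"C{i + 1:07d}" for i in range(n)]
    deleted = sorted(np.asarray(all_cases)[rng.random(n) < cfg.deletion_rate].tolist())

    remap = pd.DataFrame(
        [(old, new, soc_map[new]) for new, old in LEGACY_SPELLINGS.items()]
        + [(pt, pt, soc_map[pt]) for pt in pts],
        columns=["old_pt", "current_pt", "soc"],
    ).sort_values("old_pt").reset_index(drop=True)

    n_surviving = n - len(deleted)
    # expected tables conditional on the realized per-drug survivor counts,
    # so the observed (cleaned) tables deviate only by event-draw noise
    deleted_set = set(deleted)
    surv_by_drug: dict[str, float] = {}
    for i in range(n):
        if f"C{i + 1:07d}" not in deleted_set:
            dg = drugs[drug_idx[i]]
            surv_by_drug[dg] = surv_by_drug.get(dg, 0) + 1
    truth = {
        "seed": cfg.seed,
        "n_reports": n,
        "n_after_deletion": n_surviving,
        "deleted_case_ids": deleted,
        "duplicate_case_groups": dup_groups,
        "implanted_signals": [
            {"drug": d, "event": e, "rr": r,
             "expected_table": list(
                 _expected_from_counts(cfg, surv_by_drug, d, e).as_tuple())}
            for d, e, r in cfg.implanted_signals
        ],
        "drug_of_case": {f"C{i + 1:07d}": drugs[drug_idx[i]] for i in range(n)},
    }

    if out_dir is not None:
        write_report_files(store, deleted, remap, truth, out_dir)
    return store, truth


def write_report_files(store: ReportStore, deleted: list[str],
                       remap: pd.DataFrame, truth: dict,
                       out_dir: str | Path) -> None:
    """Write the packet as '$'-delimited ASCII plus sidecar files."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name in ("demo", "drug", "reac", "ther", "outc"):
        df = getattr(store, name).copy()
        if name == "demo":
            df["age"] = df["age"].map(lambda v: "" if pd.isna(v) else str(int(v)))
        df.to_csv(out / f"{name.upper()}.txt", sep="$", index=False)
    (out / "deleted_cases.txt").write_text("".join(c + "\n" for c in deleted))
    remap.to_csv(out / "pt_remap.tsv", sep="\t", index=False)
    (out / "truth.json").write_text(json.dumps(truth, indent=1, sort_keys=True))


# ---------------------------------------------------------------------------
# GWAS summary statistics

_ALLELE_PAIRS = (("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"))
_PALINDROMIC_PAIRS = (("A", "T"), ("C", "G"))


def simulate_gwas_pair(cfg: GwasSimConfig = GwasSimConfig(),
                       out_dir: str | Path | None = None,
                       ) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Paired exposure/outcome summary statistics under a known causal model.

    Per variant j:  ``gamma_j ~ N(gamma_mean, gamma_sd²)`` is the true
    exposure effect; the observed ``beta_x_j`` adds N(0, se_x²) noise;
    the true outcome effect is ``true_beta·gamma_j + alpha_j`` with
    pleiotropy ``alpha_j ~ N(pleiotropy_mean, pleiotropy_sd²)``, and the
    observed ``beta_y_j`` adds N(0, se_y² + het_sd²) noise while the
    *reported* outcome SE stays ``se_y`` (het_sd models unacknowledged
    heterogeneity).  A fraction of outcome rows are emitted with their
    alleles swapped and beta negated, to be undone by harmonization.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_snps
    gamma = rng.normal(cfg.gamma_mean, cfg.gamma_sd, n)
    alpha = rng.normal(cfg.pleiotropy_mean, cfg.pleiotropy_sd, n)
    beta_x = gamma + rng.normal(0.0, cfg.se_x, n)
    beta_y = cfg.true_beta * gamma + alpha + rng.normal(
        0.0, np.sqrt(cfg.se_y**2 + cfg.het_sd**2), n)

    n_pal = int(round(cfg.palindromic_fraction * n))
    pair_idx = rng.integers(0, len(_ALLELE_PAIRS), n)
    ea = np.array([_ALLELE_PAIRS[k][0] for k in pair_idx])
    oa = np.array([_ALLELE_PAIRS[k][1] for k in pair_idx])
    if n_pal:
        which = rng.choice(n, size=n_pal, replace=False)
        pal_idx = rng.integers(0, len(_PALINDROMIC_PAIRS), n_pal)
        ea[which] = [_PALINDROMIC_PAIRS[k][0] for k in pal_idx]
        oa[which] = [_PALINDROMIC_PAIRS[k][1] for k in pal_idx]

    eaf = rng.uniform(*cfg.maf_range, n)
    from scipy import stats as sps
    pval_x = 2 * sps.norm.sf(np.abs(beta_x / cfg.se_x))

    base = dict(
        snp=[f"rs{100000 + j}" for j in range(n)],
        chr=(np.arange(n) % 22) + 1,
        pos=2_000_000 * (np.arange(n) // 22 + 1) + np.arange(n) * 5000,
        eaf=eaf,
    )
    exposure = pd.DataFrame({
        **base, "effect_allele": ea, "other_allele": oa,
        "beta": beta_x, "se": np.full(n, cfg.se_x), "pval": pval_x,
    })
    swapped = rng.random(n) < cfg.swap_fraction
    outcome = pd.DataFrame({
        **base,
        "effect_allele": np.where(swapped, oa, ea),
        "other_allele": np.where(swapped, ea, oa),
        "eaf": np.where(swapped, 1 - eaf, eaf),
        "beta": np.where(swapped, -beta_y, beta_y),
        "se": np.full(n, cfg.se_y),
        "pval": 2 * sps.norm.sf(np.abs(beta_y / cfg.se_y)),
    })
    cols = ["snp", "effect_allele", "other_allele", "eaf", "beta", "se",
            "pval", "chr", "pos"]
    exposure, outcome = exposure[cols], outcome[cols]

    truth = {
        "seed": cfg.seed,
        "true_beta": cfg.true_beta,
        "gamma": gamma.tolist(),
        "alpha": alpha.tolist(),
        "swapped_snps": [s for s, f in zip(base["snp"], swapped) if f],
        "palindromic_snps": [s for s, e, o in zip(base["snp"], ea, oa)
                             if (e, o) in _PALINDROMIC_PAIRS
                             or (o, e) in _PALINDROMIC_PAIRS],
        "significant_snps": [s for s, p in zip(base["snp"], pval_x) if p < 5e-8],
    }
    if out_dir is not None:
        write_gwas_files(exposure, outcome, truth, out_dir)
    return exposure, outcome, truth


def write_gwas_files(exposure: pd.DataFrame, outcome: pd.DataFrame,
                     truth: dict, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    exposure.to_csv(out / "exposure.tsv", sep="\t", index=False)
    outcome.to_csv(out / "outcome.tsv", sep="\t", index=False)
    (out / "truth.json").write_text(json.dumps(truth, indent=1, sort_keys=True))
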