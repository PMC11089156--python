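"""Reading and cleaning FAERS-style quarterly ASCII report tables.

The FDA Adverse Event Reporting System publishes quarterly packets of
'$'-delimited ASCII tables: DEMO (one row per report version), DRUG,
REAC (MedDRA preferred terms), THER (therapy dates) and OUTC (outcome
codes), plus — since 2019Q1 — a list of case ids to delete.  This module
reads such packets into a :class:`ReportStore` of pandas DataFrames and
applies the FDA-recommended cleaning rules:

1. **Deduplicate**: among rows sharing a CASEID keep the one with the
   highest FDA_DT (receive date); ties break by the highest PRIMARYID.
2. **Delete**: after deduplication, drop any case named on the deletion
   lists (lists from all provided quarters are unioned).
3. **Remap PTs**: reaction preferred terms are normalised against a
   user-supplied PT→(current PT, SOC) table, since the MedDRA dictionary
   revises term spellings and SOC assignments twice a year.  MedDRA is
   licensed, so the mapping is always caller-provided.

Dates are kept as integer YYYYMMDD; unparseable dates become missing
with a logged warning rather than failing the load.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "FaersDialect",
    "ReportStore",
    "read_quarter",
    "read_deletion_list",
    "read_pt_remap",
    "deduplicate",
    "apply_deletion_list",
    "remap_pt",
    "clean_store",
    "match_drug_cases",
]

#: canonical column sets; the first names are mandatory in each table
_TABLE_COLUMNS = {
    "demo": ["primaryid", "caseid", "fda_dt", "age", "sex", "occp_cod",
             "reporter_country", "serious"],
    "drug": ["primaryid", "caseid", "drug_seq", "role_cod", "drugname"],
    "reac": ["primaryid", "caseid", "pt"],
    "ther": ["primaryid", "caseid", "dsg_drug_seq", "start_dt"],
    "outc": ["primaryid", "caseid", "outc_cod"],
}
_MANDATORY = {
    "demo": ["primaryid", "caseid"],
    "drug": ["primaryid", "caseid", "drugname"],
    "reac": ["primaryid", "caseid", "pt"],
    "ther": ["primaryid", "caseid"],
    "outc": ["primaryid", "caseid"],
}


@dataclass(frozen=True)
class FaersDialect:
    """File-format knobs for a quarterly packet."""
    delimiter: str = "$"
    encoding: str = "utf-8"
    #: glob patterns per table, tried in order within the quarter directory
    patterns: dict = field(default_factory=lambda: {
        t: [f"{t.upper()}*.txt", f"{t}*.txt"] for t in _TABLE_COLUMNS
    })


@dataclass
class ReportStore:
    """Report database as five aligned DataFrames keyed by primaryid/caseid."""
    demo: pd.DataFrame
    drug: pd.DataFrame
    reac: pd.DataFrame
    ther: pd.DataFrame
    outc: pd.DataFrame

    @property
    def n_reports(self) -> int:
        return len(self.demo)

    def restrict(self, primaryids: pd.Series | set) -> "ReportStore":
        """New store containing only the given report versions."""
        keep = set(primaryids)
        return ReportStore(
            demo=self.demo[self.demo["primaryid"].isin(keep)].reset_index(drop=True),
            drug=self.drug[self.drug["primaryid"].isin(keep)].reset_index(drop=True),
            reac=self.reac[self.reac["primaryid"].isin(keep)].reset_index(drop=True),
            ther=self.ther[self.ther["primaryid"].isin(keep)].reset_index(drop=True),
            outc=self.outc[self.outc["primaryid"].isin(keep)].reset_index(drop=True),
        )


def _parse_dates(s: pd.Series, table: str, col: str) -> pd.Series:
    """YYYYMMDD strings -> nullable Int64; invalid dates become <NA>."""
    num = pd.to_numeric(s, errors="coerce")
    parsed = pd.to_datetime(num.astype("Int64").astype(str), format="%Y%m%d",
                            errors="coerce")
    out = num.astype("Int64").where(parsed.notna())
    bad = int((s.notna() & (s.astype(str).str.strip() != "") & out.isna()).sum())
    if bad:
        logger.warning("%s.%s: %d unparseable date(s) set to missing", table, col, bad)
    return out


def _read_table(path: Path, table: str, dialect: FaersDialect) -> pd.DataFrame:
    df = pd.read_csv(path, sep=dialect.delimiter, dtype=str,
                     encoding=dialect.encoding, engine="python",
                     skipinitialspace=True)
    df.columns = [c.strip().lower() for c in df.columns]
    for col in _MANDATORY[table]:
        if col not in df.columns:
            raise ValueError(f"{path.name}: missing mandatory column {col!r}")
    for col in _TABLE_COLUMNS[table]:
        if col not in df.columns:
            df[col] = pd.NA
    if "fda_dt" in df.columns and table == "demo":
        df["fda_dt"] = _parse_dates(df["fda_dt"], table, "fda_dt")
    if table == "ther":
        df["start_dt"] = _parse_dates(df["start_dt"], table, "start_dt")
    if table == "demo":
        df["age"] = pd.to_numeric(df["age"], errors="coerce")
    logger.info("%s: read %d rows", path.name, len(df))
    return df[_TABLE_COLUMNS[table]]


def read_quarter(dir_path: str | Path, dialect: FaersDialect = FaersDialect()) -> ReportStore:
    """Read one quarterly packet directory into a raw (uncleaned) store."""
    dir_path = Path(dir_path)
    frames = {}
    for table in _TABLE_COLUMNS:
        found = None
        for pat in dialect.patterns[table]:
            hits = sorted(dir_path.glob(pat))
            if hits:
                found = hits[0]
                break
        if found is None:
            raise FileNotFoundError(f"no {table.upper()} file in {dir_path}")
        frames[table] = _read_table(found, table, dialect)
    return ReportStore(**frames)


def read_quarters(dir_paths, dialect: FaersDialect = FaersDialect()) -> ReportStore:
    """Concatenate several quarterly packets into one raw store."""
    stores = [read_quarter(p, dialect) for p in dir_paths]
    return ReportStore(**{
        t: pd.concat([getattr(s, t) for s in stores], ignore_index=True)
        for t in _TABLE_COLUMNS
    })


def read_deletion_list(path: str | Path) -> set[str]:
    """One case id per line; blank lines ignored."""
    with open(path) as fh:
        return {line.strip() for line in fh if line.strip()}


def read_pt_remap(path: str | Path) -> pd.DataFrame:
    """PT remap table: TSV with columns old_pt, current_pt[, soc]."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    df.columns = [c.strip().lower() for c in df.columns]
    for col in ("old_pt", "current_pt"):
        if col not in df.columns:
            raise ValueError(f"remap table missing column {col!r}")
    if "soc" not in df.columns:
        df["soc"] = "UNMAPPED-SOC"
    key = df["old_pt"].str.strip().str.casefold()
    if key.duplicated().any():
        dups = df.loc[key.duplicated(), "old_pt"].tolist()
        raise ValueError(f"remap table maps these PTs more than once: {dups}")
    return df


def _pid_sort_key(pid: pd.Series) -> pd.Series:
    """Numeric primaryid order when all parse as integers, else lexicographic."""
    num = pd.to_numeric(pid, errors="coerce")
    if num.notna().all():
        return num
    return pid.astype(str)


def deduplicate(demo: pd.DataFrame) -> pd.DataFrame:
    """Keep, per CASEID, the row maximising (FDA_DT, PRIMARYID).

    A missing FDA_DT sorts below every real date, so an undated report
    survives only when no dated duplicate exists.  Idempotent; the
    output has exactly one row per distinct caseid.
    """
    if demo.empty:
        return demo.copy()
    work = demo.assign(
        _dt=demo["fda_dt"].fillna(-1).astype("int64"),
        _pid=_pid_sort_key(demo["primaryid"]),
    )
    work = work.sort_values(["caseid", "_dt", "_pid"], kind="mergesort")
    kept = work.groupby("caseid", sort=False).tail(1)
    return kept.drop(columns=["_dt", "_pid"]).reset_index(drop=True)


def apply_deletion_list(demo: pd.DataFrame, deleted_case_ids: set[str]) -> pd.DataFrame:
    """Drop rows whose caseid appears on the (unioned) deletion lists.

    Applied after deduplication, per the FDA cleaning order.  Ids absent
    from the data are ignored.
    """
    if not deleted_case_ids:
        return demo.copy()
    mask = demo["caseid"].isin(deleted_case_ids)
    n_removed = int(mask.sum())
    logger.info("deletion list: removed %d of %d reports", n_removed, len(demo))
    missing = len(deleted_case_ids) - demo["caseid"][mask].nunique()
    if missing:
        logger.debug("deletion list: %d id(s) not present in data", missing)
    return demo[~mask].reset_index(drop=True)


def remap_pt(store: ReportStore, remap: pd.DataFrame) -> ReportStore:
    """Attach current PT spellings and SOCs to every reaction.

    Matching is on the trimmed, case-folded PT.  Unmapped PTs pass
    through unchanged with SOC ``"UNMAPPED-SOC"``.
    """
    reac = store.reac.copy()
    key = reac["pt"].astype(str).str.strip().str.casefold()
    lut = remap.set_index(remap["old_pt"].str.strip().str.casefold())
    reac["pt_current"] = key.map(lut["current_pt"]).fillna(reac["pt"].astype(str).str.strip())
    reac["soc"] = key.map(lut["soc"]).fillna("UNMAPPED-SOC")
    return replace_reac(store, reac)


def replace_reac(store: ReportStore, reac: pd.DataFrame) -> ReportStore:
    return ReportStore(store.demo, store.drug, reac, store.ther, store.outc)


def clean_store(store: ReportStore, deleted_case_ids: set[str] = frozenset(),
                remap: pd.DataFrame | None = None) -> ReportStore:
    """Full cleaning pipeline: dedup → deletion list → PT remap."""
    demo = apply_deletion_list(deduplicate(store.demo), set(deleted_case_ids))
    out = store.restrict(demo["primaryid"])
    out.demo = demo.reset_index(drop=True)
    if remap is not None:
        out = remap_pt(out, remap)
    return out


def match_drug_cases(drug: pd.DataFrame, name: str,
                     synonyms: tuple[str, ...] = ()) -> set[str]:
    """Caseids whose DRUG rows mention the drug (or a synonym).

    Case-insensitive substring match on the drug-name field, so
    combination-product strings like "ATORVASTATIN CALCIUM" match.
    """
    names = [name, *synonyms]
    hay = drug["drugname"].astype(str).str.casefold()
    mask = pd.Series(False, index=drug.index)
    for nm in names:
        mask |= hay.str.contains(nm.strip().casefold(), regex=False)
    return set(drug.loc[mask, "caseid"])
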