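import numpy as np
import pandas as pd
import pytest

from pharmsignal import faers_io, synthetic
from pharmsignal.contingency import reconstruct_table_from_stats

# anchors of the atorvastatin / erectile-dysfunction signal table:
# drug-event pair count, drug total, published ROR and EBGM
ED_A = 345
ED_AB_TOTAL = 227263
ED_ROR = 3.707078559
ED_EBGM = 3.656567867


@pytest.fixture(scope="session")
def ed_table():
    """The atorvastatin-ED 2x2 table recovered from published statistics."""
    return reconstruct_table_from_stats(ED_A, ED_AB_TOTAL, ED_ROR, ED_EBGM)


@pytest.fixture(scope="session")
def report_fixture(tmp_path_factory):
    """One synthetic report packet on disk plus its in-memory truth."""
    out = tmp_path_factory.mktemp("packet")
    cfg = synthetic.ReportSimConfig(seed=7)
    store, truth = synthetic.simulate_reports(cfg, out_dir=out)
    return {"cfg": cfg, "store": store, "truth": truth, "dir": out}


@pytest.fixture(scope="session")
def cleaned_store(report_fixture):
    d = report_fixture["dir"]
    raw = faers_io.read_quarter(d)
    deleted = faers_io.read_deletion_list(d / "deleted_cases.txt")
    remap = faers_io.read_pt_remap(d / "pt_remap.tsv")
    return faers_io.clean_store(raw, deleted, remap)


@pytest.fixture(scope="session")
def gwas_fixture():
    cfg = synthetic.GwasSimConfig(seed=11)
    exposure, outcome, truth = synthetic.simulate_gwas_pair(cfg)
    return {"cfg": cfg, "exposure": exposure, "outcome": outcome, "truth": truth}


def demo_frame(rows):
    """Build a DEMO DataFrame from (primaryid, caseid, fda_dt) triples."""
    df = pd.DataFrame(rows, columns=["primaryid", "caseid", "fda_dt"])
    for col in ("age", "sex", "occp_cod", "reporter_country", "serious"):
        df[col] = pd.NA
    df["fda_dt"] = df["fda_dt"].astype("Int64")
    df["age"] = pd.to_numeric(df["age"], errors="coerce")
    return df


def random_tables(rng: np.random.Generator, n: int, low: int = 1, high: int = 500):
    """Random strictly-positive 2x2 tables for property tests."""
    from pharmsignal.contingency import ContingencyTable

    cells = rng.integers(low, high, size=(n, 4))
    return [ContingencyTable(*map(int, row)) for row in cells]
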