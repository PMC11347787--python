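import datetime as dt

import pytest

from toxsig.reports import DrugEntry, ReportRecord, ReportSet
from toxsig.simulate import SyntheticConfig


def make_report(report_id, drug="selumetinib", pts=("rash",), role="primary suspect",
                **kw):
    return ReportRecord(report_id=report_id,
                        drug_entries=(DrugEntry(drug, role),),
                        pts=tuple(pts), **kw)


@pytest.fixture
def toy_reports():
    """Four reports covering every cell of the drug x PT table exactly once."""
    return ReportSet([
        make_report("r1", drug="drug_x", pts=("headache",)),
        make_report("r2", drug="drug_x", pts=("nausea",)),
        make_report("r3", drug="drug_y", pts=("headache",)),
        make_report("r4", drug="drug_y", pts=("nausea",)),
    ])


@pytest.fixture
def mixed_reports():
    """Small heterogeneous set with demographics, multi-PT rows and unknowns."""
    return ReportSet([
        make_report("r1", pts=("rash", "alopecia"), sex="male", age_years=9.0,
                    country="US", received_date=dt.date(2022, 5, 1),
                    outcome="hospitalization"),
        make_report("r2", pts=("diarrhoea",), sex="female", age_years=14.0,
                    country="FR", received_date=dt.date(2023, 1, 15),
                    outcome="non-serious"),
        make_report("r3", drug="other drug", pts=("rash",), sex="male",
                    country="US", received_date=dt.date(2023, 7, 2)),
    ])


@pytest.fixture
def small_vocab_config():
    """Small-vocabulary generator config whose ground truth is enumerable."""
    return SyntheticConfig(
        n_reports=800,
        drug_weights={"DRUG_A": 2.0, "DRUG_B": 1.0, "DRUG_C": 1.0},
        pt_baseline_weights={f"PT_{i:02d}": 1.0 for i in range(1, 9)},
        implanted_signals=[("DRUG_A", "PT_01", 4.0)],
        events_per_report_mean=2.5,
        seed=11,
    )


@pytest.fixture
def power_config():
    """Wider-vocabulary config used for sensitivity / null-rate studies."""
    return SyntheticConfig(
        n_reports=600,
        drug_weights={f"DRUG_{c}": 1.0 for c in "ABCDE"},
        pt_baseline_weights={f"PT_{i:02d}": 1.0 for i in range(1, 31)},
        implanted_signals=[("DRUG_A", "PT_01", 10.0)],
        events_per_report_mean=2.0,
        seed=5,
    )
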