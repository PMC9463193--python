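import pytest

from cvclm.registry import CVCRecord, Cohort


def make_record(record_id="R1", center_id="C1", age_years=60, sex="male",
                disease="AML", insertion_site="jugular", antimicrobial_coated=False,
                chg_dressing=False, neutropenic_at_insertion=False, dwell_days=14,
                crbsi_class="none", crbsi_onset_day=None, pathogen=None,
                platelets_d7=None, platelets_d14=None, platelets_d21=None):
    return CVCRecord(
        record_id=record_id, center_id=center_id, age_years=age_years, sex=sex,
        disease=disease, insertion_site=insertion_site,
        antimicrobial_coated=antimicrobial_coated, chg_dressing=chg_dressing,
        neutropenic_at_insertion=neutropenic_at_insertion, dwell_days=dwell_days,
        crbsi_class=crbsi_class, crbsi_onset_day=crbsi_onset_day, pathogen=pathogen,
        platelets_d7=platelets_d7, platelets_d14=platelets_d14,
        platelets_d21=platelets_d21)


@pytest.fixture
def record_factory():
    return make_record


@pytest.fixture
def small_cohort():
    """Eight records in one center with a mix of events and dwell times."""
    return Cohort(records=[
        make_record("R1", dwell_days=5),
        make_record("R2", dwell_days=20, crbsi_class="definite",
                    crbsi_onset_day=16, pathogen="CoNS", platelets_d7=50000,
                    platelets_d14=20000),
        make_record("R3", dwell_days=10, crbsi_class="probable",
                    crbsi_onset_day=9, pathogen="Candida", platelets_d7=80000),
        make_record("R4", dwell_days=14, crbsi_class="definite",
                    crbsi_onset_day=14, pathogen="CoNS", platelets_d7=30000,
                    platelets_d14=15000),
        make_record("R5", dwell_days=30, platelets_d7=60000, platelets_d14=25000,
                    platelets_d21=40000),
        make_record("R6", dwell_days=7, platelets_d7=90000),
        make_record("R7", dwell_days=3),
        make_record("R8", dwell_days=22, crbsi_class="definite",
                    crbsi_onset_day=8, pathogen="Enterobacteriaceae"),
    ])
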