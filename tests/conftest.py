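import pytest
from hypothesis import HealthCheck, settings

from rorsignal import DrugMention, ReportRecord

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def make_report(report_id, case_id=None, version=20170101, drugs=(), events=()):
    """Terse report constructor for fixtures."""
    return ReportRecord(
        report_id=str(report_id),
        case_id=str(case_id if case_id is not None else report_id),
        version_marker=version,
        drugs=[DrugMention(verbatim_name=d) for d in drugs],
        events=list(events),
    )


@pytest.fixture
def toy_reports():
    """Six reports: 2 exposed cases, 1 exposed non-case, 1 unexposed case,
    2 unexposed non-cases, for the single drug 'edoxaban' and event
    'tubulointerstitial nephritis'."""
    tin = "Tubulointerstitial nephritis"
    return [
        make_report(1, drugs=["edoxaban"], events=[tin]),
        make_report(2, drugs=["edoxaban", "aspirin"], events=["Nausea", tin]),
        make_report(3, drugs=["edoxaban"], events=["Nausea"]),
        make_report(4, drugs=["warfarin"], events=[tin]),
        make_report(5, drugs=["warfarin"], events=["Rash"]),
        make_report(6, drugs=[], events=[]),
    ]


def write_faers_files(tmp_path, demo_rows, drug_rows, reac_rows):
    """Write minimal $-delimited DEMO/DRUG/REAC files; returns their paths."""
    demo = tmp_path / "DEMO.txt"
    drug = tmp_path / "DRUG.txt"
    reac = tmp_path / "REAC.txt"
    demo.write_text(
        "primaryid$caseid$fda_dt\n"
        + "".join(f"{p}${c}${d}\n" for p, c, d in demo_rows)
    )
    drug.write_text(
        "primaryid$drugname\n" + "".join(f"{p}${n}\n" for p, n in drug_rows)
    )
    reac.write_text("primaryid$pt\n" + "".join(f"{p}${t}\n" for p, t in reac_rows))
    return demo, drug, reac
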