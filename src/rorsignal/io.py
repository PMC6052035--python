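"""Reading and writing the FAERS-dialect tables and analysis configuration.

The on-disk dialect is a strict subset of the FAERS quarterly ASCII
layout: ``$``-delimited text files with a header row.  Only the columns
the pipeline needs are required — DEMO ``primaryid, caseid, fda_dt``,
DRUG ``primaryid, drugname``, REAC ``primaryid, pt`` — and extra columns
are ignored by name.  There is no quoting or escaping: a field that
itself contains ``$`` is a fatal parse error.

Also here: the brand/synonym -> generic drug-name mapping table (2-column
TSV), the YAML analysis configuration, and the results TSV writer.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

from .stats import EventDefinition, ExposureDefinition, RorResult

__all__ = [
    "FaersDataError",
    "DrugMention",
    "ReportRecord",
    "ReadResult",
    "DrugMap",
    "AnalysisConfig",
    "read_reports",
    "write_reports",
    "read_drug_map",
    "read_analysis_config",
    "write_results",
    "DELIMITER",
]

DELIMITER = "$"

#: two-sided 95% standard-normal quantile used for Woolf intervals
DEFAULT_Z_QUANTILE = 1.959964

DEMO_COLUMNS = ("primaryid", "caseid", "fda_dt")
DRUG_COLUMNS = ("primaryid", "drugname")
REAC_COLUMNS = ("primaryid", "pt")


class FaersDataError(ValueError):
    """Malformed input data (parse errors, schema violations, conflicts)."""


@dataclass(slots=True)
class DrugMention:
    """One drug row of a report: the name as reported, plus normalization state."""

    verbatim_name: str
    normalized_name: str | None = None
    mapped: bool = False

    def __post_init__(self) -> None:
        if not self.verbatim_name.strip():
            raise FaersDataError("drug mention with empty verbatim name")
        if self.normalized_name is not None and not self.normalized_name:
            raise FaersDataError("normalized drug name must be non-empty when set")


@dataclass(slots=True)
class ReportRecord:
    """One spontaneous adverse-event report (one version of a case).

    ``report_id`` is unique per version (FAERS primaryid); ``case_id`` is
    shared by all versions of the same case; ``version_marker`` is the
    YYYYMMDD integer date stamp (FAERS fda_dt) that orders versions.
    """

    report_id: str
    case_id: str
    version_marker: int
    drugs: list[DrugMention] = field(default_factory=list)
    events: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.report_id:
            raise FaersDataError("report with empty report_id")
        if self.version_marker < 0:
            raise FaersDataError(
                f"report {self.report_id}: negative version_marker {self.version_marker}"
            )


@dataclass(slots=True)
class ReadResult:
    """Loaded report set plus orphan-row accounting.

    DRUG/REAC rows whose primaryid has no DEMO row are counted here and
    not attached to any report.
    """

    reports: list[ReportRecord]
    n_orphan_drug_rows: int = 0
    n_orphan_reac_rows: int = 0


@dataclass(frozen=True)
class DrugMap:
    """Case-folded synonym -> generic-name lookup.

    Every generic appearing as a value also maps to itself, so reports
    already coded with the generic name resolve without a synonym row.
    """

    entries: Mapping[str, str]

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]]) -> "DrugMap":
        entries: dict[str, str] = {}
        conflicts: list[str] = []
        for synonym, generic in pairs:
            key = synonym.strip().casefold()
            value = generic.strip().casefold()
            if not key or not value:
                raise FaersDataError("drug map row with empty synonym or generic")
            if key in entries and entries[key] != value:
                conflicts.append(synonym.strip())
                continue
            entries[key] = value
        if conflicts:
            raise FaersDataError(
                "conflicting drug map entries for: " + ", ".join(sorted(set(conflicts)))
            )
        # self-mapping closure
        for generic in list(entries.values()):
            entries.setdefault(generic, generic)
        return cls(entries=entries)

    def lookup(self, name: str) -> str | None:
        return self.entries.get(name.strip().casefold())

    def __len__(self) -> int:
        return len(self.entries)

    def to_frame(self) -> pd.DataFrame:
        rows = sorted(self.entries.items())
        return pd.DataFrame(rows, columns=["synonym", "generic"])


@dataclass
class AnalysisConfig:
    """Exposure/event definitions plus statistical knobs for the analysis.

    ``z_quantile`` defaults to the two-sided 95% normal quantile.
    ``zero_cell_policy`` is ``undefined`` (zero cell -> no estimate) or
    ``haldane`` (+0.5 to every cell).  ``ci_rounding`` is the number of
    decimals used when writing results.
    """

    exposures: list[ExposureDefinition] = field(default_factory=list)
    events: list[EventDefinition] = field(default_factory=list)
    z_quantile: float = DEFAULT_Z_QUANTILE
    zero_cell_policy: str = "undefined"
    ci_rounding: int = 2

    def __post_init__(self) -> None:
        if self.z_quantile <= 0:
            raise FaersDataError(f"z_quantile must be > 0, got {self.z_quantile}")
        if self.zero_cell_policy not in ("undefined", "haldane"):
            raise FaersDataError(
                f"zero_cell_policy must be 'undefined' or 'haldane', "
                f"got {self.zero_cell_policy!r}"
            )
        if self.ci_rounding < 0:
            raise FaersDataError("ci_rounding must be >= 0")

    @classmethod
    def minimal(cls) -> "AnalysisConfig":
        """Statistical defaults only, for direct table computations."""
        return cls()

    def require_definitions(self) -> None:
        if not self.exposures or not self.events:
            raise FaersDataError(
                "analysis config must define at least one exposure and one event"
            )


def _read_table(path: Path, required: Sequence[str]) -> pd.DataFrame:
    if not path.exists():
        raise FileNotFoundError(f"input file not found: {path}")
    try:
        with warnings.catch_warnings():
            # a row with more fields than the header means an unescaped
            # delimiter inside a field; refuse rather than drop data
            warnings.simplefilter("error", pd.errors.ParserWarning)
            df = pd.read_csv(
                path,
                sep=DELIMITER,
                dtype=str,
                keep_default_na=False,
                encoding="utf-8",
                engine="c",
                index_col=False,
            )
    except (pd.errors.ParserError, pd.errors.ParserWarning) as exc:
        raise FaersDataError(
            f"{path}: malformed {DELIMITER}-delimited table "
            f"(a field containing {DELIMITER!r} cannot be escaped): {exc}"
        ) from exc
    df.columns = [str(c).strip().casefold() for c in df.columns]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FaersDataError(f"{path}: missing required column(s): {', '.join(missing)}")
    return df


def read_reports(demo_path: str | Path, drug_path: str | Path, reac_path: str | Path) -> ReadResult:
    """Load DEMO/DRUG/REAC tables into one ReportRecord per DEMO row.

    Drug and reaction rows are attached by primaryid join, preserving
    file row order within each report.  Orphan DRUG/REAC rows (primaryid
    absent from DEMO) are counted, not attached.
    """
    demo = _read_table(Path(demo_path), DEMO_COLUMNS)
    drug = _read_table(Path(drug_path), DRUG_COLUMNS)
    reac = _read_table(Path(reac_path), REAC_COLUMNS)

    reports: list[ReportRecord] = []
    by_id: dict[str, ReportRecord] = {}
    for pos, (pid, caseid, fda_dt) in enumerate(
        zip(demo["primaryid"], demo["caseid"], demo["fda_dt"])
    ):
        try:
            marker = int(str(fda_dt).strip())
        except ValueError:
            # +2: one for the header line, one for 0-based position
            raise FaersDataError(
                f"{demo_path}: non-integer fda_dt {fda_dt!r} at row {pos + 2}"
            ) from None
        rec = ReportRecord(report_id=str(pid).strip(), case_id=str(caseid).strip(),
                           version_marker=marker)
        if rec.report_id in by_id:
            raise FaersDataError(f"{demo_path}: duplicate primaryid {rec.report_id}")
        reports.append(rec)
        by_id[rec.report_id] = rec

    n_orphan_drug = 0
    for pid, name in zip(drug["primaryid"], drug["drugname"]):
        rec = by_id.get(str(pid).strip())
        if rec is None:
            n_orphan_drug += 1
        else:
            rec.drugs.append(DrugMention(verbatim_name=str(name)))

    n_orphan_reac = 0
    for pid, term in zip(reac["primaryid"], reac["pt"]):
        rec = by_id.get(str(pid).strip())
        if rec is None:
            n_orphan_reac += 1
        else:
            rec.events.append(str(term))

    return ReadResult(reports, n_orphan_drug, n_orphan_reac)


def _check_no_delimiter(value: str, what: str) -> str:
    if DELIMITER in value:
        raise FaersDataError(
            f"{what} contains the field delimiter {DELIMITER!r} and cannot be written: {value!r}"
        )
    return value


def write_reports(reports: Sequence[ReportRecord], out_dir: str | Path) -> dict[str, Path]:
    """Write a report set as the three-file DEMO/DRUG/REAC dialect.

    Returns the paths written, keyed ``demo``/``drug``/``reac``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {"demo": out / "DEMO.txt", "drug": out / "DRUG.txt", "reac": out / "REAC.txt"}

    demo_rows, drug_rows, reac_rows = [], [], []
    for r in reports:
        demo_rows.append(
            (
                _check_no_delimiter(r.report_id, "primaryid"),
                _check_no_delimiter(r.case_id, "caseid"),
                r.version_marker,
            )
        )
        for m in r.drugs:
            drug_rows.append((r.report_id, _check_no_delimiter(m.verbatim_name, "drugname")))
        for t in r.events:
            reac_rows.append((r.report_id, _check_no_delimiter(t, "pt")))

    pd.DataFrame(demo_rows, columns=list(DEMO_COLUMNS)).to_csv(
        paths["demo"], sep=DELIMITER, index=False
    )
    pd.DataFrame(drug_rows, columns=list(DRUG_COLUMNS)).to_csv(
        paths["drug"], sep=DELIMITER, index=False
    )
    pd.DataFrame(reac_rows, columns=list(REAC_COLUMNS)).to_csv(
        paths["reac"], sep=DELIMITER, index=False
    )
    return paths


def read_drug_map(path: str | Path) -> DrugMap:
    """Load the 2-column (synonym, generic) TSV into a DrugMap.

    Keys are case-folded and trimmed; duplicate synonyms mapping to
    different generics are a fatal error; generics gain self-mappings.
    """
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"drug map file not found: {p}")
    df = pd.read_csv(p, sep="\t", dtype=str, keep_default_na=False)
    if df.shape[1] < 2:
        raise FaersDataError(f"{p}: drug map needs 2 tab-separated columns")
    if df.empty:
        raise FaersDataError(f"{p}: drug map has no entries")
    pairs = list(zip(df.iloc[:, 0], df.iloc[:, 1]))
    return DrugMap.from_pairs(pairs)


def read_analysis_config(path: str | Path) -> AnalysisConfig:
    """Load the YAML analysis configuration.

    Schema::

        exposures:           # name -> list of generic drug names
          fxa inhibitors: [edoxaban, rivaroxaban, apixaban]
        events:              # name -> list of reaction terms
          tubulointerstitial nephritis: [tubulointerstitial nephritis]
        z_quantile: 1.959964          # optional
        zero_cell_policy: undefined   # optional: undefined | haldane
        ci_rounding: 2                # optional
    """
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"analysis config not found: {p}")
    with open(p, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise FaersDataError(f"{p}: analysis config must be a YAML mapping")
    try:
        exposures = [
            ExposureDefinition(name=str(name), generics=frozenset(map(str, generics)))
            for name, generics in (raw.get("exposures") or {}).items()
        ]
        events = [
            EventDefinition(name=str(name), terms=frozenset(map(str, terms)))
            for name, terms in (raw.get("events") or {}).items()
        ]
    except (TypeError, ValueError) as exc:
        raise FaersDataError(f"{p}: bad exposure/event definition: {exc}") from exc
    config = AnalysisConfig(
        exposures=exposures,
        events=events,
        z_quantile=float(raw.get("z_quantile", DEFAULT_Z_QUANTILE)),
        zero_cell_policy=str(raw.get("zero_cell_policy", "undefined")),
        ci_rounding=int(raw.get("ci_rounding", 2)),
    )
    config.require_definitions()
    return config


def _fmt(value: float | None, decimals: int) -> str:
    return "NA" if value is None else f"{value:.{decimals}f}"


def results_frame(results: Sequence[RorResult], ci_rounding: int = 2) -> pd.DataFrame:
    """Results as a DataFrame, sorted by (exposure, event), values rendered."""
    if not results:
        raise FaersDataError("no results to write")
    ordered = sorted(results, key=lambda r: (r.exposure_name, r.event_name))
    rows = [
        {
            "exposure": r.exposure_name,
            "event": r.event_name,
            "a": r.table.a,
            "b": r.table.b,
            "c": r.table.c,
            "d": r.table.d,
            "ror": _fmt(r.ror, ci_rounding),
            "ci_lower": _fmt(r.ci_lower, ci_rounding),
            "ci_upper": _fmt(r.ci_upper, ci_rounding),
            "signal": r.signal,
        }
        for r in ordered
    ]
    return pd.DataFrame(rows)


def write_results(results: Sequence[RorResult], path: str | Path, ci_rounding: int = 2) -> None:
    """Write the results TSV (header + one row per exposure-event pair)."""
    df = results_frame(results, ci_rounding)
    df.to_csv(Path(path), sep="\t", index=False)
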