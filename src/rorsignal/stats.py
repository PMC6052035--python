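"""Case/non-case disproportionality statistics.

Implements the reporting odds ratio (ROR) for spontaneous-report data.
For one exposure (a drug or drug class) and one adverse event, every
deduplicated report falls into one cell of a 2x2 table:

              case    non-case
    exposed     a        b
    unexposed   c        d

A report is a *case* if any of its reaction terms matches the event
definition, and *exposed* if any of its normalized drug mentions belongs
to the exposure's generic-name set.  The ROR is the odds of exposure
among cases over the odds among non-cases, ``(a*d)/(b*c)``, with a Woolf
(log-normal) confidence interval: ``se = sqrt(1/a + 1/b + 1/c + 1/d)``
on the log scale.

Signal conventions: a lower CI bound above 1 is a *signal*
(disproportionately frequent reporting); an upper bound below 1 is an
*inverse signal* (disproportionately infrequent reporting).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Iterable, Sequence

if TYPE_CHECKING:  # pragma: no cover - annotation only
    from .io import AnalysisConfig, ReportRecord

__all__ = [
    "ExposureDefinition",
    "EventDefinition",
    "ContingencyTable",
    "RorResult",
    "SIGNAL",
    "INVERSE_SIGNAL",
    "NO_SIGNAL",
    "UNDEFINED",
    "is_case",
    "is_exposed",
    "build_contingency",
    "compute_ror",
    "classify_signal",
    "analyze",
]

SIGNAL = "signal"
INVERSE_SIGNAL = "inverse_signal"
NO_SIGNAL = "none"
UNDEFINED = "undefined"


def _fold(s: str) -> str:
    return s.strip().casefold()


@dataclass(frozen=True)
class ExposureDefinition:
    """A named drug class: a report is exposed if it mentions any member.

    A single drug is the singleton special case.  ``generics`` are
    case-folded at construction so membership tests are case-insensitive.
    """

    name: str
    generics: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        folded = frozenset(_fold(g) for g in self.generics)
        if not folded:
            raise ValueError(f"exposure {self.name!r}: generics must be non-empty")
        object.__setattr__(self, "generics", folded)


@dataclass(frozen=True)
class EventDefinition:
    """A named adverse event: a set of preferred-term-like strings."""

    name: str
    terms: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        folded = frozenset(_fold(t) for t in self.terms)
        if not folded:
            raise ValueError(f"event {self.name!r}: terms must be non-empty")
        object.__setattr__(self, "terms", folded)


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 case/non-case counts; ``a`` exposed cases ... ``d`` unexposed non-cases."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for cell, v in zip("abcd", (self.a, self.b, self.c, self.d)):
            if v < 0:
                raise ValueError(f"contingency cell {cell} is negative: {v}")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass(frozen=True)
class RorResult:
    """ROR point estimate, 95% CI and signal label for one exposure-event pair.

    ``ror``/``ci_lower``/``ci_upper`` are ``None`` when a zero cell makes
    the estimate undefined under the ``undefined`` zero-cell policy;
    ``corrected`` is True when the Haldane-Anscombe +0.5 correction was
    applied instead.
    """

    exposure_name: str
    event_name: str
    table: ContingencyTable
    ror: float | None
    ci_lower: float | None
    ci_upper: float | None
    signal: str
    corrected: bool = False


def is_case(report: "ReportRecord", event: EventDefinition) -> bool:
    """True iff any reaction term of ``report`` matches the event definition."""
    return any(_fold(t) in event.terms for t in report.events)


def is_exposed(report: "ReportRecord", exposure: ExposureDefinition) -> bool:
    """True iff any normalized drug mention belongs to the exposure class.

    Exposure is report-level: several matching mentions still count once.
    Falls back to the verbatim name (case-folded) when normalization has
    not run.
    """
    for m in report.drugs:
        name = m.normalized_name if m.normalized_name is not None else _fold(m.verbatim_name)
        if name in exposure.generics:
            return True
    return False


def build_contingency(
    reports: Iterable["ReportRecord"],
    exposure: ExposureDefinition,
    event: EventDefinition,
) -> ContingencyTable:
    """Count reports into the 2x2 table for one exposure-event pair.

    Every report lands in exactly one cell, so a+b+c+d equals the number
    of reports passed in.
    """
    a = b = c = d = 0
    for r in reports:
        exp = is_exposed(r, exposure)
        case = is_case(r, event)
        if exp:
            if case:
                a += 1
            else:
                b += 1
        elif case:
            c += 1
        else:
            d += 1
    return ContingencyTable(a, b, c, d)


def _classify(ci_lower: float | None, ci_upper: float | None) -> str:
    if ci_lower is None or ci_upper is None:
        return UNDEFINED
    if ci_upper < 1.0:
        return INVERSE_SIGNAL
    if ci_lower > 1.0:
        return SIGNAL
    return NO_SIGNAL


def compute_ror(
    table: ContingencyTable,
    config: "AnalysisConfig | None" = None,
    *,
    exposure_name: str = "",
    event_name: str = "",
) -> RorResult:
    """ROR with Woolf 95% CI for one 2x2 table.

    With all cells positive: ``ror = (a*d)/(b*c)`` and
    ``CI = exp(ln ror -/+ z*se)`` with ``se = sqrt(1/a+1/b+1/c+1/d)``.
    A zero cell is handled per ``config.zero_cell_policy``: ``undefined``
    (default) yields an undefined result; ``haldane`` adds 0.5 to all
    four cells before computing and flags the result as corrected.
    """
    from .io import AnalysisConfig  # local import avoids a cycle

    if config is None:
        config = AnalysisConfig.minimal()
    z = config.z_quantile
    a, b, c, d = float(table.a), float(table.b), float(table.c), float(table.d)
    corrected = False
    if min(a, b, c, d) == 0.0:
        if config.zero_cell_policy == "undefined":
            return RorResult(
                exposure_name, event_name, table, None, None, None, UNDEFINED
            )
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        corrected = True
    ror = (a * d) / (b * c)
    se = math.sqrt(1.0 / a + 1.0 / b + 1.0 / c + 1.0 / d)
    log_ror = math.log(ror)
    lo = math.exp(log_ror - z * se)
    hi = math.exp(log_ror + z * se)
    return RorResult(
        exposure_name, event_name, table, ror, lo, hi, _classify(lo, hi), corrected
    )


def classify_signal(result: RorResult) -> str:
    """Signal label from the CI: inverse_signal iff upper < 1, signal iff lower > 1."""
    return _classify(result.ci_lower, result.ci_upper)


def analyze(
    reports: Sequence["ReportRecord"], config: "AnalysisConfig"
) -> list[RorResult]:
    """One RorResult per (exposure, event) pair in the configuration.

    Results come out sorted by (exposure name, event name) so downstream
    output is deterministic regardless of configuration order.
    """
    results = []
    for exposure in config.exposures:
        for event in config.events:
            table = build_contingency(reports, exposure, event)
            results.append(
                compute_ror(
                    table,
                    config,
                    exposure_name=exposure.name,
                    event_name=event.name,
                )
            )
    results.sort(key=lambda r: (r.exposure_name, r.event_name))
    return results
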