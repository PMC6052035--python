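"""Deduplication of case versions and drug-name normalization.

Spontaneous-report databases receive revised versions of the same case
over time; only the most recent version should be analyzed.  The rule
used here is the FDA convention for FAERS quarterly files: keep, per
case, the record with the greatest date stamp (fda_dt), breaking ties by
the lexicographically greatest report id.

Drug names arrive as free text, frequently brand names.  Normalization
maps each mention through the synonym table onto a generic name; names
absent from the table are retained case-folded (not dropped) so that
reports already coded with generic names still match exposure
definitions, and the unmapped tally surfaces mapping gaps.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .io import DrugMap, DrugMention, ReportRecord

__all__ = ["PreprocessSummary", "deduplicate", "normalize_drug_names", "preprocess"]


@dataclass(frozen=True)
class PreprocessSummary:
    n_input: int = 0
    n_after_dedup: int = 0
    n_duplicates_removed: int = 0
    n_mentions_total: int = 0
    n_mentions_unmapped: int = 0


def deduplicate(
    reports: Sequence[ReportRecord],
) -> tuple[list[ReportRecord], PreprocessSummary]:
    """Keep one record per case: greatest version_marker, then greatest report_id.

    Retained records are returned unmodified, in first-appearance order
    of their case ids.  Idempotent, and order-independent as a set.
    """
    best: dict[str, ReportRecord] = {}
    for r in reports:
        cur = best.get(r.case_id)
        if cur is None or (r.version_marker, r.report_id) > (cur.version_marker, cur.report_id):
            best[r.case_id] = r
    kept = list(best.values())
    summary = PreprocessSummary(
        n_input=len(reports),
        n_after_dedup=len(kept),
        n_duplicates_removed=len(reports) - len(kept),
        n_mentions_total=sum(len(r.drugs) for r in kept),
    )
    return kept, summary


def normalize_drug_names(
    reports: Sequence[ReportRecord], drug_map: DrugMap
) -> tuple[list[ReportRecord], PreprocessSummary]:
    """Resolve each mention's verbatim name to a generic through the map.

    Mapped mentions get the table's generic; unmapped ones keep the
    trimmed, case-folded verbatim name with ``mapped=False``.  Report
    structure (count, order, events) is unchanged; the input records are
    not mutated.
    """
    out: list[ReportRecord] = []
    n_mentions = 0
    n_unmapped = 0
    for r in reports:
        mentions: list[DrugMention] = []
        for m in r.drugs:
            n_mentions += 1
            generic = drug_map.lookup(m.verbatim_name)
            if generic is None:
                n_unmapped += 1
                mentions.append(
                    DrugMention(m.verbatim_name, m.verbatim_name.strip().casefold(), False)
                )
            else:
                mentions.append(DrugMention(m.verbatim_name, generic, True))
        out.append(
            ReportRecord(r.report_id, r.case_id, r.version_marker, mentions, list(r.events))
        )
    summary = PreprocessSummary(
        n_input=len(reports),
        n_after_dedup=len(reports),
        n_mentions_total=n_mentions,
        n_mentions_unmapped=n_unmapped,
    )
    return out, summary


def preprocess(
    reports: Sequence[ReportRecord], drug_map: DrugMap
) -> tuple[list[ReportRecord], PreprocessSummary]:
    """Deduplicate then normalize; summary counts cover both stages."""
    kept, dedup_summary = deduplicate(reports)
    normalized, norm_summary = normalize_drug_names(kept, drug_map)
    summary = PreprocessSummary(
        n_input=dedup_summary.n_input,
        n_after_dedup=dedup_summary.n_after_dedup,
        n_duplicates_removed=dedup_summary.n_duplicates_removed,
        n_mentions_total=norm_summary.n_mentions_total,
        n_mentions_unmapped=norm_summary.n_mentions_unmapped,
    )
    return normalized, summary
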