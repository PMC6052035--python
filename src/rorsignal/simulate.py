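"""Synthetic spontaneous-report generator with known ground truth.

Emulates the structure of a FAERS-style extract — reports carrying drug
mentions (optionally written as brand synonyms) and reaction terms, with
stale duplicate case versions injected — under a generative model whose
drug-event association is a known multiplicative odds effect.

Model.  Each of ``N`` base reports draws drug exposures independently,
drug ``j`` with probability ``p_j``.  Event ``k`` then occurs with the
odds-model probability ``q'_k = o_k / (1 + o_k)`` where

    o_k = [q_k / (1 - q_k)] * prod_{j exposed} theta_jk

so that, when drug ``j`` is the only drug affecting event ``k``, the
population odds ratio of the exposed-vs-unexposed 2x2 table equals
``theta_jk`` exactly.  The reporting odds ratio estimates exactly this
quantity, which makes parameter-recovery tests sharp.

Randomness comes from one numpy Generator consumed in a fixed order —
exposures, then events, then synonym choices, then duplicate flags — so
a given (config, seed) pair reproduces the identical report set within
this implementation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .io import DrugMap, DrugMention, FaersDataError, ReportRecord, write_reports

__all__ = [
    "DrugSpec",
    "EventSpec",
    "SyntheticConfig",
    "GroundTruth",
    "generate_reports",
    "expected_counts",
    "drug_map_from_config",
    "read_synthetic_config",
    "write_ground_truth",
    "simulate_to_dir",
]


@dataclass(frozen=True)
class DrugSpec:
    """A generic drug with its exposure probability and brand synonyms."""

    name: str
    p: float
    synonyms: tuple[str, ...] = ()


@dataclass(frozen=True)
class EventSpec:
    """A reaction term with its baseline (unexposed) occurrence probability."""

    term: str
    q: float


@dataclass
class SyntheticConfig:
    """Generator settings; ``theta[j, k]`` is drug j's odds effect on event k.

    ``duplicate_rate`` is the probability that a base report also emits a
    stale earlier version of the same case; ``synonym_rate`` the
    probability that a mention is written as a random brand synonym of
    its drug instead of the generic name.
    """

    n_reports: int
    drugs: list[DrugSpec]
    events: list[EventSpec]
    theta: np.ndarray | None = None
    duplicate_rate: float = 0.0
    synonym_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_reports < 1:
            raise ValueError(f"n_reports must be >= 1, got {self.n_reports}")
        if not self.drugs:
            raise ValueError("drugs must be non-empty")
        if not self.events:
            raise ValueError("events must be non-empty")
        for d in self.drugs:
            if not 0.0 < d.p < 1.0:
                raise ValueError(f"drugs[{d.name!r}].p must be in (0, 1), got {d.p}")
        for e in self.events:
            if not 0.0 <= e.q < 1.0:
                raise ValueError(f"events[{e.term!r}].q must be in [0, 1), got {e.q}")
        if not 0.0 <= self.duplicate_rate < 1.0:
            raise ValueError(
                f"duplicate_rate must be in [0, 1), got {self.duplicate_rate}"
            )
        if not 0.0 <= self.synonym_rate <= 1.0:
            raise ValueError(f"synonym_rate must be in [0, 1], got {self.synonym_rate}")
        J, K = len(self.drugs), len(self.events)
        if self.theta is None:
            self.theta = np.ones((J, K))
        else:
            self.theta = np.asarray(self.theta, dtype=float)
            if self.theta.shape != (J, K):
                raise ValueError(
                    f"theta must have shape ({J}, {K}), got {self.theta.shape}"
                )
            if not np.all(self.theta > 0):
                raise ValueError("theta entries must all be > 0")


@dataclass(frozen=True)
class GroundTruth:
    """Configured effects plus analytic expected 2x2 cells per drug-event pair.

    ``expected_tables`` maps (generic name, event term) to (E[a], E[b],
    E[c], E[d]); pairs whose event is influenced by more than one drug
    are omitted (no closed form under confounding).
    """

    theta: np.ndarray
    expected_tables: Mapping[tuple[str, str], tuple[float, float, float, float]]


def expected_counts(config: SyntheticConfig, j: int, k: int) -> tuple[float, float, float, float]:
    """Closed-form expected 2x2 cells for drug ``j`` and event ``k``.

    Valid only when drug j is the sole drug with a non-unit effect on
    event k; otherwise the unexposed arm is confounded and the call is
    refused.  With ``q' = theta*q / (1 - q + theta*q)``::

        E[a] = N p q'        E[b] = N p (1 - q')
        E[c] = N (1-p) q     E[d] = N (1-p) (1 - q)

    The implied odds ratio (E[a] E[d]) / (E[b] E[c]) equals theta exactly.
    """
    theta = config.theta
    others = [jj for jj in range(len(config.drugs)) if jj != j]
    if any(theta[jj, k] != 1.0 for jj in others):
        raise ValueError(
            f"expected_counts is exact only when drug index {j} is the sole "
            f"drug with a non-unit effect on event index {k}; another drug "
            "also affects this event (multi-drug confounding)"
        )
    N = config.n_reports
    p = config.drugs[j].p
    q = config.events[k].q
    t = theta[j, k]
    q_prime = t * q / (1.0 - q + t * q)
    return (N * p * q_prime, N * p * (1.0 - q_prime), N * (1.0 - p) * q, N * (1.0 - p) * (1.0 - q))


def _ground_truth(config: SyntheticConfig) -> GroundTruth:
    tables: dict[tuple[str, str], tuple[float, float, float, float]] = {}
    for j, drug in enumerate(config.drugs):
        for k, event in enumerate(config.events):
            try:
                tables[(drug.name, event.term)] = expected_counts(config, j, k)
            except ValueError:
                continue
    return GroundTruth(theta=np.array(config.theta, copy=True), expected_tables=tables)


# version markers for generated reports: the retained version post-dates
# the injected stale one by construction
_CURRENT_MARKER = 20170401
_STALE_MARKER = 20160401


def generate_reports(config: SyntheticConfig) -> tuple[list[ReportRecord], GroundTruth]:
    """Draw a report set from the generative model.

    Base report i gets case id ``C<i>``; its current version carries
    version_marker 20170401.  With probability ``duplicate_rate`` a
    content-identical stale version (marker 20160401, distinct report
    id) is appended after the base reports.
    """
    rng = np.random.default_rng(config.seed)
    N = config.n_reports
    J, K = len(config.drugs), len(config.events)
    p = np.array([d.p for d in config.drugs])
    q = np.array([e.q for e in config.events])

    # phase 1: exposures
    exposed = rng.random((N, J)) < p
    # phase 2: events under the multiplicative-odds model
    with np.errstate(divide="ignore"):
        base_logodds = np.where(q > 0, np.log(q) - np.log1p(-q), -np.inf)
    logodds = base_logodds + exposed.astype(float) @ np.log(config.theta)
    q_prime = 1.0 / (1.0 + np.exp(-logodds))
    occurred = rng.random((N, K)) < q_prime
    # phase 3: synonym choice per mention (row-major mention order); one
    # uniform decides whether to use a synonym, a second picks which one
    m_rows, m_cols = np.nonzero(exposed)
    n_mentions = m_rows.shape[0]
    use_synonym = (rng.random(n_mentions) < config.synonym_rate).tolist()
    synonym_pick = rng.random(n_mentions)
    # phase 4: duplicate flags
    dup = rng.random(N) < config.duplicate_rate

    drug_lists: list[list[DrugMention]] = [[] for _ in range(N)]
    m_rows_l, m_cols_l = m_rows.tolist(), m_cols.tolist()
    for m in range(n_mentions):
        drug = config.drugs[m_cols_l[m]]
        name = drug.name
        if use_synonym[m] and drug.synonyms:
            name = drug.synonyms[int(synonym_pick[m] * len(drug.synonyms))]
        drug_lists[m_rows_l[m]].append(DrugMention(verbatim_name=name))

    event_lists: list[list[str]] = [[] for _ in range(N)]
    e_rows, e_cols = np.nonzero(occurred)
    for i, k in zip(e_rows.tolist(), e_cols.tolist()):
        event_lists[i].append(config.events[k].term)

    reports = [
        ReportRecord(
            report_id=str(10_000_000 + i),
            case_id=f"C{i}",
            version_marker=_CURRENT_MARKER,
            drugs=drug_lists[i],
            events=event_lists[i],
        )
        for i in range(N)
    ]

    stale: list[ReportRecord] = []
    for i in np.flatnonzero(dup):
        r = reports[i]
        stale.append(
            ReportRecord(
                report_id=str(90_000_000 + int(i)),
                case_id=r.case_id,
                version_marker=_STALE_MARKER,
                drugs=[DrugMention(m.verbatim_name) for m in r.drugs],
                events=list(r.events),
            )
        )
    return reports + stale, _ground_truth(config)


def drug_map_from_config(config: SyntheticConfig) -> DrugMap:
    """Complete synonym->generic map for the configured drugs."""
    pairs = [(d.name, d.name) for d in config.drugs]
    for d in config.drugs:
        pairs.extend((s, d.name) for s in d.synonyms)
    return DrugMap.from_pairs(pairs)


def read_synthetic_config(path: str | Path, seed: int | None = None) -> SyntheticConfig:
    """Load a generator configuration from YAML; ``seed`` overrides the file.

    Schema::

        n_reports: 1000
        duplicate_rate: 0.05
        synonym_rate: 0.3
        seed: 42
        drugs:
          - name: edoxaban
            p: 0.1
            synonyms: [SAVAYSA, LIXIANA]
        events:
          - term: tubulointerstitial nephritis
            q: 0.01
        theta:                      # omitted entries default to 1
          edoxaban:
            tubulointerstitial nephritis: 0.65
    """
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"synthetic config not found: {p}")
    with open(p, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise FaersDataError(f"{p}: synthetic config must be a YAML mapping")
    drugs = [
        DrugSpec(
            name=str(d["name"]),
            p=float(d["p"]),
            synonyms=tuple(str(s) for s in d.get("synonyms", [])),
        )
        for d in raw.get("drugs", [])
    ]
    events = [EventSpec(term=str(e["term"]), q=float(e["q"])) for e in raw.get("events", [])]
    theta = None
    if "theta" in raw and raw["theta"] is not None:
        theta = np.ones((len(drugs), len(events)))
        by_drug = {d.name: j for j, d in enumerate(drugs)}
        by_event = {e.term: k for k, e in enumerate(events)}
        for dname, row in raw["theta"].items():
            if dname not in by_drug:
                raise ValueError(f"theta names unknown drug {dname!r}")
            for ename, val in row.items():
                if ename not in by_event:
                    raise ValueError(f"theta names unknown event {ename!r}")
                theta[by_drug[dname], by_event[ename]] = float(val)
    return SyntheticConfig(
        n_reports=int(raw.get("n_reports", 0)),
        drugs=drugs,
        events=events,
        theta=theta,
        duplicate_rate=float(raw.get("duplicate_rate", 0.0)),
        synonym_rate=float(raw.get("synonym_rate", 0.0)),
        seed=int(seed if seed is not None else raw.get("seed", 0)),
    )


def write_ground_truth(truth: GroundTruth, config: SyntheticConfig, path: str | Path) -> None:
    """TSV sidecar: per drug-event pair, theta and (when exact) expected cells."""
    rows = []
    for j, drug in enumerate(config.drugs):
        for k, event in enumerate(config.events):
            cells = truth.expected_tables.get((drug.name, event.term))
            rows.append(
                {
                    "drug": drug.name,
                    "event": event.term,
                    "theta": truth.theta[j, k],
                    "e_a": "NA" if cells is None else f"{cells[0]:.6g}",
                    "e_b": "NA" if cells is None else f"{cells[1]:.6g}",
                    "e_c": "NA" if cells is None else f"{cells[2]:.6g}",
                    "e_d": "NA" if cells is None else f"{cells[3]:.6g}",
                }
            )
    pd.DataFrame(rows).to_csv(Path(path), sep="\t", index=False)


def simulate_to_dir(config: SyntheticConfig, out_dir: str | Path) -> dict[str, Path]:
    """Generate reports and write the DEMO/DRUG/REAC files plus sidecars.

    Writes the three report tables, the ground-truth TSV, and a complete
    drug map TSV so the output is directly consumable by the pipeline.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    reports, truth = generate_reports(config)
    paths = write_reports(reports, out)
    truth_path = out / "ground_truth.tsv"
    write_ground_truth(truth, config, truth_path)
    map_path = out / "drug_map.tsv"
    drug_map_from_config(config).to_frame().to_csv(map_path, sep="\t", index=False)
    paths["ground_truth"] = truth_path
    paths["drug_map"] = map_path
    return paths
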