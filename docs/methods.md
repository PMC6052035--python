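# Methods

## The case/non-case design and the ROR

Spontaneous-report databases have no exposure denominator, so
association is assessed within the database: for an event definition E
(a set of reaction terms) and an exposure definition X (a set of
generic drug names), every analyzed report is cross-classified as
case/non-case (does any of its reaction terms, case-folded and trimmed,
belong to E?) and exposed/unexposed (does any of its normalized drug
mentions belong to X?). Classification is report-level: a report with
two matching terms, or two drugs of the same class, counts once. The
unit of analysis is the deduplicated report, not the patient or the
drug–event pair.

The reporting odds ratio on the resulting 2×2 table (a, b, c, d) is

    ROR = (a·d) / (b·c)
    se  = sqrt(1/a + 1/b + 1/c + 1/d)
    CI  = exp(ln ROR ∓ z·se),   z = 1.959964

The Woolf log-normal interval is the standard choice for ROR
disproportionality screening. `z_quantile` is configurable (default the
two-sided 95% normal quantile). Signals are read off the CI: lower
bound > 1 → `signal`; upper bound < 1 → `inverse_signal`; otherwise
`none`.

### Zero cells

With any zero cell the ROR is undefined. The default policy
(`zero_cell_policy: undefined`) reports NA and the label `undefined`;
the alternative `haldane` applies the Haldane–Anscombe correction
(+0.5 to all four cells) and flags the result `corrected`. The default
is `undefined` because silent continuity corrections can manufacture
or suppress borderline signals; `haldane` exists mainly for
small-sample synthetic runs where zeros are expected.

### Numerical conventions

Full precision is kept internally; output values are rendered at
`ci_rounding` decimals (default 2) using Python's float formatting,
i.e. round-half-even on the underlying binary value. Ties in the
results table are avoided by sorting rows lexicographically by
(exposure, event). A negative cell is a programming error and raises
immediately.

## Input handling

The report dialect is a strict subset of the FAERS quarterly ASCII
layout: `$`-delimited files with a header row, DEMO (primaryid, caseid,
fda_dt), DRUG (primaryid, drugname), REAC (primaryid, pt). Extra
columns are ignored by name; a row with more fields than the header
(an unescaped `$` inside a field) is a fatal parse error rather than
silent data loss. DRUG/REAC rows whose primaryid has no DEMO row are
counted as orphans and dropped. Dates are integer YYYYMMDD stamps; no
calendar validation is performed beyond non-negativity, since the stamp
is used only to order case versions.

## Deduplication

FAERS cases are revised over time; all versions share a case id.
Deduplication keeps, per case, the record with the greatest date stamp,
breaking ties by the lexicographically greatest report id — the FDA
convention for quarterly files. The operation is idempotent and
order-independent (as a set). Cross-case duplicates (the same clinical
episode reported under different case ids, e.g. by different
manufacturers) are out of scope; detecting them requires probabilistic
record linkage and is not reproducible from report structure alone.

## Drug-name normalization

Each mention's verbatim name is trimmed, case-folded and looked up in a
user-supplied synonym→generic table (in practice derived from a
resource such as DrugBank). Generics self-map, so already-generic
mentions resolve without a synonym row. Names absent from the table are
retained case-folded rather than dropped — dropping them would silently
shrink the non-case denominators — and tallied as unmapped so mapping
gaps are visible in the run summary. All drug mentions count toward
exposure regardless of reported role (suspect/concomitant), since role
information is not part of the reduced dialect.

## The synthetic generator

The generator emulates the structural features the pipeline must
handle: multi-drug, multi-event reports; brand-name synonyms; stale
duplicate case versions — with a known association strength so the
whole chain can be validated against ground truth.

For each of N base reports, exposure to drug j is an independent
Bernoulli(p_j) draw. Event k then occurs with probability
q'_k = o_k/(1 + o_k), where

    o_k = [q_k / (1 − q_k)] · ∏_{j exposed} θ_jk

a multiplicative-odds model chosen so that, when drug j is the only
drug with θ_jk ≠ 1, the population odds ratio of the exposed-vs-
unexposed table equals θ_jk *exactly*. The ROR estimates precisely this
odds ratio, so parameter-recovery tests are sharp: any systematic
deviation of the estimate from θ indicates a pipeline defect rather
than an estimand mismatch. `expected_counts` provides the closed-form
expected cells (E[a] = N·p·q′ etc.) and refuses pairs where a second
drug also affects the event, since the unexposed arm is then
confounded and no closed form holds.

Each mention is written as a uniformly chosen brand synonym with
probability `synonym_rate`; with probability `duplicate_rate` a report
also emits a content-identical stale version (same case id, earlier
date stamp, distinct report id). One numpy Generator is consumed in a
fixed phase order — exposures, events, synonym choices, duplicate
flags — so a (config, seed) pair reproduces the identical report set
within this implementation; seeds are portable across implementations
in distribution only.

What the generator does *not* emulate: realistic report-volume trends,
demographic structure, correlated polypharmacy, masking/competition
bias, or content-divergent duplicates. Tests passing on synthetic data
therefore demonstrate correctness of the mechanics and the estimator,
not robustness to those real-data phenomena.

## Validation conditions

The study conditions used by the test suite and acceptance script, with
rationale:

- **Recovery**: single drug (p = 0.1 exposure prevalence, typical of a
  widely used drug class in a large database), single event with
  baseline q = 0.01, θ ∈ {0.5, 1, 2}, N = 200,000 reports,
  duplicate_rate 0.1 and synonym_rate 0.3 so both cleaning stages are
  exercised. Seed-averaged over 20 seeds, ln(ROR) must lie within 0.15
  of ln(θ); the observed deviation is an order of magnitude smaller.
- **Calibration**: 500 independent null replicates (θ = 1) at N = 5,000
  with p = 0.1, q = 0.05, giving expected exposed-case cells around 25
  so the normal approximation is in its working range; the 95% CI must
  contain 1 in 93–97% of replicates.
- **Published counts**: the full-database marginals (8,281,917 reports;
  4,947 event cases) and the exposed-row counts for the FXa-inhibitor
  class and warfarin are treated as fixed inputs; the package
  recomputes ROR = 0.65 (inverse signal) and ROR = 0.94 (no signal)
  from them at run time.

Problem sizes were chosen to keep the whole suite under a few minutes
on a single CPU while leaving wide statistical margins.

## Known limitations

- Crude (unstratified, unadjusted) RORs only; no PRR, information
  component, or Bayesian shrinkage estimators, and no multiplicity
  control across many drug–event pairs.
- Event matching is exact string membership after trim/case-fold; no
  dictionary rollup (LLT→PT→SOC) or fuzzy matching.
- The Woolf interval is asymptotic; with expected cells below ~5 its
  coverage degrades and the `haldane` policy only partially compensates.
- Reports mentioning drugs from two configured exposures contribute to
  both tables; exposure definitions are independent by design.
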