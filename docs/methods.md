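# Methods

This note records how each engine works, the defaults that matter, what the
synthetic generator does and does not emulate, and the design choices made
where the underlying SOP leaves the design open.

## Knowledge model and rule engine

Records are permissive dataclasses: any field may be absent or malformed, and
the rule engine reports every breach as a `Violation` (rule id, severity,
entity reference, message) rather than raising. This is deliberate — a curation
pipeline needs a complete triage report for a whole corpus, not the first
exception. Reports are sorted by (entity, rule id), so identical corpora yield
byte-identical reports.

The 12 universally required evidence-item fields are the 11 the model figure
enumerates plus **Source ID**: the source *type* alone does not identify a
citation, and an uncitable claim is unusable, so both halves of the source
reference are required. Per-type clinical-significance vocabularies are:
Predictive {Sensitivity/Response, Resistance, Reduced Sensitivity, Adverse
Response, N/A}; Diagnostic {Positive, Negative}; Prognostic {Better Outcome,
Poor Outcome, N/A}; Functional {Gain of Function, Loss of Function, Unaltered
Function, Neomorphic, Dominant Negative, Unknown}; Predisposing {N/A} (single
studies rarely settle predisposition; the call is made at the assertion
level). All vocabularies are overridable from a YAML config so a corrected
table drops in without a code change.

Other calibrated validation choices: statements longer than 3 sentences warn
(guidance, not a hard rule); unknown drug names warn while trade names
(detected via a bundled trade→generic alias table) warn with the generic
suggested; a free-text disease with the could-not-find-disease flag downgrades
the unresolved-disease error to a warning; HGVS strings get a regex
well-formedness check only (`reference:prefix.change`), not a grammar parse.

## Scoring

`evidence_item_score(rating, level) = rating × w(level)` with default weights
A=10, B=5, C=3, D=1, E=0.5 (dimensionless score points; one point per star).
`fractions.Fraction` keeps the E weight exact; serialized scores need at most
one decimal under the defaults. The variant score sums items whose moderation
state is in `included_statuses` — default `{accepted}`, configurable to
include `submitted`, because rejected evidence should never score and the
public-facing number should reflect vetted content. Direction and significance
are ignored by design: the score measures curation volume, not verdict.
Unscoreable items (missing or out-of-range rating/level) are skipped by the
aggregator; reporting them is the validator's job.

## ACMG combining engine

The 28 germline evidence codes default to prefix strengths (PVS→very strong,
PS→strong, PM→moderate, PP→supporting, BA→standalone, BS→strong benign,
BP→supporting benign); explicit strength overrides are applied before
counting, mirroring refinement practice. The combining table is data
(`data/acmg_combining.yaml`) so updated rule sets can be layered in: rows fire
on per-strength minimum counts (with an optional maximum, used by the
"1 strong + 1–2 moderate" row), and the strongest fired row per side wins.

Conflict handling: a rule firing on one side while any code from the opposite
side is present yields VUS with `conflict=true`. This is intentionally broader
than "both sides fired" — a BA1 (standalone benign) together with PVS1 is
contradictory evidence even though PVS1 alone fires no pathogenic row — and
matches the guideline's instruction to default contradictory evidence to VUS.
Two very-strong codes (only reachable via overrides) classify through the
very-strong rows, which is the table's literal reading.

## AMP tier/level assignment

Somatic assertion types (Predictive, Prognostic, Diagnostic) are mapped to
Tier/Level by a deterministic table; Predisposing assertions are refused and
routed to the ACMG engine. Only accepted, Supports-direction items whose
significance matches the asserted one count toward the level; Does-not-support
items count toward contradiction detection. Level A requires a regulatory
anchor (FDA approval, companion diagnostic, or an NCCN guideline) corroborated
by an accepted Level-A item; Level B, an accepted Level A/B item (a Level-A
item without a regulatory anchor still demonstrates at-least-clinical
evidence, closing the gap where it would otherwise fall through every row);
Levels C and D follow the best accepted item (D also covers E). Tier I ⇔
Level A/B, Tier II ⇔ Level C/D. Tier III (no level) marks missing consensus:
no counted supporting item, or refuting items at least matching supporting
ones in number. Tier IV (no level) marks benign-side asserted significance;
since the somatic evidence vocabularies contain no benign-side token, the
assertion-level vocabularies are extended with {Benign, Likely Benign}. The
whole mapping stands in for guideline evidence-minimum tables not reproduced
here and is isolated for easy replacement.

## Coordinate normalization

Coordinates are 1-based inclusive with trimmed alleles; an insertion occupies
its two flanking bases (stop = start + 1), keeping start ≤ stop and making the
insertion point unambiguous. Internally normalization converts to an
(position, ref-allele, alt-allele) representation, right-trims the shared
suffix, left-trims the shared prefix, and then slides a pure indel leftward
one base at a time while the preceding reference base equals the last base of
the moving allele, re-trimming after each step. Insertions stop at start 1
(between the first two bases) — the leftmost position the trimmed dialect can
express. The result is idempotent and allele-equivalent, verified against a
string-application oracle and an exhaustive enumeration oracle in the tests.
A degenerate variant (identical alleles after trimming) raises rather than
returning a no-op. Only primary coordinates are normalized; fusion-partner
coordinates get a reference check only, since left-shifting across a
breakpoint is undefined. FASTA references are loaded whole (fixtures are
small) with case-insensitive contig lookup.

## Moderation workflow

The engine is event-sourced: every action appends a JSON event carrying a
logical sequence number (no wall clock, for determinism), the acting actor's
role and conflict-of-interest date, and — for submissions — the full entity
payload, so a log alone deterministically rebuilds its corpus. Guards:
deciders must be Editors/Admins with a COI statement no older than 365 days
(configurable; the SOP requires a statement but names no period); nobody
accepts their own submission or revision, while anyone may reject their own;
rejections, revisions, and flag resolutions require comments (the SOP requires
them for revisions; symmetric treatment aids auditability); assertions cannot
be accepted without an accepted supporting item, and rejecting an accepted
assertion's last accepted item auto-demotes it to submitted with a flag — a
conservative choice for a case the SOP does not cover. Unknown actors default
to the Curator role.

## Synthetic generator

`generate_corpus(GeneratorConfig)` emits a referentially intact corpus from a
single seed. Defaults (8 genes, 25 variants, 100 evidence items, 8 assertions,
violation rate 0) span the full model: all five evidence types and levels,
both directions (80% Supports — curated content skews supportive), per-type
significance values, 1–3 drugs on Predictive items with interaction types,
one two-locus fusion variant, germline assertions cycling ACMG code sets that
reach every classification outcome, and somatic assertions whose tier/level
come from the real engine. Moderation states are drawn 0.7/0.2/0.1
accepted/submitted/rejected, a plausible steady-state mix for a moderated
resource.

With a nonzero violation rate, `round(rate × n_eids)` defects are injected,
each breaking exactly one rule on one otherwise-clean record, drawn from ten
defect kinds (missing required fields, out-of-range ratings, predisposing
significance misuse, missing interaction types, drugs on non-predictive items,
trade names, vocabulary outsiders, unresolvable diseases, unversioned
transcripts, ancestor/descendant type pairs). Ground-truth labels are stored
on the corpus, making validator recall and precision well-defined (and, by
construction, 1.0/1.0 — the point is to detect regressions in the rule
engine, not to simulate ambiguous curation errors).

What the generator does not emulate: real literature text (statements are
templated), genuine ontology breadth (bundled subsets are curated miniatures
of ≤~30 terms with real-world identifiers), correlated or multi-rule defects,
curator disagreement, or coordinate/reference consistency against a genome
build (contig fixtures for normalization are generated separately,
repeat-biased so left-shifting is exercised). Passing tests therefore show the
engines implement the model faithfully, not that they capture the messiness
of real curated corpora.

## Problem sizes and numerical choices

The test suite checks the ACMG engine exhaustively against an independent
rule-table oracle on all code sets of size ≤ 4 (24,157 sets), normalization on
10,000 seeded random indels over ≤ 60 bp contigs plus exhaustive leftmost
oracles on repeat fixtures, moderation safety over 1,000 randomized action
sequences, and validator recall on a seed-7 corpus of 100 items at a 20%
defect rate — sizes chosen to make the checks exhaustive or statistically
dense while keeping the whole suite in seconds. All scores are exact
rationals; all comparisons are equality, not tolerance-based.

## Known limitations

HGVS is validated, never parsed or projected; no liftover between builds; no
right-shift (3') normalization; drug/ontology linkage is by bundled table, not
live services; the AMP mapping is a documented stand-in at the tier/level
granularity; assertion-level disease specificity (assert on the broadest
disease consistent with the evidence) is guidance the validator cannot check
mechanically and does not attempt to.
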