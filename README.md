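# varkb

A toolkit for the knowledge model behind community-curated cancer-variant
interpretation knowledgebases. It implements the four-level hierarchy used by
such resources — **Genes → Variants → Evidence Items → Assertions** — as typed
records with a validating rule engine, evidence scoring, germline and somatic
classification engines, representative-coordinate normalization, and the
curation/moderation workflow, all runnable fully offline on bundled ontology
subsets and seeded synthetic corpora.

It is aimed at people who build, audit, or mirror curation pipelines: the rule
engine turns a curation SOP into machine-checkable rules, and the synthetic
generator produces labeled defective corpora for measuring validator recall.

## The model in brief

**Evidence Items (EIDs)** are single literature- or abstract-derived clinical
claims with 12 universally required fields (gene, variant, source type and ID,
variant origin, disease, statement, evidence type, level, direction, clinical
significance, star rating). Five evidence types (Predictive, Diagnostic,
Prognostic, Predisposing, Functional) each carry their own clinical-significance
vocabulary; Predictive items require drugs, and a drug-interaction type
(Combination / Sequential / Substitutes) when more than one drug is involved.

**Scoring.** Each item scores `rating × w(level)` with level weights
`A=10, B=5, C=3, D=1, E=0.5` (one point per star). The **Variant Evidence
Score** is the plain sum over the variant's accepted items:

    score(V) = Σ_i rating_i · w(level_i)

It measures curation volume, deliberately ignoring conflicting directions.
Arithmetic uses exact rationals, so the 0.5 weight never drifts.

**Classification.** Predisposing (germline) assertions combine ACMG-AMP 2015
evidence codes (PVS1, PS1–4, PM1–6, PP1–5, BA1, BS1–4, BP1–7, with optional
strength overrides) through the published combining table into
Pathogenic / Likely Pathogenic / VUS / Likely Benign / Benign; contradictory
sides force VUS with a conflict flag. Somatic assertion types receive an
AMP-ASCO-CAP 2017 Tier (I–IV) and, for Tiers I–II, a Level (A–D) derived from
regulatory flags and the strength of accepted supporting evidence.

**Coordinates.** Representative coordinates are 1-based with trimmed alleles
(`-` for the empty side; insertions span their two flanking bases). Indels are
canonicalized by left-shift normalization: trim shared suffix/prefix bases,
then slide through repeat tracts to the smallest equivalent start.

**Moderation.** Entities cycle submitted → accepted/rejected with revisions and
flags. Editors need a current conflict-of-interest statement; nobody accepts
their own submission; rejections and revisions require comments; an assertion
cannot be accepted without an accepted supporting EID, and losing its last one
demotes it with an auto-flag. The event log is append-only and replayable.

## Worked example

```sh
$ varkb simulate --seed 7 --violation-rate 0.2 --out corpus.json
wrote 100 evidence items, 25 variants, 8 assertions, 20 labeled defects to corpus.json

$ varkb validate corpus.json | tail -1
[validate] error=17, records=141, warning=3 (exit 1)

$ varkb score corpus.json | head -4
variant	n_items	variant_evidence_score
ALK:E529R	2	6.5
ALK:Exon 19 Deletion	4	14
ALK:T380F	3	60.5

$ varkb classify acmg --codes PVS1,PS1
{"classification": "Pathogenic", "conflict": false, "fired_rules": ["P1a"]}

$ printf '>chr1\nGCATTTAC\n' > ref.fa
$ varkb normalize --fasta ref.fa --coords 'chr1:6-6:T>-'
{"chromosome": "chr1", "reference_base": "T", "shifted_by": 2, "start": 4,
 "stop": 4, "trimmed": false, "variant_base": "-"}
```

The simulated corpus carries 20 labeled defects; `validate` finds exactly those
20 (17 errors, 3 warnings) and nothing else, and exits 1 because violations are
present. The score table shows exact sums — `varkb score --detail` shows the
`6.5` is a 2-star Level C item (2×3=6) plus a 1-star Level E item (0.5);
opposing directions would still add, never cancel. Deleting the `T` at
position 6 of `GCATTTAC` left-shifts through the
`TTT` homopolymer to position 4. Other subcommands: `classify amp`, `export`,
`replay`, `rules`.

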