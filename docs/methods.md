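# Methods

## Scope and model

`mvld` implements the Minimal Variant Level Data (MVLD) standard for the
curation of clinically interpreted somatic cancer variants as a validating
library and command-line tool.  One `MVLDRecord` is one *variant-level
assertion*: one variant, in one cancer type, with one biomarker class and —
for predictive assertions — one therapeutic context.  A curation effort that
interprets the same variant against two drug regimens holds two records.
This atomicity is what makes the flat ClinVar-style export well defined, and
it is why lists (transcripts, PMIDs, drugs, trial identifiers) are
first-class within a record while multiple therapeutic contexts are not.

The record is composed of the standard's three blocks:

* **Allele descriptive** — genome build (GRCh37/GRCh38, optional patch
  suffix such as `.p13`, because the actual reference version used for
  calling is part of the claim), HUGO gene symbol, chromosome (1–22, X, Y,
  MT, stored without a `chr` prefix so one spelling round-trips), 1-based
  genomic position, RefSeq transcript (`NM_`/`NR_`) and protein (`NP_`)
  accessions.
* **Allele interpretive** — somatic classification (`Confirmed somatic`,
  `Confirmed germline`, `Unknown`; `Unknown` is fully conformant because it
  is the designated placeholder when no matched normal was sequenced), DNA
  and protein HGVS descriptions, the four-way variant type (SNV, MNV, INS,
  DEL), the twelve-term molecular consequence vocabulary, supporting PMIDs.
* **Cancer interpretive** — cancer type as an ontology term (NCI Thesaurus
  or Oncotree), biomarker class (Diagnostic / Prognostic / Predictive),
  therapeutic context (drug names, stored free-text), effect (five base
  terms plus the `other` escape, which is the only term that carries free
  text), level of evidence (pluggable scheme; CanDL built in), and sub-level
  evidence assertions in six categories with per-category citation
  requirements.

## Where checking happens

Checking is split deliberately between construction and validation:

* **Constructors** reject *invariant-violating combinations* — an `other`
  effect without its description, a CanDL label outside Tier 1–4, an
  interpretation with neither HGVS form, empty transcripts for a
  non-genomic DNA description, malformed NCT/RefSeq/build patterns.  In
  memory you cannot accidentally author such a state.
* **The validator** (`validate_record`) decides *conformance* — whether
  required fields are present, conditional logic holds, vocabulary terms are
  canonical and HGVS strings parse.  It returns ordered findings with frozen
  rule ids and never raises, so a whole corpus can be checked in one pass.

Ingestion (the TSV/JSON readers, the violation injector) must be able to
represent broken upstream data so the validator has something to report on;
it uses the documented unchecked construction path (`build_unchecked` /
`evolve`), which is the package's equivalent of parsing into a draft.

Two profiles are provided.  `submission` errors on everything the standard
requires and *warns* about the strongly-suggested items — both the DNA and
the protein HGVS description for coding variants, and supporting PMIDs —
which the standard marks optional in its current iteration.  `strict`
upgrades exactly those suggestions to errors.  For every record the strict
error set is a superset of the submission error set (tested property).  A
record is treated as *noncoding* — and therefore exempt from the
both-HGVS-forms suggestion — when its consequence is one of 3UTR, 5UTR,
Splice, Splice-region, Intronic, Upstream, Downstream, or when its DNA
description is `n.`- or `g.`-anchored.

Cross-field consistency checks (declared variant type vs. the type implied
by the DNA HGVS; a frameshift consequence on an equal-length substitution;
an intronic consequence with a protein change) are warnings, never errors:
the standard does not mandate internal agreement and curated legacy tables
may legitimately disagree.

Gene symbols are checked against a packaged list of HUGO-approved symbols
covering the fixture genes; an unknown symbol is a warning, not an error,
because the package performs no live HGNC lookup.

## HGVS handling

Validation of HGVS strings is *syntactic only*.  The grammar covers the core
common to all recent nomenclature versions: for DNA (`g.`, `c.`, `n.`)
single-base substitution, deletion, duplication, insertion and
deletion–insertion, with UTR markers (`-`, `*`) and intronic offsets
(`88+2`) on transcript-anchored molecules; for protein (`p.`) substitutions
in one- or three-letter code (including nonsense `*` and silent `=`),
frameshifts, simple deletions, terminal extensions and the parenthesized
predicted form.  Protein residues normalize to one-letter code, which is the
canonical serialization.  Exotic constructs (alleles in cis/trans,
mosaicism, repeats, uncertain positions) are rejected with a distinct
"unsupported HGVS construct" error rather than a generic failure, so a
curator can tell "outside the subset" from "mistyped".  No reference
sequence, transcript model or 3'-shifting normalization is ever applied;
projecting between transcripts is out of scope.

Parsing is total (property-tested with fuzzed input): any string yields a
parse or a structured error.  Serialization is the inverse of parsing on
the supported grammar: `serialize(parse(s))` is the canonical form of `s`
and `parse(serialize(p)) == p`.

The MVLD variant type is derived from a DNA parse by the length rule: a
one-base-for-one-base substitution is SNV; any other replacement — including
deletion-plus-insertion, the classic "deletion plus substitution" complex
case — is MNV; pure gains (insertion, duplication — a duplication adds
bases) are INS; pure losses are DEL.  A `delins` that replaces exactly one
base with one base is classified SNV, because the length rule, not the
spelling, defines the type.  The implementation is tested exhaustively
against an independent enumeration oracle over all reference/alternate
allele pairs of length ≤ 3.

## CanDL tiering

`assign_tier` returns the strongest (numerically smallest) tier whose
predicate holds:

| Tier | Predicate | Structured sentence (fixed) |
|------|-----------|------------------------------|
| 1 | `fda_approved` or `nccn_recommended` flag | "Alteration has matching FDA approved or NCCN recommended therapy" |
| 2 | any sub-level 1, 2 or 4 assertion | "Alteration has matching therapy based on evidence from clinical trials, case reports, or exceptional responders" |
| 3 | any sub-level 5 assertion | "Alteration predicts for response or resistance to therapy based on evidence from pre-clinical data (in vitro or in vivo models)" |
| 4 | `pathway_driver` flag or sub-level 6 assertion | "Alteration is a putative oncogenic driver based on functional activation of a pathway" |

Design choices where the scheme leaves room: retrospective trials/metadata
(sub-level 2) count toward Tier 2, reading "clinical trials" as covering
both directions of study; inferential/in-silico evidence (sub-level 6) sits
with the pathway-driver rationale at Tier 4; FDA/NCCN status is an explicit
caller-supplied flag because no computable registry linkage exists; expert
opinion (sub-level 3) does not tier on its own — expert-only evidence raises
`NoTierableEvidence`.  The sentence table is the single source of truth: a
`TierResult` cannot be built with a sentence that does not match its tier.
Adding evidence or enabling flags never weakens the result (exhaustively
tested against a brute-force minimum-applicable-tier oracle over all
2^3 × 2^6 flag/category combinations).

A non-CanDL level of evidence is stored verbatim (`schema_name`,
`level_label`) and never re-tiered.

## Interchange formats

The MVLD table is UTF-8, tab-separated, with one header row of canonical
snake_case column names in the standard's field order and `;` as the in-cell
list delimiter (chosen because commas occur in drug names and in the tier
sentences).  Absent optionals are empty cells.  Unknown columns are
preserved into `extensions` (with an `IO.UNKNOWN_COLUMN` warning) and
survive a read→write cycle byte-identically.  The structured sub-level block
does not flatten losslessly into a delimited cell, so that one cell holds a
compact JSON array.  The JSON document mirrors the type model one-to-one
under a top-level `mvld_version: "1.0"` marker, anticipating iteration of
the standard.

The ClinVar-style export is a generic flat submission-sheet approximation,
not a bit-exact copy of any dated ClinVar template (none is fixed by the
standard).  The level of evidence renders into the assertion-method column
— for CanDL with the structured tier sentence appended — mirroring how
ClinVar's "Review Status (Assertion Method)" names a described scheme.  The
condition renders as `source:code (label)`.  Export refuses records with
submission-profile errors and is lossless for the required fields: the
descriptor, the interpretation (including record-level PMIDs, which are the
only PMIDs placed in the citations column), the cancer type, the biomarker
class and the level of evidence are reconstructed exactly by
`from_clinvar_row`.  Effect and therapeutic context are rendered into the
clinical-significance text for human readers but are not round-tripped.

The packaged cancer-ontology fixture is a hand-curated, 50-term subset of
public Oncotree labels with their paired NCI Thesaurus codes, sufficient for
desk-scale testing; it is not a mirror of the live services, and codes for
rare entities should be verified against the NCI Term Browser before
clinical use.  Lookups match codes exactly (case-insensitively) or labels
case-insensitively and suggest nearest labels on a miss.

## Fixture generator

`generate_records(n, seed, error_spec)` emulates the *shape* of a curated
variant table: gene symbols and RefSeq accessions from the packaged gene
table, grammar-conforming HGVS edits spanning all four variant types,
consequences driving coherent DNA/protein pairs (noncoding consequences get
DNA-only descriptions with UTR/intronic anchors), uniform draws over the
cancer-term, biomarker-class and effect vocabularies, evidence assertions
across all six sub-levels with their mandated citations, and a CanDL level
computed from the drawn evidence so every clean record is internally
coherent.  Draw probabilities (85 % of records carry a therapeutic context,
80 % of those an effect; one to three evidence items per record) were fixed
once as typical of predictive-biomarker tables; over 200 records every term
of every enumerated vocabulary appears at least once.

Record *i* is generated from a pseudo-random sub-stream keyed by
`(seed, i)`, so corpora are stable prefixes of each other as `n` grows.
Violations are injected exactly as requested, each on a distinct record
(hence the requested total may not exceed `n`), and logged as
`(index, rule_id, field_path)` in the manifest; injected HGVS violations
come from a fixed catalogue of malformed strings so error text is stable.
The generator emulates table structure, not tumor biology: there is no
mutational spectrum, no hotspot structure, no drug–gene plausibility and no
case-level linkage between records.  Green tests therefore demonstrate
contract fidelity (validation, round-trips, exact violation recovery), not
performance on real tumor sequencing data.

## Problem sizes and determinism

The exhaustive checks are small by construction: 512 flag/category
combinations for tiering, 7 224 allele pairs for the variant-type rule,
200-record corpora for round-trip and recovery properties — all complete in
seconds on one CPU.  Identical inputs produce byte-identical reports and
tables; all randomness flows from the single integer seed.
`scripts/acceptance.py --seed N --out results.json` recomputes every
headline quantity from scratch.

## Validation rule registry

Frozen rule ids referenced by reports and fixture manifests:

| Rule id | Severity | Meaning |
|---------|----------|---------|
| REQ.GENOME_BUILD | error | Genome Build missing |
| REQ.GENE_NAME | error | Gene Name missing |
| REQ.CHROMOSOME | error | Chromosome missing |
| REQ.DNA_POSITION | error | DNA Position missing |
| REQ.TRANSCRIPT | error | RefSeq transcript missing for a non-genomic description |
| REQ.SOMATIC_CLASS | error | Somatic Classification missing |
| REQ.VARIANT_TYPE | error | Variant Type missing |
| REQ.CONSEQUENCE | error | Variant Consequence missing |
| REQ.CANCER_TYPE | error | Cancer Type missing |
| REQ.BIOMARKER_CLASS | error | Biomarker Class missing |
| REQ.EVIDENCE_LEVEL | error | Level of Evidence missing |
| COND.HGVS_PRESENT | error | neither DNA nor protein HGVS present |
| COND.EFFECT_CONTEXT | error | Effect without Therapeutic Context |
| COND.EFFECT_OTHER_TEXT | error | `other` / free-text pairing violated |
| COND.CANDL_LABEL | error | CanDL label outside Tier 1–4 |
| VOC.GENOME_BUILD, VOC.CHROMOSOME, VOC.POSITION, VOC.TRANSCRIPT, VOC.PROTEIN_ID | error | format of a descriptive field |
| VOC.SOMATIC_CLASS, VOC.VARIANT_TYPE, VOC.CONSEQUENCE, VOC.BIOMARKER_CLASS, VOC.EFFECT, VOC.PMID | error | term outside a controlled vocabulary |
| HGVS.DNA, HGVS.PROTEIN | error | description is not grammar-conforming HGVS |
| SUGG.HGVS_BOTH, SUGG.PMIDS | warning (error under `strict`) | strongly-suggested item absent |
| SUGG.PROTEIN_ID | warning | protein HGVS without a RefSeq protein id |
| WARN.GENE_UNKNOWN | warning | symbol not in the packaged HUGO subset |
| EVID.TRIAL_REQUIRED, EVID.EXPERT_REQUIRED, EVID.PMID_REQUIRED, EVID.CITATION_REQUIRED, EVID.NCT_FORMAT, EVID.CATEGORY_RANGE | error | sub-level citation requirements |
| CONS.TYPE_MISMATCH, CONS.FRAMESHIFT_SNV, CONS.INTRONIC_PROTEIN | warning | cross-field consistency |
| IO.UNKNOWN_COLUMN | warning | column preserved into extensions |
| IO.ROW_SKIPPED | error | row could not be structured as a record |

## Known limitations

* HGVS validation is a grammar subset; repeats, alleles and uncertain
  positions are rejected even when valid nomenclature.
* No live services are consulted: gene symbols, ontology codes and drug
  names are checked only against packaged fixtures or not at all.
* Case-level data — multiple variants in one sample, contraindications
  across variants, RNA or structural-variation evidence, outcomes data —
  is outside the record model by design.
* The ClinVar export approximates a submission sheet; a real submission
  still requires mapping onto the template version in force at NCBI.
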