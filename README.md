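# mvld

A validating toolkit for **Minimal Variant Level Data (MVLD)** — the
consensus field set for curating one clinically interpreted somatic cancer
variant.  It is written for variant curators, knowledgebase maintainers and
clinical bioinformaticians who exchange tables of somatic variant
assertions and need those tables to mean the same thing everywhere.

Somatic variant interpretations are scattered across knowledgebases that
capture similar content in incompatible shapes.  MVLD fixes a common
language: every record is one *variant-level assertion* — one variant × one
cancer type × one biomarker class × one therapeutic context — described by
three blocks of fields:

* **allele descriptive** — genome build (GRCh37/GRCh38), HUGO gene symbol,
  chromosome, 1-based position, RefSeq transcript/protein identifiers;
* **allele interpretive** — somatic classification (*Confirmed somatic* /
  *Confirmed germline* / *Unknown*), DNA and protein change in HGVS
  nomenclature, variant type (SNV/MNV/INS/DEL), a twelve-term molecular
  consequence vocabulary, supporting PMIDs;
* **cancer interpretive** — cancer type as an NCI Thesaurus or Oncotree
  term, biomarker class (*Diagnostic* / *Prognostic* / *Predictive*),
  therapeutic context, effect (*resistant, responsive, not-responsive,
  sensitive, reduced sensitivity* + *other*), level of evidence, and
  sub-level evidence in six citation-bearing categories.

The package models these records with checked constructors, validates them
against the standard's required/conditional/vocabulary/HGVS rules, assigns
CanDL four-tier levels of evidence from the supporting evidence, reads and
writes MVLD TSV/JSON, exports ClinVar-submission-style tables, and generates
seeded test corpora with controllable rule violations.  HGVS checking is
grammar-level by design — no genome or transcript is consulted.

## Worked example

```python
from mvld import (EvidenceAssertion, TierFlags, assign_tier,
                  check_dna_hgvs, infer_variant_type,
                  generate_records, validate_records)

# grammar-level HGVS checking and variant typing
parse = check_dna_hgvs("c.76_78delinsTT")
print(parse.edit_kind, infer_variant_type(parse))
# delins MNV                       <- a deletion-plus-insertion is an MNV

# CanDL tiering: strongest applicable tier, with its fixed sentence
result = assign_tier([EvidenceAssertion(category=5, pmids=(26619011,))], TierFlags())
print(f"Tier {result.tier}: {result.sentence}")
# Tier 3: Alteration predicts for response or resistance to therapy based
# on evidence from pre-clinical data (in vitro or in vivo models)

# a seeded corpus with two deliberate violations, run through the validator
records, manifest = generate_records(
    n=5, seed=11, error_spec={"REQ.GENE_NAME": 1, "COND.EFFECT_CONTEXT": 1})
print(validate_records(records).to_text())
# ERROR   COND.EFFECT_CONTEXT    records[0].cancer.therapeutic_context: ...
# ERROR   REQ.GENE_NAME          records[3].descriptor.gene_symbol: ...
# 2 error(s), 0 warning(s)
```

Each finding names a frozen rule id, the record index and the dotted field
path of the offending value; the validator reports problems and never
raises, so whole corpora are checked in one pass.  The `examples/`
directory holds one short script per capability (validation, HGVS syntax,
tiering, ClinVar export).

## Command line

```sh
mvld fixtures --n 50 --seed 1 --output corpus.tsv        # seeded corpus + manifest
mvld validate corpus.tsv --profile strict                # exit 0/1/2
mvld tier corpus.tsv --output tiered.tsv                 # fill CanDL levels
mvld convert tiered.tsv --output clinvar.tsv             # ClinVar-style export
```

Exit codes are fixed for pipelines: 0 — no errors, 1 — validation errors
(or a refused conversion), 2 — unreadable input.  Logs go to standard
error; data to standard output or `--output`.

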