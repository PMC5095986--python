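"""Export curated records as a ClinVar-submission-style table.

Only records with zero validation errors may be exported; the cancer type
renders as ``source:code (label)`` and the CanDL level renders into the
assertion-method column together with its structured tier sentence.
"""

import io

from mvld import generate_records, lookup_cancer_term, to_clinvar_row, write_clinvar_table

records, _ = generate_records(n=3, seed=42)

row = to_clinvar_row(records[0])
for key in ("gene_symbol", "dna_hgvs", "condition", "assertion_method", "citations"):
    print(f"{key:18s} {row[key]}")

buf = io.StringIO()
write_clinvar_table(records, buf)
print(f"\nwrote {len(buf.getvalue().splitlines()) - 1} rows")

# the packaged ontology subset resolves codes and labels either way
print(lookup_cancer_term("RGNT", "Oncotree"))
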