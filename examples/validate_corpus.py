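"""Generate a small curation table, break two records, and validate it.

Shows the rule engine's findings: deleting the gene symbol triggers the
required-field rule REQ.GENE_NAME; an effect recorded without naming a drug
triggers the conditional rule COND.EFFECT_CONTEXT.
"""

from mvld import generate_records, validate_records

records, _ = generate_records(n=5, seed=11)
broken, manifest = generate_records(
    n=5, seed=11, error_spec={"REQ.GENE_NAME": 1, "COND.EFFECT_CONTEXT": 1}
)

report = validate_records(broken, profile="submission")
print(report.to_text())
# Each ERROR line names the frozen rule id, the record index and the dotted
# field path of the offending value; warnings never block a submission.
print("injected:", [(v.index, v.rule_id) for v in manifest.injected])
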