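"""Syntax-check HGVS variant descriptions and derive the MVLD Variant Type.

Parsing is grammar-level only (no genome or transcript is consulted): each
string either yields a structured parse or a parse error naming the
offending span.  The variant type follows the length rule — one base for one
base is an SNV, any larger replacement is an MNV, pure gains are INS, pure
losses are DEL.
"""

from mvld import HgvsSyntaxError, check_protein_hgvs, check_dna_hgvs, infer_variant_type

for text in ["c.76A>T", "c.76_78delinsTT", "c.76_77insG", "c.76del", "c.88+2T>G", "76A>T"]:
    try:
        parse = check_dna_hgvs(text)
    except HgvsSyntaxError as exc:
        print(f"{text:18s} REJECTED: {exc}")
        continue
    print(f"{text:18s} {parse.edit_kind:13s} -> {infer_variant_type(parse)}")

# protein descriptions normalize to one-letter code
print(check_protein_hgvs("p.Val600Glu").serialize())  # p.V600E
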