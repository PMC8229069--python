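"""Classify IUPAC consensus calls against a reference allele.

A Sanger consensus of a PCR-amplified satellite monomer reports variable
positions as ambiguity codes: a single base is a homozygous call, a two-base
code heterozygous, a three-base code a "triplet" heterozygous state.
"""

from satprofile import base_set, classify_state, encode_set

for code in ("A", "G", "R", "Y", "B", "N", "-"):
    bases = sorted(base_set(code)) if code not in "-" else []
    z = classify_state(code, ref="A")
    print(f"call {code!r:4} base set {bases!s:18} vs reference A -> {z.value}")

print()
print("encode {A,G}   ->", encode_set({"A", "G"}))
print("encode {C,G,T} ->", encode_set({"C", "G", "T"}))
# HOM_REF/HOM_ALT: single-base calls; HET_*: two-base codes; HET3: triplets;
# MISSING: gap or N, which assert no call at all.
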