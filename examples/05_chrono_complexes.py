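"""Rule-based enumeration of CHRONO-containing protein complexes.

CHRONO's pairwise contact map (binds BMAL1, PER2 and DEC2; the PER1,
CRY1 and DEC1 contacts are absent, and the CHRONO-CRY2 contact is
deliberately excluded from the clock model) determines which complexes
can exist.  This is the machinery the detailed-mode extension uses to add
CHRONO species to an externally supplied base model.
"""

from chronosim import CHRONO_BINDING_RULES, enumerate_chrono_complexes

monomers = ["BMAL1", "PER1", "PER2", "CRY1", "CRY2", "DEC1", "DEC2"]
for size in (2, 3, 4):
    out = enumerate_chrono_complexes(monomers, CHRONO_BINDING_RULES, size)
    print(f"max complex size {size}: {len(out)} CHRONO-containing species")
    for sp in out:
        print("   ", sp.name)
# No complex ever contains PER1, CRY1, DEC1 (no binding) or CRY2 (contact
# not represented in the model); larger complexes are cliques of allowed
# pairwise contacts.
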