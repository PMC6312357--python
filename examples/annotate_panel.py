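"""Annotate a synthetic ECC panel and inspect one record's feature map.

Generates a small noise-free panel (one sequence per group), runs the
full annotation pass, and prints the located features of a group D ECC:
helix spans, the EDVID motif and its upstream polar stretch, CC-END, the
CCVX linker, the charged motif and the pre-P-loop/P-loop anchors.  All
coordinates are 1-based residue positions.
"""

from ecckit import annotate_ecc
from ecckit.simulate import PanelSpec, gen_ecc_panel

records, truths = gen_ecc_panel(
    PanelSpec(seed=4, counts={"A": 1, "B": 1, "C": 1, "D": 1, "E": 1})
)
record = next(r for r in records if r.id.startswith("ECC_D"))
ann = annotate_ecc(record)

print(f"record {record.id}: {len(record.residues)} residues")
for h in ann.helices:
    print(f"  helix {h.label:4s} {h.start:4d}-{h.end}")
for m in ann.motifs:
    print(f"  motif {m.name:14s} {m.start:4d}-{m.end}  {m.matched_text}")
print(f"  CC-END at {ann.cc_end}")
s, e, canonical = ann.ccvx
print(f"  CCVX {s}-{e} (length {e - s + 1}, canonical={canonical})")
cm = ann.charged
print(
    f"  charged motif {cm.start}-{cm.end}: {cm.n_acidic} acidic, "
    f"{cm.n_basic} basic, fraction {cm.charged_fraction:.2f}"
)
print(f"  ECC boundary (last residue before P-loop): {ann.ecc_boundary}")
# The charged window sits at -11..-3 of the VG dipeptide; CCVX fills the
# gap between the last heptad hydrophobic of H2b and that window.
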