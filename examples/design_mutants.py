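"""Build the chimera/deletion/point-mutant series from two annotated ECCs.

Breakpoints are features, not coordinates: CC-END, the first acidic
residue of the charged motif, or the VG of the pre-P-loop.  Every product
is re-annotated, so downstream feature coordinates are always recomputed
on the mutant itself.
"""

from ecckit import annotate_ecc
from ecckit.mutagen import (
    ChimeraSpec,
    PointMutation,
    apply_point_mutations,
    delete_segment,
    swap_at_breakpoint,
)
from ecckit.simulate import PanelSpec, gen_ecc_panel

records, _ = gen_ecc_panel(
    PanelSpec(seed=13, counts={"A": 0, "B": 2, "C": 0, "D": 0, "E": 0})
)
a, b = (annotate_ecc(r) for r in records)
print(f"parents: {a.record.id} ({len(a.record.residues)} aa), "
      f"{b.record.id} ({len(b.record.residues)} aa)")

for breakpoint in ("CC_END", "CHARGED", "VG"):
    ab, ba = swap_at_breakpoint(ChimeraSpec(a, b, breakpoint, label=breakpoint))
    print(f"swap at {breakpoint:7s}: {ab.id} ({len(ab.residues)} aa), "
          f"{ba.id} ({len(ba.residues)} aa)")

deleted = delete_segment(a, "charged")
print(f"charged-motif deletion: {deleted.id} "
      f"({len(a.record.residues)} -> {len(deleted.residues)} aa)")

# charge-reversal within the charged island (E -> K), then re-annotate
seq = a.record.residues
acidic = [
    i for i in range(a.charged.start, a.charged.end + 1) if seq[i - 1] in "DE"
][:2]
mutant = apply_point_mutations(
    a, [PointMutation(i, seq[i - 1], "K") for i in acidic]
)
ann = annotate_ecc(mutant)
print(f"E->K mutant {mutant.id}: charged motif now {ann.charged.n_acidic} acidic / "
      f"{ann.charged.n_basic} basic (was {a.charged.n_acidic}/{a.charged.n_basic})")
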