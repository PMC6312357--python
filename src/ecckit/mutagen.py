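"""Design of chimeric, deletion and point-mutant ECC variants.

Chimeras are cut at one of three feature-defined breakpoints: CC-END (the
last a/d heptad hydrophobic of the final helix), the first acidic residue
of the charged motif, or the V of the pre-P-loop VG dipeptide.  Recipes
reference features rather than absolute positions, because breakpoint
coordinates differ between parents.  Every constructed variant should be
re-annotated — the pipeline never trusts parental coordinates on a mutant.
"""

from __future__ import annotations

from dataclasses import dataclass

from ecckit.architecture import ACIDIC, EccAnnotation
from ecckit.seqio import SequenceRecord

BREAKPOINTS = ("CC_END", "CHARGED", "VG")


@dataclass(frozen=True)
class ChimeraSpec:
    parent_a: EccAnnotation
    parent_b: EccAnnotation
    breakpoint: str
    label: str = ""

    def __post_init__(self):
        if self.breakpoint not in BREAKPOINTS:
            raise ValueError(
                f"unknown breakpoint {self.breakpoint!r}; expected one of {BREAKPOINTS}"
            )


@dataclass(frozen=True)
class PointMutation:
    position: int
    from_res: str
    to_res: str


def _breakpoint_anchor(ann: EccAnnotation, breakpoint: str) -> int:
    """1-based anchor residue of a breakpoint feature; raises if absent."""
    pid = ann.record.id
    if breakpoint == "CC_END":
        if ann.cc_end is None:
            raise ValueError(f"parent {pid!r} has no CC-END")
        return ann.cc_end
    if breakpoint == "CHARGED":
        if ann.charged is None:
            raise ValueError(f"parent {pid!r} has no charged motif")
        seg = ann.record.slice(ann.charged.start, ann.charged.end)
        for i, aa in enumerate(seg):
            if aa in ACIDIC:
                return ann.charged.start + i
        raise ValueError(
            f"parent {pid!r}: charged motif contains no acidic (E/D) residue "
            "to anchor the breakpoint"
        )
    # VG
    pre = ann.motif("preploop")
    if pre is None:
        raise ValueError(f"parent {pid!r} has no pre-P-loop VG")
    return pre.start


def swap_at_breakpoint(spec: ChimeraSpec):
    """Reciprocal swap: each chimera keeps one parent's N-terminus up to the
    breakpoint anchor and takes the other parent's remainder."""
    a, b = spec.parent_a, spec.parent_b
    bp_a = _breakpoint_anchor(a, spec.breakpoint)
    bp_b = _breakpoint_anchor(b, spec.breakpoint)
    seq_a, seq_b = a.record.residues, b.record.residues
    suffix = f"_{spec.label}" if spec.label else f"_swap{spec.breakpoint}"
    chimera_ab = SequenceRecord(
        id=f"{a.record.id}{suffix}",
        residues=seq_a[:bp_a] + seq_b[bp_b:],
        description=f"chimera {a.record.id}[1..{bp_a}]+{b.record.id}[{bp_b + 1}..]",
    )
    chimera_ba = SequenceRecord(
        id=f"{b.record.id}{suffix}",
        residues=seq_b[:bp_b] + seq_a[bp_a:],
        description=f"chimera {b.record.id}[1..{bp_b}]+{a.record.id}[{bp_a + 1}..]",
    )
    return chimera_ab, chimera_ba


def delete_segment(parent: EccAnnotation, segment) -> SequenceRecord:
    """Excise a segment, given as a feature name ('charged', 'ccvx', 'EDVID',
    ...) or an explicit 1-based inclusive (start, end) pair.

    An empty segment (start > end) is the identity.
    """
    if isinstance(segment, str):
        start, end = _named_segment(parent, segment)
    else:
        start, end = segment
    seq = parent.record.residues
    if start > end:  # empty deletion
        return parent.record
    if not (1 <= start and end <= len(seq)):
        raise ValueError(
            f"segment [{start}, {end}] out of range for {parent.record.id!r} "
            f"(length {len(seq)})"
        )
    return SequenceRecord(
        id=f"{parent.record.id}_del{start}-{end}",
        residues=seq[: start - 1] + seq[end:],
        description=f"deletion of [{start}, {end}] from {parent.record.id}",
    )


def _named_segment(ann: EccAnnotation, name: str):
    if name == "charged":
        if ann.charged is None:
            raise ValueError(f"{ann.record.id!r} has no charged motif")
        return ann.charged.start, ann.charged.end
    if name == "ccvx":
        if ann.ccvx is None:
            raise ValueError(f"{ann.record.id!r} has no CCVX segment")
        return ann.ccvx[0], ann.ccvx[1]
    hit = ann.motif(name)
    if hit is None:
        raise ValueError(f"{ann.record.id!r} has no feature {name!r}")
    return hit.start, hit.end


def apply_point_mutations(parent: EccAnnotation, mutations) -> SequenceRecord:
    """Apply substitutions; each mutation's from_res is checked against the
    parent to guard against coordinate drift."""
    seq = list(parent.record.residues)
    for mut in mutations:
        if not (1 <= mut.position <= len(seq)):
            raise ValueError(
                f"position {mut.position} out of range for {parent.record.id!r}"
            )
        actual = seq[mut.position - 1]
        if actual != mut.from_res:
            raise ValueError(
                f"{parent.record.id!r} position {mut.position}: expected "
                f"{mut.from_res!r} but found {actual!r}"
            )
        seq[mut.position - 1] = mut.to_res
    tag = "".join(f"_{m.from_res}{m.position}{m.to_res}" for m in mutations) or "_wt"
    return SequenceRecord(
        id=f"{parent.record.id}{tag}",
        residues="".join(seq),
        description=f"point mutant of {parent.record.id}",
    )
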