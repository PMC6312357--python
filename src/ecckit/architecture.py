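"""Feature annotation of ECC fragments.

An ECC (extended coiled-coil domain) is the whole N-terminus of a CC-NLR up
to, but not including, the Walker-A P-loop of the NB-ARC domain.  This
module locates every sequence feature the downstream classifier and mutant
designer rely on:

* Kyte-Doolittle hydropathy profile (window 3 by default);
* alpha-helix blocks (internal Chou-Fasman-type propensity heuristic, or a
  user-supplied per-residue track);
* the coiled-coil heptad register (a-g), chosen per helix as the frame that
  maximises L/I/V occupancy of the a/d interface positions;
* the EDVID motif of helix H2a and the 10-residue polar stretch that
  precedes it in group D;
* the pre-P-loop motif [VI] G x8 [LI] x3 L whose VG dipeptide anchors the
  downstream coordinate system;
* the Walker-A P-loop G x4 G K [ST], defining the ECC boundary;
* the charged motif at positions -11..-3 relative to the VG dipeptide;
* CC-END (last a/d heptad hydrophobic of the final helix) and the variable
  CCVX segment between CC-END and the charged motif;
* N-terminal acylation signals (myristoylation Gly-2/Gly-3, palmitoylation
  Cys-4/Ser-4).

All coordinates are 1-based inclusive.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

from ecckit.seqio import SequenceRecord

# Kyte & Doolittle (1982) hydropathicity scale, kcal-free arbitrary units.
KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}

# Chou-Fasman alpha-helix propensities (P_alpha), used by the internal
# helix heuristic when no external secondary-structure track is supplied.
CHOU_FASMAN_HELIX = {
    "A": 1.42, "C": 0.70, "D": 1.01, "E": 1.51, "F": 1.13,
    "G": 0.57, "H": 1.00, "I": 1.08, "K": 1.16, "L": 1.21,
    "M": 1.45, "N": 0.67, "P": 0.57, "Q": 1.11, "R": 0.98,
    "S": 0.77, "T": 0.83, "V": 1.06, "W": 1.08, "Y": 0.69,
}

HEPTAD_HYDROPHOBIC = frozenset("LIV")
POLAR = frozenset("STNQDEKRHY")
ACIDIC = frozenset("DE")
BASIC = frozenset("KR")
CHARGED = frozenset("DEKR")

#: default threshold on smoothed helix propensity
THETA_HELIX = 1.03
#: minimum helix block length (residues)
MIN_HELIX_LEN = 6
#: default polar-stretch threshold: >= 8 of the 10 upstream residues polar
THETA_POLAR = 8

PREPLOOP_RE = re.compile(r"[VI]G.{8}[LI].{3}L")
PLOOP_RE = re.compile(r"G.{4}GK[ST]")
#: canonical CCVX length range (residues)
CCVX_CANONICAL = (16, 18)


@dataclass(frozen=True)
class HydropathyProfile:
    values: tuple
    window: int
    offset: int = 1  # profile index i (0-based) covers residues offset+i .. +window-1


@dataclass(frozen=True)
class HelixSpan:
    label: str  # H1a, H1b, H2a, H2b, H1, other
    start: int
    end: int

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError(f"helix span start {self.start} > end {self.end}")

    def __len__(self):
        return self.end - self.start + 1

    def contains(self, pos: int) -> bool:
        return self.start <= pos <= self.end


@dataclass(frozen=True)
class MotifHit:
    name: str
    start: int
    end: int
    matched_text: str
    mismatches: int = 0

    def __post_init__(self):
        if self.end - self.start + 1 != len(self.matched_text):
            raise ValueError("matched_text length disagrees with span")


@dataclass(frozen=True)
class ChargedMotif:
    """The 9-residue window at -11..-3 relative to the pre-P-loop VG."""

    start: int
    end: int
    n_acidic: int
    n_basic: int
    charged_fraction: float
    relative_window: tuple = (-11, -3)


@dataclass
class EccAnnotation:
    record: SequenceRecord
    helices: list = field(default_factory=list)
    heptad_register: str = ""
    motifs: list = field(default_factory=list)
    cc_end: int | None = None
    ccvx: tuple | None = None  # (start, end, canonical: bool)
    charged: ChargedMotif | None = None
    ecc_boundary: int | None = None
    myristoylation: bool = False
    palmitoylation: bool = False
    group: object = None  # GroupAssignment, filled by ecckit.classify

    def motif(self, name: str):
        for m in self.motifs:
            if m.name == name:
                return m
        return None

    def check_feature_order(self) -> None:
        """Assert the canonical feature order along the sequence.

        helices < cc_end < ccvx < charged < VG < P-loop; raises on violation.
        """
        if self.cc_end is not None and self.helices:
            if self.cc_end > max(h.end for h in self.helices):
                raise AssertionError("cc_end lies beyond the last helix")
        if self.ccvx is not None and self.cc_end is not None:
            if not self.cc_end < self.ccvx[0]:
                raise AssertionError("ccvx does not follow cc_end")
        if self.ccvx is not None and self.charged is not None:
            if self.ccvx[1] != self.charged.start - 1:
                raise AssertionError("ccvx does not abut the charged motif")
        pre = self.motif("preploop")
        if self.charged is not None and pre is not None:
            if not self.charged.end < pre.start:
                raise AssertionError("charged motif does not precede the VG dipeptide")
        ploop = self.motif("ploop")
        if ploop is not None and pre is not None:
            if not pre.start < ploop.start:
                raise AssertionError("pre-P-loop does not precede the P-loop")
        if ploop is not None and self.ecc_boundary is not None:
            if not self.ecc_boundary < ploop.start:
                raise AssertionError("ECC boundary overlaps the P-loop")


def hydropathy_profile(record: SequenceRecord, window: int = 3) -> HydropathyProfile:
    """Sliding-window mean Kyte-Doolittle hydropathy (full windows only)."""
    if window % 2 == 0 or window < 1:
        raise ValueError(f"window must be odd and positive, got {window}")
    n = len(record.residues)
    if window > n:
        raise ValueError(f"window {window} exceeds sequence length {n}")
    vals = np.array([KYTE_DOOLITTLE[aa] for aa in record.residues])
    kernel = np.ones(window) / window
    means = np.convolve(vals, kernel, mode="valid")
    return HydropathyProfile(values=tuple(float(v) for v in means), window=window)


def _smoothed_propensity(residues: str, window: int = 7) -> np.ndarray:
    """Centered moving average of helix propensity; edge windows truncated."""
    vals = np.array([CHOU_FASMAN_HELIX[aa] for aa in residues])
    n = len(vals)
    half = window // 2
    cum = np.concatenate([[0.0], np.cumsum(vals)])
    out = np.empty(n)
    for i in range(n):
        lo = max(0, i - half)
        hi = min(n, i + half + 1)
        out[i] = (cum[hi] - cum[lo]) / (hi - lo)
    return out


#: a first block at least this long is taken as a merged H1a+H1b helix
MERGED_H1_MIN_LEN = 24


def _label_helices(spans: list) -> list:
    """Assign H1a/H1b/H2a/H2b to the first four blocks in order.

    A first block long enough to host both N-terminal helices (the H1a-H1b
    separation is often not predicted) is labelled H1 (merged).
    """
    labels = ["H1a", "H1b", "H2a", "H2b"]
    if spans and spans[0][1] - spans[0][0] + 1 >= MERGED_H1_MIN_LEN:
        labels = ["H1", "H2a", "H2b"]
    out = []
    for i, (s, e) in enumerate(spans):
        label = labels[i] if i < len(labels) else "other"
        out.append(HelixSpan(label=label, start=s, end=e))
    return out


def predict_helix_blocks(
    record: SequenceRecord,
    tracks=None,
    theta: float = THETA_HELIX,
    window: int = 7,
    min_len: int = MIN_HELIX_LEN,
) -> list:
    """Helix blocks from a propensity heuristic or a user-supplied track.

    ``tracks``, when given, is a boolean per-residue iterable (True =
    helical) that overrides the internal heuristic entirely.
    """
    n = len(record.residues)
    if tracks is not None:
        flags = list(tracks)
        if len(flags) != n:
            raise ValueError(f"track length {len(flags)} != sequence length {n}")
        helical = np.asarray(flags, dtype=bool)
    else:
        helical = _smoothed_propensity(record.residues, window=window) > theta
    spans = []
    i = 0
    while i < n:
        if helical[i]:
            j = i
            while j + 1 < n and helical[j + 1]:
                j += 1
            if j - i + 1 >= min_len:
                spans.append((i + 1, j + 1))  # to 1-based inclusive
            i = j + 1
        else:
            i += 1
    return _label_helices(spans)


def assign_heptad_register(record: SequenceRecord, helices: list) -> str:
    """Per-residue heptad letters a-g inside helices, '.' outside.

    Within each helix the frame (of 7) maximising the number of L/I/V at
    the a and d interface positions is chosen; ties break toward the
    smaller frame offset.
    """
    letters = "abcdefg"
    register = ["."] * len(record.residues)
    for h in helices:
        seg = record.residues[h.start - 1 : h.end]
        best_frame, best_count = 0, -1
        for frame in range(7):
            count = sum(
                1
                for i, aa in enumerate(seg)
                if aa in HEPTAD_HYDROPHOBIC and (i - frame) % 7 in (0, 3)
            )
            if count > best_count:
                best_frame, best_count = frame, count
        for i in range(len(seg)):
            register[h.start - 1 + i] = letters[(i - best_frame) % 7]
    return "".join(register)


def find_edvid(record: SequenceRecord, max_mismatch: int = 0):
    """Best (fewest mismatches, then leftmost) EDVID occurrence, or None."""
    target = "EDVID"
    seq = record.residues
    best = None
    for i in range(len(seq) - len(target) + 1):
        mm = sum(1 for a, b in zip(seq[i : i + 5], target) if a != b)
        if mm <= max_mismatch and (best is None or mm < best[1]):
            best = (i, mm)
            if mm == 0:
                break
    if best is None:
        return None
    i, mm = best
    return MotifHit(
        name="EDVID", start=i + 1, end=i + 5, matched_text=seq[i : i + 5], mismatches=mm
    )


def find_polar_stretch(
    record: SequenceRecord, edvid: MotifHit, theta_polar: int = THETA_POLAR
):
    """The group-D polar stretch: 10 residues immediately before EDVID.

    A hit requires >= ``theta_polar`` of those 10 residues to be polar
    (S/T/N/Q/D/E/K/R/H/Y); fewer than 10 upstream residues means no hit.
    """
    if edvid is None:
        raise ValueError("find_polar_stretch requires an EDVID hit")
    start = edvid.start - 10
    if start < 1:
        return None
    seg = record.slice(start, edvid.start - 1)
    n_polar = sum(1 for aa in seg if aa in POLAR)
    if n_polar < theta_polar:
        return None
    return MotifHit(
        name="polar_stretch",
        start=start,
        end=edvid.start - 1,
        matched_text=seg,
        mismatches=10 - n_polar,
    )


def find_preploop(record: SequenceRecord):
    """Leftmost pre-P-loop motif [VI] G x8 [LI] x3 L (15 residues)."""
    m = PREPLOOP_RE.search(record.residues)
    if m is None:
        return None
    return MotifHit(
        name="preploop", start=m.start() + 1, end=m.end(), matched_text=m.group(0)
    )


def find_ploop(record: SequenceRecord, after: int | None = None):
    """Leftmost Walker-A P-loop G x4 G K [ST] after ``after`` (1-based)."""
    offset = after if after is not None else 0
    m = PLOOP_RE.search(record.residues, pos=offset)
    if m is None:
        return None
    return MotifHit(
        name="ploop", start=m.start() + 1, end=m.end(), matched_text=m.group(0)
    )


def locate_charged_motif(record: SequenceRecord, vg_position: int) -> ChargedMotif:
    """Charged-motif window at -11..-3 relative to the VG dipeptide's V."""
    start = vg_position - 11
    end = vg_position - 3
    if start < 1:
        raise ValueError(
            f"charged-motif window starts at {start} (< 1): VG at {vg_position} "
            f"leaves only {vg_position - 1} upstream residues, 11 required"
        )
    seg = record.slice(start, end)
    n_acidic = sum(1 for aa in seg if aa in ACIDIC)
    n_basic = sum(1 for aa in seg if aa in BASIC)
    frac = sum(1 for aa in seg if aa in CHARGED) / len(seg)
    return ChargedMotif(
        start=start, end=end, n_acidic=n_acidic, n_basic=n_basic, charged_fraction=frac
    )


def find_cc_end(record: SequenceRecord, register: str, helices: list):
    """CC-END: last L/I/V at an a/d register position within the last helix."""
    if not helices:
        return None
    last = helices[-1]
    for pos in range(last.end, last.start - 1, -1):
        aa = record.residues[pos - 1]
        if aa in HEPTAD_HYDROPHOBIC and register[pos - 1] in ("a", "d"):
            return pos
    return None


def extract_ccvx(record: SequenceRecord, cc_end: int, charged: ChargedMotif):
    """CCVX segment between CC-END and the charged motif.

    Returns (start, end, canonical) where canonical marks a length within
    the 16-18 residue range seen for natural ECCs.
    """
    if cc_end >= charged.start:
        raise ValueError(
            f"cc_end {cc_end} does not precede the charged motif at {charged.start}"
        )
    start, end = cc_end + 1, charged.start - 1
    length = end - start + 1
    canonical = CCVX_CANONICAL[0] <= length <= CCVX_CANONICAL[1]
    return (start, end, canonical)


def detect_acylation(record: SequenceRecord) -> dict:
    """N-terminal acylation flags: myristoylation Gly-2/Gly-3, palmitoylation
    Cys-4 or Ser-4."""
    seq = record.residues
    if len(seq) < 4:
        raise ValueError("sequence shorter than 4 residues")
    return {
        "myristoylation": seq[1] == "G" and seq[2] == "G",
        "palmitoylation": seq[3] in ("C", "S"),
    }


def annotate_ecc(
    record: SequenceRecord,
    tracks=None,
    max_mismatch: int = 0,
    theta_polar: int = THETA_POLAR,
    theta_helix: float = THETA_HELIX,
) -> EccAnnotation:
    """Run every feature finder in dependency order and compose the result.

    Absent features are recorded as absent — never fabricated; the charged
    motif and CCVX are only defined when the pre-P-loop VG anchor exists.
    """
    ann = EccAnnotation(record=record)
    ann.helices = predict_helix_blocks(record, tracks=tracks, theta=theta_helix)

    pre = find_preploop(record)
    if pre is not None:
        ann.motifs.append(pre)
        if pre.start - 11 >= 1:
            ann.charged = locate_charged_motif(record, pre.start)
        # the CC helix bundle lies N-terminal of the linker: propensity runs
        # that sit mostly in or after the charged motif belong to the linker
        # or NB region (charged and Walker-A residues are themselves helix
        # favourable) and are not CC helices — keep a run only if the
        # majority of its residues precede the charged motif
        cc_limit = ann.charged.start if ann.charged is not None else pre.start
        spans = [
            (h.start, h.end)
            for h in ann.helices
            if (min(h.end, cc_limit - 1) - h.start + 1) * 2 > len(h)
        ]
        ann.helices = _label_helices(spans)
    ann.heptad_register = assign_heptad_register(record, ann.helices)

    edvid = find_edvid(record, max_mismatch=max_mismatch)
    if edvid is not None:
        ann.motifs.append(edvid)
        polar = find_polar_stretch(record, edvid, theta_polar=theta_polar)
        if polar is not None:
            ann.motifs.append(polar)

    ploop = find_ploop(record, after=pre.start if pre is not None else None)
    if ploop is not None:
        ann.motifs.append(ploop)
        ann.ecc_boundary = ploop.start - 1
    else:
        ann.ecc_boundary = len(record.residues)

    ann.cc_end = find_cc_end(record, ann.heptad_register, ann.helices)
    if ann.cc_end is not None and ann.charged is not None and ann.cc_end < ann.charged.start:
        ann.ccvx = extract_ccvx(record, ann.cc_end, ann.charged)

    if len(record.residues) >= 4:
        acyl = detect_acylation(record)
        ann.myristoylation = acyl["myristoylation"]
        ann.palmitoylation = acyl["palmitoylation"]

    ann.check_feature_order()
    return ann


# --------------------------------------------------------------------------
# export

_GFF_TYPES = {
    "EDVID": "EDVID",
    "polar_stretch": "polar_stretch",
    "preploop": "preploop",
    "ploop": "ploop",
}


def annotation_to_gff3(annotations) -> str:
    """Serialise annotations as GFF3 in protein coordinates (1-based incl.)."""
    lines = ["##gff-version 3"]

    def row(seqid, ftype, start, end, attrs):
        lines.append(
            "\t".join([seqid, "ecckit", ftype, str(start), str(end), ".", ".", ".", attrs])
        )

    for ann in annotations:
        sid = ann.record.id
        for h in ann.helices:
            row(sid, "ECC_helix", h.start, h.end, f"Name={h.label}")
        for m in ann.motifs:
            row(sid, _GFF_TYPES.get(m.name, m.name), m.start, m.end,
                f"Name={m.name};mismatches={m.mismatches}")
        if ann.charged is not None:
            row(sid, "charged_motif", ann.charged.start, ann.charged.end,
                f"n_acidic={ann.charged.n_acidic};n_basic={ann.charged.n_basic}")
        if ann.ccvx is not None:
            s, e, canonical = ann.ccvx
            row(sid, "CCVX", s, e, f"canonical={str(canonical).lower()}")
        if ann.cc_end is not None:
            row(sid, "CC_END", ann.cc_end, ann.cc_end, "Name=CC_END")
    return "\n".join(lines) + "\n"


def annotation_table(annotations):
    """Flat per-record feature summary as a pandas DataFrame."""
    import pandas as pd

    rows = []
    for ann in annotations:
        edvid = ann.motif("EDVID")
        polar = ann.motif("polar_stretch")
        pre = ann.motif("preploop")
        ploop = ann.motif("ploop")
        rows.append(
            {
                "id": ann.record.id,
                "length": len(ann.record.residues),
                "n_helices": len(ann.helices),
                "edvid_start": edvid.start if edvid else None,
                "polar_stretch": polar is not None,
                "preploop_start": pre.start if pre else None,
                "ploop_start": ploop.start if ploop else None,
                "cc_end": ann.cc_end,
                "ccvx_start": ann.ccvx[0] if ann.ccvx else None,
                "ccvx_len": (ann.ccvx[1] - ann.ccvx[0] + 1) if ann.ccvx else None,
                "ccvx_canonical": ann.ccvx[2] if ann.ccvx else None,
                "charged_fraction": ann.charged.charged_fraction if ann.charged else None,
                "ecc_boundary": ann.ecc_boundary,
                "myristoylation": ann.myristoylation,
                "palmitoylation": ann.palmitoylation,
                "group": ann.group.group if ann.group else None,
            }
        )
    return pd.DataFrame(rows)
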