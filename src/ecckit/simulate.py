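"""Synthetic inputs with planted ground truth for every pipeline stage.

Three generators cover the study conditions the pipeline is built for:

* :func:`gen_ecc_panel` — protein panels with group-structured ECC
  architectures: group-specific N-terminal caps, helix blocks carrying
  L/I at the a/d heptad interface, P/G-rich turns, a 16-18 residue CCVX
  linker, a charged motif at -11..-3 of a planted VG pre-P-loop, and a
  Walker-A terminus.  Substitution noise at rate ``epsilon`` is applied
  outside planted anchors by default, and the true coordinates of every
  planted feature accompany each record.

* :func:`gen_y2h_screen` — replicated yeast-two-hybrid matings over a
  panel: latent true edges drawn per group-pair probability, then each of
  the 8 orientation-replicates (4 for self pairs) flips positive with
  probability 1-FN on true edges and FP otherwise.

* :func:`gen_f2_population` — a single-QTL F2 intercross (default n = 75,
  5 chromosomes x 10 markers at 10 cM) with Haldane-map-function
  recombination and an incomplete-dominance phenotype (d = a/2)
  discretised onto the ordinal 1-5 scale at quintile cut points.

All generators are pure functions of (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ecckit.interactome import MatingResult
from ecckit.qtl import F2Population, GeneticMap
from ecckit.seqio import SequenceRecord

# ----------------------------------------------------------------- panels

#: heptad building block, 'a' position L and 'd' position I
HEPTAD_UNIT = "LAEIAQA"
TURN = "PGSNPG"
CAP_B = "MGGC"  # myristoylation (G2, G3) + palmitoylation (C4)
CAP_CD = "MSDA"
#: synthetic CC_R/RPW8-like signature used for planted group A sequences
#: and as the package's default consensus for the group A classifier rule
RPW8_SIGNATURE = "MSDNPRWQTHYSNDPGRWTQHNSE"
POLAR10 = "QEQEDQHEQE"
EDVID = "EDVID"
PREPLOOP_X = "STN"  # filler alphabet inside the pre-P-loop wildcards
CCVX_FILL = "STNPG"
CCVX_CAP = "QAM"  # helix-capping start keeps the terminal H2b 'a'-L detectable
SPACER = "NS"  # positions -2, -1 relative to the VG dipeptide
PLOOP = "GMGGLGKTT"
DISORDER_ALPHABET = "STNGP"
#: substitution alphabet under anchor protection: cannot seed L/I/V heptads,
#: [VI]G, G..GK[ST] or EDVID at a mutated site
SAFE_SUBS = "ASTNQDERHFYWMCP"
ALL_AA = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class PanelSpec:
    """Per-group sequence counts plus noise and layout parameters."""

    counts: dict = field(default_factory=lambda: {"A": 6, "B": 23, "C": 8, "D": 14, "E": 5})
    linker_lengths: tuple = (16, 17, 18)
    epsilon: float = 0.0
    protect_anchors: bool = True
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.epsilon <= 1.0:
            raise ValueError(f"epsilon {self.epsilon} outside [0, 1]")
        if any(c < 0 for c in self.counts.values()):
            raise ValueError("group counts must be non-negative")
        if any(l < 3 for l in self.linker_lengths):
            raise ValueError("linker lengths must be at least 3 (CCVX cap)")


def _helix_truth(label, start, length):
    return {"label": label, "start": start, "end": start + length - 1}


def _build_canonical(group: str, linker_len: int, rng) -> tuple:
    """Assemble one noise-free sequence and its ground-truth coordinates."""
    parts = []
    truth = {
        "group": group,
        "helices": [],
        "edvid": None,
        "polar": None,
        "anchors": set(),
    }

    def emit(text):
        start = sum(len(p) for p in parts) + 1
        parts.append(text)
        return start

    if group == "A":
        cap_start = emit(RPW8_SIGNATURE)
        truth["anchors"].update(range(cap_start, cap_start + len(RPW8_SIGNATURE)))
    elif group == "B":
        cap_start = emit(CAP_B)
        truth["anchors"].update(range(1, 5))
    else:
        cap_start = emit(CAP_CD)
        truth["anchors"].update(range(1, 5))

    if group == "E":
        length = int(rng.integers(100, 131))
        emit("".join(rng.choice(list(DISORDER_ALPHABET), size=length)))
    else:
        for label in ("H1a", "H1b", "H2a", "H2b"):
            if label == "H2a":
                if group == "D":
                    block = HEPTAD_UNIT + POLAR10 + EDVID + "QAEAQA" + HEPTAD_UNIT
                elif group == "C":
                    block = HEPTAD_UNIT + EDVID + "QA" + HEPTAD_UNIT
                else:
                    block = HEPTAD_UNIT * 3
            elif label == "H2b":
                block = HEPTAD_UNIT * 2 + "L"
            else:
                block = HEPTAD_UNIT * 2
            start = emit(block)
            truth["helices"].append(_helix_truth(label, start, len(block)))
            # a/d interface positions are planted anchors
            for i, aa in enumerate(block):
                if aa in "LIV" and i % 7 in (0, 3):
                    truth["anchors"].add(start + i)
            if label == "H2a" and group in ("C", "D"):
                off = len(HEPTAD_UNIT) + (len(POLAR10) if group == "D" else 0)
                truth["edvid"] = (start + off, start + off + 4)
                truth["anchors"].update(range(start + off, start + off + 5))
                if group == "D":
                    truth["polar"] = (start + 7, start + 16)
                    truth["anchors"].update(range(start + 7, start + 17))
            if label != "H2b":
                emit(TURN)

        truth["cc_end"] = truth["helices"][-1]["end"]  # terminal 'a'-position L
        truth["anchors"].add(truth["cc_end"])
        ccvx_start = emit(
            CCVX_CAP + "".join(rng.choice(list(CCVX_FILL), size=linker_len - len(CCVX_CAP)))
        )
        truth["ccvx"] = (ccvx_start, ccvx_start + linker_len - 1)

    charged_seq = "E" + "".join(rng.choice(list("DEKR"), size=8))
    charged_start = emit(charged_seq)
    truth["charged"] = (charged_start, charged_start + 8)
    truth["anchors"].update(range(charged_start, charged_start + 9))
    emit(SPACER)
    x8 = "".join(rng.choice(list(PREPLOOP_X), size=8))
    x3 = "".join(rng.choice(list(PREPLOOP_X), size=3))
    pre_start = emit("VG" + x8 + "L" + x3 + "L")
    truth["preploop_start"] = pre_start
    truth["anchors"].update({pre_start, pre_start + 1, pre_start + 10, pre_start + 14})
    ploop_start = emit(PLOOP)
    truth["ploop_start"] = ploop_start
    truth["anchors"].update(range(ploop_start, ploop_start + len(PLOOP)))

    if group == "E":
        truth["cc_end"] = None
        truth["ccvx"] = None

    seq = "".join(parts)
    truth["length"] = len(seq)
    truth["ecc_boundary"] = ploop_start - 1
    truth["myristoylation"] = seq[1:3] == "GG"
    truth["palmitoylation"] = seq[3] in "CS"
    return seq, truth


def _apply_noise(seq: str, truth: dict, spec: PanelSpec, rng) -> str:
    if spec.epsilon == 0.0:
        return seq
    protected = truth["anchors"] if spec.protect_anchors else set()
    alphabet = SAFE_SUBS if spec.protect_anchors else ALL_AA
    out = list(seq)
    for pos in range(2, len(seq) + 1):  # never mutate the initiator Met
        if pos in protected:
            continue
        if rng.random() < spec.epsilon:
            choices = [aa for aa in alphabet if aa != out[pos - 1]]
            out[pos - 1] = str(rng.choice(choices))
    return "".join(out)


def gen_ecc_panel(spec: PanelSpec):
    """Generate a panel of ECC records plus one ground-truth dict each.

    Returns (records, truths) in a fixed group order A..E; ids are
    ``ECC_<group><index>``.  Fully reproducible from (spec, seed).
    """
    rng = np.random.default_rng(spec.seed)
    records, truths = [], []
    for group in "ABCDE":
        for i in range(spec.counts.get(group, 0)):
            linker = int(rng.choice(spec.linker_lengths))
            seq, truth = _build_canonical(group, linker, rng)
            seq = _apply_noise(seq, truth, spec, rng)
            rid = f"ECC_{group}{i + 1:02d}"
            truth["id"] = rid
            truth["anchors"] = sorted(truth["anchors"])
            records.append(
                SequenceRecord(id=rid, residues=seq, description=f"synthetic group {group}")
            )
            truths.append(truth)
    return records, truths


# ------------------------------------------------------------------- Y2H


@dataclass(frozen=True)
class Y2HModel:
    """Group-pair interaction probabilities plus per-replicate error rates.

    Defaults emulate the observed screen density: heteromeric edges at a
    uniform ~8% across group pairs (interaction frequency was similar
    between sequence-related and unrelated ECCs), self edges at ~9%.
    """

    edge_prob: dict = field(default_factory=dict)
    default_edge_prob: float = 0.08
    self_prob: dict = field(default_factory=dict)
    default_self_prob: float = 0.09
    false_negative: float = 0.1
    false_positive: float = 0.01
    seed: int = 0

    def pair_prob(self, ga: str, gb: str) -> float:
        return self.edge_prob.get(
            (ga, gb), self.edge_prob.get((gb, ga), self.default_edge_prob)
        )

    def homo_prob(self, g: str) -> float:
        return self.self_prob.get(g, self.default_self_prob)


def gen_y2h_screen(groups: dict, model: Y2HModel):
    """Simulate a replicated screen over a panel.

    ``groups`` maps ecc id -> group letter.  Returns (matings, true_edges)
    where matings cover both orientations x 4 replicates for heteromeric
    pairs and 4 replicates for self pairs.
    """
    for p in (model.false_negative, model.false_positive,
              model.default_edge_prob, model.default_self_prob):
        if not 0.0 <= p <= 1.0:
            raise ValueError("Y2H probabilities must lie in [0, 1]")
    rng = np.random.default_rng(model.seed)
    ids = sorted(groups)
    matings, true_edges = [], set()
    for i, a in enumerate(ids):
        for b in ids[i:]:
            if a == b:
                prob = model.homo_prob(groups[a])
                orientations = [(a, a)]
            else:
                prob = model.pair_prob(groups[a], groups[b])
                orientations = [(a, b), (b, a)]
            edge = rng.random() < prob
            if edge:
                true_edges.add((a, b))
            p_pos = (1.0 - model.false_negative) if edge else model.false_positive
            for bait, prey in orientations:
                for rep in range(1, 5):
                    matings.append(
                        MatingResult(
                            bait=bait, prey=prey, replicate=rep,
                            growth=bool(rng.random() < p_pos),
                        )
                    )
    return matings, true_edges


# -------------------------------------------------------------------- F2


@dataclass(frozen=True)
class QtlModel:
    """Single-locus F2 design.

    Defaults match the study design: 75 individuals scored on an ordinal
    1-5 scale, a single QTL with incomplete dominance (d = a/2) explaining
    roughly 30% of the continuous phenotypic variance.
    """

    n_individuals: int = 75
    n_chromosomes: int = 5
    markers_per_chrom: int = 10
    spacing_cm: float = 10.0
    qtl_chrom: int = 1
    qtl_pos_cm: float = 45.0
    additive: float = 0.87
    dominance: float = 0.435
    residual_sd: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.n_individuals < 10:
            raise ValueError("need at least 10 individuals")
        if not 1 <= self.qtl_chrom <= self.n_chromosomes:
            raise ValueError("qtl_chrom outside the map")
        max_pos = (self.markers_per_chrom - 1) * self.spacing_cm
        if not 0 <= self.qtl_pos_cm <= max_pos:
            raise ValueError(f"qtl position {self.qtl_pos_cm} outside [0, {max_pos}]")


def haldane_r(d_cm: float) -> float:
    """Recombination fraction for a map distance in cM (Haldane)."""
    return 0.5 * (1.0 - np.exp(-0.02 * d_cm))


def _simulate_gametes(rng, n, positions):
    """n gametes over loci at ``positions`` (cM) via Markov recombination."""
    m = len(positions)
    alleles = np.empty((n, m), dtype=np.int8)
    alleles[:, 0] = rng.random(n) < 0.5
    for j in range(1, m):
        r = haldane_r(positions[j] - positions[j - 1])
        recomb = rng.random(n) < r
        alleles[:, j] = np.where(recomb, 1 - alleles[:, j - 1], alleles[:, j - 1])
    return alleles


def gen_f2_population(model: QtlModel) -> F2Population:
    """Simulate genotypes and the discretised ordinal phenotype.

    The QTL is carried as a hidden pseudo-locus at its cM position; the
    continuous phenotype a*x + d*z + noise (x in {-1,0,1}, z = het
    indicator) is cut at its own quintiles into categories 1-5, which
    keeps the class distribution comparable across effect sizes.
    """
    rng = np.random.default_rng(model.seed)
    n = model.n_individuals
    markers, geno_cols = [], {}
    qtl_geno = None
    code = {0: "AA", 1: "AB", 2: "BB"}
    for c in range(1, model.n_chromosomes + 1):
        positions = [j * model.spacing_cm for j in range(model.markers_per_chrom)]
        names = [f"m{c}_{j + 1}" for j in range(model.markers_per_chrom)]
        sim_positions = list(positions)
        qtl_idx = None
        if c == model.qtl_chrom:
            sim_positions = sorted(set(positions + [model.qtl_pos_cm]))
            qtl_idx = sim_positions.index(model.qtl_pos_cm)
        g1 = _simulate_gametes(rng, n, sim_positions)
        g2 = _simulate_gametes(rng, n, sim_positions)
        geno = g1 + g2  # 0/1/2 copies of the B allele
        if qtl_idx is not None:
            qtl_geno = geno[:, qtl_idx]
        marker_cols = [sim_positions.index(p) for p in positions]
        for name, pos, col in zip(names, positions, marker_cols):
            markers.append((name, f"chr{c}", float(pos)))
            geno_cols[name] = [code[int(v)] for v in geno[:, col]]
    assert qtl_geno is not None
    x = qtl_geno.astype(float) - 1.0
    z = (qtl_geno == 1).astype(float)
    continuous = (
        model.additive * x + model.dominance * z + rng.normal(0.0, model.residual_sd, n)
    )
    cuts = np.quantile(continuous, [0.2, 0.4, 0.6, 0.8])
    phenotype = np.searchsorted(cuts, continuous, side="left") + 1
    gmap = GeneticMap(markers=tuple(markers))
    genotypes = pd.DataFrame(geno_cols, columns=gmap.names)
    pop = F2Population(gmap=gmap, genotypes=genotypes, phenotype=phenotype.astype(float))
    pop.qtl_truth = {  # attached ground truth, not part of the data model
        "chrom": f"chr{model.qtl_chrom}",
        "pos_cm": model.qtl_pos_cm,
        "genotype": qtl_geno.copy(),
    }
    return pop
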