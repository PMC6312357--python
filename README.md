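# ecckit

Toolkit for the computational analysis of plant CC-NLR (CNL) immune-receptor
N-terminal domains — the *extended coiled-coil* (ECC) fragments spanning the
whole N-terminus up to the Walker-A P-loop of the NB-ARC domain.

CNL receptors trigger immune signalling and localized cell death through
their N-termini, which homo- and heterodimerize into a signalling network.
Analysing a genome's CNL repertoire at the sequence level requires a chain of
small, well-defined steps that this package implements as a tested library:

* **Annotation** (`ecckit.architecture`) — Kyte–Doolittle hydropathy
  (window 3), α-helix blocks (Chou–Fasman-type propensity heuristic or
  user tracks), the coiled-coil heptad register (the frame of 7 maximising
  L/I/V at the *a*/*d* interface positions), the EDVID motif, the group-D
  10-residue polar stretch, the pre-P-loop motif `[VI] G x8 [LI] x3 L`, the
  Walker-A P-loop `G x4 G K [ST]`, the charged motif at −11..−3 of the VG
  dipeptide, CC-END (last *a*/*d* hydrophobic of the final helix), the
  16–18-residue CCVX linker, and N-terminal acylation signals.
* **Classification** (`ecckit.classify`) — structure-word encoding
  (hydropathy class, heptad letter, helix state), weighted-Jaccard
  distances with *a*/*d*-word up-weighting, neighbour-joining trees,
  Robinson–Foulds comparison, a rule cascade assigning groups A–E, percent
  identity/similarity (BLOSUM62), and a discriminative-conservation scan
  for residues unique to frequently interacting members.
* **Mutant design** (`ecckit.mutagen`) — feature-anchored reciprocal swaps
  (CC-END / charged motif / VG breakpoints), segment deletions and
  reference-checked point mutations.
* **Interactome statistics** (`ecckit.interactome`) — edge calling from
  4-replicate, two-orientation yeast-two-hybrid matings, network summaries,
  degree–phenotype Pearson correlation, Fisher tests of group-pair
  interaction frequency, higher-affinity-partner sets, and cross-species
  response persistence.
* **QTL mapping** (`ecckit.qtl`) — single-marker regression LOD scan over
  an F2 population (additive + dominance coding), genome-wide permutation
  thresholds (Churchill–Doerge), 1.5-LOD support intervals and segregation
  χ² tests.
* **Synthetic data** (`ecckit.simulate`) — generators for group-structured
  ECC panels, replicated Y2H screens and single-QTL F2 populations, each
  emitting full ground truth so every stage is testable offline.

The LOD score at a marker is `(n/2)·log10(RSS₀/RSS₁)`, comparing the null
(intercept-only) with the additive+dominance regression; the genome-wide
threshold is the empirical 95th percentile of the max LOD over phenotype
permutations.

## Worked example

`examples/` holds one short script per capability. Annotating a canonical
group D fragment (`python examples/annotate_panel.py`) prints:

```
record ECC_D01: 153 residues
  helix H1a     1-17
  helix H1b    26-37
  helix H2a    46-78
  helix H2b    87-103
  motif preploop        130-144  VGSSNNSSTNLNSNL
  motif EDVID            62-66  EDVID
  motif polar_stretch    52-61  QEQEDQHEQE
  motif ploop           145-152  GMGGLGKT
  CC-END at 100
  CCVX 101-118 (length 18, canonical=True)
  charged motif 119-127: 6 acidic, 3 basic, fraction 1.00
  ECC boundary (last residue before P-loop): 144
```

Reading it: the four CC helices carry the heptad interface, the EDVID motif
sits in H2a with the polar stretch immediately upstream (the group D
signature), CC-END marks the last interface hydrophobic of H2b, the CCVX
linker (18 aa, within the canonical 16–18 range) runs up to the charged
motif, which occupies positions −11..−3 relative to the V of the pre-P-loop
VG dipeptide; the ECC ends just before the Walker-A P-loop.

Mapping a simulated F2 population (`python examples/qtl_mapping.py`):

```
simulated QTL on chr1 at 45.0 cM
genome-wide permutation threshold (alpha 0.05): 3.13
peak m1_5 on chr1 at 40 cM, LOD 5.38; 1.5-LOD interval 30-70 cM
```

The peak clears the permutation threshold on the planted chromosome and the
1.5-LOD interval covers the true position.

A thin CLI mirrors the library (`ecckit annotate|classify|tree|network|qtl|
simulate|run`); `ecckit run --config cfg.yaml` executes the whole pipeline
and writes a manifest with input checksums for reproducibility.

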