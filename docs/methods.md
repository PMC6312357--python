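# Methods

## Scope and coordinate conventions

ecckit operates on extended coiled-coil (ECC) fragments: the N-terminus of
a CC-NLR up to, but not including, the Walker-A P-loop of the NB-ARC
domain. All residue coordinates are 1-based with the initiator Met at
position 1, so published residue labels (Gly-2, C21, G158) map directly;
segments are 1-based inclusive. Sequences use the strict 20-letter
alphabet; ambiguity codes are rejected at parse time so every scanner can
assume clean input. Alignments use `-` as the only gap character.

## Feature annotation

**Hydropathy.** Sliding-window mean of the Kyte–Doolittle scale, default
window 3. Only fully contained windows are evaluated, so a profile is
`n − window + 1` long; edge positions are simply not scored rather than
padded, which keeps every value an honest mean of real residues.

**Helix blocks.** In the absence of the external secondary-structure
predictor consensus that a full-scale analysis would use, helices come
from an internal heuristic: Chou–Fasman α-helix propensities smoothed with
a centred window of 7 (edge windows truncated), thresholded at
θ_helix = 1.03, runs shorter than 6 residues discarded. A user-supplied
boolean per-residue track overrides the heuristic entirely, which is the
recommended route when predictions from dedicated tools are available.
The first four blocks are labelled H1a/H1b/H2a/H2b; a first block of ≥ 24
residues is labelled H1 (merged), reflecting that the H1a–H1b separation
is frequently not resolved by prediction. Because charged and Walker-A
residues are themselves helix-favourable, propensity runs whose majority
lies at or beyond the charged motif are discarded: the CC bundle is
N-terminal of the linker, and those runs belong to the linker/NB region.
Helix *boundaries* from the heuristic are approximate (±3 residues at
block edges); all motif coordinates are exact.

**Heptad register.** Within each helix the frame (of 7) maximising the
count of L/I/V at the *a* and *d* positions is selected; ties break toward
the smaller offset. Register letters a–g are emitted inside helices, `.`
outside. This is an exhaustive 7-frame search, verified against an
independent brute-force oracle in the test suite.

**Motifs.** EDVID is matched exactly by default (fewest mismatches, then
leftmost, when `max_mismatch > 0` is requested); the group D polar stretch
is the 10 residues immediately upstream of EDVID, called a hit when at
least θ_polar = 8 of them are polar (S/T/N/Q/D/E/K/R/H/Y). The pre-P-loop
motif is the leftmost `[VI] G x8 [LI] x3 L`; the Walker-A P-loop is the
leftmost `G x4 G K [ST]` downstream of it (the exact P-loop pattern is an
operational choice — the canonical Walker A — and is configurable). The
charged motif is the fixed 9-residue window at −11..−3 relative to the V
of the VG dipeptide, both ends inclusive; "charged" counts {D,E,K,R} with
His excluded, because His protonation is ambiguous at cytosolic pH and the
charge-reversal mutants of interest target E↔K. CC-END is the largest
index in the last helix holding an L/I/V at an *a*/*d* register position;
CCVX is the segment between CC-END and the charged motif, flagged
non-canonical (not an error) outside the 16–18-residue range. When the
pre-P-loop is absent, the charged motif and CCVX are reported absent —
they are defined relative to VG — and the ECC boundary falls at the
sequence end when no P-loop exists.

## Group classification

A rule cascade over the annotation: (1) no helix/heptad evidence → E;
(2) N-terminal identity to a CC_R/RPW8-like consensus ≥ θ_rpw8 = 0.7 → A;
(3) EDVID + polar stretch → D; (4) EDVID → C; (5) otherwise → B. The
evidence map records every rule outcome, including ones that did not fire
(acylation flags, β-flank evidence when tracks supply it). The CC_R
consensus is a configuration input; the package default is the synthetic
signature planted by the panel generator, suitable for self-contained
runs, and should be replaced by a consensus built from real RPW8-family
sequences when classifying natural panels. Whether the C/D split in real
data rests on the polar stretch alone is not fully resolvable; the
cascade commits to the polar stretch as the operational criterion.

**Structure words and trees.** Each residue maps to a symbol triple
(hydropathy class by Kyte–Doolittle sign, heptad letter or `.`, helix
state). Sequences are compared by the weighted Jaccard similarity of
their multisets of contiguous k = 3 symbol words; words containing an
*a*/*d* symbol carry weight 2.0, others 1.0, so shared interface
architecture dominates the distance. This scheme is a declared
concretisation of "structural-word weighting": the published clustering's
exact weighting is not recoverable, so reproducing a specific published
cladogram is not promised, and both k and the weights are configurable.
Weighted Jaccard distance is a true metric; the suite verifies symmetry,
identity and the triangle inequality empirically. Trees come from a
classical Saitou–Nei neighbour-joining implementation (negative branch
estimates clamped to zero and flagged); topology comparison uses
Robinson–Foulds on non-trivial bipartitions, cross-checked against an
independent tree library.

## Mutant design

Chimeras are cut at feature anchors, never absolute coordinates: CC-END,
the first acidic residue within the charged window (the published swap
points mark "E or EE" residues; the first acidic position is the
reproducible proxy, and its absence is an error rather than a guess), or
the V of the VG dipeptide. Reciprocal swaps conserve the residue multiset
and are involutions; point mutations verify the reference residue before
applying, so coordinate drift fails loudly. All products are re-annotated;
parental coordinates are never trusted on a mutant.

## Interactome statistics

Matings carry (bait, prey, replicate 1–4, growth on −His/−Ade). An
unordered pair is an interaction when positive replicates across both
orientations reach min_support = 3 (of 8 for heteromeric pairs, 4 for
self pairs). The replicate design is fixed by the assay; the calling rule
itself is this package's choice — tolerant to one replicate dropping out,
strict enough to demand reproduction — and is configurable. Degree counts
heteromeric partners plus 1 for a self edge. "Higher affinity toward a
partner" is operationalised as replicate support, a proxy for relative
affinity. Group-pair interaction frequency uses Fisher's exact test on
the 2×2 table of dyad class × edge presence over all heteromeric dyads;
the correlation of degree with the ordinal response category is Pearson's
r with the two-sided t-based p. Response categories are 0–6 in
Arabidopsis (6 = full resistance) and 0–3 in N. benthamiana and lettuce;
"active" for persistence counts means necrosis-or-stronger (category ≥ 4
in At, ≥ 2 in Nb/Ls by default).

## QTL scan

Phenotype (ordinal 1–5, treated as numeric — the standard practice for
interval-mapping software fed ordinal scores) is regressed per marker on
the additive code (AA = −1, AB = 0, BB = +1) plus a dominance indicator
(AB = 1), complete-case per marker with no imputation. LOD is
`(n/2)·log10(RSS_null/RSS_full)`; numerically perfect fits are capped at
LOD_MAX = 50 with a flag, markers with one observed genotype class score
0 with a flag. The genome-wide threshold is the empirical (1 − α)
quantile (`higher` interpolation) of the max LOD over n_perm phenotype
permutations, which preserves the genotype LD structure. The support
interval is the contiguous marker run within 1.5 LOD of the peak,
bracketed by the first marker falling below on each side — a deliberate,
stated convention, since interval rules differ between tools. This
single-marker scan deliberately replaces composite interval mapping:
CIM's cofactor selection is tool-specific, and the simplification is
recorded in the output metadata.

## Synthetic data

**Panels.** Each canonical sequence is assembled from a group-specific
N-terminal cap (group B: `MGGC`, carrying the myristoylation and
palmitoylation signals; groups C/D: a neutral cap; group A: a 24-residue
synthetic CC_R-like signature, which is an invented stand-in for the
unpublished RPW8 consensus, not a transcription of it), four helix blocks
built from the heptad unit `LAEIAQA` (L at *a*, I at *d*), P/G-rich
turns, a CCVX linker of planted length 16–18 (helix-capping `QAM` start,
then low-propensity filler), a 9-residue charged island from {D,E,K,R}
with a guaranteed acidic first residue, a 2-residue spacer, the
pre-P-loop `VG x8 L x3 L` and a Walker-A terminus. Group D additionally
plants the 10-polar stretch before EDVID; group E replaces the helix
region with a disorder-promoting S/T/N/G/P stretch. Substitution noise at
rate ε is applied per residue outside planted anchors (the initiator Met
is never mutated); under anchor protection the substitution alphabet also
excludes {G,K,L,I,V} so that noise cannot seed spurious pattern matches.
Disabling protection exposes every position and the full alphabet.
Ground-truth coordinates for every planted feature accompany each record.

What the generator does *not* emulate: natural sequence diversity within
groups (real ECCs differ far more than ε-substituted copies of one
scaffold), indels and length variation of helices, group-specific
phenotype distributions, and genuine RPW8 consensus content. Perfect
recovery on these panels therefore demonstrates the correctness of the
scanners' logic and coordinate arithmetic, not their sensitivity on
diverged natural sequences.

**Y2H screens.** Latent true edges are drawn per group-pair probability
(default uniform 0.08 heteromeric / 0.09 self, matching the observed
screen density of roughly 123 edges among 56 fragments); each of the 8
orientation-replicates (4 for self pairs) is positive with probability
1 − FN (default FN = 0.1) on true edges and FP (default 0.01) otherwise.

**F2 populations.** Defaults mirror the mapping design: 75 individuals,
5 chromosomes × 10 markers at 10 cM, one QTL at 45 cM of chromosome 1
with additive effect a = 0.87 and dominance d = a/2 = 0.435 (incomplete
dominance) on residual SD 1 — about 30% of the continuous variance.
Gametes follow per-chromosome Markov recombination with the Haldane map
function; the QTL is a hidden pseudo-locus. The continuous phenotype is
discretised at its own quintiles onto 1–5, keeping the ordinal
information content stable across effect sizes (and leaving the null case
exactly independent of genotype).

## Problem sizes and numerical choices

The test suite exercises: ≥ 200 noise-free fixtures for exact planted
recovery; 50 fixtures per group for classification; 200 null F2
populations × 200 permutations for type-I calibration (the acceptance
script repeats this from scratch); 50 populations × 200 permutations for
power and interval coverage; 20 screens for Y2H density calibration.
Permutation LOD computation is vectorised via per-marker QR projections,
so a full calibration run takes seconds. Tolerances: binomial 95% CIs for
all rate calibrations; exact equality for coordinates and counts; 1e-10
relative RSS for the perfect-fit cap; NJ Q-criterion ties break toward
the earlier pair.

## Known limitations

* The helix heuristic is a stand-in for a multi-predictor consensus; its
  boundaries are approximate and real ECC helices will be noisier.
* The structure-word weighting is one defensible concretisation among
  several; trees built with different k or weights can differ.
* Bootstrap support values for NJ trees are not implemented.
* The Y2H caller does not model auto-activation or vector-system effects
  beyond the replicate threshold.
* The QTL scan is single-marker: positions between markers are not
  scored, and no cofactors are used, so resolution is bounded by marker
  spacing.
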