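# Methods

## Model and assumptions

`lphist` treats a DNA sequence as a path statistic: bases map to the four
diagonal unit vectors of the plane, positions are scaled by the
self-information of their trinucleotide context, the path is rasterized to
a binary image, and the image is summarized by the occurrence frequencies
of its 3×3 local pixel patterns. Two sequences are similar when their
pattern histograms are close. The underlying assumptions are:

- **Order-2 Markov context is informative.** Weights come from
  P(z|xy) = N_xyz / Σ_s N_xys with counts pooled over *all* input
  sequences (a per-run corpus model, not a per-sequence one; a
  precomputed weight table can be supplied to decouple model and
  drawing). No pseudocounts are added: the probability is the plain
  ratio, and a context never seen in the corpus simply falls back to
  weight 1 — the same convention as the first two positions of every
  sequence, which have no preceding doublet. This keeps weights finite
  without inventing counts.
- **Linearity.** Sequences are drawn from a fixed origin to a terminus,
  so circular genomes (e.g. mitochondria) are treated as linearized at
  their deposited origin. Histograms are not rotation-invariant with
  respect to the sequence start.
- **Ambiguity codes carry no geometry.** Only A, C, G, T have vectors;
  all other characters are removed during cleaning, with a logged count.
  They are not randomly resolved because any resolution would inject
  noise into the trajectory.

## Parameters

| parameter | default | meaning |
|---|---|---|
| assignment scheme | `ATGC` | base → diagonal vector bijection, labelled by counterclockwise base order from the (+,+) quadrant; `ATGC` puts A/T up, G/C down so trajectory height reads AT/GC composition. The 24 possible bijections form exactly 3 classes under 90° rotations and axis reflections; the three labels name those classes. |
| weighting | on | multiply vector k by w_k = −log₂ P(s_k \| s_{k−2}s_{k−1}) bits |
| pixel size | 1 | raster pitch in trajectory units; 1 makes an unweighted step span exactly one pixel diagonal |
| block size | 10 | side of the marked-block grid used to restrict pattern counting |
| window | 3 (fixed) | local-pattern window side; serial numbers are defined for 9 bits |
| measures | HI, MD, BD, JS, TAU | histogram distances computed |

Weights are kept at full floating precision everywhere; two-significant-
figure output is display formatting only.

## Numerical and algorithmic conventions

- **Rasterization** uses closed-pixel membership: pixel (i,j) covers the
  *closed* square [i,i+1]×[j,j+1] and is black iff a segment touches it,
  so a segment through a lattice corner marks all four adjacent pixels.
  This is the only unambiguous reading of "touches the pixel", and it is
  testable against an exhaustive closed-square/segment intersection
  oracle (the suite checks exact agreement on 1000+ random segments).
  Crossings are found by parametric grid walking; boundary contact is
  resolved by the closed rule itself, never by epsilon perturbation.
- **Pattern counting** enumerates window anchors only over marked blocks
  expanded by a 2-pixel halo and deduplicated, which is provably
  count-identical to a full-plane scan (all-white windows are excluded
  anyway); the suite asserts exact equality with a brute-force scan on
  100+ random images and across block sizes, including size 1.
- **Serial numbers** read the window row-major from the upper-left pixel
  (highest bit) to the lower-right (lowest). Window anchors are the
  top-left pixel; the anchoring choice cannot change counts.
- **Kendall's τ** is computed as tau-b, τ = (X−Y)/√((X+Y+r)(X+Y+s)),
  over all serial pairs with doubly-tied pairs excluded, by a vectorized
  full pair scan (N = 511, so 130k pairs; no need for an O(N log N)
  algorithm). The distance is D = (1−τ)/2. When every pair is doubly
  tied τ is undefined and an error is raised.
- **Bhattacharyya on disjoint supports** is +∞; matrix construction
  fails loudly naming the offending pair instead of clamping, because a
  silently clamped value would distort UPGMA merges.
- **UPGMA** merges the closest pair (merged height d/2, size-weighted
  average update), breaking ties by the lexicographically smallest pair
  of cluster labels (a cluster is labelled by its smallest leaf), so the
  tree is deterministic and independent of input order. Output is
  ultrametric by construction; on ultrametric inputs the reconstruction
  is exact (property-tested at 1e−9).
- **Robinson–Foulds** counts the symmetric difference of non-trivial
  bipartitions with both trees treated as unrooted — the convention under
  which two fully resolved trees on n leaves can differ by at most
  2(n−3). Multifurcating references are accepted and contribute only the
  bipartitions they resolve. Branch lengths are ignored.
- **Pearson correlation between distance matrices** uses strict
  upper-triangle entries only; including the zero diagonal or the
  duplicated lower triangle would bias r upward.
- Distance matrices are written with 17 significant digits so that a tree
  built from a written matrix is bit-identical to one built in memory.

## Synthetic data

The generator produces i.i.d.-uniform DNA or order-2 Markov DNA from a
user transition table (rows validated to sum to 1 within 1e−6); under a
Markov table the first two bases are drawn uniformly, since the chain has
no context yet and the choice washes out of trinucleotide statistics
within a few positions. Generation is bit-reproducible given an integer
seed.

Synthetic corpora emulate the *mechanics* of real genome panels — many
sequences sharing one trinucleotide model, genome-like alphabet and
pooling — but not their biology: no phylogenetic signal, no strand or
codon structure, no shared ancestry. Tests on synthetic data therefore
demonstrate correctness of the computation (counting, distances,
clustering) and its invariants, not phylogenetic accuracy on real
genomes; the latter is exercised by the optional full-scale benchmark,
which scores trees from 31 mammalian mitochondrial genomes against an
alignment-based reference topology and requires externally fetched data.

The weight-robustness check (`bootstrap_weights`) redraws subsets without
replacement, rebuilds the model per subset, and reports per-triplet mean
and SD of all 64 weights; unseen contexts in a subset record the fallback
weight 1 so the statistics are always defined.

## Problem sizes

The default test suite runs entirely on synthetic data: corpora of up to
31 sequences of a few hundred bases, plus genome-length spot checks. A
16.5 kb sequence rasterizes to roughly 26k black pixels in ~650 marked
blocks and its histogram is counted in well under a second, so full
mitochondrial panels are practical; the acceptance script's end-to-end
self-check uses five 1.5 kb sequences.

## Known limitations

- Distances are not true metrics in general (HI/MD are; BD and JS
  violate the triangle inequality in principle, D_τ is rank-based), and
  none is additive in evolutionary time — UPGMA's molecular-clock
  assumption is inherited, not checked.
- The histogram discards the absolute position and orientation of the
  trajectory; two different sequences can in principle collide to the
  same image statistics.
- Window size other than 3×3 and adaptive block sizes are not
  implemented; block size only affects speed, never counts (tested).
- The corpus model makes distances corpus-dependent: adding a sequence
  to the input changes the weights and hence, slightly, all pairwise
  distances. Supply a fixed weight table for corpus-independent runs.
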