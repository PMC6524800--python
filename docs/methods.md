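# Methods

## Scope and model

`corecluster` implements structure-based classification for sets of
protein chains that share a conserved fold but little sequence
similarity. The analysis reduces each chain to its C-alpha trace and
asks three questions: which residue positions are structurally
equivalent across *all* members (the common core), how far apart are the
members when compared only over those positions, and how robust is the
resulting grouping to the removal of individual structures.

## Pairwise structural alignment

Two traces are aligned by iterating rigid superposition and dynamic
programming until the equivalence set stabilizes.

**Per-residue properties.** Amino-acid identity is held as a profile
vector over a 21-letter alphabet (20 standard + X); the similarity of
two profiles is the bilinear form `pᵀ B q` where `B` is BLOSUM62 shifted
positive and cross-normalized (`s_ij / √(s_ii s_jj)`), so identical
residues score exactly 1 and all scores lie in [0, 1]. Local geometry
is the pseudo bond angle θ(i) over Cα(i−1), Cα(i), Cα(i+1) (degrees, in
[0, 180]) and the pseudo dihedral τ(i) over Cα(i−1..i+2) (in
(−180, 180]); backbone direction is the unit vector Cα(i)→Cα(i+1); a
burial proxy counts Cα neighbours within 10 Å excluding sequence
neighbours ±2. Entries undefined at the termini are NaN and are dropped
from scoring (the remaining weighted terms are rescaled to the full
weight budget rather than zero-filled).

**Position score.** For residues i of a and j of b, after superposing b
onto a with rotation R,

    S(i,j) = w_aa·sim_aa + w_geo·sim_geo + w_dir·sim_dir + w_dist·(1 − d_ij/d_cut)

with `sim_geo = 1 − (|Δθ| + |Δτ|_circ/2)/270°` and
`sim_dir = (1 + cos α)/2` for the angle α between direction vectors
after rotation. All four weights default to 1. The distance term is
deliberately a *soft* penalty: cells beyond `d_cut` score increasingly
negative instead of being banned outright. A hard ban pins the
alignment to the neighbourhood of the seed window on elongated chains —
a superposition fitted on a local region places remote regions beyond
`d_cut`, so a banned alignment can never grow past them — whereas under
the soft penalty each iteration extends the matched region and the
refitted superposition follows, converging to the global registration
in a few iterations. The hard contract survives at the output: a final
pruning loop refits the superposition on the reported pairs and drops
pairs beyond `d_cut` until all satisfy it.

**Seeding and restarts.** The iteration starts from the pair of gapless
8-residue windows with the lowest superposition rmsd, found by an
exhaustive scan (batched closed-form Kabsch over all window pairs). Up
to three non-overlapping seed window pairs are tried and the
best-scoring final alignment kept; the restarts make the registration
robust to internal symmetry and repeats, where the single best window
can sit in a wrong phase. If no window pair superposes below 5 Å rmsd
the structures are deemed unalignable (empty map, score 0).

**Dynamic programming.** Global alignment with affine gaps
(open 2.0, extend 0.2 on the score scale above) and free end gaps, so
unshared terminal decorations cost nothing. Tie-breaks prefer the
diagonal for determinism. The DP inner loop is numba-jitted.

**Convergence.** The iteration stops when a pair set repeats or after
`max_iter = 50` rounds; the best-scoring pair set seen is returned, so
oscillation cannot degrade the result.

## Common-core identification

All structures are aligned pairwise; the pair with the highest merge
score `n_eq / (1 + rmsd)` — many equivalences, low rmsd — is merged into
a core that represents the pair from then on, and the new core is
re-aligned against every remaining node (ties broken on the
lexicographically smallest pair of node keys, which makes the whole
procedure invariant to input order). Cores expose the same interface as
chains: representative coordinates are member means in a common frame,
amino acids are mean profiles, angles circular means, directions
renormalized mean vectors. After each merge every member's transform is
refreshed by one Kabsch refit onto the mean trace, keeping the frame
stable as cores deepen.

Column semantics are strict intersection: a merged column survives only
if every member of both children contributes a residue. Column counts
are therefore non-increasing toward the root (asserted on every run),
and the root core holds positions equivalent across the entire input
set.

`parameter_scan` reruns the hierarchy over a parameter grid and ranks
by core size (descending) then average rmsd (ascending), emitting the
full table; failing grid points become flagged rows.

## Distance matrix and tree

The distance between two members is computed over the core columns
only: superpose one onto the other restricted to those columns, then

    d(a,b) = w_xyz · mean per-column Cα deviation (Å)
           + w_prop · mean per-column property dissimilarity

with both weights defaulting to 1. The property dissimilarity averages
four terms in [0, 1] mirroring the alignment score: `1 − sim_aa`, the
geometry term `(|Δθ| + |Δτ|_circ/2)/270°`, `(1 − cos α)/2` for rotated
directions, and `min(|Δn|, 10)/10` for the neighbour count. The matrix
of all pairs is divided by its maximum entry (an all-zero matrix is
returned unnormalized with a warning). The distance is a premetric —
non-negative, zero for identical or rigidly moved members, symmetric —
but the triangle inequality is not guaranteed and not asserted.

Trees minimize the Fitch–Margoliash weighted least-squares objective
`Σ_{i<j} (d_ij − p_ij)²/d_ij²` (weights floor the denominator at
ε = 10⁻⁶ for zero distances). The search is the standard practice for
distance trees: a neighbor-joining starting topology (scikit-bio), exact
non-negative WLS branch lengths per topology (scipy NNLS, which solves
the constrained problem that clamping negative lengths approximates),
and nearest-neighbor-interchange hill climbing accepting the best
improving move per sweep until none improves. On additive matrices this
recovers the generating topology with a zero objective (verified to
1e−10 in the tests). Trees are unrooted; serialization is Newick via
scikit-bio, with jackknife support fractions as internal labels.

## Simplified jackknife

One replicate per family/subfamily unit (subfamily where defined, else
family): the unit's lexicographically first member — or a seeded random
draw — is removed, and core, matrix, and tree are recomputed from the
remaining structures. A group's stability is the fraction of replicate
trees in which its present members form a clade under unrooted
bipartition semantics (some edge splits exactly them from the rest);
groups reduced to fewer than two present members count as trivially
stable. Single-member units are skipped with a warning, since removing
their member would empty the unit. Removing a member can only grow or
preserve the intersection core, so replicate cores are never smaller
than the full-data core (asserted in the tests).

## Synthetic clans and what they do (not) show

The generator emulates the data regime the pipeline targets: families
sharing a conserved spatial core decorated with family-specific
insertions.

- **Ancestral core**: a self-avoiding Cα trace, consecutive spacing
  exactly 3.8 Å, bend angles uniform in [80°, 160°], non-consecutive
  contacts below 4.0 Å rejected and resampled.
- **Family divergence**: smooth correlated Cartesian noise (Gaussian,
  smoothed along the chain with a 5-residue kernel), re-spaced to exact
  3.8 Å steps. Re-spacing damps the displacement field, so the noise
  amplitude is calibrated by fixed-point iteration until the realized
  rigid-motion-free RMS displacement equals `family_shift_sigma`.
  Family sequences mutate the ancestral sequence at
  `mutation_rate_family` per site (uniform substitution).
- **Decorations**: loops inserted between consecutive core residues as
  equal-chord circular arcs (exact 3.8 Å spacing; internal clashes are
  geometrically impossible for this construction). The arc's plane
  angle is resampled until the loop clears 4.0 Å from everything else;
  sites whose local backbone bend admits no clash-free orientation are
  redrawn. The two core residues flanking a loop remain one bond apart
  and are exempt from the clash check. Loop lengths are geometric with
  mean `decoration_mean_length`.
- **Members**: i.i.d. Gaussian coordinate noise (`member_sigma`), point
  mutations (`mutation_rate_member`), and deletions confined to
  decorations (`deletion_rate_member`), which leave author-numbering
  gaps exactly as missing residues do in real files. Ground truth
  records each core column's residue index in every member.

All randomness flows from the single spec seed; identical specs give
byte-identical PDB output.

Defaults — 4 families × 4 members, 60-residue core, 2 decorations of
mean length 10, `family_shift_sigma` 1.0 Å, `member_sigma` 0.5 Å,
mutation rates 0.30/0.05, deletion rate 0.05 — put family divergence
well above member noise, which is what makes a clan classifiable and is
the regime the full-scale analysis assumes. What passing tests show is
that the machinery recovers a planted core and planted families under
realistic noise; they do not show that real β-barrel proteases align
this well: synthetic traces lack secondary-structure regularity,
circular loops are idealized, deformation is isotropic, and sequences
are uniform at the root rather than evolved under a substitution model.
Full-scale behaviour on real PDB chains therefore still depends on
parameter tuning (`parameter_scan` exists for exactly that).

## Numerical choices

- Kabsch superposition excludes reflections (det = +1); fewer than 3
  points or collinear input raise a degeneracy error. An rmsd below
  1e−12 is reported as exactly 0 (identity/translation cases).
- Sub-4.0 Å tolerance choices in the generator are asserted, not
  assumed: every family template passes spacing (3.8 ± 0.01 Å) and
  clash validation before member noise is applied.
- DP ban/sentinel value is −10¹⁵, safe under addition; tie-breaks are
  fixed (diagonal, then up, then left).
- Normalization of an all-zero distance matrix is skipped below a 1e−9
  maximum to avoid dividing by numerical dust.
- Greedy identity clustering visits models longest-first (ties:
  lexicographic id); a model joins on identity strictly above the
  threshold, with exact sequence duplicates always joining so a
  threshold of 1.0 removes only duplicates.
- Unknown resolution (e.g. NMR entries) passes the resolution filter;
  the filter targets poor crystallographic models.
- Missing residues are counted from SEQRES when present, else from
  author-numbering gaps; altloc duplicates keep the highest-occupancy
  C-alpha (ties: first encountered).

## Problem sizes

The shipped tests and the acceptance script run at desk scale: clans of
16 structures of ~60–110 residues, jackknives of 4 replicates, tree
fitting on 4–16 taxa. These sizes exercise every code path (multiple
families, decorations, deletions, ties) while keeping the full suite in
a few minutes on one CPU. The algorithms themselves are polynomial —
O(n²) alignments per hierarchy, O(nm) per DP — and carry no constants
tied to these sizes.

## Known limitations

- Alignment is sequential (no topology-independent matching): circular
  permutations or domain swaps are out of reach.
- The distance is not guaranteed metric; Fitch–Margoliash fitting is a
  heuristic search (NJ + NNI), not an exhaustive topology optimum.
- Cores carry mean coordinates; highly divergent members can drag the
  representative trace away from every individual member.
- mmCIF input is not supported; one chain per model.
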