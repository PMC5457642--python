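# Methods

## Model

The folding model is pure base-pair maximization: the score of a structure
is its number of base pairs, a pair is admissible iff it is AU, GC or GU
with the 5' index strictly smaller, and structures are non-crossing (no
pseudoknots). There is no thermodynamic energy model, no stacking, and by
default no minimum hairpin span — adjacent residues may pair, because the
recursion only requires `i < j`. An optional `min_loop` parameter (default
0, units: residues; `j - i` must exceed it for a pair) restores the common
three-residue hairpin constraint when set to 3. Indices are 0-based
throughout; the recursion region is `0 ≤ i < j ≤ N-1`.

The reference kernel executes the recursion with i descending, j ascending,
and for each cell all split evaluations (statement s0, k ascending)
followed by the pairing update (statement s1). This order is the ground
truth: both tiled executors must reproduce its matrix integer-exactly, and
its read/write footprint on S is what the dependence relations describe.
The test suite re-derives those relations empirically (a shadow kernel
records every memory access and the resulting dependence pairs are compared
instance-exactly against the relation images for N ≤ 10), so the loop-nest
reconstruction is verified, not assumed.

## Dependence model and closure

All polyhedral objects are materialized concretely for a fixed N rather
than manipulated symbolically. This trades generality in N for exactness
and testability: every set or relation is a finite object that can be
compared against an independent oracle. The dependence graph for length N
has N(N−1)(N+1)/6 s0 vertices and N(N−1)/2 s1 vertices and O(N⁴) edges;
the machinery is intended for analysis scales N ≲ 200. Folding itself never
needs the graph at run time — tile correction is the only consumer, and the
executors only need the corrected tiles.

The positive transitive closure R+ is computed by an iterative
Floyd–Warshall-style sweep on per-vertex reachability bitmasks; its oracle
in the tests is per-vertex breadth-first reachability, compared
vertex-exactly for all N ≤ 20. Acyclicity (no self-reachability) holds on
the same range, as it must for the dependence graph of a sequential
program.

## Tiling and correction

Original tiles block i downward from N−1 with width b1 (the kernel
decrements i), j on its offset d = j−i−1 from the moving lower bound i+1
with width b2, and k with width b3. A tile identifier is (ii, jj, g, kk)
with a statement-group bit g ordering each block's s0 tiles before its s1
tile; identifiers compare lexicographically. Tile-identifier constraints
are realized as non-emptiness of the member set rather than as a standalone
predicate, since the printed constraint form references point variables.

Correction follows the TILE_ITR / TVLD_LT / TILE_VLD set algebra. Two
implementations exist on purpose:

- a literal transcription driven by a ClosureRelation (the specification of
  record, practical at small N and used as the oracle in route-equality
  tests);
- a task-local route used by default. It rests on a structural property of
  the relations: i never increases and j−i never decreases along any
  dependence edge, so the block coordinates (ii, jj) are componentwise
  non-decreasing along every edge and any dependence path that leaves a
  block never returns to it. Correction therefore decomposes exactly into
  independent per-(ii, jj) problems over intra-block edges only. The
  monotonicity is not trusted: the validity checker asserts it on every
  edge each time it runs. Inside a block, the self-cell clause
  [i,j,k]→[i,j,k'] is thinned to consecutive steps k'=k+1, which preserves
  reachability (the full clause is the transitive closure of the chain and
  the correction algebra consumes only R+).

If a point were ever claimed by several corrected tiles it would be
assigned to the lexicographically earliest claimant; the set algebra makes
multiple claims impossible (a later claimant's TILE_ITR is inside an
earlier claimant's TILE_GT-closure), so the count is asserted to be 0 and
any violation of the partition raises rather than degrades. Observed
migrations (points absorbed by a later tile's TVLD_LT — characteristically
s0 stragglers joining their block's s1 tile) are logged at DEBUG.

## Schedule, validity, wavefronts

The tile schedule prefix is (ii+jj, jj, g, kk) and the within-tile point
order (−i, j, s, k); constant separator digits of the underlying schedule
encoding are dropped since they never affect lexicographic comparison. The
executable validity relation walks every dependence edge, maps both
endpoints to their corrected tiles, and flags pairs where the source tile's
prefix is ≥ the target's (distinct tiles), plus — belt and braces — any
intra-tile pair whose point order is wrong. Emptiness proves the serial
tiled order and the skewed order legal for that (N, B).

Lexicographic tile-level comparison alone cannot see a same-time dependence
between two *different* blocks running concurrently, so wavefront safety is
verified separately: `wavefront_cross_edge_count` counts dependence edges
connecting distinct blocks of equal ii+jj and must return 0. The parallel
unit is deliberately the whole (ii, jj) block, not the individual g/kk
tile, because a block's tiles carry serial intra-block dependences.

A deliberately invalid skew ii' = ii − jj is built in as a negative
control; it produces violations (77 tile pairs at N=8, B=(2,2,2)) and
non-zero cross edges, demonstrating that the checkers can fail.

## Execution

The wavefront executor runs time partitions serially with a barrier between
them and dispatches block tasks to a thread pool one task at a time
(dynamic dispatch, chunk size 1). Threads share the matrix; correctness
relies on the verified wavefront independence, not on the interpreter's
locking, and is probed by seeded adversarial shuffles of the task order
within each wavefront — results must be bit-identical for any worker count
and shuffle. The default tile size is 16×16×16, the empirically
best-performing block for this kernel family. Tiled execution asserts
schedule validity first; the check is cached per (N, B) and, because it
materializes every dependence edge (~N⁴/8), is skipped above N = 96 unless
`force_validate` is passed — at tool scale the validity of the scheme is
established on the checked grid, not re-derived per fold.

## Synthetic data

Random sequences draw residues i.i.d. uniform over {A, C, G, U} from a
seeded generator — matching how the algorithm is exercised in practice,
since base-pair maximization's control flow and operation count depend only
on sequence length, not content (the tests' call-count accounting confirms
this: bonding-function evaluations are exactly N(N−1)/2 regardless of the
sequence). Uniform strings do not emulate biological base composition,
codon structure or repeat content; passing tests therefore certify the
*algorithmic* machinery (optimality, equivalence, schedule legality) on
arbitrary inputs, and say nothing about the biological accuracy of
base-pair maximization itself, which is a deliberately simplified model.

## Problem sizes and numerical choices

All arithmetic is exact integer arithmetic; there are no tolerances.
Equivalence checks compare matrices bit-exactly. Grid choices in the test
suite: executor equivalence and schedule validity over every N in 2..48
plus {52, 56, 60, 64} crossed with B ∈ {1³, 2³, (3,2,4), 4³, 16³} (255
cases); enumeration-oracle agreement over 500 seeded sequences with N ≤ 12;
closure oracle N ≤ 20; kernel consistency N ≤ 10; wavefront independence
N ≤ 40. Traceback breaks ties deterministically (pairing branch first,
then smallest split k) and is iterative, so long sequences cannot overflow
the recursion stack. Degenerate inputs: N = 1 yields an empty iteration
space, an all-zero matrix and an empty structure; empty sequences are
rejected at construction.

## Known limitations

- No energy model (the recursion maximizes pair count only), no suboptimal
  structures, no partition function, no pseudoknots.
- The dependence relations are specific to this kernel; other loop nests
  are out of scope (the relation container is the extension point).
- Concrete enumeration means analysis cost grows as O(N⁴) edges; the
  closure/validity machinery is for validation scale, not for N in the
  thousands (folding itself remains O(N³) and unaffected).
- The thread-based wavefront backend demonstrates scheduling correctness;
  it is not a performance harness and no speed-up claims are made for it.
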