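# nustile

Base-pair-maximization RNA secondary-structure prediction with fully tiled,
wavefront-parallel execution — and the polyhedral machinery to prove the
tiled schedule correct on any concrete instance.

## The problem

Given an RNA sequence `x_1 … x_N` over {A, C, G, U}, base-pair maximization
fills the dynamic-programming matrix

    S(i,j) = max( S(i+1, j-1) + δ(i,j),  max_{i ≤ k < j} S(i,k) + S(k+1,j) )

over `0 ≤ i < j ≤ N-1` (zero elsewhere), where the bonding function
`δ(i,j)` is 1 for AU, GC and GU (wobble) pairs with `i < j`, else 0.
`S(0, N-1)` is the maximum number of non-crossing complementary base pairs;
a traceback yields one optimal structure in dot-bracket notation.

The O(N³) loop nest has two statements (the split maximization `s0` and the
pairing update `s1`) with *non-uniform* dependences: `S(i,j)` depends on
cells at distances that grow with i and j. Standard affine tiling can block
only the two outer loops of this recursion. This package implements an
alternative: block all three loops rectangularly, then *correct* the tiles
using the transitive closure `R+` of the exact dependence graph

    TILE_ITR = TILE − R+(TILE_GT)
    TVLD_LT  = (R+(TILE_ITR) ∩ TILE_LT) − R+(TILE_GT)
    TILE_VLD = TILE_ITR ∪ TVLD_LT

so that the corrected tiles partition the iteration space and their
inter-tile dependence graph is acyclic. Skewing the tile space with
`ii' = ii + jj` then yields wavefronts: all tile blocks with equal `ii+jj`
are mutually independent and run in parallel between barriers. An
executable validity relation (`R_VALID`) checks, dependence edge by
dependence edge, that the skewed schedule runs every source before its
target — an empty violation set proves the schedule legal for that (N, B).

Everything is materialized concretely per instance (no symbolic Presburger
arithmetic): the package is both a folding tool and a testbed in which every
claim — tile-partition validity, schedule legality, wavefront independence,
bit-exact equivalence of serial and parallel execution — is machine-checked.

## Worked example

```sh
$ nustile -v fold --random 60 --seed 1 --mode wavefront --tile 16,16,16
>random_n60_s1 pairs=23
CGUUAAUUACUCCUCCGGAAUUUGUCCUACACUACCUAGCAUACCCAUGUAGCGUCGACU
.((((())(.)..(.((((())(((..().))()..()()())))(())()).)..))).
INFO nustile: record=random_n60_s1 N=60 mode=wavefront delta_calls=1770 tiles=30 wavefronts=7 workers=4
```

A random 60-mer folds into an optimal structure with 23 base pairs
(`pairs=` is `S(0, N-1)`; the dot-bracket line matches paired positions).
The bonding function was evaluated 1770 = N(N−1)/2 times; the corrected
tiling produced 30 tiles executed in 7 wavefronts by 4 workers. FASTA files
work the same way (`nustile fold input.fasta`), and `--mode
reference|tiled|wavefront` selects the executor — all three produce
identical matrices.

The validity checker is a command of its own:

```sh
$ nustile validate --n 20 --tile 4,4,4
EMPTY (N=20, B=(4, 4, 4), skew=plus: all 22687 dependences respected)

$ nustile validate --n 8 --tile 2,2,2 --skew minus   # deliberately broken skew
NONEMPTY (N=8, B=(2, 2, 2), skew=minus: 77 violating tile pairs)
VIOLATION: (1, 0, 0, 0) -> (1, 1, 0, 0) via s0(4, 5, 0) -> s0(4, 7, 1)
...
```

`nustile selftest [--quick]` runs the whole invariant battery and prints
one machine-readable PASS/FAIL line per check.

## Layout

- `src/nustile/sequence_io.py` — FASTA I/O, seeded random sequences, δ, dot-bracket
- `src/nustile/nussinov.py` — reference serial DP, traceback, enumeration oracle
- `src/nustile/dependence_graph.py` — iteration space, dependence relations, R+
- `src/nustile/tiling.py` — rectangular tiles and closure-based correction
- `src/nustile/scheduling.py` — skewed schedule, wavefronts, validity relation
- `src/nustile/executor.py` — tiled-serial and wavefront execution, selftest
- `src/nustile/cli.py` — `nustile fold | validate | selftest`

See `docs/methods.md` for the model, algorithmic choices and limitations.
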