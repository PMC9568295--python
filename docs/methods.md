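# Methods

## Model

`topodnn` treats a feed-forward neural architecture purely as an
undirected simple graph. `DNN(M; N₁…N_r; N)` has `r + 2` layers — input
width `M`, hidden widths `N₁…N_r` (`r ≥ 1`), output width `N`, all
positive integers — with complete bipartite wiring between consecutive
layers and no other edges. Consequences used throughout:

- `|V| = M + ΣNᵢ + N` and `|E| = M·N₁ + Σᵢ Nᵢ·Nᵢ₊₁ + N_r·N`.
- All nodes of a layer share a degree: the sum of the adjacent layer
  widths. With the boundary convention `N₀ := M`, `N_{r+1} := N`, layer
  `i ∈ 1..r` has degree `Nᵢ₋₁ + Nᵢ₊₁`, the input layer `N₁`, the output
  layer `N_r`.
- The edge partition by canonical degree pairs therefore has at most
  `r + 1` classes, one per consecutive layer pair: pair
  `(deg(layer i), deg(layer i+1))` with count `Nᵢ·Nᵢ₊₁`. Classes whose
  canonical pairs coincide are merged by summing counts — every index
  functional is symmetric in the two degrees, so merging changes no
  value. (The seven-layer worked example merges two blocks into one
  `(9, 10)` class of 50 edges.)

Every degree-based index is then evaluated two independent ways:

1. **Oracle route** — build the graph explicitly (node labels `L{layer}:{k}`,
   `k` 0-based) and iterate every edge once.
2. **Closed-form route** — generate the partition from the widths alone
   and take the count-weighted sum (or count-exponent product) over
   classes.

The two routes must agree on every architecture; `topodnn verify`, the
property tests and the acceptance script all enforce this. The generic
consecutive-layer generator is the normative closed form for every
`r ≥ 1`. The traditional displayed expressions — two head terms, an
interior sum over `i = 2..r−2`, two tail terms — are well formed only for
`r ≥ 3`; a verbatim transcription of them (`literal_closed_form`) exists
purely as an independent cross-check for the Randić/general-Randić,
Zagreb, multiplicative-Zagreb, forgotten and hyper-Zagreb indices. For
ABC, GA, SCI and AZI no separate transcription is kept: their displayed
forms are error-prone to typeset (nested radicals over ratios), and the
partition route is the definition; the catalog functionals evaluated on
the partition are authoritative. Note the historical naming wrinkle: the
result usually displayed as "the Randić index" of this family is general
Randić at `α = +1/2`, while `χ` proper is `α = −1/2`; the package
supports both and the literal cross-check covers both exponents.

## Index catalog and conventions

Twelve entries (formulas in the README): ten sum-aggregated, two
product-aggregated (`mult_zagreb1` over degree sums, `mult_zagreb2` over
degree products — these are distinct indices, not variants of one
formula). Conventions:

- **Exact integers.** Sum-type values carry an exact arbitrary-precision
  integer whenever every edge term is integral (`zagreb1`, `zagreb2`,
  `hyper_zagreb`, `forgotten`, `general_randic` at non-negative integer
  `α`); product-type values always do, alongside `log₁₀` of the product.
  Equality checks between the two routes are exact in the integers, never
  floating-point, wherever an exact value exists.
- **Log-space products.** `PM₁`/`PM₂` explode (a product over `|E|`
  integer terms — already a 202-digit number for a 29-node graph), so
  `log_space_product` computes `Σ count·log₁₀(term)` without forming the
  big integer; it must agree with `log₁₀` of the exact value to 1e−9
  relative. The float `value` field becomes `inf` past float range; the
  exact integer and `log₁₀` remain usable. JSON serializes exact integers
  as strings, since numeric JSON would silently round them.
- **Domains.** `ABC` at degree pair `(1, 1)` is 0 (zero numerator under
  the root). `AZI` at `(1, 1)` is a domain error (zero denominator);
  layered-family graphs can never produce such an edge (any hidden-layer
  endpoint has degree ≥ 2) but the guard applies to arbitrary input
  graphs. Degrees below 1 on an edge are rejected.
- **Edgeless graphs** return the aggregation identity (0 for sums, 1 for
  products) with a logged warning; the descriptors are meant for graphs
  with edges.
- **`α`** is any real, default `−0.5` in the CLI (the classical Randić
  case); non-integer powers use floating point.

## Tolerances and numerical choices

- Integer-valued indices: exact equality, always.
- Real-valued indices, closed form vs oracle: 1e−9 relative (with a
  1e−12 absolute floor for near-zero values) — both routes sum the same
  finitely many double-precision terms in different orders, so observed
  discrepancies are a few ULPs; 1e−9 leaves three orders of headroom.
- Algebraic identities asserted in floating point (`R₀ = |E|`,
  `R₋₁/₂ = χ`, `GA = |E|` on degree-regular edge sets): 1e−12 relative,
  since both sides are computed from identical terms.
- Degree pairs are canonicalized `(min, max)`; partition class order is
  sorted lexicographically, making reports byte-deterministic.

## Verification design

Three independent anchors guard against a self-consistent but wrong
implementation:

- the handshake identities (`Σ d_v = 2|E|`; partition counts sum to
  `|E|`; `Σ count·(a+b) = Σ d_v²`), asserted exactly on every random
  graph;
- classical cross-index identities (`HM = F + 2M₂`, `M₁ = Σ d_v²`,
  `PM₂ = Π d_v^{d_v}`, `R₀ = |E|`, `R₋₁/₂ = χ`, `GA ≤ |E|` with equality
  iff every edge joins equal degrees), which tie the catalog entries to
  each other through formulas none of the evaluation code uses;
- the literal transcription of the displayed `r ≥ 3` closed forms, a
  third evaluation path sharing no code with the partition generator.

Random inputs are seeded throughout (`random_spec_generator`; sweep
default seed 20221007). Problem sizes, chosen to exercise every code
path (boundary-class merging, empty interior sums at `r = 3`, width-1
layers) while keeping the whole suite in seconds: 200 random
architectures with depth uniform on [1, 8] and every width uniform on
[1, 12]; 200 Erdős–Rényi-style graphs with 2–14 nodes and edge
probability 0.15–0.7; growth sweeps over uniform families
`DNN(k; [k]×r; k)`, `k ∈ {1, 2, 3}`, `r = 1..8`.

## Growth with depth

For the uniform family, appending a width-`k` hidden layer adds `k²`
edges of class `(2k, 2k)` and alters no existing degree, so every
sum-aggregated index with strictly positive terms is strictly increasing
in depth (e.g. `M₁` gains exactly `k²·4k` per layer — 32 at `k = 2`).
`growth_profile` generalizes to non-uniform bases by padding with the
last hidden width; for such families monotonicity is an empirical
observation, not a theorem, since early degrees can change between
depths.

## What the synthetic inputs do and do not show

All fixtures are generated: random layered architectures and random
Erdős–Rényi-style graphs. They fully exercise the mathematics — the
closed forms are exact combinatorial statements, so a match on random
architectures is as strong as a match on "real" ones. What they do not
address is any empirical claim linking index values to trained-network
accuracy or to molecular properties; the package computes descriptors
and makes no such claims. Directed, weighted and multigraph inputs,
distance-based indices (Wiener, Harary, PI) and spectral invariants
(energy, Estrada, Kirchhoff) are out of scope; molecular file formats
(SMILES/SDF) are not parsed, though any molecule already reduced to a
two-column edge list works through `topodnn graph`.

## Known limitations

- The literal-transcription cross-check covers the eight indices whose
  displayed forms are unambiguous; ABC/GA/SCI/AZI are verified through
  the oracle route only (twice over, graph vs partition).
- Node identifiers in edge lists are opaque strings; two labels differing
  only in surrounding whitespace are distinct after stripping.
- `general_randic` at large positive `α` on wide architectures can lose
  precision in the float `value`; the exact field (integer `α ≥ 0`) is
  the reliable carrier there.
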