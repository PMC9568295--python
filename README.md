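# topodnn

Degree-based topological indices for layered fully-connected
neural-network graphs — and for arbitrary undirected simple graphs — via
the edge-partition method of chemical graph theory.

## The problem

A topological index is a single number determined by the structure of a
graph. In QSPR/QSAR work such indices serve as molecular descriptors that
correlate with physicochemical properties (boiling point, molar volume,
enthalpy of vaporization, ...). The degree-based family is the workhorse:
every index here is a sum or product over edges `uv` of a symmetric
function of the endpoint degrees `d_u`, `d_v`:

| name | formula |
| --- | --- |
| Randić `χ` | `Σ (d_u d_v)^(−1/2)` |
| general Randić `R_α` | `Σ (d_u d_v)^α` |
| first Zagreb `M₁` | `Σ (d_u + d_v)` |
| second Zagreb `M₂` | `Σ d_u d_v` |
| first multiplicative Zagreb `PM₁` | `Π (d_u + d_v)` |
| second multiplicative Zagreb `PM₂` | `Π d_u d_v` |
| hyper-Zagreb `HM` | `Σ (d_u + d_v)²` |
| atom-bond connectivity `ABC` | `Σ √((d_u + d_v − 2)/(d_u d_v))` |
| sum-connectivity `SCI` | `Σ (d_u + d_v)^(−1/2)` |
| geometric-arithmetic `GA` | `Σ 2√(d_u d_v)/(d_u + d_v)` |
| forgotten `F` | `Σ (d_u² + d_v²)` |
| augmented Zagreb `AZI` | `Σ (d_u d_v/(d_u + d_v − 2))³` |

A feed-forward network with an input layer of `M` nodes, hidden layers of
widths `N₁…N_r` and an output layer of `N` nodes, fully connected between
consecutive layers, is as a graph a chain of complete bipartite blocks,
written `DNN(M; N₁…N_r; N)`. Every node of layer `i` has the same degree
(the sum of the neighbouring layer widths), so the edge set partitions
into at most `r + 1` degree-pair classes and each index above has a
closed form in the widths. `topodnn` implements both routes — the closed
form and brute-force evaluation on the explicitly constructed graph — and
continually cross-validates one against the other.

## Worked example

The seven-layer architecture with 4 inputs, hidden widths 4, 5, 6, 4, 3,
and 3 outputs:

```
$ topodnn dnn --arch 4,4,5,6,4,3,3 --indices zagreb1,randic,mult_zagreb2 --partition
index	alpha	value	exact	log10
zagreb1		1872	1872	
randic		14.0796150044		
mult_zagreb2		8.10337959293e+201	81033795929290288...	201.908666183

d_u	d_v	count
3	7	9
4	9	16
7	9	12
9	9	24
9	10	50
```

The graph has 29 nodes and 111 edges. The partition table says, e.g.,
that 50 edges join a degree-9 node to a degree-10 node (two bipartite
blocks merge into one class). `zagreb1 = 1872` is the first Zagreb index,
which also equals the sum of squared node degrees; `mult_zagreb2` is a
202-digit integer, reported exactly (truncated here for width) and as a
base-10 logarithm.

Verify every closed form against brute force on random architectures:

```
$ topodnn verify --trials 200 --seed 20221007
verified: 200 random architectures (depth <= 8, width <= 12), all indices match the brute-force oracle
```

Arbitrary graphs come in as TSV edge lists (`topodnn graph --edge-list
edges.tsv`), and `topodnn sweep --width 2 --max-depth 8` tabulates how
every index grows as hidden layers are added.

The same API is available from Python:

```python
from topodnn import DNNSpec, closed_form_index
spec = DNNSpec(4, (4, 5, 6, 4, 3), 3)
closed_form_index(spec, "zagreb1").exact   # 1872
```

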