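# degvar — normalised degree variance for networks

`degvar` measures **degree heterogeneity** — how unequally connections are
spread over the nodes of a network — in a way that is comparable across
networks of different sizes and densities. It is aimed at network
scientists (neuroimaging connectomics, ecology, systems biology, social
networks) who need a heterogeneity index that does not silently track the
number of nodes or edges.

## The index

For a simple graph G with n nodes, m edges, density d = 2m/(n(n−1)) and
degrees k₁,…,kₙ, the degree variance is the sample variance of the degree
sequence,

    v(G) = ‖k‖₂² / (n−1) − (2m)² / (n(n−1)),

and the **normalised degree variance** is

    v̄(G) = (n−1) / (n·m·(1−d)) · v(G)        for d ∈ (0,1),
    v̄(G) = 0                                  for d ∈ {0,1}.

Key properties, all enforced by the test suite:

* **0 ≤ v̄ ≤ 1** for every simple graph, with 0 exactly on regular graphs;
* **complement invariance**: v̄(G) = v̄(Ĝ);
* the star graph is maximal among quasi-stars, v̄(star_n) → 1 as n → ∞,
  with the closed form (n³−5n²+8n−4)/(n³−3n²+2n);
* for Erdős–Rényi ensembles G(n,m) the expectation E[v̄] = 2(n−1)/(n²+n)
  is exactly independent of m (and hence of density);
* v̄ is defined for graphs with isolated nodes, where the inverse-√-degree
  heterogeneity index ρ is not.

The package also implements the competing normalisations it is designed to
replace — the quasi-star normalisation J (which exceeds 1 on quasi-complete
graphs), the average-degree normalisation σ² (which grows with n), Estrada's
heterogeneity index ρ and the Albertson irregularity — plus the extremal
quasi-star/quasi-complete constructors, seeded random-graph ensembles,
density thresholding for weighted matrices, degree-multiplicity lower
bounds on v̄, a sweep/coefficient-of-variation harness and node/edge
subsampling robustness procedures.

## Worked example

```python
from degvar import report
from degvar.generators import star_graph, er_gnm, quasi_complete
from degvar.metrics import expected_vbar_er_gnm

r = report(star_graph(16))
print(r.n, r.m, r.v, r.v_bar, r.J, r.rho)
# 16 15 12.25 0.875 1.0 1.0000000000000002
```

The star on 16 nodes has degree variance 12.25; its normalised value 0.875
is already close to the upper bound 1 (stars approach it as n grows). J and
ρ both equal 1 here by construction — but compare:

```python
r = report(quasi_complete(6, 10))          # K5 plus an isolated node
print(r.v_bar, r.J, r.rho)
# 0.6666666666666666 1.4285714285714284 Undefined('isolated_node')
```

The quasi-complete graph drives J above 1 (it is not a valid normalisation)
and ρ is undefined because of the isolated node, while v̄ stays in [0,1].
For an ER draw the value sits near the size-only expectation:

```python
g = er_gnm(64, 300, seed=7)
print(report(g).v_bar, expected_vbar_er_gnm(64))
# 0.02224099099099099 0.030288461538461538
```

The same operations are available from the shell:

```sh
degvar generate --model er_gnm --n 20 --m 50 --seed 3 --out g.tsv
degvar metrics --input g.tsv --out report.tsv
degvar sweep --models quasi_star,er_gnm --sizes 16,32 --densities 10:90 \
             --reps 100 --seed 1 --out sweep.tsv --cov-out cov.tsv
degvar subsample --input g.tsv --fracs 5,10,15,20,25 --reps 50 --seed 2 \
                 --out robustness.tsv
```

## Layout

| module | contents |
| --- | --- |
| `degvar.graph` | `Graph` / `WeightedMatrix` containers, degrees, density, complement, thresholding |
| `degvar.metrics` | all heterogeneity indices, closed forms, ER expectations, lower bounds |
| `degvar.generators` | quasi-star/quasi-complete constructors, ER/geometric/scale-free ensembles |
| `degvar.subsampling` | node/edge removal schemes and robustness profiles |
| `degvar.experiments` | sweep harness, coefficient-of-variation summaries, lower-bound survey |
| `degvar.io` / `degvar.cli` | edge-list/adjacency readers, report writers, `degvar` command |

See `docs/methods.md` for the modelling choices, parameter conventions and
known limitations.
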