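# icmsim

Agent-based simulation and spatial statistics for inner-cell-mass (ICM)
organoid patterning.

During mammalian preimplantation development the inner cell mass segregates
into epiblast (NANOG-high) and primitive endoderm (GATA6-high). ICM
organoids — stem-cell aggregates of a few hundred cells — mimic this second
fate decision, and cells of the same expression type are observed to
cluster locally more than random fate assignment would predict. `icmsim`
implements a centre-based off-lattice model to test whether that clustering
can arise from **cell division plus cell-fate heredity alone**, with no
chemical signalling and no cell sorting, together with the neighbourhood
and radial statistics needed to compare simulated spheroids against
organoid data.

## The model

Each cell *i* carries a position **x**ᵢ, a radius *r*ᵢ and one of four
expression types ε ∈ {N₊G₊, N₋G₋, N₊G₋, N₋G₊}. Motion is overdamped and
driven by pairwise Morse-type forces,

    F_{i,k} = F₀ · F(rᵢ, r_k, d) · (xᵢ − x_k)/d,
    F(rᵢ, r_k, d) = 2(e^{−2a(d−(rᵢ+r_k))} − e^{−a(d−(rᵢ+r_k))})  for d < σrᵢ, else 0,

repulsive below contact distance rᵢ+r_k, adhesive up to the cutoff σrᵢ
(F₀ = 1, a = 0.6, σ = 4). Radii grow as dr/dt = k(r\* − r) with k = 1,
r\* = 1. A cell above 95 % of r\* divides with constant hazard; division
conserves total volume exactly (both daughters get radius r·2^(−1/3)) and
the daughter is placed at a small random offset.

Fates are assigned i.i.d. from a proportion vector when the population
first reaches a configurable count t₀ ∈ {200, 300, 400}; snapshots are
taken at 441 cells (t₁, the 24 h stage) and 1041 cells (t₂, the 48 h
stage). At division, daughter types follow one of four nested heredity
hypotheses: H1 (strict heredity) through H4 (increasingly many permitted
type switches). Because all fates divide at the same rate, expected
proportions follow a linear flow in s = ln(cell count),
dp/ds = (Dᵀ − 2I)p with D the expected-daughter matrix, which the package
uses to back-solve t₀ proportions from t₁ targets and to fit switch rates.

Analyses: Delaunay-triangulation neighbourhoods, per-type neighbour
composition matrices, same-type enrichment, the effect size
ψ = mean |s̄−m̄|/m̄, Wilcoxon–Mann–Whitney comparisons with Bonferroni
correction, MAD-normalised radial fate profiles and pooled kernel density
maps. A synthetic organoid generator with controllable proportions,
clustering strength and rim bias makes the whole pipeline testable without
any experimental download.

## Worked example

```python
import numpy as np
from icmsim import (ExperimentConfig, simulate_replicate,
                    delaunay_adjacency, neighbourhood_composition,
                    same_type_enrichment)
from icmsim.types import TYPE_NAMES, etype_codes

config = ExperimentConfig(hypothesis="H1", n_reps=1, base_seed=0)
t1, t2, p0 = simulate_replicate(config, seed=0)
print(f"snapshot sizes: t1={len(t1)} cells, t2={len(t2)} cells")
print("assigned t0 proportions:",
      {n: round(float(v), 3) for n, v in zip(TYPE_NAMES, p0)})

pos = t1[["x", "y", "z"]].to_numpy()
codes = etype_codes(t1["etype"])
stats = neighbourhood_composition(codes, delaunay_adjacency(pos))
baseline = np.bincount(codes, minlength=4) / len(codes)
for name, e, b in zip(TYPE_NAMES, same_type_enrichment(stats, baseline),
                      baseline):
    print(f"{name}: global proportion {b:.3f}, same-type enrichment {e:+.3f}")
```

prints

```
snapshot sizes: t1=441 cells, t2=1041 cells
assigned t0 proportions: {'NpGp': 0.15, 'NnGn': 0.1, 'NpGn': 0.4, 'NnGp': 0.35}
NpGp: global proportion 0.184, same-type enrichment +0.022
NnGn: global proportion 0.068, same-type enrichment +0.026
NpGn: global proportion 0.397, same-type enrichment +0.046
NnGp: global proportion 0.351, same-type enrichment +0.025
```

The simulation grew a 200-cell spheroid to exactly 441 and then 1041 cells.
Fates were assigned at 200 cells from the configured t₁ target proportions
(under H1 the back-solved t₀ proportions equal the targets). The positive
same-type enrichment for every type — each fate sees more neighbours of its
own type than its global share — is the headline effect: local fate
clusters produced purely by division and heredity. Shuffling the fates over
the same positions drives all four values to ≈ 0, and delaying assignment
to t₀ = 300 or 400 cells shrinks them monotonically (see
`tests/test_acceptance.py`).

The same pipeline is scriptable from a shell:

```sh
icmsim simulate --hypothesis H1 --n-reps 10 --seed 0 --out runs/h1
icmsim synth --n-organoids 10 --out data/synthetic
icmsim neighbours runs/h1/reps/rep0000_t1.csv
icmsim fit-rates --hypothesis H2
```

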