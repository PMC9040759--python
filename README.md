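# ncycomm

Community-assembly analysis for marine nitrogen-cycling metagenome
profiles: diversity, biogeography, environmental-driver attribution,
variation partitioning, and richness-constrained null models yielding the
stochastic ratio.

## The problem

Shotgun-metagenome profiling of N-cycling communities produces two views
of the same samples: a **taxonomic** table (samples x species) and a
**functional-trait** table (samples x gene families such as *amoA*,
*nirS*, *nosZ*). Because many taxa encode the same trait (functional
redundancy), the two views can assemble differently: the environment may
select *functions* deterministically while the *taxa* carrying them turn
over stochastically. `ncycomm` provides, for both views, the statistics
used to test this:

- alpha/beta diversity (Shannon-Wiener, Chao1, richness, Bray-Curtis,
  PCoA/PCA) and group tests (PERMANOVA, ANOSIM, MRPP);
- the latitudinal diversity gradient (richness ~ |latitude|) and the
  distance-decay relationship (log10 similarity ~ log10 km, slope *S*);
- Mantel / partial Mantel tests and random-forest factor importance for
  geo-environmental drivers;
- PCNM spatial eigenvectors, forward selection and variation
  partitioning (pure-environment *a*, shared *b*, pure-space *c*,
  unexplained *d*, from adjusted R² of partial RDA/CCA models);
- the **stochastic ratio**: null communities preserving each sample's
  richness and total (features drawn with probability proportional to
  occupancy) give an expected similarity Ē per pair; observed similarity
  C is compared branch-wise,

      ST_ij = Ē/C          if C ≥ Ē,
      ST_ij = (1−Ē)/(1−C)  if C < Ē,

  and pooled into ST ∈ [0, 1] — 1 means assembly indistinguishable from
  the null (stochastic), values toward 0 mean deterministic selection.

A synthetic-community generator with a tunable niche-vs-neutral weight
*w* and taxa-per-trait redundancy *R* exercises the whole pipeline with
known ground truth.

## Worked example

```python
import numpy as np
from ncycomm import SyntheticConfig, make_community, run_stochasticity

config = SyntheticConfig(n_stations=10, n_taxa=150, n_traits=30,
                         stochastic_weight=0.5, seed=1)
metadata, taxon, trait, truth = make_community(config)

for name, table in (("taxon", taxon), ("trait", trait)):
    results = run_stochasticity(table, metadata, n_null=200,
                                rng=np.random.default_rng(0))
    print(name, {grp: round(res.st, 3) for grp, res in results.items()})
```

prints

```
taxon {'all': 0.238, 'SRF': 0.422, 'DCM': 0.409, 'MES': 0.445}
trait {'all': 0.158, 'SRF': 0.328, 'DCM': 0.308, 'MES': 0.314}
```

Read: globally, observed taxon similarities sit at ~24% of their null
expectation structure while traits sit at ~16% — both communities are
strongly deterministic at these simulation settings (w = 0.5), and the
trait level is consistently *more* deterministic than the taxon level,
the functional-redundancy signature. Per-layer ratios are higher because
each layer's regional pool is more homogeneous.

The `examples/` directory holds one short script per capability
(synthesis, diversity + biogeography, group tests + drivers, VPA,
stochasticity, full pipeline); each prints its numbers with a line of
interpretation. The `ncycomm` CLI wraps the pipeline for shell use:

```bash
ncycomm synth --out-dir data/ --n-stations 10 -w 0.5 --seed 1
ncycomm run --config run.yaml     # stages, seeds, outputs in YAML
ncycomm demo --out-dir demo_run/  # synthesize + run everything
```

Every stage writes machine-readable JSON plus a manifest with per-stage
checksums; identical config + seed reproduces checksums bit for bit.

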