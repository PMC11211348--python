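# ammodiv

Regionalised diversification dynamics from fossil occurrence data.

`ammodiv` is a pipeline for estimating origination and extinction rates from
taxonomically classified, stratigraphically dated fossil occurrences — built
around the Late Cretaceous ammonoid record, but applicable to any clade with
a dense occurrence record — and for asking what drove those rates. It
addresses the two biases that dominate such data: *spatial* sampling bias is
removed by standardising each time slice to a common geographic extent, and
*temporal* sampling bias by jointly modelling fossil preservation with the
birth-death process.

## What it does

1. **Occurrence handling** (`ammodiv.occurrences`) — validated CSV I/O,
   removal of occurrences with stratigraphic age uncertainty exceeding
   10 Myr, flagging against reference stratigraphic ranges, flagging of
   anomalously long range tails, and locality-consistent age randomisation
   (occurrences from one locality share a drawn point age in each replicate).
2. **Spatial standardisation** (`ammodiv.spatial`) — occurrences are binned
   on a geodesic hexagonal grid (Voronoi cells of a subdivided icosahedron,
   `10f² + 2` cells, no latitudinal area distortion); the spatial extent of a
   time slice is the summed great-circle length of the minimum spanning tree
   (MST) over occupied cell centres; MST tips with the fewest occurrences are
   pruned until the extent best matches a target. Sliding spatial windows
   track drifting bioprovinces, coverage-based richness (shareholder quorum
   subsampling, quorum 0.5) and one-tailed extent–diversity correlations
   verify that residual extent no longer drives diversity.
3. **Birth–death–sampling inference** (`ammodiv.bds`) — the joint posterior
   of per-lineage origination/extinction ages (`ts`, `te`), piecewise
   origination and extinction rates λ(t), μ(t) with reversible-jump sampling
   of the number and position of rate shifts, and stage-binned Poisson
   preservation rates q under a Gamma(1.5) prior with an exponential
   hyper-prior. Outputs: rates through time with 95 % HPDs, shift support as
   log Bayes factors (2 ln BF; 2 = positive, 6 = strong), and range-through
   diversity at 0.5 Myr resolution.
4. **Driver models** (`ammodiv.mbd`) — λ and μ as exponential or linear
   functions of time-continuous drivers (sea level, temperature, CO₂, the
   clade's own diversity, …) rescaled to [0,1] on a 0.1 Myr grid, with a
   horseshoe prior per driver; the shrinkage weight W ∈ [0,1] flags
   significant drivers at W > 0.5. AICM and harmonic-mean Bayes factors
   compare link functions.
5. **Trait-dependent extinction** (`ammodiv.mte`) — lineage extinction rate
   = mean rate × discrete trait-category multipliers (suborder and
   superfamily membership as ecological proxies), with Bayesian variable
   selection placing 95 % prior mass on "no effect"; a trait is significant
   when its posterior inclusion frequency exceeds 51.4 % (the posterior
   probability equivalent to logBF > 6 at a 5 % prior).
6. **Synthetic records** (`ammodiv.simulate`) — a forward simulator (birth–
   death lineages, Poisson preservation, substage dating, shared localities,
   regional spatial clustering, covariate and trait effects) with fully
   serialised truth, used to validate every stage.

## Worked example

```python
from ammodiv import pipeline

cfg = pipeline.load_config()          # desk-scale defaults
cfg["seed"] = 1
results = pipeline.run_pipeline(cfg, "runs/demo")
print(results["mte"].head())
```

which prints (`runs/demo/` holds all output tables):

```
      trait category  posterior_mean_multiplier  inclusion_frequency  significant
0  suborder     SubA                   0.999952             0.030513        False
1  suborder     SubB                   0.999795             0.030513        False
2  suborder     SubC                   0.998644             0.030513        False
3  suborder     SubD                   1.001619             0.030513        False
4  suborder     SubE                   1.000565             0.030513        False
```

Here the simulated record has no trait effects, and the model correctly
keeps both traits' inclusion frequencies near the 5 % prior (well below the
51.4 % significance threshold) with multipliers pinned at 1. The same run
writes `rtt.tsv` (λ, μ and net diversification through time with HPDs),
`diversity.tsv` (range-through richness at 0.5 Myr steps), `sqs.tsv`
(coverage-standardised richness per stage) and `standardization.tsv`
(MST extent before/after pruning per stage).

The same stages are available from a shell:

```bash
ammodiv simulate --out runs/demo --seed 1
ammodiv clean --out runs/demo
ammodiv standardize --out runs/demo
ammodiv bds --out runs/demo
ammodiv mbd --out runs/demo
ammodiv mte --out runs/demo
```

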