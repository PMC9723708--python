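# micasm — community assembly under repeated micropollutant exposure

`micasm` analyzes serial-transfer microcosm experiments in which a
freshwater bacterial community is repeatedly exposed to trace
micropollutants (bisphenol A and S, triclosan, triclocarban) over
multiple 5-day transfer batches. It answers three questions: how fast
are the compounds removed, how does the community turn over relative to
unexposed controls, and which ecological processes — selection, dispersal,
or drift — drive its assembly as exposure continues.

The toolkit bundles:

* **`micasm.synthio`** — a synthetic serial-transfer experiment
  generator (coalescent phylogeny, Brownian tolerance trait, degrader
  guild, seed-bank activation, demographic drift, first-order chemical
  decay, multinomial sequencing) with full ground truth, emulating a
  5-arm × 3-replicate × 7-batch design with 10% transfers (105 samples).
* **`micasm.assembly`** — null-model partitioning of assembly processes.
  Phylogenetic turnover per sample pair is the abundance-weighted
  β-mean nearest taxon distance,

  βMNTD(x, y) = ½ [ Σᵢ xᵢ · minⱼ D(i, j) + Σⱼ yⱼ · minᵢ D(j, i) ],

  standardized against 999 tip-shuffle randomizations into the z-score
  βNTI = (βMNTD_obs − μ_null)/σ_null. Taxonomic turnover is positioned
  within a richness- and occupancy-constrained null by RC_bray ∈ [−1, 1].
  Each pair is classified: βNTI > +2 variable selection, βNTI < −2
  homogeneous selection, |βNTI| ≤ 2 with RC_bray > 0.95 dispersal
  limitation, RC_bray < −0.95 homogenizing dispersal, otherwise drift.
* **`micasm.doc`** — dissimilarity–overlap analysis: per pair, overlap
  O = ½ Σ_{i∈shared}(xᵢ + yᵢ) and dissimilarity = root Jensen–Shannon
  divergence (base 2) of the shared fractions renormalized to 1, with a
  linear fit above the median-overlap cutoff and a sample-bootstrap
  fraction of negative slopes.
* **`micasm.copynum`** — community-weighted mean 16S rRNA gene copy
  number and growth-phase inference by complete-linkage clustering of
  batch profiles with a time-contiguity constraint.
* **`micasm.ecogroups`** — sensitive / opportunistic / tolerant OTU
  calls from one-sided phase contrasts on median-of-ratios-normalized
  counts, with joint Benjamini–Hochberg control at α = 0.05.
* **`micasm.community`** — Bray–Curtis, rarefaction without
  replacement, removal-rate computation, exact/asymptotic rank-sum and
  Kruskal–Wallis tests, turnover regression.
* **`micasm.pipeline` / `micasm` CLI** — one-config orchestration of
  every stage with a single seed.

## Worked example

```bash
python analysis/01_simulate_experiment.py --seed 1   # writes results/data/
python analysis/02_removal_kinetics.py
python analysis/03_growth_phases.py
python analysis/04_community_turnover.py
python analysis/05_assembly_processes.py --n-null 999
python analysis/06_dissimilarity_overlap.py
python analysis/07_ecological_groups.py
```

With seed 1 the simulation writes 105 samples (150 OTUs, 36 000 reads
each). Selected output:

```
mean removal (%) by arm and compound:
BPA  BPA  80.47     # subsidy compound, degraded by the degrader guild
TCS  TCS  48.67     # stress compound, slower tolerance-gated removal
MI   BPA  49.23     # BPA removal suppressed when TCS co-occurs
```

BPA alone is largely consumed within a batch (>80%), the antimicrobial
TCS is removed more slowly (<60%), and in the mixture arm BPA removal
drops because TCS suppresses the growth of its degraders.

```
TCS vs Control (189 pairs, n_null=999):
       variable_selection  dispersal_limitation  drift
1                   0.000                 0.556  0.444
2                   0.000                 1.000  0.000
3                   0.007                 0.903  0.090
```

Early batches are dominated by stochastic processes (drift plus
dispersal limitation from the transfer bottlenecks); deterministic
selection appears only as exposure accumulates. The
dissimilarity–overlap stage prints, per arm, the slope of dissimilarity
against overlap and the fraction of bootstrap slopes below zero (e.g.
`BPA: ... slope -0.449, fraction of negative bootstrap slopes 1.000`),
the signature of shared taxon dynamics across batches.

Equivalent single-command run:

```bash
micasm run-all --config run.yaml --out report.json
```

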