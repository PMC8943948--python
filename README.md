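# iegnet

Functional-connectivity network analysis of regional immediate-early-gene
(IEG) expression.

When a cohort of animals performs a memory task, regions that were engaged
together show correlated counts of plasticity-related IEG products (EGR-1,
ARC) across animals.  `iegnet` turns such count tables — 12 brain regions
(PrL, IL, Orb, Ins, ACC, Ssp, aRC, pRC, DG, CA3, CA1, EC), four behavioural
groups (OPA, NPA, NM, CC), two IEGs per animal — into functional networks
and tests how their module structure differs between behavioural
conditions.  It is written for systems-neuroscience labs running
IEG-imaging cohort studies, and ships a synthetic-cohort generator so the
entire pipeline is testable without access to any particular dataset.

The pipeline:

1. **Correlation matrices** — observations are (animal, IEG) rows; for each
   group the 12x12 Pearson matrix r is computed.  Networks keep edges with
   r strictly above a threshold; at n = 14 observations the thresholds
   r > 0.80 / 0.87 / 0.92 correspond to two-tailed p < 0.001 / 0.0001 /
   0.00001 under t = r·sqrt(n−2)/sqrt(1−r²).
2. **Hierarchical clustering** — UPGMA on the uncentered-correlation
   distance d(x, y) = 1 − Σxᵢyᵢ / sqrt(Σxᵢ² Σyᵢ²).
3. **Module detection** — Louvain maximization of signed modularity
   Q = Q⁺ − (v⁻/(v⁺+v⁻))·Q⁻ with resolution γ on the *unthresholded*
   matrix; γ is chosen by a stability sweep (γ ∈ [0.1, 2.0], step 0.01,
   100 seeded runs per γ, agreement scored with adjusted mutual
   information), taking the widest plateau of perfectly stable, constant
   partitions.
4. **Group comparison** — Fisher z = arctanh r and
   D = (z₁−z₂)/sqrt(1/(n₁−3)+1/(n₂−3)) per region pair, plus a paired
   t-test (Bonferroni-corrected) on the 15 within-module pair correlations
   between a reference group and each other group.
5. **Behaviour** — performance index 100 − 100·(errors/5) and cued-recall
   dig-time proportions.

See `docs/methods.md` for the statistical details and design choices.

## Worked example

```python
import iegnet as ig
from iegnet.community import gamma_sweep, select_stable_plateau

# a synthetic cohort with the default study design: 4 groups x 7 animals,
# NPA carrying a planted {DG, CA3, CA1, PrL, ACC, aRC} module
table = ig.normalize_counts(ig.simulate_counts(ig.default_paper_spec(seed=1)))

obs = ig.build_observation_matrix(table, groups=["NPA"])   # 14 x 12
C = ig.pearson_matrix(obs)
print(C.r("DG", "CA3"), C.r("DG", "Ssp"))   # 0.811  0.087
print(len(ig.threshold_network(C, 0.80).edges))            # 15

profile = gamma_sweep(C.to_numpy(), regions=C.labels, runs=100, base_seed=1)
sel = select_stable_plateau(profile)        # plateau [0.56, 1.38] -> gamma 0.97
part = ig.louvain(C.to_numpy(), regions=C.labels, gamma=sel.gamma, seed=2)
print(part.modules())
# module 1: {ACC, CA1, CA3, DG, Orb, PrL, aRC}   module 2: the rest
```

At this cohort size (n = 14 observations) the planted hippocampal–midline
module comes back with one extra region (Orb) absorbed by sampling noise —
the module structure is recovered, its exact boundary is not guaranteed.
Comparing module strength across groups:

```python
mats = {g: ig.pearson_matrix(ig.build_observation_matrix(table, groups=[g]))
        for g in ["OPA", "NPA", "NM", "CC"]}
res = ig.compare_module_strength(mats, ig.NPA_MODULE, reference="NPA")
print(res.mean_r)
# {'CC': 0.273, 'NM': 0.008, 'NPA': 0.859, 'OPA': 0.152}
print(res.comparisons)
#  group      t      df  p_raw     p_bonferroni
#  OPA    7.85   14  1.7e-06      5.1e-06
#  NM    10.89   14  3.2e-08      9.6e-08
#  CC     5.35   14  1.0e-04      3.1e-04
```

The NPA group's within-module correlations exceed every other group's
(paired t over the 15 region pairs, all Bonferroni p < 0.001): the module is
specific to the condition in which it was planted.

## Command line

```bash
iegnet simulate --seed 1 --out counts.csv        # synthetic cohort
iegnet correlate --counts counts.csv --group NPA --out corr.csv
iegnet cluster   --counts counts.csv --out dendrogram.nwk
iegnet modules   --counts counts.csv --group NPA --seed 1 --out partition.json
iegnet compare   --counts counts.csv --out strength.csv
iegnet all       --seed 1 --outdir report/       # everything, plus manifest
```

`iegnet all` writes, per group and pooled: the correlation matrix, Newick
dendrogram, edge lists at r > 0.80/0.87/0.92, the γ-stability profile, the
module partition, Fisher z-difference tables for each group pair over the
module of interest, the module-strength comparison, and a JSON manifest of
all seeds and options (reruns are bit-identical).

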