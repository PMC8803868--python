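# mapgraph

Graph-based analysis of granule-cell → Purkinje-cell (GC→PC) synaptic
connectivity maps in the cerebellar cortex.

Functional GC→PC maps — rectangular grids of light-evoked EPSC amplitudes
recorded in one Purkinje cell while photostimulating the granule-cell layer —
are patchy: clusters of connected sites surrounded by silent ones. `mapgraph`
quantifies that spatial structure and relates it to behavior:

1. **Map processing.** Each site is z-scored against the recording's pooled
   synaptic-noise distribution, `z = (A − X)/σ`; sites with `z ≥ 3` are
   synaptically connected. Per-column maxima give mediolateral synaptic
   profiles, aligned across animals by normalising positions to the
   ipsilateral P1− zebrin band. Group median profiles (± MAD), averaged maps,
   cumulative-strength curves and 2×2 downsampling complete the stage.
2. **Graph representation.** Columns become nodes; edge weights are Pearson
   correlations between column amplitude profiles, clipped to [0, 1]. Louvain
   community detection partitions each graph, and four weighted metrics
   summarise it: modularity `Q^w`, module-degree z-score `z_i^w`,
   participation `y_i^w`, and degree assortativity `r^w`. Metrics are
   optionally expressed as Δ% = (actual − null)/null × 100 against
   degree-preserving rewired null graphs.
3. **Zoning.** Columns are labeled by anatomical zebrin band (structural
   zones) and by graph module (functional zones, contiguous or module-wise);
   correspondence is the mutual information normalised by the larger label
   entropy, with permutation chance levels.
4. **Models.** t-SNE embeddings of per-map feature vectors, random-forest
   classification of locomotor condition (150 trees, depth 30, 100 stratified
   80:20 trials) against shuffled-label chance, and prediction of individual
   behavioral features by a Gaussian GLM with a group-interaction term,
   `Y = β0 + Σβ_j G_j + Σγ_j T G_j + ε`, `T ∈ {±1}`.
5. **Behavior.** Balance index `BI = log10(∫left/∫right)` time courses with
   phase AUCs and day-15 summaries, and wheel-training totals/slopes.

A synthetic-data module generates full cohorts — zebrin geometries sampled
from printed band statistics, patchy maps with condition-specific amplitude
distributions, trial-level draws, and behavior coupled to map features by a
planted GLM — so every stage runs and is testable without any recordings.

## Worked example

```python
import numpy as np
import mapgraph as mg

cfg = mg.CohortConfig(counts={"control": 5, "early_cuff": 5, "adapted_sham": 5}, seed=42)
cohort = mg.generate_cohort(cfg, with_trials=False)

m = cohort.maps[0]
zm = mg.compute_zscore_map(amplitudes=m.amplitudes,
                           noise_mean=cfg.noise.mean, noise_sd=cfg.noise.sd)
stats = mg.active_site_stats(zm, m)
prof = mg.project_profile(m, zm, mode="max_weight")
g = mg.build_correlation_graph(m)
part = mg.detect_modules(g, seed=42)
sz = mg.structural_zones(m.column_positions, m.geometry)
fz = mg.functional_zones(part)
mi = mg.mi_chance(sz, fz, n_perm=500, seed=42)
```

prints (via the obvious `print` calls):

```text
map control_00: 6x64 sites, 13.8% active, mean active weight 70.6 pA
cumulative strength: 1.79 nA
graph: 64 nodes, Q = 0.319, 3 modules
g_global = [ 0.319 -0.009  0.489  0.553]
structural/functional NMI = 0.479 (chance 95% CI 0.277-0.337)
```

Reading this: ~14% of the 384 sites are connected (the control regime), the
mean significant weight sits near the configured 72.3 pA control
distribution, the map's graph splits into 3 modules with modularity 0.32,
and the functional zones share substantially more information with the
zebrin bands than label-shuffled chance.

The same pipeline runs end to end from the shell:

```bash
mapgraph run-all --seed 0 --out run/        # generate → ... → classify/predict
mapgraph generate --seed 0 --out cohort_run # synthetic cohort only
```

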