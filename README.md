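# connectogcn

Classification of brain functional connectomes across acquisition sites,
with graph convolutional networks and interpretable node saliency.

Pooling resting-state fMRI from several scanners is the only way to reach
sample sizes at which single-subject psychiatric classification is
meaningful, but scanner- and sequence-driven *site effects* on functional
connectivity can rival the case-control effect itself. This package
implements the full analysis chain for that setting:

1. **Connectivity** — regional BOLD time series → Pearson correlation
   between all region pairs → Fisher r-to-z; for the standard 90-region
   anatomical parcellation this yields 4005 unique edges per subject.
2. **Harmonization** — parametric empirical-Bayes **ComBat** on the edge
   level: per edge *g*, site *i*, subject *j*,
   `y_ijg = α_g + x_ij'β_g + γ_ig + δ_ig ε_ijg`, with site location γ and
   scale δ shrunk toward site-level priors (normal / inverse-gamma, moment
   matched) before removal; diagnosis, age and sex are protected
   covariates. A before/after audit (per-edge ANOVA across sites, BH-FDR)
   quantifies what harmonization removed.
3. **Graph encoding** — each subject's z-matrix becomes a weighted graph
   `G = (V, E, W)`: nodes are regions, node features are connectivity
   profiles, and `W` comes from a k-nearest-neighbor rule (k = 10) on
   Euclidean distance between profiles, with Gaussian edge weights.
4. **GCN classifier** — stacked graph convolutions
   `H^(l+1) = ReLU(Ŵ H^(l) Θ^(l))` with
   `Ŵ = D̃^{-1/2}(W + I) D̃^{-1/2}`, global average pooling over nodes, and
   a single linear head — implemented directly in NumPy (manual
   backpropagation, Adam, early stopping) with bit-reproducible seeding.
5. **CAM saliency** — because the head is linear after pooling, class
   activation mapping is exact: `M_c(v) = Σ_k w^c_k H^(L)_{v,k}` with
   `mean_v M_c(v) = logit_c − b_c`, attributing the decision to individual
   brain regions.
6. **Baselines and statistics** — a linear SVM on the edge vector with
   nested 10-fold selection of C and per-region weight aggregation; nodal
   degree / efficiency / betweenness of the salient regions on thresholded
   networks; permutation tests for group differences; POMP-standardized
   symptom scores and their FDR-corrected correlations with nodal topology.
7. **Evaluation** — stratified k-fold and leave-one-site-out (LOSO)
   cross-validation with balanced accuracy, sensitivity, specificity and
   AUC, each with 95% CIs.

Because clinical MRI cohorts of this kind are not publicly deposited, the
package ships a first-class synthetic cohort generator (`connectogcn.synth`)
that reproduces the statistical structure the analysis assumes: a 6-site
case-control layout with one control-only site, block-structured regional
correlations, planted hypoconnectivity among designated signal regions,
per-site additive/multiplicative edge batch effects, and symptom scores
coupled to per-subject effect severity.

## Worked example

```python
import numpy as np
from sklearn.model_selection import train_test_split
from connectogcn import (
    SynthConfig, generate_cohort, inject_site_effects,
    pearson_connectivity, fisher_z, stack_edges,
    CombatHarmonizer, design_from_records, site_effect_scan,
    GCNClassifier, aggregate_saliency, confusion_metrics,
)
from connectogcn.connectome import devectorize_upper

cfg = SynthConfig(n_regions=90, n_sites=3,
                  site_sizes=((0, 60), (60, 30), (60, 30)),
                  effect_size=0.4, symptom_coupling=0.6, seed=1)
records, series = generate_cohort(cfg)
mats = [fisher_z(pearson_connectivity(ts.values, subject_id=ts.subject_id))
        for ts in series]
edges = stack_edges(mats).to_numpy()
sites = np.array([r.site_id for r in records])
y = np.array([r.diagnosis for r in records])

edges, _ = inject_site_effects(edges, list(sites), cfg)
controls = y == "control"
pre = site_effect_scan(edges[controls], sites[controls], q=0.05)
harmonized = CombatHarmonizer().fit_transform(
    edges, sites=sites, covariates=design_from_records(records))
post = site_effect_scan(harmonized[controls], sites[controls], q=0.05)
print(f"site-dependent edges: {pre.percent_significant:.1f}% -> "
      f"{post.percent_significant:.1f}% after ComBat")

Z = np.stack([devectorize_upper(e, 90) for e in harmonized])
tr, te = train_test_split(np.arange(len(y)), test_size=0.25,
                          stratify=y, random_state=0)
clf = GCNClassifier(seed=0).fit(Z[tr], y[tr])
bacc, sens, spec = confusion_metrics(clf.predict(Z[te]), y[te])
print(f"held-out balanced accuracy {bacc:.1f}% "
      f"(sensitivity {sens:.1f}%, specificity {spec:.1f}%)")

sal = aggregate_saliency(clf.cam_scores(Z[te], target_class="patient"),
                         top_k=10, region_labels=cfg.region_labels)
print("top-10 region indices:", sorted(sal.top_regions.tolist()))
print("planted signal nodes:", sorted(cfg.signal_nodes))
```

Output:

```
site-dependent edges: 99.5% -> 0.3% after ComBat
held-out balanced accuracy 98.3% (sensitivity 96.7%, specificity 100.0%)
top-10 region indices: [40, 41, 70, 71, 72, 73, 74, 75, 76, 77]
planted signal nodes: [40, 41, 70, 71, 72, 73, 74, 75, 76, 77]
```

Reading the numbers: before harmonization virtually every edge differs
significantly across the three synthetic sites (the injected batch
effects); after ComBat essentially none do, while the diagnostic signal is
preserved — the GCN separates patients from controls on held-out subjects
and its CAM saliency map recovers exactly the ten regions in which
hypoconnectivity was planted.

The same pipeline is available from the shell:

```bash
connectogcn run --config config.yaml --seed 1 --out runs/demo
connectogcn run --config config.yaml --seed 1 --no-harmonize --out runs/raw
connectogcn simulate --seed 1 --out cohort/
```

Each run directory contains the subject table, edge tables, the site-effect
audit, the CV report (CSV + JSON with CIs), the saliency table, nodal-
topology test results, symptom correlations, and a manifest with the config
hash — rerunning with the same config and seed reproduces every report file
byte for byte.

A caveat worth knowing: like the study design it follows, the default
pipeline fits ComBat on the pooled data *before* cross-validation splitting,
which leaks distributional information between folds. A methodologically
strict mode that fits ComBat on each training fold and applies it to the
test fold is available (`--harmonize-within-folds` /
`harmonize: {within_folds: true}`).

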