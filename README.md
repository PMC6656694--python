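# cytomon

Standardized mass-cytometry (CyTOF) immune monitoring as a tested, scriptable
pipeline: from raw per-event dual counts through bead normalization,
debarcoding, pre-gating, hierarchical gating, self-organizing-map clustering
with automatic lineage annotation, panel-coverage QC, cross-run
reproducibility metrics, and differential-abundance discovery of
disease-associated immune signatures.

It is aimed at immunologists and computational biologists running
immune-monitoring studies (e.g. immunotherapy or transplantation cohorts) who
want a single, reproducible path from FCS files to per-population frequency
tables and group comparisons — and at method developers, who get a bundled
synthetic-data generator with per-event ground truth so every stage is
testable without instrument data.

## What it computes

* **Reference panel.** A packaged 33-antibody panel covering all major
  peripheral immune lineages plus activation and checkpoint targets,
  together with auxiliary channels (Ir-DNA ×2, cisplatin viability, event
  length, Ce140 beads, Pd barcodes). Populations are defined as marker-sign
  profiles in a tree rooted at CD45⁺ leukocytes; `high`/`low` levels are
  judged against a secondary cutoff (e.g. Treg = CD25^high CD127^low
  FoxP3⁺).
* **Transforms.** x → asinh(x/5) and per-channel normalization to the 99.5th
  percentile.
* **Gating.** Sequential pre-gating (non-beads, DNA⁺, singlets, live, CD45⁺,
  CD235ab/CD61⁻, optional non-neutrophil rule), then conjunctive
  marker-threshold gates down the population tree; an event descends only
  while exactly one sibling predicate holds.
* **Clustering + annotation.** Batch SOM (Euclidean, D²-seeded codebook),
  average-linkage metaclustering of the codebook, and labeling of each
  metacluster with the deepest population definition whose clause-match
  score ≥ 0.9 along its whole ancestor chain; lineages are recursively
  subclustered against their child definitions.
* **Statistics.** Per-cell positive-antigen coverage; OLS/Pearson agreement
  of replicate frequencies; hclust-style sample dendrograms; bootstrap SEM
  of the median (1000 resamples); per-population precision/recall/F1 and
  MCC = (TP·TN − FP·FN)/√((TP+FP)(TP+FN)(TN+FP)(TN+FN)); and differential
  abundance via a negative-binomial GLM of counts with log-total offset,
  shrunk method-of-moments dispersion, Wald t test and Benjamini–Hochberg
  FDR.
* **Simulation.** Truncated-Gaussian marker intensities on the arcsinh scale
  placed per population from its sign profile, inverse-transformed to dual
  counts; EQ-bead events, cisplatin-high dead cells, DNA/event-length
  doublets, palladium barcode pools, acquisition drift, and logit-normal
  per-sample frequency dispersion. Bundled profiles: a healthy-PBMC sample
  and a 28-sample bone-marrow-transplant cohort (15 donors, 3 with GvHD)
  with group-specific effects on CD27⁻ B cells and naive CD4 T cells.

## Worked example

```python
import cytomon as cm
from cytomon import simulate as sim, gate, stats

cfg = sim.profile_config("pbmc_default", 20000, seed=7)
events, truth = sim.simulate_sample(cfg)

panel = cm.load_reference_panel()
cutoffs = gate.default_cutoffs(panel)
t = gate.arcsinh_transform(events, cofactor=5)
keep, attrition = gate.pregate(t, cutoffs)

tree = gate.build_gating_tree(cm.load_lineage_table("pbmc_core"))
res = gate.apply_gating(t, tree, cutoffs, mask=keep)
cov = stats.antigen_coverage(t.subset(keep), cutoffs, k=4)

print(f"pre-gated: {keep.sum()} / {events.n_events} events")
print(f"assigned to a lineage leaf: {100*res.assigned_to_leaf_fraction:.2f}%")
print(f"cells with >=4 positive antigens: {100*cov.fraction_ge_k:.2f}%")
for pop in ("T cells", "Monocytes", "CD56low CD16+ NK cells", "Treg"):
    print(f"{pop}: {100*res.frequency(pop):.2f}%")
```

prints

```
pre-gated: 18088 / 20000 events
assigned to a lineage leaf: 99.86%
cells with >=4 positive antigens: 99.95%
T cells: 50.81%
Monocytes: 22.39%
CD56low CD16+ NK cells: 10.12%
Treg: 3.25%
```

The pre-gating removed the simulated beads, doublets and dead cells
(attrition is itemized per stage in `attrition`); virtually every remaining
cell is identified by at least four positive antigens and lands in exactly
one leaf population, at frequencies matching the generator's ground truth
(T cells were simulated at 51%, monocytes at 22%, CD56^low NK at 10%,
Tregs at 3%).

The same workflow is available from the shell:

```bash
cyto sim sample --n-events 20000 --seed 7 --out run/
cyto gate run run/S1.fcs --lineages pbmc_core --out run/gated
cyto qc coverage run/S1.fcs
cyto run --config run.yaml        # full simulate→gate→cluster→stats pipeline
```

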