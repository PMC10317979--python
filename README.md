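# protatlas

Analysis pipeline for **spatiotemporal label-free quantification (LFQ)
proteomic atlases** of the developing brain: protein × sample intensity
matrices collected over developmental stages (F50, F90, F120 days
post-fertilization and postnatal day 3) and anatomical brain regions grouped
into cortex (CTX), subcortical tissue (sCTX) and cerebellum (CB).

It is written for proteomics and developmental-neuroscience analysts who
have an LFQ intensity table (e.g. MaxLFQ output) plus sample metadata and
want the full downstream statistical workflow as tested, scriptable code
rather than a pile of one-off notebook cells.

## What it computes

| Stage | Method |
|---|---|
| Differential abundance | two-sided pooled-variance Student's *t* on log2 LFQ, one group vs rest, Bonferroni per contrast; DEP ⇔ adjusted *p* < 0.05 |
| Marker proteins | one-vs-rest ROC AUC via the Mann–Whitney construction, AUC = (#{a>b} + ½#{a=b})/(n_in·n_out); marker ⇔ AUC > 0.7 and fold change > 1 |
| Composition trends | per-sample share of a subcellular localization / protein family: Σ LFQ(category) / Σ LFQ(all) × 100, with adjacent-stage *t*-tests |
| Regional dynamics | inter-regional difference (mean \|Δlog2\| over cross-region sample pairs), CB Euclidean distances, stage Pearson correlations, centered PCA |
| Temporal events | "new" proteins (0 at earlier stage, detected later, *p* < 0.05 & FC > 1), per-day log2 rates, gene-set trajectories |
| Trend clustering | fuzzy c-means (c = 4, m = 2) on z-scored stage-mean trajectories |
| Enrichment dynamics | exact hypergeometric ORA with BH correction; adjacent-stage overlap rate and newly enriched processes |
| Cross-species | pairwise Pearson correlations of 1:1-ortholog regional profiles across human/monkey/mouse; human-specific / primate-specific / conserved classes; KS comparison of correlation distributions |
| RNA/protein concordance | six-type partition of prenatal→postnatal fold-change pairs by twofold magnitude and direction agreement |

Zero LFQ intensity always means *not detected*; undetected entries are
excluded from every mean, test and AUC — never entered as measured zeros.

A first-class synthetic-data module generates atlases with the full
5/11/18/18-region sampling design, log-normal intensities, zero-inflated
detection, and planted markers, emergent proteins, conservation classes and
concordance types — with a truth ledger, so every analysis is validated by
recovery of known structure.  See `docs/methods.md` for models, parameters
and limitations.

## Worked example

```python
import protatlas as pa
from protatlas.simulate import SimConfig, simulate_atlas

sim = simulate_atlas(SimConfig(n_proteins=500, seed=11))
m = sim.matrix                          # 500 proteins x 156 samples

deps = pa.dep_region_vs_rest(m, "F120")
print("DEPs at F120 (region vs rest):", int(deps["dep"].sum()))

markers = pa.find_markers(m.subset(m.samples(exclude_region="CB")), "stage")
calls = pa.call_new_proteins(m, ("F90", "F120"), macro_region="CTX")
print("new proteins F90->F120 (cortex):", (calls.status == "new").sum())
```

prints

```
DEPs at F120 (region vs rest): 28
new proteins F90->F120 (cortex): 15
```

28 proteins differ between some region and the rest of the F120 brain after
Bonferroni correction (the planted region structure plus strong macro-region
markers), and the 15 cortical proteins appearing between F90 and F120 are
exactly the emergent proteins the generator planted for that transition.
The marker table recovers 79 of the 80 planted stage markers at
AUC > 0.7 & FC > 1.

The same workflow is available from a shell:

```bash
protatlas simulate --seed 1 --n-proteins 1000 --outdir atlas/
protatlas dep --matrix atlas/lfq_matrix.tsv --meta atlas/sample_meta.tsv --outdir dep/
protatlas full-run --seed 1 --outdir run/       # all stages + manifest.json
```

All inputs and outputs are plain TSV/GMT; a YAML config (`--config`) carries
thresholds, stage→day table and generator settings, and one root seed makes
a `full-run` byte-reproducible.

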