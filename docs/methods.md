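# Methods

This note documents the statistical models behind `protatlas`, the design
choices taken where conventions genuinely diverge, what the synthetic-data
generator does and does not emulate, and known limitations.

## Data model

An atlas is a protein × sample matrix of LFQ intensities with per-sample
metadata: developmental stage (F50, F90, F120 days post-fertilization; P3 =
postnatal day 3, i.e. day 153 on a ~150-day gestation clock), brain region,
macro-region (CTX / sCTX / CB), animal, and replicate kind (biological or
technical).  The stage→day table is configurable; defaults are 50/90/120/153.

**Detection.** LFQ intensity 0 encodes *not detected*.  Throughout the
package an undetected entry is missing for averaged or tested statistics and
absent for presence/emergence logic.  No pseudocount or imputation is
applied anywhere: imputing zeros on the log2 scale would fabricate enormous
negative abundances and manufacture differential signal.  The one deliberate
exception is the emergence test (below).

**Fold change** is a linear-scale ratio of group means over detected
entries.  Where a twofold criterion appears ("|FC| > 2"), |FC| means
max(ratio, 1/ratio), equivalently |log2 FC| ≥ 1.  The marker criterion
"fold change > 1" is read as linear ratio > 1 (up in the class); a config
switch (`log2_fc`) reinterprets the threshold in log2 units for users who
prefer the stricter reading.

## Differential abundance

Two-sided pooled-variance Student's *t* on log2 intensities, one group
versus the rest (region vs rest within a stage; stage vs rest over a pool
that excludes the cerebellum by default, since its divergence would swamp
the stage axis).  Welch's correction is available as an option but is not
the default, because the classical test is the field's convention for this
workflow.  A protein enters a contrast only when each side retains at least
2 detected values; untested proteins are reported with a flag rather than
dropped silently.  Bonferroni families are *per contrast* — the number of
proteins actually tested in that comparison — not pooled across contrasts;
DEP ⇔ adjusted *p* < 0.05.  Degenerate rows (zero pooled variance) resolve
deterministically: equal means → t = 0, p = 1; unequal → p = 0.

## Marker detection

One-vs-rest AUC by the Mann–Whitney construction, computed from average
ranks; ties receive half credit (the behavior of the pair-count definition,
which the test suite enforces exhaustively up to 8×8 groups).  Undetected
values are excluded rather than imputed, and a candidate must be detected
in ≥ 2 class samples.  Markers require AUC > 0.7 and fold change > 1;
ranking is AUC descending, ties broken by fold change, then protein id for
determinism.  With 3 replicates per class the null probability of
AUC > 0.7 is far from negligible — chance calibration by Monte-Carlo
simulation accompanies any marker-count claim in the validation suite.

## Composition profiles

Per sample, a category's share is the summed LFQ intensity of member
proteins over the sample total, × 100.  Multi-label proteins count fully
toward each label (membership, not apportionment), so profile sums can
exceed 100%; unannotated proteins remain in the denominator; categories
with no member in the matrix report exactly 0%.  Adjacent-stage trend tests
are raw per-segment two-sided *t*-tests (the solid/dashed convention of
trend figures); an optional Bonferroni over a category's segments is
available but off by default, mirroring figure-level practice.

## Regional dynamics

The *inter-regional difference* of a macro-region group at one stage is the
mean |Δlog2| over proteins detected in both members of a sample pair,
averaged over pairs.  Pairs are restricted to *different* regions — the
statistic is inter-regional; replicate pairs of the same region measure
noise, not regional divergence.  When a group holds a single region (the
cerebellum), the statistic falls back to all pairs with a warning, which is
then a replicate-variability value and is labeled as such in logs.
An `include_same_region` flag restores the all-pairs reading.

Cerebellum divergence: Euclidean distance between mean log2 profiles over
proteins detected in both profiles.  Stage correlations: replicates are
averaged into stage-mean profiles first, then Pearson r on pairwise-complete
proteins with the correlation-test p-value.  PCA: centered (not scaled)
SVD on complete-case proteins only — imputation would distort the geometry,
and the complete-case restriction matches the cited default behavior of
standard PCA implementations.

## Temporal events

A protein is *new* over an adjacent-stage transition within a region class
when every earlier-stage intensity is exactly 0, it is detected later, and
the later-vs-earlier comparison passes p < 0.05 and FC > 1.  A p-value for
an all-zero group is undefined without a convention: the earlier group is
placed at the dataset's *detection floor* (the smallest positive LFQ
intensity observed), a conservative stand-in for the instrument's detection
limit.  The floor used is recorded in every output row.

Rates of change are (Δ mean log2)/(Δ days) per protein over a transition —
with the default day table the gaps are 40, 30 and 33 days — and telescope
exactly across consecutive transitions.  Gene-set trajectories sum member
abundances per sample (gene symbols mapped through the annotation), average
per stage, and test adjacent segments as above.

**Fuzzy c-means.** Trend clustering standardizes each protein's stage-mean
log2 trajectory to zero mean and unit variance, then runs classical fuzzy
c-means: memberships u_ik ∝ d_ik^(−2/(m−1)) normalized per protein,
centroids as u^m-weighted means, objective J = Σ u^m d².  Defaults: c = 4
clusters, fuzzifier m = 2.0, tolerance 1e-6, ≤ 500 iterations, seeded
initialization from distinct data rows.  Membership updates are normalized
by the row-minimum distance so small fuzzifiers cannot overflow, and in the
m → 1 limit the assignment hardens to k-means (verified against scikit-learn
from a shared initialization).

## Enrichment dynamics

ORA uses the exact hypergeometric upper tail P(X ≥ k) with
Benjamini–Hochberg across the sets of one query; enriched ⇔ q < 0.05
(configurable — the raw-p variant some tools report is a threshold switch).
The universe is all detected, annotated proteins, the standard ORA
background.  The adjacent-stage *overlap rate* has no single established
denominator, so both are computed and reported: 100·|A∩B|/|A∪B| (symmetric,
default) and 100·|A∩B|/|B| (the share of the later stage's processes
already present).  Newly enriched processes are the set difference B \ A.

## Cross-species conservation

Each 1:1 ortholog carries a 5-region mean-abundance vector per species;
the three pairwise Pearson correlations (monkey–human, mouse–human,
monkey–mouse) feed interval rules: human-specific ⇔ both human comparisons
in [−1, −0.5]; conserved ⇔ monkey–human and monkey–mouse in [0.75, 1];
primate-specific ⇔ monkey–human in [0.75, 1] with neither other comparison
there.  Interval endpoints are closed; human-specific is evaluated first,
then conserved, then primate-specific (its own subtraction clause makes it
residual), and anything matching no rule — the majority, with only five
regions per vector — is *unclassified*.  Five-point correlations are
intrinsically high-variance; this is a property of the design being
emulated, not something the implementation smooths over.  Distributions are
summarized in eight 0.25-wide bins over [−1, 1] with cumulative curves,
medians, and two-sample Kolmogorov–Smirnov comparisons.

## RNA/protein concordance

Genes are placed in six types by the prenatal→postnatal fold changes of
RNA and protein (defaults: F120 vs P3 on the protein side).  The six
printed definitions in circulation overlap when read literally (a pair with
a small RNA change and a large same-direction protein change satisfies both
the "higher change at protein level" wording and the "consistent direction,
>2 at one level" wording).  `protatlas` uses the unique disambiguation that
tiles fold-change space, keeps the magnitude-discrepancy cells (Types 2/3)
dominant as observed empirically, and assigns every unambiguous case to its
stated type.  With a = log2 FC_RNA, b = log2 FC_protein, "large" ⇔ |·| ≥ 1:

- Type1: neither large;
- Type2: protein large, RNA small;
- Type3: RNA large, protein small, direction not consistently nonzero;
- Type4: RNA large, protein small, consistent nonzero direction;
- Type5: both large, opposite direction;
- Type6: both large, same direction.

Direction uses sign(log2 FC); a gene with either FC exactly 1 has no
direction and can never be Type5.  A rule-order-free oracle in the test
suite verifies on a 10⁴-point grid that exactly one predicate fires per
point.  Type5 requires *both* changes to be large: under measurement noise
half of all no-change genes would otherwise flip sign and land in
"opposite direction", which would make Type5 the largest class instead of
a small one.

## Synthetic data: what it emulates, what it does not

`simulate_atlas` draws log2 intensity = baseline + stage effect + region
effect × stage-specific scale + noise, all Gaussian (LFQ intensities are
approximately log-normal, and all downstream analysis is on log2).
Defaults mirror the emulated sampling design: 5 regions at F50, 11 at F90,
18 at F120 and P3, three biological replicates each (156 samples); baseline
N(25, 2²) log2 units; stage effects N(0, 0.6²); region effects N(0, 0.3²)
— stage variability exceeding regional variability, as observed in fetal
brain proteomes; measurement noise N(0, 0.5²), a typical LFQ replicate CV.
Planted structure (all recorded in a truth ledger, roles disjoint):
20 markers per stage and 10 per macro-region at +2 log2 in their class;
15 emergent proteins per adjacent transition forced to 0 before onset.

Missingness defaults to an intensity-dependent logistic mechanism: entry
dropout probability 2·r/(1 + exp((baseline − μ)/0.5)) with overall rate
r = 0.10, so low-abundance proteins drop out preferentially — the dominant
missingness mode of real LFQ data — and a realistic minority of
high-abundance proteins is observed in every sample (without which
complete-case analyses such as PCA would have an empty support).  An
intensity-independent mode (`dropout_logistic_scale=None`) is available.

`simulate_ortholog_panel` constructs species vectors as r·e₁ + √(1−r²)·e⊥
over an orthonormal centered basis, so pairwise correlations hit their
class-defining intervals exactly (noiseless mode) or approximately under
an optional perturbation.  `simulate_rna_protein_pairs` draws log2
fold-change pairs uniformly from each type's region of FC-space with a
0.05-log2 margin from the twofold boundary, so typing is exact.

What the generator does **not** emulate: peptide-level quantification and
razor-peptide assignment, batch and instrument drift, correlated
protein–protein covariance (co-regulation), annotation errors, and ortholog
mapping mistakes.  Passing recovery tests therefore demonstrates
correctness of the statistical machinery under the stated generative model,
not robustness to every artifact of real acquisitions.

## Validation problem sizes

The validation suite and `scripts/acceptance.py` use: exhaustive AUC oracle
checks to 8×8 groups; hypergeometric enumeration to N = 12; 200 null
datasets of 1000 proteins for familywise-error calibration; 1000-protein
atlases for marker power and false-rate calibration; 400–500-protein
atlases for emergence and recovery checks; 500-ortholog panels; 10⁴-point
grids for the classification partitions; and a 250-protein full pipeline
executed twice for byte-level determinism.

## Known limitations

- Technical replicates are kept as samples tagged `technical`; no
  mixed-model collapsing is attempted (out of scope by design).
- No moderated-variance (limma-style) testing; with n = 3 the classical
  *t*-test is noisy, faithfully so.
- The cerebellum inter-regional value is replicate-based by necessity
  (single region in its group) and not directly comparable to CTX/sCTX
  values; outputs carry a warning.
- ORA ignores gene-set topology (no parent–child correction) and GSEA-style
  rank statistics are out of scope.
- UMAP embeddings and publication graphics are out of scope; outputs are
  TSV tables intended for any plotting layer.
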