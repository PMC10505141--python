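# Methods

This note documents the models, procedures and numerical choices behind
`pseudomix`, in the order the pipeline runs them.

## The synthetic corpus model

The generator produces an annotated scRNA-seq corpus with the structural
features that matter to mixture benchmarking: multiple patients across
three breast-cancer molecular subtypes, a three-level cell-type hierarchy
(major > minor > subset), per-patient abundances spanning absent (0 cells),
rare (<10 cells) and dominant (up to 1500 cells) types, and disjoint marker
genes that make types separable.

Counts for cell *c* of type *t* in patient *p* are negative binomial with
mean `μ_g = baseline_mean · m_g(t) · e_g(p)` and size (dispersion) `θ`,
where `m_g(t) = marker_fold` on type *t*'s marker genes and 1 elsewhere,
and `e_g(p)` is a per-patient, per-gene log-normal factor with log-sd
`patient_effect_sd`. Parameters and defaults:

| parameter | default | meaning |
|---|---|---|
| `n_genes` | 2000 | gene-space size |
| `markers_per_type` | 20 | disjoint markers per leaf type |
| `baseline_mean` | 0.5 | NB mean off-marker (counts/cell/gene) |
| `marker_fold` | 8 | multiplicative marker up-weighting |
| `dispersion` | 2 | NB size; smaller = more overdispersed |
| `patient_effect_sd` | 0.15 | log-sd of donor effect |

The demo configuration (`demo_config`) fixes 6 patients (2 per subtype),
9 major types with 2–3 minor children each, 24 leaf types, and abundance
draws that include one 1500-cell extreme, rare types that exercise the
<10-cell filter, and ~12% absent (patient, type) pairs.

What the generator does **not** emulate: batch/trajectory structure,
doublets, ambient RNA, gene–gene correlation beyond type means, and
realistic dropout patterns. Tests passing on this corpus therefore
establish the bookkeeping, the simulation arithmetic and the recovery
behaviour of the baseline under controlled signal/noise — not performance
on real tissue.

## Preprocessing order

Counts-per-10,000 normalization (no log transform) runs first; SMOTE and
mixture simulation operate on the normalized values. Rare-type filtering
(`< 10` cells, strict) is applied per patient at the lineage level of the
current experiment, before SMOTE. Gene order is canonicalized
lexicographically after cross-corpus intersection so outputs are bit-stable.
Train/test splits are patient-level and validated so that every major cell
type and molecular subtype occurs on both sides; the check can be
overridden explicitly but never silently.

## SMOTE balancing

Within each patient, each retained type is brought to the patient's maximum
type count by synthesizing `x_new = x_i + λ(x_j − x_i)` with `λ ~ U[0,1]`
and `x_i, x_j` distinct original cells of the same patient and type. The
partner `x_j` is uniform over the other same-group cells; a
k-nearest-neighbour restriction (as in some SMOTE variants) is deliberately
not used — with CP10K-scale expression and modest group sizes the uniform
rule is the simplest well-defined choice. Synthesized values stay real
(no re-integerization). Per-patient sub-seeds derive from the cohort seed
and the patient id, so cohort results are order-independent; every
synthesized cell stores `(parent_a, parent_b, λ)` and can be reconstructed
exactly (`replay_synthesized`).

The balancing level is a parameter (default `major`). Synthesized cells
inherit labels finer than the balancing level from their first parent;
experiments at a given granularity should balance at that granularity
(mixed per-major level configs are supported everywhere).

## Mixture simulation

Every mixture has exactly 500 cells from a single donor, sampled uniformly
without replacement within the mixture from the donor's (augmented) pool
per type. Expression is the plain sum of the selected cells' CP10K vectors,
so each mixture totals 5,000,000 within float error.

Fraction drawing (sparse design): the number of included types `k` is a
uniform integer on `[min(5, n_available), n_available]` (donors with fewer
than 5 available types degrade to using all, logged); one included
non-fixed type is the *free-range* type with `f_c = u · B`, `u ~ U(0,1)`,
where `B` is the free budget (1, or `1 − purity` when the cancer fraction
is pinned); the remaining included types split `B − f_c` proportionally to
i.i.d. `U(0,1)` draws. This gives per-type marginals spanning nearly (0, 1)
rather than clustering near `1/k`.

Counts: largest-remainder rounding of `f · 500`, ties broken by earliest
position — deterministic and sum-exact. Ground truth is defined from the
realized integer counts (`counts/500`, percent scale), not the continuous
fractions, because the 500 sampled cells are the physical content of the
pseudobulk; both are recorded on the spec. On the default purity grid
(5%–95% in 5% steps) `purity × 500` is integral, so recorded cancer truth
equals the nominal purity exactly.

Reproducibility: each mixture's seed derives from `(cohort seed, mixture
index)`; planning (fractions, counts, truth) is separable from assembly
(cell selection, expression), which makes full-scale design arithmetic
cheap and corpus-independent.

## Reference and baseline

The deconvolution reference keeps original cells only (synthesized cells
are simulation substrate, not biology) from training patients, projected to
the experiment's label level. The signature matrix is the per-type mean
CP10K profile; an optional `top_markers` restriction keeps the union of
each type's highest fold-change genes. The in-repo baseline solves
per-mixture NNLS on the shared gene space and renormalizes the weights to
percentages; it is deterministic, gene-order invariant, and exact on
noiseless mixtures whose cells sit at their type means. It is a floor, not
a competitor: external methods attach through the adapter contract
(declared executable, input dialect `linear` or `log2(x+1)`, TSV output
parsing, negative/NaN clipping with logging, row renormalization to 100).

## Evaluation conventions

All metrics use the percent scale; with the fixed 500-cell total,
count-based and percent-based Bray-Curtis coincide. Numerical choices:

* **CLR zeros**: additive pseudocount `δ = 1e-6` on the closed simplex,
  followed by re-closure (configurable). Zeros are legitimate in both
  predictions and truths, and the Aitchison geometry needs positivity.
* **Severity bins** are lower-inclusive: `[0.1, 1)`, `[1, 10)`, `[10, ∞)`
  percent; the presence threshold comparison is strict `< 0.1%` for
  negatives. This makes boundary behaviour deterministic.
* **Median RMSE / Pearson**: RMSE and r are computed within each
  (type, group) — group defaulting to the evaluation's grouping keys, e.g.
  purity level — and the median is taken across groups. Zero-variance
  groups have undefined r and are excluded from medians with a count
  reported. A single-RMSE-across-all-mixtures alternative is available by
  passing no grouping keys.
* **Raw errors** are only ever reported as distributions, never summed or
  averaged (signs cancel).
* **Confusion analysis** excludes design-fixed types (the cancer label in
  fixed-purity experiments) when asked, since their presence carries no
  information about the method.
* The immune-only Aitchison variant re-closes the immune sub-composition
  and excludes mixtures with zero immune truth mass (logged).

## Problem sizes

Full-scale *planning* (90,000 training mixtures, 38,000 purity mixtures,
2,000 lineage mixtures, 18,000 confusion components) runs in seconds and is
exercised at full scale. *Assembled* expression runs in tests and in the
acceptance script use the demo corpus with 2 simulation donors and 10–25
mixtures per condition — enough for stable medians from 150–380 mixtures
while keeping a complete run under a minute. The marker-strength recovery
check uses the default demo configuration at `marker_fold ∈ {2, 4, 8}`
with 30 mixtures per fold.

## Known limitations

* The SMOTE partner rule is uniform rather than distance-weighted; variants
  that restrict partners to nearest neighbours would concentrate synthesis
  in dense regions.
* Summed CP10K pseudobulk has an effective library of ~5M "counts", below
  typical bulk depth; lowly expressed genes are under-represented relative
  to real bulk data.
* The NNLS baseline shares the signature's linear-mixing assumptions with
  the simulation, so its absolute performance on this corpus is optimistic;
  it is intended as an end-to-end exerciser and floor.
* No statistical testing between methods is provided; rankings are by
  median Bray-Curtis only.
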