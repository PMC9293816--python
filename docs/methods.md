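# Methods

## Setting and model

The pipeline targets digital-counting expression panels (nCounter CodeSets)
measured on blood samples of hairy cell leukemia (HCL) patients and two
reference groups: normal peripheral-blood mononuclear cells (nMNC — a
mixture of T cells, monocytes and 12–30% B cells) and CD19-selected normal
B lymphocytes (nB, ≥ 95% pure). Patient lanes are unsorted: a malignant-B
fraction between 0.3 and 0.9 mixed with contaminating T cells and
monocytes. Every design choice below follows from this mixture structure.

## Normalization chain

Order is fixed: positive-control scaling → background correction →
housekeeping normalization. Each stage writes its per-lane factor into a
`LaneFactors` table and appends to the count matrix's audit log.

* **Positive-control scaling.** `g_i` = geometric mean of the positive
  spike-in probes of lane *i*; every non-positive probe is multiplied by
  `F_i = mean_j(g_j) / g_i`. The reference is the arithmetic mean over
  lanes of per-lane geometric means — the common nCounter convention. A
  consequence worth knowing: rescaling one whole lane by *c* moves the
  global reference by `(c−1)·g_i/(n·mean g)`, so single-lane invariance is
  exact for cross-lane ratios (the quantity every downstream contrast uses)
  but the absolute level shifts by that one common factor. Tests assert the
  exact ratio form.
* **Background correction.** `b_i = mean(neg_i) + k·SD(neg_i)` with k = 2
  and the sample SD (n−1 denominator, hence ≥ 2 negative probes required).
  Subtracted from endogenous *and* housekeeping probes — background is
  additive on all hybridizations — and floored at zero. Downstream log
  transforms use log2(x+1), so floored zeros stay finite.
* **Housekeeping normalization.** `h_i` = geometric mean of the nine
  designated housekeeping genes after background correction;
  endogenous counts are multiplied by `K_i = mean_j(h_j)/h_i`. Zeros inside
  a geometric mean are substituted by 1 by default (`substitute_one`);
  `exclude_zeros` is available and errors on an all-zero lane.

Counts move raw → positive_scaled → background_corrected → normalized; raw
state enforces integers, later states hold reals.

## Group contrasts and filters

Each contrast compares arithmetic means of normalized counts between two
lane groups over the endogenous genes. Selection requires all three of:

* expression: mean ≥ 20 counts in the claimed-expressing group
  (`higher_group`; `either_group`/`both_groups` switchable);
* effect: fold change ≥ 2 (up) or ≤ ½ (down), computed on the group means
  with zero means floored at 0.5 counts so reciprocal contrasts stay
  exactly consistent;
* significance: Benjamini–Hochberg adjusted p ≤ 0.05, adjusted across the
  290 endogenous genes within the contrast.

Thresholds are inclusive by default (a gene exactly at 2-fold and p = 0.05
counts), switchable to strict. The default test is the **pooled-variance
two-sided t-test on log2(x+1) counts**. This is a deliberate choice for the
tiny reference groups this design carries: with a 3-lane reference a
per-gene Welch test has ≈ 2 degrees of freedom and essentially no power at
any effect size, whereas pooling borrows the larger group's replication
(df = n_a + n_b − 2). Welch and Mann–Whitney remain selectable in
`FilterCriteria`. Genes with zero variance in both groups get p = 1 when
the means agree and p = 0 otherwise. Two-lane groups are allowed with a
logged low-power warning — the variant-HCL group itself has n = 2.

## Signature set logic

"Deconvolution" here is reference-group set algebra, not proportion
estimation:

* B-cell-specific = up in nB vs nMNC;
* leukemia over-expression = (up in pooled HCL vs nMNC) ∩ (up in HCL vs
  nB). A contaminant-driven gene (T/monocyte) rises only against nB; a
  pan-B-cell gene rises only against nMNC; the intersection isolates
  malignant-B biology;
* leukemia under-expression = down in HCL vs a configurable reference
  (default nB; nMNC and the intersection of both are exposed because the
  three are equally defensible readings of the published workflow);
* classical vs variant = cHCL vs vHCL under the same criteria.

`signature_decision_grid` enumerates the twelve combinations of
{pooled, Welch} × {inclusive, strict} × {nB, nMNC, both} for reproduction
studies where the original configuration is not recorded.

## Clustering

Lanes and genes are clustered agglomeratively on z-scored log2(x+1) rows;
default distance 1 − Pearson correlation, average linkage (both
configurable: euclidean, complete, Ward). Zero-variance genes are dropped
with a warning. scipy's deterministic merge rules provide reproducible
trees and leaf orders; real-valued expression data makes distance ties a
measure-zero event, so no extra tie-break layer is added. Group purity is
the fraction of lanes whose nearest lane in cophenetic distance shares
their group label. On simulated data the malignant clade is clean when
clustering the informative genes (union of the derived differential sets);
on all 290 genes the tumor-fraction mixture axis dominates the correlation
structure and low-burden leukemia lanes drift toward the mixed-cell
reference — a real property of mixture data worth remembering when reading
all-gene heatmaps.

## Enrichment

* Over-representation: upper-tail hypergeometric p for the overlap of a
  query set with each term of a GMT collection, inside a finite universe
  (default: the endogenous panel), BH-adjusted across terms, with a
  Haldane-corrected odds ratio as effect size.
* Preranked GSEA: weighted Kolmogorov–Smirnov running sum; hits step by
  `|score|^w / Σ_hits |score|^w` (w = 1 default), misses by `−1/(N−N_hits)`;
  ES = signed maximum deviation. The permutation null draws random
  same-size gene sets from the ranked list ("gene-label" permutation) — the
  appropriate null when the input is a derived ranking with no sample-level
  phenotypes to permute (a documented divergence from phenotype-permuting
  implementations). p uses the add-one convention over same-sign
  permutation scores; NES = ES / mean(|same-sign permuted ES|).

## Synthetic experiment generator

Per lane *i*: technical factor `L_i ~ LogNormal(0, σ)` (σ = 0.25);
positive probes = `round(L_i × ladder)` with a six-step geometric ladder
spanning 128×; negatives ~ Poisson(λ = 8); endogenous gene *g*:
`count ~ NB(mean = L_i·Σ_c f_{c,i}·μ_{g,c} + λ, var = m + α·m²)` with
dispersion α = 0.05 — technical nCounter replicates are near-Poisson,
biological replicates overdispersed; α → 0 recovers Poisson exactly.
Housekeeping means are cell-type-independent, drawn high (300–2000 counts)
and DE-free by construction so they are usable for normalization.

Cell-type structure: a 100-gene B-lineage block expressed 10× higher in
both B-cell types than in T/monocytes; 17 genes planted 3–9× up in the
malignant profile, chosen outside the B block so the signal must survive
mixture dilution against both references; 17 genes planted 3–9× down,
chosen inside the B block (silencing a gene the contaminants don't express
is undetectable in a mixture — losing a B-program gene is the realistic
analogue); 25 genes split ±√FC between the classical and variant malignant
profiles (FC 4–16, mirroring the size of the published subtype difference
list). Mixing fractions: leukemia lanes draw a tumor fraction from
U(0.3, 0.9) with a small residual normal-B compartment (10% of the
remainder); nMNC lanes draw their B fraction from U(0.12, 0.30); nB lanes
from U(0.95, 1). Baseline expression is log-normal (median 150 counts,
log-SD 1).

Every realized parameter — lane factors, mixing fractions, per-type means,
planted genes and fold changes — is emitted in a `SimulationTruth` ledger
sufficient to recompute each expected count, and
`truth_recovery_report` scores a derived signature against the planted one
(sensitivity, specificity, observed FDR; an empty recovery has FDR 0 by
convention).

What the generator does *not* emulate: the real panel's per-gene expression
values and correlation structure, probe-level sequence effects, lane QC
failures, or batch structure across collection sites. Passing recovery
benchmarks therefore demonstrate that the pipeline's statistics behave
correctly under the study's sampling design, not that the published gene
lists would be re-derived from real measurements.

## Pipeline, configuration, provenance

`run_full_analysis` composes ingest/simulate → normalize → signatures →
classical-vs-variant → fold-change correlation → clustering → optional
enrichment. The YAML config mirrors `PipelineConfig`: exactly one of a
real-input block (`counts_path`, `metadata_path`) or a `simulation` block
(`ExperimentDesign` fields), plus `normalization:`, `criteria:`, clustering
options, `out_dir` and `seed`. One global seed is fanned out by fixed
offsets per stage, so adding a stage never perturbs earlier stages'
randomness. The manifest records version, seed, config hash (output
directory excluded), per-stage counters and timings, and every output file;
with a fixed config and seed all data outputs are byte-identical across
runs (the manifest differs only in wall-clock timings).

## Numerical choices and edge cases

* Fold changes floor zero means at 0.5 counts; reciprocal contrasts
  multiply to 1 within 1e-9.
* BH adjustment delegates to statsmodels' step-up implementation and is
  verified against an independent brute-force oracle to 1e-12.
* Geometric means substitute 1 for zeros by default.
* Volcano tables clip p at the smallest positive float before −log10.
* TSV writers use 17 significant digits so write→read round-trips are
  bit-exact for integers and ≤ 1e-12 relative for reals.

## Benchmark problem sizes

The self-contained acceptance suite uses the study design (24 lanes, 299
probes): 20 seeds for planted-signature recovery (mean sensitivity ≥ 0.85,
mean observed FDR ≤ 0.15; measured ≈ 0.98 / 0.003), 100 seeds for null
calibration with the tumor fraction forced to zero (empty signature in
≥ 95%; measured 100%), 1000 random vectors for the BH oracle, universes
≤ 15 for exact hypergeometric enumeration, and 20 seeds for clustering
separation. These sizes were chosen to make Monte-Carlo noise negligible
relative to the asserted margins.

## Known limitations

* The statistical test operates gene-by-gene with no variance moderation;
  with 2–3 lane groups the pooled test assumes homoscedasticity across
  groups on the log scale.
* Set-logic deconvolution yields membership, not mixture proportions or
  purified expression estimates.
* The under-expression reference ambiguity is exposed, not resolved.
* GSEA significance uses gene-label permutation; its null is narrower than
  phenotype permutation when inter-gene correlation is strong.
* RCC parsing reads only the Code_Summary and lane-ID fields of the
  text dialect; vendor binary formats are out of scope.
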