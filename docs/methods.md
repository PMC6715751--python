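# Methods

This note records the models, defaults and design decisions behind
`sirnascreen`, and what the synthetic benchmark does and does not show about
real screening data.

## Assay model and normalization

The package targets well-based reverse siRNA screens: one gene knocked down
per library well, 384-well plates, each plate carrying its own negative
(siNC, non-targeting) and positive (siPLK1, essential-gene) control wells,
measured in triplicate. Readouts are 2D monolayer cell count (imaged
nuclei), 2D total viability (a metabolic, resazurin-type signal per well),
and 3D sphere count under low-attachment culture.

All analysis is fold-change-centric, so each well is normalized to
`log2fc = log2(raw) − center(log2(raw_siNC))` within its own
(cell line, readout, plate, replicate) group. The center defaults to the
arithmetic mean of the log2 siNC values — the geometric mean on the raw
scale — because it makes the siNC wells average exactly to zero on the scale
the thresholds are applied to; a median option is exposed for robustness
against control outliers. Zero raw values are floored (counts at
pseudo-count 1, continuous readouts at the smallest positive observed value,
both configurable) with a warning. Normalization is invariant to a global
rescaling of a plate's raw values; no positional (edge/row/column) bias
correction and no inter-plate quantile normalization are applied.

QC uses the standard screening-window statistic
`Z′ = 1 − 3(σ₊ + σ₋)/|μ₊ − μ₋|` on log2-scale control values, with sample
(n−1) standard deviations, pooling a plate's replicates. Z′ is undefined
(reported missing) when the control means coincide, and is invariant under
positive affine transformations of the log2 values.

## Hit calling

Per gene and screen, replicate log2fc values are aggregated (mean, sample
s.d.) and tested against the pooled siNC log2fc values of the gene's own
plate — the control pool matches the normalization unit. The test is a
one-sided two-sample Student *t* (pooled variance; Welch optional), lower
tail, because hits are sought in the decrease direction only. Degenerate
zero-variance groups resolve by mean comparison (equal means give p = 0.5),
which makes the zero-noise limit well defined. A gene is a hit when
p < 0.01 **and** its mean log2fc is below the readout's threshold: −1
(2-fold) for cell and sphere counts, −0.6 for total viability (an
all-readouts-at-−1 preset, `HitThresholds.twofold_all()`, is also provided,
since the viability column of a screen summary can be computed under either
convention). No multiple-testing correction is applied by default — the
screening convention is a raw p cutoff — but Benjamini–Hochberg flagging is
available behind a flag.

A calibration caveat: genes on one plate share that plate's control pool,
and the per-replicate centering constrains each replicate's controls to mean
zero, which slightly deflates the control variance estimate. The realized
type-I rate at p < 0.01 in all-neutral simulations is ≈ 0.012 rather than
0.010, and rejection events are weakly positively correlated within a
plate. This is a property of the prescribed plate-local testing scheme, not
of the t machinery (which matches reference implementations exactly on
independent samples).

Percentages (hit rates, discordance fractions) are rounded half-up via
decimal arithmetic — 2 decimals for per-screen rates, 1 or 0 for summary
displays — so printed values are reproducible exactly.

## Cross-screen classification

Two taxonomies, kept as separate operations because they serve different
questions with different cutoffs:

* **2D dichotomy** over the 2D count screens of ≥ 2 cell lines:
  *sample-independent common* when the across-line mean log2fc < −2
  (>4-fold) with across-line s.d. < 1; *sample-selective* when mean < −1
  with s.d. > 1. All inequalities strict; boundary genes are unlabeled.
* **Four groups** from the per-screen hit flags of the 2D count and 3D
  sphere screens: *common_2d_3d* = hit in all 2D and all 3D screens;
  *two_d_only* = hit in all 2D screens and in no 3D screen; *three_d_only*
  = the converse; *selective_2d_3d* = hit in at least one screen but in
  none of the preceding patterns (sample-specific profiles); *none*
  otherwise. The non-none groups partition the set of genes hit anywhere,
  and tightening any threshold can only move genes toward *none*. The "hit
  in all 3D screens" criterion operationalizes sphere inhibition as
  log2fc < −1 with p < 0.01 in each 3D line; expert curation of
  "functionally unrelated" selective hits is deliberately not automated.

## Per-cell viability dissection

Total viability is a per-well aggregate, so a cytotoxic knockdown can lower
it while the *surviving* cells are individually healthier. Viability per
cell is total viability divided by cell count in the same well — on the
log2 scale, `log2fc(viability) − log2fc(count)` — computed per replicate
well and then averaged, so its significance test (same pooled-t machinery,
upper tail) runs on replicate-level values. Labels: *concordant_inhibitor*
(count hit and total-viability hit), *count_only_inhibitor* (count hit
only), *viability_up_resistant* (count hit whose per-cell viability exceeds
+0.5 log2 — ≈1.4-fold, echoing the 2–4-fold single-cell increases such
resistance responses show — with increase-direction p below the hit
threshold), *neutral*, and *other*. The identity
`per_cell + count = total` holds exactly by construction.

## Functional similarity and enrichment

Gene–gene functional similarity is the Tanimoto (Jaccard) score
`|A∩B| / |A∪B|` between annotation term sets, taken from any GMT collection
(GO biological-process slims in practice; a namespace choice is just a
choice of GMT). Unannotated genes score 0 everywhere. The network stage
emits all unordered pairs above a threshold (default 0.2, chosen only for
legible networks) as a TSV edge list for external layout tools; no
graph-structural or information-content semantic similarity is attempted.

Over-representation uses the plain hypergeometric upper tail
P(X ≥ k) with gene ratio k/K; the reported p is two-sided
(`min(1, 2·min(upper, lower))`) by default. An EASE-style mode scoring
P(X ≥ k−1) is available for comparability with DAVID-derived lists.

Rank-based enrichment is the GSEA running-sum statistic on a gene list
ranked by a per-gene score (the per-cell viability measure in the
pipeline): members contribute `|score|^w` (normalized), non-members
−1/(N−K), and ES is the maximum-magnitude deviation. Weight defaults to
w = 1 (w = 0 gives the Kolmogorov–Smirnov-like unweighted form).
Significance uses gene-label permutations — per-gene scores, not sample
phenotypes, are the input — with `p = (1 + #{same-sign |ES*| ≥ |ES|}) /
(1 + #same-sign)` and `NES = ES / mean(|ES*| same sign)`; 1,000
permutations by default, seed required. Under null rankings the permutation
p is uniform to the resolution of the permutation grid. FDR beyond BH on
the permutation p, and leading-edge reporting, are out of scope.

## Synthetic campaign generator

The generator exists so every stage can be validated against known truth;
it emulates the assay design, not any particular dataset. Defaults: 384-well
plates with 16 siNC + 8 siPLK1 wells (control counts per plate are a design
choice of the generator), library genes filling plates sequentially,
triplicate measurement, three 2D lines (two of them also with total
viability) and two 3D lines, baseline 2,000 cells and 50 spheres per well,
siPLK1 planted at −2 log2.

Noise is additive Gaussian on the log2 scale (multiplicative log-normal on
raw), σ = 0.15 for 2D and 0.4 for 3D readouts — the 3D excess encodes that
sphere counts are small and highly variable, and reproduces the qualitative
QC signature of lower 3D Z′. Sphere counts add a Poisson layer on the
log-scale mean (counts are small integers); a continuous log-normal mode
exists as the exact zero-noise limit used by recovery oracles. Effect
classes: neutral (75%), and 5% each of common-essential (count ≤ −2
everywhere, spheres ≤ −1), 2D-only (count ≤ −1, spheres 0), 3D-only
(converse), selective (one strong effect in a single randomly chosen cell
line), and count-down/per-cell-viability-up (count ≤ −1 with per-cell
viability ≥ +0.5). Magnitudes are drawn uniformly from ranges strictly
beyond the hit thresholds so the zero-noise limit is unambiguous. Total
viability is simulated as the realized count times
`2^(per-cell effect + noise)`, which makes the per-cell identity exact. A
synthetic annotation couples gene-set membership to effect class (70% of a
set's members drawn from one class) so enrichment and network stages have
planted signal. All randomness flows from one seed through documented child
streams (`[seed, 0]` truth, `[seed, 1]` readouts, `[seed, 2]` annotation).

What passing on this benchmark does **not** show: real screens have
transfection-efficiency gradients, plate positional effects, batch drift,
off-target siRNA activity and heavy-tailed noise, none of which are
modeled. Recovery rates here are therefore upper bounds on real-data
performance; the benchmark's role is correctness of the computations, not
effect-size realism.

## Problem sizes and numerical choices

Validation workloads are sized to keep the full suite in seconds-to-minutes
on one core: type-I calibration uses four independent all-neutral
5,000-gene campaigns (20,000 tests); sensitivity/FPR uses 1,000 genes with
5% planted at −2.5 log2; QC direction uses 50 plates per condition;
exhaustive-enumeration oracles cap universes at ≤ 26 genes and permutation
nulls at 500 replicates × 200 permutations. Floating-point contracts:
normalization and the per-cell identity hold to 1e-9; TSV round trips use
round-trip float parsing; edge scores print at 4 decimals; strict
inequalities at every classification boundary; Spearman uses average ranks
for ties and is undefined below 3 shared genes.

## Known limitations

Pooled single-record-per-gene analysis only (no redundant-siRNA/RSA
statistics); no SSMD or robust-Z alternatives; no image-derived readouts
(sphere counts enter as numbers); the four-group "selective" rule is a
declared mechanical interpretation of what is partly an expert judgment;
and the plate-local control pooling makes the raw-p hit test mildly
anticonservative, as quantified above.
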