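# Methods

## Stable-isotope-dilution PRM quantification

The assay model: for each target protein one signature tryptic peptide is
monitored in two isotope channels. The heavy channel is a synthetic
stable-isotope-labeled standard spiked at a known amount (`spike_fmol`,
default 50 fmol) into a known mass of digested tissue protein
(`protein_input_ug`, default 100 µg). Each channel is observed as several
fragment-ion transitions with chromatographic peak areas. Assuming equal
ionization and fragmentation efficiency of the light and heavy forms, the
endogenous amount is the area ratio scaled by the spike:

    fmol/µg = (Σ light area / Σ heavy area) · spike_fmol / protein_input_µg

Transition-level QC before the ratio:

1. **Mass accuracy** — light transitions with |mass error| > `ppm_tol`
   (default 5 ppm, boundary inclusive) are discarded.
2. **Co-elution** — a light transition must have a heavy partner of the same
   fragment ion within `rt_coelute_tol` (default 0.2 min). The tolerance is
   a free parameter: co-elution of an analyte with its isotopic standard is
   effectively exact, so the default only needs to be wide enough to absorb
   apex-interpolation jitter.
3. **Top-n summation** — peak areas are summed over the `top_n` (default 3)
   most abundant transitions. Ranking uses the **heavy** channel: the spike
   is constant across samples, so the selected fragment set cannot depend on
   the quantity being measured (ranking by the light channel would couple
   transition selection to the analyte level and bias low-abundance
   samples). Both channels are summed over the same fragment set so the
   ratio is unbiased. Rank ties break lexicographically on fragment id.
4. **Pattern concordance** — when ≥ 3 retained fragments carry both
   channels, the light fragment-area pattern must match the heavy pattern:
   normalized dot product (spectral contrast, the quantity Skyline-style
   workflows call dotp) ≥ `ratio_concordance_min` (default 0.8). The check
   is waived at 2 fragments, where any two positive patterns are weakly
   informative. A rank-correlation form of this check was considered and
   rejected: over 3 fragments Spearman's rho only takes values ±1 and ±0.5,
   so any threshold above 0.5 demands a *perfect* rank order and rejects
   ~a third of clean peptides at 10% area CV whenever two response factors
   are close; the dot product degrades continuously and is insensitive to
   noise-induced rank flips while still collapsing under genuinely
   discordant ratios. An undefined similarity (a zero-intensity pattern) is
   not treated as discordance.

Detection calling: ≥ `min_coeluting_transitions` (default 2) valid light
transitions → **detected**; exactly one → **zero_assigned** (the abundance
is reported as 0, a value, not missing — single-transition signals are too
weak to quantify but indicate near-absence); none → **not_detected**
(missing). For cohort detection tallies both zero_assigned and not_detected
count as "not detected", while zero_assigned contributes a 0 to abundance
tables. Multiple quantifiable peptides per protein are averaged
(arithmetic mean) and the best peptide status wins; in practice the panel
uses one signature peptide per target.

Degenerate inputs: a peptide group with no heavy transitions raises
(`MissingStandardError` — the internal standard is the measurement's
backbone); a zero heavy area sum likewise. Unknown label channels raise.

The noise-free round trip (generator → quantifier) is algebraically exact;
tests assert it at 1e-12 relative tolerance because the sum-ratio arithmetic
rounds at machine epsilon. Zero-assigned values are asserted exactly 0.

## Cohort association statistics

Correlations are squared Pearson coefficients over pairwise-complete cases
with two-sided p-values from the t distribution (n−2 df), computed on the
linear scale by default with a log₁₀ option (log drops non-positive values).
Zeros are values; only missing (not-detected) entries are dropped.
Exceedance, co-expression and dual-high statistics instead treat missing as
0, since those statistics describe the whole cohort including
non-detections. "Above the cohort average" means strictly above the
arithmetic mean computed with absent-as-zero. Raw p-values are the primary
report; Benjamini–Hochberg q-values are available behind a flag but off by
default, matching common practice for small fixed panels.

## Proteotype gene-set enrichment

**Normalization.** Global normalization is per-sample scaling of spectral
counts to the cohort **median** library size (total-count and quantile
variants behind a flag), then log₂(x+1), then per-protein z-scores across
samples (ddof = 1; constant proteins become all-zero rows). A sample with
zero total counts is an error. The pseudocount of 1 keeps zero counts at
zero after the log.

**Ranking.** Each protein's z-score profile is scored by Pearson correlation
with the targeted (fmol/µg) abundance vector of one drug target;
constant profiles score 0; ties break on protein id so rankings are total
orders. A signal-to-noise alternative (mean difference between high/low
target halves over the sum of their SDs, SD floored at 1e-12) is provided
behind a flag for users who prefer the classic two-class statistic.

**Enrichment score.** Weighted Kolmogorov–Smirnov running sum: walking the
ranking, a member ("hit") steps up by |score|^p normalized by the sum over
hits, a non-member steps down by 1/(N − N_hits); ES is the signed maximum
deviation, always in [−1, 1]. `weight_p` defaults to 1; p = 0 is the classic
unweighted KS form. If every hit has score exactly 0 (so the weighted steps
are undefined) the hit steps fall back to uniform. When the positive and
negative extrema tie in magnitude (within 1e-9) the positive deviation is
reported — the tie is real (it occurs whenever the running sum is
symmetric) and an explicit rule keeps the statistic deterministic across
implementations and floating-point accumulation orders. A set with no
member in the ranking is flagged not-evaluable; a set covering every
protein is an error (the statistic is undefined without misses).

**Null model.** Sample-label permutation of the target vector, re-ranking
all proteins per permutation. Phenotype permutation (rather than gene-set
permutation) preserves the inter-protein correlation structure of the
matrix, which is what inflates naive gene-wise nulls. Per set,
NES = ES / mean |same-sign null ES| and
p = (1 + #{same-sign null, |ES_null| ≥ |ES|}) / (n_same_sign + 1), so p is
never 0. FDR is Benjamini–Hochberg over the per-set permutation p-values —
a deliberate simplification versus pooled-NES FDR estimation, chosen
because it is exact to state and easy to test. When fewer distinct
permutations exist than requested (n! ≤ n_perm) the exhaustive set is used
with a warning. `n_perm` must be ≥ 100 (coarser nulls make the add-one
p-value floor dominate).

## Synthetic cohort generator

The generator produces data with the statistical structure the analysis
assumes, with every draw seeded (`numpy.random.default_rng`; identical
config ⇒ bit-identical output):

* **Protein abundance** per target: log-normal (default median 0.2 fmol/µg,
  log-SD 1.0), spanning the order-of-magnitude range typical of checkpoint
  proteins in tumor tissue.
* **mRNA (RPM)**: jointly log-normal with protein; the log-scale squared
  correlation equals `protein_mrna_r2` by construction (shared standard-
  normal component weighted √r²). Defaults follow the observed pattern in
  NSCLC panels: appreciable coupling for PD-1 (0.17), PD-L1 (0.70) and
  IDO1 (0.74), near-none (0.05) for the rest.
* **TPS**: a logistic saturation of log PD-L1 abundance (midpoint
  0.35 fmol/µg, scale 0.5 log-units) mapped to 0–100%, plus additive
  Gaussian noise (SD 25 percentage points), rounded and clipped — wide
  noise reproduces the characteristic TPS scatter (near 0 to near 100%) at
  mid protein abundance.
* **TMB**: log-normal, independent of every target (log-SD 1.2, roughly a
  200-fold cohort range).
* **Transitions**: per-fragment response factors are log-normal and shared
  by both channels; heavy area = rf · spike, light area = rf · (abundance ·
  input µg), each with multiplicative log-normal noise of CV `area_cv`.
  Mass errors are N(0, `ppm_sd`); retention times jitter at a tenth of the
  co-elution tolerance. **Interference** corrupts a light transition with
  probability `interference_rate`, choosing one of two modes with equal
  probability: an off-mass transition (|ppm| drawn in 6–20) or an
  off-elution transition (RT shifted 2–10 tolerances) with a distorted
  (×10^±0.7–1.5) area. Both modes fail QC deterministically, so full
  interference forcibly defeats the two-transition rule; the concordance
  branch of the filter is exercised by hand-built fixtures instead. Below
  `detection_floor_fmol_per_ug` the light channel emits a single transition,
  which the zero-assignment rule maps to 0.
* **Spectral counts**: gamma-Poisson (negative binomial, dispersion 0.3)
  with per-sample library sizes uniform in 40–80k and log-normal protein
  base rates; the members of one designated set are mean-shifted on the log
  scale by `gene_set_effect` × the standardized log abundance of the chosen
  target; remaining sets are disjoint null draws.

What the generator does **not** emulate: chromatographic peak shapes or raw
spectra (areas are drawn directly), correlated transition noise within a
peptide, batch effects or run-order drift, histology-dependent abundance
structure, protein–protein abundance correlation in the background
proteome, zero-inflation beyond the NB, or missingness mechanisms other
than the detection floor. Passing tests therefore demonstrate correctness
of the *computation* under the stated statistical model, not robustness to
every artifact of real FFPE data.

## Problem sizes used in tests and the acceptance script

Quantification accuracy uses 1000 peptides (100 samples × 10 targets) at
10% area CV; the type-I simulation uses 200 independent 15-sample cohorts
(250 background proteins, five 30-member sets, 199 permutations, first set
monitored); the power simulation uses 100 cohorts of 20 samples
(400 proteins, six 50-member sets, effect 1.0, 200 permutations);
correlation recovery uses n = 5000. These sizes put Monte-Carlo error
comfortably inside the asserted bounds while keeping the suite quick to run.

## Known limitations

* One signature peptide per target is the designed use; multi-peptide
  aggregation is a plain mean without peptide weighting.
* The concordance statistic is a pattern dot product, not a full
  chromatographic co-elution model; severely correlated interference across
  all fragments is undetectable by construction.
* BH-on-permutation-p FDR is conservative relative to pooled-NES FDR when
  many sets share signal.
* The CLI's `associate` stage computes all pairwise statistics for the
  panel; it does not model multiple testing across pairs.
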