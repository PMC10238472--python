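# Methods

This note records the models, parameter choices and numerical decisions
behind `psdpharm`, and what the synthetic-data experiments do and do not
demonstrate about real data.

## Generative model of the multiplexed experiment

Subjects belong to three groups (AD+P, AD−P, cognitively normal; default
sizes 59/47/19) and are dealt round-robin within (group, sex) strata into
plexes of 10–11, so every plex is approximately balanced for diagnosis
and sex as in a blocked TMT design. Each plex carries two pooled-control
channels whose content is the across-subject average of the true
(noise-free) peptide profile.

The log2 abundance of peptide p (protein g) in subject s, plex b is

    y = baseline_g + offset_p + effect_p·1[s ∈ AD+P]
        + Σ_c β_c (x_cs − x̄_c) + batch_{b,p} + ε,   ε ~ N(0, σ²)

with:

- `baseline_g ~ N(10, 2)`, `offset_p ~ N(0, 1)`: arbitrary log2 intensity
  scales; they cancel out of every downstream contrast.
- `effect_p = −log2(r)` for peptides of "altered" proteins, where the
  altered set is a fraction π of proteins (default 0.15) and r is the
  mean linear group ratio (default 1.17, AD+P lower) — the effect size
  the study's power analysis was built around. Designated "uncorrelated"
  peptides (default 1% of peptides, only from multi-peptide proteins)
  instead receive an independent discordant effect (+1.0 log2 in AD+P).
- residual SD σ = 1.0 on the log2 scale (the study's stated assumption),
  and a per-(plex, peptide) batch effect `batch ~ N(0, batch_sd²)`
  (default 0.5) — exactly the structure IRS is designed to remove, since
  pooled channels carry the same batch term.
- covariate slopes β_c on centered covariates; defaults are small
  (e.g. −0.005/year of age) so that covariate adjustment matters but does
  not dominate.

Values are exponentiated to the linear scale. Equal protein amounts are
labeled per channel, so PSD yield does **not** enter the abundances; it
lives in the metadata (group means 0.8 / 1.0 / 1.05 µg PSD per µg gray
matter, SD 0.12, AD+P lowest) and is multiplied back in at the roll-up
stage. This mirrors the assay: the biological loss of synapses is
invisible to equal-loading quantitation and must be restored from the
fractionation yield.

Missingness: exported reporter tables encode missing as zero. An iid
per-entry zero rate q would leave essentially no peptide observed in all
~125 subjects (0.95^125 ≈ 0.002 at q = 0.05), which contradicts how such
data behave — missingness concentrates in low-quality ("spotty")
peptides. The generator therefore draws a fraction `missing_peptide_frac`
(default 0.3) of peptides and gives them per-entry zero probability
q / 0.3, keeping the marginal zero fraction equal to `missing_rate`
(default 0.05) while leaving most peptides complete. A small fraction of
peptides (default 2%) is mapped ambiguously to a second protein to
exercise the multi-mapped filter.

Covariate marginals (age ~ N(84, 7), PMI ~ N(7, 4) truncated at 1 h,
APOE\*ε4 carrier rates ≈ 0.59/0.53/0.16 by group, Lewy-body rates
0.30/0.25/0.05, phospho-tau area log-normal) qualitatively match an
elderly autopsy cohort; their exact values are immaterial to every test.

What the generator does **not** emulate: spectral-level structure (PSMs,
m/z, co-isolation interference), intensity-dependent missingness,
peptide-specific ionization efficiency, correlated protein covariance
(proteins are independent given the group effect), or real
protein–protein interaction topology. Passing tests therefore demonstrate
the correctness and calibration of the *procedures* under the stated
stochastic model, not performance claims about any real cohort.

## QC and normalization

Chain order: zeros-to-missing → sample loading normalization →
pooled-control presence filter → multi-mapped removal → outlier-sample
removal → IRS → median normalization → present-call filter. Decisions:

- Loading normalization scales each channel to the grand mean of channel
  totals (symmetric and scale-preserving); totals use present values
  only. All channels (subject and pooled) are included; including only
  subject channels is the plausible alternative and changes nothing
  structural.
- "Missing in both pooled controls in at least half of the plexes" is
  implemented as a real-valued comparison: removed iff the count of
  all-pooled-missing plexes ≥ n_plexes / 2.
- Outlier samples: |log2 total − median| > k·MAD (MAD scaled by 1.4826,
  default k = 3) — a reproducible analogue of the visual total-abundance
  screen; pooled channels are never flagged. Because loading
  normalization equalizes the very totals this rule inspects, the
  pipeline computes the flags on raw totals and removes the channels at
  the stated position in the chain.
- IRS: per peptide and plex, factor = (mean of all present pooled values
  across plexes) / (within-plex pooled mean). If a surviving peptide has
  no present pooled value in some plex, no valid factor exists and its
  values in that plex are set missing.
- Median normalization scales each channel's median to the overall
  pre-scaling median. Note the present-call filter that follows changes
  the peptide subset, so channel medians of the *filtered* matrix need
  not be exactly equal; the invariant holds at the stage itself.
- Present-call denominators use subject channels only (thresholds are
  phrased per subject); the headline analyses use threshold 1.0, with
  0.5 as the supplementary setting.

All operations are pure (new matrices) and log factors and removals to a
`NormalizationReport`.

## Roll-up

PSD yield multiplies the linear-scale normalized abundances of each
subject channel (pooled channels untouched). The uncorrelated-peptide
test follows the PeCorA idea: per target peptide within a multi-peptide
protein, peptide-centered log2 values of all the protein's peptides are
modeled as `value ~ group + is_target + group:is_target` and the
interaction is F-tested; BH adjustment runs across all tested peptides
with flagging at adjusted p < 0.01 (α exposed). Under study-like noise
(σ = 1.0) the power to recover a 1-log2-unit discordant peptide at this
strict threshold is modest — the default-seed demo recovers few of the
six injected discordant peptides — which is a property of the conditions,
not a defect; the dedicated power check (σ = 0.3, five peptides, n = 60)
detects the discordant peptide in ≥ 95% of runs.

Protein values are the mean of available per-peptide z-scores of the
log2 values (z computed over subject channels, sample SD). Flagged
peptides leave their parent and appear as `"<protein>|<peptide>"`
entries. Zero-variance peptides have no z-score and are excluded with a
warning. Z-scoring makes protein values dimensionless; group differences
on this scale are shrunken by each peptide's total SD relative to raw
log2 fold changes, which is why the parameter-recovery experiment (below)
fits the regression on log2 values directly.

## Differential abundance

Per protein, complete-case OLS of the rolled-up value on an AD+P
indicator plus covariates (age, PMI, sex as 0/1, APOE\*ε4 0/1, Lewy body
0/1, log2 phospho-tau area for the AD+P vs AD−P contrast; age, PMI, sex
only against the normal group). The group coefficient is the model-based
log2FC. Residual variances are moderated by the standard empirical-Bayes
squeeze: with per-protein variance s² on d df, the posterior is
(d₀s₀² + d·s²)/(d₀ + d), the prior (d₀, s₀²) estimated by method of
moments on log variances (trigamma inversion by Newton iteration). When
the observed variances are no more dispersed than sampling predicts the
prior df is infinite and every variance shrinks to the common geometric
mean — so identical observed variances pass through unchanged. Moderated
t uses df d + d₀. Implemented natively so the package is self-contained;
`moderate=False` gives plain OLS t. BH runs across proteins within a
contrast; all tests two-sided. Rank-deficient per-protein designs yield
missing statistics rather than failures.

The global-shift statistic is the one-sample two-sided t-test of the
per-protein log2FC vector against 0, df = #proteins − 1. With the default
generator the yield adjustment moves *every* protein down in AD+P (by
log2 of the yield ratio) on top of the π-altered effects, so the global
shift is strongly negative — the qualitative signature of a proteome-wide
synaptic deficit.

Parameter recovery is assessed at the design's stated conditions
(n = 47/59, σ = 1.0, π = 0.15, r = 1.17) with one peptide per protein,
equal yields and the regression fit on log2 values, isolating the
estimation stage: the mean recovered log2FC over altered proteins matches
−log2 1.17 ≈ −0.2265 within Monte-Carlo error, and on π = 0 nulls the
nominal p < 0.05 rate is 4–6%.

## Network enrichment

A protein "interacts" iff it has ≥ 1 edge (self-loops ignored, optional
score cutoff, default none) to any seed-set member. Seed members are
excluded from both the DE and non-DE rows; the background is the analyzed
universe minus the seed. The test is Pearson χ² on the 2 × 2 table
without Yates continuity correction — the uncorrected statistic
reproduces the published value (χ² = 8.97 from 76/217 vs 348/1373),
where the corrected one would give ≈ 8.6.

## Pharmacology chain

- Disease signatures: sign(log2FC) with |log2FC| magnitudes; "full" is
  every nonzero protein, "top" restricts to raw p < 0.05.
- Knockdown screening: Spearman correlation (Pearson optional) between a
  gene's knockdown signature and the disease signature over shared
  entities; genes with < 10 shared entities or constant vectors are
  skipped with a reason.
- Nomination requires the correlation to be *significant* (p < 0.01 by
  default), standing in for the inclusion screen a curated knockdown
  atlas applies before reporting a gene at all; on correlation sign alone
  a null gene's drug would be nominated half the time. Then: negative
  correlation + {inhibitor, antagonist, negative modulator} or positive
  correlation + {agonist, potentiator, positive modulator}. Free-text
  action strings are normalized through an editable alias table
  (e.g. "blocker" → antagonist); unknown actions are skipped with a
  warning.
- Subset consistency: candidates whose correlation sign against the top
  signature differs from their full-signature sign are dropped (the
  MTOR-style exclusion); genes untestable on the subset are retained
  flagged.
- LINCS validation: rows filtered to CNS cell lines and dose ≥ 1 µM;
  per-gene mean Z across remaining tests; |mean Z| > 1 defines the drug
  signature; statuses distinguish "not found" and "not tested in CNS
  cells". The drug signature is scored against the disease signature with
  the Signed Jaccard Index (support = signed entities; zero-sign entities
  excluded; empty union → 0).
- Output ordering: Signed Jaccard ascending, ties by drug name.

The pharmacology fixtures construct one gene per qualitative case:
sign-flipped ± noise (reversing), same-sign (recapitulating), permuted
(null), and a subset-inconsistent gene that tracks the disease signature
off the top subset while being ordered oppositely *within* the top subset
around a mid-level offset — the centering keeps its overall rank
correlation clearly positive while the top-subset correlation is reliably
negative.

## Reversal evaluation

The treatment generator gives treated samples a log2 shift opposing the
disease sign on a configurable fraction (default 0.6) of signature
proteins, scaled by the disease magnitude — so the most disrupted
proteins reverse hardest, the pattern the in-vivo validation showed — and
can include one low-yield outlier sample (yield 0.35 vs ≈ 1.31) whose
abundances are scaled down accordingly; the total-abundance screen flags
it. Evaluation: per-protein treated-minus-vehicle means on rolled-up
values (complete-case), one-sample two-sided t-tests over the full
disease-signature overlap and the top-DE overlap, and the Signed Jaccard
of sign(fold change) against the disease signature (all overlap proteins,
no significance filter, mirroring the use of every quantified overlap
protein; an optional |fc| threshold exists). The same Signed Jaccard
implementation serves the LINCS and treatment scores.

## Problem sizes and tolerances

The packaged analyses and tests run at reduced scale chosen for quick
iteration: 250 simulated proteins (~640 peptides) for the cohort
pipeline, 60 proteins × 200 replicates for the Monte-Carlo recovery
study, 130-entity signatures × 100–200 seeds for the pharmacology and
reversal properties. Exact invariants (IRS/median equalization, roll-up
vs brute-force oracle, BH vs step-up enumeration, Signed Jaccard
algebra) are asserted at 1e-9–1e-12; stochastic properties use
Monte-Carlo error bars (3 SE) or ≥ 95%-of-seeds criteria. Quantities that
depend on the unreleased human cohort (the published global-shift t, the
1613/4025 protein counts, the specific Signed Jaccard values) are covered
by these structural substitutes, not reproduced numerically.

## Known limitations

- The correlation metric of the knockdown screen (Spearman) and the
  nomination significance threshold are design choices; the upstream
  services that produced the original tables do not publish theirs.
- PeCorA flagging power at σ = 1.0 is low; flagged-peptide splitting is
  therefore rare at default conditions.
- The z-score roll-up discards absolute scale; cross-study comparison of
  protein values requires the same subject set.
- Homolog mapping for cross-species treatment experiments is assumed done
  upstream (shared identifier namespace).
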