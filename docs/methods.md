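# Methods

This note documents the models and procedures implemented in `ptmplex`, the
assumptions behind them, the tunable parameters and their defaults, what the
synthetic-data generator does and does not emulate, and the numerical
choices made where the design was genuinely open.

## Data model

A multiplexed multi-PTM experiment is described by a **plex design**: one
row per (plex, TMT channel) giving the sample, its condition and timepoint,
its replicate number, its batch (one batch per plex), and a channel role.
Roles distinguish **oxidation** channels (+NEM samples; these are also the
quantitative samples for the global, phospho and acetyl data), **total
thiol** channels (−NEM samples used only as the stoichiometry denominator),
**standard** channels (designs without a redox arm), and **empty** channels
(deliberately skipped to limit reporter isotope-impurity bleed into
low-intensity neighbors).

PSM tables are tab-separated, one row per peptide-spectrum match, with
modifications encoded as `name@pos` tokens (zero-based position within the
peptide, `nt` for the N-terminus) and one raw reporter-intensity column per
channel. Zero reporter intensities are treated as non-detections and
converted to missing before any transformation: a true zero is not
observable in reporter-ion data, and log2 of zero would otherwise poison
downstream medians.

## Filters and site mapping

PSMs are retained when |mass error| ≤ 10 ppm (inclusive) **and**
PepQ < 0.01 (strict); both bounds are arguments. Peptide modifications are
mapped to 1-based protein coordinates via the declared peptide start and
verified letter-by-letter against the FASTA sequence; a peptide bearing
several target modifications becomes one **composite site key** over all
modified positions (e.g. `P1-S727S731`), distinct from the single-site
keys. Accessions are taken verbatim — no isoform collapsing is attempted
because no collapsing rule is defensible without isoform-level evidence.

Search-level QC: **labeling efficiency** is the fraction of labelable
positions (peptide N-termini plus lysines) carrying the TMT label in a
search where the label was dynamic. **Enrichment selectivity** is the
fraction of unique peptides (default; PSMs optionally) bearing the
enrichment target — a cysteine residue for thiol-affinity capture, the
phospho/acetyl modification for IMAC/IAP. Unique peptides are the default
denominator because selectivity describes the identification list, not the
spectrum count; the flag `unit="psm"` gives the alternative.

## Rollup and the normalization chain

Protein- and site-level abundances are sums of raw reporter intensities
over contributing PSMs, per sample; a cell is missing only when every
contribution is missing. The site chain then applies, in enforced order
(each matrix carries an ordered tag list and operations assert their
prerequisites):

1. `log2`.
2. `global-scaled`: subtract, per sample, the median of the log2 **global
   peptide** matrix (which must *not* be batch corrected). The global
   medians estimate TMT channel loadings; subtracting them removes loading
   offsets and median-centers in one step. Samples with no matching global
   column pass through tagged `unscaled` — missingness across matrices is
   a real feature of multi-plex PTM data, and silently dropping such
   samples would bias contrasts.
3. `batch-corrected`: per feature, subtract the batch mean and restore the
   grand mean, computed over non-missing values. This is the minimal
   correction that removes inter-plex offsets exactly while preserving
   within-plex sample differences verbatim, and it is idempotent. Features
   observed in a single batch pass through and are recorded. More elaborate
   corrections can be substituted behind the same call.
4. `protein-corrected`: subtract the per-condition mean of the parent
   protein's fully normalized abundance, so the residual tracks site
   occupancy rather than protein expression. Condition means use
   non-missing replicates only; with fewer than 2 the (site, condition)
   cell passes through and is recorded as uncorrected.

Global protein data runs log2 → batch correction → median centering.

Before statistics, features with more than `max_na_per_condition = 2`
missing values in **any single** condition are dropped (the strictest
reading of a per-condition missingness rule; a flag relaxes it).

### Error budget of the chain

Per-sample median steps are only exactly effect-invariant when the injected
or biological effects do not move the feature medians; with balanced up/down
regulation the bias is O(1/√n_features). Through the full chain the
variance of an occupancy log2FC estimate combines the site-level
measurement noise (σ√(2/n) for an n-vs-n contrast) and the propagated
protein-correction noise (the per-condition protein mean is itself
estimated from n samples). At σ = 0.25 and n = 4 with two peptides per
protein, the expected median absolute error of recovered occupancy log2FCs
is ≈ 0.15 — the protein-correction term contributes almost half of it, a
direct cost of the (correct) decision to subtract per-condition protein
means. Noise-free, the chain is exact to machine precision; the test suite
asserts both regimes.

## % cysteine thiol oxidation

Per site and condition:
`100 × mean(oxidation-channel intensities) / mean(total-thiol intensities)`
on the raw scale. Channels are first divided by **loading factors** derived
from the global (unenriched) data: `2^(median(log2 global column) − grand
median)`. This cancels loading differences between +NEM and −NEM channels
without touching the systematic oxidation/total intensity gap, which *is*
the signal. (Normalizing each channel by its own column sum — a tempting
alternative — forces oxidation and total columns to the same total signal
and rescales every stoichiometry by Σtotal/Σoxidation; it is therefore not
used.) With `loading_factors=None` the raw ratio is returned, which is
exactly invariant to rescaling any single site.

Values above 100% are flagged `over_range`, not clipped (clipping is an
explicit option): the over-range rate is itself a QC signal for
normalization failure or interference. Total-thiol channels are matched to
oxidation channels by condition, falling back to all total channels when a
condition has no matched singlet.

The estimator's absolute error grows proportionally with the stoichiometry:
with independent multiplicative channel noise of CV c, the ratio of means
over 4 oxidation and 2 total channels has relative SD ≈ c·√(1/4 + 1/2)
(≈ 8.7% at c = 10%). Recovery to within a *fixed* ±5 percentage points is
therefore essentially certain below ~25% oxidation and increasingly
unlikely at high stoichiometries (SD ≈ 9 points at s = 95%); the tests
assert the tight band where it holds and homogeneous ~9% relative error
overall. The estimator is unbiased (mean error < 0.5 points at s = 50%
over 10,000 simulated sites).

## Statistics

The default differential test is the pooled-variance two-sample t-test on
log2 abundances, two-sided, applied per feature with ≥ 2 non-missing
replicates per group, followed by Benjamini–Hochberg adjustment over all
tested features (via `statsmodels`; an independent brute-force step-up
implementation serves as the test oracle). Zero within-group variance is
handled with a 1e-12 variance floor and flagged rather than returning NaN.
An optional empirical-Bayes mode shrinks per-feature variances toward the
cohort median with a prior of 4 degrees of freedom — a lightweight
approximation of moderated-t machinery, provided for exploration and
documented as such; exact equivalence with linear-model pipelines is not
claimed, and the calibration tests run on the default estimator.

The significance convention used downstream is adj p ≤ 0.05 and
|log2FC| ≥ 0.8 (`DEFAULT_DE_CUTOFFS`). One-way ANOVA is the classic F test
per feature with per-condition log2FCs against a reference condition
(default `"Control 4 h"`); the hit filter is adj p ≤ 0.05 and max
|log2FC| ≥ 1 in a non-reference condition.

Precision QC: %CV is 100·SD/mean of raw intensities within replicate
groups. Note the small-sample bias of the sample CV (the c₄ factor):
with 4 replicates the sample CV underestimates a true 15% CV by ~12%, so
calibration checks use ≥ 24 replicates where the bias is negligible.
Sample correlations are pairwise-complete Pearson (≥ 3 shared features per
pair); PCA runs on complete-case, feature-centered data.

## Over-representation

`p = P[X ≥ k]` for `X ~ Hypergeometric(N, K, n)` per gene set, after
intersecting each set with the universe. The universe is the set of
quantified-and-tested features in the relevant modality (not the genome):
using a genome-wide universe inflates significance for any set enriched in
detectable proteins. PTM-site hit lists are collapsed to parent accessions
so a gene counts once. q is reported as the BH-adjusted p by default; a
Storey-style estimator (π₀ at λ = 0.5) is available behind a flag. Note
that for fixed counts the tail probability *decreases* as the universe
grows — padding the universe with set-free genes sharpens, not weakens,
the same overlap.

## Structures

Predicted single-chain models are read with `gemmi` (PDB or mmCIF);
per-residue confidence (pLDDT, 0–100) is taken from the Cα B-factor and
author numbering is assumed to equal UniProt numbering, both standard for
predicted structures. Distances are Euclidean Cα–Cα in Å; requested
residues are validated against the model's residue letters. Sites with
pLDDT below 70 (the conventional "low" boundary; configurable) are flagged
and their matrix cells annotated, because low-confidence regions are often
intrinsically disordered and inter-residue distances there describe one
transient conformation at best. Side-chain (closest heavy atom) distances
are deliberately out of scope for the default path.

## Synthetic data generator

The generator emulates a two-plex TMT18 cytokine time-course:
{Control, Cytokine} × {4, 8, 24 h}, quadruplicate oxidation channels split
2+2 across plexes, one total-thiol singlet per condition, three empty
channels per plex. Raw intensity of feature f in channel c of plex b is

    2^(baseline_f + protein_effect + occupancy_effect + peptide_offset
       + λ_c + δ_b + ε),   ε ~ N(0, σ²) independent per (feature, channel),

with redox oxidation channels scaled by the site's per-condition
stoichiometry s/100. Defaults: baseline ~ N(17, 1.5²) log2; λ ~ N(0, 0.3²);
δ ~ N(0, 0.5²); σ = 0.25; dropout 0.1 missing-at-random; 1 + Poisson(1)
peptides per protein with N(0,1) ionization offsets; site occupancy offsets
~ N(−2, 1); stoichiometries 100·Beta(1.2, 4) clipped to [0.5, 100]; 20% of
features affected with ±1 log2 effects in the treatment arm (deterministic
count, random signs); TMT labeling rate 0.993; enrichment selectivity
0.914 (redox) / 0.868 (phospho) / 0.95 (acetyl). Noise, loading and batch
magnitudes are chosen to represent a well-executed TMT experiment (raw
replicate CV ≈ 17–20% before normalization at σ = 0.25); they are study
conditions, not tuning knobs. All randomness flows from one seed through
per-modality child streams, so adding a modality does not perturb another
modality's draws (sequence letters may still change where a new modality
patches its target residues into the shared synthetic proteome).

What the generator does **not** emulate: reporter-ion ratio compression
from co-isolation, isotope-impurity bleed between adjacent channels,
intensity-dependent (left-censored) missingness, shared-peptide protein
inference ambiguity, and correlated biological variation between sites on
one protein. Tests passing on synthetic data therefore validate the
bookkeeping, the normalization algebra and the statistical calibration of
the pipeline — not robustness to those instrument-level artifacts.

## Numerical and interface choices

- Matrices carry ordered processing tags; operations assert prerequisite
  tags/scales and raise `StateError` on misordered chains, rather than
  producing silently wrong numbers.
- Median centering leaves all-missing columns untouched with a warning;
  batch correction of a single-batch matrix is a warned no-op.
- Ties in BH adjustment follow the step-up definition exactly (verified
  against brute force to 1e-12).
- TSV everywhere, with a YAML sidecar per matrix recording scale, modality
  and tags; the run manifest records thresholds, seed and per-stage feature
  counts so filter accounting can be audited.
- Problem sizes in the test-suite simulations (hundreds of proteins, a few
  thousand sites) are chosen so each check exercises the full design while
  the whole suite stays fast; recovery statistics quoted above are computed
  at those sizes.

## Known limitations

- The moderated-variance mode is an approximation, not a limma
  re-implementation (no contrast matrices, trend fitting, or array
  weights).
- No imputation and no isobaric interference correction; values the
  instrument did not measure stay missing.
- Stoichiometry estimates above ~75% carry wide absolute error bands at
  realistic channel CVs (see the error analysis above); interpret the
  over-range flag rate alongside them.
- ORA depends on the supplied GMT release; pathway membership counts are
  not comparable across database versions.
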