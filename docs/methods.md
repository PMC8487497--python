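# Methods

## Data model

A `CqDataset` is a long table of quantification cycles (Cq, interchangeably
CP) keyed by (sample, gene), with sample annotations animal / tissue /
condition. Invariants enforced at construction: Cq finite and > 0, unique
(sample, gene) keys, consistent per-sample annotations. Each animal
contributes one sample per tissue (`sample_id = <animal>_<tissue>`), which
is how multi-tissue designs are usually plated even when not stated
explicitly. Gene symbols are case-preserved, matched case-insensitively,
and `36b4` is an alias of `Rplp0` — both names circulate for the same
ribosomal-protein gene and published tables mix them.

Technical replicate wells are not modeled. If an input file carries a
`replicate` column, wells are collapsed to one Cq per (sample, gene) by
arithmetic mean before validation, with a log entry; single-reaction
protocols make this the least-surprising default. Missing Cq (undetermined
wells, sparse wide tables) are stored as explicit missing markers, never
imputed; every downstream method is complete-case within its own scope
(per gene for BestKeeper's marginal statistics, per pair for ΔCq, per
panel for the index, NormFinder and ΔΔCq) and logs how many samples it
dropped. Silent imputation would deflate exactly the dispersion statistics
these methods rank by.

## Synthetic data generator

The generator emulates a two-condition (pair-fed iron-replete PF vs
iron-deficient ID), six-tissue, n = 8-per-group rat design:

    Cq(a, t, c, g) = mu_g + tau_{g,t} + delta_g * 1[c = ID] + alpha_a + eps

with `alpha_a ~ N(0, sigma_a^2)` drawn once per animal (shared across that
animal's six tissues — the within-animal correlation a pair-fed design
induces) and `eps ~ N(0, (sigma_g * scale_{g,t})^2)` i.i.d. Noise is normal
on the Cq scale, the standard qPCR error model (Cq is already log2
expression). Randomness uses numpy's `default_rng` (PCG64), a named,
versioned generator, so a seed pins the dataset bit-for-bit.

Defaults, chosen once as the emulated study's conditions:

| parameter | default | why |
|---|---|---|
| `mu_g` | per-gene combined-tissue geometric means (16.9–24.2 cycles) | matches the published panel's central values |
| `sigma_g` | per-gene, 0.58–1.43 cycles | the published combined-tissue Cq dispersions, the only dispersion information in print; real between-animal vs technical shares are unpublished, so the whole marginal dispersion is carried by `sigma_g` |
| `sigma_a` | 0.2 cycles | order-of-magnitude animal effect, small relative to `sigma_g` |
| `delta_g` (RG) | 0 | the default panel is the ideal-RG limit; instability is injected explicitly via `inject_instability` |
| target | `Tfrc`, delta = −3.32 cycles, sigma = 0.3 | a 2^3.32 ≈ 10-fold induction under ID, the canonical iron-deficiency positive control |
| `tau_{g,t}` | 0 (`flat` preset) | per-tissue offsets are unpublished |

The `realistic` preset adds fixed per-gene tissue offsets up to ±2 cycles
(reproducing the large combined-tissue min–max ranges real panels show)
and small positive shifts for *Actb*, *Gapdh* and *Ppia*, the genes
repeatedly reported as condition-responsive.

Sign convention: `delta_g` is a **Cq** shift under ID. Negative delta =
lower Cq = induction. A reference gene co-induced with the target
(delta_ref < 0) therefore *shrinks* the measured target fold by
2^|delta_ref|, and a suppressed reference gene inflates it — the measured
fold is 2^(3.32 + delta_ref) in the noiseless limit.

What the generator does **not** emulate: amplification-efficiency
deviations from perfect doubling, plate/run batch effects, inhibitors,
heteroscedastic high-Cq noise, and non-normal outliers. Tests passing on
this generator therefore certify the statistical machinery under the
additive-Gaussian model, not robustness of qPCR practice to assay
artifacts.

## BestKeeper statistics

Per gene: GM = geometric mean of Cq; dispersion `sd_cp` is by default the
mean absolute deviation from GM (the original BestKeeper definition), with
the n−1 sample SD as the alternative `sample_sd` mode — published tables
cannot discriminate the two without raw data, so both are implemented and
the mode is recorded in every result. CV is reported as the proportion
SD/GM (matching published magnitudes ~0.02–0.07), not a percentage.
Signed folds: x-fold(Cq) = sign(Cq−GM)·2^|Cq−GM|, +1 at zero deviation;
deviations below GM (higher expression) are negative. A constant vector
short-circuits GM to the common value so the zero-deviation limit is exact
rather than off by exp/log roundoff. The suitability criterion is strict:
`sd_cp < 1.0` cycle; a gene at exactly 1.0 is unsuitable. The BestKeeper
index is the per-sample GM over the complete-case panel; per-gene Pearson
r (and two-sided p) against the index, with NaN as the undefined marker
when either vector is constant. Ranking is by ascending `sd_cp`, average
ranks at ties. Known caveat, surfaced here rather than resolved: published
prose and table orderings for the least-stable gene can disagree; this
implementation ranks strictly by the dispersion statistic.

## Comparative ΔCq and geNorm

For each ordered pair (a, b): per-sample differences Cq_a − Cq_b over the
samples where both genes are observed, summarized by mean and n−1 SD.
Antisymmetry of means and symmetry of SDs are exact by construction (the
reverse pair is emitted by negation, not recomputed). A pair with < 2
common samples is flagged missing, never fabricated. The stability score
is the arithmetic mean of a gene's partner SDs; because Cq is log2
expression, this *is* the geNorm M-value, and `genorm_m` shares the code
path so the identity holds exactly. Published "Mean SD" columns may differ
in the third decimal from the mean of the rounded printed SDs (they were
averaged before rounding); only printed-column arithmetic is testable
without raw data. Stepwise geNorm exclusion removes the highest-M gene and
recomputes until two remain; ties at the maximum break deterministically
by gene-list order (earliest-listed excluded first), and the final pair is
tied at rank 1.5 — pairwise variation cannot separate two genes.

## Model-based stability (NormFinder-style)

Within each group γ the k × n_γ grid is two-way centered (gene and sample
effects removed). The naive per-gene residual mean square s²_g is biased —
each gene contributes 1/k of the estimated sample effects — with
expectation (1 − 2/k)σ²_g + mean(σ²)/k, so the estimator

    σ̂²_g = k/(k−2) · ( s²_g − Σ s² / (k(k−1)) ),  clipped at 0

is used; this is why k ≥ 3 genes are required. Intergroup deviations
d(g,γ) are the doubly centered group means (per gene, the group-size-
weighted deviations sum to zero — asserted to 1e−10 in tests). Since d is
estimated with sampling variance σ̂²_g/n_γ, it is shrunk by the
empirical-Bayes factor γ̂²/(γ̂² + σ̂²_g/n_γ), where
γ̂² = max(0, Σ_g d²_gγ/(k−1) − mean_g(σ̂²_gγ/n_γ)) is the between-gene
deviation variance net of noise. The stability value is

    ρ_g = mean_γ ( |d̃(g,γ)| + sqrt(σ̂²(g,γ)/n_γ) ),

lower = more stable. The reference publications print rankings, not
stability values, so correctness is established by properties: exact
invariance to global and per-sample Cq shifts, zero ρ in the noiseless
no-effect limit, and rank-level recovery of injected condition shifts and
inflated noise in seeded simulations. The untreated control condition C,
when present, is excluded by default — stability is judged between the
pair-fed and deficient groups, which are matched for food intake. A
variance-only ungrouped variant (same bias-corrected residual variance
over the full grid) serves single-condition scopes. The "best pair of
genes" combined output of the original tool is out of scope.

## Aggregation

The comprehensive score is the geometric mean of a gene's ranks across
methods (the established RefFinder definition; no alternative weighting is
offered, and no method is up-weighted). The counting consensus takes each
method's top-n and bottom-n genes (n = 2 by default; fractional ties
expand a nomination set past n and the expansion is flagged) and orders
genes by nomination count; equal counts form explicit tie groups reported
as sets. A single method is accepted (the consensus then reproduces that
method's extreme sets); the comprehensive ranking requires at least two.
When the pipeline computes everything internally, the consensus counts
votes from BestKeeper, ΔCq, NormFinder and the comprehensive ranking —
geNorm enters through the comprehensive ranking rather than voting twice,
since its scores duplicate ΔCq's exactly on a full panel.

## ΔΔCq quantification

ΔCq = Cq_target − Cq_ref per sample (multi-reference: arithmetic mean of
reference Cq, i.e. geometric mean on the expression scale); the calibrator
is the control-group mean ΔCq, so the control group's geometric mean
relative quantity is exactly 1. Amplification efficiency is fixed at
perfect doubling; no Pfaffl-style correction. The t test (pooled-variance,
two-sided, hand-rolled to give the natural degenerate limits: t = 0, p = 1
at zero variance and equal means; ±inf, p = 0 at zero variance and unequal
means; cross-checked against an independent implementation) runs on
per-sample ΔCq values — the approximately normal scale — while fold-scale
means ± SEM are reported for presentation. The sensitivity report re-runs
the quantification per candidate RG and reports the max/min fold ratio as
the spread statistic.

## Orchestration and reproducibility

`run_evaluate` executes the configured methods over the all-tissues scope
plus each tissue, computes the comprehensive ranking and consensus per
scope, and captures provenance (config, version, input SHA-256, sample
counts). Per-scope errors are collected without aborting other scopes;
exit codes are 0 / 2 (validation) / 3 (partial failure). Rounding to the
report precision (default 2 decimals) happens only at render time;
machine-readable JSON keeps full precision with sorted keys, so identical
config + seed reproduce it byte-for-byte. Rank ties are ordered
alphabetically in tables for determinism; tie *groups* are preserved as
data, never broken.

Problem sizes in the test suite and acceptance script follow the emulated
design (10 genes × 96 samples; 100-replicate blocks for rank-recovery
rates; 10,000 draws for the variance-accounting check), which the whole
suite completes in well under a minute.

## Known limitations

- Printed-table reproduction is limited to internal-consistency arithmetic
  (x-fold/CV identities, criterion counts, column means, antisymmetry);
  the underlying per-animal Cq values are unpublished, so Tables-level
  recomputation and plotted stability magnitudes are not claimed.
- The MAD-vs-SD ambiguity of published BestKeeper dispersions is
  undecidable without raw data; both modes ship.
- geNorm's pairwise-variation V(n/n+1) statistic for choosing the number
  of reference genes is not implemented (not used by the validation
  workflow targeted here).
- Instrument-native export parsing (e.g. ABI SDS) is out of scope; inputs
  are pre-exported CSV/TSV.
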