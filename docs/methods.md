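# Methods

This note records the models, conventions and design choices behind
`specfx`, and what the synthetic data does and does not emulate.

## Fingerprint model

A fingerprint is a sample × peak matrix of integrated peak areas with one
block per ESI ion mode (ids `P*` positive, `N*` negative — the prefix is
enforced as an invariant). The analysis unit is the *common characteristic
peak*: a peak found in every sample of the batch.

**Common-peak detection.** Peak lists are pooled per mode, sorted by
retention time, and grouped greedily: an entry joins the current group when
its t_R is within `rt_tol` (default 0.1 min) of the group mean, else it
starts a new group. A group is a common peak only when every sample
contributes exactly one member. Two same-sample peaks closer than `rt_tol`
make matching ill-defined and raise an ambiguity error rather than guessing.
The greedy rule is adequate because chromatographic alignment upstream keeps
within-peak jitter (±0.02 min in the generator) an order of magnitude below
both `rt_tol` and the spacing of distinct peaks; it is not a general
clustering of arbitrarily dense peak lists.

**Equalization.** The source workflow's "equalization" of peak areas is not
defined operationally anywhere we could recover, so it is implemented as the
natural reading: within each ion mode, a sample's areas are divided by that
sample's total common-peak area, making each (sample, mode) row a
composition summing to 1. This is idempotent and invariant to per-sample
scale (injection volume, dilution), which is precisely what cross-sample
comparability requires.

**Reference and similarity.** The reference fingerprint is the per-peak
median over samples (even count: mean of the two middle values — this
convention shapes the reference atlas and is therefore documented). Sample
similarity to the reference defaults to the cosine (congruence) coefficient,
which lies in [0, 1] for nonnegative profiles and is scale-invariant;
Pearson correlation is available as an option. Which of the two the
historical fingerprint-evaluation software used is unrecoverable, so no
result depends on the choice.

**Clustering.** UPGMA (average linkage) on Euclidean distances between
equalized profiles, run separately per ion mode — modes are never mixed in
one distance computation. Inputs are the equalized areas without per-peak
autoscaling (no z-scoring) because no scaling step is documented for the
source workflow; the flat-cluster cut removes the k−1 highest merges.
Correctness is checked against an O(n³) brute-force UPGMA oracle in the
tests.

## Annotation

Monoisotopic masses are computed from molecular formulas (elements C, H, N,
O, S, P) via pyteomics' NIST isotope masses; adduct m/z is mass ± the proton
mass (1.00727646 Da) for [M+H]⁺ / [M−H]⁻. Feature matching gates on both
mass error (ppm) and retention time, then picks the candidate with the
smallest |ppm|. Two conventions matter:

- **Per-mode ppm defaults: 25 ppm positive, 10 ppm negative.** The curated
  positive-mode observed m/z values deviate from theory by up to ~19 ppm
  (chlorogenic acid P2: 355.0956 observed vs 355.1024 theoretical, while its
  own listed fragment 355.1034 is near-exact — likely a transcription
  artifact in the source table, recorded here rather than "fixed"). A single
  10 ppm default would orphan a curated identification.
- **The t_R gate is mandatory.** Hyperoside (N8, 10.62 min) and
  isoquercitrin (N9, 10.82 min) are isomers with identical adduct masses, as
  are the malonyl-glucoside/galactoside pair; only retention time separates
  them.

Fragment ions are used as optional evidence (a count of matched library
fragments), never as a gate. Compound-level deduplication merges peaks with
an identical non-"Unknown" compound name; Unknowns never merge with each
other.

## Pharmacology statistics

Group cells are summarized as mean ± sample SD (n−1). One-way ANOVA uses the
standard sum-of-squares decomposition; the degenerate zero-within-variance
case with unequal means is flagged and reported as F = ∞, p = 0 rather than
raising. Duncan's multiple-range test takes the ANOVA MSE and error df; the
least significant range for a stretch of p ordered means is

    LSR_p = q((1−α)^(p−1); p, df_error) · sqrt(MSE / n)

i.e. the studentized-range quantile at Duncan's protection level
α_p = 1 − (1−α)^(p−1), computed from `scipy.stats.studentized_range` rather
than printed tables so that any df is supported (at p = 2 this reduces
exactly to the two-sample t critical difference, which the tests verify to
1e−9). Step-down protection: stretches are tested from widest to narrowest,
and a stretch inside any stretch already declared non-significant is not
tested. Unbalanced designs use the harmonic-mean n (the study itself is
balanced at n = 6, so this is an extension). Letters are assigned by
insert-and-absorb over the pairwise significance matrix, with 'a' starting
at the largest mean; the six indicators are tested independently, with no
multiplicity correction across indicators, matching per-indicator reporting
practice.

## Grey relational analysis

Sequences are first normalized (default: mean normalization x/mean(x);
min-max and initial-value schemes are provided). For reference x₀ and
comparisons xᵢ, with Δᵢ(k) = |x₀(k) − xᵢ(k)|,

    ξᵢ(k) = (Δmin + ρ·Δmax) / (Δᵢ(k) + ρ·Δmax),   grade_i = mean_k ξᵢ(k)

with resolution coefficient ρ = 0.5. Δmin and Δmax are **global** over all
peaks and sample points of one indicator — a per-peak Δmax would destroy
cross-peak comparability of grades. ξ ∈ (0, 1] always; grade = 1 iff the
comparison coincides with the reference after normalization; if every
comparison coincides (Δmax = 0) all grades are 1 by continuity, not an
error. Ranking is per indicator and per ion mode; the top-5 screen includes
all peaks tied with the 5th grade (deterministic, order-independent).

Mean normalization and ρ = 0.5 are the canonical grey-relational
conventions; both are exposed in `GreyParams` and recorded in result
metadata since the source workflow does not pin them down.

## Pairing fingerprints with efficacy

Fingerprint samples carry a salt treatment; efficacy groups carry dose ×
treatment. The default policy pairs each fingerprint sample with the
**high-dose** group mean of its treatment (H0…H300), giving n = 12 aligned
points; this is consistent with the reported correlation significance
pattern, where starred values all exceed the n = 12, α = 0.05 critical
r ≈ 0.576 and an unstarred 0.575 falls just below. Low-dose and
per-treatment-mean (n = 4) policies are available.

## Bivariate correlation screen

Pearson r per (peak, indicator) with a two-sided p from
t = r·sqrt((n−2)/(1−r²)). The default screening rule is |r| > 0.5 for at
least one indicator; a p < α rule is provided because reported significance
stars follow it. Note the reference tables' CAT column contains three values
above 0.5 (N5 0.521, N9 0.656, N14 0.701) although the narrative summary of
the original selection omits N5; the packaged reported selection is shipped
verbatim, and the rule-based screen reproduces the per-column sets, not the
undocumented editorial union. Likewise, the literal top-5 GCA rule yields a
20-peak union (adding P9, P12, N5) versus the 17-peak reported list; both
routes are supported, and the marker arithmetic is validated on the reported
lists.

## Synthetic-data generator

The generator emulates the study design, not the instrument: 4 NaCl
treatments × 3 replicates; 26 peaks with the library's retention times and
m/z; 11 efficacy groups (control, CCl₄ model, silymarin, low/high dose ×
4 treatments) × 6 indicators × 6 animals.

- **Effect profile.** Polyphenol-class peaks (flavonoids and
  phenylpropanoids) get multipliers {0 mM: 1.0, 100: 1.35, 200: 0.60,
  300: 0.50} — accumulation peaks under low salt stress and declines under
  medium/high stress — while other classes are flat. This encodes the
  biological narrative (moderate salinity stimulates secondary metabolism)
  and is what makes the 0/100 vs 200/300 mM two-cluster split recoverable.
- **Noise model.** Replicate variation is multiplicative unit-mean lognormal
  with CV 0.10. Areas are positive by construction and the CV is
  scale-stable; no replicate-level variance is published for the source
  data, so the level is a calibration choice: large enough that clustering
  is a real test (the split holds in ≈96/100 seeds per mode, not 100/100),
  small enough to respect the reported fingerprint similarity floor (≥0.7).
- **Efficacy defaults.** Group means are taken from the published endpoint
  values where printed (model ALT 130.67, control 25.4 U/L; model AST 99.77,
  control 24.63 U/L; low-dose groups via the printed percent reductions) and
  otherwise set to respect the narrated ordering (H100 best; SOD order
  H100 > H200 > H300 > H0; POD decreasing with salt at high dose). SDs are
  ~10% of the mean. The silymarin "reduced to 58.19%/60.16%" phrasing is
  ambiguous between *to* and *by*; the defaults read it as *by* (ALT
  54.6 U/L), consistent with high-dose groups halving transaminases "to a
  level similar to silymarin". No test asserts either reading. Draws are
  normal truncated at zero (enzyme activities cannot be negative) via
  resampling.
- **Decoys.** Decoy peaks are placed ≥0.3 min from every other peak inside
  the 0–22.1 min gradient window and appear in a random proper subset of
  samples, so a brute-force all-samples intersection provably removes them.
- **Planted correlation.** `plant_correlated_peak` appends a peak
  proportional to an indicator sequence plus Gaussian noise sized so the
  population r equals the target; at r = 1 the peak is exactly proportional,
  hence identical to the indicator after mean normalization, hence grade 1
  and rank 1 under GCA — the parameter-recovery tests rest on this.
- **Determinism.** All draws flow from `numpy.random.default_rng` seeded by
  (config seed, operation stream), so identical (config, seed) gives
  byte-identical outputs regardless of call order.

What the generator does **not** emulate: raw chromatograms, peak picking,
mass spectra, isotope envelopes, matrix effects, inter-batch drift, animal
attrition, or any correlation structure between indicators beyond their
group means. Passing tests therefore demonstrate that the statistical
machinery recovers planted structure under the stated noise model — not that
the biological conclusions would survive instrument-level artifacts.

## Numerical and scale choices

Tolerances: equalized row sums to 1 within 1e−12; Pearson and the grey
worked example verified to 1e−12; UPGMA against the brute-force oracle to
1e−9; the Duncan/t identity to 1e−9. Simulation sizes are chosen to keep the
full suite fast while leaving the calibration checks sharp: 10⁴ null ANOVA
simulations (type-I error asserted within [0.04, 0.06]), 1000 random
significance matrices for the letter-display equivalence, 100 seeds each for
the clustering-split and parameter-recovery rates, 40 random matrices of
≤8 samples for the UPGMA oracle. The acceptance script re-derives per-run
sub-seeds from a single `--seed` and completes in well under a minute.

## Known limitations

- The greedy RT grouping assumes well-separated peaks (see above).
- Compound dedupe keys on exact name equality; synonyms would need
  harmonizing upstream.
- The insert-and-absorb letter display is guaranteed correct (share-a-letter
  ⇔ non-significant) but not guaranteed minimal in pathological
  non-transitive cases.
- `percent_change` compares means only; it carries no uncertainty.
- The packaged reference tables are transcriptions of printed values and
  inherit their rounding (grades to 3 decimals, r to 3 decimals).
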