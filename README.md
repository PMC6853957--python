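# specfx

Spectrum–effect relationship modeling for LC-MS herbal fingerprints.

`specfx` is for analysts evaluating the quality of a medicinal herb from two
coupled data sets: a **chemical fingerprint** (the areas of common
characteristic chromatographic peaks, one sample × peak matrix per ESI ion
mode) and **in vivo efficacy endpoints** (here, hepatoprotection markers in
the CCl₄ acute-liver-injury mouse model: serum ALT/AST, hepatic MDA, and the
antioxidant enzymes SOD/CAT/POD). The packaged worked case is Apocyni Veneti
Folium (AVF, *Apocynum venetum* leaf) grown under four NaCl treatments
(0/100/200/300 mM, three replicates each), with a curated 26-compound library
(12 positive-mode peaks P1–P12, 14 negative-mode peaks N1–N14).

## What it computes

**Fingerprint stage.** Common characteristic peaks are detected as peaks
present in every sample (retention-time matching within a tolerance); areas
are *equalized* (each sample's areas divided by its per-mode total); the
reference fingerprint is the per-peak **median** across samples; each sample
is scored by cosine (or Pearson) similarity to the reference; samples are
clustered by UPGMA (Euclidean distance, average linkage).

**Pharmacology stage.** Per-group mean ± SD, percent change versus the model
group, one-way ANOVA, Duncan's multiple-range test (least significant ranges
from the studentized-range distribution with protection level
1 − (1 − α)^(p−1)), and a compact letter display.

**Fingerprint–activity stage.** Two screens per efficacy indicator:

- *Grey relational analysis (GCA).* After normalization, with deviations
  Δᵢ(k) = |x₀(k) − xᵢ(k)| and global extrema Δmin/Δmax, the grey relational
  coefficient is ξᵢ(k) = (Δmin + ρΔmax) / (Δᵢ(k) + ρΔmax) with resolution
  coefficient ρ = 0.5; a peak's relational grade is the mean of its ξ series,
  and the top five peaks per indicator and ion mode are screened.
- *Bivariate correlation analysis (BCA).* Pearson r between peak areas and
  indicator values with a two-sided t-test; peaks with |r| > 0.5 for at least
  one indicator are screened.

The union of both screens is deduplicated at the compound level (the same
compound observed as [M+H]⁺ and [M−H]⁻ peaks collapses to one marker) to give
the bioactive-marker report. A seeded synthetic-data generator reproduces the
study design (12 samples × 26 peaks with low-salt-enriched polyphenols;
11 dose groups × 6 indicators × 6 animals), so the whole pipeline is testable
end to end.

## Worked example

The packaged reference screening tables (grey relational grades and Pearson
correlations for all 26 peaks against the six indicators, plus the reported
GCA/BCA selections) drive the marker report directly:

```sh
$ specfx reference-screen
union 19 peaks -> 15 markers (2 unknown)
                                        compound  compound_class member_peaks  is_unknown
                      Citric acid/isocitric acid    organic acid           P1       False
                                Chlorogenic acid phenylpropanoid        P2+N3       False
                                    Unknown (P3)         unknown           P3        True
                          Cryptochlorogenic acid phenylpropanoid           P4       False
                                  Procyanidin B2       flavonoid        P5+N6       False
                                      Hyperoside       flavonoid        P8+N8       False
...
```

The 19-peak union screened by GCA (17 peaks) and BCA (7 peaks) collapses to
15 compound-level markers because four compounds were observed in both ion
modes (chlorogenic acid P2/N3, procyanidin B2 P5/N6, hyperoside P8/N8, and
the quercetin malonyl-glucoside P11/N11); two markers (P3, N4) remain
unidentified.

The synthetic pipeline runs the same stages on generated data:

```sh
$ specfx simulate --seed 7 --out-dir demo
$ specfx pharm demo/efficacy.csv
indicator     group    mean     sd  n letters
      ALT   control  24.778  3.385  6       g
      ALT     model 139.105  6.660  6       a
      ALT silymarin  53.532  5.593  6       f
      ALT      H100  56.524  3.733  6      ef
...
```

The CCl₄ model group has the highest serum ALT (letter "a"); the control and
silymarin/high-dose groups are significantly lower, with groups sharing a
letter not significantly different under Duncan's test at α = 0.05.
`specfx cluster demo/fingerprints.csv --mode negative -k 2` separates the
0/100 mM samples from the 200/300 mM samples, and
`specfx report demo/fingerprints.csv demo/efficacy.csv` runs the full
GCA + BCA screen to a marker report.

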