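# floralshift

Analysis pipeline for **intraspecific red-to-yellow floral transitions** —
the situation where a yellow-flowered morph arises inside an otherwise
red-flowered, hummingbird-pollinated species and begins attracting
bumblebees. Understanding such an incipient pollinator shift requires
measuring the flower at several levels at once: scent, colour as a bee sees
it, antennal perception, behavioural preference, reward and morphology
phenotypes, trait integration, and genome-wide divergence. `floralshift`
implements the quantitative core of each level as a tested, reusable
library with a thin command-line interface, plus a synthetic-data generator
that emulates every input shape so the whole pipeline runs and validates
without any external download.

## What it computes

* **volatiles** — GC-MS peak-table processing: a four-stage filter cascade
  (area ≥ 10⁵ counts; retention ≤ 30 min; removal of peaks matching a
  paired-blank peak within 0.1 min at < 5-fold the blank area; removal of
  peaks whose all three library hits are siloxane/silica/phthalate
  contaminants), Kovats retention indices against an n-alkane ladder by the
  temperature-programmed (van den Dool–Kratz) formula
  RI = 100·n + 100·(t − tₙ)/(tₙ₊₁ − tₙ), standard-curve quantification to
  ng · flower⁻¹ · h⁻¹, per-sample totals, group fold changes, and Welch's
  *t*.
* **bee_vision** — reflectance spectra (300–700 nm) averaged hierarchically
  and projected into the trichromatic colour hexagon: quantum catch
  Q = ∫R(λ)S(λ)I(λ)dλ, von Kries adaptation q = Q/Q_background, excitation
  E = q/(q+1), coordinates x = (√3/2)(E_G − E_UV),
  y = E_B − (E_UV + E_G)/2; distance from the origin is chromatic contrast
  against the green background.
* **eag** — electroantennogram normalization: first-response removal,
  piecewise-linear drift baseline anchored on interleaved positive-control
  (PAA) blocks, division by the local baseline, scaling to the initial
  control response.
* **choice** — bee choice-trial statistics: pooled χ² goodness of fit
  against a 50:50 null (no continuity correction), first-choice test,
  per-bee summaries.
* **phenotype** — pigment absorbance standardized by corolla mass
  (AU · g⁻¹), capillary column height → nectar volume
  (h/100 · 103.87 µL), herkogamy (pistil − stamen, sign preserved).
* **integration** — all-pairs Pearson correlation censuses (pair counts
  k(k−1)/2, percent significant at α = 0.05), one-way F comparison of |PCC|
  distributions across lines, terpenoid–carotenoid correlations by colour
  group.
* **variants** — VCF variant positions binned into fixed windows tiling
  each chromosome, second-order Savitzky–Golay-style smoothing (default 50
  neighbours each side) with symmetric edge shrinkage, and cross-species
  overlay summaries.
* **synthdata** — deterministic generators for every input above with
  embedded ground truth (emission fold change, stimulus response ratios,
  choice probability, per-window Poisson intensities) for
  parameter-recovery testing.

## Worked example

Generate a full synthetic dataset, run the volatile pipeline and the choice
statistics:

```sh
floralshift synth --seed 42 --out data/
floralshift volatiles --peaks data/peaks.csv --blanks data/blanks.csv \
    --ladder data/ladder.csv --curves data/curves.csv --out vol/
floralshift choice --events data/events.csv --out prefs/
```

which prints

```
150/510 peaks retained; wrote vol/emissions.csv
MvY-vs-MvR visits: yellow 65 vs red 35 (chi2_1 = 9.00, p = 0.0027)
MvY-vs-MvR probes: yellow 39 vs red 15 (chi2_1 = 10.67, p = 0.001091)
MvY-vs-MvR first_choice: yellow 7 vs red 3 (chi2_1 = 1.60, p = 0.2059)
```

The filter cascade removed the 360 planted junk peaks (sub-threshold,
late-eluting, contaminant and blank-matched) and kept exactly the 150 true
compound peaks (5 compounds × 30 samples). The choice log was generated at
a true 2:1 yellow preference with ten bees: the pooled visit test rejects
the 50:50 null (p = 0.0027) while the ten first choices alone do not —
the same qualitative pattern expected at these sample sizes. Group mean
total emissions from `vol/totals.csv` (556.4 vs 184.2 ng · flower⁻¹ · h⁻¹
for this seed) estimate the generator's planted 2.3-fold difference.

Direct library use:

```python
from floralshift import choice, phenotype
choice.chisq_gof(59, 30).chi_square   # 9.449438202247191
phenotype.nectar_volume(100.0)        # 103.87 µL, a full capillary
```

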