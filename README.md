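# ftirquant

Macromolecular quantification of cultured-cell FTIR spectra, with the
small-sample statistics and the differential-expression concordance
bookkeeping that typically accompany such experiments.

## The problem

Fourier-transform infrared (FTIR) spectroscopy of lyophilized cells reads
out bulk macromolecular composition without labels: C–H stretching bands
(2800–3020 cm⁻¹) report on lipids and proteins, and the fingerprint region
(890–1478 cm⁻¹) on nucleic acids, glycogen and phosphates. Treatment
effects (a drug, an RNA knockdown) appear as changes in band intensities,
intensity *ratios* and small band-position shifts between replicate groups.
`ftirquant` implements that analysis end to end for two-column
wavenumber/absorbance traces:

1. **Baselining** — subtract the straight line through the trace values at
   two anchor points of each analysis region, making every downstream
   quantity invariant to an additive affine background.
2. **Normalization** — divide by a reference-band apex (PO₂⁻ symmetric at
   1082 cm⁻¹ in the fingerprint, CH₂ asymmetric at 2924 cm⁻¹ in the C–H
   region) so intensities are comparable across samples.
3. **Band measurement** — locate the discrete maximum in each catalog
   band's search window (center ± 8 cm⁻¹) and refine position and apex
   height with a three-point parabola, resolving positions well below the
   4 cm⁻¹ sampling step.
4. **Indices** — per replicate:
   - lipid-to-protein ratio `I(2852)/I(2872)` (CH₂ sym / CH₃ sym),
   - acyl chain-length index `I(2924)/I(2958)` (CH₂ asym / CH₃ asym),
   - olefinic (lipid unsaturation/peroxidation) index `I(3006)/I(2924)`,
   - RNA content `I(1121)/I(1082)`,
   - glycogen (996, 1156 cm⁻¹) and protein C–O (1171 cm⁻¹) intensities on
     the PO₂-sym-normalized trace,
   - PO₂⁻ symmetric/asymmetric band positions (cm⁻¹).
5. **Group statistics** — mean ± SD per group, percent change of group
   means `100·(treated − control)/control`, and a two-sided p-value from
   the **exact Mann–Whitney U test** (full enumeration of all
   C(n₁+n₂, n₁) labelings for tie-free pooled samples up to 12
   observations; note the smallest attainable exact two-sided p at
   n = 3 vs 3 is 0.1) or the unpaired t-test.

A separate module reproduces the cross-condition **differential-expression
concordance** procedure: filter two DE result tables at padj < α
(strictly), intersect on gene id, count direction-concordant ("parallel")
genes, and correlate the shared log2 fold changes (Pearson r).

Because real deposited spectra and count matrices are not shipped, a
synthetic-data generator produces pseudo-Voigt band spectra and DE-table
pairs with *planted, exactly recoverable* truth; generator presets emulate
a cisplatin-treatment and an antisense-knockdown contrast on HeLa cells
(n = 3 per group). See `docs/methods.md` for the model details.

## Worked example

Simulate a planted cisplatin-style experiment and analyze it:

```sh
ftirquant simulate --preset cisplatin --n 3 --seed 7 --out demo/sim
ftirquant analyze --control demo/sim/control --treated demo/sim/treated \
    --out demo/report
```

`demo/report/comparison_report.csv` then contains (this exact seed):

```
             metric  control_mean  control_sd  treated_mean  percent_change  p_value               test
lipid_protein_ratio        1.0907      0.1105        1.2639         15.9000      0.2 mann_whitney_exact
 chain_length_index        1.5069      0.0162        1.6987         12.7000      0.1 mann_whitney_exact
     olefinic_index        0.0128      0.0021        0.0117         -8.4500      1.0 mann_whitney_exact
   rna_content_1121        0.8986      0.0625        0.9187          2.2400      0.7 mann_whitney_exact
       glycogen_996        0.5077      0.0195        0.4490        -11.6000      0.1 mann_whitney_exact
      glycogen_1156        0.6677      0.0246        0.5651        -15.4000      0.1 mann_whitney_exact
    protein_CO_1171        0.7499      0.0439        0.9582         27.8000      0.1 mann_whitney_exact
   po2_sym_position     1082.0400      0.0968     1082.1600          0.0115      0.4 mann_whitney_exact
  po2_asym_position     1234.1300      0.2647     1235.4500          0.1060      0.1 mann_whitney_exact
```

Reading it: the control group's lipid-to-protein ratio is 1.09 ± 0.11 and
the treated group's 1.26, a +15.9% change in this noisy n = 3 draw (the
preset plants +20.9%; replicate scatter at CV 0.04 makes single draws
wander around that). At n = 3 vs 3 the exact Mann–Whitney p cannot go
below 0.1, so even fully separated groups show p = 0.1. The PO₂⁻
asymmetric band moved from 1234.13 to 1235.45 cm⁻¹ — a +1.3 cm⁻¹ shift
recovered on a 4 cm⁻¹ grid. With `--cv 0 --noise-sd 0` the planted values
are recovered essentially exactly (+20.9%).

DE-table concordance works the same way from files:

```sh
ftirquant overlap --t1 de_condition_a.csv --t2 de_condition_b.csv \
    --alpha 0.05 --out overlap.json
```

The library API mirrors the CLI (`ftirquant.compare_groups`,
`ftirquant.concordance`, `ftirquant.simulate_group_pair`, ...).

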