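# qibrepeat

Repeatability and reproducibility analysis of quantitative imaging
biomarkers — apparent diffusion coefficient (ADC) and Dixon fat fraction
(FF) — measured in focal bone-marrow lesions by manually contoured ROIs.

Whole-body MRI with diffusion weighting is the most sensitive technique for
detecting focal myeloma deposits, and per-lesion ADC and FF statistics are
candidate response biomarkers. Before such measurements can carry clinical
decisions, their measurement error must be known: how much do two ROIs drawn
by the same reader (repeatability) or by two readers (reproducibility)
disagree, and does that disagreement depend on lesion size? `qibrepeat`
implements the full analysis workflow for a two-reader study design — each
subject contributes one small (5–10 mm) and one large (≥10 mm) lesion,
outlined on ADC and FF maps three times (reader 1 twice, reader 2 once) —
plus the synthetic data needed to validate every stage without patient data.

## What it computes

For per-subject differences $d_n$ between two estimates of the same lesion
(intra-reader: reader 1's two replicates; inter-reader: the first estimates
of readers 1 and 2):

- **within-subject SD**
  $s_w = \sqrt{\tfrac{1}{2N}\sum_{n=1}^{N}(d_n-\bar d)^2}$,
- **coefficient of variation** $\mathrm{CoV} = 100\, s_w/\bar x$ with
  $\bar x$ the group mean (mean of each lesion's three estimates, averaged
  over subjects),
- **Bland–Altman limits of agreement** $\pm 1.96\sqrt{2}\, s_w$ (zero-centred),
- **mean difference** with its $t$-based 95% CI,
- **ICC(1)** — one-way random-effects, single-measurement intraclass
  correlation $\frac{\mathrm{MSB}-\mathrm{MSW}}{\mathrm{MSB}+(k-1)\mathrm{MSW}}$
  with an $F$-based CI, banded poor/moderate/good/excellent,
- **Levene's test** (mean-centred) comparing small- vs large-lesion
  difference variances,
- paired $t$-tests of small vs large group means, and the pilot-style sweep
  of the inter-reader difference SD over a lesion-size threshold.

The **Monte Carlo power module** answers the design question: how many
lesions per size group are needed for Levene's test at $\alpha=0.05$ to
detect a within-subject SD ratio of 2 with 80% power.

The **synthetic module** generates (a) measurement tables with configurable
between-subject / intra-reader / inter-reader variance components
(defaults calibrated to a published 22-subject myeloma study) and (b) 2-D
elliptical lesion phantoms — ADC and Dixon fat-only/water-only maps with
$FF = FO/(FO+WO)$, mono-exponential DWI stacks
$S(b) = S_0 e^{-b\cdot ADC}$ — with simulated reader contours (smooth
radial jitter plus a signed boundary offset), so boundary-contamination
biases can be studied mechanistically.

## Worked example

```python
import qibrepeat as q

cfg = q.default_study_config(seed=7)          # 22 subjects, reference calibration
table = q.generate_measurement_table(cfg)     # 264-row measurement table
report = q.analyze_study(table)

for cls in ("small", "large"):
    s = report.summaries[("FF-Mean", "intra", cls)]
    print(f"FF-Mean intra {cls}: sw={s.sw:.2f} CoV={s.cov_percent:.1f}% "
          f"ICC={s.icc:.3f} ({s.icc_band}) LoA=+/-{s.loa_halfwidth:.2f}")
lev = report.levene[("FF-Mean", "intra")]
print(f"Levene small vs large: W={lev.statistic:.2f}, p={lev.p_value:.4f}")

est = q.simulate_power(22, 2.0, n_sim=100_000, seed=7)
print(f"power: {est.power:.3f} (MC SE {est.mc_se:.4f})")
```

prints

```
FF-Mean intra small: sw=2.95 CoV=9.2% ICC=0.972 (excellent) LoA=+/-8.18
FF-Mean intra large: sw=1.12 CoV=7.9% ICC=0.955 (excellent) LoA=+/-3.11
Levene small vs large: W=11.73, p=0.0014
power: 0.800 (MC SE 0.0013)
```

The synthetic study was configured with intra-reader $s_w$ of 3.44
(small) and 1.27 (large) ml/100 ml for the FF mean; the analysis recovers
estimates near those values (2.95 and 1.12 at this seed and $N=22$), and
Levene's test flags the small-lesion variance inflation ($p=0.0014$). The
power line reproduces the design computation: with 22 lesions per group, a
twofold SD ratio is detected with power 0.80.

The same pipeline runs from the shell:

```bash
qibrepeat simulate-table --seed 7 --out table.csv
qibrepeat analyze table.csv --outdir results/
qibrepeat power --n 22 --ratio 2 --nsim 100000 --seed 7 --out power.json
qibrepeat sweep-threshold table.csv --metric FF-Mean --out sweep.csv
```

`analyze` writes the full study grid (`report_grid.csv`, one row per
metric × comparison), a JSON report, and Bland–Altman point sets per
metric × comparison.

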