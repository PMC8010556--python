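# Methods

## Study model

The package models a two-reader, two-size-class lesion measurement study.
Each of $n$ subjects contributes one small and one large lesion; each
lesion is outlined three times per map contrast (ADC and FF): twice by
reader 1 (blinded replicates) and once by reader 2. Six summary metrics
are recorded per ROI — the mean, the pixel SD and the area, on each map —
giving the measurement-table schema
`subject_id,lesion_class,lesion_diameter_mm,map,reader,replicate,roi_mean,roi_sd,roi_area_mm2`.
Units: ADC statistics in 1e-6 mm²/s, FF statistics in ml/100 ml
(fractions × 100), areas in mm².

## Agreement statistics

**Differences.** For a metric and size class, the intra-reader difference
is $d_n = x^{(1,1)}_n - x^{(1,2)}_n$ (reader 1's two replicates) and the
inter-reader difference $d_n = x^{(1,1)}_n - x^{(2,1)}_n$; one difference
per subject.

**Within-subject SD.** $s_w = \sqrt{\frac{1}{2N}\sum_n (d_n - \bar d)^2}$.
The $1/(2N)$ factor halves the difference variance because each difference
carries the noise of two measurements. Algebraically
$s_w = \mathrm{sd}(d)\sqrt{(N-1)/(2N)}$ with the sample ($n-1$) SD; when
$\bar d = 0$ exactly, $s_w^2$ equals the within-subject mean square of the
one-way ANOVA of the paired data — only then, which is why the test suite
asserts the ANOVA equivalence in the $\bar d = 0$ case.

**CoV.** $100\, s_w / \bar x$, where $\bar x$ is the group mean of that
metric and size class, computed as the mean of each lesion's three
estimates averaged over subjects. CoV is invariant under rescaling all
measurements; $s_w$ and the LoA scale linearly.

**Limits of agreement.** $\pm 1.96\sqrt 2\, s_w$, centred at zero: under
no true change, the difference between two measurements falls inside this
interval with 95% probability. Conventional $\bar d$-centred lines are
available via `loa_center_at_zero=False`; the Bland–Altman point sets
carry the centre explicitly.

**Mean difference CI.** $\bar d \pm t_{1-\alpha/2,\,N-1}\,
\mathrm{sd}(d)/\sqrt N$. Published grids rounded from unrounded inputs
cannot be regenerated exactly from printed $s_w$/$\bar d$ under either a
$t$ or a $z$ convention, so CI correctness is asserted structurally
(coverage of the estimate, hand-computed examples), not against printed
values.

**ICC.** One-way random-effects, single measurement (ICC(1)):
$(\mathrm{MSB}-\mathrm{MSW})/(\mathrm{MSB}+(k-1)\mathrm{MSW})$ with $k=2$;
the CI transforms $F$-quantiles of $\mathrm{MSB}/\mathrm{MSW}$ with
degrees of freedom $(n-1,\,n(k-1))$. The exact variant behind published
grids of this kind is often ambiguous; ICC(1) is the most conservative
(it absorbs reader bias into disagreement) and is cross-checked against
`pingouin.intraclass_corr`'s ICC(1,1) to 1e-10 in the tests. Bands use
half-open intervals: ICC < 0.5 poor, [0.5, 0.75) moderate, [0.75, 0.9)
good, ≥ 0.9 excellent. With MSW = 0 (noise-free data and real
between-subject spread) the ICC is 1 with a degenerate CI.

**Levene's test.** Classic mean-centred Levene (the Brown–Forsythe
median-centred variant is available by option): the one-way ANOVA $F$ of
the absolute deviations $z_{ij}=|x_{ij}-\bar x_i|$, $p$ from
$F(k-1, N-k)$. Identical groups give $W=0$, $p=1$; data with all $z$
identical raise a degenerate-statistic error.

**Paired group-mean comparison.** Per-lesion value = mean of its three
estimates; two-sided paired $t$ across subjects. When the paired
differences have zero variance the statistic is undefined and the result
reports $p=1$ with an explicit `zero_variance` flag rather than failing —
the degenerate case arises routinely in noise-free synthetic checks.

**Threshold sweep.** For each candidate size threshold, the SD of the
inter-reader differences below vs at/above the threshold, using the
population (1/n) SD by default (`ddof` switchable; no convention is
standard for pilot sweeps); thresholds leaving fewer than two lesions on
either side are marked not evaluable.

All p-values are two-sided. The full-study report covers the 6 metrics ×
{intra, inter} × {small, large} grid; non-computable cells are marked NaN
/ `not-computable` instead of aborting the report.

## Synthetic measurement tables

Per subject × class × map metric, a true lesion value is drawn with the
configured between-subject mean and SD; estimates add reader noise:

- reader 1, both replicates: truth + $N(0, s_\text{intra})$, so the
  intra-reader $s_w$ estimate converges to the configured value;
- reader 2: truth + $N(0, \sqrt{2 s_\text{inter}^2 - s_\text{intra}^2})$,
  so the *measured* inter-reader $s_w$ — whose difference also contains
  reader 1's noise — converges to the configured $s_\text{inter}$. This
  keeps the configuration in the units the analysis estimates and
  requires $s_\text{inter} \ge s_\text{intra}/\sqrt 2$ (validated; every
  cell of the reference calibration satisfies it).

Truth distributions: Gaussian for the map means; for the positive-support
metrics (areas, pixel SDs) a lognormal moment-matched to the configured
mean and SD. These quantities are right-skewed in practice, and for one
reference cell (large-lesion ADC-SD, between-subject SD ≈ 97 at mean 143)
a truncated Gaussian would shrink the recovered $s_w$ by ~20%; the
lognormal reproduces the configured moments exactly. Estimate noise that
would produce an invalid record (negative SD, non-positive area) is
redrawn from the same stream; the residual distortion is a few percent.
Averaged over 20 seeds at $n=200$, every configured $s_w$ (24 cells) is
recovered within 5%, against the 15% tolerance asserted in the tests.

Defaults (`default_study_config`) are calibrated to the reference study
grid in `qibrepeat.datasets`: printed group means and intra-/inter-reader
$s_w$ per metric and class. The between-subject SD is not printed and is
recovered from the printed intra-reader ICC via
$\sigma_b = s_w\sqrt{\mathrm{ICC}/(1-\mathrm{ICC})}$. Small-lesion
diameters default to 5–10 mm and large to 10–30 mm, drawn uniformly (the
upper large bound is a modelling choice; only the class label enters the
analysis). Seeding is record-wise: every draw derives its stream from the
base seed plus the (subject, class, map, reader, replicate) coordinates,
so tables are bit-reproducible and insensitive to generation order.

## Phantoms and reader contours

Lesions are ellipses (eccentricity default 0) rasterised at 1.0 mm pixel
spacing by default — finer than typical whole-body acquisition (4–5 mm
slices, coarser in-plane), chosen so 5 mm lesions span several pixels;
phantom results characterise the contouring mechanism, not scanner
resolution. ADC maps take lesion/background values (defaults 800e-6 /
400e-6 mm²/s); Dixon FO/WO pairs are synthesised from lesion/background
fat fractions (defaults 0.10 / 0.60 — active lesions replace fatty
marrow) at an arbitrary total signal, with additive Gaussian noise
clipped at zero, and $FF = FO/(FO+WO)$ recomputed from the noisy pair.
Pixels with zero Dixon signal or non-positive DWI signal are NaN and
excluded from ROI statistics (counted separately). ADC fitting is an
unweighted per-pixel log-linear least squares over all b-values (the
scanner's proprietary fit is unknown); negative fitted ADCs are retained
and flagged by sign, not clamped. ROI SD uses the sample ($n-1$)
denominator by default, switchable, since PACS conventions vary.

Reader contours perturb the true boundary radially about the mask
centroid: a signed constant offset (systematic over-/under-inclusion)
plus zero-mean noise band-limited to a few Fourier harmonics (default 4),
with pointwise SD `radial_jitter_sd` in millimetres — absolute, so small
lesions suffer proportionally larger area errors, which is the mechanism
by which the model reproduces the small-lesion FF-mean inflation:
an outward offset admits a high-FF background ring whose area fraction
scales as 1/diameter. Membership is evaluated on the signed Euclidean
distance to the boundary (distance transforms with a half-pixel centring
correction), so a zero perturbation returns the true mask exactly and a
−1 mm offset on a 10 mm disc shrinks the area to ≈ 0.64 of the original
(within one perimeter ring of discretisation).

## Monte Carlo power

Per replicate, one group of $n$ differences is drawn from $N(0,1)$ and one
from $N(0,r)$ (scale-free), and mean-centred Levene at $\alpha$ is applied;
power is the rejection fraction, with Monte Carlo standard error
$\sqrt{p(1-p)/n_\text{sim}}$. The statistic is evaluated vectorised over
replicates, so the reference computation (100,000 replicates, $n=22$,
$r=2$) runs in seconds and yields power ≈ 0.80. Group pairing (the same
subjects contribute both lesions) is deliberately ignored — Levene's test
is an independent-groups test and is applied that way to the real data.
The difference distribution is normal by default with a Laplace option
for tail-sensitivity checks. `required_sample_size` scans a range of $n$
with per-$n$ derived seeds and returns the smallest $n$ reaching the
target power together with the full curve; Monte Carlo noise can make the
raw curve locally non-monotone, which tests handle by comparing against
an isotonic projection.

## What the synthetic data does and does not show

The generators reproduce the variance structure the analysis estimates
(between-subject spread, intra-/inter-reader noise), the class-dependent
group means, and — via the phantoms — boundary-driven size effects. They
do not model Rician magnitude noise, 3-D partial-volume effects,
irregular lesion shapes, reader-specific systematic bias, or the
T1-weighting bias of high-flip-angle Dixon FF estimates. Passing tests
therefore validate the statistical pipeline and the direction of
boundary-contamination effects, not scanner-level accuracy of ADC or FF.

## Problem sizes and numerical choices

Test-suite simulations use 20 seeds × 200 subjects for parameter
recovery, 100 seeds × 22 subjects for the ratio-recovery check, 10,000
replicates for type-I calibration and 100,000 for the power computation —
sizes at which Monte Carlo error is small against the asserted
tolerances. Ties at ICC band boundaries resolve to the higher band
(half-open intervals). Degenerate inputs (constant data, empty ROIs,
lesions outside the grid, contour perturbations that empty the mask)
raise typed errors named in `qibrepeat.exceptions`.
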