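# Methods

This document describes the scientific methods implemented in `nirtransfer`
and the design decisions behind them. Notation: the master instrument
measures spectra $R_m$ (samples × wavelengths) on grid $\lambda_m$, the
slave instrument measures $R_s$ on grid $\lambda_s$; $y$ is the vector of
reference analyte values (e.g. soluble solids content, %Brix).

## 1. The calibration-transfer problem

A multivariate calibration model maps an absorbance spectrum to an analyte
value. The model is tied to the instrument it was trained on: a second
instrument with a different wavelength grid, optical resolution, detector
gain, and baseline produces spectra the model has never seen, and
predictions collapse (in the default synthetic scenario, cross-instrument
R² drops from ~0.98 to ~0). Re-measuring hundreds of reference samples on
every new instrument is expensive; calibration transfer instead measures a
small set of *standardization samples* on both instruments and learns a map
from slave spectra to master-equivalent spectra, after which the original
master model is reused unchanged.

## 2. Preprocessing

- **Moving average** smoothing with window $w$: truncated (shrinking)
  windows at the edges rather than reflection or zero padding, so no
  out-of-range absorbance is fabricated. Even windows are centered with the
  extra point on the left.
- **Standard normal variate (SNV)**: each spectrum is centered by its own
  mean and scaled by its own standard deviation, removing multiplicative
  scatter and additive offsets per sample.
- **Mean normalization**: each spectrum divided by its mean absorbance.

Steps compose through an ordered, serializable `PreprocessPlan`; master and
slave instruments can use different plans (smoothing windows should scale
with each instrument's channel spacing: the defaults use a 3-point window
on the 1 nm master grid and an 18-point window on the finer interpolated
slave data).

## 3. Sample selection (Kennard-Stone)

Kennard-Stone picks a maximin-diverse subset in spectral space: start from
the two most distant samples, then repeatedly add the sample whose minimum
Euclidean distance to the already-selected set is largest (ties broken by
lowest index). It is deterministic and invariant to row order up to the tie
rule. `ks_split` uses it to carve a representative calibration set (the
remainder is the prediction set), and `select_standardization` to pick the
standardization samples from the calibration set.

## 4. Regression

### PLS1 (NIPALS)

Univariate partial least squares via NIPALS with deflation, returning the
nested coefficient vectors for 1..A components; with all components the
coefficients coincide with the ordinary-least-squares solution (tested to
1e-6). The component count is chosen by cross-validated PRESS with a
*first-local-minimum* rule: the smallest $a$ whose PRESS is lower than both
neighbours, falling back to the global minimum when the curve is monotone.
This guards against the late shallow minima that pure argmin tends to pick.

### LS-SVM (RBF kernel)

Least-squares support vector regression with kernel
$\Omega_{kl} = \exp(-\lVert x_k - x_l\rVert^2 / \sigma^2)$, solved from the
bordered dual system

$$\begin{bmatrix} 0 & \mathbf{1}^\top \\ \mathbf{1} & \Omega + I/\gamma \end{bmatrix}
\begin{bmatrix} b \\ \alpha \end{bmatrix} =
\begin{bmatrix} 0 \\ y \end{bmatrix}.$$

Hyperparameters $(\gamma, \sigma^2)$ are tuned by exhaustive leave-one-out
cross-validation on log grids ($\gamma \in 10^{0..6}$,
$\sigma^2 \in 10^{-1..5}$) using the closed form
$e_i = \alpha_i / (A^{-1})_{i+1,i+1}$, which equals brute-force
leave-one-out refitting (tested to 1e-8) at a fraction of the cost.

## 5. Transfer methods

### Piecewise direct standardization (PDS)

For every master channel $i$, regress the master standards' column $i$ on
the slave standards' window of columns $[i-h,\, i+h]$ (half-width $h$)
using a small window PLS (default 2 components, clipped to the window
size). The window coefficient vectors are assembled into a banded
transformation matrix $F$, so transferred spectra are $R_s F$.

Each window regression is fit on centered data and the fitted intercept is
kept as a per-channel additive correction
$b_i = \bar{y}_i - \bar{x}_i^\top \beta_i$: SNV-preprocessed instruments
can still differ by a fixed additive pattern that a purely multiplicative
$F$ cannot absorb. On an identical master/slave pair with $h = 0$ the
procedure still returns $F = I$ and all intercepts exactly zero, so the
identity case is preserved bit-for-bit.

The half-width can be fixed or searched (`half_width="auto"`): each
candidate is scored by RMSEP of the transferred prediction set and the best
is kept.

### Linear interpolation-PDS (headline method)

PDS needs the two instruments on a common grid. When the grids differ
(e.g. a Fourier-transform instrument on an uneven wavenumber-derived grid
vs. a 1 nm grating grid), the slave spectra are first resampled onto the
master grid by two-point linear interpolation: for a query wavelength $c$
bracketed by adjacent slave wavelengths $i < c \le j$,

$$\hat{y}_c = \text{Slope}_c \cdot c + b_c, \qquad
\text{Slope}_c = \frac{y_j - y_i}{j - i},$$

i.e. the chord through the bracketing points. Queries that hit a slave
node exactly return that node's value bit-for-bit, and affine spectra are
reproduced exactly at any query. PDS is then built in master-grid space.
The fitted `TransferModel` records the interpolation map, so it consumes
raw slave spectra directly.

### Common-wavelengths-reserved-PDS (baseline)

Instead of interpolating, keep only the wavelengths the two grids share
(within a tolerance, default 0.1 nm) via greedy nearest-first one-to-one
matching, and run PDS in that reduced space. The master model must be
retrained on the matched channels. This baseline discards every master
channel without a close slave counterpart — on realistic grid pairs the
matched set is sparse and has wide gaps, so analyte-informative regions
falling inside the gaps are lost, which is why it trails interpolation-PDS.

### Protocol variants

After transfer the standardization samples can be *kept* in the master
calibration set (their master spectra are ordinary calibration spectra) or
*removed* from it. Both variants are implemented; the sweep utilities score
them side by side, and keeping the standards is typically not worse.

## 6. Evaluation and method comparison

- **R², RMSE (RMSEC/RMSEP by context), RPD** = SD(reference of the
  evaluated set) / RMSE.
- **SEL** (standard error of laboratory) from replicate reference
  measurements: $\text{SEL} = \sqrt{\sum_{\text{samples}}\sum_{\text{reps}}
  (y_r - \bar{y})^2 / N}$ with $N$ the number of usable samples (rows with
  ≥2 finite replicates). It is the noise floor of the reference method; a
  model RMSEP near the SEL cannot be meaningfully improved.
- **Passing-Bablok regression** (1983 procedure) for nonparametric method
  agreement, robust to error in both variables: the slope is the shifted
  median of all pairwise slopes $S_{ij} = (y_j - y_i)/(x_j - x_i)$, with
  offset $K$ = number of slopes < −1; 95% CIs come from rank bounds with
  variance $n(n-1)(2n+5)/18$; the intercept is
  $\text{median}(y - \text{slope}\cdot x)$ with CI endpoints from the slope
  CI. $H_0$ (methods agree) is accepted iff the slope CI contains 1 *and*
  the intercept CI contains 0. `choose_master` uses this to pick a master
  instrument: the accepted candidate whose slope is closest to 1.

## 7. Synthetic paired-instrument data

No public dual-instrument grape dataset exists, so the package ships a
seeded generator that makes every stage testable end to end.

**Physics-style forward model.** Each sample gets a reference value from a
truncated normal (mean 19.1, SD 2.0, range 12.9–23.2 %Brix, matching
typical grape SSC statistics). A clean absorbance spectrum on a dense
internal grid is the sum of (i) a smooth background with a gentle slope,
(ii) Gaussian analyte bands whose amplitudes scale with the reference value
— including a mild quadratic (Beer-Lambert deviation) term so the
concentration–absorbance relation is not perfectly linear, (iii) random-
amplitude interferent bands, and (iv) multiplicative/additive scatter.
Band positions sit in the physically sensible 1000–1800 nm overtone
region (e.g. 1050, 1185, 1450 nm water/sugar features).

**Instrument model.** `measure` applies, in order: wavelength shift,
Gaussian resolution blur (FWHM), linear resampling to the instrument grid,
wavelength-dependent detector response (tilt/curvature), gain, baseline,
and i.i.d. noise. The default master is a grating instrument (1000–1800 nm
at 1 nm); the default slave is an FT-style instrument specified on an even
wavenumber grid (4 cm⁻¹ steps), which converts to an *uneven* nm grid that
shares almost no exact wavelengths with the master — the situation
interpolation-PDS exists for. Master and slave measure the *same*
underlying samples (shared compositional draws), differing only in
instrument effects and noise.

**Why the defaults look the way they do.** The default scenario is
deliberately calibrated so the qualitative regime matches real
cross-instrument transfer: the distortions (shift 3 nm, gain 1.25,
baseline, response curvature, coarser blur) are strong enough that the
untransferred slave is useless (R² < 0.3) yet smooth enough that
interpolation-PDS recovers to within 0.1 of the master R². Several narrow
analyte bands are placed where the two grids have no common wavelengths
within 0.1 nm, so the common-wavelengths baseline structurally loses
analyte information and lands between the other two routes — the ordering
R²(interp-PDS) > R²(common-PDS) > R²(untransferred) is a property of the
scenario's design, not of one lucky seed (it holds across seeds 0–9).

## 8. Pipeline and reproducibility

`ExperimentConfig` (constructor or YAML) fixes data source or simulation
seed, per-instrument preprocessing, split sizes (default 700 samples,
550/150 Kennard-Stone split, 45 standardization samples), model type and
grids, transfer method and half-width search. Given the same config and
seed, `run_experiment`, `compare_methods`, and `sweep_standardization`
are bit-reproducible. `scripts/acceptance.py --seed N --out results.json`
runs the full battery and writes every headline quantity as JSON.
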