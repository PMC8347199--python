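# Methods

`hypospec` re-creates, on synthetic data, a chemometric workflow for
discriminating Raman micro-spectroscopy maps of hypothalamic
arcuate–median eminence (Arc-ME) tissue from control (CTRL) and
high-fat-diet (HFD) mice. Because no raw spectra from such studies are
publicly deposited, the package pairs each analysis stage with a generator
that encodes the reported band-level biochemistry as ground truth, so every
claim the pipeline makes can be checked against what was put in.

## Synthetic spectrum model

A spectrum on wavenumber axis $\nu$ is

$$ y(\nu) = \sum_k A_k m_k(c) \, L(\nu - \nu_k; \Gamma_k) + P_5(\nu) + \varepsilon(\nu), $$

where $L$ is a unit-height Lorentzian with FWHM $\Gamma_k$ (default
12 cm⁻¹, a typical condensed-phase Raman width), $A_k$ the base amplitude
of band $k$, $m_k(c)$ its class multiplier, $P_5$ a map-level 5th-order
polynomial fluorescence background, and $\varepsilon \sim
\mathcal N(0, \sigma^2/E)$ exposure-averaged Gaussian noise (default
$\sigma = 0.6$ intensity units, $E = 30$ exposures, i.e. an effective
noise SD of ≈0.11 against band heights of 0.1–3).

The channel axis defaults to 3180 channels covering 200–3400 cm⁻¹ with
spacing $3200/3180 \approx 1.0063$ cm⁻¹ (left-edge sampling, as
spectrometer channel grids are laid out). With this spacing the channel
nearest each library band rounds to the band's nominal integer position,
so detected peak positions can be compared against the nominal values
exactly.

### Band library

The default library holds 18 bands: glycogen (484, 858, 1460 cm⁻¹),
collagen amino-acid and amide modes (747, 1007, 1105, 1127, 1172,
amide III at 1260 representing the 1240–1280 range, amide I at 1661),
lipid CH₂ bending (1444), amide I / C=C lipid stretch (1655), the
triacylglycerol ester carbonyl (1748), the silent-zone cyanide stretch
(2248), C–H stretches (2850, 2878, 2930) and the unsaturation marker
=C–H at 3000. Class multipliers encode the contrast of the study system:
HFD above CTRL for the glycogen, collagen, carbonyl and cyanide bands,
CTRL above HFD at 3000, and no difference at 2850/2878/2930.

The amide-I band at 1661 is deliberately given a modest base amplitude
(0.5): its Lorentzian wing overlaps the 1655 band, and because band
"intensity" is defined as the maximum within a ±10 cm⁻¹ window, a strong
1661 neighbour would shift the window maximum between the two peaks and
distort the measured ratio even without noise.

### The 1655/1444 saturation ratio

The 1655/1444 height ratio is a lipid unsaturation index (lower = more
saturated lipid); the generator encodes 0.88 for CTRL and 0.55 for HFD.
Because 1444/1460 and 1655/1661 overlap within a linewidth, the 1444 and
1655 amplitudes cannot be assigned naively. For each class the two
amplitudes are solved from the 2×2 linear system requiring that the *net*
analytic heights at exactly 1444 and 1655 cm⁻¹ — including all other
bands' wings — equal a chosen 1444 height (2.0 CTRL, 3.0 HFD; HFD lipid
bands are stronger) and the target ratio times it. The noiseless profile
therefore reproduces the ratios to machine precision, which is asserted to
1e-6 in the tests.

### Background and map structure

Each map draws one random 5th-order polynomial, affinely rescaled so its
trough sits at 0.5–1.5× and its peak-to-trough span at 5–20× the tallest
band. The background therefore always dominates the signal, which is what
makes the two-stage baseline correction a real part of the problem rather
than a formality. Spectra within a map share the background (the map-level
correlation real mosaics show); each map is assigned to its own animal.
The default layout is 4 maps per class of 1000 spectra on a 25 µm raster;
an ROI fraction below 1 keeps a random subset per map (largest-remainder
allocation, so 8×1000 at fraction 7409/8000 keeps exactly 7409 spectra,
reproducing the emulated study's matrix of 7409 × 3180).

What the generator does **not** emulate: shot (intensity-dependent) noise,
cosmic-ray spikes, wavenumber miscalibration, instrument response, spatial
structure within a map beyond the shared background, and within-class
biological variability of band amplitudes. Passing tests therefore show
that the pipeline recovers the encoded contrasts through a dominating
background and i.i.d. noise — not that it is robust to all artifacts of
real acquisitions.

## Preprocessing

1. **Modified polyfit** (order 5): fit a polynomial, clip the working
   signal to the pointwise minimum of signal and fit, refit; stop when the
   fit changes by < 1e-4 (relative sup norm) or after 100 iterations. This
   removes the gross fluorescence. The polynomial basis is evaluated on a
   [-1, 1]-scaled axis and solved through a pseudo-inverse for
   conditioning. Note that only the *clipped signal* is guaranteed
   pointwise non-increasing across iterations; the fitted polynomial
   itself may locally rise, which is inherent to least squares.
2. **Asymmetric least squares** (λ = 1e5, p = 0.001, 10 reweighting
   iterations, second-difference penalty): removes residual slowly-varying
   baseline and smooths. The system $(W + \lambda D^\top D) z = W y$ is
   pentadiagonal and solved with a banded Cholesky routine, so cost is
   linear in channel count. Iteration count is fixed (no convergence
   test), matching common practice. On noisy flat regions the estimated
   baseline sits near the lower noise envelope, so corrected spectra carry
   a small positive offset (~2 noise SD); this is common-mode between
   classes and is the main reason recovered ratios sit ~0.02–0.03 above
   their encoded values.
3. **Region selection**: keep 500–1800 cm⁻¹ (fingerprint) and
   2100–3100 cm⁻¹ (high-wavenumber + silent zone), closed intervals,
   membership by wavenumber value. The retained blocks are tracked as
   segments.
4. **Unit-area normalization**: each spectrum is divided by its
   trapezoidal integral computed piecewise over the retained segments
   (never bridging the 1800–2100 gap). Normalization happens after
   cropping — the only self-consistent reading when the analyzed matrix is
   the cropped one.
5. **Mean centering**: column means computed on training rows only and
   applied to all rows; the mean vector is persisted with the model.

Band-level analytics (class averages, peak detection, the saturation
ratio) are computed on the baseline-corrected but *uncropped* spectra:
the ratio is invariant under the positive rescaling that normalization
applies, and the 484 cm⁻¹ glycogen band lies below the 500 cm⁻¹ crop.

## Duplex splitting

The duplex algorithm partitions each class deterministically: the two
mutually farthest spectra (full-spectrum Euclidean distance on the
preprocessed matrix) seed the training set, the two farthest remaining
seed the test set, and remaining spectra are assigned alternately, each
time the one with the largest minimum distance to the set being grown;
once the test set reaches its quota the remainder goes to training. Ties
break toward the lowest row index. The default training fraction is
5600/7409 ≈ 0.756, the emulated study's realized split; per-class training
counts are round(fraction × class size) since only the totals are known.

## PLS-DA

Class membership is dummy-coded HFD = 1, CTRL = 0, so a positive
regression coefficient means "higher in HFD" (matching the usual
red/positive display convention). The PLS1 core is NIPALS: per component
$w = X^\top y / \lVert X^\top y\rVert$, $t = Xw$, $p = X^\top t / t^\top t$,
$q = y^\top t / t^\top t$, deflate $X \leftarrow X - t p^\top$. The
response is not deflated — for a univariate response predictions are
identical either way. The regression vector is
$b = W (P^\top W)^{-1} q$; because $P^\top W$ is upper triangular for
NIPALS PLS1, truncating components and truncating $b$ agree, which the
cross-validation exploits to score all model sizes from one fit per fold.

A sample is classified HFD iff $\hat y > 0.5$ (strict inequality). Model
complexity is chosen by stratified 10-fold cross-validation (rows shuffled
once within class by a fixed seed, dealt round-robin; per-fold
recentering so no leakage), maximizing overall CV accuracy with ties to
the smallest model. Map- or animal-grouped folds are available as an
option but are not the default, and no fidelity claim is attached to them.

Variable importance in projection is

$$ \mathrm{VIP}_j = \sqrt{ J \sum_a \mathrm{SSY}_a (w_{ja}/\lVert w_a \rVert)^2 \Big/ \sum_a \mathrm{SSY}_a }, \qquad \mathrm{SSY}_a = q_a^2 \, t_a^\top t_a, $$

whose squared values average to exactly 1 over the $J$ channels (asserted
in the tests). Channels with VIP > 1 are flagged; contiguous flagged
channels merge into discriminant regions labeled by the sign of the mean
regression coefficient inside the region (positive → HFD-higher).

## Numerical and design notes

- All randomness flows from explicit seeds (generator seed, CV seed); a
  run with fixed seeds is bit-reproducible, and the run report contains no
  wall-clock information for that reason.
- On degenerate inputs (e.g. noiseless data of rank 1) NIPALS stops when
  the residual covariance vanishes; cross-validation truncates gracefully,
  direct fits raise unless truncation is requested.
- Duplex is O(n²) in distances; at the default scales (≤2000 rows per
  class) distances are computed blockwise against running minimum-distance
  arrays rather than storing a full matrix.
- Peak detection uses strict-neighbour local maxima with a prominence
  threshold expressed as a fraction of the window maximum; positions are
  reported as nearest-integer wavenumbers, matching how bands are labeled
  on published spectra. The 3000 cm⁻¹ band sits exactly between two
  channels of the default grid and therefore reads 2999 — intrinsic
  quantization, not a detection error.
- Default problem sizes in the analysis scripts and acceptance runs
  (1000 spectra per class for band analytics, 2000 per class for
  classification) are the package's chosen desk scale: large enough that
  class-average noise is negligible and the duplex/CV machinery runs at
  realistic dimensionality, small enough to iterate on comfortably.

## Known limitations

- The AsLS lower-envelope offset biases recovered band heights slightly
  upward; ratios inherit a ~+0.03 bias at the default noise level. The
  tolerance on ratio recovery (±0.05) absorbs this; applications needing
  unbiased heights should model the offset or lower `p` further.
- Class separation in the default system is strong: held-out accuracy is
  near 100%, comfortably above the 90% floor the acceptance run checks,
  so the classifier is not exercised near its decision boundary.
- The generator's within-class variability is noise plus per-map
  background only; real tissue maps vary biologically per animal, which
  would lower accuracy and raise the selected model complexity.
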