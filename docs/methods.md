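# Methods

`deepesi` implements an envelope-correlation analysis that asks whether
scalp EEG source imaging can detect and localize electrophysiological
activity generated in deep brain structures, using simultaneously recorded
intracranial signals as ground truth. Because the corresponding patient
recordings are not publicly distributable, the package ships a fully
specified synthetic forward simulator, and every stage of the analysis is
validated by parameter recovery on simulated sessions.

## The analysis

**Signal model.** During eyes-closed rest, both cortex and deep nuclei
(thalamus, nucleus accumbens) express alpha oscillations at the same
individual peak frequency (8–10 Hz). The quantity that distinguishes a
specific deep generator from the cortical alpha background is not the
oscillation itself but its *amplitude envelope*: envelope fluctuations on
the scale of seconds are source-specific. The analysis therefore:

1. re-references scalp EEG to the common average and intracranial lead
   contacts to bipolar derivations (adjacent-contact differences, deeper
   minus shallower, which cancel far-field common-mode signals);
2. finds the individual alpha peak in the Welch power spectrum and
   band-passes all signals to peak ± 1 Hz. A clear spectral peak above the
   1/f background is a prerequisite: channels (and sessions) without one
   are excluded rather than analyzed;
3. computes the analytic signal per sensor (Hilbert transform), applies a
   distributed linear inverse separately to the real and imaginary parts,
   takes the complex magnitude per Cartesian component at each solution
   point, and combines x/y/z by the Euclidean norm — yielding a
   nonnegative alpha-envelope time course at every point of a volumetric
   source grid;
4. thresholds the envelope field at its spatial mean at every time frame
   (points below the frame mean are zeroed) to limit spatial leakage;
5. correlates the intracranial bipolar alpha envelope with the
   reconstructed envelope at every solution point (Pearson, zero lag;
   negative values are set to zero since they can stem from the
   thresholding step);
6. assesses significance with a max-statistic permutation test: the
   reference envelope is circularly shifted by random lags, the map-wide
   maximum correlation is recorded per permutation, and observed values
   above the (1 − α) quantile of the maxima are significant. This controls
   the family-wise error over the whole solution space. Lags with circular
   distance ≤ 2 s from zero are excluded because alpha envelopes are
   autocorrelated on that scale;
7. reports the Euclidean distance from the true contact position to the
   correlation maximum of the closest significant cluster (26-connected
   components on the source grid), the min–max contact distance over that
   cluster, correlation-vs-distance profiles, cross-correlation lag
   curves, and the stability of the map across non-overlapping analysis
   windows.

## Forward model

A realistic, MRI-derived head model is not reproducible at desk scale, so
the forward model is an analytic 3-shell concentric sphere (brain 80 mm,
skull 85 mm, scalp 92 mm; conductivities 0.33 S/m for brain and scalp with
a skull 25× more resistive — both the radii and the ratio are
configurable). Dipole potentials are computed from the Legendre-series
solution of Laplace's equation: per spherical-harmonic degree the radial
transfer through the shells is obtained by solving the 5×5 linear system
given by continuity of potential and radial current at the interfaces and
zero flux at the scalp. The series is truncated adaptively at a relative
term magnitude of 1e-10 (cap 200 terms); for the deepest sources a few
dozen terms suffice. In the equal-conductivity limit the series matches
the closed-form homogeneous-sphere solution to machine precision, and both
radial and tangential terms are pinned independently against
finite-difference pairs of the classical point-source-in-sphere closed
form (which carries no orientation convention). The lead-field container
accepts any externally supplied gain matrix, so a BEM/FEM model can be
substituted without touching the rest of the pipeline.

The source space is a regular 3-D grid clipped to the brain shell
(default target ≈ 5000 points, realized within 20%), which always includes
deep, low-eccentricity locations.

## Inverse operator

The inverse is the weighted-minimum-norm family with a local
autoregressive spatial prior:

    G = M⁻¹ Lᵀ (L M⁻¹ Lᵀ + λC)⁻¹,   M = (DA)ᵀ(DA),  C = I

where A = I − cW penalizes, per point and Cartesian component, deviation
from the inverse-distance-weighted average of grid neighbours
(26-neighbourhood within 1.05·√3·spacing; weights ∝ d⁻², coupling
c = 0.95 < 1 keeps the prior proper), and D is an optional depth
weighting. Orientations are free; the three components couple only
through the spatial prior. With the neighbour coupling and depth
weighting off, G reduces *exactly* to the classical Tikhonov minimum-norm
operator — an identity the tests assert to 1e-10.

**Depth weighting (γ).** Minimum-norm-family inverses assign
systematically small amplitudes to deep points. That bias interacts
destructively with the per-frame spatial threshold: deep points fall
below the frame mean in nearly every frame, their envelopes are zeroed,
and the correlation map peaks tens of millimetres too superficially. Two
compensations are implemented. Weighting by lead-field column norm,
D_jj = (‖L_j‖/max‖L‖)^γ, is the textbook choice but interacts badly with
a one-sided sensor cap: points below the covered region have the
smallest gains, get amplified the most, and drag correlation maxima
downward. The default is therefore a rotationally symmetric *radial*
basis, D_jj = ((r_j + c)/(r_max + c))^γ with r_j the point's distance
from the head centre and c = 10 mm a softening constant, which
compensates the radial amplitude bias without favouring uncovered
regions. With γ = 2 (radial) the validation suite recovers deep sources
to within 25 mm (median ≈ 13 mm across sessions). γ defaults to 0 in
`build_laura_operator` (the plain autoregressive metric) and to 2 radial
in the pipeline preset; the basis, exponent and the held-out-seed grid
over (γ, λ) used to fix them are the package's own convention, since the
cited inverse family's exact weights are not published.

**Regularization (λ).** Two policies are provided, both deterministic.
`lam="auto"` selects λ by generalized cross-validation; exact-zero
eigendirections of K = LM⁻¹Lᵀ (the average-reference null space) are
excluded from the GCV functional, because they carry no data by
construction and would otherwise make λ → 0 look like a perfect fit. GCV
should be driven by broadband data: after narrow-band filtering, the
sensor noise floor inside the passband is nearly invisible and GCV
under-regularizes — the pipeline therefore passes the broadband record to
GCV when `lam="auto"`. The pipeline preset instead fixes
λ = 1e-4 × mean positive eigenvalue of K, which on synthetic sessions is
robust across the SNR range studied.

## Envelope imaging rates

Inversion, magnitude and the per-frame threshold act framewise, so
retaining every k-th frame commutes exactly with those steps. The complex
analytic signal of a 2-Hz-wide band is representable far below the
recording rate, so envelopes are subsampled to 25 Hz before inversion —
this is an exact reordering, not an approximation, and makes the
permutation stage (10⁴ map-wide maxima by default) cheap. A full-rate mode
(`envelope_fs=None`) is available. The first and last 2/bandwidth seconds
(1 s for a 2-Hz band), and the same margin around concatenation seams, are
flagged and excluded from all correlation statistics (filter and Hilbert
edge transients).

## Permutation details

Circular shifting (wrap-around) preserves the sample count and the
marginal distribution of the reference per permutation. Admissible lags
are the integers whose circular distance from zero — and from every
concatenation-seam offset — exceeds `min_lag_s` (default 2 s); draws are
uniform with replacement. The significance threshold is the empirical
order-statistic quantile with upper interpolation
(`numpy.quantile(..., method="higher")`), and a point is significant iff
its correlation strictly exceeds it. The per-frame spatial threshold is
applied once to the field; permutations shift only the reference, which
leaves the field unchanged. An exhaustive mode evaluates every admissible
lag exactly once and is tested against brute-force enumeration.

## Synthetic sessions

The generator emulates the statistical structure the analysis assumes, not
anatomical realism (no cortical folding, no individual anatomy, no
eye/muscle or stimulation artifacts):

* **Envelopes** are exponentiated Ornstein–Uhlenbeck processes:
  a unit-variance AR(1) Gaussian latent with autocorrelation time
  `envelope_timescale` (default 2 s, i.e. "dynamics on the scale of
  seconds") through exp(σx) with σ = 0.4 (≈ 40% modulation depth,
  lognormal amplitudes). The closed form
  corr(y₁,y₂) = (e^{σ²ρ} − 1)/(e^{σ²} − 1) is inverted to calibrate
  latent mixing weights, so target envelope correlations are achieved
  exactly in expectation.
* **Deep sources**: one per hemisphere at (±22, −12, 8) mm (eccentricity
  ≈ 0.33 of the brain radius, thalamic/accumbens-like depth), amplitude
  envelopes correlated across hemispheres at `interhemi_rho` (default
  0.6, mirroring the interhemispheric envelope correlation seen in deep
  recordings), independent carrier phases at the common alpha peak
  (default 9 Hz).
* **Cortical background**: `n_cortical_sources` (default 8) sources on a
  shell at 0.87 of the brain radius under the sensor cap, envelopes
  loosely coupled to the deep pair (`cortico_deep_rho`, default 0.3),
  independent phases.
* **Scalp**: potentials through the 3-shell model, vertex-referenced, plus
  white sensor noise (default 1 µV SD). Sensors are a deterministic
  Fibonacci covering of the upper ~2.6π sr cap — geodesic-net-like
  coverage without claiming any commercial montage's coordinates.
* **Intracranial leads**: four collinear contacts per hemisphere along a
  straight trajectory from a parietal entry to the deep target (spacing
  1.5 mm by default), each recording the local deep source scaled by
  1/(1 + d) with d the contact–source distance, referenced to a
  mastoid-like scalp potential (a genuine common mode for the bipolar
  stage to reject), plus independent contact noise (default 2 µV SD).
  No published intracranial forward model exists for this geometry; the
  1/(1 + d) pickup is a deliberate minimal choice.
* **Deep-source scalp SNR** is the one quantity real data do not pin
  down, and it is exposed as a free parameter (`deep_moment`). The
  default, 120 nA·m (≈ 9 µV deep contribution at the scalp against
  ≈ 2.7 µV of cortical alpha and 1 µV noise), is the "adequate SNR"
  regime in which the pipeline's localization errors match the order
  reported for real subcortical recordings; silencing the source
  (`deep_moment=0`) is the negative control.

What passing tests on these sessions shows: the full chain — referencing,
band selection, Hilbert envelopes, inversion, thresholding, correlation
and FWE-controlled inference — recovers deep bilateral sources to within
~25 mm and controls false positives at the nominal level *under the
model's assumptions*. What it does not show: robustness to realistic
artifacts, non-spherical anatomy, or envelope dynamics outside the
lognormal-OU family.

## Study scales and numerical choices

Validation presets (chosen as the package's study conditions): 128
sensors, ~1500 solution points, 250 Hz, 300-s sessions and 1000
permutations for parameter recovery; 64 sensors, ~500 points, 240 s and
500 permutations for the 100-session false-positive calibration and the
negative controls. Welch spectra use 2-s Hamming windows with 50% overlap;
the alpha peak is the most prominent local maximum ≥ 3 dB above a log–log
linear 1/f fit within 7–13 Hz (the scalp peak is taken from the
posterior-channel average; each intracranial bipolar channel uses its own
peak). The band-pass is a 4th-order zero-phase Butterworth (forward–
backward). Ties at exactly the frame mean are kept by the spatial
threshold. Degenerate correlation inputs (constant series) yield r = 0
with a logged count rather than NaNs.

## Known limitations

* The spherical head model shifts absolute localization errors relative
  to realistic-geometry inverses; the numbers produced here are
  order-of-magnitude comparable, not subject-level predictions.
* Depth weighting trades instantaneous point-spread fidelity (best with
  no weighting) against envelope-correlation depth recovery; the preset
  optimizes the latter, which is the pipeline's target quantity.
* GCV is unreliable for narrow-band data (see above); prefer the relative
  fixed λ unless inverting broadband records.
* The lag-permutation null assumes envelope stationarity across shifts;
  strongly non-stationary references would need segment-aware surrogates.
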