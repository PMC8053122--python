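# Methods

`dropletkd` quantifies the recruitment of a fluorescently labelled,
pH-switchable DNA motif ("switch", a triplex-forming strand, tsDNA) to the
periphery of water-in-oil droplets functionalized with a cholesterol-tagged
single-stranded DNA handle (ssDNA).  This note documents the models, the
numerical choices, and what the synthetic-data tests do and do not
demonstrate.

## Surface-binding equilibrium

Binding is confined to a thin reaction layer of apparent thickness
&epsilon; at the droplet surface (radius r&#8320;).  With S_tot the handle
concentration referenced to the layer volume, T_tot the total switch
concentration per droplet volume, T_eq the free switch concentration at
steady state and K_D = k_off/k_on the apparent dissociation constant, the
peripheral-to-inner per-area intensity ratio is

    I_peri / I_in = 1 + S_tot / (T_eq + K_D).

Mass-action equilibrium, C_eq = S_tot T_eq / (K_D + T_eq), combined with
conservation of the switch amount per droplet, T_tot = T_eq + g C_eq with
the thin-shell volume fraction g = 3&epsilon;/r&#8320;, gives a quadratic
whose non-negative root is T_eq.  We evaluate it in the cancellation-free
form (2 T_tot K_D)/(b + sqrt(b&sup2; + 4 T_tot K_D)) when
b = g S_tot + K_D − T_tot > 0, so the residuals stay at relative 1e-9 even
when T_tot ≪ g S_tot.

**Reference volume of S_tot.**  The two equations above are mutually
consistent only if S_tot is referenced to the reaction-layer volume; a
bulk-prepared handle concentration (as pipetted, e.g. 1.66 uM) converts by
the factor r&#8320;/(3&epsilon;) (`bulk_to_layer`).  The imaging pipeline
performs this conversion per droplet using the measured radius and rim
thickness.

**Inversion.**  `invert_kd` solves predict_ratio(K_D) = ratio by Brent
bracketing on K_D in [1e-6, 1e6] uM with a bisection fallback; the
algebraic closed form K_D = u(u + gS_tot − T_tot)/(u + gS_tot),
u = S_tot/(ratio − 1), serves as a cross-check and as the fallback outside
the bracket.  A measured ratio ≤ 1 carries no binding information and is
returned as an "unbound" sentinel (K_D effectively infinite); a ratio above
the K_D = 0 maximum is physically inconsistent and raises a diagnostic.

**Uncertainty.**  sigma(K_D) is first-order propagation over
{I_peri, I_in, r&#8320;, &epsilon;} with independent Gaussian errors and
central finite-difference partials (relative step 1e-6).  The acceptance
suite verifies agreement with a 1e5-draw Monte-Carlo propagation within 5%
at 5% input noise.  No covariance between I_in and I_peri is modelled.

## Image quantification

The quantifier mirrors the standard macro for this assay: droplets are
detected by Otsu thresholding, hole filling (a bright rim around a dimmer
interior would otherwise be segmented as an annulus), and a watershed on
the distance transform so tangent droplets separate; each region becomes a
circular ROI with its centroid and equivalent-area radius.  Selection keeps
droplets of 40–50 um diameter without touching neighbours.  I_in is the
pixel mean inside radius 0.5 r&#8320;; I_peri is the mean of per-line maxima
along 20 radial segments every 18°, each of half-length 0.25 r&#8320;,
sampled bilinearly at 0.5 px steps.  The line half-length and interpolation
order are package defaults; the macro they mirror does not specify them.

**Rim thickness.**  The default estimator fits the angularly averaged
radial profile with a 1-D model of a PSF-blurred disk plus rim annulus
(error-function edges; curvature terms of order sigma/r&#8320; neglected)
and reports the deconvolved annulus width.  We do not use the raw FWHM of
the interior-subtracted peak as the default because the droplet-edge
roll-off overlaps the outer half of the rim peak whenever the rim contrast
C_eq/T_eq is of order one, which biases the downstream K_D by several tens
of percent at weak binding; the FWHM reading remains available as
`method="fwhm"` and is what the apparent (blur-convolved) thickness means.
With the deconvolved &epsilon; and a rim a few PSF widths wide, the
peripheral line maximum is essentially unattenuated and the inversion is
close to unbiased (worst-case median error ~2% across
K_D ∈ {0.1, 0.5, 2, 10} uM under the default noise model).

## Synthetic droplet fields

The generator paints each droplet as a uniform interior disk at
gain·T_eq and a rim annulus [r&#8320;−&epsilon;, r&#8320;] at
gain·(T_eq + C_eq), so rim/interior equals the equilibrium ratio exactly
before optics; then applies a Gaussian PSF and pixel noise.  Defaults (all
configurable, chosen once as representative assay conditions): bulk
concentrations 1.66/1.25 uM, rim &epsilon; = 3 um, PSF sigma = 0.5 um,
Gaussian noise at 2% of the dynamic range, 0.5 um pixels, radii
20.5–24.5 um, 25 droplets per field.  The rim default is several PSF widths
so that rim quantification operates in the resolved regime; real confocal
rims can be thinner, in which case the deconvolving profile fit matters
more, not less.  What the generator does **not** emulate: Airy-disk optics
and axial sectioning, photobleaching, droplet polydispersity beyond the
stated radius window, background structure, and detector-specific noise.
Passing the recovery tests therefore demonstrates self-consistency of
quantification + inversion under idealized optics, not instrument fidelity.

## Sigmoidal response fits

pH titrations and detachment time courses are fitted with the base-10
logistic I(x) = I_min + (I_max − I_min)/(1 + 10^(±&alpha;(x − x_turn)))
(falling for pH, rising for time), with x_turn the effective pKa or
half-detachment time and t_d = 1/&alpha; the decay time.  The numerator is
(I_max − I_min); the (I_min − I_max) variant sometimes printed for this fit
yields asymptotes (I_min, 2I_min − I_max) that contradict the curves it
describes and is treated as a sign typo.  The base-10 form is kept so
&alpha; matches the titration-literature scale.  Fits are weighted least
squares (1/yerr&sup2; when per-point SDs are available), with initial
values from the data extremes and the half-height crossing and up to five
seeded ±50% restarts.  Parameter covariance is scaled by the reduced
chi-square, so standard errors reflect the actual scatter; a coverage test
(200 seeded curves) verifies 95% ± 4% CI coverage of x_turn.  t_d carries a
delta-method SE, se(&alpha;)/&alpha;&sup2;.

## Reaction-diffusion oracle

The independent check of the equilibrium formula integrates free-switch
diffusion in a sphere with layer-confined binding (non-diffusing bound
complex — the handles are anchored at the interface), no flux at
r&#8320;, regularity at 0.  Discretization is a conservative finite-volume
scheme on a uniform node-centered grid; time stepping is backward-Euler
diffusion (banded solve) plus an explicit, locally mass-conserving reaction
substep (default), or fully explicit with a stability guard — the
spherical center cell is the binding constraint, so the explicit default
step is 0.25 dr&sup2;/D.  The total site amount is normalized to
S_tot·4&pi;r&#8320;&sup2;&epsilon;, i.e. the same thin-shell coupling
g = 3&epsilon;/r&#8320; as the analytic model; the discrete steady state
then reproduces the closed form independently of the grid (observed
relative error ~1e-11 at 400 nodes), and grid convergence is demonstrated
on the transient solution instead (first order or better, with grids
aligned to the layer boundary to avoid the staircase effect of the
discrete layer edge).

## Correlated samples and bootstrap bands

Molecular-trajectory observables are serially correlated; the integrated
autocorrelation time tau = 1 + 2 Σ&rho;(k) is estimated with the standard
self-consistent window (truncate at the first W ≥ 5·tau(W)), ACF by FFT.
Synthetic correlated series use a Gaussian-copula AR(1): lag-1 coefficient
phi = (tau − 1)/(tau + 1) (clipped at 0 for tau ≤ 1), which makes the
process's integrated autocorrelation time exactly tau, mapped through the
target inverse CDF so the marginal is exact.  (The alternative
parametrization phi = e^(−1/tau) sets the *exponential* ACF time to tau and
roughly doubles the integrated one; we use the integrated convention
throughout because it is what the estimator returns and what controls
effective sample size.)

`bootstrap_pdf` resamples trajectories with the empirical marginal and the
estimated tau (copula by default; a moving-block bootstrap with block
length ~2·tau is the cross-check) and reports pointwise 95% percentile
bands for the binned density (Freedman–Diaconis bins by default; bands are
pointwise, not simultaneous).  Note that correlation widens density bands
far less than the naive sqrt(tau) effective-sample-size argument suggests:
bin-count variance is governed by the autocorrelation time of the bin
*indicator*, which decorrelates faster than the series.  The bands were
validated against the true ensemble spread of independent correlated
realizations (agreement within a few percent) and by bin-wise coverage of
a known density (95% ± 5%).  Production-scale workloads (1e6 resamples of
1e5 points) are supported by chunked generation; tests and the analysis
scripts run scaled down (n_boot ≈ 200–2000) as the package's standard
problem sizes.

## Degenerate inputs and tie-breaks

K_D = 0 (tight binding) is handled as an explicit limit; T_tot = 0 or
S_tot = 0 reduce algebraically and are tested.  Flat curves cannot be
normalized or fitted; constant series have undefined tau; droplets whose
radial lines leave the image are dropped, and a droplet with fewer than 10
valid lines (or fewer than 10 inner-disk pixels) is an error.  Fitted
plateaus swap labels if the optimizer crosses I_min > I_max; the fit
object always reports I_max > I_min with the covariance permuted
accordingly.

## Known limitations

* The rim-thickness profile fit assumes a radially symmetric droplet and a
  Gaussian PSF; aberrated or saturated rims will bias &epsilon; and hence
  K_D.
* The equilibrium model treats the layer as well mixed and the interior as
  uniform at steady state; it cannot separate k_on from k_off.
* The per-line maximum statistic is noise-biased upward by order of the
  pixel noise; at the default 2% noise this is a ≲1% effect on the ratio.
* Copula resampling matches marginal and integrated autocorrelation time
  but not higher-order temporal structure (e.g. long dwell times of a
  metastable state beyond AR(1)).
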