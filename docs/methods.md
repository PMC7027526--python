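# Methods

## Model

Axons are represented as spin-carrying, infinitesimally thin, effectively
infinite planar curves

    y(x) = a sin(2*pi*x/lambda + phi(x)),

with undulation amplitude `a` (um), wavelength `lambda` (um), and a phase
`phi` that is constant (harmonic case), constant per member of a gamma
ensemble (n-harmonic case), or a smoothed AR(1) random walk (stochastic
case).  Spins diffuse one-dimensionally along the curve with bulk
diffusivity D0; only the transverse displacement y enters the analysis,
because that component is what cylinder-based axon-diameter models read out.
Macroscopic orientation dispersion (across fibers) is deliberately excluded:
fibers are generated with zero mean transverse coordinate so the main fiber
direction is the x axis.

The object of study is the transverse diffusion spectrum D(f) — the Fourier
transform of the velocity autocorrelation function — summarized by four
features:

* height `D_hi`: the high-frequency plateau, equal to muOD * D0 for thin
  fibers (muOD = <sin^2 theta> over segments) and D0 for cylinders;
* width `f_half`: the lowest frequency where D(f) crosses D_hi/2, predicted
  by k_c D0/d^2 (cylinders), k_h D0 muOD/a^2 (harmonic), the D_hi-weighted
  member average (n-harmonic), and k_s (D0/a_max^2) <muOD(x)^2>/<muOD>
  (stochastic);
* a single-Lorentzian approximation L(f) = D_hi f^2/(f_half^2 + f^2);
* the low-frequency power-law exponent p of D(f) ~ c f^p.

Matching the f^2 expansions of the cylinder and harmonic spectra yields the
undulation-induced apparent diameter d = sqrt(k_c/k_h) a muOD^(-1/4), the
quantitative statement of how undulations bias diameter estimation.

All Lorentzian rates are angular (alpha_k = a_k D0 in rad/ms, omega = 2 pi
f).  This is forced by consistency: only with angular rates does the
analytic cylinder sum give k_c = sqrt(1536/7)/(2 pi) ~ 2.357, and with it
both the printed a1*B1 = 0.83 and the d = 10 um width of ~40 Hz.  Internal
units are um, ms, kHz; every public frequency axis is in Hz, with the
conversion centralized in `units.py`.

## Discretization

Fibers are discretized with segment length dl = 0.1 um.  Vertices are
placed by chord marching on a 100x-oversampled dense curve: each next
vertex sits at Euclidean distance exactly dl from the previous one (the
quadratic equation per dense segment is solved in closed form), so
consecutive chords equal dl to machine precision and sin(theta_i) =
(y_{i+1}-y_i)/dl exactly.  An equal-arc placement would make chords fall
short of dl by O((kappa dl)^2/24); at dl = 0.1 um the two constructions
give muOD values differing well below the reported precision.

Stochastic phases: AR(1) innovations (rho = 0.9) on the dl grid are
standardized, cumulatively summed, scaled by `ar1_noise_scale`, and smoothed
with a 0.5 um moving average before entering the sine argument.  The noise
scale is not published; the default 0.005 rad was fixed once so that the
realized global muOD of stochastic fibers stays within ~20% of the
constant-phase fiber with the same (a, lambda) across the validated box
(measured ratios 1.00-1.14).  A consequence worth stating: with this mild
default the stochastic spectra remain close to Lorentzian, and their
low-frequency exponents do not drop as far toward p = 1 as they would for
strongly disordered phase walks.

Gamma ensembles default to shape 4 with means (a, lambda) = (2, 30) um,
rejection-truncated to the validated box 1 <= a <= 3 um, 10 <= lambda <= 50
um.  These are package choices: the upstream distribution parameters were
not available, so the defaults are centered on the validated grid.

## Gaussian sampling

The production route assumes 1-D Gaussian diffusion along the arc: after
time t the arc displacement is N(0, 2 D0 t), so

    msd(t) = sum_r W(r, t) * S(r),
    S(r)   = < (y_{i+r} - y_i)^2 >_i  (two-sided structure function),
    W(r,t) = Gaussian pdf(r*dl; 2 D0 t) * dl,

with start vertices i uniform over one central period (harmonic) or the
fiber interior (stochastic), and the fiber built long enough that the
kernel's +/-6 sigma support never leaves it.  Defaults: dt = 0.25 ms and
t_max = 2000 ms, giving a 2 kHz Nyquist frequency (needed by the 900-1000 Hz
plateau estimator) and sub-Hz frequency resolution; the plateau estimate
msd_inf is the mean over the last decile of times, with a metadata warning
if the MSD still drifts by more than 1% there.

Spectra follow from the MSD by exact piecewise-linear (Filon-type)
quadrature, which is accurate at all frequencies regardless of the time
step.  Two independent routes are implemented and must agree within 1%:

* "parts": D(f) = omega^2 * Re int (msd_inf - msd)/2 e^{-i omega t} dt, the
  velocity-autocorrelation transform integrated by parts twice (no
  numerical derivatives);
* "vacf": central-difference instantaneous diffusivity D_inst = msd'/2
  followed by the sine transform omega int D_inst sin(omega t) dt — the
  VACF route with its t = 0 delta function carried analytically.

A third, fully independent oracle expands y(s) in arc-length Fourier modes:
for Gaussian motion along the arc the spectrum is exactly
sum_m |c_m|^2 alpha_m omega^2/(alpha_m^2 + omega^2) with alpha_m = D0 k_m^2.
Gaussian sampling agrees with this oracle to <3% (typically <0.1%) across
the 15-substrate grid.

## Monte Carlo validation

Thin-fiber walkers diffuse freely in arc length (default dt = 10 us) and
are remapped through the discretized trajectory; MSDs agree with Gaussian
sampling within 3 standard errors, and phase-accrual signals
(S = |<exp(-i gamma int g y dt)>|) agree with the first-cumulant signal to
~1% at low b and to a few percent up to ~60% attenuation.

Undulating cylinders of finite diameter are simulated as fixed-step 3-D
walkers inside the tube (y - a sin(2 pi x/lambda))^2 + z^2 <= (d/2)^2 with
the rejection (stay) rule at the impermeable wall and step time
dt = dx^2/(6 D0).  A 3-D tube rather than a 2-D strip is essential: a strip
is a planar restriction whose low-frequency spectral coefficient is ~1.8x
the cylinder's, so only the tube can (and does, within 5%) reproduce the
analytic cylinder spectrum at a = 0.  The test suite runs these walkers at
reduced scale — 1e5 particles, dx = 0.3 um, t_max = 40 ms for the d = 10 um
straight-cylinder check; 4e4 particles, dx = 0.2 um, t_max = 120 ms for the
d = 1 um undulating tube — sizes chosen so each check carries statistical
power at desk-scale cost.  One artifact of the reduced scale must be
handled explicitly: with dx = 0.2 um in a d = 1 um tube the rejection rule
discards ~20% of steps, lowering the walker's effective diffusivity to
~0.84 D0 (a generic property of rejection walkers, ~2% at the fine steps a
full-scale run would use).  The comparison therefore measures the realized
axial diffusivity with a straight-tube oracle and evaluates the thin-fiber
prediction at that rate; tube and fiber MSDs then agree to <3%.  At these
particle counts the d = 1 um spectral comparison is noise-limited (~20% per
frequency band); the MSD-level comparison of the same data is the binding
assertion.

## Feature estimation

D_hi is the mean of D(f) over 900-1000 Hz; f_half the first upward
half-height crossing, linearly interpolated on the 0.5 Hz grid.  The
single-Lorentzian fit is plain least squares on the uniform grid,
initialized from the estimates.  Power-law exponents are straight-line fits
of log D vs log f over grid points in (0, min(f_half, 20 Hz)], excluding
f = 0; the lowest fitted frequency is the grid resolution (0.5 Hz).  The
median exponent over the 15-substrate grid shifts by ~0.06 if the fit
starts at 1 Hz instead — the quantity is intrinsically sensitive to that
choice, which is why the acceptance test allows +/-0.1 about the reference
median.

Width constants are calibrated by through-origin regression (the theory has
no intercept) of estimated widths on the k = 1 predictor: k_h = 0.343 on
the 15-substrate grid (reference 0.34; small-amplitude limit 1/pi), with
width and height correlations above 0.99.

## Encoding and diameter fitting

PGSE waveforms are rectangular (only G, delta, Delta are specified by the
protocol; ramps are not modeled).  Encoding spectra are zero-padded DFTs of
q(t) = gamma int g dt, stored one-sided with doubled power so that
int |q(f)|^2 df = b; the discrete Parseval identity makes the spectral
b-value match gamma^2 G^2 delta^2 (Delta - delta/3) to <0.1%.  The
reference four-waveform protocol has encoding widths of ~5.1-5.7 Hz (three
long-Delta waveforms) and ~18.9 Hz (the short-Delta one).  b-values are
always computed from (G, delta, Delta); the printed b column of the source
protocol table pairs its rows inconsistently with the Stejskal-Tanner
formula and is not used.

Diameter fitting reproduces the constrained cylinder fit: noise-free
signals, intra-axonal radial model only, D0 fixed at 1.7 um^2/ms (not
estimated).  The objective sum_w (S_w - S_cyl(d)_w)^2 is minimized by a
200-point log grid over d in [0.1, 20] um plus bounded refinement; minima
at a search bound are flagged rather than silently returned.  Round trips
on analytic-cylinder signals recover d to <2% across 2-15 um.

## What the synthetic substrates do and do not emulate

The generators produce the study conditions themselves: mild planar
undulations (a/lambda <= 0.3), gamma-mixed harmonic ensembles, and weakly
stochastic phases, all without macroscopic dispersion, membranes,
permeability, varying calibers, beading, or 3-D trajectory torsion.  Tests
passing on these substrates therefore validate the analysis chain and the
model's internal claims — not that real white-matter axons follow the
model.  In particular the plateau D_hi = muOD * D0 persists to infinite
frequency here, whereas real axons have finite diameters whose intra-axonal
time dependence takes over at short times; the undulating-cylinder
simulations bound where that approximation breaks (d above ~3 um).

## Numerical choices and limitations

* Gaussian kernels truncated at +/-6 sigma (tail mass < 1e-8); propagator
  discretization requires sigma >~ 2 dl before the short-time slope is
  quantitatively meaningful (earliest ~12 us at D0 = 1.7).
* Non-monotone (stochastic) spectra: f_half takes the first upward
  crossing.
* Ensemble averaging uses equal weights (equal spin density per fiber)
  unless weights are given.
* Degenerate inputs fail loudly: straight fibers have no width or diameter
  prediction (muOD = 0), unrefocused waveforms and Nyquist-violating grids
  raise.
* The stochastic-case width constant k_s and exponent distribution depend
  on the unpublished phase-noise scale; with the muOD-matched default the
  package reports k_s from its own calibration rather than asserting the
  literature value.
* Wall-clock scale: one harmonic substrate spectrum ~2 s; the 15-substrate
  grid ~30 s; the largest Monte Carlo check ~2 min.
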