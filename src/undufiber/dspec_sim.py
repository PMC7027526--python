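"""Simulated diffusion spectra of fiber substrates.

The central quantity is the transverse diffusion spectrum D(f), the Fourier
transform of the velocity autocorrelation function of the y-displacements of
spins diffusing along a fiber.  Three routes produce it:

* Gaussian sampling (`gaussian_sampling_msd` + `spectrum_from_msd`): spins
  perform 1-D Gaussian diffusion along the fiber arc, so the transverse mean
  square displacement is a propagator-weighted double sum over fiber
  segments.  This is the fast production route (~seconds per substrate).
* Fourier-mode decomposition (`mode_decomposition_spectrum`): for Gaussian
  motion along the arc the spectrum is exactly a sum of Lorentzians over the
  arc-harmonics of y(s); used as an independent oracle.
* Monte Carlo (`mc_thin_fiber`, `mc_undulating_cylinder`): random walkers,
  either remapped 1-D walkers on the thin fiber or rejection-bounded 3-D
  walkers inside an undulating cylinder of finite diameter.

Internally lengths are um, times ms and rates rad/ms; all public frequency
axes are in Hz.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .substrate import FiberTrajectory, UndulationParams, build_harmonic_fiber
from .units import hz_to_khz

__all__ = [
    "MsdCurve",
    "DiffusionSpectrum",
    "default_times",
    "default_frequencies",
    "gaussian_sampling_msd",
    "spectrum_from_msd",
    "mode_decomposition_spectrum",
    "mc_thin_fiber",
    "simulate_thin_fiber_paths",
    "mc_undulating_cylinder",
    "average_spectra",
    "harmonic_fiber_for_sampling",
    "simulate_harmonic_spectrum",
    "simulate_stochastic_spectrum",
    "write_spectrum",
    "read_spectrum",
]

#: Default bulk diffusivity, um^2/ms (intra-axonal water at body temperature).
D0_DEFAULT = 1.7

#: Gaussian propagator kernels are truncated at +/- 6 sigma (tail mass < 1e-8).
_KERNEL_SIGMAS = 6.0


def default_times(dt: float = 0.25, t_max: float = 2000.0) -> np.ndarray:
    """Uniform time grid (ms).  dt = 0.25 ms puts the Nyquist frequency at
    2 kHz (needed by the 900-1000 Hz plateau estimator); t_max = 2000 ms
    resolves spectral widths down to a few Hz."""
    return np.arange(0.0, t_max + dt / 2, dt)


def default_frequencies(df: float = 0.5, f_max: float = 1000.0) -> np.ndarray:
    """Uniform frequency grid in Hz from 0 to f_max."""
    return np.arange(0.0, f_max + df / 2, df)


@dataclass
class MsdCurve:
    """Transverse mean square displacement on a uniform time grid from 0."""

    times: np.ndarray  # ms
    msd: np.ndarray  # um^2
    msd_infinity: float  # um^2
    D0: float  # um^2/ms
    stderr: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.msd = np.asarray(self.msd, dtype=float)
        if self.times[0] != 0.0:
            raise ValueError("time grid must start at 0")
        dt = np.diff(self.times)
        if dt.size and not np.allclose(dt, dt[0], rtol=1e-9):
            raise ValueError("time grid must be uniform")

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])


@dataclass
class DiffusionSpectrum:
    """D(f) on a non-negative frequency grid; frequencies in Hz, values in
    um^2/ms."""

    frequencies: np.ndarray
    values: np.ndarray
    D0: float
    provenance: str = "gaussian_sampling"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.frequencies < 0):
            raise ValueError("frequency grid must be non-negative")

    def interp(self, f_hz) -> np.ndarray:
        return np.interp(f_hz, self.frequencies, self.values)


# ---------------------------------------------------------------------------
# Gaussian sampling
# ---------------------------------------------------------------------------


def _start_window(traj: FiberTrajectory, margin: int) -> tuple[int, int]:
    """Vertex index window of start positions: one full undulation period in
    the middle for harmonic fibers, everything margin-deep for stochastic."""
    n = len(traj.x)
    lam = traj.metadata.get("wavelength")
    if traj.period_arc_length is not None and lam is not None:
        x_mid = 0.5 * (traj.x[0] + traj.x[-1])
        i0 = int(np.searchsorted(traj.x, x_mid - lam / 2))
        i1 = int(np.searchsorted(traj.x, x_mid + lam / 2))
    else:
        i0, i1 = margin, n - margin
    if i0 < margin or i1 + margin > n or i1 <= i0:
        raise ValueError(
            "fiber too short for the requested diffusion times: need "
            f"{margin} segments of margin on both sides of the start window"
        )
    return i0, i1


def _structure_function(y: np.ndarray, i0: int, i1: int, r_max: int) -> np.ndarray:
    """S(r) = mean over start vertices of the two-sided squared transverse
    displacement at vertex offset r."""
    y0 = y[i0:i1]
    s = np.empty(r_max + 1)
    s[0] = 0.0
    for r in range(1, r_max + 1):
        fwd = y[i0 + r : i1 + r] - y0
        bwd = y[i0 - r : i1 - r] - y0
        s[r] = 0.5 * (np.mean(fwd**2) + np.mean(bwd**2))
    return s


def gaussian_sampling_msd(
    traj: FiberTrajectory, D0: float = D0_DEFAULT, times: np.ndarray | None = None
) -> MsdCurve:
    """Transverse MSD assuming 1-D Gaussian diffusion along the fiber arc.

    For each time t the displacement along the arc is N(0, 2*D0*t); the MSD
    is the propagator-weighted average of (y_j - y_i)^2 over segment pairs,
    with start segments uniform over one period (harmonic) or the interior
    of the fiber (stochastic).
    """
    if times is None:
        times = default_times()
    times = np.asarray(times, dtype=float)
    t_max = times[-1]
    dl = traj.dl
    sigma_max = np.sqrt(2.0 * D0 * t_max)
    r_max = int(np.ceil(_KERNEL_SIGMAS * sigma_max / dl))
    i0, i1 = _start_window(traj, r_max)
    meta = {"D0": D0, "r_max": r_max, "start_window": (i0, i1)}

    if traj.period_arc_length is not None:
        t_plateau = 20.0 * (traj.period_arc_length / (2 * np.pi)) ** 2 / D0
        if t_max < t_plateau:
            meta["plateau_time_warning"] = (
                f"t_max={t_max} ms < {t_plateau:.1f} ms needed to safely reach the plateau"
            )

    s_r = _structure_function(traj.y, i0, i1, r_max)
    radii = dl * np.arange(r_max + 1)

    msd = np.empty_like(times)
    coeff = np.empty(r_max + 1)
    chunk = max(1, int(2**22 // (r_max + 1)))
    for lo in range(0, len(times), chunk):
        t_c = times[lo : lo + chunk]
        var = 2.0 * D0 * t_c[:, None]
        with np.errstate(divide="ignore", invalid="ignore"):
            w = dl * np.exp(-(radii[None, :] ** 2) / (2.0 * var)) / np.sqrt(2.0 * np.pi * var)
        w[:, 1:] *= 2.0  # +/- r both contribute
        w[var[:, 0] == 0.0, :] = 0.0
        msd[lo : lo + chunk] = w @ s_r
    msd[times == 0.0] = 0.0

    last = slice(max(1, int(0.9 * len(times))), len(times))
    msd_inf = float(np.mean(msd[last]))
    if len(times) > 20:
        t_l, m_l = times[last], msd[last]
        slope = np.polyfit(t_l, m_l, 1)[0]
        if msd_inf > 0 and abs(slope) * (t_l[-1] - t_l[0]) / msd_inf > 0.01:
            meta["plateau_warning"] = "MSD still drifting by >1% over the last decile of times"
    del coeff
    return MsdCurve(times=times, msd=msd, msd_infinity=msd_inf, D0=D0, metadata=meta)


# ---------------------------------------------------------------------------
# MSD -> spectrum transforms (Filon quadrature, exact for piecewise-linear
# integrands at any frequency)
# ---------------------------------------------------------------------------


def _filon_parts(times, g, omega):
    """omega^2 * Re int_0^inf g(t) e^{-i omega t} dt for piecewise-linear g
    with g(t > t_max) ~ 0:  omega*g_N*sin(omega T) + (1/dt) sum dg*dcos."""
    dt = times[1] - times[0]
    dg = np.diff(g)
    out = np.empty_like(omega)
    for i, w in enumerate(omega):
        if w == 0.0:
            out[i] = 0.0
            continue
        c = np.cos(w * times)
        out[i] = w * g[-1] * np.sin(w * times[-1]) + np.dot(dg, np.diff(c)) / dt
    return out


def _filon_vacf(times, d_inst, omega):
    """omega * int_0^inf D_inst(t) sin(omega t) dt for piecewise-linear
    D_inst:  g_0 - g_N cos(omega T) + (1/(omega dt)) sum dg*dsin."""
    dt = times[1] - times[0]
    dg = np.diff(d_inst)
    out = np.empty_like(omega)
    for i, w in enumerate(omega):
        if w == 0.0:
            out[i] = 0.0
            continue
        s = np.sin(w * times)
        out[i] = d_inst[0] - d_inst[-1] * np.cos(w * times[-1]) + np.dot(dg, np.diff(s)) / (w * dt)
    return out


def _instantaneous_diffusivity(times, msd):
    """D_inst(t) = msd'(t)/2 by central differences, third-order one-sided
    stencils at the ends (the t=0 value is the high-frequency plateau)."""
    dt = times[1] - times[0]
    d = np.gradient(msd, dt) / 2.0
    if len(msd) >= 4:
        d[0] = (-11 * msd[0] + 18 * msd[1] - 9 * msd[2] + 2 * msd[3]) / (6 * dt) / 2.0
        d[-1] = (11 * msd[-1] - 18 * msd[-2] + 9 * msd[-3] - 2 * msd[-4]) / (6 * dt) / 2.0
    return d


def spectrum_from_msd(
    msd: MsdCurve, f_grid_hz: np.ndarray | None = None, method: str = "parts"
) -> DiffusionSpectrum:
    """Diffusion spectrum from an MSD curve.

    method="parts" (default): D(f) = (2 pi f)^2 Re int (msd_inf - msd(t))/2
    e^{-2 pi i f t} dt, i.e. the velocity-autocorrelation transform
    integrated by parts twice, which needs no numerical derivatives.

    method="vacf": finite-difference instantaneous diffusivity
    D_inst = msd'/2 followed by the sine transform
    D(f) = omega int D_inst(t) sin(omega t) dt (the VACF route integrated by
    parts once; the VACF's delta function at t=0 is carried analytically).
    """
    if f_grid_hz is None:
        f_grid_hz = default_frequencies()
    f_grid_hz = np.asarray(f_grid_hz, dtype=float)
    nyquist_hz = 1.0 / (2.0 * msd.dt) * 1e3
    if f_grid_hz[-1] > nyquist_hz * (1 + 1e-9):
        raise ValueError(f"frequency grid exceeds the Nyquist limit {nyquist_hz:.0f} Hz")
    if not np.isfinite(msd.msd_infinity):
        raise ValueError("msd_infinity must be finite")
    omega = 2.0 * np.pi * hz_to_khz(f_grid_hz)
    if method == "parts":
        g = 0.5 * (msd.msd_infinity - msd.msd)
        vals = _filon_parts(msd.times, g, omega)
    elif method == "vacf":
        d_inst = _instantaneous_diffusivity(msd.times, msd.msd)
        vals = _filon_vacf(msd.times, d_inst, omega)
    else:
        raise ValueError(f"unknown method {method!r}")
    meta = dict(msd.metadata)
    meta["transform"] = method
    return DiffusionSpectrum(
        frequencies=f_grid_hz, values=vals, D0=msd.D0, provenance="gaussian_sampling", metadata=meta
    )


def mode_decomposition_spectrum(
    traj: FiberTrajectory, D0: float = D0_DEFAULT, f_grid_hz: np.ndarray | None = None
) -> DiffusionSpectrum:
    """Exact spectrum for Gaussian motion along the arc, via the Fourier
    series of y(s): D(f) = sum_m |c_m|^2 alpha_m w^2/(alpha_m^2 + w^2) with
    alpha_m = D0 k_m^2.  Fast independent oracle for the sampling route."""
    if f_grid_hz is None:
        f_grid_hz = default_frequencies()
    f_grid_hz = np.asarray(f_grid_hz, dtype=float)
    s_v = traj.arc
    lam = traj.metadata.get("wavelength")
    if lam is not None:
        n_full = int(np.floor((traj.x[-1] - traj.x[0]) / lam))
        if n_full < 1:
            raise ValueError("trajectory shorter than one wavelength")
        s_end = float(np.interp(traj.x[0] + n_full * lam, traj.x, s_v))
    else:
        s_end = float(s_v[-1])
    m_res = 4096
    s_u = np.linspace(0.0, s_end, m_res, endpoint=False)
    y_u = np.interp(s_u, s_v, traj.y)
    c = np.fft.rfft(y_u - y_u.mean()) / m_res
    power = np.abs(c) ** 2
    power[1:] *= 2.0  # +/- m pairs
    k_m = 2.0 * np.pi * np.arange(len(c)) / s_end
    alpha = D0 * k_m**2
    omega = 2.0 * np.pi * hz_to_khz(f_grid_hz)
    w2 = omega[:, None] ** 2
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = power[None, 1:] * alpha[None, 1:] * w2 / (alpha[None, 1:] ** 2 + w2)
    vals = terms.sum(axis=1)
    plateau = float(np.sum(power[1:] * alpha[1:]))
    return DiffusionSpectrum(
        frequencies=f_grid_hz,
        values=vals,
        D0=D0,
        provenance="mode_oracle",
        metadata={"plateau": plateau, "n_modes": len(c) - 1},
    )


# ---------------------------------------------------------------------------
# Monte Carlo: thin fiber
# ---------------------------------------------------------------------------


def simulate_thin_fiber_paths(
    traj: FiberTrajectory,
    D0: float,
    n_particles: int,
    dt: float,
    n_steps: int,
    seed: int,
    start_window: tuple[int, int] | None = None,
):
    """Yield (step_index, y_positions) for walkers diffusing 1-D along the
    arc and remapped through the trajectory.  Generator form so callers can
    accumulate MSD or gradient phase without storing all paths."""
    rng = np.random.default_rng(seed)
    s_v = traj.arc
    if start_window is None:
        margin = int(np.ceil(_KERNEL_SIGMAS * np.sqrt(2 * D0 * dt * n_steps) / traj.dl))
        start_window = _start_window(traj, margin)
    i0, i1 = start_window
    s = rng.uniform(s_v[i0], s_v[i1], size=n_particles)
    step_scale = np.sqrt(2.0 * D0 * dt)
    yield 0, np.interp(s, s_v, traj.y)
    for step in range(1, n_steps + 1):
        s += step_scale * rng.standard_normal(n_particles)
        np.clip(s, s_v[0], s_v[-1], out=s)  # reflecting fiber ends (rarely hit)
        yield step, np.interp(s, s_v, traj.y)


def mc_thin_fiber(
    traj: FiberTrajectory,
    D0: float = D0_DEFAULT,
    n_particles: int = 100_000,
    dt: float = 0.01,
    t_max: float = 30.0,
    seed: int = 0,
    record_dt: float | None = None,
) -> MsdCurve:
    """Monte Carlo transverse MSD of the thin fiber (free 1-D diffusion in
    arc length, remapped to (x, y)); per-time standard errors included."""
    meta = {"D0": D0, "n_particles": n_particles, "dt": dt, "seed": seed}
    lam = traj.metadata.get("wavelength")
    if lam is not None and dt > 0.01 * lam**2 / (2 * D0 * 4 * np.pi**2):
        meta["dt_warning"] = "time step coarse relative to the undulation period"
    if record_dt is None:
        record_dt = max(dt, t_max / 400)
    every = max(1, int(round(record_dt / dt)))
    n_steps = int(round(t_max / dt))
    rec_steps = np.arange(0, n_steps + 1, every)
    sums = np.zeros(len(rec_steps))
    sums2 = np.zeros(len(rec_steps))
    y0 = None
    j = 0
    for step, y in simulate_thin_fiber_paths(traj, D0, n_particles, dt, n_steps, seed):
        if step == 0:
            y0 = y.copy()
        if j < len(rec_steps) and step == rec_steps[j]:
            dy2 = (y - y0) ** 2
            sums[j] = dy2.mean()
            sums2[j] = dy2.std(ddof=1) / np.sqrt(n_particles) if step else 0.0
            j += 1
    times = rec_steps * dt
    last = slice(max(1, int(0.9 * len(times))), len(times))
    return MsdCurve(
        times=times,
        msd=sums,
        msd_infinity=float(np.mean(sums[last])),
        D0=D0,
        stderr=sums2,
        metadata=meta,
    )


# ---------------------------------------------------------------------------
# Monte Carlo: undulating cylinder (2-D strip of width d around the sine)
# ---------------------------------------------------------------------------


@njit(cache=True)
def _walk_tube(n_particles, n_steps, every, dx, amp, k_wave, radius, n_batches, seed):
    """Fixed-step 3D walk inside the undulating tube
    (y - amp*sin(k x))^2 + z^2 <= radius^2 with the rejection (stay) rule."""
    np.random.seed(seed)
    n_rec = n_steps // every + 1
    sums = np.zeros((n_batches, n_rec))
    counts = np.zeros(n_batches)
    lam = 2.0 * np.pi / k_wave if k_wave > 0 else 1.0
    r2 = radius * radius
    for p in range(n_particles):
        batch = p % n_batches
        counts[batch] += 1.0
        # uniform start inside the tube: the (x, eta=y-amp sin(kx), z) shear
        # map has unit Jacobian, so sample a uniform disk in (eta, z)
        x = np.random.uniform(0.0, lam)
        while True:
            eta = np.random.uniform(-radius, radius)
            z = np.random.uniform(-radius, radius)
            if eta * eta + z * z <= r2:
                break
        y = amp * np.sin(k_wave * x) + eta
        y_start = y
        rec = 1
        for step in range(1, n_steps + 1):
            cos_t = 1.0 - 2.0 * np.random.random()
            sin_t = math.sqrt(1.0 - cos_t * cos_t)
            phi = 2.0 * np.pi * np.random.random()
            xn = x + dx * sin_t * math.cos(phi)
            yn = y + dx * sin_t * math.sin(phi)
            zn = z + dx * cos_t
            dy = yn - amp * np.sin(k_wave * xn)
            if dy * dy + zn * zn <= r2:
                x = xn
                y = yn
                z = zn
            if step % every == 0:
                d = y - y_start
                sums[batch, rec] += d * d
                rec += 1
    return sums, counts


def mc_undulating_cylinder(
    d: float,
    a: float,
    lam: float,
    D0: float = D0_DEFAULT,
    n_particles: int = 100_000,
    dx: float = 0.1,
    t_max: float = 100.0,
    seed: int = 0,
    record_dt: float | None = None,
    n_batches: int = 4,
) -> MsdCurve:
    """Transverse MSD inside the undulating cylinder, the 3-D tube
    (y - a sin(2 pi x/lam))^2 + z^2 <= (d/2)^2.

    Fixed-step walker with step length dx and the rejection (stay) rule at
    the impermeable boundary; the step time is dt = dx^2/(6*D0) so that the
    free-walk diffusivity is D0.  Standard errors come from particle batches.
    """
    if d <= 0:
        raise ValueError("diameter must be positive")
    if dx >= d / 4:
        raise ValueError(f"step length dx={dx} too coarse for d={d} (need dx < d/4)")
    dt = dx**2 / (6.0 * D0)
    if record_dt is None:
        record_dt = max(dt, t_max / 1500)
    every = max(1, int(round(record_dt / dt)))
    n_steps = int(round(t_max / dt / every)) * every
    k_wave = 2.0 * np.pi / lam
    sums, counts = _walk_tube(
        n_particles, n_steps, every, dx, a, k_wave, d / 2.0, n_batches, seed
    )
    per_batch = sums / counts[:, None]
    msd = per_batch.mean(axis=0)
    stderr = per_batch.std(axis=0, ddof=1) / np.sqrt(n_batches)
    times = dt * every * np.arange(sums.shape[1])
    last = slice(max(1, int(0.9 * len(times))), len(times))
    return MsdCurve(
        times=times,
        msd=msd,
        msd_infinity=float(np.mean(msd[last])),
        D0=D0,
        stderr=stderr,
        metadata={"d": d, "a": a, "lam": lam, "dx": dx, "dt": dt, "seed": seed},
    )


# ---------------------------------------------------------------------------
# Ensembles and pipelines
# ---------------------------------------------------------------------------


def average_spectra(spectra: list[DiffusionSpectrum], weights=None) -> DiffusionSpectrum:
    """Weighted arithmetic mean of spectra on a common frequency grid
    (equal spin density per fiber by default)."""
    if not spectra:
        raise ValueError("need at least one spectrum")
    f0 = spectra[0].frequencies
    for sp in spectra[1:]:
        if sp.frequencies.shape != f0.shape or not np.allclose(sp.frequencies, f0):
            raise ValueError("spectra must share a common frequency grid")
    if weights is None:
        weights = np.ones(len(spectra))
    weights = np.asarray(weights, dtype=float)
    weights = weights / weights.sum()
    vals = np.einsum("i,ij->j", weights, np.vstack([sp.values for sp in spectra]))
    return DiffusionSpectrum(
        frequencies=f0,
        values=vals,
        D0=spectra[0].D0,
        provenance="ensemble_average",
        metadata={"n_members": len(spectra)},
    )


def harmonic_fiber_for_sampling(
    params: UndulationParams,
    dl: float = 0.1,
    D0: float = D0_DEFAULT,
    t_max: float = 2000.0,
) -> FiberTrajectory:
    """Build a harmonic fiber long enough that Gaussian sampling with the
    given t_max has full kernel support around a central start period."""
    reach = _KERNEL_SIGMAS * np.sqrt(2.0 * D0 * t_max)
    n_periods = int(np.ceil((2 * reach + 3 * params.wavelength) / params.wavelength))
    return build_harmonic_fiber(params, n_periods=n_periods, dl=dl)


def simulate_harmonic_spectrum(
    a: float,
    lam: float,
    D0: float = D0_DEFAULT,
    dl: float = 0.1,
    times: np.ndarray | None = None,
    f_grid_hz: np.ndarray | None = None,
):
    """Full Gaussian-sampling pipeline for a 1-harmonic fiber; returns
    (trajectory, msd, spectrum)."""
    params = UndulationParams(amplitude=a, wavelength=lam)
    if times is None:
        times = default_times()
    traj = harmonic_fiber_for_sampling(params, dl=dl, D0=D0, t_max=float(times[-1]))
    msd = gaussian_sampling_msd(traj, D0=D0, times=times)
    spec = spectrum_from_msd(msd, f_grid_hz)
    return traj, msd, spec


def simulate_stochastic_spectrum(
    params: UndulationParams,
    seed: int,
    total_length: float | None = None,
    D0: float = D0_DEFAULT,
    dl: float = 0.1,
    times: np.ndarray | None = None,
    f_grid_hz: np.ndarray | None = None,
):
    """Gaussian-sampling pipeline for a stochastic (AR(1)-phase) fiber."""
    from .substrate import build_stochastic_fiber

    if times is None:
        times = default_times(t_max=500.0)
    if total_length is None:
        total_length = 2.2 * _KERNEL_SIGMAS * np.sqrt(2.0 * D0 * float(times[-1]))
        total_length = max(total_length, 12 * params.wavelength)
    traj = build_stochastic_fiber(params, total_length=total_length, dl=dl, seed=seed)
    msd = gaussian_sampling_msd(traj, D0=D0, times=times)
    spec = spectrum_from_msd(msd, f_grid_hz)
    return traj, msd, spec


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def write_spectrum(spec: DiffusionSpectrum, path) -> None:
    """Tab-separated (f_Hz, D_um2_per_ms) with parameter header; bit-exact
    round trip."""
    with open(path, "w") as fh:
        fh.write("# undufiber spectrum\n")
        fh.write(f"# D0={spec.D0!r}\n")
        fh.write(f"# provenance={spec.provenance}\n")
        for key, val in sorted(spec.metadata.items()):
            fh.write(f"# meta {key}={val!r}\n")
        fh.write("# f_Hz\tD_um2_per_ms\n")
        for f, v in zip(spec.frequencies, spec.values):
            fh.write(f"{float(f)!r}\t{float(v)!r}\n")


def read_spectrum(path) -> DiffusionSpectrum:
    d0 = None
    provenance = "gaussian_sampling"
    freqs, vals = [], []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if body.startswith("D0="):
                    d0 = float(body[3:])
                elif body.startswith("provenance="):
                    provenance = body.split("=", 1)[1]
                continue
            sf, sv = line.split("\t")
            freqs.append(float(sf))
            vals.append(float(sv))
    if d0 is None:
        raise ValueError(f"{path} is not an undufiber spectrum file")
    return DiffusionSpectrum(
        frequencies=np.array(freqs), values=np.array(vals), D0=d0, provenance=provenance
    )
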