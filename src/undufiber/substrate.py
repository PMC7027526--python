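"""Undulating thin-fiber substrates.

Axons are represented as infinitesimally thin planar curves

    y(x) = a * sin(2*pi*x/lambda + phi(x)),

with undulation amplitude ``a`` (um), wavelength ``lambda`` (um) and a phase
``phi`` that is either constant (harmonic case) or a smoothed AR(1) random
walk (stochastic case).  Curves are discretized into polylines whose
consecutive vertices are exactly ``dl`` apart (equal chord lengths), so the
per-segment angle ``theta_i`` to the main fiber axis satisfies
``sin(theta_i) = (y_{i+1} - y_i)/dl``.

The microscopic orientation dispersion of a single fiber is

    muOD = < sin^2(theta) >

averaged over its equal-length segments; it is the arc-length average of the
squared transverse slope and the key predictor of the fiber's diffusion
spectrum (height muOD*D0, width ~ D0*muOD/a^2).
"""

from __future__ import annotations

import io
import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from numba import njit
from scipy import integrate

__all__ = [
    "UndulationParams",
    "FiberTrajectory",
    "EnsembleSpec",
    "build_harmonic_fiber",
    "build_stochastic_fiber",
    "sample_harmonic_ensemble",
    "microscopic_orientation_dispersion",
    "local_dispersion_profile",
    "period_arc_length",
    "write_trajectory",
    "read_trajectory",
]

#: Oversampling factor of the dense x-grid relative to dl used when marching.
_DENSE_FACTOR = 100

#: Default AR(1) lag-one correlation of the raw phase innovations.
DEFAULT_AR1_RHO = 0.9

#: Default scale (radians) of the cumulated, standardized phase walk.  Chosen
#: once so that the realized global muOD of a stochastic fiber stays within
#: ~20% of the constant-phase fiber with the same (a, lambda); see
#: docs/methods.md.
DEFAULT_AR1_NOISE_SCALE = 0.005


@dataclass(frozen=True)
class UndulationParams:
    """Geometry of one undulating fiber.

    amplitude, wavelength in um; ``phase_mode`` is "constant" or "ar1".
    ``ar1_noise_scale`` is the standard-deviation scale (radians) applied to
    the standardized cumulative phase walk; ``smoothing_width`` (um) is the
    moving-average window that suppresses unphysically sharp fiber turns.
    """

    amplitude: float
    wavelength: float
    phase_mode: str = "constant"
    constant_phase: float = 0.0
    ar1_correlation: float = DEFAULT_AR1_RHO
    ar1_noise_scale: float = DEFAULT_AR1_NOISE_SCALE
    smoothing_width: float = 0.5

    def __post_init__(self):
        if not (np.isfinite(self.amplitude) and self.amplitude >= 0):
            raise ValueError(f"amplitude must be finite and >= 0, got {self.amplitude}")
        if not (np.isfinite(self.wavelength) and self.wavelength > 0):
            raise ValueError(f"wavelength must be finite and > 0, got {self.wavelength}")
        if self.phase_mode not in ("constant", "ar1"):
            raise ValueError(f"phase_mode must be 'constant' or 'ar1', got {self.phase_mode!r}")
        if not 0 <= self.ar1_correlation < 1:
            raise ValueError("ar1_correlation must lie in [0, 1)")
        if self.smoothing_width <= 0:
            raise ValueError("smoothing_width must be positive")
        if self.amplitude / self.wavelength > 0.3:
            warnings.warn(
                "a/lambda > 0.3: the model is only validated for mild undulations",
                stacklevel=3,
            )


@dataclass
class FiberTrajectory:
    """Equal-chord polyline (x, y) with dl spacing, both in um.

    ``period_arc_length`` is the arc length of one undulation period (None
    for stochastic fibers).  ``metadata`` carries generation parameters,
    seeds and any warnings raised while the trajectory was used.
    """

    x: np.ndarray
    y: np.ndarray
    dl: float
    period_arc_length: float | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.x.ndim != 1 or self.x.shape != self.y.shape:
            raise ValueError("x and y must be 1-D arrays of equal length")
        if len(self.x) < 2:
            raise ValueError("a trajectory needs at least two vertices")

    @property
    def n_segments(self) -> int:
        return len(self.x) - 1

    @property
    def arc(self) -> np.ndarray:
        """Arc-length coordinate of each vertex (chord-summed), um."""
        return self.dl * np.arange(len(self.x), dtype=float)

    @property
    def segment_angles(self) -> np.ndarray:
        """Angle of each segment to the x axis, radians."""
        return np.arctan2(np.diff(self.y), np.diff(self.x))

    @property
    def sin2_theta(self) -> np.ndarray:
        """sin^2(theta_i) per segment; equals (dy_i/dl)^2 for equal chords."""
        return (np.diff(self.y) / self.dl) ** 2

    @property
    def a_max(self) -> float:
        """Maximal transverse deviation from the mean transverse position."""
        return float(np.max(np.abs(self.y - self.y.mean())))


@dataclass(frozen=True)
class EnsembleSpec:
    """Gamma-distributed (amplitude, wavelength) ensemble, truncated to the
    numerically validated box 1 <= a <= 3 um, 10 <= lambda <= 50 um."""

    a_shape: float = 4.0
    a_scale: float = 0.5
    lam_shape: float = 4.0
    lam_scale: float = 7.5
    a_bounds: tuple = (1.0, 3.0)
    lam_bounds: tuple = (10.0, 50.0)
    n_fibers: int = 25
    weights: np.ndarray | None = None
    seed: int = 0

    def __post_init__(self):
        if self.n_fibers < 1:
            raise ValueError("n_fibers must be >= 1")
        for lo, hi in (self.a_bounds, self.lam_bounds):
            if not (0 <= lo < hi):
                raise ValueError("bounds must satisfy 0 <= lo < hi")
        if self.weights is not None:
            w = np.asarray(self.weights, dtype=float)
            if w.shape != (self.n_fibers,) or np.any(w < 0):
                raise ValueError("weights must be n_fibers non-negative values")


@njit(cache=True)
def _march_equal_chords(x_dense, y_dense, dl, x_end):
    """Place vertices on the dense polyline so consecutive vertices are at
    Euclidean distance exactly dl; stop at the first vertex with x >= x_end.

    Within each dense segment the curve is linear, so the step reduces to a
    quadratic equation solved exactly.
    """
    n = x_dense.shape[0]
    cap = int((x_end - x_dense[0]) / dl * 3) + 8
    xs = np.empty(cap)
    ys = np.empty(cap)
    xs[0] = x_dense[0]
    ys[0] = y_dense[0]
    m = 1
    vx = xs[0]
    vy = ys[0]
    j = 1
    dl2 = dl * dl
    while m < cap:
        # advance to the first dense point at distance >= dl from the vertex
        while j < n:
            dx = x_dense[j] - vx
            dy = y_dense[j] - vy
            if dx * dx + dy * dy >= dl2:
                break
            j += 1
        if j >= n:
            break
        ax = x_dense[j - 1]
        ay = y_dense[j - 1]
        ux = x_dense[j] - ax
        uy = y_dense[j] - ay
        wx = ax - vx
        wy = ay - vy
        qa = ux * ux + uy * uy
        qb = 2.0 * (wx * ux + wy * uy)
        qc = wx * wx + wy * wy - dl2
        disc = qb * qb - 4.0 * qa * qc
        if disc < 0.0:
            disc = 0.0
        t = (-qb + math.sqrt(disc)) / (2.0 * qa)
        vx = ax + t * ux
        vy = ay + t * uy
        xs[m] = vx
        ys[m] = vy
        m += 1
        if vx >= x_end:
            break
    return xs[:m], ys[:m]


def period_arc_length(amplitude: float, wavelength: float) -> float:
    """Arc length of one undulation period, by adaptive quadrature of
    integral of sqrt(1 + y'(x)^2) over one wavelength."""
    k = 2.0 * np.pi / wavelength
    val, _ = integrate.quad(
        lambda x: np.sqrt(1.0 + (amplitude * k * np.cos(k * x)) ** 2),
        0.0,
        wavelength,
        limit=200,
    )
    return float(val)


def _dense_grid(x_end: float, dl: float) -> np.ndarray:
    step = dl / _DENSE_FACTOR
    return np.arange(0.0, x_end + 2.0 * dl + step, step)


def _finalize(x, y, dl, params, period_len, extra_meta):
    y = y - y.mean()  # main fiber direction along x; no macroscopic dispersion
    meta = {
        "amplitude": params.amplitude,
        "wavelength": params.wavelength,
        "phase_mode": params.phase_mode,
        "constant_phase": params.constant_phase,
        "ar1_correlation": params.ar1_correlation,
        "ar1_noise_scale": params.ar1_noise_scale,
        "smoothing_width": params.smoothing_width,
        "dl": dl,
    }
    meta.update(extra_meta)
    return FiberTrajectory(x=x, y=y, dl=dl, period_arc_length=period_len, metadata=meta)


def build_harmonic_fiber(
    params: UndulationParams, n_periods: int = 1, dl: float = 0.1
) -> FiberTrajectory:
    """Discretize y = a*sin(2*pi*x/lambda + phi) over ``n_periods`` periods
    into an equal-chord polyline with spacing ``dl`` (um)."""
    if params.phase_mode != "constant":
        raise ValueError("build_harmonic_fiber requires phase_mode='constant'")
    if dl <= 0:
        raise ValueError("dl must be positive")
    if dl > params.wavelength / 20:
        raise ValueError(f"dl={dl} too coarse for wavelength {params.wavelength} (need dl <= lambda/20)")
    if n_periods < 1:
        raise ValueError("n_periods must be >= 1")
    x_end = n_periods * params.wavelength
    if params.amplitude == 0.0:
        x = np.arange(0.0, x_end + dl / 2, dl)
        if x[-1] < x_end:
            x = np.append(x, x[-1] + dl)
        y = np.zeros_like(x)
        return _finalize(x, y, dl, params, params.wavelength, {"n_periods": n_periods})
    xd = _dense_grid(x_end, dl)
    k = 2.0 * np.pi / params.wavelength
    yd = params.amplitude * np.sin(k * xd + params.constant_phase)
    x, y = _march_equal_chords(xd, yd, dl, x_end)
    lam_arc = period_arc_length(params.amplitude, params.wavelength)
    return _finalize(x, y, dl, params, lam_arc, {"n_periods": n_periods})


def _ar1_phase(n: int, rho: float, noise_scale: float, window: int, rng) -> np.ndarray:
    """Smoothed AR(1) phase walk: AR(1) innovations, standardized, cumulated,
    scaled, then moving-average smoothed with edge-corrected weights."""
    eps = rng.standard_normal(n)
    raw = np.empty(n)
    raw[0] = eps[0]
    for i in range(1, n):
        raw[i] = rho * raw[i - 1] + eps[i]
    sd = raw.std()
    if sd == 0.0:
        return np.zeros(n)
    walk = np.cumsum((raw - raw.mean()) / sd) * noise_scale
    kernel = np.ones(window)
    smooth = np.convolve(walk, kernel, mode="same")
    counts = np.convolve(np.ones(n), kernel, mode="same")
    return smooth / counts


def build_stochastic_fiber(
    params: UndulationParams,
    total_length: float,
    dl: float = 0.1,
    seed: int | None = None,
) -> FiberTrajectory:
    """Fiber with AR(1)-phase modulation, covering ``total_length`` um in x.

    The phase series lives on an x-grid with spacing ``dl``; it is linearly
    interpolated onto the dense marching grid.  ``ar1_noise_scale = 0``
    reproduces the constant-phase fiber exactly.
    """
    if params.phase_mode != "ar1":
        raise ValueError("build_stochastic_fiber requires phase_mode='ar1'")
    if dl <= 0 or dl > params.wavelength / 20:
        raise ValueError("dl must be positive and <= lambda/20")
    if total_length < 10 * params.wavelength:
        raise ValueError("total_length must be at least 10 wavelengths")
    if params.ar1_noise_scale > 0 and seed is None:
        raise ValueError("a seed is required for stochastic fibers")
    x_end = float(total_length)
    xd = _dense_grid(x_end, dl)
    k = 2.0 * np.pi / params.wavelength
    if params.ar1_noise_scale == 0.0:
        phase_dense = np.zeros_like(xd)
    else:
        rng = np.random.default_rng(seed)
        x_coarse = np.arange(0.0, x_end + 2.0 * dl + dl, dl)
        window = max(1, int(round(params.smoothing_width / dl)))
        phi = _ar1_phase(len(x_coarse), params.ar1_correlation, params.ar1_noise_scale, window, rng)
        phase_dense = np.interp(xd, x_coarse, phi)
    yd = params.amplitude * np.sin(k * xd + params.constant_phase + phase_dense)
    x, y = _march_equal_chords(xd, yd, dl, x_end)
    return _finalize(x, y, dl, params, None, {"seed": seed, "total_length": total_length})


def sample_harmonic_ensemble(spec: EnsembleSpec) -> list[UndulationParams]:
    """Draw (a_i, lambda_i) pairs from independent gamma laws truncated to
    the spec's bounds, by rejection sampling; reproducible given the seed."""
    rng = np.random.default_rng(spec.seed)
    out = []
    drawn = 0
    batch = max(256, 4 * spec.n_fibers)
    while len(out) < spec.n_fibers:
        a = rng.gamma(spec.a_shape, spec.a_scale, size=batch)
        lam = rng.gamma(spec.lam_shape, spec.lam_scale, size=batch)
        keep = (
            (a >= spec.a_bounds[0])
            & (a <= spec.a_bounds[1])
            & (lam >= spec.lam_bounds[0])
            & (lam <= spec.lam_bounds[1])
        )
        drawn += batch
        for ai, li in zip(a[keep], lam[keep]):
            out.append(UndulationParams(amplitude=float(ai), wavelength=float(li)))
            if len(out) == spec.n_fibers:
                break
        if drawn >= 100_000 and len(out) / drawn < 1e-3:
            raise RuntimeError(
                "rejection acceptance probability below 1e-3; "
                "gamma shapes/scales are inconsistent with the truncation bounds"
            )
    return out


def microscopic_orientation_dispersion(traj: FiberTrajectory) -> float:
    """muOD = mean of sin^2(theta_i) over equal-length segments (the
    arc-length average of the squared transverse slope)."""
    if traj.n_segments < 2:
        raise ValueError("need at least two segments")
    return float(traj.sin2_theta.mean())


def local_dispersion_profile(traj: FiberTrajectory):
    """Per-segment muOD(x) = sin^2(theta_i) and the maximal deviation a_max
    from the mean transverse position."""
    if traj.n_segments < 2:
        raise ValueError("need at least two segments")
    return traj.sin2_theta, traj.a_max


def write_trajectory(traj: FiberTrajectory, path) -> None:
    """Tab-separated (x_um, y_um) with a '#'-prefixed parameter header;
    round-trips bit-exactly through read_trajectory."""
    buf = io.StringIO()
    buf.write("# undufiber trajectory\n")
    buf.write(f"# dl={traj.dl!r}\n")
    buf.write(f"# period_arc_length={traj.period_arc_length!r}\n")
    for key, val in sorted(traj.metadata.items()):
        buf.write(f"# meta {key}={val!r}\n")
    buf.write("# x_um\ty_um\n")
    for xi, yi in zip(traj.x, traj.y):
        buf.write(f"{float(xi)!r}\t{float(yi)!r}\n")
    with open(path, "w") as fh:
        fh.write(buf.getvalue())


def read_trajectory(path) -> FiberTrajectory:
    dl = None
    period = None
    meta = {}
    xs, ys = [], []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if body.startswith("dl="):
                    dl = float(body[3:])
                elif body.startswith("period_arc_length="):
                    val = body.split("=", 1)[1]
                    period = None if val == "None" else float(val)
                elif body.startswith("meta "):
                    key, val = body[5:].split("=", 1)
                    try:
                        meta[key] = eval(val, {"__builtins__": {}}, {})  # noqa: S307 - own header
                    except Exception:
                        meta[key] = val
                continue
            sx, sy = line.split("\t")
            xs.append(float(sx))
            ys.append(float(sy))
    if dl is None:
        raise ValueError(f"{path} is not an undufiber trajectory file")
    return FiberTrajectory(
        x=np.array(xs), y=np.array(ys), dl=dl, period_arc_length=period, metadata=meta
    )
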