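"""Closed-form diffusion spectra of restricted geometries.

For diffusion restricted between parallel planes (dim=1), inside a cylinder
(dim=2) or a sphere (dim=3) of radius r, the transverse diffusion spectrum is
an infinite sum of Lorentzians over Bessel-root kernels zeta_k:

    D(f) = D0 * sum_k a_k B_k * w^2 / ((a_k D0)^2 + w^2),   w = 2*pi*f,

with a_k = (zeta_k / r)^2, B_k = 2 (r/zeta_k)^2 / (zeta_k^2 + 1 - dim) and
zeta_k the positive roots of

    zeta * J_{dim/2-1}(zeta) - (dim - 1) * J_{dim/2}(zeta) = 0.

The rates a_k*D0 are angular frequencies (rad/ms internally); spectra are
reported against cyclic frequency in Hz.  The completeness relation
sum_k a_k B_k = 1 guarantees D(f) -> D0 at high frequency.

Two constants follow from the sum for cylinders: the first coefficient
product a1*B1 = 2/(zeta_1^2 - 1) ~ 0.83, and the width constant
k_c = sqrt(1536/7)/(2*pi) ~ 2.357 linking the half-width at half maximum to
the diameter via f_half = k_c * D0 / d^2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy import optimize, special

from .units import hz_to_khz

__all__ = ["RestrictedGeometry", "restriction_kernels", "analytic_spectrum", "kc_constant"]

#: Exact cylinder spectral-width constant, f_half = KC * D0 / d^2.
KC = math.sqrt(1536.0 / 7.0) / (2.0 * math.pi)


def _kernel_equation(zeta: np.ndarray, dim: int) -> np.ndarray:
    nu = dim / 2.0 - 1.0
    return zeta * special.jv(nu, zeta) - (dim - 1) * special.jv(nu + 1, zeta)


def restriction_kernels(dim: int, n_terms: int) -> np.ndarray:
    """First ``n_terms`` positive roots zeta_k of the kernel equation, by
    dense bracketing with certified sign changes and brentq refinement."""
    return _restriction_kernels_cached(dim, n_terms).copy()


@lru_cache(maxsize=64)
def _restriction_kernels_cached(dim: int, n_terms: int) -> np.ndarray:
    if dim not in (1, 2, 3):
        raise ValueError("dim must be 1, 2 or 3")
    if n_terms < 1:
        raise ValueError("n_terms must be >= 1")
    # Roots are interlaced roughly pi apart; scan well past the requested count.
    grid = np.linspace(1e-9, (n_terms + 3) * np.pi, 40 * (n_terms + 3))
    vals = _kernel_equation(grid, dim)
    sign_change = np.nonzero(np.sign(vals[:-1]) * np.sign(vals[1:]) < 0)[0]
    roots = []
    for idx in sign_change:
        root = optimize.brentq(_kernel_equation, grid[idx], grid[idx + 1], args=(dim,))
        if root > 1e-6:
            roots.append(root)
        if len(roots) == n_terms:
            break
    if len(roots) < n_terms:
        raise RuntimeError(f"failed to bracket root {len(roots) + 1} of dim={dim} kernel")
    return np.array(roots)


@dataclass
class RestrictedGeometry:
    """Restriction of dimension ``dim`` with radius r (um) and bulk
    diffusivity D0 (um^2/ms); diameter d = 2r."""

    dim: int
    radius: float
    D0: float
    n_terms: int = 20
    kernels: np.ndarray = field(init=False)

    def __post_init__(self):
        if self.radius <= 0 or self.D0 <= 0:
            raise ValueError("radius and D0 must be positive")
        self.kernels = restriction_kernels(self.dim, self.n_terms)

    @property
    def diameter(self) -> float:
        return 2.0 * self.radius

    @property
    def a_k(self) -> np.ndarray:
        """Inverse-squared confinement lengths, um^-2."""
        return (self.kernels / self.radius) ** 2

    @property
    def B_k(self) -> np.ndarray:
        """Amplitude coefficients, um^2."""
        z = self.kernels
        return 2.0 * (self.radius / z) ** 2 / (z**2 + 1.0 - self.dim)

    def extend(self, n_terms: int) -> "RestrictedGeometry":
        return RestrictedGeometry(self.dim, self.radius, self.D0, n_terms)


def analytic_spectrum(geom: RestrictedGeometry, f_grid_hz: np.ndarray):
    """Truncated Lorentzian-sum spectrum on ``f_grid_hz``; the truncation is
    auto-extended until the plateau sum reaches 0.99 * D0."""
    from .dspec_sim import DiffusionSpectrum  # local import to avoid a cycle

    while np.sum(geom.a_k * geom.B_k) < 0.99:
        geom = geom.extend(2 * geom.n_terms)
    f_grid_hz = np.asarray(f_grid_hz, dtype=float)
    omega = 2.0 * np.pi * hz_to_khz(f_grid_hz)  # rad/ms
    alpha = geom.a_k * geom.D0  # rad/ms
    w2 = omega[:, None] ** 2
    vals = geom.D0 * np.sum(
        (geom.a_k * geom.B_k)[None, :] * w2 / (alpha[None, :] ** 2 + w2), axis=1
    )
    return DiffusionSpectrum(
        frequencies=f_grid_hz,
        values=vals,
        D0=geom.D0,
        provenance="analytic",
        metadata={"dim": geom.dim, "radius": geom.radius, "n_terms": geom.n_terms},
    )


def kc_constant(n_terms: int = 50, cross_check_tol: float = 5e-3) -> float:
    """Cylinder width constant k_c = sqrt(1536/7)/(2*pi).

    The closed form is cross-checked against the truncated low-frequency
    coefficient of the Lorentzian sum: D(f) ~ (1/k_c^2) (d^4/D0) f^2 with
    1/k_c^2 = (pi^2/2) * sum_k 1/(zeta_k^4 (zeta_k^2 - 1)).
    """
    zeta = restriction_kernels(2, n_terms)
    inv_kc2 = 0.5 * np.pi**2 * np.sum(1.0 / (zeta**4 * (zeta**2 - 1.0)))
    numeric = 1.0 / math.sqrt(inv_kc2)
    if abs(numeric - KC) / KC > cross_check_tol:
        raise RuntimeError(
            f"k_c cross-check failed: closed form {KC:.6f} vs truncated sum {numeric:.6f}"
        )
    return KC
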