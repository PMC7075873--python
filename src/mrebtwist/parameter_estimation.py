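"""Fluctuation-based estimation of the coarse-grained filament parameters.

Equilibrium windows of angle time series are fit with Gaussians; the elastic
moduli follow from equipartition of the quadratic modes,

    K = kBT * dl / sigma_twist^2        (torsional modulus)
    C = kBT * dl / sigma_bend^2         (bending modulus, averaged over the
                                         two bending directions)

with ``dl`` the monomer rise (~5 nm) and sigma the per-monomer-step angular
standard deviation in radians.  Mean angles convert to intrinsic rates,
omega0 = theta3 / dl and k0 = sqrt(theta1^2 + theta2^2) / dl.  Per-monomer
binding and polymerization energies convert to per-length densities for the
double protofilament.  Energies are in kBT throughout (kBT = 1).

Degrees at every public interface; radians only inside the formulas.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from mrebtwist.core_model import MONOMER_RISE_NM
from mrebtwist.trajectory_geometry import AngleSeries


@dataclass(frozen=True)
class GaussianFit:
    """Gaussian fit of an equilibrium-window angle distribution (degrees)."""

    mean: float
    sd: float
    window: tuple[float, float]   # (t_start, t_end), ns
    n_frames: int
    degenerate: bool = False      # True when the histogram fit fell back to moments

    def __post_init__(self) -> None:
        if not self.degenerate and self.sd <= 0:
            raise ValueError("sd must be positive for a non-degenerate fit")


def equilibrium_window_fit(series: AngleSeries, window_ns: float = 40.0,
                           bin_width_deg: float = 0.5) -> GaussianFit:
    """Gaussian fit of the last ``window_ns`` of an angle series.

    Histograms the window at ``bin_width_deg`` resolution and least-squares
    fits a Gaussian; falls back to the sample mean/SD (flagged ``degenerate``)
    when the fit cannot converge or the distribution has no width.
    """
    t_end = series.times[-1]
    win = series.window(t_end - window_ns, t_end)
    vals = win.values
    if len(vals) < 20:
        raise ValueError(f"only {len(vals)} frames in the window; need >= 20")
    m0, s0 = float(np.mean(vals)), float(np.std(vals, ddof=1))
    wspan = (float(win.times[0]), float(t_end))
    if s0 < bin_width_deg / 10.0:
        return GaussianFit(mean=m0, sd=s0, window=wspan, n_frames=len(vals),
                           degenerate=True)
    lo = np.floor(vals.min() / bin_width_deg) * bin_width_deg
    hi = np.ceil(vals.max() / bin_width_deg) * bin_width_deg
    edges = np.arange(lo, hi + bin_width_deg, bin_width_deg)
    hist, edges = np.histogram(vals, bins=edges)
    centers = 0.5 * (edges[1:] + edges[:-1])

    def gauss(x, amp, mu, sigma):
        return amp * np.exp(-0.5 * ((x - mu) / sigma) ** 2)

    try:
        popt, _ = optimize.curve_fit(gauss, centers, hist,
                                     p0=[hist.max(), m0, s0], maxfev=5000)
        mu, sigma = float(popt[1]), abs(float(popt[2]))
        if sigma <= 0 or not np.isfinite(mu) or not np.isfinite(sigma):
            raise RuntimeError
    except RuntimeError:
        return GaussianFit(mean=m0, sd=s0, window=wspan, n_frames=len(vals),
                           degenerate=True)
    return GaussianFit(mean=mu, sd=sigma, window=wspan, n_frames=len(vals))


# ---------------------------------------------------------------------------
# moduli and intrinsic rates
# ---------------------------------------------------------------------------


def torsional_modulus(sigma_deg: float, delta_l: float = MONOMER_RISE_NM) -> float:
    """K = kBT dl / sigma^2 from the per-monomer twist-angle SD, kBT nm."""
    if sigma_deg <= 0:
        raise ValueError("sigma must be positive")
    return delta_l / math.radians(sigma_deg) ** 2


def bending_modulus(sigma1_deg: float, sigma2_deg: float,
                    delta_l: float = MONOMER_RISE_NM) -> float:
    """Bending modulus C, kBT nm, averaged over the two bending directions.

    Warns when the direction-wise estimates C1 and C2 differ by more than 5%,
    since the model assumes a single isotropic bending modulus.
    """
    c1 = torsional_modulus(sigma1_deg, delta_l)
    c2 = torsional_modulus(sigma2_deg, delta_l)
    c = 0.5 * (c1 + c2)
    if abs(c1 - c2) / c > 0.05:
        warnings.warn(f"direction-wise bending moduli differ by "
                      f"{abs(c1 - c2) / c:.0%} (> 5%); averaging anyway",
                      RuntimeWarning)
    return c


def intrinsic_rates(mean_theta1_deg: float, mean_theta2_deg: float,
                    mean_theta3_deg: float,
                    delta_l: float = MONOMER_RISE_NM) -> tuple[float, float]:
    """Intrinsic curvature k0 and twist rate omega0, rad/nm.

    omega0 comes from the mean twist angle theta3 per monomer step; k0 from
    the two bending means in quadrature (theta2 is typically ~0, so k0 is in
    practice set by theta1).
    """
    omega0 = math.radians(mean_theta3_deg) / delta_l
    k0 = math.hypot(math.radians(mean_theta1_deg),
                    math.radians(mean_theta2_deg)) / delta_l
    return k0, omega0


def binding_potential_per_length(energy_per_monomer: float,
                                 delta_l: float = MONOMER_RISE_NM,
                                 n_protofilaments: int = 2) -> float:
    """Membrane-binding potential V, kBT/nm, from the per-monomer energy."""
    if energy_per_monomer < 0:
        raise ValueError("binding energy must be non-negative")
    return n_protofilaments * energy_per_monomer / delta_l


def polymerization_density(delta_g_per_monomer: float,
                           delta_l: float = MONOMER_RISE_NM,
                           n_protofilaments: int = 2) -> float:
    """Polymerization energy density mu0, kBT/nm.

    ``delta_g_per_monomer`` is the free-energy gain of adding one monomer to
    one protofilament (kBT); a monomer pair extends the double protofilament
    by one rise.
    """
    return n_protofilaments * delta_g_per_monomer / delta_l


def equilibrium_constant_to_delta_g(k_c: float) -> float:
    """Polymerization free energy, kBT, from the off/on equilibrium constant.

    dG = -ln(Kc) in kBT units; Kc = 1 gives dG = 0.
    """
    if k_c <= 0:
        raise ValueError("Kc must be positive")
    return -math.log(k_c)


# ---------------------------------------------------------------------------
# correlation statistics
# ---------------------------------------------------------------------------


def pearson_with_p(x, y) -> tuple[float, float]:
    """Pearson r with a two-tailed Student-t p-value.

    t = r sqrt((n - 2) / (1 - r^2)) on n - 2 degrees of freedom.  Raises for
    constant input, where r is undefined.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and of equal length")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 points")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for constant input")
    xc = x - x.mean()
    yc = y - y.mean()
    r = float(np.dot(xc, yc) / math.sqrt(np.dot(xc, xc) * np.dot(yc, yc)))
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        return r, 0.0
    t = r * math.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * float(stats.t.sf(abs(t), df=n - 2))
    return r, p
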