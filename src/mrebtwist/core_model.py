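"""Coarse-grained energy model of a chiral filament bound to a rigid membrane.

An MreB double protofilament is modelled as an inextensible elastic beam lying
on the inner surface of a rigid cylinder of radius ``r`` (flat membrane =
``r -> inf``).  Its configuration is described by the local pitch angle
``theta(s)`` between the filament tangent and the cylinder axis and the local
twist angle ``psi(s)`` between the membrane-binding face and the inward surface
normal.  The energy per filament (in units of kBT, lengths in nm) is

    H = 1/2 \int_{-L/2}^{L/2} ds [ C (sin^2(theta)/r - k0)^2 + C theta'^2
        + K (psi' - sin(2 theta)/(2 r) - omega0)^2 + 2 V sin^2(psi/2) ]

with bending modulus ``C``, torsional modulus ``K``, membrane-binding potential
per unit length ``V``, intrinsic curvature ``k0`` and intrinsic twist rate
``omega0`` (positive = left-handed).  The binding term is minimal only at
``psi = 0`` because the filament has a single membrane-binding face.

On a flat membrane the Euler-Lagrange equation for ``psi`` has a first
integral, and the minimizer family is parameterized by the boundary twist
amplitude ``psi_m = psi(L/2)``; filament length and energy follow by
quadrature (the normative path here) or equivalently via incomplete elliptic
integrals.  The filament stops growing at the limit length where the marginal
energy cost of extension equals the polymerization energy density,
``dE/dL = mu0``.

Only the zero-winding sector is treated (no full 360 deg twist along the
filament); see the methods note for why that restriction is physical and
load-bearing.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import integrate, interpolate, optimize, special

logger = logging.getLogger(__name__)

#: conventional MreB monomer rise used to convert per-monomer angles to rates, nm
MONOMER_RISE_NM = 5.0

#: default maximum filament length probed when deciding "unbounded", nm
DEFAULT_L_MAX = 2000.0


class PsiBoundError(ValueError):
    """Raised when psi_m reaches the bound-state limit sin(psi_m/2) >= l_m.

    There the quadrature integrand develops a non-integrable singularity at
    psi = 0 and the filament length diverges: psi_m has hit its upper bound.
    """


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FilamentParams:
    """Physical constants of the coarse-grained filament model.

    Attributes
    ----------
    C : float
        Bending modulus, kBT nm.
    K : float
        Torsional modulus, kBT nm.
    V : float
        Membrane-binding potential per unit length, kBT / nm.
    k0 : float
        Intrinsic curvature, rad / nm (directed away from the binding face).
    omega0 : float
        Intrinsic twist rate, rad / nm; positive = left-handed.
    mu0 : float
        Polymerization energy per unit length, kBT / nm.
    r : float
        Cylinder radius, nm; ``math.inf`` means a flat membrane.
    """

    C: float
    K: float
    V: float
    k0: float
    omega0: float
    mu0: float
    r: float = math.inf

    def __post_init__(self) -> None:
        for name in ("C", "K", "V", "mu0"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not self.r > 0:
            raise ValueError("r must be positive (math.inf for a flat membrane)")

    @property
    def e0(self) -> float:
        """Baseline bending-frustration energy density C k0^2 / 2, kBT/nm."""
        return 0.5 * self.C * self.k0**2

    @property
    def flat(self) -> bool:
        return math.isinf(self.r)

    @property
    def l_m(self) -> float:
        """Twist boundary-layer parameter sqrt(K / 2V) * omega0 (dimensionless)."""
        if self.V == 0:
            return math.inf
        return math.sqrt(self.K / (2.0 * self.V)) * self.omega0

    def with_(self, **kwargs) -> "FilamentParams":
        """Copy with some fields replaced."""
        cur = dict(C=self.C, K=self.K, V=self.V, k0=self.k0,
                   omega0=self.omega0, mu0=self.mu0, r=self.r)
        cur.update(kwargs)
        return FilamentParams(**cur)

    # -- parameter-file round trip (flat TOML key=value) --------------------

    @classmethod
    def wild_type(cls, r: float = math.inf) -> "FilamentParams":
        """Wild-type parameter set.

        K, V, k0 and mu0 are the published coarse-grained values; omega0 is the
        ATP-state doublet twist (10.3 deg per 5 nm monomer rise); C is set to
        K's magnitude (its contribution enters only through e0 ~ 0.01 kBT/nm).
        """
        return cls(C=4.6e3, K=4.6e3, V=4.0, k0=2.3e-3,
                   omega0=math.radians(10.3) / MONOMER_RISE_NM, mu0=2.0, r=r)

    @classmethod
    def from_toml(cls, path: str | Path) -> "FilamentParams":
        import tomllib

        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        r = raw.get("r", math.inf)
        if isinstance(r, str):  # "inf" spelled out
            r = math.inf
        return cls(C=raw["C"], K=raw["K"], V=raw["V"], k0=raw["k0"],
                   omega0=raw["omega0"], mu0=raw["mu0"], r=float(r))

    def to_toml(self, path: str | Path) -> None:
        lines = [
            "# coarse-grained filament parameters (kBT / nm / rad units)",
            f"C = {self.C!r}        # bending modulus, kBT nm",
            f"K = {self.K!r}        # torsional modulus, kBT nm",
            f"V = {self.V!r}        # membrane binding potential, kBT/nm",
            f"k0 = {self.k0!r}      # intrinsic curvature, rad/nm",
            f"omega0 = {self.omega0!r}  # intrinsic twist rate, rad/nm (positive = left-handed)",
            f"mu0 = {self.mu0!r}    # polymerization energy density, kBT/nm",
        ]
        if not self.flat:
            lines.append(f"r = {self.r!r}       # membrane cylinder radius, nm")
        Path(path).write_text("\n".join(lines) + "\n")


@dataclass
class FilamentState:
    """Discretized filament configuration.

    ``theta`` and ``psi`` hold angle values (radians) at the ``N + 1`` nodes
    bounding ``N`` segments of length ``segment_length``; the total length is
    ``L = N * segment_length``.  ``psi`` is stored unwrapped (continuous).
    """

    segment_length: float
    theta: np.ndarray
    psi: np.ndarray

    def __post_init__(self) -> None:
        self.theta = np.asarray(self.theta, dtype=float)
        self.psi = np.asarray(self.psi, dtype=float)
        if self.segment_length <= 0:
            raise ValueError("segment_length must be positive")
        if self.theta.shape != self.psi.shape or self.theta.ndim != 1:
            raise ValueError("theta and psi must be 1-D arrays of equal length")
        if self.n_segments < 2:
            raise ValueError("need at least 2 segments")
        if not (np.all(np.isfinite(self.theta)) and np.all(np.isfinite(self.psi))):
            raise ValueError("angles must be finite")
        if np.any(self.theta < -1e-12) or np.any(self.theta > np.pi + 1e-12):
            raise ValueError("theta must lie in [0, pi]")
        if np.any(np.abs(np.diff(self.psi)) > np.pi):
            raise ValueError("psi must be continuous (no inter-node jumps > pi)")

    @property
    def n_segments(self) -> int:
        return len(self.theta) - 1

    @property
    def L(self) -> float:
        return self.n_segments * self.segment_length

    @classmethod
    def uniform(cls, L: float, segment_length: float = MONOMER_RISE_NM,
                theta: float = np.pi / 2, psi: float = 0.0) -> "FilamentState":
        """Untilted/untwisted starting configuration of total length ``L``."""
        n = max(2, int(round(L / segment_length)))
        return cls(segment_length=L / n,
                   theta=np.full(n + 1, theta),
                   psi=np.full(n + 1, psi))


@dataclass
class EnergyProfile:
    """Energy-versus-length relation E(L) with its numerical derivative."""

    L_grid: np.ndarray
    E: np.ndarray
    dEdL: np.ndarray
    psi_m_grid: np.ndarray | None = None   # analytical branch only
    E_sd: np.ndarray | None = None         # replicate SD (Monte Carlo branch)

    def __post_init__(self) -> None:
        self.L_grid = np.asarray(self.L_grid, dtype=float)
        self.E = np.asarray(self.E, dtype=float)
        self.dEdL = np.asarray(self.dEdL, dtype=float)
        if not (len(self.L_grid) == len(self.E) == len(self.dEdL)):
            raise ValueError("L_grid, E and dEdL must have equal lengths")
        if np.any(np.diff(self.L_grid) <= 0):
            raise ValueError("L_grid must be strictly increasing")
        if not np.all(np.isfinite(self.E)):
            raise ValueError("E must be finite everywhere")


# ---------------------------------------------------------------------------
# discretized Hamiltonian
# ---------------------------------------------------------------------------


def hamiltonian_energy(state: FilamentState, params: FilamentParams) -> float:
    """Total energy (kBT) of a discretized filament configuration.

    Midpoint-rule discretization over the ``N`` segments: gradient terms use
    nearest-neighbour node differences, pointwise terms use nearest-neighbour
    node averages, each segment weighted by its length, so the quadrature
    covers exactly ``L``.  The flat limit drops the 1/r geometric terms.
    """
    ds = state.segment_length
    th, ps = state.theta, state.psi
    inv_r = 0.0 if params.flat else 1.0 / params.r
    th_bar = 0.5 * (th[1:] + th[:-1])
    ps_bar = 0.5 * (ps[1:] + ps[:-1])
    dth = np.diff(th) / ds
    dps = np.diff(ps) / ds
    dens = (
        params.C * (np.sin(th_bar) ** 2 * inv_r - params.k0) ** 2
        + params.C * dth**2
        + params.K * (dps - np.sin(2.0 * th_bar) * inv_r / 2.0 - params.omega0) ** 2
        + 2.0 * params.V * np.sin(ps_bar / 2.0) ** 2
    )
    return 0.5 * float(np.sum(dens)) * ds


# ---------------------------------------------------------------------------
# flat-membrane analytical branch
# ---------------------------------------------------------------------------


def psi_m_bound(params: FilamentParams) -> float:
    """Largest boundary twist amplitude of the zero-winding bound branch.

    The first integral of the flat Euler-Lagrange equation requires
    ``sin(psi_m / 2) < l_m``; beyond that the filament length diverges.  When
    ``l_m >= 1`` the branch extends to ``psi_m = pi``.
    """
    lm = params.l_m
    if lm >= 1.0:
        return math.pi
    return 2.0 * math.asin(lm)


def _twist_speed(psi: np.ndarray, psi_m: float, params: FilamentParams) -> np.ndarray:
    """|d psi / d s| along the flat minimizer (first integral), rad/nm."""
    return np.sqrt(
        params.omega0**2
        + (2.0 * params.V / params.K)
        * (np.sin(psi / 2.0) ** 2 - math.sin(psi_m / 2.0) ** 2)
    )


def _check_psim(psi_m: float, params: FilamentParams) -> None:
    if psi_m < 0:
        raise ValueError("psi_m must be non-negative")
    if params.omega0 <= 0 or params.V <= 0:
        raise ValueError("flat branch requires omega0 > 0 and V > 0")
    if math.sin(psi_m / 2.0) >= params.l_m * (1.0 - 1e-12) or psi_m > math.pi:
        raise PsiBoundError(
            f"psi_m={psi_m:.6f} rad is at/above the branch bound "
            f"{psi_m_bound(params):.6f} rad (sin(psi_m/2) >= l_m): L diverges"
        )


def flat_length_of_psim(psi_m: float, params: FilamentParams, n: int = 0,
                        method: str = "quad") -> float:
    """Filament length whose flat-membrane minimizer has boundary twist psi_m.

    ``method="quad"`` (normative) integrates ds/dpsi over the symmetric twist
    range; ``method="elliptic"`` evaluates the closed form in terms of
    incomplete elliptic integrals of the first kind (validated against the
    quadrature path to 1e-6 relative).  ``n`` counts full 2*pi twist repeats;
    only ``n = 0`` is exercised against published results.
    """
    if psi_m == 0 and n == 0:
        return 0.0
    _check_psim(psi_m, params)
    if method == "elliptic":
        lm = params.l_m
        denom = 2.0 * lm**2 + math.cos(psi_m) - 1.0
        m = -2.0 / denom
        pref = math.sqrt(lm**2 / denom) / params.omega0
        L = 4.0 * math.sqrt(2.0) * pref * special.ellipkinc(psi_m / 2.0, m)
        if n:
            L += 8.0 * math.sqrt(2.0) * n * pref * special.ellipk(m)
        return float(L)
    if method != "quad":
        raise ValueError(f"unknown method {method!r}")

    def inv_speed(p: float) -> float:
        return 1.0 / _twist_speed(np.asarray(p), psi_m, params)

    # symmetric part, psi in (-psi_m, psi_m)
    val, _ = integrate.quad(inv_speed, 0.0, psi_m, limit=200)
    L = 2.0 * val
    if n:
        # n full repeats traverse the periodic potential 2n more times
        per, _ = integrate.quad(inv_speed, -psi_m, 2.0 * math.pi - psi_m, limit=200)
        L += n * per
    return float(L)


def flat_energy_of_psim(psi_m: float, params: FilamentParams, n: int = 0,
                        method: str = "quad") -> float:
    """Minimized flat-membrane energy (kBT) at boundary twist psi_m.

    Includes the twist/binding boundary-layer terms plus the extensive
    ``V sin^2(psi_m/2) L`` and ``e0 L`` contributions.
    """
    if psi_m == 0 and n == 0:
        return 0.0
    _check_psim(psi_m, params)
    L = flat_length_of_psim(psi_m, params, n=n, method=method)
    tail = params.V * math.sin(psi_m / 2.0) ** 2 * L + params.e0 * L
    if method == "elliptic":
        lm = params.l_m
        denom = 2.0 * lm**2 + math.cos(psi_m) - 1.0
        m = -2.0 / denom
        pref = params.K * params.omega0 * math.sqrt(denom / lm**2)
        E = 2.0 * math.sqrt(2.0) * pref * special.ellipeinc(psi_m / 2.0, m)
        if n:
            E += 4.0 * math.sqrt(2.0) * n * pref * special.ellipe(m)
        return float(E - 2.0 * params.K * params.omega0 * (psi_m + n * math.pi) + tail)

    def speed(p: float) -> float:
        return float(_twist_speed(np.asarray(p), psi_m, params))

    val, _ = integrate.quad(speed, 0.0, psi_m, limit=200)
    E = 2.0 * params.K * val
    if n:
        per, _ = integrate.quad(speed, -psi_m, 2.0 * math.pi - psi_m, limit=200)
        E += n * params.K * per
    return float(E - 2.0 * params.K * params.omega0 * (psi_m + n * math.pi) + tail)


def flat_psim_at_length(L: float, params: FilamentParams) -> float:
    """Invert L(psi_m) on the monotone zero-winding branch (bisection)."""
    if L < 0:
        raise ValueError("L must be non-negative")
    if L == 0:
        return 0.0
    bound = psi_m_bound(params)
    hi = bound * (1.0 - 1e-10)
    if flat_length_of_psim(hi, params) < L:
        raise PsiBoundError(f"L={L} nm beyond the zero-winding branch")
    return float(optimize.brentq(
        lambda p: flat_length_of_psim(p, params) - L, 1e-12, hi, xtol=1e-12))


def flat_energy_at_length(L: float, params: FilamentParams) -> float:
    """Minimized flat-membrane energy at total length ``L`` (kBT)."""
    return flat_energy_of_psim(flat_psim_at_length(L, params), params)


def asymptotic_density(params: FilamentParams) -> float:
    """Large-L flat energy density e0 + K omega0^2 / 2 (fully bound interior)."""
    return params.e0 + 0.5 * params.K * params.omega0**2


def energy_length_curve(params: FilamentParams, L_max: float = DEFAULT_L_MAX,
                        n_points: int = 400, n_psi: int = 1200) -> EnergyProfile:
    """Analytical flat-membrane energy-length curve up to ``L_max``.

    Sweeps psi_m over the zero-winding branch, restricts to the monotone
    L(psi_m) branch, resamples onto a uniform L grid and differentiates a
    monotone (PCHIP) spline for dE/dL.  Deterministic.
    """
    if not params.flat:
        raise ValueError("analytical curve requires a flat membrane; use monte_carlo")
    if params.omega0 == 0 or params.V == 0:
        # no twist frustration: optimal psi identically 0 (or free), E = e0 L
        L_grid = np.linspace(0.0, L_max, n_points)
        dens = params.e0 if params.V > 0 or params.omega0 == 0 else asymptotic_density(params)
        return EnergyProfile(L_grid=L_grid[1:], E=dens * L_grid[1:],
                             dEdL=np.full(n_points - 1, dens),
                             psi_m_grid=np.zeros(n_points - 1))

    bound = psi_m_bound(params)
    # cluster points toward the bound where L blows up
    pms = bound * (1.0 - np.geomspace(1.0, 1e-9, n_psi))
    pms = pms[pms > 0]
    Ls = np.empty_like(pms)
    Es = np.empty_like(pms)
    for i, pm in enumerate(pms):
        Ls[i] = flat_length_of_psim(pm, params)
        Es[i] = flat_energy_of_psim(pm, params)
    keep = Ls <= max(L_max * 1.1, Ls[0])
    # guard the monotone branch
    mono = np.concatenate(([True], np.diff(Ls) > 0))
    if not mono.all():
        first_bad = np.argmin(mono)
        logger.info("restricting to monotone L(psi_m) branch: %d of %d points kept",
                    first_bad, len(Ls))
        keep &= np.arange(len(Ls)) < first_bad
    pms, Ls, Es = pms[keep], Ls[keep], Es[keep]
    spline = interpolate.PchipInterpolator(Ls, Es)
    L_grid = np.linspace(Ls[0], min(Ls[-1], L_max), n_points)
    E = spline(L_grid)
    dEdL = spline.derivative()(L_grid)
    psi_on_grid = np.interp(L_grid, Ls, pms)
    return EnergyProfile(L_grid=L_grid, E=E, dEdL=dEdL, psi_m_grid=psi_on_grid)


def limit_length(profile: EnergyProfile, mu0: float) -> float:
    """Smallest L on the profile where dE/dL reaches mu0, by interpolation.

    Returns ``math.inf`` ("unbounded") when dE/dL stays below mu0 over the
    whole grid.  Multiple crossings are logged; the first is returned.
    """
    above = profile.dEdL >= mu0
    if not above.any():
        return math.inf
    crossings = np.flatnonzero(~above[:-1] & above[1:])
    if above[0]:
        logger.info("dE/dL already above mu0 at the smallest tabulated length")
        return float(profile.L_grid[0])
    if len(crossings) > 1:
        logger.info("multiple dE/dL = mu0 crossings at L ~ %s; returning the first",
                    profile.L_grid[crossings + 1])
    i = crossings[0]
    x0, x1 = profile.L_grid[i], profile.L_grid[i + 1]
    y0, y1 = profile.dEdL[i], profile.dEdL[i + 1]
    return float(x0 + (mu0 - y0) * (x1 - x0) / (y1 - y0))


# ---------------------------------------------------------------------------
# cylinder: tilted interior density and quasi-1D pitch prediction
# ---------------------------------------------------------------------------


def bound_state_density(theta: float, params: FilamentParams) -> float:
    """Energy density of a fully bound, uniformly tilted interior (kBT/nm).

    Interior state psi = 0, psi' = 0, uniform pitch ``theta`` on a cylinder:
    the geometric rotation rate sin(2 theta)/(2 r) of the surface normal along
    a helix offsets part of the intrinsic twist frustration.
    """
    inv_r = 0.0 if params.flat else 1.0 / params.r
    return 0.5 * (
        params.C * (math.sin(theta) ** 2 * inv_r - params.k0) ** 2
        + params.K * (math.sin(2.0 * theta) * inv_r / 2.0 + params.omega0) ** 2
    )


def optimal_tilt(params: FilamentParams) -> float:
    """Pitch angle (radians) minimizing the bound interior density."""
    res = optimize.minimize_scalar(bound_state_density, bounds=(0.0, math.pi),
                                   args=(params,), method="bounded")
    return float(res.x)


def tilted_energy_at_length(theta: float, L: float, params: FilamentParams) -> float:
    """Quasi-1D energy of a uniformly tilted filament of length L on a cylinder.

    The tilt renormalizes the twist frustration to
    ``omega_eff = omega0 + sin(2 theta)/(2 r)``; the twist/binding profile then
    solves the same flat boundary-layer problem at ``omega_eff``, and the
    bending mismatch ``C (sin^2 theta / r - k0)^2 / 2`` accrues per length.
    Used for fast pitch predictions; the Monte Carlo module is the full model.
    """
    inv_r = 0.0 if params.flat else 1.0 / params.r
    om_eff = params.omega0 + math.sin(2.0 * theta) * inv_r / 2.0
    bend = 0.5 * params.C * (math.sin(theta) ** 2 * inv_r - params.k0) ** 2 * L
    if om_eff <= 0:
        # frustration fully cancelled: untwisted bound interior
        return bend + 0.5 * params.K * om_eff**2 * L
    eff = params.with_(omega0=om_eff, k0=0.0, C=0.0, r=math.inf)
    try:
        twist = flat_energy_at_length(L, eff)
    except PsiBoundError:
        # beyond the bound branch at this tilt; disfavoured strongly
        twist = 0.5 * params.K * om_eff**2 * L
    return bend + twist


def predicted_pitch(L: float, params: FilamentParams) -> float:
    """Pitch angle (degrees) minimizing the quasi-1D energy at length L."""
    res = optimize.minimize_scalar(tilted_energy_at_length, bounds=(0.0, math.pi),
                                   args=(L, params), method="bounded",
                                   options={"xatol": 1e-6})
    return math.degrees(float(res.x))
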