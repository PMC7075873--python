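"""Metropolis minimization of the discretized filament Hamiltonian.

The filament of length ``L`` is discretized into segments carrying node angles
(theta_i, psi_i); starting from theta = 90 deg, psi = 0, single-angle moves are
accepted with the Metropolis rule p = exp(-dE/kBT) (1 for downhill).  The run
has an exploration phase at the working temperature, then cools geometrically
so the printed convergence rule (energy fluctuations below 1% of the minimized
energy across the previous 1e4 steps) can actually trigger, and finally the
best-found state is polished by a deterministic quasi-Newton descent.  A
``pure`` mode (no cooling, no polish) retains the literal fixed-temperature
algorithm for acceptance-statistics checks.

Proposals that would take |psi| past pi are rejected: the model's analytics
live in the zero-winding sector (no full 360 deg twist along the filament),
and unconstrained dynamics would escape it at large L via twist walls.

Energies are in kBT, lengths in nm; the inner loop is numba-compiled.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
from numba import njit
from scipy import optimize

from mrebtwist.core_model import (
    EnergyProfile,
    FilamentParams,
    FilamentState,
    MONOMER_RISE_NM,
    hamiltonian_energy,
    limit_length,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class MCConfig:
    """Knobs of the Metropolis minimization.

    ``max_steps``/``convergence_window``/``convergence_tol``/``replicates``
    follow the published protocol (1e7 steps, 1% fluctuation over the previous
    1e4 steps, 20 replicates); the proposal amplitude is auto-tuned to a
    30-50% acceptance rate.  ``anneal_frac`` of the budget runs at
    ``temperature`` before geometric cooling to ``t_final``; ``polish`` adds a
    deterministic descent from the best-found state.  ``pure=True`` disables
    cooling and polishing (literal fixed-temperature Metropolis).
    """

    segment_length: float = MONOMER_RISE_NM
    max_steps: int = 10_000_000
    convergence_window: int = 10_000
    convergence_tol: float = 0.01
    proposal_amplitude: float = 0.3
    replicates: int = 20
    seed: int = 0
    temperature: float = 1.0
    anneal_frac: float = 0.3
    t_final: float = 1e-4
    abs_fluct_tol: float = 0.05
    polish: bool = True
    pure: bool = False
    trace_every: int = 1000

    def __post_init__(self) -> None:
        if self.max_steps < self.convergence_window:
            raise ValueError("max_steps must be >= convergence_window")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.convergence_tol <= 0:
            raise ValueError("convergence_tol must be positive")


@dataclass
class MCResult:
    """Outcome of one Metropolis minimization."""

    final_state: FilamentState
    energy: float
    energy_trace: np.ndarray
    converged: bool
    accepted_fraction: float
    seed: int
    steps_run: int
    # uphill-proposal statistics for acceptance-rule checks
    n_uphill: int = 0
    n_uphill_accepted: int = 0
    mean_uphill_boltzmann: float = 0.0


class PitchSummary(NamedTuple):
    pitch_deg: float
    deviation_deg: float


@njit(cache=True)
def _interval_energy(t0, t1, p0, p1, ds, C, K, V, k0, w0, inv_r):
    tb = 0.5 * (t0 + t1)
    pb = 0.5 * (p0 + p1)
    dt = (t1 - t0) / ds
    dp = (p1 - p0) / ds
    s = math.sin(tb)
    sp = math.sin(0.5 * pb)
    return 0.5 * ds * (
        C * (s * s * inv_r - k0) ** 2
        + C * dt * dt
        + K * (dp - math.sin(2.0 * tb) * inv_r * 0.5 - w0) ** 2
        + 2.0 * V * sp * sp
    )


@njit(cache=True)
def _total_energy(theta, psi, ds, C, K, V, k0, w0, inv_r):
    e = 0.0
    for i in range(theta.shape[0] - 1):
        e += _interval_energy(theta[i], theta[i + 1], psi[i], psi[i + 1],
                              ds, C, K, V, k0, w0, inv_r)
    return e


@njit(cache=True)
def _node_energy(theta, psi, j, ds, C, K, V, k0, w0, inv_r):
    """Sum of the interval energies touching node j."""
    e = 0.0
    if j > 0:
        e += _interval_energy(theta[j - 1], theta[j], psi[j - 1], psi[j],
                              ds, C, K, V, k0, w0, inv_r)
    if j < theta.shape[0] - 1:
        e += _interval_energy(theta[j], theta[j + 1], psi[j], psi[j + 1],
                              ds, C, K, V, k0, w0, inv_r)
    return e


@njit(cache=True)
def _mc_kernel(theta, psi, ds, C, K, V, k0, w0, inv_r,
               n_steps, temp0, t_final, anneal_start, delta0,
               window, tol, abs_tol, seed, trace_every, pure):
    """Annealed single-angle Metropolis walk; returns best-found state.

    Returns (theta_best, psi_best, trace, n_trace, steps_done, accepted,
    converged, n_uphill, n_uphill_acc, sum_boltzmann).
    """
    np.random.seed(seed)
    n_nodes = theta.shape[0]
    theta_best = theta.copy()
    psi_best = psi.copy()
    e_cur = _total_energy(theta, psi, ds, C, K, V, k0, w0, inv_r)
    e_best = e_cur

    trace = np.empty(n_steps // trace_every + 2, dtype=np.float64)
    trace[0] = e_cur
    n_trace = 1

    temp = temp0
    cool = 1.0
    if not pure and n_steps > anneal_start:
        cool = (t_final / temp0) ** (1.0 / (n_steps - anneal_start))

    delta = delta0
    acc_win = 0
    prop_win = 0
    accepted = 0
    wmin = e_cur
    wmax = e_cur
    converged = False
    n_up = 0
    n_up_acc = 0
    sum_boltz = 0.0
    steps_done = 0

    for t in range(n_steps):
        steps_done = t + 1
        if not pure and t >= anneal_start:
            temp *= cool
        j = int(np.random.random() * n_nodes)
        if j == n_nodes:
            j = n_nodes - 1
        move_theta = np.random.random() < 0.5
        step = (2.0 * np.random.random() - 1.0) * delta
        prop_win += 1

        acc = False
        if move_theta:
            new = theta[j] + step
            if 0.0 <= new <= math.pi:
                e_old = _node_energy(theta, psi, j, ds, C, K, V, k0, w0, inv_r)
                old = theta[j]
                theta[j] = new
                e_new = _node_energy(theta, psi, j, ds, C, K, V, k0, w0, inv_r)
                d_e = e_new - e_old
                if d_e <= 0.0:
                    acc = True
                else:
                    n_up += 1
                    p = math.exp(-d_e / temp)
                    sum_boltz += p
                    if np.random.random() < p:
                        acc = True
                        n_up_acc += 1
                    else:
                        theta[j] = old
        else:
            new = psi[j] + step
            if -math.pi <= new <= math.pi:
                e_old = _node_energy(theta, psi, j, ds, C, K, V, k0, w0, inv_r)
                old = psi[j]
                psi[j] = new
                e_new = _node_energy(theta, psi, j, ds, C, K, V, k0, w0, inv_r)
                d_e = e_new - e_old
                if d_e <= 0.0:
                    acc = True
                else:
                    n_up += 1
                    p = math.exp(-d_e / temp)
                    sum_boltz += p
                    if np.random.random() < p:
                        acc = True
                        n_up_acc += 1
                    else:
                        psi[j] = old
        if acc:
            accepted += 1
            acc_win += 1
            e_cur += d_e
            if e_cur < e_best:
                e_best = e_cur
                for q in range(n_nodes):
                    theta_best[q] = theta[q]
                    psi_best[q] = psi[q]
            if e_cur < wmin:
                wmin = e_cur
            if e_cur > wmax:
                wmax = e_cur

        if (t + 1) % trace_every == 0:
            trace[n_trace] = e_cur
            n_trace += 1
        if (t + 1) % 1000 == 0:
            rate = acc_win / prop_win
            if rate > 0.5:
                delta *= 1.15
            elif rate < 0.3:
                delta /= 1.15
            if delta > 1.0:
                delta = 1.0
            elif delta < 1e-5:
                delta = 1e-5
            acc_win = 0
            prop_win = 0
        if (t + 1) % window == 0:
            # re-sync accumulated energy against drift
            e_cur = _total_energy(theta, psi, ds, C, K, V, k0, w0, inv_r)
            fluct = wmax - wmin
            floor = tol * abs(e_best)
            if not pure:
                if temp <= 2.0 * t_final and fluct < max(floor, abs_tol):
                    converged = True
                    break
            elif fluct < floor:
                converged = True
                break
            wmin = e_cur
            wmax = e_cur

    return (theta_best, psi_best, trace[:n_trace], steps_done, accepted,
            converged, n_up, n_up_acc, sum_boltz)


def _energy_and_grad(x: np.ndarray, ds: float, C: float, K: float, V: float,
                     k0: float, w0: float, inv_r: float):
    """Vectorized energy + analytic gradient over packed [theta, psi] nodes."""
    n = x.size // 2
    th, ps = x[:n], x[n:]
    tb = 0.5 * (th[1:] + th[:-1])
    pb = 0.5 * (ps[1:] + ps[:-1])
    dt = np.diff(th) / ds
    dp = np.diff(ps) / ds
    bend_mis = np.sin(tb) ** 2 * inv_r - k0
    twist_mis = dp - np.sin(2.0 * tb) * inv_r * 0.5 - w0
    e = 0.5 * ds * np.sum(
        C * bend_mis**2 + C * dt**2 + K * twist_mis**2
        + 2.0 * V * np.sin(pb / 2.0) ** 2
    )
    # d/d tb and d/d pb of the per-interval density, times ds
    g_tb = ds * (C * bend_mis * np.sin(2.0 * tb) * inv_r
                 - K * twist_mis * np.cos(2.0 * tb) * inv_r)
    g_pb = 0.5 * ds * V * np.sin(pb)
    g_th = np.zeros(n)
    g_ps = np.zeros(n)
    g_th[:-1] += 0.5 * g_tb - C * dt
    g_th[1:] += 0.5 * g_tb + C * dt
    g_ps[:-1] += 0.5 * g_pb - K * twist_mis
    g_ps[1:] += 0.5 * g_pb + K * twist_mis
    return e, np.concatenate([g_th, g_ps])


def _polish(theta: np.ndarray, psi: np.ndarray, ds: float,
            params: FilamentParams) -> tuple[np.ndarray, np.ndarray]:
    inv_r = 0.0 if params.flat else 1.0 / params.r
    x0 = np.concatenate([theta, psi])
    n = theta.size
    bounds = [(0.0, math.pi)] * n + [(-math.pi, math.pi)] * n
    res = optimize.minimize(
        _energy_and_grad, x0, jac=True,
        args=(ds, params.C, params.K, params.V, params.k0, params.omega0, inv_r),
        method="L-BFGS-B", bounds=bounds,
        options={"maxiter": 2000, "ftol": 1e-14, "gtol": 1e-10},
    )
    return res.x[:n].copy(), res.x[n:].copy()


def metropolis_minimize(params: FilamentParams, L: float,
                        config: MCConfig | None = None) -> MCResult:
    """Minimize the discretized Hamiltonian for a filament of length L (nm).

    Fully reproducible from ``config.seed``.  The returned energy is always
    recomputed with :func:`mrebtwist.core_model.hamiltonian_energy` on the
    final state.
    """
    if L <= 0:
        raise ValueError("L must be positive")
    config = config or MCConfig()
    n_seg = max(2, int(round(L / config.segment_length)))
    ds = L / n_seg
    theta = np.full(n_seg + 1, math.pi / 2.0)
    psi = np.zeros(n_seg + 1)
    inv_r = 0.0 if params.flat else 1.0 / params.r
    anneal_start = int(config.anneal_frac * config.max_steps)

    (theta_b, psi_b, trace, steps_done, accepted, converged,
     n_up, n_up_acc, sum_boltz) = _mc_kernel(
        theta, psi, ds, params.C, params.K, params.V, params.k0, params.omega0,
        inv_r, config.max_steps, config.temperature, config.t_final,
        anneal_start, config.proposal_amplitude, config.convergence_window,
        config.convergence_tol, config.abs_fluct_tol, config.seed,
        config.trace_every, config.pure,
    )
    if config.polish and not config.pure:
        theta_b, psi_b = _polish(theta_b, psi_b, ds, params)
    state = FilamentState(segment_length=ds, theta=theta_b, psi=psi_b)
    energy = hamiltonian_energy(state, params)
    if not converged:
        logger.warning("MC run (seed=%d, L=%.0f nm) hit max_steps without "
                       "meeting the fluctuation criterion", config.seed, L)
    return MCResult(
        final_state=state, energy=energy, energy_trace=trace,
        converged=converged, accepted_fraction=accepted / max(steps_done, 1),
        seed=config.seed, steps_run=steps_done, n_uphill=n_up,
        n_uphill_accepted=n_up_acc,
        mean_uphill_boltzmann=sum_boltz / n_up if n_up else 0.0,
    )


def replicate_seeds(base_seed: int, n: int) -> list[int]:
    """Independent per-replicate seeds derived from one base seed."""
    return [int(s) for s in np.random.SeedSequence(base_seed).generate_state(n)]


def energy_vs_length_mc(params: FilamentParams, L_grid,
                        config: MCConfig | None = None) -> EnergyProfile:
    """Replicate-averaged Monte Carlo energy-length curve.

    Runs ``config.replicates`` independent minimizations per length (distinct
    seeds spawned from the base seed), averages converged replicates, records
    the replicate SD, and differentiates by centred differences.
    """
    config = config or MCConfig()
    L_grid = np.asarray(L_grid, dtype=float)
    if L_grid.size < 2:
        raise ValueError("need at least 2 lengths to differentiate E(L)")
    if np.any(np.diff(L_grid) <= 0):
        raise ValueError("L_grid must be strictly increasing")
    means = np.empty(L_grid.size)
    sds = np.empty(L_grid.size)
    for i, L in enumerate(L_grid):
        energies = []
        for rep, seed in enumerate(replicate_seeds(config.seed + i, config.replicates)):
            res = metropolis_minimize(params, L, _with(config, seed=seed))
            if res.converged or config.pure:
                energies.append(res.energy)
            else:
                logger.warning("excluding non-converged replicate %d at L=%.0f", rep, L)
        if not energies:
            raise RuntimeError(f"no converged replicate at L={L} nm")
        means[i] = np.mean(energies)
        sds[i] = np.std(energies, ddof=1) if len(energies) > 1 else 0.0
    dEdL = np.gradient(means, L_grid)
    return EnergyProfile(L_grid=L_grid, E=means, dEdL=dEdL, E_sd=sds)


def _with(config: MCConfig, **kw) -> MCConfig:
    d = {f: getattr(config, f) for f in MCConfig.__dataclass_fields__}
    d.update(kw)
    return MCConfig(**d)


def limit_length_mc(params: FilamentParams, config: MCConfig | None = None,
                    L_max: float = 1000.0, L_grid=None) -> float:
    """Limit length from the Monte Carlo energy-length curve.

    Returns ``math.inf`` ("unbounded") when dE/dL stays below mu0 on the grid.
    """
    if L_grid is None:
        L_grid = np.arange(40.0, L_max + 1e-9, 60.0)
    profile = energy_vs_length_mc(params, L_grid, config)
    return limit_length(profile, params.mu0)


def pitch_angle_summary(result: MCResult) -> PitchSummary:
    """Length-weighted mean pitch angle of a minimized state, degrees.

    With uniform segment lengths this is the plain mean of the per-segment
    midpoint tilt; the deviation |pitch - 90 deg| measures how far the
    filament leans away from the circumferential direction.
    """
    th = result.final_state.theta
    mid = 0.5 * (th[1:] + th[:-1])
    pitch = math.degrees(float(np.mean(mid)))
    return PitchSummary(pitch_deg=pitch, deviation_deg=abs(pitch - 90.0))
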