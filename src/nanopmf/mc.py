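"""Metropolis Monte Carlo with inverse-temperature annealing.

Sampling protocol: the coupling parameter lam = beta/beta_T runs over an
equally spaced grid from 0 (hard-sphere fluid, infinite temperature) to 1
(target temperature, 25 °C), and the final configuration at each lam seeds
the chain at the next, higher lam.  At each lam the chain runs until the
cumulative post-burn-in mean energy changes by less than a salt-dependent
threshold over a 10^4-step window, the convergence rule used throughout this
package (0.005 k_BT for 1:1 salt, 0.001 k_BT for 2:2 salt).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from . import _kernels, energy
from .results import BetaResult, TIResult, Trajectory
from .state import MCState
from .system import SimulationCell, SystemSpec

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class BetaSchedule:
    """Equally spaced grid of lam = beta/beta_T values from 0 to 1."""

    n_intervals: int = 20

    def __post_init__(self):
        if self.n_intervals < 1:
            raise ValueError("need at least one interval")

    @property
    def lambdas(self) -> np.ndarray:
        return np.linspace(0.0, 1.0, self.n_intervals + 1)


@dataclass(frozen=True)
class ConvergenceSpec:
    """Stopping rule for the per-lam chains.

    ``threshold`` is the tolerated change of the cumulative mean energy over
    one ``window`` of steps; ``burn_in`` steps are discarded before averaging
    starts (during them the proposal width adapts toward 30-50% acceptance).
    """

    window: int = 10_000
    threshold: float = 0.005  # k_BT
    max_steps: int = 3_000_000
    burn_in: int = 50_000
    min_windows: int = 4

    def __post_init__(self):
        if self.window <= 0 or self.threshold <= 0:
            raise ValueError("window and threshold must be positive")
        if self.burn_in < 0 or self.max_steps <= 0:
            raise ValueError("burn_in and max_steps must be sensible")


def default_threshold(spec: SystemSpec) -> float:
    """Convergence threshold by salt type: 0.005 k_BT (1:1), 0.001 (2:2+)."""
    if max(spec.cation.valence, -spec.anion.valence) >= 2:
        return 0.001
    return 0.005


def convergence_for(spec: SystemSpec, **overrides) -> ConvergenceSpec:
    kw = {"threshold": default_threshold(spec)}
    kw.update(overrides)
    return ConvergenceSpec(**kw)


def acceptance_probability(delta_u: float, lam: float) -> float:
    """Metropolis acceptance min(1, exp(-lam * dU)) for non-overlapping moves."""
    if lam < 0:
        raise ValueError("lam must be non-negative")
    if delta_u <= 0.0:
        return 1.0
    return math.exp(-lam * delta_u)


def metropolis_step(spec: SystemSpec, cell: SimulationCell, state: MCState,
                    lam: float, max_displacement: float) -> bool:
    """One reference-implementation Metropolis move (mutates ``state``).

    Picks an ion uniformly, proposes a uniform displacement in a cube of
    half-width ``max_displacement``, rejects hard-core overlaps outright and
    otherwise accepts with min(1, exp(-lam dU)).  Used for unit checks; the
    production chains run through the compiled kernel.
    """
    rng = state.rng
    i = int(rng.integers(state.n_ions))
    proposal = state.positions[i] + max_displacement * (2.0 * rng.random(3) - 1.0)
    proposal = energy.wrap_positions(proposal, cell)
    state.steps += 1
    if energy.hardcore_overlap(spec, cell, state.positions, state.radii,
                               candidate=proposal,
                               candidate_radius=state.radii[i],
                               exclude_index=i):
        return False
    du = energy.move_delta_energy(spec, cell, state, i, proposal)
    if du > 0.0 and rng.random() >= math.exp(-lam * du):
        return False
    state.positions[i] = proposal
    state.energy += du
    return True


def _kernel_seed(rng: np.random.Generator) -> int:
    return int(rng.integers(1, 2**31 - 1))


@dataclass
class _ChainDriver:
    """Thin wrapper that feeds the compiled kernel in segments."""

    spec: SystemSpec
    cell: SimulationCell
    state: MCState
    lam: float
    displacement: float
    lattice: float = 0.0
    lattice_kmax: int = 2
    jump_prob: float = 0.15
    target_prob: float = 0.0
    target_radius: float = 0.0

    def run(self, nsteps: int) -> tuple[int, float]:
        """Advance ``nsteps``; returns (accepted, sum of U over the steps)."""
        if nsteps <= 0:
            return 0, 0.0
        st = self.state
        if st.n_ions == 0:
            st.steps += nsteps
            return 0, st.energy * nsteps
        u, nacc, usum = _kernels.run_chain(
            st.positions, st.valences, st.radii,
            self.spec.nanoparticles.centers,
            float(self.spec.nanoparticles.charge),
            float(self.spec.nanoparticles.radius),
            self.cell.lengths, self.spec.bjerrum_length, float(self.lam),
            float(self.displacement), int(nsteps), _kernel_seed(st.rng),
            float(st.energy), float(self.lattice), int(self.lattice_kmax),
            float(self.jump_prob), float(self.target_prob),
            float(self.target_radius if self.target_radius > 0.0
                  else self.spec.nanoparticles.radius + 10.0))
        st.energy = float(u)
        st.steps += nsteps
        return int(nacc), float(usum)


def run_at_beta(spec: SystemSpec, cell: SimulationCell, state: MCState,
                lam: float, conv: ConvergenceSpec,
                displacement: float | None = None,
                adapt: bool = True, jump_prob: float = 0.15,
                target_prob: float = 0.0, target_radius: float = 0.0,
                lattice: float = 0.0, lattice_kmax: int = 2) -> BetaResult:
    """Sample <U> at one lam point until the running mean stabilises.

    Mutates ``state`` (it ends equilibrated at this lam, ready to seed the
    next point of the annealing schedule).  The mean is the cumulative
    running mean over post-burn-in steps; the chain stops once its change
    across one window is at or below ``conv.threshold``, or is flagged
    unconverged at ``conv.max_steps``.  The standard error comes from batch
    means over windows.
    """
    if displacement is None:
        displacement = min(4.0 * np.min(state.radii, initial=2.0),
                           float(np.min(cell.lengths)) / 8.0)
    driver = _ChainDriver(spec, cell, state, lam, displacement,
                          lattice=lattice, lattice_kmax=lattice_kmax,
                          jump_prob=0.0 if lattice > 0.0 else jump_prob,
                          target_prob=0.0 if lattice > 0.0 else target_prob,
                          target_radius=target_radius)

    if state.n_ions == 0:
        # nothing mobile: <U> is the fixed nanoparticle energy, exactly
        return BetaResult(lam=lam, mean_energy=state.energy, stderr=0.0,
                          steps=0, acceptance=0.0, converged=True,
                          displacement=displacement)

    # burn-in with proposal-width adaptation (frozen afterwards)
    adapt_chunk = 2000
    done = 0
    while done < conv.burn_in:
        n = min(adapt_chunk, conv.burn_in - done)
        nacc, _ = driver.run(n)
        done += n
        if adapt and lattice <= 0.0:
            rate = nacc / n
            if rate < 0.30:
                driver.displacement = max(driver.displacement * 0.85, 0.3)
            elif rate > 0.50:
                driver.displacement = min(driver.displacement * 1.15,
                                          float(np.min(cell.lengths)) / 4.0)

    usum_total = 0.0
    steps_total = 0
    acc_total = 0
    window_means: list[float] = []
    prev_mean = None
    converged = False
    while steps_total < conv.max_steps:
        nacc, usum = driver.run(conv.window)
        acc_total += nacc
        usum_total += usum
        steps_total += conv.window
        window_means.append(usum / conv.window)
        mean_now = usum_total / steps_total
        if prev_mean is not None and len(window_means) >= conv.min_windows:
            if abs(mean_now - prev_mean) <= conv.threshold:
                converged = True
                prev_mean = mean_now
                break
        prev_mean = mean_now

    wm = np.asarray(window_means)
    mean = usum_total / steps_total
    stderr = float(np.std(wm, ddof=1) / math.sqrt(len(wm))) if len(wm) > 1 else float("nan")
    if not converged:
        logger.warning("lam=%.3f not converged after %d steps (|d<U>| > %.4g)",
                       lam, steps_total, conv.threshold)
    return BetaResult(lam=lam, mean_energy=float(mean), stderr=stderr,
                      steps=steps_total, acceptance=acc_total / steps_total,
                      converged=converged, displacement=driver.displacement)


def anneal(spec: SystemSpec, cell: SimulationCell, state: MCState,
           schedule: BetaSchedule | None = None,
           conv: ConvergenceSpec | None = None,
           lattice: float = 0.0, lattice_kmax: int = 2,
           jump_prob: float = 0.15, target_prob: float = 0.0,
           seed: int | None = None) -> TIResult:
    """Chain ``run_at_beta`` over the full annealing schedule.

    The configuration equilibrated at each lam is the initial state for the
    next, higher lam.  Returns the <U> samples needed by the TI sum.
    """
    schedule = schedule or BetaSchedule()
    conv = conv or convergence_for(spec)
    lambdas = schedule.lambdas
    means = np.empty_like(lambdas)
    errs = np.empty_like(lambdas)
    flags = np.zeros(lambdas.shape, dtype=bool)
    accs = np.empty_like(lambdas)
    steps = np.zeros(lambdas.shape, dtype=np.int64)
    displacement = None
    for k, lam in enumerate(lambdas):
        res = run_at_beta(spec, cell, state, float(lam), conv,
                          displacement=displacement, jump_prob=jump_prob,
                          target_prob=target_prob,
                          lattice=lattice, lattice_kmax=lattice_kmax)
        displacement = res.displacement
        means[k] = res.mean_energy
        errs[k] = res.stderr
        flags[k] = res.converged
        accs[k] = res.acceptance
        steps[k] = res.steps
    return TIResult(lambdas=lambdas, mean_energy=means, stderr=errs,
                    converged=flags, acceptance=accs, steps=steps, seed=seed)


def sample_frames(spec: SystemSpec, cell: SimulationCell, state: MCState,
                  n_frames: int, stride: int = 1000,
                  displacement: float = 4.0, lam: float = 1.0) -> Trajectory:
    """Collect decorrelated snapshots from an equilibrated chain at lam.

    The state should already be equilibrated (e.g. by :func:`anneal`); frames
    are taken every ``stride`` accepted-or-rejected steps.
    """
    driver = _ChainDriver(spec, cell, state, lam, displacement)
    frames = np.empty((n_frames, state.n_ions, 3))
    for f in range(n_frames):
        driver.run(stride)
        frames[f] = state.positions
    return Trajectory(positions=frames, valences=state.valences.copy(),
                      radii=state.radii.copy(),
                      cell_lengths=cell.lengths.copy(), stride=stride)


def equilibrate_at_target(spec: SystemSpec, cell: SimulationCell, seed,
                          schedule: BetaSchedule | None = None,
                          conv: ConvergenceSpec | None = None) -> MCState:
    """Populate ions and anneal them from lam = 0 to the target temperature."""
    from .system import populate_ions

    state = populate_ions(spec, cell, seed)
    anneal(spec, cell, state, schedule=schedule, conv=conv)
    return state
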