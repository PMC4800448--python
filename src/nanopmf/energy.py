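"""Primitive-model interaction energy: Coulomb plus hard cores.

Pair energy between charges q_i, q_j (in e) at minimum-image distance r:

    U_ij = q_i q_j l_B / r    (k_B T)

with l_B the Bjerrum length.  Overlapping hard spheres (r < sigma_ij, the sum
of radii) carry infinite energy and are handled as outright rejections, never
as numeric infinities inside energy sums.  Periodic boundaries use the
minimum-image convention without Ewald summation: cells are sized to at least
eight Debye lengths, so interactions are screened out well inside half a box.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import constants
from .state import MCState
from .system import SimulationCell, SystemSpec


@dataclass(frozen=True)
class EnergyModel:
    """Dielectric/temperature context for energy evaluation."""

    dielectric: float = constants.DEFAULT_DIELECTRIC
    temperature: float = constants.DEFAULT_TEMPERATURE

    @property
    def bjerrum_length(self) -> float:
        return constants.bjerrum_length(self.temperature, self.dielectric)


def min_image_displacement(pos_i, pos_j, cell: SimulationCell) -> np.ndarray:
    """Shortest periodic displacement vector pos_i - pos_j (Å).

    Supports broadcasting over leading axes.  Each component of the result
    has magnitude at most half the corresponding cell edge.
    """
    d = np.asarray(pos_i, dtype=float) - np.asarray(pos_j, dtype=float)
    L = cell.lengths
    per = np.array(cell.periodic, dtype=bool)
    shift = np.where(per, L * np.round(d / L), 0.0)
    return d - shift


def pair_coulomb(q_i: float, q_j: float, r_ij, lb: float) -> float:
    """Coulomb energy q_i q_j l_B / r in k_B T; r must be positive."""
    r = np.asarray(r_ij, dtype=float)
    if np.any(r <= 0):
        raise ValueError("pair distance must be positive")
    return q_i * q_j * lb / r


def hardcore_overlap(spec: SystemSpec, cell: SimulationCell,
                     positions: np.ndarray, radii: np.ndarray,
                     candidate: np.ndarray | None = None,
                     candidate_radius: float | None = None,
                     exclude_index: int | None = None) -> bool:
    """True iff any minimum-image pair distance is below the contact distance.

    Without a candidate, checks the whole configuration (ion-ion and
    ion-nanoparticle).  With one, checks only the candidate against
    nanoparticles and all ions except ``exclude_index``.
    """
    positions = np.atleast_2d(positions)
    centers = spec.nanoparticles.centers
    np_rad = spec.nanoparticles.radius
    if candidate is not None:
        if candidate_radius is None:
            raise ValueError("candidate_radius required with candidate")
        d = min_image_displacement(candidate[None, :], centers, cell)
        if np.any(np.linalg.norm(d, axis=-1) < np_rad + candidate_radius):
            return True
        if len(positions):
            mask = np.ones(len(positions), dtype=bool)
            if exclude_index is not None:
                mask[exclude_index] = False
            d = min_image_displacement(candidate[None, :], positions[mask], cell)
            if np.any(np.linalg.norm(d, axis=-1) < radii[mask] + candidate_radius):
                return True
        return False

    n = len(positions)
    if n:
        d = min_image_displacement(positions[:, None, :], centers[None, :, :], cell)
        if np.any(np.linalg.norm(d, axis=-1) < np_rad + radii[:, None]):
            return True
    if n >= 2:
        iu = np.triu_indices(n, k=1)
        d = min_image_displacement(positions[iu[0]], positions[iu[1]], cell)
        if np.any(np.linalg.norm(d, axis=-1) < radii[iu[0]] + radii[iu[1]]):
            return True
    return False


def nanoparticle_coulomb_energy(spec: SystemSpec, cell: SimulationCell | None = None) -> float:
    """Fixed nanoparticle-nanoparticle Coulomb energy U_MM in k_B T.

    Uses direct (non-periodic) distances between the fixed centres; assembly
    extents are far below half a box for every supported condition.
    """
    lb = spec.bjerrum_length
    centers = spec.nanoparticles.centers
    z = spec.nanoparticles.charge
    m = spec.nanoparticles.count
    u = 0.0
    for i in range(m):
        for j in range(i + 1, m):
            r = float(np.linalg.norm(centers[i] - centers[j]))
            u += z * z * lb / r
    return u


def total_electrostatic_energy(spec: SystemSpec, cell: SimulationCell,
                               state: MCState) -> float:
    """Sum of all distinct-pair Coulomb terms (k_B T), minimum image.

    Includes ion-ion, ion-nanoparticle and the constant
    nanoparticle-nanoparticle contribution.  Raises on hard-core overlap.
    """
    if hardcore_overlap(spec, cell, state.positions, state.radii):
        raise ValueError("configuration contains hard-core overlaps")
    lb = spec.bjerrum_length
    pos = state.positions
    q = state.valences
    u = nanoparticle_coulomb_energy(spec, cell)
    centers = spec.nanoparticles.centers
    zq = spec.nanoparticles.charge
    n = len(pos)
    if n:
        d = min_image_displacement(pos[:, None, :], centers[None, :, :], cell)
        r = np.linalg.norm(d, axis=-1)
        u += float(np.sum(q[:, None] * zq * lb / r))
    if n >= 2:
        iu = np.triu_indices(n, k=1)
        d = min_image_displacement(pos[iu[0]], pos[iu[1]], cell)
        r = np.linalg.norm(d, axis=-1)
        u += float(np.sum(q[iu[0]] * q[iu[1]] * lb / r))
    return u


def move_delta_energy(spec: SystemSpec, cell: SimulationCell, state: MCState,
                      ion_index: int, proposed: np.ndarray) -> float:
    """Energy change (k_B T) from moving one ion, from its interactions only."""
    n = state.n_ions
    if not 0 <= ion_index < n:
        raise IndexError("ion index out of range")
    lb = spec.bjerrum_length
    qi = state.valences[ion_index]
    old = state.positions[ion_index]
    centers = spec.nanoparticles.centers
    zq = spec.nanoparticles.charge

    d_new = min_image_displacement(proposed[None, :], centers, cell)
    d_old = min_image_displacement(old[None, :], centers, cell)
    du = float(np.sum(qi * zq * lb * (1.0 / np.linalg.norm(d_new, axis=-1)
                                      - 1.0 / np.linalg.norm(d_old, axis=-1))))
    if n > 1:
        mask = np.ones(n, dtype=bool)
        mask[ion_index] = False
        others = state.positions[mask]
        qo = state.valences[mask]
        r_new = np.linalg.norm(min_image_displacement(proposed[None, :], others, cell), axis=-1)
        r_old = np.linalg.norm(min_image_displacement(old[None, :], others, cell), axis=-1)
        du += float(np.sum(qi * qo * lb * (1.0 / r_new - 1.0 / r_old)))
    return du


def wrap_positions(positions: np.ndarray, cell: SimulationCell) -> np.ndarray:
    """Wrap coordinates into the primary cell centred on the origin."""
    L = cell.lengths
    return positions - L * np.floor(positions / L + 0.5)
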