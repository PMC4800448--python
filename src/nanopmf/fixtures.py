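"""Tiny exactly solvable systems used as oracles for the samplers.

Each fixture couples a small :class:`SystemSpec` with expected values that
are computed here analytically or by exhaustive enumeration, never by the
Monte Carlo or PB machinery they are meant to check.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np

from . import constants
from .state import MCState
from .system import (IonSpecies, NanoparticleSet, SimulationCell, SystemSpec,
                     build_geometry, symmetric_salt)

FIXTURE_NAMES = ("no_ions_pair", "zero_charge", "lattice_toy",
                 "single_sphere_dh")


@dataclass
class LatticeToy:
    """Two divalent cations on a coarse lattice around two small nanospheres.

    The configuration space (unordered pairs of allowed lattice sites) is
    small enough to enumerate, giving exact Boltzmann averages and the exact
    excess free energy the TI chain must reproduce.
    """

    spec: SystemSpec
    cell: SimulationCell
    lattice_spacing: float
    sites: np.ndarray  # (n_allowed, 3) allowed site coordinates

    def _pair_energies(self) -> np.ndarray:
        """U (k_BT) for every unordered pair of distinct allowed sites."""
        lb = self.spec.bjerrum_length
        L = self.cell.lengths
        centers = self.spec.nanoparticles.centers
        zq = self.spec.nanoparticles.charge
        q_ion = float(self.spec.cation.valence)

        d = self.sites[:, None, :] - centers[None, :, :]
        d -= L * np.round(d / L)
        u_np = (q_ion * zq * lb / np.sqrt((d ** 2).sum(-1))).sum(axis=1)

        m = self.spec.nanoparticles.count
        u_mm = 0.0
        for i in range(m):
            for j in range(i + 1, m):
                u_mm += zq * zq * lb / np.linalg.norm(centers[i] - centers[j])

        pairs = np.array(list(itertools.combinations(range(len(self.sites)), 2)))
        dij = self.sites[pairs[:, 0]] - self.sites[pairs[:, 1]]
        dij -= L * np.round(dij / L)
        rij = np.sqrt((dij ** 2).sum(-1))
        return (u_np[pairs[:, 0]] + u_np[pairs[:, 1]]
                + q_ion * q_ion * lb / rij + u_mm)

    def exact_mean_energy(self, lam: float) -> float:
        """Exact <U> at coupling lam = beta/beta_T by enumeration."""
        u = self._pair_energies()
        w = np.exp(-lam * (u - u.min()))
        return float(np.sum(u * w) / np.sum(w))

    def exact_excess_free_energy(self) -> float:
        """Exact G_ex = -ln(Z(beta_T)/Z(0)) in k_BT over the lattice states."""
        u = self._pair_energies()
        shift = u.min()
        return float(shift - math.log(np.mean(np.exp(-(u - shift)))))

    def initial_state(self, seed: int) -> MCState:
        """Both ions on randomly chosen distinct allowed sites."""
        from . import energy as energy_mod

        rng = np.random.default_rng(seed)
        i, j = rng.choice(len(self.sites), size=2, replace=False)
        state = MCState(
            positions=self.sites[[i, j]].copy(),
            valences=np.full(2, float(self.spec.cation.valence)),
            radii=np.full(2, self.spec.cation.radius),
            rng=rng)
        state.energy = energy_mod.total_electrostatic_energy(
            self.spec, self.cell, state)
        return state


def _make_lattice_toy(separation: float = 10.0) -> LatticeToy:
    spacing = 5.0
    edge = 30.0  # 6 sites per axis; must be a multiple of the spacing
    cell = SimulationCell(lengths=np.full(3, edge))
    npset = build_geometry(2, separation, charge=-2.0, radius=4.0)
    cation = IonSpecies(valence=2, radius=1.0, bulk_concentration=0.0)
    anion = IonSpecies(valence=-2, radius=1.0, bulk_concentration=0.0)
    spec = SystemSpec(nanoparticles=npset, cation=cation, anion=anion)

    grid1d = (np.arange(6) + 0.5) * spacing - edge / 2.0
    gx, gy, gz = np.meshgrid(grid1d, grid1d, grid1d, indexing="ij")
    sites = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
    d = sites[:, None, :] - npset.centers[None, :, :]
    d -= cell.lengths * np.round(d / cell.lengths)
    dist = np.sqrt((d ** 2).sum(-1)).min(axis=1)
    allowed = dist >= npset.radius + cation.radius
    return LatticeToy(spec=spec, cell=cell, lattice_spacing=spacing,
                      sites=sites[allowed])


def bare_coulomb_pmf(charge: float, x: float, x_ref: float,
                     n_pairs: int = 1,
                     temperature: float = constants.DEFAULT_TEMPERATURE,
                     dielectric: float = constants.DEFAULT_DIELECTRIC) -> float:
    """Closed-form PMF of ion-free nanoparticles: sum of bare pair terms."""
    lb = constants.bjerrum_length(temperature, dielectric)
    return n_pairs * charge * charge * lb * (1.0 / x - 1.0 / x_ref)


def dh_potential(r, charge: float, concentration: float,
                 exclusion_radius: float = 12.0,
                 temperature: float = constants.DEFAULT_TEMPERATURE,
                 dielectric: float = constants.DEFAULT_DIELECTRIC):
    """Linearized (Debye-Hückel) sphere potential in k_BT/e, valid r >= a."""
    lb = constants.bjerrum_length(temperature, dielectric)
    n = concentration * constants.MOLAR_TO_PER_A3
    kappa = math.sqrt(4.0 * math.pi * lb * 2.0 * n)  # 1:1 salt
    a = exclusion_radius
    r = np.asarray(r, dtype=float)
    return charge * lb * np.exp(-kappa * (r - a)) / (r * (1.0 + kappa * a))


def dh_screening_free_energy(charge: float, concentration: float,
                             exclusion_radius: float = 12.0,
                             temperature: float = constants.DEFAULT_TEMPERATURE,
                             dielectric: float = constants.DEFAULT_DIELECTRIC) -> float:
    """Born-like screening term -Z^2 l_B kappa / (2 (1 + kappa a)) in k_BT."""
    lb = constants.bjerrum_length(temperature, dielectric)
    n = concentration * constants.MOLAR_TO_PER_A3
    kappa = math.sqrt(4.0 * math.pi * lb * 2.0 * n)
    a = exclusion_radius
    return -charge * charge * lb * kappa / (2.0 * (1.0 + kappa * a))


def make_fixture(name: str, **kwargs) -> dict:
    """Return a tiny system plus its independently computed expectations.

    Known names: ``no_ions_pair`` (two bare -24e spheres, closed-form PMF),
    ``zero_charge`` (uncharged spheres in salt, PMF identically zero),
    ``lattice_toy`` (enumerable two-ion lattice system) and
    ``single_sphere_dh`` (weakly charged sphere, Debye-Hückel closed forms).
    """
    if name == "no_ions_pair":
        x = kwargs.get("separation", 25.0)
        x_ref = kwargs.get("x_ref", 40.0)
        charge = kwargs.get("charge", -24.0)
        npset = build_geometry(2, x, charge=charge)
        cat, an = symmetric_salt(1, 0.0)
        spec = SystemSpec(nanoparticles=npset, cation=cat, anion=an)
        return {
            "spec": spec,
            "neutralize": False,
            "expected": {
                "dg": bare_coulomb_pmf(charge, x, x_ref),
                "x": x, "x_ref": x_ref,
            },
        }
    if name == "zero_charge":
        x = kwargs.get("separation", 25.0)
        conc = kwargs.get("concentration", 0.1)
        npset = build_geometry(2, x, charge=0.0)
        cat, an = symmetric_salt(1, conc)
        spec = SystemSpec(nanoparticles=npset, cation=cat, anion=an)
        return {"spec": spec, "neutralize": True,
                "expected": {"dg": 0.0, "all_mean_energies": 0.0}}
    if name == "lattice_toy":
        toy = _make_lattice_toy(kwargs.get("separation", 10.0))
        return {
            "toy": toy,
            "spec": toy.spec,
            "cell": toy.cell,
            "expected": {
                "g_ex": toy.exact_excess_free_energy(),
                "mean_energy": toy.exact_mean_energy,
            },
        }
    if name == "single_sphere_dh":
        charge = kwargs.get("charge", -1.0)
        conc = kwargs.get("concentration", 0.05)
        npset = NanoparticleSet(count=1, charge=charge)
        cat, an = symmetric_salt(1, conc)
        spec = SystemSpec(nanoparticles=npset, cation=cat, anion=an)
        a = npset.radius + cat.radius
        return {
            "spec": spec,
            "expected": {
                "potential": lambda r: dh_potential(r, charge, conc, a),
                "screening_free_energy":
                    dh_screening_free_energy(charge, conc, a),
            },
        }
    raise KeyError(f"unknown fixture {name!r}; choose from {FIXTURE_NAMES}")
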