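"""Model systems: charged nanospheres, salt species, and the periodic cell.

The physical model is the restricted primitive model: nanoparticles and ions
are charged hard spheres in a structureless dielectric continuum (water,
eps = 78).  Nanoparticles are held fixed in maximally symmetric arrangements
(a pair on a line, an equilateral triangle, a regular tetrahedron) while ions
move; counterions identical to the salt cation are added so the whole system
is exactly electroneutral.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np

from . import constants
from .state import MCState

logger = logging.getLogger(__name__)

DEFAULT_ION_RADIUS = 2.0  # Å
DEFAULT_NP_RADIUS = 10.0  # Å
DEFAULT_X_REF = 40.0  # Å, outer reference separation for PMFs
DEFAULT_MAX_CELL_EDGE = 1300.0  # Å, geometric cap at extremely low salt


@dataclass(frozen=True)
class IonSpecies:
    """One mobile ion species: hard sphere of given valence and radius."""

    valence: int
    radius: float = DEFAULT_ION_RADIUS
    bulk_concentration: float = 0.0  # mol/L

    def __post_init__(self):
        if self.valence == 0:
            raise ValueError("ion valence must be nonzero")
        if self.radius <= 0:
            raise ValueError("ion radius must be positive")
        if self.bulk_concentration < 0:
            raise ValueError("bulk concentration must be non-negative")


@dataclass(frozen=True)
class NanoparticleSet:
    """Fixed, like-charged nanospheres with all pairwise separations equal.

    ``count`` of 2, 3 or 4 gives a line, an equilateral triangle or a regular
    tetrahedron; a single sphere (count 1) is allowed for reference
    calculations where no separation is defined.
    """

    count: int
    charge: float  # e, total on each nanoparticle
    radius: float = DEFAULT_NP_RADIUS
    separation: float = 0.0  # Å, centre-to-centre
    centers: np.ndarray = field(default=None, repr=False)

    def __post_init__(self):
        if self.count not in (1, 2, 3, 4):
            raise ValueError("nanoparticle count must be 1, 2, 3 or 4")
        if self.radius <= 0:
            raise ValueError("nanoparticle radius must be positive")
        if self.centers is None:
            object.__setattr__(self, "centers",
                               _symmetric_centers(self.count, self.separation))
        centers = np.asarray(self.centers, dtype=float)
        if centers.shape != (self.count, 3):
            raise ValueError(f"centers must have shape ({self.count}, 3)")
        object.__setattr__(self, "centers", centers)
        if self.count >= 2:
            if self.separation < 2.0 * self.radius:
                raise ValueError("separation below hard-sphere contact")
            d = _pairwise_distances(centers)
            if not np.allclose(d, self.separation, rtol=0, atol=1e-9):
                raise ValueError("all pairwise centre distances must equal the separation")

    @property
    def n_pairs(self) -> int:
        return self.count * (self.count - 1) // 2

    def with_separation(self, x: float) -> "NanoparticleSet":
        return NanoparticleSet(count=self.count, charge=self.charge,
                               radius=self.radius, separation=float(x))


def _pairwise_distances(centers: np.ndarray) -> np.ndarray:
    diff = centers[:, None, :] - centers[None, :, :]
    d = np.sqrt((diff ** 2).sum(-1))
    iu = np.triu_indices(len(centers), k=1)
    return d[iu]


def _symmetric_centers(count: int, x: float) -> np.ndarray:
    """Centres of the maximally symmetric arrangement, centroid at origin."""
    if count == 1:
        return np.zeros((1, 3))
    if count == 2:
        return np.array([[-x / 2.0, 0.0, 0.0], [x / 2.0, 0.0, 0.0]])
    if count == 3:
        # equilateral triangle in the xy plane, circumradius x/sqrt(3)
        r = x / math.sqrt(3.0)
        angles = np.array([90.0, 210.0, 330.0]) * math.pi / 180.0
        return np.column_stack([r * np.cos(angles), r * np.sin(angles),
                                np.zeros(3)])
    if count == 4:
        # regular tetrahedron: alternating cube vertices, edge x
        s = x / (2.0 * math.sqrt(2.0))
        verts = np.array([[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]],
                         dtype=float)
        return verts * s
    raise ValueError("count must be 1-4")


def build_geometry(count: int, separation: float, charge: float = -24.0,
                   radius: float = DEFAULT_NP_RADIUS) -> NanoparticleSet:
    """Place ``count`` in {2, 3, 4} nanospheres with all pair distances equal.

    Raises ``ValueError`` for unsupported counts or separations below contact.
    """
    if count not in (2, 3, 4):
        raise ValueError("build_geometry supports 2, 3 or 4 nanoparticles")
    return NanoparticleSet(count=count, charge=charge, radius=radius,
                           separation=float(separation))


@dataclass(frozen=True)
class SimulationCell:
    """Periodic cuboid cell, centred on the origin."""

    lengths: np.ndarray  # (3,) Å
    periodic: tuple = (True, True, True)

    def __post_init__(self):
        lengths = np.asarray(self.lengths, dtype=float)
        if lengths.shape == ():
            lengths = np.full(3, float(lengths))
        if lengths.shape != (3,) or np.any(lengths <= 0):
            raise ValueError("cell needs three positive edge lengths")
        object.__setattr__(self, "lengths", lengths)

    @property
    def volume_a3(self) -> float:
        return float(np.prod(self.lengths))

    @property
    def volume_liters(self) -> float:
        return self.volume_a3 * 1.0e-27


@dataclass(frozen=True)
class SystemSpec:
    """Complete physical description of one simulation condition."""

    nanoparticles: NanoparticleSet
    cation: IonSpecies
    anion: IonSpecies
    temperature: float = constants.DEFAULT_TEMPERATURE  # K
    dielectric: float = constants.DEFAULT_DIELECTRIC

    def __post_init__(self):
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if self.cation.valence <= 0 or self.anion.valence >= 0:
            raise ValueError("cation must be positive, anion negative")

    @property
    def bjerrum_length(self) -> float:
        return constants.bjerrum_length(self.temperature, self.dielectric)

    def stoichiometry(self) -> tuple[int, int]:
        """(n_cation, n_anion) per electroneutral salt formula unit."""
        zp, zm = self.cation.valence, -self.anion.valence
        g = math.gcd(zp, zm)
        return zm // g, zp // g

    def with_separation(self, x: float) -> "SystemSpec":
        return replace(self, nanoparticles=self.nanoparticles.with_separation(x))


def symmetric_salt(valence: int, concentration: float,
                   radius: float = DEFAULT_ION_RADIUS) -> tuple[IonSpecies, IonSpecies]:
    """Convenience constructor for z:z salts (1:1, 2:2, ...)."""
    return (IonSpecies(valence, radius, concentration),
            IonSpecies(-valence, radius, concentration))


def debye_length(cation: IonSpecies, anion: IonSpecies,
                 temperature: float = constants.DEFAULT_TEMPERATURE,
                 dielectric: float = constants.DEFAULT_DIELECTRIC,
                 include_counterions: bool = False,
                 nanoparticles: NanoparticleSet | None = None,
                 cell_volume_a3: float | None = None) -> float:
    """Debye-Hückel screening length of the salt solution in Å.

    By default only the bulk salt contributes.  With
    ``include_counterions=True`` the neutralising counterions released by the
    nanoparticles are added at their cell-average density (requires
    ``nanoparticles`` and ``cell_volume_a3``).  Returns ``inf`` when there is
    nothing to screen with.
    """
    dens = [cation.bulk_concentration * constants.MOLAR_TO_PER_A3,
            anion.bulk_concentration * constants.MOLAR_TO_PER_A3]
    vals = [cation.valence, anion.valence]
    if include_counterions:
        if nanoparticles is None or cell_volume_a3 is None:
            raise ValueError("counterion contribution needs the nanoparticle "
                             "set and the cell volume")
        n_ci = abs(nanoparticles.count * nanoparticles.charge) / cation.valence
        dens.append(n_ci / cell_volume_a3)
        vals.append(cation.valence)
    return constants.debye_length_from_number_densities(
        dens, vals, temperature, dielectric)


def build_cell(spec: SystemSpec, x_ref: float = DEFAULT_X_REF,
               max_edge: float = DEFAULT_MAX_CELL_EDGE,
               min_debye_multiples: float = 8.0) -> SimulationCell:
    """Size the periodic cubic cell for a PMF run.

    The edge is at least eight Debye lengths (boundary effects) and at least
    the geometric extent of the nanoparticle assembly at the reference
    separation plus a two-nanoparticle-surface margin of four ion diameters.
    The same cell is reused at every separation of a PMF scan so that the
    beta = 0 hard-sphere reference free energy cancels exactly.
    """
    npset = spec.nanoparticles
    geo = x_ref + 2.0 * (npset.radius + 4.0 * spec.cation.radius)
    kappa_inv = debye_length(spec.cation, spec.anion, spec.temperature,
                             spec.dielectric)
    if math.isinf(kappa_inv):
        edge = geo
        logger.info("unscreened system: cell sized by geometric bound %.1f Å", edge)
    else:
        edge = max(min_debye_multiples * kappa_inv, geo)
    if edge > max_edge:
        logger.warning("cell edge %.0f Å exceeds cap, truncating to %.0f Å",
                       edge, max_edge)
        edge = max_edge
    return SimulationCell(lengths=np.full(3, edge))


def ion_counts(spec: SystemSpec, cell: SimulationCell) -> dict:
    """Numbers of salt ions and added counterions for an electroneutral box.

    Salt formula units are rounded from c0 * N_A * V; counterions identical
    to the salt cation neutralise the nanoparticle charge, |M Z| / z+ of
    them, which must be integral.
    """
    n_cat_stoich, n_an_stoich = spec.stoichiometry()
    c_formula = spec.cation.bulk_concentration / n_cat_stoich
    n_units = int(round(c_formula * constants.NA * cell.volume_liters))
    np_charge = spec.nanoparticles.count * spec.nanoparticles.charge
    n_counter_f = abs(np_charge) / spec.cation.valence
    if abs(n_counter_f - round(n_counter_f)) > 1e-9:
        raise ValueError(
            f"nanoparticle charge {np_charge} e is not neutralisable by an "
            f"integer number of z=+{spec.cation.valence} counterions")
    return {
        "salt_units": n_units,
        "cations": n_units * n_cat_stoich,
        "anions": n_units * n_an_stoich,
        "counterions": int(round(n_counter_f)),
    }


def populate_ions(spec: SystemSpec, cell: SimulationCell, seed,
                  neutralize: bool = True, max_tries: int = 200000) -> MCState:
    """Place salt ions plus neutralising counterions uniformly at random.

    Uniform rejection sampling against all hard cores (minimum image).  With
    ``neutralize=False`` only the salt ions are placed (reference toys; the
    system is then net charged).  The returned state has its total energy
    cached.
    """
    from . import energy as energy_mod

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    counts = ion_counts(spec, cell)
    n_counter = counts["counterions"] if neutralize else 0
    n_cat = counts["cations"] + n_counter
    n_an = counts["anions"]
    n_total = n_cat + n_an

    valences = np.concatenate([
        np.full(n_cat, float(spec.cation.valence)),
        np.full(n_an, float(spec.anion.valence)),
    ])
    radii = np.concatenate([
        np.full(n_cat, spec.cation.radius),
        np.full(n_an, spec.anion.radius),
    ])
    if neutralize:
        total = spec.nanoparticles.count * spec.nanoparticles.charge + valences.sum()
        if abs(total) > 1e-9:
            raise ValueError("generated populations are not electroneutral")

    L = cell.lengths
    centers = spec.nanoparticles.centers
    np_radius = spec.nanoparticles.radius
    positions = np.empty((n_total, 3))
    placed = 0
    tries = 0
    while placed < n_total:
        if tries >= max_tries:
            raise RuntimeError("could not place ions without overlap; "
                               "cell too crowded")
        tries += 1
        cand = (rng.random(3) - 0.5) * L
        # against nanoparticles
        d = cand[None, :] - centers
        d -= L * np.round(d / L)
        if np.any(np.sqrt((d ** 2).sum(-1)) < np_radius + radii[placed]):
            continue
        if placed:
            d = cand[None, :] - positions[:placed]
            d -= L * np.round(d / L)
            if np.any(np.sqrt((d ** 2).sum(-1)) < radii[:placed] + radii[placed]):
                continue
        positions[placed] = cand
        placed += 1

    state = MCState(positions=positions, valences=valences, radii=radii,
                    rng=rng)
    state.energy = energy_mod.total_electrostatic_energy(spec, cell, state)
    return state
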