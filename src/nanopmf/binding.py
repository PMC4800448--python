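"""Ensemble statistics of ion binding around the nanoparticles.

The central quantity is the net ion charge fraction

    Q(r) = < sum of z_i over ions within r of any nanoparticle centre >
           / (M |Z|),

i.e. the fraction of the total nanoparticle charge neutralised by the net
mobile charge found within distance r of the centres (union convention: an
ion inside more than one sphere counts once).  Q grows from 0 inside the
excluded layer to 1 when r covers the whole electroneutral cell.  The "bound"
shell used throughout is the region within 8 Å of the nanoparticle surface
(two ion layers), r = radius + 8 Å from the centre.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import constants
from .results import Trajectory
from .system import SystemSpec

logger = logging.getLogger(__name__)

BINDING_SHELL_WIDTH = 8.0  # Å from the nanoparticle surface


@dataclass
class QProfile:
    """Net ion charge fraction vs distance from the nanoparticle centres."""

    r: np.ndarray  # Å
    q: np.ndarray  # dimensionless fraction of M|Z|
    metadata: dict = field(default_factory=dict)


@dataclass
class ConcentrationField:
    """Frame-averaged ion concentration on a 3D grid (mol/L per species)."""

    edges: tuple  # (ex, ey, ez) bin edges, Å
    concentration: dict  # valence -> (nx, ny, nz) array, mol/L
    n_frames: int

    @property
    def voxel_volume_a3(self) -> float:
        dx = self.edges[0][1] - self.edges[0][0]
        dy = self.edges[1][1] - self.edges[1][0]
        dz = self.edges[2][1] - self.edges[2][0]
        return float(dx * dy * dz)


def _min_image_dist_to_centers(positions: np.ndarray, centers: np.ndarray,
                               lengths: np.ndarray) -> np.ndarray:
    """(..., M) minimum-image distances from each position to each centre."""
    d = positions[..., None, :] - centers
    d -= lengths * np.round(d / lengths)
    return np.sqrt((d ** 2).sum(-1))


def q_profile(spec: SystemSpec, traj: Trajectory, r_grid) -> QProfile:
    """Q(r) over a radial grid, averaged over trajectory frames."""
    if traj.n_frames == 0:
        raise ValueError("empty trajectory")
    z_total = spec.nanoparticles.count * abs(spec.nanoparticles.charge)
    if z_total == 0:
        raise ValueError("Q(r) undefined for uncharged nanoparticles")
    r_grid = np.asarray(r_grid, dtype=float)
    dmin = _min_image_dist_to_centers(traj.positions,
                                      spec.nanoparticles.centers,
                                      traj.cell_lengths).min(axis=-1)
    q = np.empty_like(r_grid)
    for k, r in enumerate(r_grid):
        inside = dmin <= r  # (frames, ions)
        q[k] = float((inside * traj.valences).sum() / traj.n_frames / z_total)
    return QProfile(r=r_grid, q=q,
                    metadata={"M": spec.nanoparticles.count,
                              "Z": spec.nanoparticles.charge,
                              "frames": traj.n_frames})


def shell_fraction(spec: SystemSpec, traj: Trajectory,
                   shell: float = BINDING_SHELL_WIDTH) -> dict:
    """Neutralisation fraction within ``shell`` Å of the nanoparticle surface.

    Returns the net-charge fraction plus the per-species contributions
    (keyed by valence), all normalised by M|Z|.
    """
    if traj.n_frames == 0:
        raise ValueError("empty trajectory")
    z_total = spec.nanoparticles.count * abs(spec.nanoparticles.charge)
    if z_total == 0:
        raise ValueError("shell fraction undefined for uncharged nanoparticles")
    r = spec.nanoparticles.radius + shell
    dmin = _min_image_dist_to_centers(traj.positions,
                                      spec.nanoparticles.centers,
                                      traj.cell_lengths).min(axis=-1)
    inside = dmin <= r
    out = {"net": float((inside * traj.valences).sum() / traj.n_frames / z_total)}
    for v in np.unique(traj.valences):
        mask = traj.valences == v
        out[float(v)] = float((inside[:, mask] * v).sum() / traj.n_frames / z_total)
    return out


def binding_count_per_nanoparticle(spec: SystemSpec, traj: Trajectory,
                                   shell: float = BINDING_SHELL_WIDTH) -> float:
    """Mean number of cations within the shell union, divided by M."""
    if traj.n_frames == 0:
        raise ValueError("empty trajectory")
    r = spec.nanoparticles.radius + shell
    dmin = _min_image_dist_to_centers(traj.positions,
                                      spec.nanoparticles.centers,
                                      traj.cell_lengths).min(axis=-1)
    cations = traj.valences > 0
    count = (dmin[:, cations] <= r).sum() / traj.n_frames
    return float(count / spec.nanoparticles.count)


def concentration_map(spec: SystemSpec, traj: Trajectory,
                      resolution: float = 1.0) -> ConcentrationField:
    """Per-species, frame-averaged 3D concentration field in mol/L."""
    if resolution < min(traj.radii, default=resolution):
        logger.warning("resolution %.2f Å finer than the ion radius; "
                       "expect sparse counts", resolution)
    L = traj.cell_lengths
    nbins = np.maximum((L / resolution).astype(int), 1)
    edges = tuple(np.linspace(-L[a] / 2.0, L[a] / 2.0, nbins[a] + 1)
                  for a in range(3))
    dv = np.prod([e[1] - e[0] for e in edges])
    conc: dict = {}
    flat = traj.positions.reshape(-1, 3)
    vals = np.tile(traj.valences, traj.n_frames)
    for v in np.unique(traj.valences):
        pts = flat[vals == v]
        h, _ = np.histogramdd(pts, bins=edges)
        conc[float(v)] = h / traj.n_frames / dv / constants.MOLAR_TO_PER_A3
    return ConcentrationField(edges=edges, concentration=conc,
                              n_frames=traj.n_frames)


def bridge_profile(spec: SystemSpec, traj: Trajectory, pair: tuple = (0, 1),
                   y_grid=None, slab_half_width: float = 2.0) -> tuple:
    """Cation concentration across the midplane between two nanoparticles.

    A thin slab bisects the pair axis (|axial| <= ``slab_half_width``, same
    bound on the out-of-plane coordinate); the profile is resolved along the
    in-plane direction y pointing from the pair midpoint toward the centroid
    of the remaining nanoparticles (an arbitrary transverse direction for a
    two-body system).  Returns (y centres, concentration in mol/L).
    """
    i, j = pair
    m = spec.nanoparticles.count
    if not (0 <= i < m and 0 <= j < m and i != j):
        raise IndexError("invalid nanoparticle pair")
    centers = spec.nanoparticles.centers
    mid = 0.5 * (centers[i] + centers[j])
    u = centers[j] - centers[i]
    u /= np.linalg.norm(u)
    others = [k for k in range(m) if k not in (i, j)]
    if others:
        toward = centers[others].mean(axis=0) - mid
    else:
        toward = np.array([0.0, 1.0, 0.0])
        if abs(np.dot(toward, u)) > 0.9:
            toward = np.array([0.0, 0.0, 1.0])
    y_dir = toward - np.dot(toward, u) * u
    ny = np.linalg.norm(y_dir)
    if ny < 1e-12:
        raise ValueError("transverse direction degenerate with the pair axis")
    y_dir /= ny
    w_dir = np.cross(u, y_dir)

    if y_grid is None:
        y_grid = np.arange(-20.0, 20.0 + 1e-9, 1.0)
    y_grid = np.asarray(y_grid, dtype=float)

    L = traj.cell_lengths
    flat = traj.positions.reshape(-1, 3)
    vals = np.tile(traj.valences, traj.n_frames)
    rel = flat[vals > 0] - mid
    rel -= L * np.round(rel / L)
    au = rel @ u
    ay = rel @ y_dir
    aw = rel @ w_dir
    sel = (np.abs(au) <= slab_half_width) & (np.abs(aw) <= slab_half_width)
    ay = ay[sel]
    counts, _ = np.histogram(ay, bins=y_grid)
    dy = np.diff(y_grid)
    vol = dy * (2.0 * slab_half_width) ** 2
    conc = counts / traj.n_frames / vol / constants.MOLAR_TO_PER_A3
    centres = 0.5 * (y_grid[:-1] + y_grid[1:])
    return centres, conc
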