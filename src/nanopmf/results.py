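"""Result containers shared by the sampling and thermodynamics layers."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class BetaResult:
    """Mean energy at one inverse-temperature point of the annealing chain."""

    lam: float  # beta / beta_T in [0, 1]
    mean_energy: float  # <U>_beta, k_BT
    stderr: float
    steps: int
    acceptance: float
    converged: bool
    displacement: float  # proposal half-width used in production (Å)


@dataclass
class TIResult:
    """Sampled <U> on the beta grid and everything needed for the TI sum."""

    lambdas: np.ndarray  # beta/beta_T grid, 0 .. 1, equally spaced
    mean_energy: np.ndarray  # k_BT per grid point
    stderr: np.ndarray
    converged: np.ndarray  # bool per grid point
    acceptance: np.ndarray
    steps: np.ndarray
    seed: int | None = None

    @property
    def all_converged(self) -> bool:
        return bool(np.all(self.converged))


@dataclass
class PMFCurve:
    """Potential of mean force vs nanoparticle separation.

    ``dg`` is Delta G_x = G_x - G_(x_ref) in k_BT, zero at x = x_ref by
    construction.  ``label`` distinguishes direct M-body curves from additive
    predictions built out of lower-order ones.
    """

    separations: np.ndarray  # Å
    dg: np.ndarray  # k_BT
    stderr: np.ndarray
    x_ref: float
    label: str
    metadata: dict = field(default_factory=dict)

    def value_at(self, x: float) -> tuple[float, float]:
        """(Delta G, stderr) at separation x; x must be on the grid."""
        idx = np.where(np.isclose(self.separations, x))[0]
        if len(idx) == 0:
            raise KeyError(f"separation {x} Å not on curve grid")
        i = int(idx[0])
        return float(self.dg[i]), float(self.stderr[i])

    def minimum(self) -> tuple[float, float, float]:
        """(x_min, Delta G_min, stderr) at the deepest point of the curve."""
        i = int(np.argmin(self.dg))
        return float(self.separations[i]), float(self.dg[i]), float(self.stderr[i])


@dataclass
class Trajectory:
    """Decorrelated equilibrium snapshots at the target temperature."""

    positions: np.ndarray  # (frames, n_ions, 3) Å
    valences: np.ndarray  # (n_ions,)
    radii: np.ndarray
    cell_lengths: np.ndarray  # (3,) Å
    stride: int  # MC steps between frames

    @property
    def n_frames(self) -> int:
        return int(self.positions.shape[0])
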