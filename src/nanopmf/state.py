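"""Mobile-ion configuration state for Monte Carlo sampling."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class MCState:
    """Positions and identities of all mobile ions plus cached bookkeeping.

    Attributes
    ----------
    positions : (N, 3) float array, Å, wrapped into the primary cell
        (centred on the origin).
    valences : (N,) float array, ion charges in units of e.
    radii : (N,) float array, hard-sphere radii in Å.
    energy : cached total electrostatic energy of the configuration in k_BT,
        including the constant nanoparticle-nanoparticle term.
    rng : the generator driving proposals for this chain.
    steps : total Metropolis steps taken so far.
    """

    positions: np.ndarray
    valences: np.ndarray
    radii: np.ndarray
    energy: float = 0.0
    rng: np.random.Generator = field(default_factory=np.random.default_rng)
    steps: int = 0

    @property
    def n_ions(self) -> int:
        return int(self.positions.shape[0])

    def copy(self) -> "MCState":
        rng = np.random.default_rng()
        rng.bit_generator.state = self.rng.bit_generator.state
        return MCState(
            positions=self.positions.copy(),
            valences=self.valences.copy(),
            radii=self.radii.copy(),
            energy=self.energy,
            rng=rng,
            steps=self.steps,
        )

    def total_ion_charge(self) -> float:
        return float(np.sum(self.valences))

    def save(self, path) -> None:
        """Checkpoint the full chain state (positions, energy, RNG) to disk."""
        import json

        rng_state = json.dumps(self.rng.bit_generator.state)
        np.savez(path, positions=self.positions, valences=self.valences,
                 radii=self.radii, energy=self.energy, steps=self.steps,
                 rng_state=np.array(rng_state))

    @classmethod
    def load(cls, path) -> "MCState":
        """Restore a checkpointed chain state; sampling resumes bit-exactly."""
        import json

        data = np.load(path, allow_pickle=False)
        rng = np.random.default_rng()
        rng.bit_generator.state = json.loads(str(data["rng_state"]))
        return cls(positions=data["positions"], valences=data["valences"],
                   radii=data["radii"], energy=float(data["energy"]),
                   rng=rng, steps=int(data["steps"]))
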