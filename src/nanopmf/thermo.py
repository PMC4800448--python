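"""Thermodynamic integration, PMF curves, and non-additivity statistics.

The excess free energy at the target temperature follows from integrating the
mean energy over inverse temperature,

    beta_T G_ex = integral_0^beta_T <U>_beta  d(beta),

evaluated as a sum over the 20 equal intervals of the annealing grid with
midpoint values interpolated linearly from the endpoint samples (equivalent
to the trapezoidal rule on the 21 grid points).  Because hard cores are
enforced at every beta, the beta = 0 reference is the hard-sphere fluid whose
free energy is identical at every nanoparticle separation (the excluded
volume does not depend on the arrangement of non-overlapping spheres), so it
cancels exactly in

    Delta G_x = G_ex(x) - G_ex(x_ref),      x_ref = 40 Å.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .mc import BetaSchedule, ConvergenceSpec, anneal, convergence_for
from .results import PMFCurve, TIResult
from .system import SimulationCell, SystemSpec, build_cell, populate_ions

logger = logging.getLogger(__name__)

DEFAULT_X_REF = 40.0


def excess_free_energy(ti: TIResult, require_converged: bool = True
                       ) -> tuple[float, float]:
    """(G_ex, stderr) in k_BT from the sampled <U>(lam) grid.

    Midpoint sum over the equal lam intervals with endpoint-interpolated
    midpoints; error propagated from the per-point standard errors.
    """
    if require_converged and not ti.all_converged:
        raise RuntimeError("TI grid contains unconverged points; pass "
                           "require_converged=False to override")
    lam = ti.lambdas
    u = ti.mean_energy
    dlam = np.diff(lam)
    if not np.allclose(dlam, dlam[0]):
        raise ValueError("lam grid must be equally spaced")
    mid = 0.5 * (u[:-1] + u[1:])
    g = float(np.sum(mid * dlam))
    # trapezoid weights: dlam/2 at the ends, dlam inside
    w = np.full_like(lam, dlam[0])
    w[0] = w[-1] = dlam[0] / 2.0
    se = ti.stderr.copy()
    se[np.isnan(se)] = 0.0
    g_se = float(np.sqrt(np.sum((w * se) ** 2)))
    return g, g_se


def free_energy_at_separation(spec: SystemSpec, cell: SimulationCell,
                              seed: int,
                              schedule: BetaSchedule | None = None,
                              conv: ConvergenceSpec | None = None,
                              target_prob: float = 0.0,
                              require_converged: bool = False
                              ) -> tuple[float, float, TIResult]:
    """One annealing chain -> (G_ex, stderr, TIResult) for this separation."""
    state = populate_ions(spec, cell, seed)
    ti = anneal(spec, cell, state, schedule=schedule, conv=conv,
                target_prob=target_prob, seed=seed)
    g, se = excess_free_energy(ti, require_converged=require_converged)
    return g, se, ti


def pmf(spec: SystemSpec, separations, x_ref: float = DEFAULT_X_REF,
        replicates: int = 3, seed: int = 0,
        schedule: BetaSchedule | None = None,
        conv: ConvergenceSpec | None = None,
        target_prob: float = 0.0,
        cell: SimulationCell | None = None) -> PMFCurve:
    """Direct M-body PMF curve Delta G_x = G_ex(x) - G_ex(x_ref).

    The same cell (sized by the reference separation so the composition is
    identical at every x) is used throughout.  ``replicates`` independent
    seeds are averaged per separation; the error combines replicate scatter
    at both endpoints (propagated TI errors when only one replicate is run).
    """
    separations = np.asarray(sorted(set(float(x) for x in separations)))
    if np.any(separations < 2.0 * spec.nanoparticles.radius):
        raise ValueError("separations below hard-sphere contact")
    if replicates < 1:
        raise ValueError("need at least one replicate")
    cell = cell or build_cell(spec, x_ref=x_ref)
    conv = conv or convergence_for(spec)
    master = np.random.default_rng(seed)
    seeds = master.integers(1, 2**31 - 1, size=replicates)

    def g_samples(x: float) -> tuple[np.ndarray, np.ndarray]:
        sx = spec.with_separation(x)
        gs, ses = [], []
        for s in seeds:
            g, se, _ = free_energy_at_separation(sx, cell, int(s),
                                                 schedule=schedule, conv=conv,
                                                 target_prob=target_prob)
            gs.append(g)
            ses.append(se)
        return np.asarray(gs), np.asarray(ses)

    g_ref, se_ref = g_samples(x_ref)
    dg = np.empty_like(separations)
    err = np.empty_like(separations)
    for i, x in enumerate(separations):
        if np.isclose(x, x_ref):
            gx, sex = g_ref, se_ref
        else:
            gx, sex = g_samples(float(x))
        dg[i] = gx.mean() - g_ref.mean()
        if replicates >= 2:
            err[i] = float(np.sqrt(gx.var(ddof=1) / replicates
                                   + g_ref.var(ddof=1) / replicates))
        else:
            err[i] = float(np.sqrt(sex[0] ** 2 + se_ref[0] ** 2))

    m = spec.nanoparticles.count
    return PMFCurve(separations=separations, dg=dg, stderr=err, x_ref=x_ref,
                    label=f"direct {m}-body",
                    metadata={"M": m, "Z": spec.nanoparticles.charge,
                              "cation_valence": spec.cation.valence,
                              "concentration": spec.cation.bulk_concentration,
                              "replicates": replicates, "seed": seed,
                              "cell_edge": float(cell.lengths[0])})


def additive_prediction(curve: PMFCurve, target_m: int = 4) -> PMFCurve:
    """Additive M=4 prediction from a direct 2-body (x6) or 3-body (x2) curve.

    The tetrahedron has six equivalent pairs; a direct two-body PMF counts one
    of them (factor 6) and a direct three-body PMF counts three (factor 2).
    """
    if target_m != 4:
        raise ValueError("additive predictions are defined for target M = 4")
    source_m = curve.metadata.get("M")
    if source_m == 2:
        factor = 6.0
    elif source_m == 3:
        factor = 2.0
    else:
        raise ValueError("source curve must be a direct 2-body or 3-body PMF")
    md = dict(curve.metadata)
    md.update({"M": target_m, "source_M": source_m, "factor": factor})
    return PMFCurve(separations=curve.separations.copy(),
                    dg=factor * curve.dg, stderr=factor * curve.stderr,
                    x_ref=curve.x_ref,
                    label=f"additive-from-{source_m}", metadata=md)


@dataclass(frozen=True)
class NonAdditivity:
    """Non-additivity of the four-body PMF at one separation.

    ``ddg`` = Delta G_x(four) - 6 Delta G_x(two) in k_BT; negative means the
    additive pair prediction overestimates the four-body PMF.
    ``percent_overestimate`` = (6 Delta G_two - Delta G_four)/|Delta G_four|
    x 100, suppressed (None) when the direct four-body value is within noise
    of zero.
    """

    x: float
    ddg: float
    ddg_stderr: float
    percent_overestimate: float | None
    dg_four: float
    dg_two: float


def nonadditivity(four: PMFCurve, two: PMFCurve, x: float = 25.0) -> NonAdditivity:
    """Compare the direct four-body PMF with the additive pair prediction."""
    if four.metadata.get("M") != 4 or two.metadata.get("M") != 2:
        raise ValueError("expected a direct four-body and a direct two-body curve")
    g4, se4 = four.value_at(x)
    g2, se2 = two.value_at(x)
    ddg = g4 - 6.0 * g2
    se = float(np.sqrt(se4 ** 2 + 36.0 * se2 ** 2))
    if abs(g4) <= 2.0 * se4:
        pct = None
        logger.info("four-body Delta G at %.1f Å within noise of zero; "
                    "percent overestimation suppressed", x)
    else:
        pct = (6.0 * g2 - g4) / abs(g4) * 100.0
    return NonAdditivity(x=x, ddg=float(ddg), ddg_stderr=se,
                         percent_overestimate=pct, dg_four=g4, dg_two=g2)


def minimum_gap(four: PMFCurve, two: PMFCurve) -> tuple[float, float]:
    """Signed gap Delta G_four(min) - 6 Delta G_two(min), with stderr.

    Each curve's minimum is taken over its own separation grid.  Positive
    values mean the additive prediction is more attractive than the direct
    four-body result.
    """
    _, g4, se4 = four.minimum()
    add = additive_prediction(two)
    _, g2x6, se2x6 = add.minimum()
    return float(g4 - g2x6), float(np.sqrt(se4 ** 2 + se2x6 ** 2))
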