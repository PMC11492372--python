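"""Synthetic event tables driven by the forward model.

No public measurement archive exists for this class of metal-gated nanopore
experiments, so validation data are synthesised from the forward model
itself: each event is the model-predicted signal pair (I_ps, V_ps) for a
known analyte, corrupted by i.i.d. Gaussian noise of configurable relative
standard deviation, with translocation times drawn around a configurable
mean.  The generating parameters are the ground truth against which
recovery is judged.

Default study conditions mirror the nanoparticle-characterisation setting:
1 mM NaF electrolyte, a 2.3 nm-radius pore, 50 events per condition, 5%
relative signal noise, and millisecond translocation times.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .baseline import BaselineState, NanoporeGeometry, baseline_state
from .errors import InvalidInputError
from .ions import ElectrolyteSolution, binary_solution
from .perturbation import Analyte, predict_signals

__all__ = [
    "default_solution",
    "default_pore",
    "synthesize_events",
    "oxidation_series",
]

DEFAULT_N_EVENTS = 50
DEFAULT_REL_NOISE = 0.05
DEFAULT_T_IC_MEAN = 1e-3  # s
DEFAULT_T_IC_REL_SD = 0.1


def default_solution(concentration: float = 1e-3) -> ElectrolyteSolution:
    """The reference electrolyte: NaF at ``concentration`` mol/L."""
    return binary_solution("Na+", "F-", concentration)


def default_pore(r_np: float = 2.3e-9) -> NanoporeGeometry:
    """The reference pore geometry (2.3 nm radius, 55/5 nm lengths)."""
    return NanoporeGeometry(r_np=r_np)


def synthesize_events(
    analyte: Analyte,
    solution: ElectrolyteSolution | None = None,
    pore: NanoporeGeometry | None = None,
    *,
    n_events: int = DEFAULT_N_EVENTS,
    rel_noise: float = DEFAULT_REL_NOISE,
    t_ic_mean: float = DEFAULT_T_IC_MEAN,
    t_ic_rel_sd: float = DEFAULT_T_IC_REL_SD,
    seed: int | np.random.Generator | None = 0,
    condition: object = None,
    baseline: BaselineState | None = None,
) -> pd.DataFrame:
    """Event table for one analyte under fixed conditions.

    Returns a DataFrame with SI columns ``I_ps_A``, ``V_ps_V``, ``t_ic_s``,
    ``V_bs_V``, ``I_bs_A`` (baseline context) and ``condition``.  Noise is
    multiplicative Gaussian, ``x * (1 + rel_noise * eps)``; ``rel_noise=0``
    reproduces the forward model exactly.  Deterministic for a fixed seed.
    """
    if n_events < 1:
        raise InvalidInputError("need at least one event")
    if rel_noise < 0:
        raise InvalidInputError("rel_noise must be non-negative")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    solution = solution if solution is not None else default_solution()
    pore = pore if pore is not None else default_pore()
    if baseline is None:
        baseline = baseline_state(solution, pore)
    t_ic = np.maximum(
        rng.normal(t_ic_mean, t_ic_rel_sd * t_ic_mean, size=n_events),
        0.1 * t_ic_mean,
    )
    i_ps = np.empty(n_events)
    v_ps = np.empty(n_events)
    for k in range(n_events):
        state = predict_signals(solution, pore, analyte, float(t_ic[k]), baseline=baseline)
        i_ps[k] = state.I_ps
        v_ps[k] = state.V_ps
    if rel_noise > 0:
        i_ps = i_ps * (1.0 + rel_noise * rng.standard_normal(n_events))
        v_ps = v_ps * (1.0 + rel_noise * rng.standard_normal(n_events))
    return pd.DataFrame(
        {
            "condition": condition if condition is not None else analyte.name,
            "I_ps_A": i_ps,
            "V_ps_V": v_ps,
            "t_ic_s": t_ic,
            "V_bs_V": baseline.V_bs,
            "I_bs_A": baseline.I_bs,
        }
    )


def oxidation_series(
    charges: tuple[int, ...] = (28, 56, 84, 112),
    radii: tuple[float, ...] | float = 1.1e-9,
    *,
    solution: ElectrolyteSolution | None = None,
    pore: NanoporeGeometry | None = None,
    use_stokes: bool = True,
    n_events: int = DEFAULT_N_EVENTS,
    rel_noise: float = DEFAULT_REL_NOISE,
    seed: int = 0,
) -> dict[int, pd.DataFrame]:
    """Titration-style fixture: one event group per oxidation step.

    Each condition ``k`` holds events generated from charge ``charges[k]``
    (monotonically increasing along an oxidation series) at the matching
    radius.  Returns ``{condition_index: events}`` suitable for
    :func:`poresig.inverse.fit_series`.
    """
    if isinstance(radii, float):
        radii = tuple(radii for _ in charges)
    if len(radii) != len(charges):
        raise InvalidInputError("radii and charges must have equal length")
    solution = solution if solution is not None else default_solution()
    pore = pore if pore is not None else default_pore()
    baseline = baseline_state(solution, pore)
    rng = np.random.default_rng(seed)
    groups: dict[int, pd.DataFrame] = {}
    for k, (z, r) in enumerate(zip(charges, radii)):
        analyte = Analyte(name=f"step_{k}", r_analyte=r, z_analyte=z, use_stokes=use_stokes)
        groups[k] = synthesize_events(
            analyte,
            solution,
            pore,
            n_events=n_events,
            rel_noise=rel_noise,
            seed=rng,
            condition=k,
            baseline=baseline,
        )
    return groups
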