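"""Single-molecule mobility and diffusivity from translocation events.

Rearranging the drift relation v = mu E with v = L/t_ic and E = V_bs/L_Au
gives the in-pore mobility of one translocating molecule directly from a
measured event duration and the baseline potential:

    mu = (L * L_Au) / (|V_bs| * t_ic)

and the Nernst–Einstein (Stokes–Einstein) relation converts it to a
diffusion coefficient, D = mu k_B T / (|z| e).  Both are reported as
magnitudes; the event polarity is carried by the signal record itself.
In-pore values come out orders of magnitude below unconfined bulk
references, reflecting hindered transport through the charge- and
size-selective pore interior.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .constants import BOLTZMANN, DEFAULT_TEMPERATURE, ELEMENTARY_CHARGE
from .errors import DegenerateStateError, InvalidInputError
from .baseline import NanoporeGeometry

__all__ = [
    "KineticEstimate",
    "mobility_from_event",
    "diffusivity_from_mobility",
    "kinetics_table",
    "summarize_kinetics",
]


@dataclass(frozen=True)
class KineticEstimate:
    """Mobility/diffusivity magnitudes for one event."""

    mobility: float  # m^2 V^-1 s^-1
    diffusivity: float  # m^2 s^-1
    t_ic: float  # s
    V_bs: float  # V


def mobility_from_event(
    t_ic: float, V_bs: float, pore: NanoporeGeometry
) -> float:
    """In-pore mobility magnitude mu = L L_Au / (|V_bs| t_ic)."""
    if t_ic <= 0:
        raise InvalidInputError("t_ic must be positive")
    if V_bs == 0:
        raise DegenerateStateError("zero baseline potential: no driving field")
    return pore.L * pore.L_Au / (abs(V_bs) * t_ic)


def diffusivity_from_mobility(
    mobility: float, z_analyte: int, temperature: float = DEFAULT_TEMPERATURE
) -> float:
    """Diffusion coefficient D = mu k_B T / (|z| e); linear in T."""
    if mobility <= 0:
        raise InvalidInputError("mobility must be positive")
    if z_analyte == 0:
        raise InvalidInputError("diffusivity undefined for a neutral analyte")
    if temperature <= 0:
        raise InvalidInputError("temperature must be positive")
    return mobility * BOLTZMANN * temperature / (abs(z_analyte) * ELEMENTARY_CHARGE)


def estimate_event(
    t_ic: float,
    V_bs: float,
    pore: NanoporeGeometry,
    z_analyte: int,
    temperature: float = DEFAULT_TEMPERATURE,
) -> KineticEstimate:
    """Mobility and diffusivity for one event; mutually consistent by
    construction (D / mu = k_B T / |z| e)."""
    mu = mobility_from_event(t_ic, V_bs, pore)
    d = diffusivity_from_mobility(mu, z_analyte, temperature)
    return KineticEstimate(mobility=mu, diffusivity=d, t_ic=t_ic, V_bs=V_bs)


def kinetics_table(
    events: pd.DataFrame,
    pore: NanoporeGeometry,
    z_analyte: int,
    temperature: float = DEFAULT_TEMPERATURE,
) -> pd.DataFrame:
    """Per-event kinetic estimates for an event table.

    ``events`` needs SI columns ``t_ic_s`` and ``V_bs_V``; any other columns
    (e.g. ``condition``) are carried through.
    """
    out = events.copy()
    out["mobility_m2_per_Vs"] = [
        mobility_from_event(t, v, pore)
        for t, v in zip(events["t_ic_s"], events["V_bs_V"])
    ]
    out["diffusivity_m2_per_s"] = [
        diffusivity_from_mobility(mu, z_analyte, temperature)
        for mu in out["mobility_m2_per_Vs"]
    ]
    return out


def summarize_kinetics(table: pd.DataFrame, by: str = "condition") -> pd.DataFrame:
    """Mean +/- SD of mobility and diffusivity per condition group."""
    cols = ["mobility_m2_per_Vs", "diffusivity_m2_per_s"]
    grouped = table.groupby(by)[cols]
    summary = grouped.agg(["mean", "std", "count"])
    summary.columns = ["_".join(c) for c in summary.columns]
    return summary.reset_index()
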