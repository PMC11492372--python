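"""Perturbed-state forward model: signals caused by a translocating analyte.

A single analyte inside the pore perturbs the baseline state through two
channels:

* **volumetric occlusion** (the classical blockade effect) — the analyte's
  excluded volume displaces baseline charge,
  ``dn_V = -n_bs * V_analyte / V_total``;
* **electrostatic compensation** — ions rearrange to screen the analyte's
  charge, but must enter through the size-selective pore, so the
  compensating charge density is partitioned:
  ``dn_E = -P_bs * z_analyte * e / V_total``.

The total electrolyte perturbation ``dn = dn_V + dn_E`` drives a drift
velocity response ``dv = v_bs * dn / n_ps`` (with ``n_ps = n_bs + dn``), and
the current signal is the bilinear expansion of I = n A v about the
baseline, ``dI_bs = A (dn v_bs + n_bs dv + dn dv)``.  The analyte itself
carries a direct current ``I_analyte = n_analyte A v_analyte`` that is
orders of magnitude below ``dI_bs`` at millisecond translocation times but
whose charge density ``n_analyte = z e / V_total`` does matter for the
potential signal:

``V_ps = V_total (dn + n_analyte) / C_EDL``,  ``I_ps = dI_bs + I_analyte``.

Signals are reported baseline-subtracted: a null analyte produces (0, 0).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .constants import (
    DEFAULT_TRANSLOCATION_TIME,
    DEFAULT_WATER_LAYER,
    ELEMENTARY_CHARGE,
)
from .errors import DegenerateStateError, InvalidInputError
from .baseline import BaselineState, NanoporeGeometry, baseline_state
from .ions import ElectrolyteSolution

__all__ = [
    "Analyte",
    "PerturbedState",
    "delta_n_volume",
    "delta_n_electric",
    "delta_velocity",
    "delta_current",
    "analyte_charge_density",
    "analyte_velocity",
    "analyte_current",
    "potential_signal",
    "predict_signals",
]


@dataclass(frozen=True)
class Analyte:
    """A translocating particle or molecule.

    Parameters
    ----------
    name : str
        Label used in outputs.
    r_analyte : float
        Bare analyte radius in metres.
    z_analyte : int
        Signed valence charge (0 allowed: a neutral analyte only blocks).
    water_layer : float
        Thickness of the bound water layer forming the Stokes radius,
        ``r_Stokes = r_analyte + water_layer`` (default one water-molecule
        radius, 0.14 nm).
    use_stokes : bool
        If True (default) the excluded volume uses the Stokes radius; large
        particles are better described by the bare radius.
    """

    name: str
    r_analyte: float
    z_analyte: int
    water_layer: float = DEFAULT_WATER_LAYER
    use_stokes: bool = True

    def __post_init__(self) -> None:
        if self.r_analyte <= 0:
            raise InvalidInputError(f"{self.name}: r_analyte must be positive")
        if self.water_layer < 0:
            raise InvalidInputError(f"{self.name}: water_layer must be non-negative")

    @property
    def r_stokes(self) -> float:
        return self.r_analyte + self.water_layer

    @property
    def effective_radius(self) -> float:
        """Radius used for the excluded volume (Stokes or bare)."""
        return self.r_stokes if self.use_stokes else self.r_analyte

    @property
    def volume(self) -> float:
        """Excluded (spherical) volume V_analyte (m^3)."""
        return 4.0 / 3.0 * math.pi * self.effective_radius**3


@dataclass(frozen=True)
class PerturbedState:
    """All perturbation components for one analyte/baseline pairing (SI)."""

    dn_volume: float
    dn_electric: float
    dn_total: float
    dv: float
    dI_bs: float
    I_analyte: float
    I_ps: float
    V_ps: float
    t_ic: float


def delta_n_volume(
    analyte: Analyte, baseline: BaselineState, pore: NanoporeGeometry
) -> float:
    """Charge-density change from volumetric occlusion (C/m^3).

    Proportional to the excluded volume and opposite in sign to ``n_bs``:
    the displaced charge reduces the in-pore total.
    """
    if analyte.volume >= pore.volume:
        raise InvalidInputError(
            f"{analyte.name}: excluded volume exceeds the pore volume"
        )
    return -baseline.n_bs * analyte.volume / pore.volume


def delta_n_electric(
    analyte: Analyte, baseline: BaselineState, pore: NanoporeGeometry
) -> float:
    """Charge-density change from electrostatic compensation (C/m^3).

    The electrolyte accumulates screening charge opposing the analyte's, at
    an efficiency set by the pore's partition coefficient; antisymmetric in
    ``z_analyte`` and valid for attraction and repulsion alike.
    """
    return -baseline.P_bs * analyte.z_analyte * ELEMENTARY_CHARGE / pore.volume


def delta_velocity(
    dn_total: float, baseline: BaselineState, pore: NanoporeGeometry
) -> float:
    """Drift-velocity perturbation dv (m/s) from the charge perturbation.

    ``dv = v_bs * dn / n_ps`` with ``n_ps = n_bs + dn``; zero perturbation
    gives zero response, and the response scales with the baseline drift.
    """
    n_ps = baseline.n_bs + dn_total
    if n_ps == 0:
        raise DegenerateStateError("perturbed charge density vanished")
    return baseline.v_bs * dn_total / n_ps


def delta_current(
    dn_total: float, dv: float, baseline: BaselineState, pore: NanoporeGeometry
) -> float:
    """Electrolyte-current signal dI_bs (A): bilinear expansion of I = n A v.

    ``dI_bs = A (dn v_bs + n_bs dv + dn dv)``, the exact difference
    ``A (n_ps v_ps - n_bs v_bs)``.
    """
    return pore.area * (
        dn_total * baseline.v_bs + baseline.n_bs * dv + dn_total * dv
    )


def analyte_charge_density(analyte: Analyte, pore: NanoporeGeometry) -> float:
    """Charge density of the analyte as a single particle in the pore,
    ``n_analyte = z e / V_total`` (C/m^3); linear in the valence."""
    return analyte.z_analyte * ELEMENTARY_CHARGE / pore.volume


def analyte_velocity(t_ic: float, pore: NanoporeGeometry) -> float:
    """Analyte drift velocity v = L / t_ic (m/s) from the translocation time."""
    if t_ic <= 0:
        raise InvalidInputError("t_ic must be positive")
    return pore.L / t_ic


def analyte_current(
    analyte: Analyte, t_ic: float, pore: NanoporeGeometry
) -> float:
    """Direct analyte current I_analyte = n_analyte A v_analyte (A).

    With V_total = A L this reduces to z e / t_ic — negligible against the
    electrolyte signal at millisecond translocation times.
    """
    return analyte_charge_density(analyte, pore) * pore.area * analyte_velocity(t_ic, pore)


def potential_signal(
    dn_total: float, n_analyte: float, C_EDL: float, pore: NanoporeGeometry
) -> float:
    """EDL potential signal V_ps (V) from the total in-pore charge change.

    ``V_ps = V_total (dn + n_analyte) / C_EDL``; the signed capacitance is
    positive for cation-majority baselines.
    """
    if C_EDL == 0:
        raise DegenerateStateError("zero EDL capacitance")
    return pore.volume * (dn_total + n_analyte) / C_EDL


def predict_signals(
    solution: ElectrolyteSolution,
    pore: NanoporeGeometry,
    analyte: Analyte | None,
    t_ic: float = DEFAULT_TRANSLOCATION_TIME,
    *,
    baseline: BaselineState | None = None,
) -> PerturbedState:
    """Compose the forward model: baseline -> perturbations -> (I_ps, V_ps).

    A ``None`` analyte returns the all-zero perturbed state.  Passing a
    precomputed ``baseline`` skips re-evaluating the baseline chain.
    """
    if baseline is None:
        baseline = baseline_state(solution, pore)
    if analyte is None:
        return PerturbedState(0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, t_ic)
    dn_v = delta_n_volume(analyte, baseline, pore)
    dn_e = delta_n_electric(analyte, baseline, pore)
    dn = dn_v + dn_e
    dv = delta_velocity(dn, baseline, pore)
    di = delta_current(dn, dv, baseline, pore)
    i_an = analyte_current(analyte, t_ic, pore)
    n_an = analyte_charge_density(analyte, pore)
    v_ps = potential_signal(dn, n_an, baseline.C_EDL, pore)
    return PerturbedState(
        dn_volume=dn_v,
        dn_electric=dn_e,
        dn_total=dn,
        dv=dv,
        dI_bs=di,
        I_analyte=i_an,
        I_ps=di + i_an,
        V_ps=v_ps,
        t_ic=t_ic,
    )
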