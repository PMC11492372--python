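"""Baseline-state predictions for a metal-gated solid-state nanopore.

With electrolyte only (no analyte), the pore settles into a *baseline state*
characterised by the EDL potential ``V_bs`` on the gold layer and the
transmembrane ionic current ``I_bs``.  The model chains four relationships:

1. ``V_bs = -sgn(z_bs) * (k_B T / e) * P_bs * ln(a_reservoir / a_nanopore)``
   — the EDL potential set by the activity imbalance between the
   one-polarity pore interior and the full reservoir, scaled by the
   size-partition coefficient ``P_bs`` and carrying a polarity opposite to
   the majority ion (the ``-sgn`` pair).
2. ``I_bs = m * V_bs + c`` — the device's linear current–potential
   regression (coefficients in :mod:`poresig.constants`).
3. ``v_bs = -sgn(z_bs) * mu_ion * E`` with ``E = V_bs / L_Au`` — drift
   velocity of the majority carrier in the field across the metal layer.
   With the polarity rule of (1) the baseline drift is positive along the
   pore axis for every supported electrolyte.
4. ``n_bs = I_bs / (A * v_bs)`` — the net charge density that carries the
   current through cross-section ``A`` (signed by the current convention).

The EDL capacitance is the sensitivity of the total in-pore baseline charge
to the EDL potential, ``C_EDL = d(V_total * n_bs)/dV_bs``, available in
closed form and as a central finite difference.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .constants import (
    BOLTZMANN,
    DEFAULT_CHARACTERISTIC_LENGTH,
    DEFAULT_METAL_LENGTH,
    DEFAULT_PORE_LENGTH,
    ELEMENTARY_CHARGE,
    IBS_INTERCEPT,
    IBS_SLOPE,
)
from .errors import ConfigurationError, DegenerateStateError, InvalidInputError
from .ions import (
    ElectrolyteSolution,
    IonSpecies,
    PartitionContext,
    ionic_activities,
    partition_coefficient,
    partition_context,
)

__all__ = [
    "NanoporeGeometry",
    "BaselineState",
    "predict_Vbs",
    "baseline_current",
    "drift_velocity",
    "baseline_charge_density",
    "edl_capacitance",
    "baseline_state",
]


@dataclass(frozen=True)
class NanoporeGeometry:
    """Cylindrical nanopore geometry.

    Parameters
    ----------
    r_np : float
        Pore radius in metres.
    L : float
        Total pore length in metres (55 nm default).
    L_Au : float
        Length of the metal (gold) layer in metres (5 nm default).
    """

    r_np: float
    L: float = DEFAULT_PORE_LENGTH
    L_Au: float = DEFAULT_METAL_LENGTH

    def __post_init__(self) -> None:
        if self.r_np <= 0:
            raise InvalidInputError("r_np must be positive")
        if not 0 < self.L_Au <= self.L:
            raise InvalidInputError("need 0 < L_Au <= L")

    @property
    def area(self) -> float:
        """Cross-sectional area A = pi r_np^2 (m^2)."""
        return math.pi * self.r_np**2

    @property
    def volume(self) -> float:
        """Interior volume V_total = A L (m^3)."""
        return self.area * self.L


@dataclass(frozen=True)
class BaselineState:
    """Derived baseline state of a pore/electrolyte pairing.

    ``E`` is the driving field V_bs/L_Au; ``z_bs`` the majority-ion valence;
    ``P_bs`` the partition coefficient used in the potential prediction.
    ``C_EDL`` is the signed charge–potential derivative, positive for the
    cation-majority electrolytes this model targets.
    """

    V_bs: float
    I_bs: float
    n_bs: float
    v_bs: float
    E: float
    C_EDL: float
    z_bs: int
    P_bs: float
    majority: IonSpecies


def predict_Vbs(
    solution: ElectrolyteSolution,
    pore: NanoporeGeometry,
    *,
    L_C: float = DEFAULT_CHARACTERISTIC_LENGTH,
    ctx: PartitionContext | None = None,
) -> float:
    """Baseline-state EDL potential (V).

    The polarity is opposite to the majority-ion valence; the magnitude
    decreases monotonically with concentration because the activity ratio
    a_reservoir/a_nanopore tightens toward its dilute-limit value as the
    activity coefficients fall.
    """
    if ctx is None:
        ctx = partition_context(solution, pore.r_np, L_C)
    a_nano, a_res = ionic_activities(solution, ctx)
    if a_nano <= 0 or a_res <= 0:
        raise InvalidInputError("activities must be positive")
    p_bs = partition_coefficient(ctx)
    thermal = BOLTZMANN * solution.temperature / ELEMENTARY_CHARGE
    sign = 1 if ctx.majority.valence > 0 else -1
    return -sign * thermal * p_bs * math.log(a_res / a_nano)


def baseline_current(V_bs: float) -> float:
    """Baseline-state ionic current (A) from the device regression,
    affine in the EDL potential."""
    if not math.isfinite(V_bs):
        raise InvalidInputError("V_bs must be finite")
    return IBS_SLOPE * V_bs + IBS_INTERCEPT


def drift_velocity(
    V_bs: float, pore: NanoporeGeometry, majority: IonSpecies
) -> float:
    """Drift velocity of the majority carrier (m/s), signed.

    ``v_bs = -sgn(z) * mu_ion * V_bs / L_Au``: a cation in the negative
    potential it induced drifts in the positive axial direction.
    """
    if majority.mobility is None:
        raise ConfigurationError(
            f"{majority.name}: mobility required for drift velocity; "
            "set it explicitly or use an ion with a tabulated value"
        )
    field = V_bs / pore.L_Au
    sign = 1 if majority.valence > 0 else -1
    return -sign * majority.mobility * field


def baseline_charge_density(I_bs: float, v_bs: float, pore: NanoporeGeometry) -> float:
    """Net in-pore charge density n_bs (C/m^3) satisfying I = n A v exactly."""
    if v_bs == 0:
        raise DegenerateStateError("zero drift velocity: charge density undefined")
    return I_bs / (pore.area * v_bs)


def _baseline_charge(
    V_bs: float, solution: ElectrolyteSolution, pore: NanoporeGeometry, majority: IonSpecies
) -> float:
    """Total baseline charge Q(V_bs) = V_total * n_bs(V_bs) (C)."""
    i_bs = baseline_current(V_bs)
    v_bs = drift_velocity(V_bs, pore, majority)
    return pore.volume * baseline_charge_density(i_bs, v_bs, pore)


def edl_capacitance(
    solution: ElectrolyteSolution,
    pore: NanoporeGeometry,
    *,
    V_bs: float | None = None,
    L_C: float = DEFAULT_CHARACTERISTIC_LENGTH,
    method: str = "closed",
    rel_step: float = 1e-6,
) -> float:
    """EDL capacitance C_EDL = d(V_total n_bs)/dV_bs (F) at the operating point.

    The operating point defaults to the baseline potential of ``solution``;
    pass ``V_bs`` to evaluate elsewhere.  ``method="closed"`` uses the
    analytic derivative of the regression/drift chain,
    ``C_EDL = sgn(z_bs) * L * L_Au * c / (mu_ion * V_bs^2)`` with ``c`` the
    regression intercept; ``method="fd"`` uses a central finite difference
    with relative step ``rel_step``.  The result is signed and positive for
    cation-majority baselines.
    """
    ctx = partition_context(solution, pore.r_np, L_C)
    majority = ctx.majority
    if V_bs is None:
        V_bs = predict_Vbs(solution, pore, L_C=L_C, ctx=ctx)
    if V_bs == 0:
        raise DegenerateStateError("zero operating potential")
    if method == "closed":
        if majority.mobility is None:
            raise ConfigurationError(f"{majority.name}: mobility required")
        sign = 1 if majority.valence > 0 else -1
        return sign * pore.L * pore.L_Au * IBS_INTERCEPT / (majority.mobility * V_bs**2)
    if method == "fd":
        h = abs(V_bs) * rel_step
        hi = _baseline_charge(V_bs + h, solution, pore, majority)
        lo = _baseline_charge(V_bs - h, solution, pore, majority)
        out = (hi - lo) / (2 * h)
        if not math.isfinite(out):
            raise DegenerateStateError("non-finite capacitance derivative")
        return out
    raise InvalidInputError(f"unknown method {method!r}")


def baseline_state(
    solution: ElectrolyteSolution,
    pore: NanoporeGeometry,
    *,
    L_C: float = DEFAULT_CHARACTERISTIC_LENGTH,
) -> BaselineState:
    """Evaluate the full baseline chain for one solution/pore pairing."""
    ctx = partition_context(solution, pore.r_np, L_C)
    v_pot = predict_Vbs(solution, pore, L_C=L_C, ctx=ctx)
    i_bs = baseline_current(v_pot)
    v_drift = drift_velocity(v_pot, pore, ctx.majority)
    n_bs = baseline_charge_density(i_bs, v_drift, pore)
    c_edl = edl_capacitance(solution, pore, V_bs=v_pot, L_C=L_C)
    return BaselineState(
        V_bs=v_pot,
        I_bs=i_bs,
        n_bs=n_bs,
        v_bs=v_drift,
        E=v_pot / pore.L_Au,
        C_EDL=c_edl,
        z_bs=ctx.majority.valence,
        P_bs=partition_coefficient(ctx),
        majority=ctx.majority,
    )
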