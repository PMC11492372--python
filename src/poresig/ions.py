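"""Ion and electrolyte property calculations.

The electrical double layer (EDL) inside a metal-gated nanopore is populated
almost exclusively by ions of one polarity — the *majority* ions, selected by
a size-partition effect: the smaller ion of an electrolyte pair enters the
confined pore more readily.  This module provides

* :class:`IonSpecies` and :class:`ElectrolyteSolution` containers,
* Debye activity coefficients and the in-pore / reservoir ionic activities,
* the Knudsen-ratio partition coefficient ``P_bs`` that quantifies the
  size-selection strength of a pore for a given electrolyte pair, and
* the majority-ion selection rule (smallest ionic radius).

Concentrations are accepted in mol/L (the conventional electrolyte unit);
all lengths are SI metres internally.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from importlib import resources

import pandas as pd

from .constants import DEBYE_A, DEBYE_B, DEFAULT_CHARACTERISTIC_LENGTH, DEFAULT_TEMPERATURE
from .errors import AmbiguityError, InvalidInputError

logger = logging.getLogger(__name__)

__all__ = [
    "IonSpecies",
    "ElectrolyteSolution",
    "PartitionContext",
    "load_ion_table",
    "ion_from_table",
    "binary_solution",
    "partition_context",
    "activity_coefficient",
    "debye_activity_coefficient",
    "ionic_activities",
    "partition_coefficient",
    "majority_ion",
    "minority_ion",
]

# Relative tolerance for the electroneutrality check of a solution.
_NEUTRALITY_RTOL = 1e-12


@dataclass(frozen=True)
class IonSpecies:
    """One ionic species.

    Parameters
    ----------
    name : str
        Species label (e.g. ``"Na+"``).
    molecular_weight : float
        Molar mass in g/mol.
    radius : float
        Ionic (crystal) radius in metres.
    valence : int
        Signed valence charge; must be nonzero.
    mobility : float, optional
        Electrophoretic mobility in m^2 V^-1 s^-1.  Defaults come from the
        shipped ion table; species without a tabulated value must be given
        one explicitly before they can act as charge carriers.
    """

    name: str
    molecular_weight: float
    radius: float
    valence: int
    mobility: float | None = None

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise InvalidInputError(f"{self.name}: radius must be positive")
        if self.molecular_weight <= 0:
            raise InvalidInputError(f"{self.name}: molecular weight must be positive")
        if self.valence == 0:
            raise InvalidInputError(f"{self.name}: valence must be nonzero")
        if self.mobility is not None and self.mobility <= 0:
            raise InvalidInputError(f"{self.name}: mobility must be positive when set")

    @property
    def polarity(self) -> int:
        """+1 for cations, -1 for anions."""
        return 1 if self.valence > 0 else -1


@dataclass(frozen=True)
class ElectrolyteSolution:
    """A set of ionic species with molar concentrations.

    ``species`` is a tuple of ``(IonSpecies, concentration)`` pairs with
    concentrations in mol/L.  The composition must be electroneutral
    (sum z_i c_i = 0 to within 1e-12 relative to sum |z_i| c_i).
    """

    species: tuple[tuple[IonSpecies, float], ...]
    temperature: float = DEFAULT_TEMPERATURE
    majority_override: str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "species", tuple(tuple(p) for p in self.species))
        if not self.species:
            raise InvalidInputError("solution must contain at least one species")
        for ion, conc in self.species:
            if conc <= 0:
                raise InvalidInputError(f"{ion.name}: concentration must be positive")
        if self.temperature <= 0:
            raise InvalidInputError("temperature must be positive")
        net = sum(ion.valence * c for ion, c in self.species)
        scale = sum(abs(ion.valence) * c for ion, c in self.species)
        if abs(net) > _NEUTRALITY_RTOL * scale:
            raise InvalidInputError(
                f"composition is not electroneutral: sum z_i c_i = {net:g} mol/L"
            )

    @property
    def ions(self) -> tuple[IonSpecies, ...]:
        return tuple(ion for ion, _ in self.species)

    @property
    def concentrations(self) -> tuple[float, ...]:
        return tuple(c for _, c in self.species)

    def ionic_strength(self) -> float:
        """Molar ionic strength I = 1/2 sum c_i z_i^2 (mol/L)."""
        return 0.5 * sum(c * ion.valence**2 for ion, c in self.species)

    def with_concentration(self, concentration: float) -> "ElectrolyteSolution":
        """Rescale all concentrations so the total salt concentration of each
        species equals ``concentration`` (uniform scaling preserving ratios
        relative to the first species)."""
        base = self.species[0][1]
        factor = concentration / base
        return replace(
            self,
            species=tuple((ion, c * factor) for ion, c in self.species),
        )


@dataclass(frozen=True)
class PartitionContext:
    """Majority/minority ion pair with the pore geometry entering ``P_bs``.

    ``L_C`` is the characteristic length scale of the confined system,
    1 nm by default.
    """

    majority: IonSpecies
    minority: IonSpecies
    r_np: float
    L_C: float = DEFAULT_CHARACTERISTIC_LENGTH

    def __post_init__(self) -> None:
        if self.r_np <= 0:
            raise InvalidInputError("r_np must be positive")
        if self.L_C <= 0:
            raise InvalidInputError("L_C must be positive")


def load_ion_table() -> pd.DataFrame:
    """Return the shipped ion table as a DataFrame (one row per species)."""
    with resources.files("poresig.data").joinpath("ions.csv").open() as fh:
        return pd.read_csv(fh)


def ion_from_table(name: str, mobility: float | None = None) -> IonSpecies:
    """Build an :class:`IonSpecies` from the shipped table by name.

    ``mobility`` overrides the tabulated value when given.
    """
    table = load_ion_table()
    row = table[table["name"] == name]
    if row.empty:
        known = ", ".join(table["name"])
        raise InvalidInputError(f"unknown ion {name!r}; shipped table has: {known}")
    rec = row.iloc[0]
    mob = mobility
    if mob is None and pd.notna(rec["mobility_m2_per_Vs"]):
        mob = float(rec["mobility_m2_per_Vs"])
    return IonSpecies(
        name=str(rec["name"]),
        molecular_weight=float(rec["molecular_weight_g_per_mol"]),
        radius=float(rec["radius_nm"]) * 1e-9,
        valence=int(rec["valence"]),
        mobility=mob,
    )


def binary_solution(
    cation: str, anion: str, concentration: float, temperature: float = DEFAULT_TEMPERATURE
) -> ElectrolyteSolution:
    """Convenience constructor for a symmetric binary electrolyte at molar
    concentration ``concentration`` (both ions at that concentration)."""
    cat = ion_from_table(cation)
    an = ion_from_table(anion)
    if cat.valence != -an.valence:
        raise InvalidInputError("binary_solution requires a symmetric valence pair")
    return ElectrolyteSolution(
        species=((cat, concentration), (an, concentration)), temperature=temperature
    )


def debye_activity_coefficient(
    ionic_strength: float, mean_radius: float, valence: int
) -> float:
    """Extended Debye–Hückel activity coefficient.

    log10 f = -A z^2 sqrt(I) / (1 + B r sqrt(I))

    Parameters
    ----------
    ionic_strength : float
        Molar ionic strength I (mol/L).
    mean_radius : float
        Average ion radius of the solution in metres.
    valence : int
        Valence charge of the species; enters squared, so the result is
        invariant under sign flips.
    """
    if ionic_strength < 0:
        raise InvalidInputError("ionic strength must be non-negative")
    sqrt_i = math.sqrt(ionic_strength)
    exponent = -DEBYE_A * valence**2 * sqrt_i / (1.0 + DEBYE_B * mean_radius * sqrt_i)
    return 10.0**exponent


def _mean_radius(ions: tuple[IonSpecies, ...], concentrations=None, weighted=False) -> float:
    if weighted:
        total = sum(concentrations)
        return sum(ion.radius * c for ion, c in zip(ions, concentrations)) / total
    return sum(ion.radius for ion in ions) / len(ions)


def activity_coefficient(
    solution: ElectrolyteSolution,
    species_index: int,
    *,
    radius_strategy: str = "unweighted",
) -> float:
    """Activity coefficient f_a of one species in ``solution``.

    The average ion radius entering the Debye law is the unweighted mean of
    all species radii by default; ``radius_strategy="concentration"`` weights
    by molar concentration instead.
    """
    if not 0 <= species_index < len(solution.species):
        raise InvalidInputError("species_index out of range")
    if radius_strategy not in ("unweighted", "concentration"):
        raise InvalidInputError(f"unknown radius strategy {radius_strategy!r}")
    r = _mean_radius(
        solution.ions,
        solution.concentrations,
        weighted=(radius_strategy == "concentration"),
    )
    ion = solution.ions[species_index]
    return debye_activity_coefficient(solution.ionic_strength(), r, ion.valence)


def majority_ion(solution: ElectrolyteSolution) -> IonSpecies:
    """The species dominating the in-pore charge: the smallest-radius ion.

    Size partitioning favours the smallest ion of the electrolyte; an exact
    radius tie cannot be resolved automatically and raises
    :class:`AmbiguityError` unless ``solution.majority_override`` names the
    intended species.
    """
    if len(solution.ions) < 2:
        raise InvalidInputError("majority-ion selection needs at least two species")
    if solution.majority_override is not None:
        for ion in solution.ions:
            if ion.name == solution.majority_override:
                logger.info("majority ion overridden by user: %s", ion.name)
                return ion
        raise InvalidInputError(
            f"majority override {solution.majority_override!r} not in solution"
        )
    smallest = min(solution.ions, key=lambda ion: ion.radius)
    ties = [ion for ion in solution.ions if ion.radius == smallest.radius]
    if len(ties) > 1:
        names = ", ".join(ion.name for ion in ties)
        raise AmbiguityError(
            f"radius tie between {names}; set majority_override on the solution"
        )
    return smallest


def minority_ion(solution: ElectrolyteSolution, majority: IonSpecies | None = None) -> IonSpecies:
    """The smallest-radius species of polarity opposite the majority ion."""
    maj = majority if majority is not None else majority_ion(solution)
    opposite = [ion for ion in solution.ions if ion.polarity != maj.polarity]
    if not opposite:
        raise InvalidInputError("no species of opposite polarity to the majority ion")
    return min(opposite, key=lambda ion: ion.radius)


def ionic_activities(
    solution: ElectrolyteSolution, pore: PartitionContext
) -> tuple[float, float]:
    """Ionic activities inside the nanopore and in the reservoir (mol/L).

    The reservoir activity sums a_i = c_i f_a over *all* species.  The
    nanopore activity considers only species sharing the majority ion's
    polarity — the pore interior is populated by one charge sign — with
    activity coefficients evaluated on that in-pore subset composition.
    """
    if pore.majority not in solution.ions:
        raise InvalidInputError("partition-context majority ion is not in the solution")
    ions = solution.ions
    concs = solution.concentrations

    r_all = _mean_radius(ions)
    i_all = solution.ionic_strength()
    a_reservoir = sum(
        c * debye_activity_coefficient(i_all, r_all, ion.valence)
        for ion, c in zip(ions, concs)
    )

    subset = [(ion, c) for ion, c in zip(ions, concs) if ion.polarity == pore.majority.polarity]
    sub_ions = tuple(ion for ion, _ in subset)
    r_sub = _mean_radius(sub_ions)
    i_sub = 0.5 * sum(c * ion.valence**2 for ion, c in subset)
    a_nanopore = sum(
        c * debye_activity_coefficient(i_sub, r_sub, ion.valence) for ion, c in subset
    )
    if a_nanopore <= 0 or a_reservoir <= 0:
        raise InvalidInputError("activities must be positive")
    return a_nanopore, a_reservoir


def partition_coefficient(ctx: PartitionContext) -> float:
    """Size-partition coefficient P_bs of the pore for an electrolyte pair.

    P_bs = (D_Kn,maj / D_Kn,min) * (L_C / r_np), with the Knudsen-diffusion
    coefficient ratio expressed through the ionic-radius ratio
    D_Kn,maj / D_Kn,min = r_maj / r_min (molecular size tracks molecular
    weight).  Identical ions give a Knudsen ratio of one; larger pores are
    less size-selective (P_bs falls off as 1/r_np).
    """
    if ctx.minority.radius <= 0:
        raise InvalidInputError("minority radius must be positive")
    knudsen_ratio = ctx.majority.radius / ctx.minority.radius
    return knudsen_ratio * ctx.L_C / ctx.r_np


def partition_context(
    solution: ElectrolyteSolution,
    r_np: float,
    L_C: float = DEFAULT_CHARACTERISTIC_LENGTH,
) -> PartitionContext:
    """Build the majority/minority :class:`PartitionContext` for a solution."""
    maj = majority_ion(solution)
    mino = minority_ion(solution, maj)
    return PartitionContext(majority=maj, minority=mino, r_np=r_np, L_C=L_C)
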