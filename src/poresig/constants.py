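"""Physical constants and the coefficients of the empirical nanopore model.

All values are SI.  The empirical coefficients gathered here define the
model's fixed relationships:

* ``DEBYE_A``/``DEBYE_B`` — extended Debye–Hückel coefficients for water at
  298 K, used by the activity-coefficient law
  ``log10 f_i = -A z_i^2 sqrt(I) / (1 + B r sqrt(I))`` with the ionic
  strength ``I`` in mol/L and the average ion radius ``r`` in metres.
* ``IBS_SLOPE``/``IBS_INTERCEPT`` — the linear regression relating the
  baseline-state transmembrane current to the baseline-state EDL potential,
  ``I_bs = IBS_SLOPE * V_bs + IBS_INTERCEPT`` (amperes, volts).  The slope
  sets the sub-nanoampere current scale of the device; the picoampere
  intercept matches the scale of the constant supply current biasing the
  metal layer.

Changing either regression coefficient rescales every downstream quantity
(charge density, capacitance, signal magnitudes) coherently; they are module
constants rather than per-call parameters because they characterise the
device, not the experiment.
"""

from __future__ import annotations

# Fundamental constants (CODATA exact values).
BOLTZMANN: float = 1.380649e-23  # J/K
ELEMENTARY_CHARGE: float = 1.602176634e-19  # C
AVOGADRO: float = 6.02214076e23  # 1/mol
FARADAY: float = 96485.33212  # C/mol

# Extended Debye-Hueckel coefficients, water at 298 K.
DEBYE_A: float = 0.509  # (mol/L)^-1/2
DEBYE_B: float = 3.28e9  # m^-1 (mol/L)^-1/2  (0.328 per angstrom)

# Baseline current--potential regression, I_bs = slope * V_bs + intercept.
IBS_SLOPE: float = 2.0e-8  # A/V
IBS_INTERCEPT: float = 5.0e-12  # A

# Default geometry and model length scales.
DEFAULT_PORE_LENGTH: float = 55e-9  # m, total nanopore length L
DEFAULT_METAL_LENGTH: float = 5e-9  # m, gold-layer length L_Au
DEFAULT_CHARACTERISTIC_LENGTH: float = 1e-9  # m, L_C in the partition factor

DEFAULT_TEMPERATURE: float = 298.0  # K

# Thickness of the bound water layer added to a bare analyte radius to form
# the Stokes radius (one water-molecule radius).
DEFAULT_WATER_LAYER: float = 0.14e-9  # m

# Default translocation time assumed when predicting signals without kinetic
# data; the analyte's direct current contribution is negligible at this scale.
DEFAULT_TRANSLOCATION_TIME: float = 1e-3  # s

# Metadata only: constant biasing current supplied to the gold ring (A).
SUPPLY_CURRENT: float = 37.4e-12

# Order-of-magnitude bulk (unconfined) mobilities used as reference points
# when flagging strongly hindered in-pore transport, m^2/(V s).  Values are
# generic small-ion magnitudes, configurable by callers.
BULK_MOBILITY_REFERENCE: dict[str, float] = {
    "oxalic_acid": 5.0e-8,
    "hydroquinone": 5.0e-8,
    "ascorbic_acid": 5.0e-8,
    "citric_acid": 5.0e-8,
}
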