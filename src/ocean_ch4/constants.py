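"""Versioned physical-constant and coefficient tables.

Every empirical coefficient set used by the package lives here, tagged with
the publication it was transcribed from, so transcriptions can be audited and
re-checked independently of the code that evaluates them.
"""

from __future__ import annotations

CONSTANTS_VERSION = "2026.09"

#: Molar mass of CH4 [g mol^-1] used for mass integrals (mmol -> Tg).
CH4_MOLAR_MASS_G = 16.043

#: Earth radius [m] for spherical cell areas and great-circle distances.
EARTH_RADIUS_M = 6.371e6

#: Standard atmosphere [Pa].
ATM_PA = 101325.0

# ---------------------------------------------------------------------------
# CH4 atmospheric-equilibrium solubility, Wiesenburg & Guinasso (1979).
#
#   ln C = ln f + A1 + A2*(100/T) + A3*ln(T/100) + A4*(T/100)
#              + S * [B1 + B2*(T/100) + B3*(T/100)^2]
#
# with T in kelvin, S in psu, f the CH4 mole fraction in the gas phase, and
# C in nmol L^-1.  With f expressed in ppb (1 ppb = 1e-9 mole fraction) the
# evaluated C is the equilibrium concentration in nM per ppb of pCH4.
# ---------------------------------------------------------------------------
WG79_CH4_NMOL_PER_L = {
    "A1": -415.2807,
    "A2": 596.8104,
    "A3": 379.2599,
    "A4": -62.0757,
    "B1": -0.059160,
    "B2": 0.032174,
    "B3": -0.0048198,
}

#: Validity range of the solubility fit accepted by this package.
SOLUBILITY_T_RANGE_C = (-2.0, 40.0)
SOLUBILITY_S_RANGE = (0.0, 45.0)

# ---------------------------------------------------------------------------
# Saturation water-vapor pressure over seawater, Weiss & Price (1980):
#   ln e_w[atm] = 24.4543 - 67.4509*(100/T) - 4.8489*ln(T/100) - 0.000544*S
# ---------------------------------------------------------------------------
WP80_VAPOR_PRESSURE = {
    "c0": 24.4543,
    "c1": -67.4509,
    "c2": -4.8489,
    "cs": -0.000544,
}

# ---------------------------------------------------------------------------
# Schmidt number of CH4 in seawater (S = 35), Wanninkhof (2014) Table 1:
#   Sc(t) = A + B*t + C*t^2 + D*t^3 + E*t^4,  t in deg C, valid -2..40 C.
# Sc(20 C) = 687.
# ---------------------------------------------------------------------------
SCHMIDT_CH4_SEAWATER = (2101.2, -131.54, 4.4931, -0.08676, 0.00070663)
SCHMIDT_T_RANGE_C = (-2.0, 40.0)

# ---------------------------------------------------------------------------
# Gas transfer velocity algorithms: k660 [cm hr^-1] as a function of U10
# [m s^-1].  Each entry: (label, (a1, a2, a3)) giving
#   k660 = a1*U + a2*U^2 + a3*U^3,
# normalized to other Schmidt numbers by (Sc/660)^-1/2.
# ---------------------------------------------------------------------------
K_ALGORITHMS = {
    1: ("Wanninkhof 2014", (0.0, 0.251, 0.0)),
    2: ("Wanninkhof 1992", (0.0, 0.39, 0.0)),
    3: ("Nightingale et al. 2000", (0.333, 0.222, 0.0)),
    4: ("Wanninkhof & McGillis 1999", (0.0, 0.0, 0.0283)),
}

CM_PER_HR_TO_M_PER_DAY = 0.24

# ---------------------------------------------------------------------------
# Bubble model environment defaults (idealized, constant water column).
# ---------------------------------------------------------------------------
SEAWATER_DENSITY = 1025.0       # kg m^-3
GRAVITY = 9.81                  # m s^-2
SURFACE_TENSION = 0.072         # N m^-1, air/seawater
GAS_CONSTANT = 8.314462618      # J mol^-1 K^-1
#: Molecular diffusivities in seawater near 15 C [m^2 s^-1].
DIFFUSIVITY_CH4 = 1.5e-9
DIFFUSIVITY_AIR = 1.8e-9
#: Henry solubility of the lumped background gas (N2/O2) [mol m^-3 atm^-1].
HENRY_AIR_MOL_M3_ATM = 0.70
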