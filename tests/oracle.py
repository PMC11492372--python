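"""Independent re-implementation of the model's equations.

Every function here is a direct, standalone evaluation of one documented
relationship (docs/methods.md), written in plain ``math`` with its own
constants and no imports from the package under test.  The tests compare
the package against these at fixed parameter points.
"""

import math

KB = 1.380649e-23
E_CHG = 1.602176634e-19

A_DH = 0.509
B_DH = 3.28e9

SLOPE = 2.0e-8
INTERCEPT = 5.0e-12


def sgn(z):
    return 1.0 if z > 0 else -1.0


def activity_coefficient(ionic_strength, mean_radius, valence):
    s = math.sqrt(ionic_strength)
    return 10.0 ** (-A_DH * valence * valence * s / (1.0 + B_DH * mean_radius * s))


def partition_coefficient(r_major, r_minor, r_np, l_c):
    return (r_major / r_minor) * (l_c / r_np)


def vbs(temperature, z_major, p_bs, a_nanopore, a_reservoir):
    return -sgn(z_major) * (KB * temperature / E_CHG) * p_bs * math.log(
        a_reservoir / a_nanopore
    )


def ibs(v_bs):
    return SLOPE * v_bs + INTERCEPT


def drift_velocity(z_major, mobility, v_bs, l_au):
    return -sgn(z_major) * mobility * v_bs / l_au


def charge_density(i_bs, area, v_drift):
    return i_bs / (area * v_drift)


def edl_capacitance(z_major, length, l_au, mobility, v_bs):
    return sgn(z_major) * length * l_au * INTERCEPT / (mobility * v_bs * v_bs)


def dn_volume(n_bs, v_analyte, v_total):
    return -n_bs * v_analyte / v_total


def dn_electric(p_bs, z_analyte, v_total):
    return -p_bs * z_analyte * E_CHG / v_total


def dv(v_bs, dn, n_bs):
    return v_bs * dn / (n_bs + dn)


def delta_current(area, dn, d_vel, n_bs, v_bs):
    return area * (dn * v_bs + n_bs * d_vel + dn * d_vel)


def n_analyte(z_analyte, v_total):
    return z_analyte * E_CHG / v_total


def v_analyte(length, t_ic):
    return length / t_ic


def i_analyte(n_an, area, v_an):
    return n_an * area * v_an


def vps(v_total, dn, n_an, c_edl):
    return v_total * (dn + n_an) / c_edl


def mobility(length, l_au, v_bs, t_ic):
    return length * l_au / (abs(v_bs) * t_ic)


def diffusivity(mob, z_analyte, temperature):
    return mob * KB * temperature / (abs(z_analyte) * E_CHG)


def naf_baseline(concentration=1e-3, r_np=2.3e-9, temperature=298.0):
    """Full baseline chain for NaF from first principles (binary 1:1 salt).

    Returns a dict with every intermediate; uses only this module.
    """
    r_na, r_f = 0.116e-9, 0.119e-9
    mu_na = 5.19e-8
    length, l_au, l_c = 55e-9, 5e-9, 1e-9
    area = math.pi * r_np * r_np

    i_all = concentration  # 1/2 (c*1 + c*1) * 2 = c for a 1:1 salt
    f_res = activity_coefficient(i_all, (r_na + r_f) / 2, 1)
    a_res = 2 * concentration * f_res
    f_pore = activity_coefficient(concentration / 2, r_na, 1)
    a_nano = concentration * f_pore

    p_bs = partition_coefficient(r_na, r_f, r_np, l_c)
    v_pot = vbs(temperature, 1, p_bs, a_nano, a_res)
    i_cur = ibs(v_pot)
    v_drift = drift_velocity(1, mu_na, v_pot, l_au)
    n_bs = charge_density(i_cur, area, v_drift)
    c_edl = edl_capacitance(1, length, l_au, mu_na, v_pot)
    return {
        "P_bs": p_bs,
        "V_bs": v_pot,
        "I_bs": i_cur,
        "v_bs": v_drift,
        "n_bs": n_bs,
        "C_EDL": c_edl,
        "area": area,
        "V_total": area * length,
    }
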