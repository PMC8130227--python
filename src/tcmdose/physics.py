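"""Photon interaction physics for the kilovoltage CT energy range (1–150 keV).

Materials are the six tissue families used to voxelize CT volumes (air, lung,
fat, water, muscle, bone) plus PMMA for the 32-cm dose-index phantom.  Partial
mass attenuation coefficients are semi-empirical:

* incoherent scatter -- exact integrated Klein--Nishina cross section per
  electron times the material electron density (the incoherent scattering
  function is neglected, a few-percent effect above ~20 keV);
* photoelectric absorption -- tau/rho = tau30 * (30 keV / E)^3 with the
  material constant tau30 scaled from a water anchor by Z_eff^3.8;
* coherent (Rayleigh) scatter -- sigma/rho = c30 * (30 keV / E)^2 scaled from
  a water anchor by Z_eff^2.5.

The water anchors reproduce the accepted total mass attenuation of water to
within ~2% over 30--120 keV (mu/rho ~ 0.21 cm^2/g at 60 keV, i.e. mu ~ 0.2/cm,
the value conventionally used for topogram water-equivalent attenuation at
120 kVp).  Aluminium total attenuation and the mass energy-absorption
coefficient of air are tabulated explicitly because half-value layers and air
kerma must come out in real units (mm Al).
"""

from __future__ import annotations

import numpy as np

# material family codes (voxel phantoms store these)
AIR, LUNG, FAT, WATER, MUSCLE, BONE, PMMA = range(7)
MATERIAL_NAMES = ("air", "lung", "fat", "water", "muscle", "bone", "pmma")
N_MATERIALS = len(MATERIAL_NAMES)

# electrons per gram is N_A * (Z/A); Z/A and effective Z per family
_Z_OVER_A = np.array([0.49919, 0.55048, 0.55579, 0.55509, 0.54938, 0.52130, 0.53937])
_Z_EFF = np.array([7.64, 7.42, 5.92, 7.42, 7.46, 13.8, 6.47])

_AVOGADRO = 6.02214076e23
ELECTRON_REST_KEV = 510.99895
_R_E_CM = 2.8179403262e-13  # classical electron radius

# water anchors at 30 keV (cm^2/g)
_TAU30_WATER = 0.133
_COH30_WATER = 0.0447
_PE_EXPONENT = 3.0
_COH_EXPONENT = 2.0

ENERGY_MIN_KEV = 1.0
ENERGY_MAX_KEV = 160.0


def kn_total_cross_section(energy_kev):
    """Integrated Klein--Nishina cross section per electron, cm^2."""
    a = np.asarray(energy_kev, dtype=float) / ELECTRON_REST_KEV
    t = 1.0 + 2.0 * a
    log_t = np.log(t)
    term1 = (1.0 + a) / a**2 * (2.0 * (1.0 + a) / t - log_t / a)
    term2 = log_t / (2.0 * a)
    term3 = (1.0 + 3.0 * a) / t**2
    return 2.0 * np.pi * _R_E_CM**2 * (term1 + term2 - term3)


def mu_rho_parts(material, energy_kev):
    """Partial mass attenuation coefficients (photoelectric, incoherent,
    coherent) in cm^2/g for a material family code at the given energies."""
    e = np.asarray(energy_kev, dtype=float)
    za = _Z_OVER_A[material]
    zf = _Z_EFF[material] / _Z_EFF[WATER]
    za_rel = za / _Z_OVER_A[WATER]
    pe = _TAU30_WATER * za_rel * zf**3.8 * (30.0 / e) ** _PE_EXPONENT
    inc = _AVOGADRO * za * kn_total_cross_section(e)
    coh = _COH30_WATER * za_rel * zf**2.5 * (30.0 / e) ** _COH_EXPONENT
    return pe, inc, coh


def mu_rho_total(material, energy_kev):
    pe, inc, coh = mu_rho_parts(material, energy_kev)
    return pe + inc + coh


def build_mu_tables(n_energies: int = 128):
    """Log-spaced energy grid and (n_material, n_energy) partial mu/rho tables
    used by the transport kernel (linear interpolation in log-log space)."""
    energies = np.geomspace(ENERGY_MIN_KEV, ENERGY_MAX_KEV, n_energies)
    pe = np.empty((N_MATERIALS, n_energies))
    inc = np.empty_like(pe)
    coh = np.empty_like(pe)
    for m in range(N_MATERIALS):
        pe[m], inc[m], coh[m] = mu_rho_parts(m, energies)
    return energies, pe, inc, coh


def _loglog_interp(energy_kev, table_e, table_v):
    """Log-log interpolation with linear (in log space) extrapolation."""
    x = np.log(np.asarray(energy_kev, dtype=float))
    xt = np.log(table_e)
    yt = np.log(table_v)
    y = np.interp(x, xt, yt)
    # linear extrapolation beyond the tabulated range
    lo = x < xt[0]
    hi = x > xt[-1]
    if np.any(lo):
        s = (yt[1] - yt[0]) / (xt[1] - xt[0])
        y = np.where(lo, yt[0] + s * (x - xt[0]), y)
    if np.any(hi):
        s = (yt[-1] - yt[-2]) / (xt[-1] - xt[-2])
        y = np.where(hi, yt[-1] + s * (x - xt[-1]), y)
    return np.exp(y)


# Aluminium total mass attenuation (cm^2/g); NIST-style grid above the K edge.
_AL_E = np.array([2, 3, 4, 5, 6, 8, 10, 15, 20, 30, 40, 50, 60, 80, 100, 150], float)
_AL_MU_RHO = np.array(
    [2263.0, 788.0, 360.5, 193.4, 115.3, 50.33, 26.23, 7.955, 3.441,
     1.128, 0.5685, 0.3681, 0.2778, 0.2018, 0.1704, 0.1378]
)
AL_DENSITY = 2.699  # g/cm^3


def mu_aluminum(energy_kev):
    """Linear attenuation coefficient of aluminium, cm^-1."""
    return AL_DENSITY * _loglog_interp(energy_kev, _AL_E, _AL_MU_RHO)


# Mass energy-absorption coefficient of air (cm^2/g), for air-kerma weighting.
_AIR_EN_E = np.array([5, 10, 15, 20, 30, 40, 50, 60, 80, 100, 150], float)
_AIR_MUEN_RHO = np.array(
    [39.3, 4.742, 1.334, 0.5389, 0.1537, 0.06833, 0.04098,
     0.03041, 0.02407, 0.02325, 0.02496]
)


def muen_air(energy_kev):
    """Mass energy-absorption coefficient of air, cm^2/g."""
    return _loglog_interp(energy_kev, _AIR_EN_E, _AIR_MUEN_RHO)


def mu_water(energy_kev):
    """Linear attenuation coefficient of unit-density water, cm^-1."""
    return mu_rho_total(WATER, energy_kev)
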