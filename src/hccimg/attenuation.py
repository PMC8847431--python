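"""Photon attenuation models for the detector and phantom materials.

Total linear attenuation is modelled as the sum of

* incoherent (Compton) scattering, computed analytically from the total
  Klein--Nishina cross section per electron times the material electron
  density, and
* photoelectric absorption, interpolated log--log on an embedded energy
  grid of mass attenuation values.

Coherent (Rayleigh) scattering and Doppler broadening are deliberately
ignored: they deflect without depositing energy and are second-order for
the energies of interest here (>= ~50 keV).  The photoelectric grids are
digitized from standard compilations for water and for the Ce:GAGG
(Gd3Al2Ga3O12) scintillator; the GAGG grid resolves the Gd K edge at
50.2 keV.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

ELECTRON_REST_KEV = 511.0
#: 2 pi r_e^2 in cm^2 (r_e = classical electron radius)
_TWO_PI_RE2 = 2.0 * np.pi * (2.8179403262e-13) ** 2
AVOGADRO = 6.02214076e23


def kn_total_cross_section(energy_kev):
    """Total Klein--Nishina cross section per electron, in cm^2.

    Closed-form integral of the differential cross section over solid
    angle, valid for any photon energy > 0.
    """
    k = np.asarray(energy_kev, dtype=float) / ELECTRON_REST_KEV
    if np.any(k <= 0):
        raise ValueError("photon energy must be positive")
    op2k = 1.0 + 2.0 * k
    log_term = np.log(op2k)
    t1 = (1.0 + k) / k**2 * (2.0 * (1.0 + k) / op2k - log_term / k)
    t2 = log_term / (2.0 * k)
    t3 = (1.0 + 3.0 * k) / op2k**2
    return _TWO_PI_RE2 * (t1 + t2 - t3)


def kn_differential(energy_kev, cos_theta):
    """Klein--Nishina differential cross section dσ/dΩ (cm^2/sr)."""
    k = np.asarray(energy_kev, dtype=float) / ELECTRON_REST_KEV
    cos_theta = np.asarray(cos_theta, dtype=float)
    eps = 1.0 / (1.0 + k * (1.0 - cos_theta))  # E'/E
    re2 = _TWO_PI_RE2 / (2.0 * np.pi)
    return 0.5 * re2 * eps**2 * (eps + 1.0 / eps - (1.0 - cos_theta**2))


@dataclass(frozen=True)
class AttenuationTable:
    """Attenuation model of one material.

    Parameters
    ----------
    material:
        Material name.
    density:
        g/cm^3.
    electrons_per_gram:
        Electron density in e-/g (sum of w_i * Z_i / A_i * N_A).
    pe_energies_kev, pe_mass_atten:
        Photoelectric mass attenuation grid (keV, cm^2/g); strictly
        increasing energies, interpolated log--log.
    """

    material: str
    density: float
    electrons_per_gram: float
    pe_energies_kev: np.ndarray = field(repr=False)
    pe_mass_atten: np.ndarray = field(repr=False)

    def __post_init__(self):
        e = np.asarray(self.pe_energies_kev, dtype=float)
        m = np.asarray(self.pe_mass_atten, dtype=float)
        if e.ndim != 1 or e.shape != m.shape:
            raise ValueError("grid arrays must be 1-D and equally sized")
        if np.any(np.diff(e) <= 0):
            raise ValueError("energy grid must be strictly increasing")
        if np.any(m <= 0):
            raise ValueError("mass attenuation values must be positive")
        object.__setattr__(self, "pe_energies_kev", e)
        object.__setattr__(self, "pe_mass_atten", m)

    # -- components, all in cm^-1 ------------------------------------
    def mu_photoelectric(self, energy_kev):
        e = np.asarray(energy_kev, dtype=float)
        if e.ndim and e.size > 8 and (e == e.flat[0]).all():
            # constant-energy batch: one interpolation, broadcast back
            return np.broadcast_to(self.mu_photoelectric(e.flat[0]), e.shape)
        lo, hi = self.pe_energies_kev[0], self.pe_energies_kev[-1]
        if np.any(e < lo) or np.any(e > hi):
            raise ValueError(
                f"energy outside tabulated range [{lo}, {hi}] keV for "
                f"{self.material}"
            )
        val = np.interp(
            np.log(e), np.log(self.pe_energies_kev), np.log(self.pe_mass_atten)
        )
        return self.density * np.exp(val)

    def mu_compton(self, energy_kev):
        e = np.asarray(energy_kev, dtype=float)
        if e.ndim and e.size > 8 and (e == e.flat[0]).all():
            return np.broadcast_to(self.mu_compton(e.flat[0]), e.shape)
        n_e = self.electrons_per_gram * self.density
        return n_e * kn_total_cross_section(e)

    def mu_total(self, energy_kev):
        return self.mu_photoelectric(energy_kev) + self.mu_compton(energy_kev)

    def photoelectric_fraction(self, energy_kev):
        pe = self.mu_photoelectric(energy_kev)
        return pe / (pe + self.mu_compton(energy_kev))

    def transmission(self, energy_kev, path_cm):
        """Narrow-beam survival probability over ``path_cm`` cm."""
        return np.exp(-self.mu_total(energy_kev) * np.asarray(path_cm))


# ---------------------------------------------------------------------------
# Embedded material data
# ---------------------------------------------------------------------------

# Water: H2O, mass fractions H 0.1119, O 0.8881.
# Photoelectric component dominated by oxygen; grid values digitized from
# standard photon cross-section compilations.
WATER = AttenuationTable(
    material="water",
    density=1.0,
    electrons_per_gram=0.5551 * AVOGADRO,
    pe_energies_kev=np.array(
        [20.0, 30.0, 40.0, 50.0, 60.0, 80.0, 100.0, 150.0, 200.0,
         300.0, 400.0, 500.0, 662.0, 800.0, 1000.0, 1500.0]
    ),
    pe_mass_atten=np.array(
        [0.1270, 0.0375, 0.0155, 0.00784, 0.00447, 0.00184, 0.00092,
         0.000264, 0.000107, 3.1e-5, 1.3e-5, 6.5e-6, 2.8e-6, 1.6e-6,
         8.0e-7, 2.4e-7]
    ),
)

# Ce:GAGG, Gd3Al2Ga3O12, density 6.63 g/cm^3.
# Mass fractions: Gd 0.509, Ga 0.226, O 0.207, Al 0.058
#   -> electrons/gram = 0.4391 * N_A.
# The Gd K edge (50.24 keV) appears as the jump between 50.1 and 50.4 keV.
GAGG = AttenuationTable(
    material="gagg",
    density=6.63,
    electrons_per_gram=0.4391 * AVOGADRO,
    pe_energies_kev=np.array(
        [40.0, 45.0, 50.1, 50.4, 52.0, 60.0, 80.0, 100.0, 150.0, 200.0,
         300.0, 400.0, 500.0, 662.0, 800.0, 1000.0, 1500.0]
    ),
    pe_mass_atten=np.array(
        [3.20, 2.30, 1.65, 8.70, 8.00, 5.67, 2.47, 1.29, 0.381, 0.170,
         0.0535, 0.0244, 0.0137, 0.0069, 0.0042, 0.0024, 0.00092]
    ),
)

MATERIALS = {"water": WATER, "gagg": GAGG}


def get_material(name: str) -> AttenuationTable:
    try:
        return MATERIALS[name.lower()]
    except KeyError:
        raise ValueError(f"unknown material {name!r}") from None
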