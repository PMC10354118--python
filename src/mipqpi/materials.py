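"""Material properties for photothermal simulations.

Thermal quantities are carried in micrometre/microsecond units throughout the
simulation modules: thermal diffusivity in µm² µs⁻¹, conductivity in the SI
W m⁻¹ K⁻¹ it is usually tabulated in (converted internally where needed).
"""

from __future__ import annotations

from dataclasses import dataclass


# 1 W m^-1 K^-1 expressed in J per (µs · µm · K)
W_PER_M_K = 1e-12


@dataclass(frozen=True)
class Medium:
    """A homogeneous heat-conducting medium.

    Parameters
    ----------
    name:
        Label used in reports and error messages.
    thermal_diffusivity:
        ν in µm² µs⁻¹ (equivalently 1e-6 m² s⁻¹).
    thermal_conductivity:
        K in W m⁻¹ K⁻¹.
    density, specific_heat:
        ρ (kg m⁻³) and c_p (J kg⁻¹ K⁻¹); optional.  When both are given
        together with K they must satisfy ν = K/(ρ c_p) within 1%.
    dn_dT:
        Thermo-optic coefficient in K⁻¹ (negative for liquid water);
        optional, only needed when converting temperature to optical phase.
    """

    name: str
    thermal_diffusivity: float
    thermal_conductivity: float | None = None
    density: float | None = None
    specific_heat: float | None = None
    dn_dT: float | None = None

    def __post_init__(self) -> None:
        if self.thermal_diffusivity <= 0:
            raise ValueError(f"{self.name}: thermal diffusivity must be > 0")
        if self.thermal_conductivity is not None and self.thermal_conductivity <= 0:
            raise ValueError(f"{self.name}: thermal conductivity must be > 0")
        if (
            self.thermal_conductivity is not None
            and self.density is not None
            and self.specific_heat is not None
        ):
            implied = self.thermal_conductivity / (self.density * self.specific_heat)
            implied_um2_us = implied * 1e6  # m² s⁻¹ → µm² µs⁻¹
            if abs(implied_um2_us - self.thermal_diffusivity) > 0.01 * self.thermal_diffusivity:
                raise ValueError(
                    f"{self.name}: inconsistent properties, K/(rho*c_p) = "
                    f"{implied_um2_us:.4g} µm²/µs but nu = {self.thermal_diffusivity:.4g}"
                )

    @property
    def volumetric_heat_capacity(self) -> float:
        """ρ c_p in J m⁻³ K⁻¹, derived from K/ν (or from ρ and c_p directly)."""
        if self.thermal_conductivity is not None:
            return self.thermal_conductivity / (self.thermal_diffusivity * 1e-6)
        if self.density is not None and self.specific_heat is not None:
            return self.density * self.specific_heat
        raise ValueError(f"{self.name}: need K or (rho, c_p) for heat capacity")


#: Liquid water at room temperature.  ρ and c_p are chosen consistent with the
#: (ν, K) pair; dn/dT is the visible-wavelength literature value (sign kept
#: negative; the imaging convention reports |Δθ|).
WATER = Medium(
    name="water",
    thermal_diffusivity=0.146,
    thermal_conductivity=0.618,
    density=997.0,
    specific_heat=4247.0,
    dn_dT=-1.4e-4,
)

#: Calcium fluoride substrate.  Only (ν, K) are specified; the volumetric heat
#: capacity used by the solvers follows from their ratio.
CAF2 = Medium(
    name="CaF2",
    thermal_diffusivity=2.92,
    thermal_conductivity=9.71,
)
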