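"""Physical constants, species definitions and dimensionless-number helpers.

Internal unit system is SI throughout: metres, seconds, pascals, and mol/m^3
for concentrations.  Because 1 mM == 1 mol/m^3, concentrations written in mM
carry over unchanged; configuration files may therefore state concentrations
in mM and volumetric rates in mM/s without any conversion factor.
"""

from __future__ import annotations

from typing import Literal, Optional

from pydantic import BaseModel, ConfigDict, Field, model_validator

__all__ = [
    "PhysicalParams",
    "SpeciesSpec",
    "default_physical_params",
    "default_species",
    "knudsen_number",
    "UL_PER_MIN",
]

#: volumetric flow conversion, 1 uL/min in m^3/s
UL_PER_MIN = 1e-9 / 60.0


class PhysicalParams(BaseModel):
    """Bulk properties of the culture medium and the imposed perfusion rate.

    Attributes
    ----------
    rho : float
        Medium density [kg/m^3].
    mu : float
        Dynamic viscosity [Pa s].
    Q : float
        Inlet volumetric flow rate [m^3/s].
    T_label : str
        Descriptive temperature tag; properties are fixed at this temperature.
    """

    model_config = ConfigDict(extra="forbid", frozen=True)

    rho: float = Field(gt=0.0)
    mu: float = Field(gt=0.0)
    Q: float = Field(gt=0.0)
    T_label: str = "37C"


class SpeciesSpec(BaseModel):
    """Transport and kinetic properties of one dissolved species.

    Diffusivities are per region [m^2/s]; solubility ratios are the
    equilibrium concentration jump factors relative to the medium
    (c_region = S_region * c_medium at an interface).  ``Vmax`` and ``Km``
    parameterise the saturating consumption rate inside the tissue,
    R = Vmax * c / (c + Km), in mol/m^3/s and mol/m^3.
    """

    model_config = ConfigDict(extra="forbid", frozen=True)

    name: Literal["oxygen", "glucose"]
    D_medium: float = Field(gt=0.0)
    D_tissue: float = Field(gt=0.0)
    D_pdms: Optional[float] = None
    S_pdms_vs_medium: Optional[float] = None
    S_tissue_vs_medium: float = Field(gt=0.0)
    Vmax: float = Field(gt=0.0)
    Km: float = Field(gt=0.0)
    c_inlet: float = Field(ge=0.0)
    pdms_permeable: bool

    @model_validator(mode="after")
    def _check_pdms_consistency(self) -> "SpeciesSpec":
        if self.pdms_permeable:
            if self.D_pdms is None or self.D_pdms <= 0.0:
                raise ValueError("pdms_permeable species requires D_pdms > 0")
            if self.S_pdms_vs_medium is None or self.S_pdms_vs_medium <= 0.0:
                raise ValueError("pdms_permeable species requires S_pdms_vs_medium > 0")
        return self


def default_physical_params() -> PhysicalParams:
    """Medium constants at 37 C and the standard perfusion rate of 5 uL/min."""
    return PhysicalParams(rho=993.3, mu=0.000692, Q=5.0 * UL_PER_MIN)


_SPECIES_DEFAULTS = {
    "oxygen": dict(
        name="oxygen",
        D_medium=2.6e-9,
        D_pdms=3.4e-9,
        D_tissue=1.83e-9,
        S_pdms_vs_medium=6.0,
        S_tissue_vs_medium=4.81,
        Vmax=0.0203,
        Km=0.00463,
        c_inlet=0.2,
        pdms_permeable=True,
    ),
    "glucose": dict(
        name="glucose",
        D_medium=9.27e-10,
        D_tissue=2.7e-10,
        S_tissue_vs_medium=1.0,
        Vmax=0.01076,
        Km=0.04,
        c_inlet=11.0,
        pdms_permeable=False,
    ),
}


def default_species(name: str) -> SpeciesSpec:
    """Return the default :class:`SpeciesSpec` for ``oxygen`` or ``glucose``."""
    try:
        kwargs = _SPECIES_DEFAULTS[name]
    except KeyError:
        raise ValueError(
            f"unknown species {name!r}; expected one of {sorted(_SPECIES_DEFAULTS)}"
        ) from None
    return SpeciesSpec(**kwargs)


def knudsen_number(lambda_mfp: float, L: float) -> float:
    """Ratio of molecular mean free path to a characteristic length.

    Both arguments are lengths in metres and must be positive.  Values well
    below 1e-3 justify the continuum flow treatment.
    """
    if lambda_mfp <= 0.0 or L <= 0.0:
        raise ValueError("knudsen_number requires positive lengths")
    return lambda_mfp / L
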