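"""Pure-component records: fusion properties and PC-SAFT parameters.

A :class:`ComponentRecord` bundles everything the package knows about one
active pharmaceutical ingredient (API): identity, the crystalline polymorph
the fusion data refer to, melting properties entering the solubility
equation, the PC-SAFT parameter block, and the pure glass-transition
temperature where known.
"""
from __future__ import annotations

from typing import Optional

from pydantic import BaseModel, ConfigDict, Field, model_validator


class PcSaftParameters(BaseModel):
    """Pure-component PC-SAFT parameter set.

    Attributes
    ----------
    segment_number : float
        Number of spherical segments per chain, m_i (>= 1).
    segment_diameter : float
        Temperature-independent segment diameter sigma_i in Angstrom.
    dispersion_energy : float
        Dispersion energy eps_i/k in K.
    association_energy : float
        Association (hydrogen-bond) well depth eps_i^assoc/k in K.
        Ignored when the molecule carries no association sites.
    association_volume : float
        Dimensionless association volume kappa_i^assoc in [0, 1].
    donor_sites, acceptor_sites : int
        Number of electron-donor and electron-acceptor sites.  A "4 (2/2)"
        scheme is two donors plus two acceptors; donors bond only to
        acceptors.
    """

    model_config = ConfigDict(frozen=True)

    segment_number: float = Field(ge=1.0)
    segment_diameter: float = Field(gt=0.0)
    dispersion_energy: float = Field(gt=0.0)
    association_energy: float = Field(default=0.0, ge=0.0)
    association_volume: float = Field(default=0.0, ge=0.0, le=1.0)
    donor_sites: int = Field(default=0, ge=0)
    acceptor_sites: int = Field(default=0, ge=0)

    @property
    def n_assoc(self) -> int:
        """Total number of association sites N_i^assoc."""
        return self.donor_sites + self.acceptor_sites


class BinaryInteraction(BaseModel):
    """Binary correction k_ij to the cross dispersion energy (default 0)."""

    model_config = ConfigDict(frozen=True)

    k_ij: float = 0.0

    @model_validator(mode="after")
    def _physical(self) -> "BinaryInteraction":
        if self.k_ij > 1.0:
            raise ValueError("k_ij > 1 gives a negative cross dispersion energy")
        return self


class FusionProperties(BaseModel):
    """Melting data entering the solubility equation.

    All values refer to the crystalline polymorph named on the parent
    :class:`ComponentRecord`.  The heat-capacity difference between liquid
    and crystal is treated as temperature independent.
    """

    model_config = ConfigDict(frozen=True)

    melting_temperature: float = Field(gt=0.0, description="T_m in K")
    fusion_enthalpy: float = Field(gt=0.0, description="Delta_fus H in J/mol")
    heat_capacity_difference: float = Field(
        ge=0.0, description="Delta_fus Cp in J/(K mol)")


class ComponentRecord(BaseModel):
    """One API: identity, fusion properties, optional PC-SAFT block and Tg."""

    model_config = ConfigDict(frozen=True)

    name: str
    abbreviation: str
    polymorph: Optional[str] = None
    structure_id: Optional[str] = None
    fusion: FusionProperties
    pcsaft: Optional[PcSaftParameters] = None
    glass_transition: Optional[float] = Field(
        default=None, description="Pure-component Tg in K")

    def require_pcsaft(self) -> PcSaftParameters:
        if self.pcsaft is None:
            raise ValueError(
                f"component {self.abbreviation!r} has no PC-SAFT parameters")
        return self.pcsaft
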