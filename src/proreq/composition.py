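"""Feed-chemistry calculators.

Deterministic arithmetic on diet composition: organic matter as the ash
complement, hemicellulose as the NDF/ADF difference, crude protein from
total nitrogen (Kjeldahl convention, N x 6.25), the NRC summative TDN
equation, and the TDN -> metabolizable-energy conversion (1 kg TDN =
3.62 Mcal).  All mass fractions are handled internally on a g/kg DM
basis; percent-of-DM appears only where the source equation is defined
in percent (the TDN equation).
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "TDNComponents",
    "organic_matter",
    "hemicellulose",
    "cp_from_n",
    "n_from_cp",
    "tdn_nrc",
    "me_from_tdn",
]

#: grams of crude protein per gram of nitrogen (Kjeldahl convention)
CP_PER_N = 6.25

#: Mcal of metabolizable energy per kg of total digestible nutrients
ME_MCAL_PER_KG_TDN = 3.62


@dataclass(frozen=True)
class TDNComponents:
    """Truly digestible fractions entering the summative TDN equation.

    All components are percent of dietary DM: non-fibre carbohydrate
    (``td_nfc``), crude protein (``td_cp``), fatty acids (``td_fa``,
    weighted 2.25x for its higher gross energy) and NDF (``td_ndf``).
    """

    td_nfc: float
    td_cp: float
    td_fa: float
    td_ndf: float

    def __post_init__(self) -> None:
        for name in ("td_nfc", "td_cp", "td_fa", "td_ndf"):
            v = getattr(self, name)
            if not 0.0 <= v <= 100.0:
                raise ValueError(f"{name} must be in [0, 100] % of DM, got {v}")


def organic_matter(ash_gkg_dm: float) -> float:
    """Organic matter (g/kg DM) as the complement of ash."""
    if not 0.0 <= ash_gkg_dm <= 1000.0:
        raise ValueError(f"ash must be in [0, 1000] g/kg DM, got {ash_gkg_dm}")
    return 1000.0 - ash_gkg_dm


def hemicellulose(ndf_gkg: float, adf_gkg: float) -> float:
    """Hemicellulose (g/kg DM) as NDF minus ADF."""
    if adf_gkg < 0.0:
        raise ValueError(f"ADF must be non-negative, got {adf_gkg}")
    if ndf_gkg < adf_gkg:
        raise ValueError(f"NDF ({ndf_gkg}) must be >= ADF ({adf_gkg})")
    return ndf_gkg - adf_gkg


def cp_from_n(n_mass: float, factor: float = CP_PER_N) -> float:
    """Crude-protein mass from nitrogen mass (any common mass unit)."""
    if n_mass < 0.0:
        raise ValueError(f"nitrogen mass must be non-negative, got {n_mass}")
    if factor <= 0.0:
        raise ValueError(f"conversion factor must be positive, got {factor}")
    return n_mass * factor


def n_from_cp(cp_mass: float, factor: float = CP_PER_N) -> float:
    """Nitrogen mass from crude-protein mass; exact inverse of :func:`cp_from_n`."""
    if cp_mass < 0.0:
        raise ValueError(f"crude-protein mass must be non-negative, got {cp_mass}")
    if factor <= 0.0:
        raise ValueError(f"conversion factor must be positive, got {factor}")
    return cp_mass / factor


def tdn_nrc(c: TDNComponents) -> float:
    """Summative TDN (% of DM): tdNFC + tdCP + 2.25*tdFA + tdNDF - 7.

    The constant -7 is the metabolic fecal correction of the summative
    equation; at the origin the formula therefore returns -7, which is
    left to the caller to interpret (real diets are nowhere near it).
    """
    return c.td_nfc + c.td_cp + 2.25 * c.td_fa + c.td_ndf - 7.0


def me_from_tdn(tdn_gkg: float, factor: float = ME_MCAL_PER_KG_TDN) -> float:
    """Metabolizable energy (Mcal/kg DM) from TDN (g/kg DM)."""
    if tdn_gkg < 0.0:
        raise ValueError(f"TDN must be non-negative, got {tdn_gkg}")
    if factor <= 0.0:
        raise ValueError(f"conversion factor must be positive, got {factor}")
    return tdn_gkg / 1000.0 * factor
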