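"""Growth performance, intake scaling, digestibility and nitrogen balance.

All per-animal quantities are computed from one :class:`AnimalPeriodRecord`
plus its diet row.  Efficiency ratios and digestibilities are computed per
animal and averaged afterwards (mean of ratios, not ratio of means), which
is the convention treatment-comparison tables in feeding trials follow.
Metabolic scaling divides by W^0.75 of the period's mean body weight.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

from .composition import n_from_cp
from .trial_io import AnimalPeriodRecord, DietComposition, RunConfig

__all__ = [
    "PerformanceSummary",
    "NitrogenBalance",
    "DigestibilitySummary",
    "metabolic_weight",
    "daily_gain",
    "scale_intakes",
    "apparent_digestibility",
    "nitrogen_balance",
    "record_nitrogen_balance",
    "record_digestibility",
]


def metabolic_weight(bw_kg: float) -> float:
    """Metabolic body weight, BW^0.75 (kg^0.75).

    The 3/4-power scaling base under which maintenance requirements are
    approximately constant across body sizes.
    """
    if bw_kg <= 0:
        raise ValueError(f"body weight must be positive, got {bw_kg}")
    return bw_kg ** 0.75


def daily_gain(initial_bw_kg: float, final_bw_kg: float, days: float) -> float:
    """Average daily gain (kg/d); negative when the animal loses weight."""
    if days <= 0:
        raise ValueError(f"days on feed must be positive, got {days}")
    return (final_bw_kg - initial_bw_kg) / days


def apparent_digestibility(intake_kg_d: float, fecal_output_kg_d: float) -> float:
    """Apparent total-tract digestibility, % of intake.

    May legitimately fall below zero on noisy data; callers flag rather
    than clip such values.
    """
    if intake_kg_d <= 0:
        raise ValueError(f"intake must be positive, got {intake_kg_d}")
    if fecal_output_kg_d < 0:
        raise ValueError(f"fecal output must be non-negative, got {fecal_output_kg_d}")
    return 100.0 * (intake_kg_d - fecal_output_kg_d) / intake_kg_d


@dataclass
class PerformanceSummary:
    """Per-animal-period growth and intake summary (one row of Tables 2-3 style)."""

    animal_id: str
    treatment_label: str
    average_bw_kg: float
    metabolic_bw_kg075: float
    adg_kg_d: float
    dmi_kg_d: float
    dmi_gkg_w075: float
    dmi_pct_bw: float
    cpi_kg_d: float
    cpi_gkg_w075: float
    tdni_kg_d: float
    tdni_gkg_w075: float
    omi_kg_d: float
    ndfi_kg_d: float
    adfi_kg_d: float
    hemi_kg_d: float
    adg_per_dmi_g_kg: Optional[float] = None
    adg_per_cpi_g_g: Optional[float] = None
    adg_per_tdni_g_kg: Optional[float] = None


def scale_intakes(
    record: AnimalPeriodRecord,
    diet: DietComposition,
    config: RunConfig | None = None,
) -> PerformanceSummary:
    """Nutrient intakes, metabolic-weight scalings and efficiency ratios.

    Nutrient intakes are DMI x the diet's composition fraction; scaled
    intakes divide by the period-mean metabolic weight; efficiency ratios
    are per-animal (undefined and left as None at zero intake).
    """
    avg_bw = record.average_bw_kg
    if avg_bw <= 0:
        raise ValueError("average body weight must be positive")
    w075 = metabolic_weight(avg_bw)
    dmi = record.dm_intake_kg_d
    adg = daily_gain(record.initial_bw_kg, record.final_bw_kg, record.days_on_feed)

    cpi = dmi * diet.cp_gkg_dm / 1000.0
    tdni = dmi * diet.tdn_gkg_dm / 1000.0
    summary = PerformanceSummary(
        animal_id=record.animal_id,
        treatment_label=record.treatment_label,
        average_bw_kg=avg_bw,
        metabolic_bw_kg075=w075,
        adg_kg_d=adg,
        dmi_kg_d=dmi,
        dmi_gkg_w075=dmi * 1000.0 / w075,
        dmi_pct_bw=100.0 * dmi / avg_bw,
        cpi_kg_d=cpi,
        cpi_gkg_w075=cpi * 1000.0 / w075,
        tdni_kg_d=tdni,
        tdni_gkg_w075=tdni * 1000.0 / w075,
        omi_kg_d=dmi * diet.om_gkg_dm / 1000.0,
        ndfi_kg_d=dmi * diet.ndf_gkg_dm / 1000.0,
        adfi_kg_d=dmi * diet.adf_gkg_dm / 1000.0,
        hemi_kg_d=dmi * diet.hemicellulose_gkg_dm / 1000.0,
    )
    if dmi > 0:
        summary.adg_per_dmi_g_kg = adg * 1000.0 / dmi
        summary.adg_per_cpi_g_g = adg / cpi if cpi > 0 else None
        summary.adg_per_tdni_g_kg = adg * 1000.0 / tdni if tdni > 0 else None
    return summary


@dataclass
class NitrogenBalance:
    """Nitrogen mass balance for one animal-period, g N/d and g N/kg W^0.75.

    Built entirely from the accounting identities

        excretion  = fecal + urinary
        absorption = intake - fecal
        retention  = intake - excretion = absorption - urinary

    so the conservation identity intake - fecal - urinary - retention = 0
    holds exactly by construction.
    """

    n_intake_g_d: float
    fecal_n_g_d: float
    urine_n_g_d: float
    n_excretion_g_d: float
    n_absorption_g_d: float
    n_retention_g_d: float
    metabolic_bw_kg075: Optional[float] = None
    scaled: dict[str, float] = field(default_factory=dict)


def nitrogen_balance(
    n_intake_g_d: float,
    fecal_n_g_d: float,
    urine_n_g_d: float,
    metabolic_bw_kg075: float | None = None,
) -> NitrogenBalance:
    """Fill the nitrogen-balance identities from the three measured flows."""
    if n_intake_g_d < 0:
        raise ValueError(f"N intake must be non-negative, got {n_intake_g_d}")
    if fecal_n_g_d < 0 or urine_n_g_d < 0:
        raise ValueError("fecal and urinary N must be non-negative")
    excretion = fecal_n_g_d + urine_n_g_d
    absorption = n_intake_g_d - fecal_n_g_d
    retention = n_intake_g_d - excretion
    nb = NitrogenBalance(
        n_intake_g_d=n_intake_g_d,
        fecal_n_g_d=fecal_n_g_d,
        urine_n_g_d=urine_n_g_d,
        n_excretion_g_d=excretion,
        n_absorption_g_d=absorption,
        n_retention_g_d=retention,
        metabolic_bw_kg075=metabolic_bw_kg075,
    )
    if metabolic_bw_kg075 is not None:
        if metabolic_bw_kg075 <= 0:
            raise ValueError("metabolic weight must be positive")
        nb.scaled = {
            "n_intake": n_intake_g_d / metabolic_bw_kg075,
            "fecal_n": fecal_n_g_d / metabolic_bw_kg075,
            "urine_n": urine_n_g_d / metabolic_bw_kg075,
            "n_excretion": excretion / metabolic_bw_kg075,
            "n_absorption": absorption / metabolic_bw_kg075,
            "n_retention": retention / metabolic_bw_kg075,
        }
    return nb


def record_nitrogen_balance(
    record: AnimalPeriodRecord,
    diet: DietComposition,
    config: RunConfig | None = None,
) -> NitrogenBalance:
    """Nitrogen balance for a trial record.

    N intake is derived from CP intake / 6.25 (diet CP is itself N x 6.25,
    so this recovers the diet's nitrogen content); fecal and urinary N come
    from the record's measured columns.
    """
    cfg = config or RunConfig()
    cp_intake_g_d = record.dm_intake_kg_d * diet.cp_gkg_dm
    n_intake = n_from_cp(cp_intake_g_d, cfg.cp_conversion_factor)
    return nitrogen_balance(
        n_intake,
        record.fecal_n_g_d,
        record.urine_n_g_d,
        metabolic_weight(record.average_bw_kg),
    )


@dataclass
class DigestibilitySummary:
    """Apparent total-tract digestibilities (%) computable from a record.

    DM and CP(N) come from the record's own fecal columns.  Other
    nutrients need a fecal-composition map (g/kg fecal DM) the record
    schema does not carry; when given, their digestibilities are filled
    too.  Values below zero are preserved and listed in ``warnings``.
    """

    dm_pct: float
    cp_pct: float
    om_pct: Optional[float] = None
    ndf_pct: Optional[float] = None
    adf_pct: Optional[float] = None
    hemicellulose_pct: Optional[float] = None
    warnings: list[str] = field(default_factory=list)


def record_digestibility(
    record: AnimalPeriodRecord,
    diet: DietComposition,
    fecal_composition_gkg: dict[str, float] | None = None,
    config: RunConfig | None = None,
) -> DigestibilitySummary:
    cfg = config or RunConfig()
    dmi = record.dm_intake_kg_d
    n_intake = n_from_cp(dmi * diet.cp_gkg_dm, cfg.cp_conversion_factor)
    out = DigestibilitySummary(
        dm_pct=apparent_digestibility(dmi, record.fecal_dm_kg_d),
        cp_pct=apparent_digestibility(n_intake, record.fecal_n_g_d),
    )
    if fecal_composition_gkg:
        nutrient_cols = {
            "om_pct": "om_gkg_dm",
            "ndf_pct": "ndf_gkg_dm",
            "adf_pct": "adf_gkg_dm",
            "hemicellulose_pct": "hemicellulose_gkg_dm",
        }
        for attr, diet_col in nutrient_cols.items():
            key = diet_col.replace("_gkg_dm", "")
            if key in fecal_composition_gkg:
                intake = dmi * getattr(diet, diet_col) / 1000.0
                fecal = record.fecal_dm_kg_d * fecal_composition_gkg[key] / 1000.0
                if intake > 0:
                    setattr(out, attr, apparent_digestibility(intake, fecal))
    for name in ("dm_pct", "cp_pct", "om_pct", "ndf_pct", "adf_pct", "hemicellulose_pct"):
        v = getattr(out, name)
        if v is not None and (v < 0 or v > 100):
            out.warnings.append(
                f"{record.animal_id}/p{record.period}: {name} = {v:.1f} outside [0, 100]"
            )
    return out


def average_bw_for_scaling(record: AnimalPeriodRecord) -> float:
    """Mean of initial and final body weight of the period (kg)."""
    return record.average_bw_kg
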