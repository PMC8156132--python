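"""Full trial analysis: per-animal accounting -> treatment tables -> requirements.

``analyze_trial`` runs every stage on a :class:`TrialDataset`: intake and
growth summaries, apparent digestibility, nitrogen balance, the purine ->
microbial-N chain, RCBD statistics per response (treatment means, pooled
SEM, polynomial-contrast p-values, Duncan letters), and the requirement
regression.  Periods are averaged per animal before the between-animal
statistics, so the block design has one observation per animal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import performance as perf
from . import purines
from .rcbd import AnovaResult, rcbd_anova
from .requirement import ProteinRequirementModel, ProteinRequirementResults
from .trial_io import Finding, RunConfig, TrialDataset, validate_dataset

__all__ = ["TrialAnalysis", "analyze_trial", "per_animal_frame", "treatment_table"]

#: response -> column groupings for the report tables
TABLE_LAYOUT = {
    "performance": [
        "average_bw_kg", "adg_kg_d", "adg_per_dmi_g_kg", "adg_per_cpi_g_g",
        "adg_per_tdni_g_kg",
    ],
    "intake_digestibility": [
        "dmi_kg_d", "dmi_gkg_w075", "dmi_pct_bw", "cpi_kg_d", "cpi_gkg_w075",
        "tdni_kg_d", "tdni_gkg_w075", "omi_kg_d", "ndfi_kg_d", "adfi_kg_d",
        "hemi_kg_d", "digest_dm_pct", "digest_cp_pct",
    ],
    "nitrogen_balance": [
        "n_intake_g_d", "fecal_n_g_d", "urine_n_g_d", "n_excretion_g_d",
        "n_absorption_g_d", "n_retention_g_d", "n_intake_gkg_w075",
        "n_retention_gkg_w075",
    ],
    "purine_microbial": [
        "allantoin_mmol_d", "uric_acid_mmol_d", "xanthine_mmol_d",
        "hypoxanthine_mmol_d", "total_pd_mmol_d", "creatinine_mmol_d",
        "ratio_a_c", "ratio_pd_c", "pdc_index", "pb_absorbed_mmol_d",
        "microbial_n_g_d", "micn_per_kg_domr", "micn_per_kg_omi",
        "micn_per_kg_dmi", "micn_per_g_cpi", "micn_per_kg_tdni",
    ],
}


def per_animal_frame(dataset: TrialDataset, config: RunConfig | None = None) -> pd.DataFrame:
    """One row per animal-period with every derived response."""
    cfg = config or RunConfig()
    rows = []
    for r in dataset.records:
        diet = dataset.diet_for(r.treatment_label)
        s = perf.scale_intakes(r, diet, cfg)
        nb = perf.record_nitrogen_balance(r, diet, cfg)
        dig = perf.record_digestibility(r, diet, config=cfg)
        # digestible OM intake approximated through DM digestibility; DOMR
        # is the configured rumen-fermented fraction of it
        domi = s.omi_kg_d * dig.dm_pct / 100.0
        denominators = {
            "domr": max(1e-9, cfg.domr_fraction * domi),
            "omi": s.omi_kg_d,
            "dmi": s.dmi_kg_d,
            "cpi_g": s.cpi_kg_d * 1000.0,
            "tdni": s.tdni_kg_d,
        }
        pm = purines.record_purine_summary(r, cfg, intake_denominators=denominators)
        rows.append(
            {
                "animal_id": r.animal_id,
                "block_id": r.block_id,
                "treatment_label": r.treatment_label,
                "period": r.period,
                "average_bw_kg": s.average_bw_kg,
                "metabolic_bw_kg075": s.metabolic_bw_kg075,
                "adg_kg_d": s.adg_kg_d,
                "dmi_kg_d": s.dmi_kg_d,
                "dmi_gkg_w075": s.dmi_gkg_w075,
                "dmi_pct_bw": s.dmi_pct_bw,
                "cpi_kg_d": s.cpi_kg_d,
                "cpi_gkg_w075": s.cpi_gkg_w075,
                "tdni_kg_d": s.tdni_kg_d,
                "tdni_gkg_w075": s.tdni_gkg_w075,
                "omi_kg_d": s.omi_kg_d,
                "ndfi_kg_d": s.ndfi_kg_d,
                "adfi_kg_d": s.adfi_kg_d,
                "hemi_kg_d": s.hemi_kg_d,
                "adg_per_dmi_g_kg": s.adg_per_dmi_g_kg,
                "adg_per_cpi_g_g": s.adg_per_cpi_g_g,
                "adg_per_tdni_g_kg": s.adg_per_tdni_g_kg,
                "digest_dm_pct": dig.dm_pct,
                "digest_cp_pct": dig.cp_pct,
                "n_intake_g_d": nb.n_intake_g_d,
                "fecal_n_g_d": nb.fecal_n_g_d,
                "urine_n_g_d": nb.urine_n_g_d,
                "n_excretion_g_d": nb.n_excretion_g_d,
                "n_absorption_g_d": nb.n_absorption_g_d,
                "n_retention_g_d": nb.n_retention_g_d,
                "n_intake_gkg_w075": nb.scaled["n_intake"],
                "n_retention_gkg_w075": nb.scaled["n_retention"],
                "allantoin_mmol_d": pm.allantoin_mmol_d,
                "uric_acid_mmol_d": pm.uric_acid_mmol_d,
                "xanthine_mmol_d": pm.xanthine_mmol_d,
                "hypoxanthine_mmol_d": pm.hypoxanthine_mmol_d,
                "total_pd_mmol_d": pm.total_pd_mmol_d,
                "creatinine_mmol_d": pm.creatinine_mmol_d,
                "ratio_a_c": pm.ratio_a_c,
                "ratio_pd_c": pm.ratio_pd_c,
                "pdc_index": pm.pdc_index,
                "pb_absorbed_mmol_d": pm.pb_absorbed_mmol_d,
                "microbial_n_g_d": pm.microbial_n_g_d,
                "micn_per_kg_domr": pm.efficiencies.get("domr"),
                "micn_per_kg_omi": pm.efficiencies.get("omi"),
                "micn_per_kg_dmi": pm.efficiencies.get("dmi"),
                "micn_per_g_cpi": pm.efficiencies.get("cpi_g"),
                "micn_per_kg_tdni": pm.efficiencies.get("tdni"),
            }
        )
    return pd.DataFrame(rows)


def treatment_table(
    animal_df: pd.DataFrame,
    variables: list[str],
    treatment_levels: dict[str, float],
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, dict[str, AnovaResult]]:
    """RCBD statistics per response, laid out as a treatment-comparison table."""
    labels = sorted(treatment_levels, key=treatment_levels.get)
    rows, anovas = [], {}
    for var in variables:
        sub = animal_df.dropna(subset=[var])
        res = rcbd_anova(
            sub[var].to_numpy(),
            sub["block_id"].to_numpy(),
            sub["treatment_label"].to_numpy(),
            treatment_levels=treatment_levels,
            alpha=alpha,
        )
        anovas[var] = res
        row = {"item": var}
        for lab in labels:
            letter = res.duncan_letters.get(lab, "")
            row[f"mean_{lab}"] = res.treatment_means[lab]
            row[f"letters_{lab}"] = letter
        row["sem"] = res.pooled_sem
        row["p_linear"] = res.contrast_p.get("linear")
        row["p_quadratic"] = res.contrast_p.get("quadratic")
        rows.append(row)
    return pd.DataFrame(rows), anovas


@dataclass
class TrialAnalysis:
    """Everything the pipeline produces for one trial."""

    per_animal: pd.DataFrame
    tables: dict[str, pd.DataFrame]
    anovas: dict[str, dict[str, AnovaResult]]
    requirement: ProteinRequirementResults
    findings: list[Finding] = field(default_factory=list)

    def summary_json(self) -> dict:
        """Machine-readable headline estimates."""
        return {
            "requirement": self.requirement.to_dict(),
            "n_records": int(len(self.per_animal)),
            "n_findings": len(self.findings),
            "findings": [f.model_dump() for f in self.findings],
        }


def analyze_trial(dataset: TrialDataset, config: RunConfig | None = None) -> TrialAnalysis:
    cfg = config or RunConfig()
    findings = validate_dataset(dataset)
    animal_period = per_animal_frame(dataset, cfg)
    # average the two periods per animal before between-animal statistics
    keys = ["animal_id", "block_id", "treatment_label"]
    animal = animal_period.groupby(keys, as_index=False, sort=True).mean(numeric_only=True)
    animal = animal.drop(columns=["period"])

    levels = {d.treatment_label: d.cp_level_pct_dm for d in dataset.diets}
    tables, anovas = {}, {}
    for name, variables in TABLE_LAYOUT.items():
        tables[name], anovas[name] = treatment_table(animal, variables, levels, cfg.alpha)

    req = ProteinRequirementModel.from_trial(dataset, cfg).fit()
    return TrialAnalysis(
        per_animal=animal_period,
        tables=tables,
        anovas=anovas,
        requirement=req,
        findings=findings,
    )
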