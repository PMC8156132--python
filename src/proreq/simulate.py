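"""Synthetic feeding-trial generator.

Emulates the study conditions of a growing swamp-buffalo protein trial:
16 bulls (initial BW ~233 +/- 25 kg) in a randomized complete block
design — 4 dietary CP levels (5.4, 6.6, 8.5, 10.5% of DM) x 4 blocks —
over 2 repeated 45-day periods at near-constant dietary energy.

The generator matches moments and accounting identities, not physiology:
per-treatment group means and pooled SEMs are the published table values,
per-animal SD = SEM x sqrt(n) with Gaussian noise, an additive block
effect acts on initial body weight (blocks were weight groups), and a
shared per-animal "appetite" factor correlates intake with gain — the
knob that sets the strength of the N-intake ~ ADG regression.  All hard
identities of the downstream accounting hold by construction (refusals
below offer, fecal DM below intake, N excretion below N intake) unless
``allow_inconsistent`` is set, which is how validator tests obtain dirty
data.  Fixed config + seed gives a byte-identical dataset.
"""

from __future__ import annotations

import math
from typing import Optional, Sequence

import numpy as np
from pydantic import BaseModel, Field, model_validator

from .requirement import RequirementPoint
from .trial_io import AnimalPeriodRecord, DietComposition, TrialDataset

__all__ = [
    "SyntheticConfig",
    "default_group_means",
    "default_group_sems",
    "default_diets",
    "generate_trial",
    "generate_requirement_points",
    "calibrate_noise_sd",
    "requirement_recovery_experiment",
    "GROUP_ADG_PER_W075",
]

CP_LEVELS = (5.4, 6.6, 8.5, 10.5)

#: group-level ADG on metabolic-weight-scaled axes, g ADG/kg W^0.75/d,
#: derived from the group ADG and mean-BW table values
GROUP_ADG_PER_W075 = (-0.84, 2.62, 4.65, 7.97)


def default_group_means() -> dict[str, tuple[float, ...]]:
    """Per-treatment generating means (one entry per CP level, low to high)."""
    return {
        "initial_bw_kg": (233.8, 234.0, 234.0, 232.8),
        "adg_kg_d": (-0.05, 0.16, 0.29, 0.51),
        "dmi_kg_d": (4.17, 4.97, 5.25, 5.60),
        "fecal_dm_kg_d": (1.67, 1.83, 2.23, 2.44),
        "urine_l_d": (3.55, 3.62, 4.48, 4.80),
        "fecal_n_g_d": (21.79, 25.19, 30.77, 35.17),
        "urine_n_g_d": (8.08, 10.06, 20.93, 32.55),
        "allantoin_mmol_d": (10.52, 14.83, 13.77, 25.26),
        "uric_acid_mmol_d": (3.00, 2.09, 1.50, 3.82),
        "xanthine_mmol_d": (1.80, 1.61, 1.74, 1.40),
        "hypoxanthine_mmol_d": (0.97, 0.83, 0.65, 0.50),
        "creatinine_mmol_d": (30.08, 25.63, 19.68, 32.56),
        "bun_mg_dl_0h": (11.94, 16.02, 19.34, 24.34),
        "bun_mg_dl_4h": (13.69, 19.02, 21.34, 26.83),
        "nh3n_mg_dl_0h": (10.39, 12.44, 16.14, 18.44),
        "nh3n_mg_dl_4h": (10.80, 16.37, 18.88, 22.12),
        "ruminal_ph_0h": (7.08, 7.05, 7.08, 6.98),
        "ruminal_ph_4h": (6.88, 6.75, 6.70, 6.75),
        "total_vfa_mm_0h": (82.55, 88.34, 86.84, 85.43),
        "total_vfa_mm_4h": (79.01, 81.56, 81.56, 85.00),
        "acetate_pct": (68.80, 69.09, 69.63, 68.75),
        "propionate_pct": (19.62, 19.35, 19.30, 20.36),
        "butyrate_pct": (11.57, 11.56, 11.07, 10.89),
        "mc_protozoa_1e5_ml": (7.81, 4.63, 6.56, 4.81),
        "mc_fungal_zoospores_1e7_ml": (1.72, 3.35, 4.14, 6.54),
        "mc_total_bacteria_1e9_ml": (1.33, 1.40, 1.39, 1.80),
    }


def default_group_sems() -> dict[str, float]:
    """Pooled SEMs of the treatment means (n = 4 animals per mean)."""
    return {
        "initial_bw_kg": 6.74,
        "adg_kg_d": 0.05,
        "dmi_kg_d": 0.16,
        "fecal_dm_kg_d": 0.12,
        "urine_l_d": 0.57,
        "fecal_n_g_d": 2.12,
        "urine_n_g_d": 2.17,
        "allantoin_mmol_d": 1.90,
        "uric_acid_mmol_d": 0.75,
        "xanthine_mmol_d": 0.22,
        "hypoxanthine_mmol_d": 0.16,
        "creatinine_mmol_d": 4.23,
        "bun_mg_dl_0h": 0.30,
        "bun_mg_dl_4h": 0.21,
        "nh3n_mg_dl_0h": 0.26,
        "nh3n_mg_dl_4h": 0.27,
        "ruminal_ph_0h": 0.04,
        "ruminal_ph_4h": 0.07,
        "total_vfa_mm_0h": 3.95,
        "total_vfa_mm_4h": 0.86,
        "acetate_pct": 0.56,
        "propionate_pct": 0.55,
        "butyrate_pct": 0.39,
        "mc_protozoa_1e5_ml": 2.10,
        "mc_fungal_zoospores_1e7_ml": 0.97,
        "mc_total_bacteria_1e9_ml": 0.18,
    }


def default_diets() -> list[DietComposition]:
    """The four experimental total-mixed-ration diets (g/kg DM)."""
    ingredients = {
        "rice_straw": (619.0, 631.0, 667.9, 655.0),
        "cassava_pulp": (148.8, 153.6, 140.2, 123.8),
        "ground_corn": (227.6, 178.1, 110.2, 108.1),
        "soybean_meal": (0.0, 31.0, 73.8, 104.4),
        "urea": (3.7, 5.5, 7.1, 7.9),
        "premix": (0.9, 0.8, 0.8, 0.8),
    }
    chem = {
        "dm_gkg_asfed": (873.7, 874.5, 874.9, 876.5),
        "om_gkg_dm": (893.5, 892.4, 884.6, 882.3),
        "cp_gkg_dm": (54.2, 66.4, 85.4, 104.5),
        "ndf_gkg_dm": (569.4, 551.6, 577.0, 570.2),
        "adf_gkg_dm": (367.3, 361.5, 384.3, 385.6),
        "hemicellulose_gkg_dm": (202.1, 190.1, 192.6, 184.6),
        "tdn_gkg_dm": (624.0, 622.0, 601.5, 598.2),
    }
    diets = []
    for j, cp in enumerate(CP_LEVELS):
        diets.append(
            DietComposition(
                treatment_label=f"CP{cp}",
                cp_level_pct_dm=cp,
                ingredients={k: v[j] for k, v in ingredients.items()},
                me_mcal_kg_dm=chem["tdn_gkg_dm"][j] / 1000.0 * 3.62,
                urea_gkg_dm=ingredients["urea"][j],
                **{k: v[j] for k, v in chem.items()},
            )
        )
    return diets


class SyntheticConfig(BaseModel):
    """Study conditions for the generator; defaults are the trial's own."""

    cp_levels: tuple[float, ...] = CP_LEVELS
    n_blocks: int = Field(default=4, ge=2)
    n_periods: int = Field(default=2, ge=1, le=2)
    days_per_period: float = Field(default=45.0, gt=0)
    group_means: dict[str, tuple[float, ...]] = Field(default_factory=default_group_means)
    group_sems: dict[str, float] = Field(default_factory=default_group_sems)
    n_per_mean: int = Field(default=4, ge=1)
    block_effect_sd_kg: float = Field(default=5.0, ge=0)
    appetite_correlation: float = Field(default=0.6, ge=0, le=1)
    period_sd_frac: float = Field(default=0.05, ge=0)
    feed_offered_ratio: float = Field(default=0.90, gt=0, le=1)
    allow_inconsistent: bool = False
    regression_truth: dict[str, float] = Field(
        default_factory=lambda: {"intercept": 0.8663, "slope": 0.0725, "target_r2": 0.577}
    )
    seed: int = 0

    @model_validator(mode="after")
    def _check_shapes(self) -> "SyntheticConfig":
        n_t = len(self.cp_levels)
        for name, means in self.group_means.items():
            if len(means) != n_t:
                raise ValueError(
                    f"group_means[{name!r}] has {len(means)} entries for {n_t} treatments"
                )
            if name not in self.group_sems:
                raise ValueError(f"group_sems missing entry for {name!r}")
            if self.group_sems[name] < 0:
                raise ValueError(f"group_sems[{name!r}] must be non-negative")
        r2 = self.regression_truth.get("target_r2", 0.5)
        if not 0 < r2 < 1:
            raise ValueError("target_r2 must be in (0, 1)")
        return self

    @classmethod
    def zero_variance(cls, **overrides) -> "SyntheticConfig":
        """Every animal exactly at its group mean (generator edge case)."""
        base = dict(
            group_sems={k: 0.0 for k in default_group_sems()},
            block_effect_sd_kg=0.0,
            period_sd_frac=0.0,
        )
        base.update(overrides)
        return cls(**base)


def _animal_sd(config: SyntheticConfig, var: str) -> float:
    return config.group_sems[var] * math.sqrt(config.n_per_mean)


def generate_trial(config: SyntheticConfig | None = None, seed: int | None = None) -> TrialDataset:
    """Draw one complete synthetic trial dataset.

    Animal-level values are drawn once per trait and perturbed per period
    with a small multiplicative-scale period effect, so period records of
    one animal are correlated the way repeated collections are.
    """
    cfg = config or SyntheticConfig()
    if seed is None:
        seed = cfg.seed
    rng = np.random.default_rng(seed)
    diets = default_diets()
    labels = [d.treatment_label for d in diets[: len(cfg.cp_levels)]]
    if len(labels) != len(cfg.cp_levels):
        raise ValueError("generator diets cover exactly the four default CP levels")

    means, sems = cfg.group_means, cfg.group_sems
    block_effects = rng.normal(0.0, cfg.block_effect_sd_kg, size=cfg.n_blocks)

    records: list[AnimalPeriodRecord] = []
    animal_no = 0
    for b in range(cfg.n_blocks):
        for j, label in enumerate(labels):
            animal_no += 1
            animal_id = f"A{animal_no:02d}"
            block_id = f"B{b + 1}"
            diet = diets[j]

            # shared appetite factor ties intake to gain within treatment
            z = rng.standard_normal()
            rho = cfg.appetite_correlation

            def draw(var: str, with_appetite: bool = False) -> float:
                sd = _animal_sd(cfg, var)
                if sd == 0:
                    return means[var][j]
                if with_appetite:
                    e = rng.standard_normal()
                    return means[var][j] + sd * (rho * z + math.sqrt(1 - rho**2) * e)
                return means[var][j] + sd * rng.standard_normal()

            bw0 = max(120.0, draw("initial_bw_kg") + block_effects[b])
            dmi_animal = max(0.5, draw("dmi_kg_d", with_appetite=True))
            adg_animal = draw("adg_kg_d", with_appetite=True)

            traits = {
                v: draw(v)
                for v in means
                if v not in ("initial_bw_kg", "dmi_kg_d", "adg_kg_d")
            }

            bw_start = bw0
            for period in range(1, cfg.n_periods + 1):
                pscale = 1.0 + cfg.period_sd_frac * rng.standard_normal()
                dmi = max(0.2, dmi_animal * pscale)
                adg = adg_animal + abs(adg_animal) * cfg.period_sd_frac * rng.standard_normal()
                bw_end = bw_start + adg * cfg.days_per_period

                def pos(var: str, floor: float = 0.01) -> float:
                    v = traits[var] * (1.0 + cfg.period_sd_frac * rng.standard_normal())
                    return max(floor, v)

                fecal_dm = pos("fecal_dm_kg_d")
                if not cfg.allow_inconsistent:
                    fecal_dm = min(fecal_dm, 0.95 * dmi)
                n_intake = dmi * diet.cp_gkg_dm / 6.25
                fecal_n = pos("fecal_n_g_d")
                urine_n = pos("urine_n_g_d")
                if cfg.allow_inconsistent:
                    # deliberately dirty data for validator tests
                    fecal_n *= 1.5
                    urine_n *= 1.5
                elif fecal_n + urine_n > n_intake:
                    shrink = 0.98 * n_intake / (fecal_n + urine_n)
                    fecal_n *= shrink
                    urine_n *= shrink

                vfa = {k: pos(k) for k in ("acetate_pct", "propionate_pct", "butyrate_pct")}
                vfa_sum = sum(vfa.values())
                if vfa_sum > 99.9:  # minor acids unreported; majors must fit in 100
                    vfa = {k: v * 99.9 / vfa_sum for k, v in vfa.items()}

                counts = {
                    k[len("mc_"):]: pos(k) for k in traits if k.startswith("mc_")
                }
                records.append(
                    AnimalPeriodRecord(
                        animal_id=animal_id,
                        block_id=block_id,
                        treatment_label=label,
                        period=period,
                        initial_bw_kg=bw_start,
                        final_bw_kg=max(100.0, bw_end),
                        days_on_feed=cfg.days_per_period,
                        dm_offered_kg_d=dmi / cfg.feed_offered_ratio,
                        dm_refused_kg_d=dmi / cfg.feed_offered_ratio - dmi,
                        fecal_dm_kg_d=fecal_dm,
                        urine_l_d=pos("urine_l_d"),
                        fecal_n_g_d=fecal_n,
                        urine_n_g_d=urine_n,
                        allantoin_mmol_d=pos("allantoin_mmol_d"),
                        uric_acid_mmol_d=pos("uric_acid_mmol_d"),
                        xanthine_mmol_d=pos("xanthine_mmol_d"),
                        hypoxanthine_mmol_d=pos("hypoxanthine_mmol_d"),
                        creatinine_mmol_d=pos("creatinine_mmol_d", floor=1.0),
                        bun_mg_dl_0h=pos("bun_mg_dl_0h"),
                        bun_mg_dl_4h=pos("bun_mg_dl_4h"),
                        nh3n_mg_dl_0h=pos("nh3n_mg_dl_0h"),
                        nh3n_mg_dl_4h=pos("nh3n_mg_dl_4h"),
                        ruminal_ph_0h=pos("ruminal_ph_0h", floor=5.0),
                        ruminal_ph_4h=pos("ruminal_ph_4h", floor=5.0),
                        total_vfa_mm_0h=pos("total_vfa_mm_0h"),
                        total_vfa_mm_4h=pos("total_vfa_mm_4h"),
                        acetate_pct=vfa["acetate_pct"],
                        propionate_pct=vfa["propionate_pct"],
                        butyrate_pct=vfa["butyrate_pct"],
                        microbial_counts=counts,
                    )
                )
                bw_start = max(100.0, bw_end)

    return TrialDataset(
        diets=diets,
        records=records,
        metadata={"generator": "proreq.simulate.generate_trial", "seed": int(seed)},
    )


# ---------------------------------------------------------------------------
# Requirement-point generator


def calibrate_noise_sd(slope: float, var_x: float, target_r2: float) -> float:
    """Noise SD giving population R^2 = s^2 Var(x) / (s^2 Var(x) + sigma^2).

    Closed form: sigma^2 = slope^2 * Var(x) * (1 - R^2) / R^2.
    """
    if not 0 < target_r2 < 1:
        raise ValueError("target R^2 must be in (0, 1)")
    if var_x <= 0:
        raise ValueError("Var(x) must be positive")
    return abs(slope) * math.sqrt(var_x * (1 - target_r2) / target_r2)


def generate_requirement_points(
    n: int = 16,
    intercept: float = 0.8663,
    slope: float = 0.0725,
    noise_sd: float | None = None,
    target_r2: float = 0.577,
    adg_values: Sequence[float] = GROUP_ADG_PER_W075,
    jitter_sd: float = 1.6,
    seed: int | None = None,
) -> list[RequirementPoint]:
    """Draw (ADG, N intake) points from the linear requirement model.

    x locations cycle through the group-level ADG values (g/kg W^0.75/d)
    with Gaussian within-group jitter; y = intercept + slope*x + noise.
    When ``noise_sd`` is None it is calibrated in closed form so the
    population R^2 equals ``target_r2`` (the x variance used is the
    population variance of the group values plus the jitter variance).
    Negative N-intake draws are truncated at zero, which cannot occur in
    practice at these parameter values.
    """
    if n < 3:
        raise ValueError("need at least 3 points")
    if jitter_sd < 0:
        raise ValueError("jitter SD must be non-negative")
    rng = np.random.default_rng(seed)
    groups = np.asarray(adg_values, dtype=float)
    if noise_sd is None:
        var_x = float(groups.var()) + jitter_sd**2
        noise_sd = calibrate_noise_sd(slope, var_x, target_r2)
    elif noise_sd < 0:
        raise ValueError("noise SD must be non-negative")
    x = groups[np.arange(n) % len(groups)] + rng.normal(0.0, jitter_sd, size=n)
    y = intercept + slope * x + rng.normal(0.0, noise_sd, size=n)
    y = np.maximum(y, 0.0)
    return [
        RequirementPoint(float(xi), float(yi), f"S{i + 1:02d}")
        for i, (xi, yi) in enumerate(zip(x, y))
    ]


def requirement_recovery_experiment(
    n_replicates: int = 200,
    n_points: int = 16,
    intercept: float = 0.8663,
    slope: float = 0.0725,
    target_r2: float = 0.577,
    seed: int = 0,
) -> dict[str, float]:
    """Monte-Carlo parameter-recovery experiment for the requirement fit.

    Generates ``n_replicates`` independent trials of ``n_points``
    regression points from the linear requirement model with the given
    truth and R^2-calibrated noise, fits each by OLS, and reports the
    means of the fitted intercept, slope and R^2 together with their
    Monte-Carlo standard errors.  A single seeded generator drives the
    whole experiment, so results are reproducible for a fixed seed.
    """
    from .requirement import ProteinRequirementModel

    if n_replicates < 2:
        raise ValueError("need at least 2 replicates")
    rng = np.random.default_rng(seed)
    rep_seeds = rng.integers(0, 2**31 - 1, size=n_replicates)
    intercepts = np.empty(n_replicates)
    slopes = np.empty(n_replicates)
    r2s = np.empty(n_replicates)
    for i, s in enumerate(rep_seeds):
        pts = generate_requirement_points(
            n=n_points, intercept=intercept, slope=slope,
            target_r2=target_r2, seed=int(s),
        )
        fit = ProteinRequirementModel.from_points(pts).fit()
        intercepts[i] = fit.intercept
        slopes[i] = fit.slope
        r2s[i] = fit.r_squared
    root_n = math.sqrt(n_replicates)
    return {
        "n_replicates": n_replicates,
        "n_points": n_points,
        "true_intercept": intercept,
        "true_slope": slope,
        "target_r2": target_r2,
        "mean_intercept": float(intercepts.mean()),
        "mean_slope": float(slopes.mean()),
        "mean_r2": float(r2s.mean()),
        "mcse_intercept": float(intercepts.std(ddof=1) / root_n),
        "mcse_slope": float(slopes.std(ddof=1) / root_n),
        "mcse_r2": float(r2s.std(ddof=1) / root_n),
    }
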