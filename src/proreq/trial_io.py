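"""Data model and delimited-text I/O for feeding-trial datasets.

A trial dataset is two CSV tables plus free-form metadata:

* ``diets.csv`` — one row per dietary treatment: ingredient inclusion
  (``ing_<name>`` columns, g/kg DM) and chemical composition (g/kg DM,
  ME in Mcal/kg DM).
* ``records.csv`` — one row per animal x collection period, carrying
  body weights, intakes, excreta, nitrogen, urinary purine derivatives,
  creatinine, blood/rumen metabolites and optional microbial counts
  (``mc_<group>`` columns).

Units are fixed per column (encoded in the column names) and never
auto-detected: silent unit drift is the main hazard in nutrition data.
Daily collections are assumed pre-averaged to the period level, which is
how composited samples are analysed in practice.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd
import yaml
from pydantic import BaseModel, Field, field_validator, model_validator

__all__ = [
    "DietComposition",
    "AnimalPeriodRecord",
    "TrialDataset",
    "RunConfig",
    "Finding",
    "SchemaError",
    "load_config",
    "read_trial",
    "write_trial",
    "validate_dataset",
    "write_report",
]


class SchemaError(ValueError):
    """Raised when a CSV does not match the documented trial schema."""


class RunConfig(BaseModel):
    """Run-wide constants and conventions for the analysis pipeline.

    The purine-excretion coefficients invert the linear model
    ``PD = recovery_slope * PB + endogenous_pd_coeff * W^0.75``.
    Defaults are the swamp-buffalo convention (0.12, 0.20); the cattle
    convention (0.85, 0.385) is available via
    :meth:`RunConfig.cattle_purine_convention`.
    """

    cp_conversion_factor: float = Field(default=6.25, gt=0)
    tdn_to_me_mcal_per_kg: float = Field(default=3.62, gt=0)
    purine_n_mg_per_mmol: float = Field(default=70.0, gt=0)
    purine_n_ratio: float = Field(default=0.116, gt=0)
    purine_digestibility: float = Field(default=0.83, gt=0, le=1)
    purine_recovery_slope: float = Field(default=0.12, gt=0, le=1)
    endogenous_pd_coeff: float = Field(default=0.20, ge=0)
    domr_fraction: float = Field(default=0.65, gt=0, le=1)
    alpha: float = Field(default=0.05, gt=0, lt=1)
    seed: int = 0

    @classmethod
    def cattle_purine_convention(cls, **overrides) -> "RunConfig":
        """Config with the cattle purine-excretion coefficients (0.85, 0.385)."""
        base = dict(purine_recovery_slope=0.85, endogenous_pd_coeff=0.385)
        base.update(overrides)
        return cls(**base)


def load_config(path: str | Path) -> RunConfig:
    """Load a :class:`RunConfig` from a YAML or JSON file."""
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    return RunConfig(**(data or {}))


class DietComposition(BaseModel):
    """Per-treatment ingredient and chemical composition (g/kg DM)."""

    treatment_label: str
    cp_level_pct_dm: float = Field(gt=0)
    ingredients: dict[str, float] = Field(default_factory=dict)
    dm_gkg_asfed: float = Field(ge=0)
    om_gkg_dm: float = Field(ge=0)
    cp_gkg_dm: float = Field(ge=0)
    ndf_gkg_dm: float = Field(ge=0)
    adf_gkg_dm: float = Field(ge=0)
    hemicellulose_gkg_dm: float = Field(ge=0)
    tdn_gkg_dm: float = Field(ge=0)
    me_mcal_kg_dm: float = Field(ge=0)
    urea_gkg_dm: float = Field(default=0.0, ge=0)

    #: tolerance for the ingredient-sum invariant, g/kg DM
    ingredient_sum_tol: float = Field(default=2.0, ge=0)

    @model_validator(mode="after")
    def _check_invariants(self) -> "DietComposition":
        if self.ndf_gkg_dm < self.adf_gkg_dm:
            raise ValueError(
                f"{self.treatment_label}: NDF ({self.ndf_gkg_dm}) < ADF ({self.adf_gkg_dm})"
            )
        hemi = self.ndf_gkg_dm - self.adf_gkg_dm
        if abs(hemi - self.hemicellulose_gkg_dm) > 0.1:
            raise ValueError(
                f"{self.treatment_label}: hemicellulose {self.hemicellulose_gkg_dm} "
                f"!= NDF - ADF = {hemi:.1f} (tolerance 0.1 g/kg)"
            )
        if self.ingredients:
            total = sum(self.ingredients.values())
            if abs(total - 1000.0) > self.ingredient_sum_tol:
                raise ValueError(
                    f"{self.treatment_label}: ingredients sum to {total:.1f} g/kg DM, "
                    f"expected 1000 +/- {self.ingredient_sum_tol}"
                )
        if any(v < 0 for v in self.ingredients.values()):
            raise ValueError(f"{self.treatment_label}: negative ingredient proportion")
        return self


class AnimalPeriodRecord(BaseModel):
    """One animal x period measurement bundle; the atomic input row."""

    animal_id: str
    block_id: str
    treatment_label: str
    period: int
    initial_bw_kg: float = Field(gt=0)
    final_bw_kg: float = Field(gt=0)
    days_on_feed: float = Field(gt=0)
    dm_offered_kg_d: float = Field(ge=0)
    dm_refused_kg_d: float = Field(ge=0)
    fecal_dm_kg_d: float = Field(ge=0)
    urine_l_d: float = Field(ge=0)
    fecal_n_g_d: float = Field(ge=0)
    urine_n_g_d: float = Field(ge=0)
    allantoin_mmol_d: float = Field(ge=0)
    uric_acid_mmol_d: float = Field(ge=0)
    xanthine_mmol_d: float = Field(ge=0)
    hypoxanthine_mmol_d: float = Field(ge=0)
    creatinine_mmol_d: float = Field(gt=0)
    bun_mg_dl_0h: Optional[float] = None
    bun_mg_dl_4h: Optional[float] = None
    nh3n_mg_dl_0h: Optional[float] = None
    nh3n_mg_dl_4h: Optional[float] = None
    ruminal_ph_0h: Optional[float] = None
    ruminal_ph_4h: Optional[float] = None
    total_vfa_mm_0h: Optional[float] = None
    total_vfa_mm_4h: Optional[float] = None
    acetate_pct: Optional[float] = None
    propionate_pct: Optional[float] = None
    butyrate_pct: Optional[float] = None
    microbial_counts: dict[str, float] = Field(default_factory=dict)

    @field_validator("period")
    @classmethod
    def _period_in_range(cls, v: int) -> int:
        if v not in (1, 2):
            raise ValueError(f"period must be 1 or 2, got {v}")
        return v

    @model_validator(mode="after")
    def _check_invariants(self) -> "AnimalPeriodRecord":
        if self.dm_refused_kg_d > self.dm_offered_kg_d:
            raise ValueError(
                f"{self.animal_id} period {self.period}: refused DM "
                f"({self.dm_refused_kg_d}) exceeds offered ({self.dm_offered_kg_d})"
            )
        vfa = (self.acetate_pct, self.propionate_pct, self.butyrate_pct)
        if all(v is not None for v in vfa) and sum(vfa) > 100.0 + 1e-9:
            raise ValueError(
                f"{self.animal_id} period {self.period}: VFA molar percentages "
                f"sum to {sum(vfa):.1f} > 100"
            )
        return self

    @property
    def dm_intake_kg_d(self) -> float:
        return self.dm_offered_kg_d - self.dm_refused_kg_d

    @property
    def average_bw_kg(self) -> float:
        return 0.5 * (self.initial_bw_kg + self.final_bw_kg)


class TrialDataset(BaseModel):
    """A full trial: diet table, animal-period records, metadata."""

    diets: list[DietComposition]
    records: list[AnimalPeriodRecord]
    metadata: dict = Field(default_factory=dict)

    @model_validator(mode="after")
    def _check_references(self) -> "TrialDataset":
        labels = {d.treatment_label for d in self.diets}
        for r in self.records:
            if r.treatment_label not in labels:
                raise ValueError(
                    f"record {r.animal_id} period {r.period} references unknown "
                    f"treatment {r.treatment_label!r}"
                )
        return self

    def diet_for(self, treatment_label: str) -> DietComposition:
        for d in self.diets:
            if d.treatment_label == treatment_label:
                return d
        raise KeyError(treatment_label)

    def design_counts(self) -> pd.DataFrame:
        """Animals per treatment x block (period-collapsed) — balance report."""
        rows = [
            {"treatment": r.treatment_label, "block": r.block_id, "animal": r.animal_id}
            for r in self.records
        ]
        df = pd.DataFrame(rows).drop_duplicates()
        return df.pivot_table(
            index="block", columns="treatment", values="animal", aggfunc="count", fill_value=0
        )


# ---------------------------------------------------------------------------
# CSV schemas

_RECORD_COLUMNS = [
    "animal_id", "block_id", "treatment_label", "period",
    "initial_bw_kg", "final_bw_kg", "days_on_feed",
    "dm_offered_kg_d", "dm_refused_kg_d", "fecal_dm_kg_d", "urine_l_d",
    "fecal_n_g_d", "urine_n_g_d",
    "allantoin_mmol_d", "uric_acid_mmol_d", "xanthine_mmol_d",
    "hypoxanthine_mmol_d", "creatinine_mmol_d",
]
_RECORD_OPTIONAL = [
    "bun_mg_dl_0h", "bun_mg_dl_4h", "nh3n_mg_dl_0h", "nh3n_mg_dl_4h",
    "ruminal_ph_0h", "ruminal_ph_4h", "total_vfa_mm_0h", "total_vfa_mm_4h",
    "acetate_pct", "propionate_pct", "butyrate_pct",
]
_DIET_COLUMNS = [
    "treatment_label", "cp_level_pct_dm", "dm_gkg_asfed", "om_gkg_dm",
    "cp_gkg_dm", "ndf_gkg_dm", "adf_gkg_dm", "hemicellulose_gkg_dm",
    "tdn_gkg_dm", "me_mcal_kg_dm", "urea_gkg_dm",
]
_STR_COLUMNS = {"animal_id", "block_id", "treatment_label"}


def _records_to_frame(records: Iterable[AnimalPeriodRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        d = r.model_dump(exclude={"microbial_counts"})
        for k, v in r.microbial_counts.items():
            d[f"mc_{k}"] = v
        rows.append(d)
    return pd.DataFrame(rows)


def _diets_to_frame(diets: Iterable[DietComposition]) -> pd.DataFrame:
    rows = []
    for d in diets:
        row = d.model_dump(exclude={"ingredients", "ingredient_sum_tol"})
        for k, v in d.ingredients.items():
            row[f"ing_{k}"] = v
        rows.append(row)
    return pd.DataFrame(rows)


def write_trial(dataset: TrialDataset, out_dir: str | Path) -> dict[str, Path]:
    """Write a dataset as ``records.csv``, ``diets.csv`` and ``metadata.json``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "records": out / "records.csv",
        "diets": out / "diets.csv",
        "metadata": out / "metadata.json",
    }
    _records_to_frame(dataset.records).to_csv(paths["records"], index=False)
    _diets_to_frame(dataset.diets).to_csv(paths["diets"], index=False)
    paths["metadata"].write_text(json.dumps(dataset.metadata, indent=1, sort_keys=True))
    return paths


def _parse_numeric(df: pd.DataFrame, columns: Iterable[str], what: str) -> None:
    for col in columns:
        if col not in df.columns or col in _STR_COLUMNS:
            continue
        parsed = pd.to_numeric(df[col], errors="coerce")
        bad = parsed.isna() & df[col].notna()
        if bad.any():
            idx = int(bad.idxmax())
            raise SchemaError(
                f"{what}: non-numeric value {df[col][idx]!r} in column "
                f"{col!r} at row {idx}"
            )
        df[col] = parsed


def read_trial(
    records_csv: str | Path,
    diets_csv: str | Path,
    config: RunConfig | None = None,
    metadata_json: str | Path | None = None,
) -> TrialDataset:
    """Read and validate a trial dataset from its delimited-text tables.

    Extra (undocumented) columns are preserved under
    ``metadata['extra_columns']`` rather than dropped.
    """
    rec_df = pd.read_csv(records_csv, dtype={c: str for c in _STR_COLUMNS})
    missing = [c for c in _RECORD_COLUMNS if c not in rec_df.columns]
    if missing:
        raise SchemaError(f"records CSV is missing mandatory column(s): {missing}")
    _parse_numeric(rec_df, list(rec_df.columns), "records CSV")

    diet_df = pd.read_csv(diets_csv, dtype={"treatment_label": str})
    missing = [c for c in _DIET_COLUMNS if c not in diet_df.columns]
    if missing:
        raise SchemaError(f"diets CSV is missing mandatory column(s): {missing}")
    _parse_numeric(diet_df, list(diet_df.columns), "diets CSV")

    diets = []
    for _, row in diet_df.iterrows():
        ingredients = {
            c[len("ing_"):]: float(row[c])
            for c in diet_df.columns
            if c.startswith("ing_") and pd.notna(row[c])
        }
        diets.append(
            DietComposition(
                ingredients=ingredients,
                **{c: row[c] for c in _DIET_COLUMNS},
            )
        )

    known = set(_RECORD_COLUMNS) | set(_RECORD_OPTIONAL)
    extra_cols = [
        c for c in rec_df.columns if c not in known and not c.startswith("mc_")
    ]
    records = []
    for _, row in rec_df.iterrows():
        counts = {
            c[len("mc_"):]: float(row[c])
            for c in rec_df.columns
            if c.startswith("mc_") and pd.notna(row[c])
        }
        kwargs = {c: row[c] for c in _RECORD_COLUMNS}
        for c in _RECORD_OPTIONAL:
            if c in rec_df.columns and pd.notna(row[c]):
                kwargs[c] = row[c]
        kwargs["period"] = int(row["period"])
        records.append(AnimalPeriodRecord(microbial_counts=counts, **kwargs))

    metadata: dict = {}
    if metadata_json is not None and Path(metadata_json).exists():
        metadata = json.loads(Path(metadata_json).read_text())
    if extra_cols:
        metadata["extra_columns"] = {
            c: rec_df[c].tolist() for c in extra_cols
        }
    return TrialDataset(diets=diets, records=records, metadata=metadata)


def read_trial_dir(trial_dir: str | Path, config: RunConfig | None = None) -> TrialDataset:
    """Read a dataset laid out as by :func:`write_trial`."""
    trial_dir = Path(trial_dir)
    return read_trial(
        trial_dir / "records.csv",
        trial_dir / "diets.csv",
        config,
        metadata_json=trial_dir / "metadata.json",
    )


# ---------------------------------------------------------------------------
# Validation findings (non-throwing checks beyond hard type invariants)


class Finding(BaseModel):
    severity: str  # "error" | "warning" | "info"
    locator: str
    message: str


def validate_dataset(ds: TrialDataset) -> list[Finding]:
    """Non-mutating consistency checks; returns machine-readable findings."""
    findings: list[Finding] = []
    for r in ds.records:
        loc = f"{r.animal_id}/p{r.period}"
        diet = ds.diet_for(r.treatment_label)
        n_intake = r.dm_intake_kg_d * diet.cp_gkg_dm / 6.25
        if r.fecal_n_g_d + r.urine_n_g_d > n_intake + 1e-9 and n_intake > 0:
            findings.append(
                Finding(
                    severity="warning",
                    locator=loc,
                    message=(
                        f"N excretion ({r.fecal_n_g_d + r.urine_n_g_d:.2f} g/d) exceeds "
                        f"diet-derived N intake ({n_intake:.2f} g/d): negative retention"
                    ),
                )
            )
        if r.dm_intake_kg_d <= 0:
            findings.append(
                Finding(severity="error", locator=loc, message="zero or negative DM intake")
            )
        if r.fecal_dm_kg_d > r.dm_intake_kg_d:
            findings.append(
                Finding(
                    severity="error",
                    locator=loc,
                    message="fecal DM output exceeds DM intake (digestibility < 0)",
                )
            )
    counts = ds.design_counts()
    if counts.size and counts.to_numpy().std() > 0:
        findings.append(
            Finding(
                severity="warning",
                locator="design",
                message=f"unbalanced design: counts per block x treatment vary\n{counts}",
            )
        )
    return findings


# ---------------------------------------------------------------------------
# Report writer


def write_report(tables: dict[str, pd.DataFrame], out_dir: str | Path) -> list[Path]:
    """Write analysis tables as deterministic CSVs, one file per block.

    Each table mirrors the conventional layout of treatment-comparison
    tables: one row per response, per-treatment means with letter
    superscripts, pooled SEM, and linear/quadratic contrast p-values.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    for name, table in tables.items():
        path = out / f"{name}.csv"
        table.to_csv(path, index=False, float_format="%.6g")
        written.append(path)
    return written
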