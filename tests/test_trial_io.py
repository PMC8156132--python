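"""Trial I/O: schema validation, round-trips, report determinism."""

import json

import pandas as pd
import pytest
from pydantic import ValidationError

from proreq.pipeline import analyze_trial
from proreq.simulate import SyntheticConfig, generate_trial
from proreq.trial_io import (
    RunConfig,
    SchemaError,
    load_config,
    read_trial,
    read_trial_dir,
    validate_dataset,
    write_report,
    write_trial,
)


class TestRoundTrip:
    @pytest.mark.parametrize("seed", [0, 1, 99])
    def test_write_read_lossless(self, tmp_path, seed):
        ds = generate_trial(SyntheticConfig(seed=seed))
        write_trial(ds, tmp_path)
        back = read_trial_dir(tmp_path)
        assert len(back.records) == len(ds.records)
        for a, b in zip(ds.records, back.records):
            da, db = a.model_dump(), b.model_dump()
            for key in da:
                if isinstance(da[key], float):
                    assert db[key] == pytest.approx(da[key], rel=1e-12), key
                elif isinstance(da[key], dict):
                    assert set(da[key]) == set(db[key])
                    for k in da[key]:
                        assert db[key][k] == pytest.approx(da[key][k], rel=1e-12)
                else:
                    assert da[key] == db[key], key
        for a, b in zip(ds.diets, back.diets):
            assert a.treatment_label == b.treatment_label
            assert b.cp_gkg_dm == pytest.approx(a.cp_gkg_dm)
            assert set(b.ingredients) == set(a.ingredients)
        assert back.metadata["seed"] == ds.metadata["seed"]

    def test_structure(self, trial):
        assert len(trial.records) == 32  # 16 animals x 2 periods
        counts = trial.design_counts()
        assert (counts.to_numpy() == 1).all()


class TestSchemaErrors:
    def test_missing_column_named(self, tmp_path):
        ds = generate_trial(SyntheticConfig(seed=0))
        paths = write_trial(ds, tmp_path)
        df = pd.read_csv(paths["records"]).drop(columns=["urine_l_d"])
        df.to_csv(paths["records"], index=False)
        with pytest.raises(SchemaError, match="urine_l_d"):
            read_trial_dir(tmp_path)

    def test_non_numeric_cell_reported_with_row(self, tmp_path):
        ds = generate_trial(SyntheticConfig(seed=0))
        paths = write_trial(ds, tmp_path)
        df = pd.read_csv(paths["records"])
        df["urine_l_d"] = df["urine_l_d"].astype(object)
        df.loc[3, "urine_l_d"] = "oops"
        df.to_csv(paths["records"], index=False)
        with pytest.raises(SchemaError, match="row 3"):
            read_trial_dir(tmp_path)

    def test_unknown_treatment_rejected(self, tmp_path):
        ds = generate_trial(SyntheticConfig(seed=0))
        paths = write_trial(ds, tmp_path)
        df = pd.read_csv(paths["records"])
        df.loc[0, "treatment_label"] = "CP99"
        df.to_csv(paths["records"], index=False)
        with pytest.raises(ValidationError, match="CP99"):
            read_trial_dir(tmp_path)

    def test_refusal_exceeding_offer_names_animal(self, tmp_path):
        ds = generate_trial(SyntheticConfig(seed=0))
        paths = write_trial(ds, tmp_path)
        df = pd.read_csv(paths["records"])
        df.loc[0, "dm_refused_kg_d"] = df.loc[0, "dm_offered_kg_d"] + 1
        df.to_csv(paths["records"], index=False)
        with pytest.raises(ValidationError, match=str(df.loc[0, "animal_id"])):
            read_trial_dir(tmp_path)

    def test_extra_columns_preserved_as_metadata(self, tmp_path):
        ds = generate_trial(SyntheticConfig(seed=0))
        paths = write_trial(ds, tmp_path)
        df = pd.read_csv(paths["records"])
        df["barn_temp_c"] = 25.0
        df.to_csv(paths["records"], index=False)
        back = read_trial_dir(tmp_path)
        assert "barn_temp_c" in back.metadata["extra_columns"]


class TestValidation:
    def test_clean_dataset_no_findings(self, trial):
        assert validate_dataset(trial) == []

    def test_validation_is_pure_and_idempotent(self, trial):
        before = [r.model_dump() for r in trial.records]
        f1 = validate_dataset(trial)
        f2 = validate_dataset(trial)
        assert f1 == f2
        assert [r.model_dump() for r in trial.records] == before

    def test_inconsistent_nitrogen_flagged(self):
        ds = generate_trial(SyntheticConfig(seed=0, allow_inconsistent=True))
        findings = validate_dataset(ds)
        assert any("retention" in f.message for f in findings)

    def test_unbalanced_design_warned(self, trial):
        ds = trial.model_copy(update={"records": trial.records[:-2]})
        findings = validate_dataset(ds)
        assert any(f.locator == "design" for f in findings)


class TestConfig:
    def test_yaml_and_json_equivalent(self, tmp_path):
        (tmp_path / "c.yaml").write_text("alpha: 0.01\nseed: 3\n")
        (tmp_path / "c.json").write_text(json.dumps({"alpha": 0.01, "seed": 3}))
        assert load_config(tmp_path / "c.yaml") == load_config(tmp_path / "c.json")

    def test_cattle_convention(self):
        cfg = RunConfig.cattle_purine_convention()
        assert cfg.purine_recovery_slope == 0.85
        assert cfg.endogenous_pd_coeff == 0.385

    def test_invalid_alpha_rejected(self):
        with pytest.raises(ValidationError):
            RunConfig(alpha=1.5)


class TestReport:
    def test_empty_results_give_headers_only(self, tmp_path):
        table = pd.DataFrame(columns=["item", "mean_CP5.4", "sem"])
        (path,) = write_report({"empty": table}, tmp_path)
        assert path.read_text().startswith("item,")

    def test_table_shape(self, trial, tmp_path):
        analysis = analyze_trial(trial)
        nb = analysis.tables["nitrogen_balance"]
        mean_cols = [c for c in nb.columns if c.startswith("mean_")]
        assert len(mean_cols) == 4
        assert {"sem", "p_linear", "p_quadratic"} <= set(nb.columns)

    def test_report_regeneration_byte_identical(self, trial, tmp_path):
        analysis = analyze_trial(trial)
        p1 = write_report(analysis.tables, tmp_path / "r1")
        p2 = write_report(analyze_trial(trial).tables, tmp_path / "r2")
        for a, b in zip(p1, p2):
            assert a.read_bytes() == b.read_bytes()
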