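"""Synthetic-database generator: structure, envelope, and ground truth."""

import numpy as np
import pytest

from odtpredict import ContractError
from odtpredict.synthetic import (
    EXCIPIENTS,
    GeneratorConfig,
    generate_dataset,
    generate_descriptor_table,
    generate_formulations,
)

ENVELOPE = {
    "Tablet mass [mg]": (67.13, 1179.98),
    "Thickness [mm]": (1.86, 6.5),
    "Punch die of tablet press [mm]": (5.5, 16.0),
    "Hardness [N]": (2.4, 155.43),
}


class TestFormulations:
    def test_same_seed_reproduces_table_exactly(self):
        cfg = GeneratorConfig(n=50, seed=9)
        t1, g1 = generate_formulations(cfg)
        t2, g2 = generate_formulations(cfg)
        assert t1.data.equals(t2.data)
        assert np.array_equal(g1.noiseless_target, g2.noiseless_target)

    def test_zero_records_rejected(self):
        with pytest.raises(ContractError):
            generate_formulations(GeneratorConfig(n=0))

    def test_inputs_respect_database_envelope(self):
        table, _ = generate_formulations(GeneratorConfig(n=250, seed=0))
        for col, (lo, hi) in ENVELOPE.items():
            v = table.data[col].to_numpy()
            assert v.min() >= lo - 1e-9 and v.max() <= hi + 1e-9, col
        for name, (_, max_pct) in EXCIPIENTS.items():
            v = table.data[name].to_numpy()
            assert v.min() >= 0.0 and v.max() <= max_pct + 1e-9, name

    def test_composition_is_zero_inflated_and_right_skewed(self):
        table, _ = generate_formulations(GeneratorConfig(n=400, seed=1))
        mannitol_occ = (table.data["Mannitol [%]"] > 0).mean()
        camphor_occ = (table.data["Camphor [%]"] > 0).mean()
        assert mannitol_occ > 0.6 > camphor_occ  # common filler vs rare porophore
        cc = table.data["CC-Na [%]"]
        present = cc[cc > 0]
        assert present.mean() > present.median()  # right skew

    def test_mass_punch_die_positive_correlation(self):
        table, _ = generate_formulations(GeneratorConfig(n=300, seed=2))
        r = np.corrcoef(table.data["Tablet mass [mg]"],
                        table.data["Punch die of tablet press [mm]"])[0, 1]
        assert r >= 0.6

    def test_tail_beyond_180s_exists_for_filter_exercise(self):
        fracs = [(generate_formulations(GeneratorConfig(n=250, seed=s))[0].y > 180).mean()
                 for s in range(5)]
        assert 0.005 <= float(np.mean(fracs)) <= 0.12

    def test_ols_on_noiseless_design_recovers_coefficients(self):
        cfg = GeneratorConfig(n=200, seed=3, noise_sd=0.0)
        table, truth = generate_formulations(cfg)
        lip = np.array([truth.api_lipophilicity[a] for a in table.data["API name"]])
        dis = sum(table.data[c].to_numpy() for c in truth.coefficients)
        design = np.column_stack(
            [table.data[c].to_numpy() for c in truth.coefficients]
            + [np.maximum(0.0, table.data["Hardness [N]"].to_numpy() - truth.hardness_hinge),
               lip, lip * dis, np.ones(table.n)]
        )
        beta, *_ = np.linalg.lstsq(design, truth.noiseless_target, rcond=None)
        expected = list(truth.coefficients.values()) + [
            truth.beta_hardness, truth.beta_lipophilicity,
            truth.beta_interaction, truth.intercept]
        assert np.allclose(beta, expected, atol=1e-6)


class TestDescriptors:
    def test_shape_and_single_constant_column(self):
        desc, informative = generate_descriptor_table(26, 50, 3, seed=0)
        assert desc.shape == (26, 51)  # 50 descriptors + key
        const_cols = [c for c in desc.columns if c != "API name"
                      and desc[c].nunique() == 1]
        assert const_cols == ["D_const"]
        assert set(informative) <= set(desc.columns)

    def test_informative_descriptors_track_lipophilicity(self):
        desc, informative = generate_descriptor_table(26, 50, 3, seed=1)
        x = desc["XLogP"].to_numpy()
        for name in informative:
            r = np.corrcoef(x, desc[name])[0, 1]
            assert abs(r) >= 0.7, name

    def test_lipophilicity_consistent_with_formulation_generator(self):
        cfg = GeneratorConfig(n=30, seed=6)
        table, truth = generate_formulations(cfg)
        desc, _ = generate_descriptor_table(cfg.n_apis, cfg.n_descriptors,
                                            cfg.n_informative_descriptors, seed=cfg.seed)
        mapping = dict(zip(desc["API name"], desc["XLogP"]))
        assert mapping == pytest.approx(truth.api_lipophilicity)

    def test_too_few_descriptor_slots_rejected(self):
        with pytest.raises(ContractError):
            generate_descriptor_table(10, 3, 3, seed=0)


class TestDataset:
    def test_enriched_table_has_geometry_and_descriptor_columns(self, small_dataset):
        table, truth, desc = small_dataset
        assert "Surface area to volume ratio [mm]" in table.data.columns
        assert "XLogP" in table.data.columns
        assert table.categories["XLogP"] == "descriptor"
        assert table.n == 100

    def test_ground_truth_names_exist_after_enrichment(self, small_dataset):
        table, truth, _ = small_dataset
        for name in truth.informative_features:
            assert name in table.data.columns, name
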