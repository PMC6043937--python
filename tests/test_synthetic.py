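import numpy as np
import pytest
from scipy import stats

from paom import (
    ConfigurationError,
    generate,
    generate_prediction_sets,
    objective_l1,
)
from paom.synthetic import true_edges, write_dataset


class TestGenerate:
    def test_noiseless_systems_are_exactly_consistent(self):
        ds = generate(n=6, m=6, k_normal=4, k_cancer=5, noise_sd=0.0, seed=3)
        assert objective_l1(ds.A_normal, ds.X_normal, ds.Y_normal) == 0.0
        assert objective_l1(ds.A_cancer, ds.X_cancer, ds.Y_cancer) == 0.0

    def test_no_changes_means_identical_conditions(self):
        ds = generate(n=5, m=5, change_fraction=0.0, seed=4)
        assert ds.changed_edges == frozenset()
        np.testing.assert_array_equal(ds.A_normal.values, ds.A_cancer.values)

    def test_default_panel_dimensions(self):
        ds = generate(seed=1)
        assert ds.A_normal.shape == (26, 26)
        assert ds.A_normal.values.size == 676
        assert ds.X_normal.n_samples == 4
        assert ds.X_cancer.n_samples == 7

    def test_inhibitory_only_coefficients(self):
        ds = generate(n=10, m=10, edge_density=0.3, seed=5)
        nonzero = ds.A_normal.values[ds.A_normal.values != 0]
        assert (nonzero < 0).all()
        assert (nonzero >= -2.0).all() and (nonzero <= -0.2).all()

    def test_mixed_sign_mode(self):
        ds = generate(n=10, m=10, edge_density=0.3, sign_mode="mixed", seed=5)
        nonzero = ds.A_normal.values[ds.A_normal.values != 0]
        assert (nonzero > 0).any() and (nonzero < 0).any()

    def test_changed_edges_match_matrix_difference(self):
        ds = generate(n=8, m=8, edge_density=0.3, change_fraction=0.5, seed=6)
        diff = {
            (ds.mrna_ids[i], ds.mirna_ids[j])
            for i, j in np.argwhere(ds.A_normal.values != ds.A_cancer.values)
        }
        assert set(ds.changed_edges) == diff
        assert len(ds.changed_edges) > 0

    def test_zero_change_mode_removes_edges(self):
        ds = generate(n=8, m=8, edge_density=0.3, change_fraction=0.5,
                      change_mode="zero", seed=6)
        for mrna, mirna in ds.changed_edges:
            i, j = ds.mrna_ids.index(mrna), ds.mirna_ids.index(mirna)
            assert ds.A_cancer.values[i, j] == 0.0
            assert ds.A_normal.values[i, j] != 0.0

    def test_bit_identical_from_seed(self):
        a, b = generate(seed=11), generate(seed=11)
        np.testing.assert_array_equal(a.X_normal.values, b.X_normal.values)
        np.testing.assert_array_equal(a.Y_cancer.values, b.Y_cancer.values)
        np.testing.assert_array_equal(a.A_cancer.values, b.A_cancer.values)
        assert a.changed_edges == b.changed_edges
        c = generate(seed=12)
        assert not np.array_equal(a.X_normal.values, c.X_normal.values)

    def test_noise_perturbs_only_mrna_panels(self):
        clean = generate(n=5, m=5, noise_sd=0.0, seed=8)
        noisy = generate(n=5, m=5, noise_sd=0.5, seed=8)
        np.testing.assert_array_equal(clean.X_normal.values, noisy.X_normal.values)
        assert not np.array_equal(clean.Y_normal.values, noisy.Y_normal.values)

    def test_impossible_sparsity_rejected(self):
        with pytest.raises(ConfigurationError):
            generate(n=2, m=2, edge_density=0.01, change_fraction=0.5, seed=1)


class TestGeneratePredictionSets:
    def test_perfect_predictions_equal_true_edges(self):
        ds = generate(n=6, m=6, edge_density=0.3, seed=9)
        sets = generate_prediction_sets(ds, 1.0, 0.0, seed=1)
        assert len(sets) == 2
        for pset in sets:
            assert pset.pairs == true_edges(ds)

    def test_zero_rates_give_empty_sets(self):
        ds = generate(n=6, m=6, seed=9)
        for pset in generate_prediction_sets(ds, 0.0, 0.0, seed=1):
            assert len(pset) == 0

    def test_reproducible_and_count_within_binomial_bounds(self):
        ds = generate(n=10, m=10, edge_density=0.4, seed=10)  # 40 true edges
        s1 = generate_prediction_sets(ds, 0.8, 0.0, seed=2)
        s2 = generate_prediction_sets(ds, 0.8, 0.0, seed=2)
        assert [p.pairs for p in s1] == [p.pairs for p in s2]
        n_true = len(true_edges(ds))
        lo, hi = stats.binom.ppf([0.005, 0.995], n_true, 0.8)
        for pset in s1:
            assert lo <= len(pset) <= hi


def test_write_dataset_round_trips_through_pipeline_formats(tmp_path):
    from paom import read_expression
    from paom.seqfilter import load_predictions

    ds = generate(n=5, m=4, k_normal=3, k_cancer=3, edge_density=0.4, seed=13)
    preds = generate_prediction_sets(ds, 1.0, 0.0, seed=13)
    paths = write_dataset(ds, tmp_path / "out", predictions=preds)
    X = read_expression(paths["mirna_normal"], species="miRNA")
    np.testing.assert_allclose(X.values, ds.X_normal.values)
    assert X.gene_ids == ds.mirna_ids
    loaded = load_predictions(paths["predictions"], "fallback")
    assert {p.source: p.pairs for p in loaded} == {p.source: p.pairs for p in preds}
    assert paths["manifest"].exists() and paths["truth"].exists()
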