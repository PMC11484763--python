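"""Synthetic population generation, view transforms, graphs and splitting."""

import numpy as np
import pytest
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import train_test_split

from fedfilter.synthetic import (ClientDataset, SyntheticSpec, ViewTransform,
                                 apply_feature_disparity, apply_scaling,
                                 apply_shuffle, build_patient_graph,
                                 generate_base_population,
                                 harmonize_common_subset, load_client_dataset,
                                 save_client_dataset, split_dataset)


def _pool(spec):
    pop = generate_base_population(spec)
    return np.vstack([d.X for d in pop]), np.concatenate([d.y for d in pop])


class TestGeneration:
    def test_same_seed_bit_identical(self, tiny_spec):
        a = generate_base_population(tiny_spec)
        b = generate_base_population(tiny_spec)
        for da, db in zip(a, b):
            np.testing.assert_array_equal(da.X, db.X)
            np.testing.assert_array_equal(da.y, db.y)

    def test_prevalence_within_three_standard_errors(self):
        prev = 0.15
        spec = SyntheticSpec(n_clients=1, samples_per_client=2000,
                             class_prevalence=prev, seed=3)
        ds = generate_base_population(spec)[0]
        se = np.sqrt(prev * (1 - prev) / 2000)
        assert abs(ds.y.mean() - prev) < 3 * se

    def test_scarce_client_gets_stated_count(self):
        spec = SyntheticSpec(seed=1)   # defaults: (2000, 2000, 2000, 200)
        pop = generate_base_population(spec)
        assert [d.n_samples for d in pop] == [2000, 2000, 2000, 200]

    def test_oracle_model_recovers_signal(self):
        spec = SyntheticSpec(n_clients=2, samples_per_client=1000, seed=5)
        X, y = _pool(spec)
        Xtr, Xte, ytr, yte = train_test_split(X, y, test_size=0.3, random_state=0,
                                              stratify=y)
        m = LogisticRegression(max_iter=2000).fit(Xtr, ytr)
        assert roc_auc_score(yte, m.predict_proba(Xte)[:, 1]) > 0.8

    def test_no_informative_features_chance_level(self):
        spec = SyntheticSpec(n_clients=2, samples_per_client=1000,
                             n_informative=0, seed=5)
        X, y = _pool(spec)
        Xtr, Xte, ytr, yte = train_test_split(X, y, test_size=0.3, random_state=0,
                                              stratify=y)
        m = LogisticRegression(max_iter=2000).fit(Xtr, ytr)
        assert abs(roc_auc_score(yte, m.predict_proba(Xte)[:, 1]) - 0.5) < 0.06

    def test_infeasible_spec_rejected(self):
        with pytest.raises(ValueError):
            SyntheticSpec(n_informative=40, n_features=28)
        with pytest.raises(ValueError):
            SyntheticSpec(class_prevalence=0.0)

    def test_timeseries_shape(self):
        spec = SyntheticSpec(n_clients=1, samples_per_client=50,
                             modality="timeseries", n_timesteps=4, seed=2)
        ds = generate_base_population(spec)[0]
        assert ds.X.shape == (50, 4, 28)

    def test_multilabel_labels(self):
        spec = SyntheticSpec(n_clients=1, samples_per_client=300,
                             task="multilabel", n_labels=3, seed=2)
        ds = generate_base_population(spec)[0]
        assert ds.y.shape == (300, 3)
        assert set(np.unique(ds.y)) <= {0.0, 1.0}


class TestViewTransforms:
    @pytest.fixture()
    def ds(self, tiny_spec):
        return generate_base_population(tiny_spec)[0]

    def test_keep_fraction_one_is_identity(self, ds):
        out, tr = apply_feature_disparity(ds, keep_fraction=1.0, seed=0)
        np.testing.assert_array_equal(out.X, ds.X)
        np.testing.assert_array_equal(tr.kept_indices, np.arange(ds.n_features))

    def test_28_to_21_column_pattern(self):
        spec = SyntheticSpec(n_clients=1, samples_per_client=50, seed=0)
        ds = generate_base_population(spec)[0]
        out, tr = apply_feature_disparity(ds, n_keep=21, seed=1)
        assert out.X.shape[1] == 21
        kept = tr.kept_indices
        assert len(set(kept.tolist())) == 21
        assert set(kept.tolist()) <= set(range(28))

    def test_shuffle_inverse_restores_bitexact(self, ds):
        out, tr = apply_shuffle(ds, seed=3)
        inv = np.argsort(tr.permutation)
        np.testing.assert_array_equal(out.X[:, inv], ds.X)
        assert [out.feature_names[j] for j in inv] == ds.feature_names

    def test_shuffle_does_not_touch_labels(self, ds):
        out, _ = apply_shuffle(ds, seed=3)
        np.testing.assert_array_equal(out.y, ds.y)

    def test_different_seeds_give_different_permutations(self, ds):
        distinct = 0
        for s in range(100):
            _, t1 = apply_shuffle(ds, seed=2 * s)
            _, t2 = apply_shuffle(ds, seed=2 * s + 1)
            distinct += int(not np.array_equal(t1.permutation, t2.permutation))
        assert distinct >= 99   # collision chance 1/D! with D=10

    def test_scaling_identity_range(self, ds):
        out, tr = apply_scaling(ds, seed=0, scale_range=(1.0, 1.0))
        np.testing.assert_array_equal(out.X, ds.X)
        np.testing.assert_array_equal(tr.scales, np.ones(ds.n_features))

    def test_scaling_restores_to_tolerance(self, ds):
        out, tr = apply_scaling(ds, seed=4)
        np.testing.assert_allclose(out.X / tr.scales, ds.X, atol=1e-12)

    def test_default_scale_factors_within_range(self, ds):
        _, tr = apply_scaling(ds, seed=5)
        assert np.all(tr.scales > 0)
        assert np.all((tr.scales >= 0.01) & (tr.scales <= 100.0))

    def test_transform_records_compose(self, ds):
        d1, _ = apply_feature_disparity(ds, keep_fraction=0.8, seed=1)
        d2, _ = apply_shuffle(d1, seed=2)
        d3, _ = apply_scaling(d2, seed=3)
        np.testing.assert_allclose(d3.transform.apply(ds.X), d3.X, atol=1e-12)


class TestHarmonisation:
    def test_identical_views_unchanged(self, tiny_spec):
        pop = generate_base_population(tiny_spec)
        views = [(ds, ViewTransform.identity(ds.n_features)) for ds in pop]
        out = harmonize_common_subset(views)
        for ds, h in zip(pop, out):
            np.testing.assert_array_equal(ds.X, h.X)
            assert ds.feature_names == h.feature_names

    def test_set_intersection_in_canonical_order(self):
        rng = np.random.default_rng(0)
        mk = lambda names: ClientDataset(client_id="x", X=rng.normal(size=(5, len(names))),
                                         y=np.zeros(5), feature_names=list(names))
        a = mk(["fa", "fb", "fc"])
        b = mk(["fb", "fc", "fd"])
        out = harmonize_common_subset([(a, None), (b, None)])
        assert out[0].feature_names == out[1].feature_names == ["fb", "fc"]

    def test_21_and_28_feature_clients_reduce_to_21(self):
        spec = SyntheticSpec(n_clients=2, samples_per_client=40, seed=0)
        pop = generate_base_population(spec)
        rich = (pop[0], ViewTransform.identity(28))
        poor_ds, poor_tr = apply_feature_disparity(pop[1], n_keep=21, seed=1)
        out = harmonize_common_subset([rich, (poor_ds, poor_tr)])
        assert out[0].X.shape[1] == out[1].X.shape[1] == 21
        assert out[0].feature_names == out[1].feature_names

    def test_empty_intersection_rejected(self):
        rng = np.random.default_rng(0)
        a = ClientDataset("a", rng.normal(size=(3, 2)), np.zeros(3), ["x", "y"])
        b = ClientDataset("b", rng.normal(size=(3, 2)), np.zeros(3), ["u", "v"])
        with pytest.raises(ValueError, match="common"):
            harmonize_common_subset([(a, None), (b, None)])


class TestPatientGraph:
    def test_collinear_points_middle_connected_to_both(self):
        X = np.array([[0.0, 0.0], [1.0, 1.0], [2.0, 2.0]])
        # cosine distance is 0 between collinear same-direction points; use
        # distinct directions so neighbourhoods are unambiguous
        X = np.array([[1.0, 0.0], [1.0, 1.0], [0.0, 1.0]])
        ds = ClientDataset("g", X, np.zeros(3), ["a", "b"])
        out = build_patient_graph(ds, k=1)
        edges = {tuple(e) for e in out.edges}
        assert (1, 0) in edges or (0, 1) in edges
        assert (1, 2) in edges or (2, 1) in edges

    def test_union_knn_degree_at_least_k(self):
        rng = np.random.default_rng(1)
        ds = ClientDataset("g", rng.normal(size=(30, 4)), np.zeros(30),
                           [f"f{i}" for i in range(4)])
        out = build_patient_graph(ds, k=5)
        deg = np.zeros(30, int)
        for s, d in out.edges:
            if s != d:
                deg[s] += 1
        assert np.all(deg >= 5)

    def test_edge_list_symmetric_with_self_loops(self):
        rng = np.random.default_rng(2)
        ds = ClientDataset("g", rng.normal(size=(12, 3)), np.zeros(12),
                           ["a", "b", "c"])
        out = build_patient_graph(ds, k=3)
        edges = {tuple(e) for e in out.edges}
        assert all((d, s) in edges for s, d in edges)
        assert all((i, i) in edges for i in range(12))

    def test_k_too_large_rejected(self):
        ds = ClientDataset("g", np.zeros((4, 2)), np.zeros(4), ["a", "b"])
        with pytest.raises(ValueError, match="k="):
            build_patient_graph(ds, k=4)


class TestSplitting:
    def _ds(self, n, prev=0.3, seed=0):
        rng = np.random.default_rng(seed)
        y = (rng.random(n) < prev).astype(float)
        return ClientDataset("s", rng.normal(size=(n, 3)), y, ["a", "b", "c"])

    def test_100_samples_split_65_15_20_exactly(self):
        ds = split_dataset(self._ds(100), seed=1)
        assert [ds.splits[s].sum() for s in ("train", "val", "test")] == [65, 15, 20]

    def test_7_samples_largest_remainder(self):
        ds = split_dataset(self._ds(7), seed=1)
        assert [ds.splits[s].sum() for s in ("train", "val", "test")] == [5, 1, 1]

    @pytest.mark.parametrize("n", [7, 23, 100, 317])
    def test_disjoint_and_exhaustive(self, n):
        ds = split_dataset(self._ds(n), seed=2)
        total = sum(ds.splits[s].astype(int) for s in ("train", "val", "test"))
        assert np.all(total == 1)

    def test_stratification_preserves_prevalence(self):
        ds = self._ds(200, prev=0.2, seed=3)
        out = split_dataset(ds, seed=4)
        n_pos = ds.y.sum()
        for name, frac in zip(("train", "val", "test"), (0.65, 0.15, 0.20)):
            pos = ds.y[out.splits[name]].sum()
            # within rounding of the stratum's proportional share
            assert abs(pos - n_pos * frac) <= 1.0


class TestRoundTripIO:
    def test_tabular_round_trip(self, tiny_spec, tmp_path):
        ds = generate_base_population(tiny_spec)[0]
        ds, tr = apply_scaling(ds, seed=1)
        ds = split_dataset(ds, seed=2)
        save_client_dataset(ds, tmp_path / "c0")
        back = load_client_dataset(tmp_path / "c0")
        np.testing.assert_allclose(back.X, ds.X, atol=1e-12)
        np.testing.assert_array_equal(back.y, ds.y)
        assert back.feature_names == ds.feature_names
        for s in ("train", "val", "test"):
            np.testing.assert_array_equal(back.splits[s], ds.splits[s])
        np.testing.assert_array_equal(back.transform.scales, ds.transform.scales)

    def test_graph_round_trip(self, tmp_path):
        rng = np.random.default_rng(3)
        ds = ClientDataset("g", rng.normal(size=(20, 3)),
                           rng.integers(0, 2, 20).astype(float), ["a", "b", "c"])
        ds = build_patient_graph(ds, k=3)
        ds = split_dataset(ds, seed=0)
        save_client_dataset(ds, tmp_path / "g")
        back = load_client_dataset(tmp_path / "g")
        np.testing.assert_array_equal(back.edges, ds.edges)
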