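import numpy as np
import pytest

import semdecode as sd
from semdecode import ConfigurationError, DataIntegrityError
from semdecode.searchlight import T_SENTINEL, _subject_searchlight, _identity_pairing


class TestNeighborhoods:
    def test_minimal_and_saturated_k(self, grid5):
        nb1 = sd.build_neighborhoods(grid5, 1)
        assert np.array_equal(nb1[:, 0], np.arange(25))
        nb_all = sd.build_neighborhoods(grid5, 25)
        for row in nb_all:
            assert sorted(row) == list(range(25))

    def test_center_plus_lattice_neighbors_matches_brute_force(self, grid5):
        nb = sd.build_neighborhoods(grid5, 5)
        center = 12  # (2, 2) on the 5x5 grid
        # brute-force sort by (distance, id)
        d = np.linalg.norm(grid5.coords - grid5.coords[center], axis=1)
        order = np.lexsort((np.arange(25), d))
        expected = [center] + [v for v in order if v != center][:4]
        assert list(nb[center]) == expected
        assert set(nb[center][1:]) == {7, 11, 13, 17}  # 4-neighborhood

    def test_k_too_large_rejected(self, grid5):
        with pytest.raises(ConfigurationError):
            sd.build_neighborhoods(grid5, 26)


@pytest.fixture(scope="module")
def maps_and_labels(small_dataset):
    nb = sd.build_neighborhoods(small_dataset.graph, 9)
    cfg = sd.SearchlightConfig(k_neighbors=9, alpha=10.0)
    acc = sd.run_searchlight(
        small_dataset.responses, small_dataset.features["multimodal"], nb, cfg
    )
    labels = next(iter(small_dataset.truths.values())).region_labels
    return acc, labels


class TestRunSearchlight:
    def test_invariant_vertices_decode_in_all_four_conditions(self):
        # low-noise recovery: interior invariant vertices clear 0.9 in every
        # condition, averaged over 10 simulation seeds
        sums = None
        for seed in range(10):
            ds = sd.simulate_dataset(
                n_subjects=1, n_vertices=144, n_train_images=80,
                n_train_captions=80, n_test_pairs=20, latent_dim=8,
                feature_dims={"vision": 32, "language": 32, "multimodal": 32},
                region_size=16, noise_sd=0.4, seed=300 + seed,
            )
            nb = sd.build_neighborhoods(ds.graph, 9)
            acc = sd.run_searchlight(
                ds.responses, ds.features["multimodal"], nb,
                sd.SearchlightConfig(k_neighbors=9, alpha=10.0),
            )
            labels = next(iter(ds.truths.values())).region_labels
            interior = [
                v
                for v in np.flatnonzero(labels == "invariant")
                if all(labels[u] == "invariant" for u in nb[v])
            ]
            assert interior
            means = np.array(
                [acc.condition(c)[:, interior].mean() for c in acc.conditions]
            )
            sums = means if sums is None else sums + means
        assert np.all(sums / 10 > 0.9)

    def test_noise_vertices_sit_at_chance(self, maps_and_labels, small_dataset):
        acc, labels = maps_and_labels
        # only noise vertices whose searchlight stays clear of signal regions
        nb = sd.build_neighborhoods(small_dataset.graph, 9)
        clean = [
            v
            for v in np.flatnonzero(labels == "noise")
            if all(labels[u] == "noise" for u in nb[v])
        ]
        assert len(clean) > 5
        vals = acc.data[:, clean, :]
        assert abs(vals.mean() - 0.5) < 0.05

    def test_image_only_region_fails_the_conjunction(self, maps_and_labels, small_dataset):
        acc, labels = maps_and_labels
        nb = sd.build_neighborhoods(small_dataset.graph, 9)
        core = [
            v
            for v in np.flatnonzero(labels == "image_only")
            if all(labels[u] == "image_only" for u in nb[v])
        ]
        assert core, "planted region should contain interior vertices"
        assert acc.condition("agnostic_image")[:, core].mean() > 0.8
        assert abs(acc.condition("cross_caption")[:, core].mean() - 0.5) < 0.08

    def test_missing_vertex_rejected(self, small_dataset):
        nb = sd.build_neighborhoods(small_dataset.graph, 5)
        nb[0, 0] = 10_000
        with pytest.raises(DataIntegrityError):
            sd.run_searchlight(
                small_dataset.responses,
                small_dataset.features["multimodal"],
                nb,
                sd.SearchlightConfig(k_neighbors=5),
            )


class TestTMaps:
    def test_null_mean_gives_zero(self):
        t = sd.one_sample_t_map(np.full((4, 6), 0.5))
        assert np.allclose(t.values, 0.0)

    def test_hand_value_sqrt3(self):
        t = sd.one_sample_t_map(np.array([[0.6], [0.5], [0.7]]))
        assert t.values[0] == pytest.approx(np.sqrt(3.0))

    def test_zero_variance_capped_at_sentinel(self):
        t = sd.one_sample_t_map(np.full((3, 2), 0.7))
        assert np.all(t.values == T_SENTINEL)
        t_dn = sd.one_sample_t_map(np.full((3, 2), 0.3))
        assert np.all(t_dn.values == -T_SENTINEL)

    def test_single_subject_rejected(self):
        with pytest.raises(DataIntegrityError):
            sd.one_sample_t_map(np.full((1, 5), 0.7))


class TestConjunction:
    def test_elementwise_minimum_and_dominance(self):
        maps = [sd.StatMap(np.array([2.0, 0.0]), "t"),
                sd.StatMap(np.array([3.0, 1.0]), "t"),
                sd.StatMap(np.array([4.0, 2.0]), "t"),
                sd.StatMap(np.array([1.0, -5.0]), "t")]
        out = sd.conjunction_min_t(maps)
        assert list(out.values) == [1.0, -5.0]
        same = sd.conjunction_min_t([maps[0]] * 4)
        assert np.array_equal(same.values, maps[0].values)

    def test_length_mismatch_rejected(self):
        with pytest.raises(DataIntegrityError):
            sd.conjunction_min_t(
                [sd.StatMap(np.zeros(3), "t"), sd.StatMap(np.zeros(4), "t")]
            )


class TestTFCE:
    def test_all_zero_map_stays_zero(self, grid5):
        out = sd.tfce(np.zeros(25), grid5)
        assert np.all(out.values == 0.0)

    def test_isolated_vertex_closed_form(self):
        # isolated spike of height 1: TFCE -> integral of h^2 dh = 1/3
        g = sd.generate_surface_graph(25, "grid")
        v = np.zeros(25)
        v[12] = 1.0
        out = sd.tfce(v, g, sd.TFCEParams(dh=0.01))
        assert out.values[12] == pytest.approx(1 / 3, rel=0.02)
        assert np.all(out.values[np.arange(25) != 12] == 0.0)

    def test_two_adjacent_vertices_closed_form(self):
        g = sd.generate_surface_graph(25, "grid")
        v = np.zeros(25)
        v[[12, 13]] = 1.0
        out = sd.tfce(v, g, sd.TFCEParams(dh=0.01))
        assert out.values[12] == pytest.approx(2 / 3, rel=0.02)
        assert out.values[13] == pytest.approx(2 / 3, rel=0.02)

    def test_negative_values_contribute_nothing(self, grid5):
        v = -np.ones(25)
        v[0] = 0.8
        out = sd.tfce(v, grid5, sd.TFCEParams(dh=0.01))
        assert out.values[0] > 0
        assert np.all(out.values[1:] == 0.0)

    def test_bad_dh_rejected(self):
        with pytest.raises(ConfigurationError):
            sd.TFCEParams(dh=0.0)

    def test_monotone_under_pointwise_increase(self):
        # raising one vertex never decreases any TFCE value (fixed dh)
        rng = np.random.default_rng(8)
        g = sd.generate_surface_graph(36, "grid")
        params = sd.TFCEParams(dh=0.05)
        for _ in range(10):
            v = rng.uniform(0, 1, 36)
            base = sd.tfce(v, g, params).values
            w = v.copy()
            w[rng.integers(36)] += rng.uniform(0.1, 1.0)
            raised = sd.tfce(w, g, params).values
            assert np.all(raised >= base - 1e-12)

    def test_dh_refinement_converges(self):
        rng = np.random.default_rng(9)
        g = sd.generate_surface_graph(36, "grid")
        v = rng.uniform(0, 2, 36)
        coarse = sd.tfce(v, g, sd.TFCEParams(dh=0.02)).values
        fine = sd.tfce(v, g, sd.TFCEParams(dh=0.01)).values
        # Riemann-sum refinement: difference bounded by one level's mass
        level_bound = 36**1 * v.max() ** 2 * 0.02
        assert np.all(np.abs(coarse - fine) <= level_bound + 1e-9)
        # where the integral has real mass the refinement error is small
        big = fine > 1.0
        assert big.any()
        assert np.all(np.abs(coarse - fine)[big] / fine[big] < 0.1)


@pytest.fixture(scope="module")
def bank(small_dataset):
    nb = sd.build_neighborhoods(small_dataset.graph, 9)
    sub = {"sub-01": small_dataset.responses["sub-01"]}
    return sd.per_subject_null(
        sub,
        small_dataset.features["multimodal"],
        nb,
        n_shuffles=8,
        seed=4,
        config=sd.SearchlightConfig(k_neighbors=9, alpha=10.0),
    )["sub-01"]


class TestPerSubjectNull:
    def test_shuffle_mean_is_chance(self, bank):
        assert abs(bank.mean() - 0.5) < 0.02

    def test_bank_shape_and_determinism(self, small_dataset, bank):
        assert bank.shape == (8, 144, 4)
        nb = sd.build_neighborhoods(small_dataset.graph, 9)
        again = sd.per_subject_null(
            {"sub-01": small_dataset.responses["sub-01"]},
            small_dataset.features["multimodal"],
            nb,
            n_shuffles=8,
            seed=4,
            config=sd.SearchlightConfig(k_neighbors=9, alpha=10.0),
        )["sub-01"]
        assert np.array_equal(bank, again)

    def test_identity_pairing_excluded(self):
        # with only 2 test pairs there is exactly one non-identity
        # permutation, so every shuffle must produce the same (swapped)
        # accuracy maps — the identity is never drawn
        ds = sd.simulate_dataset(
            n_subjects=1, n_vertices=36, n_train_images=20, n_train_captions=20,
            n_test_pairs=2, latent_dim=4,
            feature_dims={"vision": 8, "language": 8, "multimodal": 8},
            region_size=6, noise_sd=0.5, seed=21,
        )
        nb = sd.build_neighborhoods(ds.graph, 5)
        bank = sd.per_subject_null(
            ds.responses, ds.features["multimodal"], nb, n_shuffles=5, seed=2,
            config=sd.SearchlightConfig(k_neighbors=5, alpha=10.0),
        )["sub-01"]
        for i in range(1, 5):
            assert np.array_equal(bank[0], bank[i])
        # and it differs from the identity (observed) maps
        obs = sd.run_searchlight(
            ds.responses, ds.features["multimodal"], nb,
            sd.SearchlightConfig(k_neighbors=5, alpha=10.0),
        )
        assert not np.allclose(bank[0], obs.data[0])


class TestGroupNull:
    @staticmethod
    def tiny_banks(n_shuffles=3, n_subjects=2, n_vertices=9, seed=0):
        rng = np.random.default_rng(seed)
        return {
            f"s{i}": np.clip(
                0.5 + 0.1 * rng.standard_normal((n_shuffles, n_vertices, 4)), 0, 1
            )
            for i in range(n_subjects)
        }

    def test_exhaustive_request_enumerates_all_tuples(self):
        g = sd.generate_surface_graph(9, "grid")
        banks = self.tiny_banks()
        maxima = sd.group_null(
            banks, sd.PermutationConfig(3, 9, seed=1), g
        )
        assert len(maxima) == 9
        # recompute directly from all 9 tuples and compare as multisets
        from itertools import product

        expected = []
        stack = np.stack([banks["s0"], banks["s1"]])
        from semdecode.searchlight import _t_values, _tfce_values

        for a, b in product(range(3), repeat=2):
            acc = np.stack([stack[0, a], stack[1, b]])
            t = _t_values(acc, 0.5)
            expected.append(
                _tfce_values(t.min(axis=1), g.edges, 9, sd.TFCEParams()).max()
            )
        assert np.allclose(sorted(maxima), sorted(expected))

    def test_infeasible_uniqueness_rejected_with_bound(self):
        g = sd.generate_surface_graph(9, "grid")
        with pytest.raises(ConfigurationError, match="9"):
            sd.group_null(
                self.tiny_banks(), sd.PermutationConfig(3, 10, seed=1), g
            )

    def test_seed_determinism(self):
        g = sd.generate_surface_graph(9, "grid")
        banks = self.tiny_banks(n_shuffles=5)
        a = sd.group_null(banks, sd.PermutationConfig(5, 12, seed=7), g)
        b = sd.group_null(banks, sd.PermutationConfig(5, 12, seed=7), g)
        assert np.array_equal(a, b)


class TestPValues:
    def test_bounds_and_hand_counting(self):
        obs = sd.StatMap(np.array([0.5, 5.0, 2.5]), "tfce")
        null = np.array([1.0, 2.0, 3.0, 4.0])
        p = sd.compute_pvalues(obs, null)
        assert list(p.values) == [1.0, 0.0, 0.5]

    def test_add_one_variant_never_zero(self):
        obs = sd.StatMap(np.array([99.0]), "tfce")
        p = sd.compute_pvalues(obs, np.arange(1, 5, dtype=float), method="add_one")
        assert p.values[0] == pytest.approx(1 / 5)

    def test_empty_null_rejected(self):
        with pytest.raises(ConfigurationError):
            sd.compute_pvalues(sd.StatMap(np.zeros(2), "tfce"), np.array([]))


class TestCorrelateMaps:
    def test_identity_and_negation(self):
        v = np.random.default_rng(10).standard_normal(50)
        r, _ = sd.correlate_maps(v, v)
        assert r == pytest.approx(1.0)
        r, _ = sd.correlate_maps(v, -v)
        assert r == pytest.approx(-1.0)

    def test_matches_direct_formula(self):
        rng = np.random.default_rng(11)
        a, b = rng.standard_normal(1000), rng.standard_normal(1000)
        r, _ = sd.correlate_maps(a, b)
        ac, bc = a - a.mean(), b - b.mean()
        direct = (ac @ bc) / np.sqrt((ac @ ac) * (bc @ bc))
        assert r == pytest.approx(direct, abs=1e-12)

    def test_constant_map_rejected_and_partition_blocks(self):
        v = np.arange(10.0)
        with pytest.raises(ConfigurationError):
            sd.correlate_maps(v, np.ones(10))
        part = np.array([0] * 5 + [1] * 5)
        out = sd.correlate_maps(v, v * 2 + 1, partition=part)
        assert set(out) == {0, 1}
        assert out[0][0] == pytest.approx(1.0)


def test_searchlight_parallel_contract_chunk_invariance(small_dataset):
    """Per-vertex results must not depend on evaluation order/batching."""
    resp = small_dataset.responses["sub-01"]
    fm = small_dataset.features["multimodal"]
    nb = sd.build_neighborhoods(small_dataset.graph, 7)
    pairing = _identity_pairing(resp)
    a = _subject_searchlight(resp, fm, nb, 10.0, pairing, chunk_size=7)
    b = _subject_searchlight(resp, fm, nb, 10.0, pairing, chunk_size=144)
    assert np.allclose(a, b, atol=1e-12)
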