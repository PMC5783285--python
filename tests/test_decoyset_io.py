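import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from irappa.decoyset_io import (
    CapriCategory,
    DecoySet,
    DecoyTableError,
    FeatureSchema,
    capri_categorize,
    default_schema,
    fit_normalizer,
    impute_missing,
    normalize,
    read_decoy_table,
    truncate_to_top,
    write_decoy_table,
)


def write_tsv(path, text):
    path.write_text(text)
    return path


class TestReadDecoyTable:
    def test_parses_toy_table(self, tmp_path):
        path = write_tsv(
            tmp_path / "cx1.tsv",
            "decoy_id\tinitial_rank\tlabel\tfA\tfB\n"
            "d1\t1\tincorrect\t0.5\t1.0\n"
            "d2\t2\tacceptable\t0.25\t2.0\n"
            "d3\t3\thigh\t0.125\t3.0\n",
        )
        dset = read_decoy_table(path)
        assert dset.complex_id == "cx1"
        assert dset.n_decoys == 3
        assert dset.features.shape == (3, 2)
        assert dset.labels == [
            CapriCategory.INCORRECT,
            CapriCategory.ACCEPTABLE,
            CapriCategory.HIGH,
        ]
        np.testing.assert_array_equal(dset.initial_ranks, [1, 2, 3])

    def test_empty_cell_becomes_single_missing_marker(self, tmp_path):
        path = write_tsv(
            tmp_path / "cx.tsv",
            "decoy_id\tinitial_rank\tlabel\tfA\tfB\n"
            "d1\t1\tincorrect\t\t1.0\n"
            "d2\t2\tincorrect\t2.0\t3.0\n",
        )
        dset = read_decoy_table(path)
        assert int(np.isnan(dset.features).sum()) == 1
        assert math.isnan(dset.features[0, 0])

    def test_duplicate_decoy_id_rejected(self, tmp_path):
        path = write_tsv(
            tmp_path / "cx.tsv",
            "decoy_id\tinitial_rank\tlabel\tfA\nd1\t1\tincorrect\t1\nd1\t2\tincorrect\t2\n",
        )
        with pytest.raises(DecoyTableError, match="repeated decoy_id"):
            read_decoy_table(path)

    def test_non_numeric_cell_names_row_and_column(self, tmp_path):
        path = write_tsv(
            tmp_path / "cx.tsv",
            "decoy_id\tinitial_rank\tlabel\tfA\nd1\t1\tincorrect\toops\n",
        )
        with pytest.raises(DecoyTableError, match=r"'d1'.*'fA'"):
            read_decoy_table(path)

    def test_labels_derived_from_quality_metrics(self, tmp_path):
        path = write_tsv(
            tmp_path / "cx.tsv",
            "decoy_id\tinitial_rank\tfnat\tlrmsd\tirmsd\tfA\n"
            "d1\t1\t0.8\t0.5\t0.5\t1\n"
            "d2\t2\t0.05\t20\t10\t2\n",
        )
        dset = read_decoy_table(path)
        assert dset.labels == [CapriCategory.HIGH, CapriCategory.INCORRECT]
        assert dset.features.shape == (2, 1)  # metric columns are reserved, not features

    def test_direct_label_wins_over_metrics(self, tmp_path):
        path = write_tsv(
            tmp_path / "cx.tsv",
            "decoy_id\tinitial_rank\tlabel\tfnat\tlrmsd\tirmsd\tfA\n"
            "d1\t1\tmedium\t0.0\t99\t99\t1\n",
        )
        assert read_decoy_table(path).labels == [CapriCategory.MEDIUM]

    def test_roundtrip_is_exact(self, tmp_path, decoyset_factory):
        dset = decoyset_factory(
            [[0.1, -2.5], [float("nan"), 3.0], [7.25, 0.0]],
            "iah",
            initial_ranks=[2, 3, 1],
        )
        path = tmp_path / "cx.tsv"
        write_decoy_table(dset, path)
        back = read_decoy_table(path)
        assert back.decoy_ids == dset.decoy_ids
        assert back.labels == dset.labels
        np.testing.assert_array_equal(back.initial_ranks, dset.initial_ranks)
        np.testing.assert_array_equal(back.features, dset.features)


class TestCapriCategorize:
    @pytest.mark.parametrize(
        "fnat, lrmsd, irmsd, expected",
        [
            (0.8, 0.5, 0.5, CapriCategory.HIGH),
            (0.05, 2.0, 1.0, CapriCategory.INCORRECT),  # fnat below acceptable floor
            (0.2, 8.0, 3.0, CapriCategory.ACCEPTABLE),
            (0.4, 4.0, 1.5, CapriCategory.MEDIUM),
            (0.1, 10.0, 4.0, CapriCategory.ACCEPTABLE),  # thresholds inclusive
            (0.5, 30.0, 0.9, CapriCategory.HIGH),  # irmsd alone qualifies
            (0.9, 30.0, 30.0, CapriCategory.INCORRECT),  # both RMSDs too large
        ],
    )
    def test_examples(self, fnat, lrmsd, irmsd, expected):
        assert capri_categorize(fnat, lrmsd, irmsd) is expected

    @pytest.mark.parametrize("fnat, lrmsd, irmsd", [(-0.1, 1, 1), (1.2, 1, 1), (0.5, -1, 1), (0.5, 1, -1)])
    def test_domain_errors(self, fnat, lrmsd, irmsd):
        with pytest.raises(ValueError):
            capri_categorize(fnat, lrmsd, irmsd)

    @given(
        fnat=st.floats(0, 1),
        lrmsd=st.floats(0, 50),
        irmsd=st.floats(0, 20),
        d_fnat=st.floats(0, 1),
        d_l=st.floats(0, 50),
        d_i=st.floats(0, 20),
    )
    def test_monotone_in_quality(self, fnat, lrmsd, irmsd, d_fnat, d_l, d_i):
        """Improving fnat and lowering both RMSDs never lowers the category."""
        base = capri_categorize(fnat, lrmsd, irmsd)
        better = capri_categorize(
            min(1.0, fnat + d_fnat), max(0.0, lrmsd - d_l), max(0.0, irmsd - d_i)
        )
        assert better >= base


class TestImputeMissing:
    def test_column_mean_fills_gap(self, decoyset_factory):
        dset = decoyset_factory([[1.0], [float("nan")], [3.0]], "iii")
        (out,) = impute_missing([dset])
        np.testing.assert_allclose(out.features[:, 0], [1.0, 2.0, 3.0])

    def test_identity_when_complete(self, decoyset_factory):
        dset = decoyset_factory([[1.0, 2.0], [3.0, 4.0]], "ia")
        (out,) = impute_missing([dset])
        np.testing.assert_array_equal(out.features, dset.features)

    def test_mean_pooled_across_complexes(self, decoyset_factory):
        a = decoyset_factory([[1.0], [3.0]], "ii", complex_id="cx1")
        b = decoyset_factory([[float("nan")]], "i", complex_id="cx2")
        _, out_b = impute_missing([a, b])
        assert out_b.features[0, 0] == pytest.approx(2.0)  # (1+3)/2 pooled

    def test_never_alters_observed_cells(self, decoyset_factory):
        feats = np.array([[1.0, float("nan")], [2.0, 5.0], [float("nan"), 7.0]])
        dset = decoyset_factory(feats, "iii")
        (out,) = impute_missing([dset])
        observed = ~np.isnan(feats)
        np.testing.assert_array_equal(out.features[observed], feats[observed])

    def test_entirely_missing_column_errors(self, decoyset_factory):
        dset = decoyset_factory([[float("nan")], [float("nan")]], "ii")
        with pytest.raises(ValueError, match="entirely missing"):
            impute_missing([dset])


class TestNormalizer:
    def test_two_point_column(self, decoyset_factory):
        dset = decoyset_factory([[0.0], [2.0]], "ia")
        schema = FeatureSchema(names=["fA"])
        fitted = fit_normalizer([dset], schema)
        assert fitted.means[0] == pytest.approx(1.0)
        assert fitted.sigmas[0] == pytest.approx(1.0)
        out = normalize(dset, fitted)
        np.testing.assert_allclose(out.features[:, 0], [-1.0, 1.0])

    def test_constant_column_flagged_and_zeroed(self, decoyset_factory):
        dset = decoyset_factory([[5.0], [5.0]], "ia")
        schema = FeatureSchema(names=["fA"])
        with pytest.warns(RuntimeWarning, match="constant"):
            fitted = fit_normalizer([dset], schema)
        assert fitted.constant_columns.tolist() == [True]
        np.testing.assert_array_equal(normalize(dset, fitted).features, [[0.0], [0.0]])

    def test_held_out_set_uses_training_parameters(self, decoyset_factory):
        train_set = decoyset_factory([[0.0], [2.0]], "ia", complex_id="tr")
        held_out = decoyset_factory([[10.0], [20.0]], "ia", complex_id="ho")
        fitted = fit_normalizer([train_set], FeatureSchema(names=["fA"]))
        out = normalize(held_out, fitted)
        # (10-1)/1 and (20-1)/1, not the held-out set's own z-scores
        np.testing.assert_allclose(out.features[:, 0], [9.0, 19.0])

    def test_training_pool_is_standardized(self, tiny_benchmark):
        schema = FeatureSchema(names=[f"f{j}" for j in range(tiny_benchmark[0].n_features)])
        fitted = fit_normalizer(tiny_benchmark, schema)
        pooled = np.vstack([normalize(s, fitted).features for s in tiny_benchmark])
        np.testing.assert_allclose(pooled.mean(axis=0), 0.0, atol=1e-9)
        np.testing.assert_allclose(pooled.std(axis=0), 1.0, atol=1e-9)

    def test_empty_pool_errors(self):
        with pytest.raises(ValueError):
            fit_normalizer([], FeatureSchema(names=["fA"]))


class TestTruncateToTop:
    def test_keeps_top_limit(self, decoyset_factory):
        n = 600
        dset = decoyset_factory(
            np.arange(n, dtype=float)[:, None], "i" * n, initial_ranks=np.arange(n, 0, -1)
        )
        out = truncate_to_top(dset, 500)
        assert out.n_decoys == 500
        assert out.initial_ranks.max() == 500

    def test_small_set_fully_retained(self, decoyset_factory):
        dset = decoyset_factory(np.zeros((100, 1)), "i" * 99 + "a")
        assert truncate_to_top(dset, 500).n_decoys == 100

    def test_flags_loss_of_near_natives(self, decoyset_factory):
        n = 30
        labels = "i" * (n - 1) + "a"  # only near-native sits at the worst rank
        dset = decoyset_factory(np.zeros((n, 1)), labels, initial_ranks=np.arange(1, n + 1))
        out = truncate_to_top(dset, 20)
        assert dset.has_near_native
        assert not out.has_near_native

    def test_invalid_limit(self, decoyset_factory):
        dset = decoyset_factory([[0.0]], "i")
        with pytest.raises(ValueError):
            truncate_to_top(dset, 0)


class TestSchema:
    def test_default_width_is_91(self):
        schema = default_schema()
        assert schema.n_features == 91
        assert sum(name.startswith("cluster_size") for name in schema.names) == 9

    def test_json_roundtrip(self, tmp_path, decoyset_factory):
        dset = decoyset_factory([[0.0, 1.0], [2.0, 1.0]], "ia")
        with pytest.warns(RuntimeWarning):
            fitted = fit_normalizer([dset], FeatureSchema(names=["fA", "fB"]))
        fitted.to_json(tmp_path / "schema.json")
        back = FeatureSchema.from_json(tmp_path / "schema.json")
        assert back.names == fitted.names
        np.testing.assert_array_equal(back.means, fitted.means)
        np.testing.assert_array_equal(back.sigmas, fitted.sigmas)


class TestDecoySetInvariants:
    def test_rank_permutation_enforced(self, decoyset_factory):
        with pytest.raises(ValueError, match="permutation"):
            decoyset_factory([[0.0], [1.0]], "ia", initial_ranks=[1, 3])

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            DecoySet(
                complex_id="cx",
                decoy_ids=["a", "b"],
                features=np.zeros((2, 1)),
                labels=[CapriCategory.INCORRECT],
                initial_ranks=np.array([1, 2]),
            )
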