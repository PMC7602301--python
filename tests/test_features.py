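import numpy as np
import pytest

import oracles
from conftest import make_fragment, random_window
from m5cpred import (
    FamilyDescriptor,
    FeatureSpec,
    LabeledDataset,
    PhysChemTable,
    build_feature_matrix,
    encode_cpd,
    encode_knf,
    encode_ksnpf,
    encode_kspsdp,
    encode_psednc,
    encode_psnp,
    fit_propensities,
)
from m5cpred.features import (
    _cpd_batch,
    _knf_batch,
    _ksnpf_batch,
    _psednc_batch,
    PropensityModel,
)
from m5cpred.sequence_core import NUC_TO_CODE


def codes_of(s: str) -> np.ndarray:
    return np.array([[NUC_TO_CODE[c] for c in s]], dtype=np.uint8)


@pytest.fixture(scope="module")
def table():
    return PhysChemTable.default()


class TestPhysChemTable:
    def test_shape_and_normalization(self, table):
        assert table.values.shape == (16, 3)
        norm = table.normalized_array()
        assert np.abs(norm.mean(axis=0)).max() < 1e-10
        assert np.abs(norm.std(axis=0) - 1).max() < 1e-10

    def test_published_values_spot_checks(self, table):
        v = table.values
        assert v.loc["GC", "free_energy"] == pytest.approx(-3.420)
        assert v.loc["CC", "hydrophilicity"] == pytest.approx(0.490)
        assert v.loc["UA", "stacking_energy"] == pytest.approx(-16.000)
        assert v.loc["AA", "free_energy"] == pytest.approx(-0.930)


class TestKNF:
    def test_homopolymer(self):
        v = _knf_batch(codes_of("A" * 41), K=4)[0]
        assert v[0] == pytest.approx(1.0)  # AAAA is index 0
        assert v[1:].sum() == 0

    def test_single_nucleotide_uniform(self):
        v = _knf_batch(codes_of("ACGU"), K=1)[0]
        assert np.allclose(v, 0.25)

    def test_matches_bruteforce(self, random_fragments):
        for frag in random_fragments[:30]:
            got = encode_knf(frag, 4)
            want = oracles.naive_knf(frag.window, 4)
            np.testing.assert_allclose(got, want, atol=1e-12)

    def test_sums_to_one_without_n(self, rng):
        frag = make_fragment(random_window(rng))
        for K in (1, 2, 3, 4):
            assert encode_knf(frag, K).sum() == pytest.approx(1.0)

    def test_k_out_of_range(self, rng):
        frag = make_fragment(random_window(rng))
        with pytest.raises(ValueError):
            encode_knf(frag, 7)


class TestKSNPF:
    def test_gapped_pairs_short_example(self):
        # "ACGU", K=1: pairs A..G and C..U, denominator L-K+1 = 4
        v = _ksnpf_batch(codes_of("ACGU"), K=1)[0]
        dinucs = oracles.DINUCS
        assert v[dinucs.index("AG")] == pytest.approx(0.25)
        assert v[dinucs.index("CU")] == pytest.approx(0.25)
        assert v.sum() == pytest.approx(0.5)

    def test_homopolymer_only_aa(self):
        v = _ksnpf_batch(codes_of("A" * 41), K=2)[0]
        assert v[0] > 0 and v[1:].sum() == 0

    def test_vector_sum_identity(self, rng):
        # sum = (L-K-1)/(L-K+1) on N-free windows (printed denominator)
        frag = make_fragment(random_window(rng))
        for K in (0, 1, 5, 10):
            assert encode_ksnpf(frag, K).sum() == pytest.approx((41 - K - 1) / (41 - K + 1))

    def test_count_denominator_sums_to_one(self, rng):
        frag = make_fragment(random_window(rng))
        assert encode_ksnpf(frag, 3, denominator="count").sum() == pytest.approx(1.0)

    def test_matches_bruteforce(self, random_fragments):
        for frag in random_fragments[:30]:
            for K in (0, 2, 5):
                np.testing.assert_allclose(
                    encode_ksnpf(frag, K),
                    oracles.naive_ksnpf(frag.window, K),
                    atol=1e-12,
                )

    def test_k_out_of_range(self, rng):
        frag = make_fragment(random_window(rng))
        with pytest.raises(ValueError):
            encode_ksnpf(frag, 40)


def _two_class_dataset(rng, n=10):
    frags = [make_fragment(random_window(rng), parent_id=f"x{i}") for i in range(2 * n)]
    labels = np.array([1] * n + [0] * n)
    return LabeledDataset(fragments=frags, labels=labels, lambda_flank=20)


class TestPropensities:
    def test_deterministic_single_position(self):
        pos = [make_fragment("A" + "C" * 19 + "C" + "G" * 20)]
        neg = [make_fragment("G" + "C" * 19 + "C" + "G" * 20)]
        ds = LabeledDataset(pos + neg, np.array([1, 0]), 20)
        model = fit_propensities(ds)
        assert model.psnp[0, 0] == pytest.approx(1.0)   # A enriched in positives
        assert model.psnp[2, 0] == pytest.approx(-1.0)  # G enriched in negatives
        assert model.psnp[[1, 3], 0] == pytest.approx([0.0, 0.0])

    def test_columns_sum_to_zero_and_center_zero(self, rng):
        ds = _two_class_dataset(rng)
        model = fit_propensities(ds, gaps=(0, 3))
        assert np.abs(model.psnp.sum(axis=0)).max() < 1e-10
        assert np.abs(model.psnp[:, 20]).max() == 0.0
        for mat in model.kspsdp.values():
            assert np.abs(mat.sum(axis=0)).max() < 1e-10

    def test_class_swap_negates(self, rng):
        ds = _two_class_dataset(rng)
        swapped = LabeledDataset(ds.fragments, 1 - ds.labels, 20)
        m1 = fit_propensities(ds, gaps=(1,))
        m2 = fit_propensities(swapped, gaps=(1,))
        np.testing.assert_allclose(m1.psnp, -m2.psnp, atol=1e-12)
        np.testing.assert_allclose(m1.kspsdp[1], -m2.kspsdp[1], atol=1e-12)

    def test_matches_bruteforce_tally(self, rng):
        ds = _two_class_dataset(rng, n=10)
        model = fit_propensities(ds, gaps=(2,))
        pos_w = [f.window for f, y in zip(ds.fragments, ds.labels) if y == 1]
        neg_w = [f.window for f, y in zip(ds.fragments, ds.labels) if y == 0]
        np.testing.assert_allclose(
            model.psnp, oracles.naive_psnp_matrix(pos_w, neg_w), atol=1e-12
        )
        np.testing.assert_allclose(
            model.kspsdp[2], oracles.naive_kspsdp_matrix(pos_w, neg_w, 2), atol=1e-12
        )

    def test_single_class_rejected(self, rng):
        frags = [make_fragment(random_window(rng)) for _ in range(4)]
        ds = LabeledDataset(frags, np.ones(4, dtype=int), 20)
        with pytest.raises(ValueError, match="both classes"):
            fit_propensities(ds)


class TestPropensityEncoders:
    def test_zero_model_gives_zero_vectors(self, rng):
        frag = make_fragment(random_window(rng))
        model = PropensityModel.zeros(20, gaps=(0, 4))
        assert not encode_psnp(frag, model).any()
        assert not encode_kspsdp(frag, model, 4).any()

    def test_psdp_is_kspsdp_gap_zero_with_dim_2lambda(self, rng):
        ds = _two_class_dataset(rng)
        model = fit_propensities(ds, gaps=(0,))
        v = encode_kspsdp(ds.fragments[0], model, 0)
        assert v.shape == (40,)

    def test_lookup_matches_oracle(self, rng, random_fragments):
        ds = _two_class_dataset(rng)
        model = fit_propensities(ds, gaps=(1, 5))
        matrix = model.psnp.tolist()
        for frag in random_fragments[:25]:
            np.testing.assert_allclose(
                encode_psnp(frag, model),
                oracles.naive_encode_psnp(frag.window, matrix),
                atol=1e-12,
            )
            for K in (1, 5):
                np.testing.assert_allclose(
                    encode_kspsdp(frag, model, K),
                    oracles.naive_encode_kspsdp(frag.window, model.kspsdp[K].tolist(), K),
                    atol=1e-12,
                )

    def test_unfitted_gap_rejected(self, rng):
        ds = _two_class_dataset(rng)
        model = fit_propensities(ds, gaps=(1,))
        with pytest.raises(ValueError, match="not fitted"):
            encode_kspsdp(ds.fragments[0], model, 3)

    def test_lambda_mismatch_rejected(self, rng):
        ds = _two_class_dataset(rng)
        model = fit_propensities(ds)
        frag = make_fragment("N" * 5 + "C" + "N" * 5, lambda_flank=5)
        with pytest.raises(ValueError, match="lambda"):
            encode_psnp(frag, model)


class TestPseDNC:
    def test_lambda_zero_is_plain_dinucleotide_frequency(self, rng):
        frag = make_fragment(random_window(rng))
        v = encode_psednc(frag, lambda_pse=0)
        assert v.shape == (16,)
        assert v.sum() == pytest.approx(1.0)

    def test_homopolymer_has_zero_tiers(self, table):
        v = _psednc_batch(codes_of("A" * 41), lambda_pse=1, w=0.1, table=table)[0]
        assert v[0] == pytest.approx(1.0)   # f(AA) fills the whole 16-dim part
        assert v[16] == pytest.approx(0.0)  # theta_1 = 0: identical dinucleotides

    def test_matches_bruteforce_recurrence(self, table, random_fragments):
        norm_props = {d: table.normalized.loc[d].tolist() for d in oracles.DINUCS}
        for frag in random_fragments[:25]:
            np.testing.assert_allclose(
                encode_psednc(frag, lambda_pse=2, w=0.1, table=table),
                oracles.naive_psednc(frag.window, 2, 0.1, norm_props),
                atol=1e-12,
            )

    def test_invalid_parameters(self, rng):
        frag = make_fragment(random_window(rng))
        with pytest.raises(ValueError):
            encode_psednc(frag, lambda_pse=40)
        with pytest.raises(ValueError):
            encode_psednc(frag, lambda_pse=2, w=0.0)


class TestCPD:
    def test_first_position_density_is_one(self, rng):
        frag = make_fragment(random_window(rng))
        v = encode_cpd(frag)
        assert v[3] == pytest.approx(1.0)  # d_1 = 1 for any non-N nucleotide

    def test_density_example(self):
        # G at position 3 of "AUG...": one G among the first three residues
        v = _cpd_batch(codes_of("AUG" + "A" * 38))[0]
        assert v[2 * 4 + 3] == pytest.approx(1 / 3)

    def test_vector_length_164(self, rng):
        assert encode_cpd(make_fragment(random_window(rng))).shape == (164,)

    def test_matches_bruteforce(self, random_fragments):
        for frag in random_fragments[:30]:
            np.testing.assert_allclose(
                encode_cpd(frag), oracles.naive_cpd(frag.window), atol=1e-12
            )


class TestFeatureSpecAndMatrix:
    def test_parse_report_names(self):
        spec = FeatureSpec.parse(["PSNP", "4NF", "5SNPF", "1SPSDP", "PseDNC", "CPD"])
        assert [d.family for d in spec] == [
            "PSNP", "KNF", "KSNPF", "KSPSDP", "PseDNC", "CPD"
        ]
        assert spec.name == "PSNP + 4NF + 5SNPF + 1SPSDP + PseDNC + CPD"

    @pytest.mark.parametrize(
        "names,expected_dim",
        [
            (["CPD"], 164),
            (["4NF", "5SNPF"], 256 + 16),
            (["PSNP"], 41),
            (["5SPSDP"], 35),
            (["PseDNC"], 18),
        ],
    )
    def test_dimensionality_table(self, names, expected_dim):
        assert FeatureSpec.parse(names).dim(20) == expected_dim

    def test_matrix_shape_and_provenance(self, rng):
        ds = _two_class_dataset(rng, n=5)
        fm = build_feature_matrix(ds, FeatureSpec.parse(["CPD"]))
        assert fm.data.shape == (10, 164)
        assert len(fm.column_provenance) == 164
        assert fm.column_provenance[0][0] == "CPD"

    def test_row_order_mirrors_input_order(self, rng):
        ds = _two_class_dataset(rng, n=6)
        spec = FeatureSpec.parse(["4NF", "PseDNC", "CPD"])
        fm = build_feature_matrix(ds, spec)
        perm = rng.permutation(len(ds))
        fm_perm = build_feature_matrix(ds.subset(perm), spec)
        np.testing.assert_allclose(fm.data[perm], fm_perm.data, atol=0)

    def test_missing_propensity_model_rejected(self, rng):
        ds = _two_class_dataset(rng, n=3)
        with pytest.raises(ValueError, match="PropensityModel"):
            build_feature_matrix(ds, FeatureSpec.parse(["PSNP"]))

    def test_empty_spec_rejected(self):
        with pytest.raises(ValueError, match="at least one"):
            FeatureSpec(())

    def test_duplicate_family_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            FeatureSpec.parse(["4NF", "4NF"])

    def test_all_n_flanks_give_finite_features(self, rng):
        ds = _two_class_dataset(rng)
        model = fit_propensities(ds, gaps=(1,))
        frag = make_fragment("N" * 20 + "C" + "N" * 20)
        all_n = LabeledDataset([frag], np.array([0]), 20)
        spec = FeatureSpec.parse(["PSNP", "1SPSDP", "4NF", "1SNPF", "PseDNC", "CPD"])
        fm = build_feature_matrix(all_n, spec, model)
        assert np.isfinite(fm.data).all()
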