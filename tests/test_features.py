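import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import acpfuse as af
from naive_oracles import naive_aac, naive_cksaagp, naive_dpc

peptides = st.text(alphabet=af.AMINO_ACIDS, min_size=7, max_size=60)


def values_by_name(fv):
    return dict(zip(fv.names, fv.values))


class TestAAC:
    def test_homopolymer(self):
        v = values_by_name(af.aac("KKKK"))
        assert v["K"] == 1.0
        assert sum(v.values()) == 1.0

    def test_uniform_four_letters(self):
        v = values_by_name(af.aac("ACDY"))
        assert v["A"] == v["C"] == v["D"] == v["Y"] == 0.25

    def test_matches_brute_force(self):
        assert np.allclose(af.aac("FLPKKFLPKK").values, naive_aac("FLPKKFLPKK"), atol=1e-12)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            af.aac("")


class TestDPC:
    def test_homopolymer(self):
        v = values_by_name(af.dpc("AAA"))
        assert v["AA"] == 1.0

    def test_alternating(self):
        v = values_by_name(af.dpc("ACAC"))
        assert v["AC"] == pytest.approx(2 / 3)
        assert v["CA"] == pytest.approx(1 / 3)

    def test_single_residue_rejected(self):
        with pytest.raises(ValueError, match="length >= 2"):
            af.dpc("A")


class TestCKSAAGP:
    def test_single_adjacent_pair(self):
        v = values_by_name(af.cksaagp("GK", kmax=0))
        assert v["G1G3"] == 1.0  # G aliphatic, K positively charged
        assert sum(v.values()) == 1.0

    def test_gapped_pair_by_hand(self):
        v = values_by_name(af.cksaagp("GAK", kmax=1))
        assert v["G1G1"] == 0.5 and v["G1G3"] == 0.5  # adjacent GA, AK
        assert v["G1XG3"] == 1.0  # G..K with one intervening residue

    def test_positive_group_homopolymer(self):
        v = values_by_name(af.cksaagp("KKKK", kmax=0))
        assert v["G3G3"] == 1.0

    def test_short_sequence_rejected_by_default(self):
        with pytest.raises(ValueError, match="length >= 7"):
            af.cksaagp("GKGKGK", kmax=5)

    def test_permissive_mode_zeroes_empty_blocks(self):
        fv = af.cksaagp("GKG", kmax=5, permissive=True)
        blocks = fv.values.reshape(6, 25)
        assert blocks[0].sum() == pytest.approx(1.0)
        assert not blocks[2:].any()  # k >= 2 has no valid pair in a 3-mer


@pytest.mark.parametrize(
    "scheme, dim", [("AAC", 20), ("DPC", 400), ("CKSAAGP", 150)]
)
def test_descriptor_dimensions(scheme, dim):
    fv = af.featurize("KLAKLAKKLAKLAK", scheme)
    assert fv.values.shape == (dim,)
    assert len(fv.names) == dim


def test_group_scheme_partitions_alphabet():
    with pytest.raises(ValueError, match="partition"):
        af.GroupScheme({"G1": "GAVLMI", "G2": "FYW"})


@settings(derandomize=True, max_examples=60)
@given(peptides)
def test_descriptors_match_naive_loops(seq):
    assert np.allclose(af.aac(seq).values, naive_aac(seq), atol=1e-12)
    assert np.allclose(af.dpc(seq).values, naive_dpc(seq), atol=1e-12)
    assert np.allclose(af.cksaagp(seq).values, naive_cksaagp(seq), atol=1e-12)


@settings(derandomize=True, max_examples=60)
@given(peptides)
def test_normalization_invariants(seq):
    assert af.aac(seq).values.sum() == pytest.approx(1.0, abs=1e-12)
    assert af.dpc(seq).values.sum() == pytest.approx(1.0, abs=1e-12)
    blocks = af.cksaagp(seq).values.reshape(6, 25)
    for k, block in enumerate(blocks):
        if len(seq) >= k + 2:
            assert block.sum() == pytest.approx(1.0, abs=1e-12)


def test_aac_permutation_invariant_but_pair_descriptors_not():
    assert np.allclose(af.aac("ACAC").values, af.aac("AACC").values)
    assert not np.allclose(af.dpc("ACAC").values, af.dpc("AACC").values)
    assert not np.allclose(
        af.cksaagp("ACACACA", kmax=0).values, af.cksaagp("AAACCCA", kmax=0).values
    )


class TestFeaturizeDataset:
    def test_shapes_and_row_order(self, tiny_dataset):
        X, y, names = af.featurize_dataset(tiny_dataset, "AAC")
        assert X.shape == (6, 20)
        assert list(y) == tiny_dataset.labels
        assert np.allclose(X.sum(axis=1), 1.0)
        assert names == tuple(af.AMINO_ACIDS)

    def test_deterministic(self, tiny_dataset):
        X1, _, _ = af.featurize_dataset(tiny_dataset, "CKSAAGP")
        X2, _, _ = af.featurize_dataset(tiny_dataset, "CKSAAGP")
        assert np.array_equal(X1, X2)

    def test_error_names_failing_record(self):
        ds = af.LabelledDataset(
            [af.PeptideRecord("ok", "KLAKLAK", 1), af.PeptideRecord("shorty", "GKGKGK", 0)]
        )
        with pytest.raises(ValueError, match="shorty"):
            af.featurize_dataset(ds, "CKSAAGP")

    def test_unknown_scheme(self, tiny_dataset):
        with pytest.raises(ValueError, match="unknown"):
            af.featurize_dataset(tiny_dataset, "MORAN")

    def test_feature_frame_columns(self, tiny_dataset):
        frame = af.feature_frame(tiny_dataset, "AAC")
        assert list(frame.columns[:2]) == ["id", "label"]
        assert frame.shape == (6, 22)
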