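import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ensuq.featurize import (
    FeatureMatrix,
    PerSampleNormalizer,
    TrainStandardizer,
    apply_scaler,
    fit_scaler,
    maccs_counts,
    morgan_counts,
    physchem_descriptors,
)

BENZENE = "c1ccccc1"
TESTOSTERONE = "CC12CCC3C(C1CCC2O)CCC4=CC(=O)CCC34C"


class TestMaccsCounts:
    def test_counts_agree_with_binary_keys_on_benzene(self):
        # independent oracle: wherever the binary MACCS bit is set,
        # the substructure occurs, so its count must be >= 1
        from rdkit import Chem
        from rdkit.Chem import MACCSkeys

        counts = maccs_counts([BENZENE]).values[0]
        bits = MACCSkeys.GenMACCSKeys(Chem.MolFromSmiles(BENZENE))
        smarts_defined = {
            pos for pos, (sm, _t) in MACCSkeys.smartsPatts.items() if sm != "?"
        }
        on = [b for b in bits.GetOnBits() if b in smarts_defined]
        assert on, "benzene should set some SMARTS-defined keys"
        assert all(counts[b] >= 1 for b in on)

    def test_methane_sparser_than_steroid(self):
        fm = maccs_counts(["C", TESTOSTERONE])
        assert (fm.values[0] > 0).sum() < (fm.values[1] > 0).sum()

    def test_deterministic_rows(self):
        fm = maccs_counts([BENZENE, BENZENE])
        np.testing.assert_array_equal(fm.values[0], fm.values[1])
        assert fm.kind == "substructure_counts"

    def test_unparsable_smiles_names_index(self):
        with pytest.raises(ValueError, match="index 1"):
            maccs_counts(["CCO", "not_a_smiles"])


class TestMorganCounts:
    def test_vector_length_2048(self):
        fm = morgan_counts(["CCO"])
        assert fm.values.shape == (1, 2048)
        assert fm.kind == "circular_counts"

    def test_total_count_matches_unhashed_environment_oracle(self):
        # folding into 2048 bins preserves the total occurrence count,
        # so the sum must equal the unhashed environment enumeration
        from rdkit import Chem
        from rdkit.Chem import rdFingerprintGenerator

        for smi in ["CC", "CCO", BENZENE]:
            gen = rdFingerprintGenerator.GetMorganGenerator(radius=3)
            sparse = gen.GetSparseCountFingerprint(Chem.MolFromSmiles(smi))
            oracle_total = sum(sparse.GetNonzeroElements().values())
            assert morgan_counts([smi]).values.sum() == oracle_total

    def test_invariant_to_atom_ordering(self):
        fm = morgan_counts([BENZENE, "C1=CC=CC=C1"])
        np.testing.assert_array_equal(fm.values[0], fm.values[1])


class TestPhyschem:
    def test_methane_molecular_weight(self):
        fm = physchem_descriptors(["C"])
        assert fm.values[0, fm.feature_names.index("MolWt")] == pytest.approx(16.043, abs=0.01)

    def test_benzene_heavy_atom_count(self):
        fm = physchem_descriptors([BENZENE])
        assert fm.values[0, fm.feature_names.index("HeavyAtomCount")] == 6

    def test_deterministic(self):
        a = physchem_descriptors(["CCO", BENZENE]).values
        b = physchem_descriptors(["CCO", BENZENE]).values
        np.testing.assert_array_equal(a, b)

    def test_order_equivariant(self):
        ab = physchem_descriptors(["CCO", BENZENE]).values
        ba = physchem_descriptors([BENZENE, "CCO"]).values
        np.testing.assert_array_equal(ab, ba[::-1])


class TestScalers:
    def test_standardize_population_stats(self):
        fm = FeatureMatrix(np.array([[1.0], [3.0]]), "physchem", ["d"])
        scaler = fit_scaler(fm)
        assert isinstance(scaler, TrainStandardizer)
        assert scaler.mean_[0] == pytest.approx(2.0)
        assert scaler.scale_[0] == pytest.approx(1.0)  # population std of {1,3}

    def test_constant_column_flagged_and_centered(self):
        fm = FeatureMatrix(np.array([[5.0, 1.0], [5.0, 2.0]]), "physchem", ["c", "d"])
        scaler = fit_scaler(fm)
        assert list(scaler.flagged_columns_) == [0]
        out = apply_scaler(fm, scaler).values
        np.testing.assert_allclose(out[:, 0], 0.0)

    def test_count_kind_uses_stateless_per_sample_norm(self):
        fm = FeatureMatrix(np.array([[3.0, 4.0], [0.0, 0.0]]), "circular_counts", ["a", "b"])
        scaler = fit_scaler(fm)
        assert isinstance(scaler, PerSampleNormalizer)
        assert not hasattr(scaler, "mean_")
        out = apply_scaler(fm, scaler).values
        np.testing.assert_allclose(out[0], [0.6, 0.8])
        np.testing.assert_allclose(out[1], [0.0, 0.0])  # zero row unchanged

    def test_standardize_own_training_matrix(self, rng):
        X = rng.normal(2.0, 3.0, (50, 4))
        fm = FeatureMatrix(X, "learned", [f"f{j}" for j in range(4)])
        out = apply_scaler(fm, fit_scaler(fm)).values
        np.testing.assert_allclose(out.mean(axis=0), 0.0, atol=1e-12)
        np.testing.assert_allclose(out.std(axis=0), 1.0, atol=1e-12)

    def test_p_mismatch_errors(self):
        fm = FeatureMatrix(np.ones((3, 2)), "learned", ["a", "b"])
        scaler = fit_scaler(fm)
        other = FeatureMatrix(np.ones((3, 5)), "learned", list("abcde"))
        with pytest.raises(ValueError, match="mismatch"):
            apply_scaler(other, scaler)

    def test_kind_mismatch_errors(self):
        fm = FeatureMatrix(np.ones((3, 2)), "circular_counts", ["a", "b"])
        scaler = fit_scaler(fm)
        other = FeatureMatrix(np.ones((3, 2)), "physchem", ["a", "b"])
        with pytest.raises(ValueError, match="kind"):
            apply_scaler(other, scaler)

    def test_no_leakage_from_test_partition(self, rng):
        train = FeatureMatrix(rng.normal(size=(20, 3)), "learned", ["a", "b", "c"])
        scaler = fit_scaler(train)
        test = rng.normal(size=(10, 3))
        perm = rng.permutation(10)
        direct = scaler.transform(test)[perm]
        permuted = scaler.transform(test[perm])
        np.testing.assert_array_equal(direct, permuted)

    @settings(derandomize=True, max_examples=50)
    @given(
        row=st.lists(
            st.integers(min_value=0, max_value=30), min_size=2, max_size=8
        ).filter(lambda r: any(r))
    )
    def test_unit_norm_and_unit_interval_for_counts(self, row):
        X = np.array([row, row], dtype=float)
        fm = FeatureMatrix(X, "substructure_counts", [f"k{j}" for j in range(len(row))])
        out = apply_scaler(fm, fit_scaler(fm)).values
        assert np.linalg.norm(out[0]) == pytest.approx(1.0)
        assert np.all((out >= 0.0) & (out <= 1.0))
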