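import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from metaselect import (
    BaseDatasetSpec,
    DomainTag,
    TabularDataset,
    VariableKind,
    characterize,
    generate_base_dataset,
)
from metaselect.metafeatures import (
    METAFEATURE_NAMES,
    discretize_equal_width,
    information_metafeatures,
    mutual_information,
    shannon_entropy,
    simple_metafeatures,
    statistical_metafeatures,
)


class TestEntropy:
    def test_uniform_four_classes_is_two_bits(self):
        assert shannon_entropy([5, 5, 5, 5]) == pytest.approx(2.0)

    def test_single_class_is_zero(self):
        assert shannon_entropy([10]) == 0.0
        assert shannon_entropy([10], base=math.e) == 0.0

    def test_all_zero_counts_rejected(self):
        with pytest.raises(ValueError):
            shannon_entropy([0, 0, 0])

    @given(st.lists(st.integers(min_value=0, max_value=50), min_size=2,
                    max_size=10).filter(lambda c: sum(c) > 0))
    @settings(deadline=None, max_examples=100)
    def test_matches_direct_summation_and_log_bound(self, counts):
        h = shannon_entropy(counts)
        total = sum(counts)
        brute = -sum(
            (c / total) * math.log2(c / total) for c in counts if c > 0
        )
        assert h == pytest.approx(brute, abs=1e-12)
        assert 0.0 <= h <= math.log2(len(counts)) + 1e-12


class TestMutualInformation:
    def test_identical_uniform_vectors(self):
        x = np.repeat(np.arange(4), 25)
        assert mutual_information(x, x) == pytest.approx(2.0)

    def test_constant_vector_gives_zero(self):
        y = np.arange(20) % 3
        assert mutual_information(np.zeros(20), y) == 0.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            mutual_information([1, 2], [1, 2, 3])

    @given(st.integers(0, 2**31 - 1))
    @settings(deadline=None, max_examples=25)
    def test_bounded_by_marginal_entropies_and_joint_oracle(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.integers(0, 4, size=60)
        y = rng.integers(0, 3, size=60)
        mi = mutual_information(x, y)
        hx = shannon_entropy(np.bincount(x, minlength=4))
        hy = shannon_entropy(np.bincount(y, minlength=3))
        assert -1e-12 <= mi <= min(hx, hy) + 1e-9
        # brute-force joint-table summation oracle
        joint = np.zeros((4, 3))
        for xi, yi in zip(x, y):
            joint[xi, yi] += 1
        p = joint / joint.sum()
        px, py = p.sum(1), p.sum(0)
        brute = sum(
            p[i, j] * math.log2(p[i, j] / (px[i] * py[j]))
            for i in range(4) for j in range(3) if p[i, j] > 0
        )
        assert mi == pytest.approx(brute, abs=1e-9)


class TestDiscretize:
    def test_two_bins(self):
        assert list(discretize_equal_width([0, 1, 2, 3], 2)) == [0, 0, 1, 1]

    def test_constant_vector_single_bin(self):
        assert set(discretize_equal_width([5.0] * 7, 4)) == {0}

    def test_counts_conserved_and_max_in_last_bin(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=100)
        bins = discretize_equal_width(x, 6)
        assert len(bins) == 100
        assert bins[np.argmax(x)] == 5


class TestSimple:
    def test_class_ratios(self):
        frame = pd.DataFrame({"a": range(10)})
        labels = pd.Series(["p"] * 2 + ["q"] * 3 + ["r"] * 5)
        ds = TabularDataset("t", frame, [VariableKind.CONTINUOUS], labels,
                            DomainTag.GENERAL)
        mf = simple_metafeatures(ds)
        assert mf["N_class"] == 3
        assert mf["R_largest"] == pytest.approx(0.5)
        assert mf["R_least"] == pytest.approx(0.2)

    def test_kind_ratios_with_binary_subset_of_discrete(self, tiny_dataset):
        mf = simple_metafeatures(tiny_dataset)
        assert mf["R_binary"] == pytest.approx(1 / 3)
        assert mf["R_discrete"] == pytest.approx(2 / 3)
        assert mf["R_continuous"] == pytest.approx(1 / 3)
        assert mf["R_discrete"] + mf["R_continuous"] == pytest.approx(1.0)


class TestStatistical:
    def test_hand_arithmetic_single_attribute(self):
        frame = pd.DataFrame({"a": [1.0, 2.0, 3.0, 4.0]})
        ds = TabularDataset("t", frame, [VariableKind.CONTINUOUS],
                            pd.Series(["x", "y"] * 2), DomainTag.GENERAL)
        mf = statistical_metafeatures(ds)
        assert mf["Var"] == pytest.approx(5 / 3)
        assert mf["Std"] == pytest.approx(math.sqrt(5 / 3))
        assert mf["MAD"] == pytest.approx(1.0)

    def test_perfectly_correlated_pair_gives_mar_one(self):
        x = np.arange(10.0)
        frame = pd.DataFrame({"a": x, "b": 2 * x + 1})
        ds = TabularDataset("t", frame, [VariableKind.CONTINUOUS] * 2,
                            pd.Series(["x", "y"] * 5), DomainTag.GENERAL)
        assert statistical_metafeatures(ds)["MAr"] == pytest.approx(1.0)

    def test_nonpositive_attribute_flagged_out_of_geomean(self):
        frame = pd.DataFrame({"pos": [1.0, 2.0, 4.0, 8.0],
                              "neg": [-1.0, 2.0, 3.0, 4.0]})
        ds = TabularDataset("t", frame, [VariableKind.CONTINUOUS] * 2,
                            pd.Series(["x", "y"] * 2), DomainTag.GENERAL)
        mf = statistical_metafeatures(ds)
        assert "Geomean" in mf.flags and "neg" in mf.flags["Geomean"]
        # geomean of [1,2,4,8] alone = (64)^(1/4)
        assert mf["Geomean"] == pytest.approx(64 ** 0.25)

    def test_all_discrete_dataset_flagged_zero(self):
        frame = pd.DataFrame({"d": [0, 1, 2, 0]})
        ds = TabularDataset("t", frame, [VariableKind.DISCRETE],
                            pd.Series(["x", "y"] * 2), DomainTag.GENERAL)
        mf = statistical_metafeatures(ds)
        assert mf["Var"] == 0.0 and "statistical" in mf.flags


class TestInformation:
    def test_env_and_nsr_ratio_definitions(self):
        # attribute identical to a binary class: MI = H(class) = E_C
        frame = pd.DataFrame({"a": [0, 1] * 8})
        ds = TabularDataset("t", frame, [VariableKind.BINARY],
                            pd.Series(["x", "y"] * 8), DomainTag.GENERAL)
        mf = information_metafeatures(ds)
        assert mf["E_C"] == pytest.approx(1.0)
        assert mf["MME_CV"] == pytest.approx(1.0)
        assert mf["ENV"] == pytest.approx(1.0)
        assert mf["NSR"] == pytest.approx(0.0)

    def test_zero_mme_cv_flagged_infinite(self):
        frame = pd.DataFrame({"a": [1, 1, 1, 1]})
        ds = TabularDataset("t", frame, [VariableKind.DISCRETE],
                            pd.Series(["x", "y"] * 2), DomainTag.GENERAL)
        mf = information_metafeatures(ds)
        assert math.isinf(mf["ENV"]) and "ENV" in mf.flags


class TestCharacterize:
    def test_all_indicators_present(self, tiny_dataset):
        mf = characterize(tiny_dataset)
        assert set(METAFEATURE_NAMES) <= set(mf.values)
        assert len(METAFEATURE_NAMES) == 26
        assert mf.field_label is DomainTag.MEDICAL

    def test_deterministic(self, separable_dataset):
        a = characterize(separable_dataset).as_series()
        b = characterize(separable_dataset).as_series()
        pd.testing.assert_series_equal(a, b)

    def test_scaling_moves_var_but_not_discrete_information(self):
        spec = BaseDatasetSpec(n_rows=300, n_continuous=2, n_discrete=2,
                               n_binary=0)
        ds = generate_base_dataset(spec, seed=4)
        scaled = ds.copy()
        scaled.frame["cont_0"] = scaled.frame["cont_0"] * 3.0
        base_mf = characterize(ds)
        scaled_mf = characterize(scaled)
        assert scaled_mf["Var"] > base_mf["Var"]
        assert scaled_mf["E_C"] == pytest.approx(base_mf["E_C"])
        for k in ("R_binary", "R_discrete", "R_continuous"):
            assert scaled_mf[k] == base_mf[k]

    @pytest.mark.parametrize("seed", range(5))
    def test_invariants_on_random_synthetic(self, seed):
        rng = np.random.default_rng(seed)
        spec = BaseDatasetSpec(
            n_rows=int(rng.integers(60, 200)),
            n_continuous=int(rng.integers(1, 4)),
            n_discrete=int(rng.integers(0, 3)),
            n_binary=int(rng.integers(0, 2)),
            n_classes=int(rng.integers(2, 5)),
            class_separation=float(rng.uniform(0, 2)),
            attribute_class_dependence=float(rng.uniform(0, 1)),
        )
        mf = characterize(generate_base_dataset(spec, seed=seed))
        k = mf["N_class"]
        assert mf["R_least"] <= 1 / k <= mf["R_largest"]
        assert mf["R_largest"] + mf["R_least"] <= 1.0 + 1e-12
        assert 0.0 <= mf["E_C"] <= math.log2(k) + 1e-9
        assert mf["MME_CV"] <= min(mf["E_C"], mf["ME_V"]) + 1e-9
        if mf["MME_CV"] > 0:
            assert mf["ENV"] >= 1.0 - 1e-9
            assert mf["NSR"] >= -1e-9
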