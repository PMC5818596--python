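"""Feature-reduction pipeline: filters, imputation, PCA characterization."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from toxpod.descriptors import (
    DescriptorInputError,
    DescriptorMatrix,
    impute_median,
    pca_summary,
    prepare_descriptors,
    reduce_correlated,
    remove_near_constant,
)


def dm(arr, cols=None, block="b"):
    arr = np.asarray(arr, dtype=float)
    cols = cols or [f"x{i}" for i in range(arr.shape[1])]
    data = pd.DataFrame(arr, columns=cols, index=[f"C{i}" for i in range(arr.shape[0])])
    return DescriptorMatrix(data, pd.Series(block, index=cols))


class TestNearConstant:
    def test_constant_column_removed_balanced_retained(self):
        n = 100
        m = dm(np.column_stack([np.zeros(n), np.tile([0.0, 1.0], n // 2)]), ["const", "bal"])
        assert list(remove_near_constant(m).data.columns) == ["bal"]

    def test_99_to_1_binary_removed_at_default_cut(self):
        col = np.zeros(100)
        col[0] = 1.0  # ratio 99 > 19
        keep = np.arange(100, dtype=float)
        m = dm(np.column_stack([col, keep]), ["skew", "cont"])
        assert list(remove_near_constant(m).data.columns) == ["cont"]

    def test_ratio_below_cut_retained(self):
        col = np.zeros(100)
        col[:10] = 1.0  # ratio 9 < 19
        m = dm(col.reshape(-1, 1), ["ok"])
        assert list(remove_near_constant(m).data.columns) == ["ok"]


def no_pair_exceeds(data: pd.DataFrame, cutoff: float) -> bool:
    """Exhaustive pair-scan oracle, independent of the greedy filter."""
    cols = list(data.columns)
    for i in range(len(cols)):
        for j in range(i + 1, len(cols)):
            r = np.corrcoef(data[cols[i]], data[cols[j]])[0, 1]
            if abs(r) > cutoff:
                return False
    return True


class TestCorrelationFilter:
    def test_duplicated_pair_loses_exactly_one(self, rng):
        x = rng.normal(size=50)
        m = dm(np.column_stack([x, x, rng.normal(size=50)]), ["a", "a_copy", "c"])
        reduced, removed = reduce_correlated(m, 0.9)
        assert len(removed) == 1 and removed[0] in {"a", "a_copy"}
        assert "c" in reduced.data.columns

    def test_independent_columns_untouched(self, rng):
        m = dm(rng.normal(size=(200, 5)))
        reduced, removed = reduce_correlated(m, 0.9)
        assert removed == []
        assert reduced.data.shape == (200, 5)

    def test_zero_variance_column_rejected(self, rng):
        m = dm(np.column_stack([np.ones(20), rng.normal(size=20)]))
        with pytest.raises(DescriptorInputError):
            reduce_correlated(m)

    def test_planted_collinear_triples_fully_resolved(self, rng):
        # 12 columns, 3 planted collinear triples; brute-force pair scan
        # verifies no surviving pair exceeds the cutoff
        base = rng.normal(size=(20, 6))
        cols = [base]
        for k in range(3):
            cols.append((base[:, k] + 0.05 * rng.normal(size=20)).reshape(-1, 1))
            cols.append((base[:, k] + 0.05 * rng.normal(size=20)).reshape(-1, 1))
        m = dm(np.hstack(cols))
        reduced, removed = reduce_correlated(m, 0.9)
        assert no_pair_exceeds(reduced.data, 0.9)
        assert set(removed).isdisjoint(reduced.data.columns)

    @given(st.integers(0, 10_000))
    def test_termination_property_random_matrices(self, seed):
        r = np.random.default_rng(seed)
        X = r.normal(size=(15, 6))
        # random exact duplicates raise the correlation floor
        for j in range(r.integers(0, 3)):
            X[:, j + 3] = X[:, j]
        X += 1e-9 * r.normal(size=X.shape)  # avoid accidental zero variance
        reduced, _ = reduce_correlated(dm(X), 0.9)
        assert no_pair_exceeds(reduced.data, 0.9)


class TestImputation:
    def test_median_fills_and_observed_cells_bit_exact(self):
        m = dm([[1.0, 0.3], [np.nan, 0.7], [3.0, np.nan], [2.0, 0.1]])
        out = impute_median(m)
        assert not out.data.isna().any().any()
        assert out.data.iloc[1, 0] == 2.0  # median of {1, 3, 2}
        assert out.data.iloc[2, 1] == 0.3  # median of {0.3, 0.7, 0.1}
        observed = ~m.data.isna()
        assert ((out.data == m.data) | ~observed).all().all()

    def test_no_missing_is_identity(self, rng):
        m = dm(rng.normal(size=(10, 3)))
        assert impute_median(m).data.equals(m.data)

    def test_all_missing_column_rejected(self):
        m = dm([[np.nan, 1.0], [np.nan, 2.0]])
        with pytest.raises(DescriptorInputError):
            impute_median(m)


class TestPCASummary:
    def test_matches_direct_eigendecomposition_oracle(self, rng):
        X = rng.normal(size=(40, 8)) @ rng.normal(size=(8, 8))
        m = dm(X)
        profile = pca_summary(m).cumulative_variance
        Z = (X - X.mean(0)) / X.std(0, ddof=1)
        eig = np.sort(np.linalg.eigvalsh(np.cov(Z, rowvar=False)))[::-1]
        expected = np.cumsum(eig) / eig.sum()
        np.testing.assert_allclose(profile, expected, atol=1e-10)

    def test_rank_one_structure_loads_first_component(self, rng):
        u = rng.normal(size=(50, 1))
        v = rng.normal(size=(1, 6))
        m = dm(u @ v + 1e-4 * rng.normal(size=(50, 6)))
        assert pca_summary(m).cumulative_variance[0] > 0.99

    def test_isotropic_data_spreads_variance(self, rng):
        m = dm(rng.normal(size=(4000, 8)))
        cum = pca_summary(m).cumulative_variance
        np.testing.assert_allclose(cum, np.arange(1, 9) / 8, atol=0.05)

    def test_single_row_rejected(self):
        with pytest.raises(DescriptorInputError):
            pca_summary(dm([[1.0, 2.0]]))


class TestFullPipeline:
    def test_synthetic_blocks_clean_after_preparation(self, small_blocks):
        from toxpod.bioactivity import BioactivityMatrix, bioactivity_descriptors
        from toxpod.descriptors import DescriptorMatrix as DM

        blocks = {}
        for name, block in small_blocks.items():
            if isinstance(block, BioactivityMatrix):
                grouped = bioactivity_descriptors(block, min_endpoints=200, min_chemicals=20)
                blocks[name] = DM(grouped, pd.Series(name, index=grouped.columns))
            else:
                blocks[name] = block
        from toxpod.descriptors import concat_blocks, remove_near_constant as rnc, reduce_correlated as rc

        combined = concat_blocks(blocks)
        nonconst = rnc(combined)
        assert set(combined.data.columns) - set(nonconst.data.columns)  # planted constants caught
        reduced, removed = rc(nonconst, 0.9)
        assert removed  # planted duplicates caught
        # pairwise-complete exhaustive scan on what the filter saw
        sub = reduced.data.sample(n=min(40, reduced.data.shape[1]), axis=1, random_state=0)
        for i, a in enumerate(sub.columns):
            for b in sub.columns[i + 1 :]:
                both = sub[a].notna() & sub[b].notna()
                r = np.corrcoef(sub.loc[both, a], sub.loc[both, b])[0, 1]
                assert abs(r) <= 0.9 + 1e-12
        imputed = impute_median(reduced)
        assert not imputed.data.isna().any().any()
        prepared, report = prepare_descriptors(blocks)
        assert report.n_output == imputed.data.shape[1]
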