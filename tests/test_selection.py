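import numpy as np
import pytest

from phradiomics.selection import (
    SelectionSpec,
    corr_filter,
    fit_selection,
    lincomb_filter,
    pca_fit,
    resolve_selection,
    standardize_fit_apply,
)


class TestStandardize:
    def test_train_moments(self):
        rng = np.random.default_rng(0)
        train = rng.normal(3, 2, size=(40, 5))
        out, _, _ = standardize_fit_apply(train)
        assert np.allclose(out.mean(axis=0), 0.0, atol=1e-12)
        assert np.allclose(out.std(axis=0, ddof=1), 1.0, atol=1e-12)

    def test_constant_column_maps_to_zero(self):
        train = np.column_stack([np.full(10, 7.0), np.arange(10.0)])
        test = np.column_stack([np.full(4, 9.0), np.arange(4.0)])
        tr, te, _ = standardize_fit_apply(train, test)
        assert np.all(tr[:, 0] == 0.0)
        assert np.all(te[:, 0] == 0.0)

    def test_test_uses_train_parameters(self):
        train = np.array([[0.0, 1.0], [2.0, 3.0], [4.0, 5.0]])
        test = train + 10.0  # shifted toy set
        _, te_with_train, _ = standardize_fit_apply(train, test)
        te_own, _, _ = standardize_fit_apply(test)
        assert not np.allclose(te_with_train, te_own)
        # shifted by 10 / train SD in every column
        assert np.allclose(te_with_train - 10.0 / train.std(0, ddof=1), te_own)


class TestCorrFilter:
    def test_duplicate_column_removed(self):
        rng = np.random.default_rng(1)
        a = rng.normal(size=30)
        x = np.column_stack([a, a.copy(), rng.normal(size=30)])
        kept = corr_filter(x, ["a", "dup", "c"], threshold=0.9)
        assert len(kept) == 2 and "c" in kept

    def test_orthogonal_columns_all_retained(self):
        x = np.array([[1.0, 0, 0], [0, 1.0, 0], [0, 0, 1.0], [0, 0, 0]])
        assert corr_filter(x, ["a", "b", "c"], threshold=0.5) == ["a", "b", "c"]

    def test_exhaustive_scan_confirms_threshold(self):
        rng = np.random.default_rng(2)
        base = rng.normal(size=(60, 3))
        x = np.column_stack([base, base @ rng.normal(size=(3, 5)) + rng.normal(size=(60, 5)) * 0.4])
        names = [f"v{j}" for j in range(8)]
        kept = corr_filter(x, names, threshold=0.6)
        idx = [names.index(n) for n in kept]
        sub = x[:, idx]
        for i in range(len(idx)):
            for j in range(i + 1, len(idx)):
                r = np.corrcoef(sub[:, i], sub[:, j])[0, 1]
                assert abs(r) <= 0.6 + 1e-12

    def test_deterministic_given_column_order(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=(25, 6))
        x[:, 4] = x[:, 0] * 0.95 + rng.normal(size=25) * 0.05
        names = list("abcdef")
        assert corr_filter(x, names, 0.7) == corr_filter(x.copy(), names, 0.7)


class TestLincombFilter:
    def test_exact_sum_column_removed(self):
        rng = np.random.default_rng(4)
        a, b = rng.normal(size=30), rng.normal(size=30)
        x = np.column_stack([a, b, a + b])
        kept = lincomb_filter(x, ["a", "b", "c"])
        assert kept == ["a", "b"]

    def test_full_rank_identity(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=(20, 6))
        assert lincomb_filter(x, list("abcdef")) == list("abcdef")

    def test_removes_exactly_p_minus_r_columns(self):
        rng = np.random.default_rng(6)
        basis = rng.normal(size=(30, 4))
        x = basis @ rng.normal(size=(4, 9))  # rank 4, 9 columns
        names = [f"v{j}" for j in range(9)]
        kept = lincomb_filter(x, names)
        r = np.linalg.matrix_rank(x)  # independent decomposition (SVD)
        assert len(kept) == r == 4

    def test_removed_columns_reconstructible_from_retained(self):
        rng = np.random.default_rng(7)
        basis = rng.normal(size=(25, 3))
        x = basis @ rng.normal(size=(3, 6))
        names = [f"v{j}" for j in range(6)]
        kept = lincomb_filter(x, names)
        kept_idx = [names.index(n) for n in kept]
        for j, name in enumerate(names):
            if name in kept:
                continue
            coef, *_ = np.linalg.lstsq(x[:, kept_idx], x[:, j], rcond=None)
            assert np.linalg.norm(x[:, kept_idx] @ coef - x[:, j]) < 1e-8


class TestPCA:
    def test_full_fraction_keeps_rank_components(self):
        rng = np.random.default_rng(8)
        basis = rng.normal(size=(30, 4))
        x = basis @ rng.normal(size=(4, 7))
        x = (x - x.mean(0)) / x.std(0, ddof=1)
        t = pca_fit(x, 1.0)
        assert t.n_components == np.linalg.matrix_rank(x - x.mean(0))

    def test_perfectly_correlated_pair_needs_one_component(self):
        rng = np.random.default_rng(9)
        a = rng.normal(size=50)
        x = np.column_stack([a, 2.0 * a])
        assert pca_fit(x, 0.9).n_components == 1

    def test_minimal_component_count_for_fraction(self):
        rng = np.random.default_rng(10)
        x = rng.normal(size=(40, 6)) * np.array([3.0, 2.5, 2.0, 1.0, 0.5, 0.2])
        x = x - x.mean(0)
        t = pca_fit(x, 0.85)
        ev = np.linalg.svd(x, compute_uv=False) ** 2
        frac = np.cumsum(ev) / ev.sum()
        k = t.n_components
        assert frac[k - 1] >= 0.85
        assert k == 1 or frac[k - 2] < 0.85

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValueError):
            pca_fit(np.eye(3), 0.0)


def test_fitted_transform_is_frozen_against_test_rows():
    rng = np.random.default_rng(11)
    train = rng.normal(size=(30, 5))
    train[:, 3] = train[:, 0]  # a duplicate to give corr work to do
    names = list("abcde")
    spec = SelectionSpec("corr", corr_threshold=0.8)
    t = fit_selection(spec, train, names)
    test = rng.normal(size=(10, 5))
    out1, names1 = t.apply(test, names)
    out2, names2 = t.apply(test + 100.0, names)  # perturbed unseen rows
    assert names1 == names2 == t.retained_names
    assert np.allclose(out2 - out1, 100.0)  # params unchanged, pure subset


class TestResolveSelection:
    def test_original_combined(self):
        specs = resolve_selection("Original", "combined")
        by_method = {s.method: s for s in specs}
        assert set(by_method) == {"full", "lincomb", "corr", "pca"}
        assert by_method["corr"].corr_threshold == 0.5
        assert by_method["pca"].pca_variance_fraction == 0.85

    def test_original_single(self):
        by_method = {s.method: s for s in resolve_selection("Original", "single")}
        assert by_method["corr"].corr_threshold == 0.6
        assert by_method["pca"].pca_variance_fraction == 0.9

    def test_icc3_is_full_only(self):
        assert [s.method for s in resolve_selection("ICC3", "single")] == ["full"]
        assert [s.method for s in resolve_selection("ICC3", "combined")] == ["full"]

    def test_icc2_thresholds(self):
        for scope in ("single", "combined"):
            by_method = {s.method: s for s in resolve_selection("ICC2", scope)}
            assert set(by_method) == {"full", "corr", "pca"}
            assert by_method["corr"].corr_threshold == 0.9
            assert by_method["pca"].pca_variance_fraction == 0.9

    def test_dafit_combined_corr_threshold(self):
        by_method = {s.method: s for s in resolve_selection("DAFIT", "combined")}
        assert by_method["corr"].corr_threshold == 0.4
        assert "lincomb" in by_method

    @pytest.mark.parametrize("approach", ["DAFIT_Filt2", "DAFIT_Filt3"])
    def test_dafit_filt_combined_only(self, approach):
        by_method = {s.method: s for s in resolve_selection(approach, "combined")}
        assert set(by_method) == {"full", "corr", "pca"}
        assert by_method["corr"].corr_threshold == 0.8
        assert by_method["pca"].pca_variance_fraction == 0.85
        with pytest.raises(ValueError, match="combined"):
            resolve_selection(approach, "single")
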