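import itertools

import numpy as np
import pandas as pd
import pytest

from chemoextract.exceptions import FlatSpectrumError
from chemoextract.spectral_asca import (
    AscaModel,
    SpectraSet,
    asca_decompose,
    bootstrap_loadings,
    effect_pca,
    permutation_test,
    snv,
)
from conftest import make_spectra_with_band_effect


def balanced_spectra(rng, n_wl=40, noise=0.0, effects=None):
    """Balanced 3x3x3 layout, one run per cell; optional main effects."""
    levels = ["lo", "mid", "hi"]
    rows = list(itertools.product(levels, levels, levels))
    labels = pd.DataFrame(rows, columns=["T", "t", "Q"],
                          index=[f"R{i}" for i in range(len(rows))])
    wl = np.arange(250.0, 250.0 + n_wl)
    X = rng.normal(0, noise, (len(rows), n_wl)) if noise else np.zeros((len(rows), n_wl))
    if effects:
        for factor, table in effects.items():
            for i, row in enumerate(rows):
                lev = row[["T", "t", "Q"].index(factor)]
                X[i] += table[lev]
    ab = pd.DataFrame(X, index=labels.index, columns=wl)
    return SpectraSet(ab, labels)


class TestSnv:
    def test_hand_computed_row(self):
        s = SpectraSet(pd.DataFrame([[1.0, 2.0, 3.0, 4.0]], index=["r1"],
                                    columns=[300.0, 301.0, 302.0, 303.0]),
                       pd.DataFrame({"T": ["a"]}, index=["r1"]))
        out = snv(s).absorbance.iloc[0].to_numpy()
        assert np.allclose(out, [-1.1619, -0.3873, 0.3873, 1.1619], atol=1e-4)

    def test_affine_invariance(self, rng):
        wl = np.arange(220.0, 260.0)
        x = rng.normal(1.0, 0.3, len(wl))
        ab = pd.DataFrame([x, 2.5 * x + 7.0], index=["a", "b"], columns=wl)
        s = snv(SpectraSet(ab, pd.DataFrame({"T": ["1", "2"]}, index=["a", "b"])))
        assert np.allclose(s.absorbance.loc["a"], s.absorbance.loc["b"], atol=1e-12)

    def test_idempotence(self, rng):
        wl = np.arange(220.0, 280.0)
        ab = pd.DataFrame(rng.normal(1, 0.2, (5, len(wl))),
                          index=list("abcde"), columns=wl)
        s = SpectraSet(ab, pd.DataFrame({"T": list("12345")}, index=list("abcde")))
        once = snv(s)
        twice = snv(once)
        assert np.allclose(once.absorbance.to_numpy(), twice.absorbance.to_numpy(),
                           atol=1e-12)

    def test_rows_exactly_standardized(self, rng):
        wl = np.arange(220.0, 300.0)
        ab = pd.DataFrame(rng.normal(1, 0.2, (4, len(wl))),
                          index=list("abcd"), columns=wl)
        out = snv(SpectraSet(ab, pd.DataFrame({"T": list("1234")},
                                              index=list("abcd")))).absorbance
        assert np.allclose(out.mean(axis=1), 0.0, atol=1e-13)
        assert np.allclose(out.std(axis=1, ddof=1), 1.0, atol=1e-13)

    def test_flat_spectrum_names_run(self):
        ab = pd.DataFrame([[1.0, 1.0, 1.0]], index=["bad"], columns=[1.0, 2.0, 3.0])
        with pytest.raises(FlatSpectrumError, match="bad"):
            snv(SpectraSet(ab, pd.DataFrame({"T": ["x"]}, index=["bad"])))


class TestDecomposition:
    def test_two_level_single_factor_half_delta(self):
        wl = [300.0, 301.0, 302.0]
        ab = pd.DataFrame([[1.0, 0, 0], [1.0, 0, 0], [3.0, 0, 0], [3.0, 0, 0]],
                          index=list("abcd"), columns=wl)
        labels = pd.DataFrame({"T": ["lo", "lo", "hi", "hi"]}, index=list("abcd"))
        d = asca_decompose(SpectraSet(ab, labels))
        eff = d.effects["T"].to_numpy()
        assert np.allclose(eff[:, 0], [-1.0, -1.0, 1.0, 1.0])
        assert np.allclose(eff[:, 1:], 0.0)

    def test_balanced_ss_additivity(self, rng):
        effects = {"T": {"lo": -0.5, "mid": 0.0, "hi": 0.5},
                   "t": {"lo": 0.2, "mid": 0.0, "hi": -0.2}}
        s = balanced_spectra(rng, noise=0.1, effects=effects)
        d = asca_decompose(s, interactions=True)
        ss_sum = sum(d.effect_ss.values()) + (d.residual.to_numpy() ** 2).sum()
        assert ss_sum == pytest.approx(d.ss_total, rel=1e-8)

    def test_exact_reconstruction(self, rng):
        s = balanced_spectra(rng, noise=0.3)
        for inter in (False, True):
            d = asca_decompose(s, interactions=inter)
            rec = d.reconstruct().to_numpy()
            assert np.max(np.abs(rec - s.absorbance.to_numpy())) < 1e-10

    def test_balanced_effect_orthogonality(self, rng):
        s = balanced_spectra(rng, noise=0.2,
                             effects={"T": {"lo": -1.0, "mid": 0.3, "hi": 0.7}})
        d = asca_decompose(s, interactions=True)
        mats = list(d.effects.values()) + [d.residual]
        scale = max((m.to_numpy() ** 2).sum() for m in mats)
        for a, b in itertools.combinations(mats, 2):
            cross = np.abs((a.to_numpy() * b.to_numpy()).sum())
            assert cross < 1e-8 * scale

    def test_pure_noise_residual_dominates(self, rng):
        s = balanced_spectra(rng, noise=1.0)
        pct = asca_decompose(s).effect_variance_pct
        assert pct["residual"] > 50.0
        assert (pct.drop("residual") < 25.0).all()

    def test_unbalanced_still_reconstructs(self, rng):
        s = balanced_spectra(rng, noise=0.2)
        keep = s.absorbance.index[:-2]  # drop two runs
        s2 = SpectraSet(s.absorbance.loc[keep], s.factor_labels.loc[keep])
        d = asca_decompose(s2)
        rec = d.reconstruct().to_numpy()
        assert np.max(np.abs(rec - s2.absorbance.to_numpy())) < 1e-10


class TestEffectPca:
    def test_rank_one_effect_explains_100(self):
        ab = pd.DataFrame([[1.0, 2.0], [1.0, 2.0], [3.0, 6.0], [3.0, 6.0]],
                          index=list("abcd"), columns=[1.0, 2.0])
        labels = pd.DataFrame({"T": ["lo", "lo", "hi", "hi"]}, index=list("abcd"))
        d = asca_decompose(SpectraSet(ab, labels))
        model = effect_pca(d, "T", 1)
        assert model.explained_variance_pct.iloc[0] == pytest.approx(100.0)

    def test_band_effect_separates_level_on_sc1(self, factorial):
        s, in_band = make_spectra_with_band_effect(factorial, effect_scale=0.5,
                                                   noise_sd=0.02, seed=4)
        d = asca_decompose(s)
        model = effect_pca(d, "T", 1)
        scores = model.scores["SC1"]
        low = s.factor_labels["T"] == "15.0"
        assert np.sign(scores[low].mean()) != np.sign(scores[~low].mean())

    def test_projections_average_to_level_mean(self, rng):
        s = balanced_spectra(rng, noise=0.2,
                             effects={"T": {"lo": -1.0, "mid": 0.0, "hi": 1.0}})
        d = asca_decompose(s)
        model = effect_pca(d, "T", 1)
        for lev in ("lo", "mid", "hi"):
            mask = (s.factor_labels["T"] == lev).to_numpy()
            assert model.projected_scores["SC1"][mask].mean() == pytest.approx(
                model.scores["SC1"][mask].mean(), abs=1e-8)


class TestPermutation:
    def test_large_effect_minimal_p(self, factorial):
        s, _ = make_spectra_with_band_effect(factorial, effect_scale=2.0,
                                             noise_sd=0.01, seed=1)
        p = permutation_test(s, "T", n_perm=999, seed=3)
        assert p == pytest.approx(1 / 1000)

    def test_matches_exhaustive_enumeration(self, rng):
        # 6 runs, 2 levels of a single factor: 20 label arrangements
        wl = np.arange(300.0, 310.0)
        X = rng.normal(0, 1.0, (6, len(wl)))
        X[:3] += 0.8
        ids = list("abcdef")
        labels = pd.DataFrame({"g": ["A"] * 3 + ["B"] * 3}, index=ids)
        s = SpectraSet(pd.DataFrame(X, index=ids, columns=wl), labels)

        from chemoextract.spectral_asca import _encode, _main_effect_ss
        codes, levels = _encode(labels)
        n_levels = [len(l) for l in levels]
        obs = _main_effect_ss(X, codes, n_levels, 0)
        exact_ge = 0
        perms = set(itertools.permutations([0, 0, 0, 1, 1, 1]))
        for pm in perms:
            c = codes.copy()
            c[:, 0] = pm
            if _main_effect_ss(X, c, n_levels, 0) >= obs - 1e-12:
                exact_ge += 1
        p_exact = exact_ge / len(perms)
        p_mc = permutation_test(s, "g", n_perm=999, seed=9)
        se = np.sqrt(p_exact * (1 - p_exact) / 999)
        assert abs(p_mc - p_exact) < max(3 * se, 0.02)

    def test_invariant_to_wavelength_relabeling(self, factorial):
        s, _ = make_spectra_with_band_effect(factorial, effect_scale=0.3,
                                             noise_sd=0.05, seed=6)
        perm = np.random.default_rng(1).permutation(s.absorbance.shape[1])
        shuffled = s.absorbance.iloc[:, perm]
        shuffled.columns = sorted(s.absorbance.columns)
        s2 = SpectraSet(shuffled, s.factor_labels)
        p1 = permutation_test(s, "T", n_perm=199, seed=42)
        p2 = permutation_test(s2, "T", n_perm=199, seed=42)
        assert p1 == p2

    def test_seed_required_and_degenerate_rejected(self, factorial):
        s, _ = make_spectra_with_band_effect(factorial, seed=0)
        with pytest.raises(ValueError):
            permutation_test(s, "T", n_perm=199)
        with pytest.raises(ValueError):
            permutation_test(s, "T", n_perm=10, seed=1)
        with pytest.raises(ValueError):
            permutation_test(s, "nosuch", n_perm=199, seed=1)


class TestBootstrap:
    def test_default_is_1000_cycles(self):
        import inspect
        assert inspect.signature(bootstrap_loadings).parameters["n_boot"].default == 1000

    def test_band_effect_flagged(self, factorial):
        s, in_band = make_spectra_with_band_effect(factorial, effect_scale=0.6,
                                                   noise_sd=0.02, seed=2)
        with pytest.warns(UserWarning, match="residual bootstrap"):
            mask = bootstrap_loadings(s, "T", component=1, n_boot=200, seed=5)
        sig = mask["significant"].to_numpy()
        core = (s.wavelengths >= 335) & (s.wavelengths <= 365)
        assert sig[core].mean() >= 0.8

    def test_within_cell_resampling_when_cells_replicated(self, rng):
        # duplicate every run of a balanced layout -> all cells have 2 runs
        s = balanced_spectra(rng, n_wl=25, noise=0.1,
                             effects={"T": {"lo": -0.6, "mid": 0.0, "hi": 0.6}})
        ab = pd.concat([s.absorbance, s.absorbance.set_axis(
            [f"{i}rep" for i in s.absorbance.index])])
        labels = pd.concat([s.factor_labels, s.factor_labels.set_axis(
            [f"{i}rep" for i in s.factor_labels.index])])
        s2 = SpectraSet(ab, labels)
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("error")  # no fallback warning expected
            mask = bootstrap_loadings(s2, "T", component=1, n_boot=100, seed=11)
        assert mask["significant"].any()


class TestModelApi:
    def test_fit_summary_and_variance_pct(self, plain_factorial):
        # balanced layout: effect + residual percentages account for everything
        s, _ = make_spectra_with_band_effect(plain_factorial, effect_scale=0.5, seed=3)
        res = AscaModel(s, apply_snv=True).fit()
        pct = res.effect_variance_pct
        assert pct.sum() == pytest.approx(100.0, abs=1e-6)
        assert "T" in res.summary()

    def test_window_restricts_grid(self, factorial):
        s, _ = make_spectra_with_band_effect(factorial, seed=3)
        model = AscaModel(s, window=(300.0, 380.0))
        assert model.spectra.wavelengths.min() >= 300
        assert model.spectra.wavelengths.max() <= 380
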