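"""SNV pretreatment and ANOVA-simultaneous component analysis of spectra.

ASCA partitions a runs x wavelengths absorbance matrix, collected under a
crossed experimental design, into additive effect matrices

    X = 1 m' + X_a + X_b + X_c (+ interactions) + X_E

where each main-effect matrix holds, for every run, the deviation of its
level-mean spectrum from the grand mean, interaction matrices hold
cell-mean deviations net of the main effects, and X_E is the residual.
Each effect matrix is then examined by its own PCA: the scores separate
the factor levels and the loadings show which wavelengths carry the
effect. Effect significance is assessed by permutation of the factor's
level labels; the wavelength-wise significance of loadings by a
bootstrap whose percentile interval must exclude zero.

Level means are unweighted means of cell means (a Type-III-like choice),
so a mildly unbalanced layout — e.g. a couple of aborted runs — keeps
the intended interpretation of the effect matrices. For a balanced
design the effect matrices are mutually orthogonal and their sums of
squares add up to the total.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import FlatSpectrumError
from .multiresponse import PcaModel

__all__ = [
    "SpectraSet",
    "snv",
    "AscaDecomposition",
    "asca_decompose",
    "effect_pca",
    "permutation_test",
    "bootstrap_loadings",
    "AscaModel",
    "AscaResults",
]


@dataclass
class SpectraSet:
    """Absorbance spectra (runs x wavelengths) plus per-run factor labels."""

    absorbance: pd.DataFrame          # index run_id, columns wavelengths (nm)
    factor_labels: pd.DataFrame       # index run_id, one column per design factor

    def __post_init__(self):
        wl = np.asarray(self.absorbance.columns, float)
        if not np.all(np.diff(wl) > 0):
            raise ValueError("wavelength grid must be strictly increasing")
        self.factor_labels = self.factor_labels.loc[self.absorbance.index]

    @property
    def wavelengths(self) -> np.ndarray:
        return np.asarray(self.absorbance.columns, float)

    @property
    def run_ids(self) -> list:
        return list(self.absorbance.index)

    def window(self, lo: float, hi: float) -> "SpectraSet":
        """Restrict to wavelengths in [lo, hi] (default analysis: 220-400 nm)."""
        wl = self.wavelengths
        keep = (wl >= lo) & (wl <= hi)
        return SpectraSet(self.absorbance.loc[:, self.absorbance.columns[keep]],
                          self.factor_labels)


def snv(spectra: SpectraSet) -> SpectraSet:
    """Standard Normal Variate: standardize each spectrum across wavelengths.

    Removes multiplicative scatter (gain) and additive baseline offsets;
    a*x + b maps to the same output as x for a > 0. Uses the n-1
    standard deviation. Idempotent up to the (fixed) per-row rescaling.
    """
    X = spectra.absorbance.to_numpy(float)
    if X.shape[1] < 2:
        raise ValueError("SNV needs at least 2 wavelengths per spectrum")
    sd = X.std(axis=1, ddof=1)
    flat = np.where(sd == 0)[0]
    if len(flat):
        raise FlatSpectrumError(spectra.absorbance.index[flat[0]])
    out = (X - X.mean(axis=1, keepdims=True)) / sd[:, None]
    return SpectraSet(pd.DataFrame(out, index=spectra.absorbance.index,
                                   columns=spectra.absorbance.columns),
                      spectra.factor_labels)


# ---------------------------------------------------------------------------
# decomposition internals (integer-coded, numpy-only for permutation speed)

def _encode(labels: pd.DataFrame):
    codes = np.empty((len(labels), labels.shape[1]), dtype=np.int64)
    levels = []
    for j, col in enumerate(labels.columns):
        cat = pd.Categorical(labels[col])
        if len(cat.categories) < 2:
            raise ValueError(f"factor {col!r} has fewer than 2 levels")
        codes[:, j] = cat.codes
        levels.append(list(cat.categories))
    return codes, levels


def _cell_means(X: np.ndarray, codes: np.ndarray, n_levels):
    """Unweighted cell means over the full factor cross; NaN for empty cells."""
    cell_id = np.ravel_multi_index(codes.T, n_levels)
    n_cells = int(np.prod(n_levels))
    sums = np.zeros((n_cells, X.shape[1]))
    counts = np.zeros(n_cells)
    np.add.at(sums, cell_id, X)
    np.add.at(counts, cell_id, 1.0)
    with np.errstate(invalid="ignore"):
        means = sums / counts[:, None]
    return means.reshape(tuple(n_levels) + (X.shape[1],)), counts.reshape(n_levels), cell_id


def _effect_rows(X: np.ndarray, codes: np.ndarray, n_levels, interactions: bool):
    """Per-run effect matrices, residual, grand mean (unweighted cell means)."""
    k = codes.shape[1]
    cmeans, counts, _ = _cell_means(X, codes, n_levels)
    present = counts > 0
    grand = np.nanmean(cmeans.reshape(-1, X.shape[1]), axis=0)

    # level means of factor j = unweighted mean of cell means at that level
    main = []
    for j in range(k):
        axes = tuple(a for a in range(k) if a != j)
        lm = np.nanmean(cmeans, axis=axes)          # levels_j x p
        main.append(lm - grand)

    effects = {j: main[j][codes[:, j]] for j in range(k)}

    inter = {}
    if interactions and k >= 2:
        for a in range(k):
            for b in range(a + 1, k):
                axes = tuple(x for x in range(k) if x not in (a, b))
                cm_ab = np.nanmean(cmeans, axis=axes) if axes else cmeans
                dev = (cm_ab - grand
                       - main[a][:, None, :]
                       - main[b][None, :, :])
                inter[(a, b)] = dev[codes[:, a], codes[:, b]]
    fitted = grand + sum(effects.values()) + (sum(inter.values()) if inter else 0.0)
    residual = X - fitted
    return grand, effects, inter, residual


def _main_effect_ss(X: np.ndarray, codes: np.ndarray, n_levels, j: int) -> float:
    """Sum of squares of factor j's main effect, from plain level means.

    Level means are simple averages of the runs at each level (not cell
    means): on a balanced layout this equals the decomposition's effect
    SS, and under label permutation it keeps the statistic exchangeable,
    which the unweighted-cell-mean estimator does not.
    """
    grand = X.mean(axis=0)
    c = codes[:, j]
    n_per_level = np.bincount(c, minlength=n_levels[j]).astype(float)
    sums = np.zeros((n_levels[j], X.shape[1]))
    np.add.at(sums, c, X)
    lm = sums / n_per_level[:, None] - grand
    return float((n_per_level * (lm ** 2).sum(axis=1)).sum())


@dataclass
class AscaDecomposition:
    """Additive decomposition of a spectra matrix by design terms."""

    grand_mean: pd.Series
    effects: dict = field(default_factory=dict)     # term -> runs x wavelengths DataFrame
    residual: pd.DataFrame = None
    effect_ss: dict = field(default_factory=dict)
    ss_total: float = 0.0                            # about the grand mean
    factor_labels: pd.DataFrame = None

    @property
    def effect_variance_pct(self) -> pd.Series:
        terms = list(self.effects) + ["residual"]
        ss = [self.effect_ss[t] for t in self.effects]
        ss.append(float((self.residual.to_numpy() ** 2).sum()))
        return pd.Series(100.0 * np.asarray(ss) / self.ss_total, index=terms)

    def reconstruct(self) -> pd.DataFrame:
        total = self.residual.copy()
        for m in self.effects.values():
            total = total + m
        return total + self.grand_mean


def asca_decompose(spectra: SpectraSet, interactions: bool = False) -> AscaDecomposition:
    """Decompose the spectra into design-term effect matrices (main effects
    by default; two-way interactions optional)."""
    X = spectra.absorbance.to_numpy(float)
    labels = spectra.factor_labels
    codes, levels = _encode(labels)
    n_levels = [len(l) for l in levels]
    grand, eff, inter, resid = _effect_rows(X, codes, n_levels, interactions)
    idx, cols = spectra.absorbance.index, spectra.absorbance.columns
    effects = {labels.columns[j]: pd.DataFrame(eff[j], index=idx, columns=cols)
               for j in range(len(n_levels))}
    for (a, b), m in inter.items():
        effects[f"{labels.columns[a]}:{labels.columns[b]}"] = pd.DataFrame(
            m, index=idx, columns=cols)
    decomp = AscaDecomposition(
        grand_mean=pd.Series(grand, index=cols),
        effects=effects,
        residual=pd.DataFrame(resid, index=idx, columns=cols),
        effect_ss={t: float((m.to_numpy() ** 2).sum()) for t, m in effects.items()},
        ss_total=float(((X - grand) ** 2).sum()),
        factor_labels=labels,
    )
    return decomp


def _svd_pca(M: np.ndarray, n_components: int):
    U, s, Vt = np.linalg.svd(M, full_matrices=False)
    rank = int((s > s[0] * 1e-12).sum()) if len(s) and s[0] > 0 else 0
    if n_components > max(rank, 1):
        raise ValueError(f"requested {n_components} components but effect rank is {rank}")
    for k in range(n_components):
        j = np.argmax(np.abs(Vt[k]))
        if Vt[k, j] < 0:
            Vt[k] *= -1.0
            U[:, k] *= -1.0
    tot = (s ** 2).sum()
    evp = 100.0 * s[:n_components] ** 2 / tot if tot > 0 else np.zeros(n_components)
    return U[:, :n_components] * s[:n_components], Vt[:n_components].T, evp


def effect_pca(decomp: AscaDecomposition, term: str, n_components: int = 2) -> PcaModel:
    """PCA of one effect matrix, plus residual-augmented score projections.

    The returned model's ``scores`` hold the level-mean scores per run;
    an extra attribute ``projected_scores`` carries (effect + residual)
    rows projected on the same loadings, so score plots can show the
    per-sample scatter around each level mean.
    """
    M = decomp.effects[term]
    scores, loadings, evp = _svd_pca(M.to_numpy(float), n_components)
    comp = [f"SC{i + 1}" for i in range(n_components)]
    model = PcaModel(
        scores=pd.DataFrame(scores, index=M.index, columns=comp),
        loadings=pd.DataFrame(loadings, index=M.columns, columns=comp),
        explained_variance_pct=pd.Series(evp, index=comp),
        mean_=pd.Series(0.0, index=M.columns),
    )
    aug = (M.to_numpy() + decomp.residual.to_numpy()) @ loadings
    model.projected_scores = pd.DataFrame(aug, index=M.index, columns=comp)
    return model


def permutation_test(spectra: SpectraSet, term: str, n_perm: int = 999,
                     seed: int | None = None) -> float:
    """Permutation p-value for a main effect's sum of squares.

    The tested factor's level labels are randomly permuted across runs
    (other factors untouched) and the effect SS recomputed; the p-value
    is (1 + #{perm SS >= observed SS}) / (n_perm + 1).
    """
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    if seed is None:
        raise ValueError("a seed is required for the permutation test")
    labels = spectra.factor_labels
    if term not in labels.columns:
        raise ValueError(f"unknown main-effect term {term!r}")
    X = spectra.absorbance.to_numpy(float)
    codes, levels = _encode(labels)
    n_levels = [len(l) for l in levels]
    j = list(labels.columns).index(term)
    if n_levels[j] < 2:
        raise ValueError(f"factor {term!r} has fewer than 2 levels")
    obs = _main_effect_ss(X, codes, n_levels, j)
    rng = np.random.default_rng(seed)
    hits = 0
    perm_codes = codes.copy()
    for _ in range(n_perm):
        perm_codes[:, j] = rng.permutation(codes[:, j])
        if _main_effect_ss(X, perm_codes, n_levels, j) >= obs - 1e-12:
            hits += 1
    return (1.0 + hits) / (n_perm + 1.0)


def bootstrap_loadings(spectra: SpectraSet, term: str, component: int = 1,
                       n_boot: int = 1000, seed: int | None = None,
                       level: float = 0.95, interactions: bool = False) -> pd.DataFrame:
    """Bootstrap significance of an effect's PCA loadings per wavelength.

    Runs are resampled with replacement within design cells; each cycle
    the decomposition and the effect PCA are recomputed and the loading
    vector sign-aligned (dot product) to the point estimate. A
    wavelength is flagged significant when the percentile interval at
    ``level`` excludes zero. Cells with a single run make within-cell
    resampling degenerate; the procedure then falls back to a residual
    bootstrap (resampling residual rows onto the fitted decomposition)
    with a warning.

    Returns a DataFrame indexed by wavelength with columns
    ``loading``, ``ci_low``, ``ci_high``, ``significant``.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    if seed is None:
        raise ValueError("a seed is required for the bootstrap")
    rng = np.random.default_rng(seed)
    decomp = asca_decompose(spectra, interactions=interactions)
    point = effect_pca(decomp, term, component).loadings.iloc[:, component - 1].to_numpy()

    labels = spectra.factor_labels
    codes, levels = _encode(labels)
    n_levels = [len(l) for l in levels]
    cell_id = np.ravel_multi_index(codes.T, n_levels)
    cells = [np.where(cell_id == c)[0] for c in np.unique(cell_id)]
    within_cell = all(len(c) >= 2 for c in cells)
    if not within_cell:
        warnings.warn(
            "single-run design cells: falling back to a residual bootstrap",
            UserWarning, stacklevel=2,
        )
    X = spectra.absorbance.to_numpy(float)
    fitted = X - decomp.residual.to_numpy()
    n = len(X)
    # residuals are deflated by the model fit; rescale so the resampled
    # noise has the right variance (standard residual-bootstrap correction)
    df_model = 1 + sum(l - 1 for l in n_levels)
    if interactions:
        for a in range(len(n_levels)):
            for b in range(a + 1, len(n_levels)):
                df_model += (n_levels[a] - 1) * (n_levels[b] - 1)
    resid = decomp.residual.to_numpy() * np.sqrt(n / max(n - df_model, 1))

    draws = np.empty((n_boot, X.shape[1]))
    for it in range(n_boot):
        if within_cell:
            idx = np.concatenate([rng.choice(c, size=len(c), replace=True) for c in cells])
            Xb = X[idx]
            cb = codes[idx]
        else:
            Xb = fitted + resid[rng.integers(0, n, size=n)]
            cb = codes
        grand, eff, inter, _ = _effect_rows(Xb, cb, n_levels, interactions)
        j = list(labels.columns).index(term)
        M = eff[j]
        _, load, _ = _svd_pca(M, component)
        v = load[:, component - 1]
        if v @ point < 0:
            v = -v
        draws[it] = v

    a = (1.0 - level) / 2.0
    lo = np.quantile(draws, a, axis=0)
    hi = np.quantile(draws, 1.0 - a, axis=0)
    return pd.DataFrame(
        {
            "loading": point,
            "ci_low": lo,
            "ci_high": hi,
            "significant": (lo > 0) | (hi < 0),
        },
        index=pd.Index(spectra.wavelengths, name="wavelength_nm"),
    )


class AscaModel:
    """ASCA of a spectra set (statsmodels style): ``fit()`` -> AscaResults."""

    def __init__(self, spectra: SpectraSet, interactions: bool = False,
                 apply_snv: bool = True, window: tuple[float, float] | None = (220.0, 400.0)):
        s = spectra
        if window is not None:
            s = s.window(*window)
        if apply_snv:
            s = snv(s)
        self.spectra = s
        self.interactions = interactions

    def fit(self) -> "AscaResults":
        return AscaResults(self, asca_decompose(self.spectra, self.interactions))


class AscaResults:
    """Fitted ASCA decomposition with significance machinery attached."""

    def __init__(self, model: AscaModel, decomposition: AscaDecomposition):
        self.model = model
        self.decomposition = decomposition

    @property
    def effect_variance_pct(self) -> pd.Series:
        return self.decomposition.effect_variance_pct

    def effect_pca(self, term: str, n_components: int = 2) -> PcaModel:
        return effect_pca(self.decomposition, term, n_components)

    def permutation_test(self, term: str, n_perm: int = 999, seed: int | None = None) -> float:
        return permutation_test(self.model.spectra, term, n_perm, seed)

    def bootstrap_loadings(self, term: str, component: int = 1, n_boot: int = 1000,
                           seed: int | None = None, level: float = 0.95) -> pd.DataFrame:
        return bootstrap_loadings(self.model.spectra, term, component, n_boot,
                                  seed, level, self.model.interactions)

    def summary(self) -> str:
        pct = self.effect_variance_pct
        lines = ["ASCA decomposition", "  % variance by term:"]
        lines += [f"    {t:>12s}: {v:6.2f}%" for t, v in pct.items()]
        return "\n".join(lines)
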