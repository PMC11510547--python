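"""Multiresponse reduction: autoscaled PCA and the PC1-score DOE response.

When a design produces many correlated responses (here, 18 chromatographic
peak areas per extract), optimizing each one separately is impractical.
Instead the autoscaled response table is decomposed by PCA and the scores
on the first component — a variance-maximizing linear combination of all
peaks — serve as a single composite "extract quality" response for the
response-surface model. The scores are sign-oriented so that the majority
of PC1 loadings are positive: a high score then reads as "more of most
compounds", independent of SVD sign conventions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import ZeroVarianceError

__all__ = ["autoscale", "pca", "pc1_response", "PcaModel"]


def autoscale(table: pd.DataFrame) -> pd.DataFrame:
    """Column-wise standardization to mean 0, sd 1 (n-1 denominator)."""
    sd = table.std(ddof=1)
    zero = sd[sd == 0]
    if len(zero):
        raise ZeroVarianceError(zero.index[0])
    return (table - table.mean()) / sd


@dataclass
class PcaModel:
    """PCA of a runs x responses table.

    scores : DataFrame runs x components (PC1, PC2, ...)
    loadings : DataFrame responses x components, columns orthonormal
    explained_variance_pct : Series, non-increasing, sums to <= 100
    mean_ : Series, column means removed before decomposition
    """

    scores: pd.DataFrame
    loadings: pd.DataFrame
    explained_variance_pct: pd.Series
    mean_: pd.Series

    def reconstruct(self) -> pd.DataFrame:
        """scores @ loadings' + mean; exact when all components are kept."""
        rec = self.scores.to_numpy() @ self.loadings.to_numpy().T
        return pd.DataFrame(rec, index=self.scores.index,
                            columns=self.loadings.index) + self.mean_


def pca(table: pd.DataFrame, n_components: int | None = None) -> PcaModel:
    """SVD-based PCA of a (typically autoscaled) table.

    Explained variance per component is the squared singular value as a
    fraction of the total. Component signs follow the convention that the
    largest-magnitude loading of each component is positive, which makes
    results reproducible across SVD implementations.
    """
    X = table.to_numpy(float)
    n, p = X.shape
    max_comp = min(n - 1, p)
    if n_components is None:
        n_components = max_comp
    if not 1 <= n_components <= max_comp:
        raise ValueError(f"n_components must be in [1, {max_comp}], got {n_components}")
    mean = X.mean(axis=0)
    Xc = X - mean
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    # deterministic sign: largest |loading| positive per component
    for k in range(len(s)):
        j = np.argmax(np.abs(Vt[k]))
        if Vt[k, j] < 0:
            Vt[k] *= -1.0
            U[:, k] *= -1.0
    evp = 100.0 * s ** 2 / (s ** 2).sum() if (s ** 2).sum() > 0 else np.zeros_like(s)
    comp = [f"PC{i + 1}" for i in range(n_components)]
    scores = pd.DataFrame((U[:, :n_components] * s[:n_components]),
                          index=table.index, columns=comp)
    loadings = pd.DataFrame(Vt[:n_components].T, index=table.columns, columns=comp)
    return PcaModel(
        scores=scores,
        loadings=loadings,
        explained_variance_pct=pd.Series(evp[:n_components], index=comp),
        mean_=pd.Series(mean, index=table.columns),
    )


def pc1_response(model: PcaModel) -> pd.Series:
    """PC1 scores oriented so most loadings are positive (the DOE response).

    Scores and loadings flip together, so the model is unchanged. An
    exact 50/50 sign split is broken by the sign of the largest-magnitude
    loading. Raw (unscaled) scores are returned: biplot scalings change
    the display, not the response.
    """
    load = model.loadings["PC1"].to_numpy()
    n_pos = int((load > 0).sum())
    n_neg = int((load < 0).sum())
    if n_pos > n_neg:
        sign = 1.0
    elif n_neg > n_pos:
        sign = -1.0
    else:
        sign = 1.0 if load[np.argmax(np.abs(load))] > 0 else -1.0
    if sign < 0:
        model.loadings["PC1"] *= -1.0
        model.scores["PC1"] *= -1.0
    return model.scores["PC1"].copy()
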