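"""Second-order response-surface modelling with pooled-variance inference.

The model is the full quadratic polynomial in coded factor levels

    Y = b0 + sum_i bi Xi + sum_{i<j} bij Xi Xj + sum_i bii Xi^2

fitted by ordinary least squares on the coded model matrix. Coefficient
significance is judged by a t-test whose standard deviation is

    S_c = sqrt(S_pooled^2 * C_ii)

where S_pooled^2 is the pooled pure-error variance estimated from
replicated runs (degrees of freedom = sum over replicate groups of
n_g - 1) and C_ii is the corresponding diagonal element of (M'M)^-1.
Testing against replicate-based pure error rather than the residual mean
square keeps the test honest when the model itself is in doubt; the
residual-based test is available via ``variance="residual"``.

Model reduction follows the hierarchy convention: linear terms and the
intercept are always retained; non-significant quadratic terms are
removed; a non-significant interaction Xi*Xj is removed only once both
Xi^2 and Xj^2 are gone. The model is refitted and retested after every
elimination until stable.

The ANOVA table splits the residual into lack of fit and pure error and
reports the upper-tail F tests (Regression MS / Residual MS and
Lack-of-fit MS / Pure-error MS).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .design import DesignMatrix, coded_to_natural
from .exceptions import (
    DegenerateVarianceError,
    NoPureErrorError,
    SingularDesignError,
)

__all__ = [
    "full_quadratic_terms",
    "build_model_matrix",
    "pooled_variance",
    "fit_quadratic",
    "coefficient_tests",
    "reduce_hierarchical",
    "anova_lack_of_fit",
    "anova_from_components",
    "predict_and_optimize",
    "ResponseSurfaceModel",
    "ResponseSurfaceResults",
]

_ALPHA_DEFAULT = 0.05


def full_quadratic_terms(factor_names) -> list[str]:
    """Canonical term order: 1, linears, two-way interactions, quadratics."""
    names = list(factor_names)
    terms = ["1"] + names
    terms += [f"{a}*{b}" for a, b in itertools.combinations(names, 2)]
    terms += [f"{n}^2" for n in names]
    return terms


def _term_column(term: str, coded: pd.DataFrame) -> np.ndarray:
    if term == "1":
        return np.ones(len(coded))
    if term.endswith("^2"):
        return coded[term[:-2]].to_numpy() ** 2
    if "*" in term:
        a, b = term.split("*")
        return coded[a].to_numpy() * coded[b].to_numpy()
    return coded[term].to_numpy()


def build_model_matrix(coded: pd.DataFrame, terms) -> np.ndarray:
    """Runs x terms model matrix from coded levels."""
    return np.column_stack([_term_column(t, coded) for t in terms])


def _collinear_terms(M: np.ndarray, terms) -> list[str]:
    # columns that add no rank beyond the preceding ones
    bad = []
    for j in range(M.shape[1]):
        sub = M[:, : j + 1]
        if np.linalg.matrix_rank(sub) <= np.linalg.matrix_rank(M[:, :j]):
            bad.append(terms[j])
    return bad


def pooled_variance(response, replicate_groups) -> tuple[float, int]:
    """Pooled pure-error variance and its degrees of freedom.

    S_pooled^2 = sum_g SS_within_g / sum_g (n_g - 1), over groups with
    at least two runs. Raises :class:`NoPureErrorError` when no
    condition is replicated.
    """
    y = pd.Series(np.asarray(response, float), index=pd.Index(replicate_groups, name="group"))
    ss, df = 0.0, 0
    for _, vals in y.groupby(level="group"):
        if len(vals) >= 2:
            ss += ((vals - vals.mean()) ** 2).sum()
            df += len(vals) - 1
    if df == 0:
        raise NoPureErrorError("no replicated condition: pure error cannot be estimated")
    return float(ss / df), int(df)


@dataclass
class QuadraticModel:
    """Fitted quadratic surface: coefficients, their C_ii, and residual stats."""

    terms: list[str]
    params: pd.Series          # coefficient per term
    cii: pd.Series             # diag of (M'M)^-1 per term
    mse: float                 # residual mean square
    df_resid: int
    ss_resid: float
    ss_total: float            # about the response mean
    n_obs: int

    @property
    def rsquared(self) -> float:
        return 1.0 - self.ss_resid / self.ss_total

    @property
    def rsquared_adj(self) -> float:
        n, p = self.n_obs, len(self.terms)
        return 1.0 - (self.ss_resid / (n - p)) / (self.ss_total / (n - 1))


def fit_quadratic(design: DesignMatrix, response, terms=None) -> QuadraticModel:
    """OLS fit of the quadratic surface on the coded model matrix.

    The solve uses a QR decomposition (numerically stable); C_ii is
    reported from the explicit inverse cross-product since the pooled
    t-test needs it.
    """
    if terms is None:
        terms = full_quadratic_terms(design.coded.columns)
    terms = list(terms)
    y = np.asarray(response, float)
    if len(y) != design.n_runs:
        raise ValueError("response length does not match the number of runs")
    if len(y) < len(terms):
        raise ValueError(f"{len(y)} runs cannot support {len(terms)} terms")
    M = build_model_matrix(design.coded, terms)
    if np.linalg.matrix_rank(M) < M.shape[1]:
        raise SingularDesignError(_collinear_terms(M, terms))
    q, r = np.linalg.qr(M)
    b = np.linalg.solve(r, q.T @ y)
    cii = np.diag(np.linalg.inv(M.T @ M))
    fitted = M @ b
    ss_resid = float(((y - fitted) ** 2).sum())
    ss_total = float(((y - y.mean()) ** 2).sum())
    df_resid = len(y) - len(terms)
    mse = ss_resid / df_resid if df_resid > 0 else np.nan
    return QuadraticModel(
        terms=terms,
        params=pd.Series(b, index=terms),
        cii=pd.Series(cii, index=terms),
        mse=mse,
        df_resid=df_resid,
        ss_resid=ss_resid,
        ss_total=ss_total,
        n_obs=len(y),
    )


def _stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def coefficient_tests(model: QuadraticModel, s_pooled2: float, df: int,
                      alpha: float = _ALPHA_DEFAULT) -> pd.DataFrame:
    """Two-sided t-tests of each coefficient against pooled pure error.

    Returns a table with estimate, S_c = sqrt(S_pooled^2 * C_ii),
    t, df, p, significance stars and the (1 - alpha) confidence interval.
    """
    if s_pooled2 < 0:
        raise ValueError("pooled variance must be nonnegative")
    if s_pooled2 == 0:
        raise DegenerateVarianceError("pooled variance is zero; t-tests undefined")
    if df < 1:
        raise ValueError("pooled degrees of freedom must be >= 1")
    sc = np.sqrt(s_pooled2 * model.cii.to_numpy())
    b = model.params.to_numpy()
    t = b / sc
    p = 2.0 * stats.t.sf(np.abs(t), df)
    half = stats.t.ppf(1 - alpha / 2.0, df) * sc
    return pd.DataFrame(
        {
            "estimate": b,
            "Sc": sc,
            "t": t,
            "df": df,
            "p": p,
            "stars": [_stars(v) for v in p],
            "ci_low": b - half,
            "ci_high": b + half,
        },
        index=pd.Index(model.terms, name="term"),
    )


def _parents(term: str):
    a, b = term.split("*")
    return f"{a}^2", f"{b}^2"


def reduce_hierarchical(design: DesignMatrix, response, s_pooled2: float, df: int,
                        terms=None, alpha: float = _ALPHA_DEFAULT):
    """Hierarchy-respecting backward elimination.

    One term is removed per pass (the least significant candidate), the
    model refitted, and the tests recomputed, until no candidate remains.
    Linear terms and the intercept are never removed; an interaction is
    eligible only when both of its quadratic parents are already out.
    """
    if terms is None:
        terms = full_quadratic_terms(design.coded.columns)
    terms = list(terms)
    while True:
        model = fit_quadratic(design, response, terms)
        tests = coefficient_tests(model, s_pooled2, df, alpha)
        candidates = []
        for t in terms:
            if t == "1" or ("*" not in t and "^2" not in t):
                continue
            if tests.loc[t, "p"] <= alpha:
                continue
            if "*" in t:
                pa, pb = _parents(t)
                if pa in terms or pb in terms:
                    continue  # protected by a retained quadratic parent
            candidates.append(t)
        if not candidates:
            return model, tests
        worst = max(candidates, key=lambda t: tests.loc[t, "p"])
        terms.remove(worst)


def anova_lack_of_fit(model: QuadraticModel, design: DesignMatrix, response) -> pd.DataFrame:
    """ANOVA with the residual split into lack of fit and pure error.

    Regression SS is about the response mean (DF = #terms - 1); pure
    error comes from the replicate groups; lack of fit is the remainder.
    """
    y = np.asarray(response, float)
    ss_reg = model.ss_total - model.ss_resid
    df_reg = len(model.terms) - 1
    try:
        ss_pe = 0.0
        df_pe = 0
        ys = pd.Series(y, index=pd.Index(design.replicate_group.to_numpy(), name="g"))
        for _, vals in ys.groupby(level="g"):
            if len(vals) >= 2:
                ss_pe += float(((vals - vals.mean()) ** 2).sum())
                df_pe += len(vals) - 1
        if df_pe == 0:
            raise NoPureErrorError
        have_pe = True
    except NoPureErrorError:
        have_pe = False
    return anova_from_components(
        ss_reg, df_reg, model.ss_resid, model.df_resid,
        ss_lof=model.ss_resid - ss_pe if have_pe else None,
        df_lof=model.df_resid - df_pe if have_pe else None,
        ss_pe=ss_pe if have_pe else None,
        df_pe=df_pe if have_pe else None,
    )


def anova_from_components(ss_reg, df_reg, ss_res, df_res,
                          ss_lof=None, df_lof=None, ss_pe=None, df_pe=None) -> pd.DataFrame:
    """Assemble the ANOVA / lack-of-fit table from sums of squares.

    Mean squares are SS/DF; F_regression = MS_reg / MS_res with an
    upper-tail p from F(df_reg, df_res); F_lof = MS_lof / MS_pe with p
    from F(df_lof, df_pe). Also usable directly on published SS/DF pairs.
    """
    rows = {}
    ms_reg, ms_res = ss_reg / df_reg, ss_res / df_res
    f_reg = ms_reg / ms_res
    rows["Regression"] = (df_reg, ss_reg, ms_reg, f_reg, float(stats.f.sf(f_reg, df_reg, df_res)))
    rows["Residual"] = (df_res, ss_res, ms_res, np.nan, np.nan)
    rows["Total"] = (df_reg + df_res, ss_reg + ss_res, np.nan, np.nan, np.nan)
    if ss_lof is not None and df_pe and df_lof and df_lof > 0:
        ms_lof, ms_pe = ss_lof / df_lof, ss_pe / df_pe
        f_lof = ms_lof / ms_pe
        rows["Lack of fit"] = (df_lof, ss_lof, ms_lof, f_lof,
                               float(stats.f.sf(f_lof, df_lof, df_pe)))
        rows["Pure error"] = (df_pe, ss_pe, ms_pe, np.nan, np.nan)
    return pd.DataFrame(rows, index=["df", "sum_sq", "mean_sq", "F", "p"]).T


def predict_and_optimize(model: QuadraticModel, design: DesignMatrix,
                         grid_step: float = 0.05, fixed: dict | None = None):
    """Evaluate the surface on a coded grid and locate the maximum.

    ``fixed`` pins factors at given coded levels (as in a contour plot at
    maximum quantity). Returns (grid DataFrame with a ``prediction``
    column in natural units, argmax natural-level dict, predicted value).
    """
    if not 0 < grid_step <= 2:
        raise ValueError("grid_step must be in (0, 2]")
    fixed = fixed or {}
    names = [f.name for f in design.factors]
    axis = np.arange(-1.0, 1.0 + grid_step / 2, grid_step)
    axes = [np.array([float(fixed[n])]) if n in fixed else axis for n in names]
    mesh = np.meshgrid(*axes, indexing="ij")
    coded = pd.DataFrame({n: m.ravel() for n, m in zip(names, mesh)})
    M = build_model_matrix(coded, model.terms)
    pred = M @ model.params.to_numpy()
    grid = coded_to_natural(coded, design.factors)
    grid["prediction"] = pred
    k = int(np.argmax(pred))
    argmax = {n: float(grid.iloc[k][n]) for n in names}
    return grid, argmax, float(pred[k])


class ResponseSurfaceModel:
    """Quadratic response-surface model on a coded design (statsmodels style).

    Parameters
    ----------
    design : DesignMatrix
    response : array-like, aligned with ``design`` runs
    terms : list of term labels, default the full 10-term quadratic

    ``fit()`` returns a :class:`ResponseSurfaceResults`.
    """

    def __init__(self, design: DesignMatrix, response, terms=None):
        self.design = design
        self.response = np.asarray(response, float)
        self.terms = list(terms) if terms is not None else full_quadratic_terms(
            design.coded.columns)

    @classmethod
    def from_frame(cls, design: DesignMatrix, frame: pd.DataFrame, response_col: str,
                   terms=None) -> "ResponseSurfaceModel":
        """Build from a table indexed by run_id, aligning on the design's runs."""
        y = frame.loc[design.run_ids, response_col]
        return cls(design, y.to_numpy(), terms)

    def fit(self, alpha: float = _ALPHA_DEFAULT, reduce: bool = False,
            variance: str = "pooled") -> "ResponseSurfaceResults":
        """Fit by OLS; optionally reduce hierarchically at level ``alpha``.

        ``variance`` selects the error estimate for the coefficient
        t-tests: ``"pooled"`` (replicate-based, the default) or
        ``"residual"`` (MSE with residual DF).
        """
        if variance not in ("pooled", "residual"):
            raise ValueError("variance must be 'pooled' or 'residual'")
        if variance == "pooled":
            s2, df = pooled_variance(self.response, self.design.replicate_group)
        else:
            base = fit_quadratic(self.design, self.response, self.terms)
            s2, df = base.mse, base.df_resid
        if reduce:
            qm, tests = reduce_hierarchical(self.design, self.response, s2, df,
                                            self.terms, alpha)
        else:
            qm = fit_quadratic(self.design, self.response, self.terms)
            tests = coefficient_tests(qm, s2, df, alpha)
        return ResponseSurfaceResults(self, qm, tests, s2, df, alpha, variance)


class ResponseSurfaceResults:
    """Fitted surface: coefficients, pooled-variance t-tests, ANOVA, optimum."""

    def __init__(self, model, quadratic, tests, s_pooled2, df_pooled, alpha, variance):
        self.model = model
        self.quadratic = quadratic
        self.coef_table = tests
        self.s_pooled2 = s_pooled2
        self.df_pooled = df_pooled
        self.alpha = alpha
        self.variance_source = variance

    # -- statsmodels-flavoured accessors -------------------------------
    @property
    def terms(self):
        return list(self.quadratic.terms)

    @property
    def params(self) -> pd.Series:
        return self.quadratic.params

    @property
    def bse(self) -> pd.Series:
        return self.coef_table["Sc"]

    @property
    def tvalues(self) -> pd.Series:
        return self.coef_table["t"]

    @property
    def pvalues(self) -> pd.Series:
        return self.coef_table["p"]

    @property
    def rsquared(self) -> float:
        return self.quadratic.rsquared

    @property
    def rsquared_adj(self) -> float:
        return self.quadratic.rsquared_adj

    def conf_int(self) -> pd.DataFrame:
        return self.coef_table[["ci_low", "ci_high"]]

    def anova(self) -> pd.DataFrame:
        return anova_lack_of_fit(self.quadratic, self.model.design, self.model.response)

    def predict(self, coded: pd.DataFrame) -> np.ndarray:
        M = build_model_matrix(coded, self.terms)
        return M @ self.params.to_numpy()

    def optimize(self, grid_step: float = 0.05, fixed: dict | None = None):
        return predict_and_optimize(self.quadratic, self.model.design, grid_step, fixed)

    def summary(self) -> str:
        lines = [
            "Response-surface model (coded levels)",
            f"  runs: {self.quadratic.n_obs}   terms: {len(self.terms)}   "
            f"R2: {self.rsquared:.4f}   adj R2: {self.rsquared_adj:.4f}",
            f"  coefficient variance: {self.variance_source} "
            f"(S^2 = {self.s_pooled2:.6g}, df = {self.df_pooled})",
            "",
            self.coef_table.round(6).to_string(),
        ]
        try:
            lines += ["", self.anova().round(4).to_string()]
        except NoPureErrorError:
            lines += ["", "(no replicates: lack-of-fit split unavailable)"]
        return "\n".join(lines)
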