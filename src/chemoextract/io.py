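"""CSV readers/writers, run configuration, and the end-to-end pipeline.

All tables are plain CSV (RFC 4180, '.' decimal separator, UTF-8).
Output files carry a comment header with the package version, a hash of
the configuration, and the seeds used, so results are traceable; readers
skip '#' comment lines.

Schemas
-------
design    run_id, <factor columns...>, [replicate_group]   (natural units)
responses run_id, <named response columns...>
spectra   wavelength_nm, <one column per run>
dpph      concentration_mg_per_ml, t0, t1                  (replicate rows)
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .design import DesignMatrix, FactorSpec, natural_to_coded
from .dpph import DpphCalibration
from .exceptions import SchemaError
from .multiresponse import autoscale, pca, pc1_response
from .rsm import ResponseSurfaceModel
from .spectral_asca import AscaModel, SpectraSet

__all__ = ["load_table", "load_design", "write_table", "RunConfig", "run_pipeline"]

log = logging.getLogger("chemoextract")


def _read_csv(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"file not found: {path}")
    try:
        return pd.read_csv(path, comment="#")
    except Exception as exc:  # malformed CSV
        raise SchemaError(f"{path}: cannot parse CSV ({exc})") from exc


def _require_columns(df: pd.DataFrame, cols, path):
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")


def _require_numeric(df: pd.DataFrame, cols, path):
    for c in cols:
        vals = pd.to_numeric(df[c], errors="coerce")
        bad = df.index[vals.isna() & df[c].notna()]
        if len(bad):
            raise SchemaError(f"{path}: non-numeric cell in column {c!r}, row {bad[0]}")
        if df[c].isna().any():
            raise SchemaError(f"{path}: missing value in column {c!r}")
        df[c] = vals


def load_design(path, factors: list[FactorSpec] | None = None) -> DesignMatrix:
    """Read a natural-unit design CSV into a :class:`DesignMatrix`.

    Without explicit ``factors``, each factor's bounds are taken from the
    column's min/max (a DOE spans its domain by construction).
    """
    df = _read_csv(path)
    _require_columns(df, ["run_id"], path)
    if df["run_id"].duplicated().any():
        dup = df.loc[df["run_id"].duplicated(), "run_id"].iloc[0]
        raise SchemaError(f"{path}: duplicated run_id {dup!r}")
    df = df.set_index("run_id")
    factor_cols = [c for c in df.columns if c != "replicate_group"]
    if factors is None:
        _require_numeric(df, factor_cols, path)
        factors = [FactorSpec(c, float(df[c].min()), float(df[c].max())) for c in factor_cols]
    else:
        names = [f.name for f in factors]
        _require_columns(df, names, path)
        _require_numeric(df, names, path)
    coded = natural_to_coded(df[[f.name for f in factors]], factors)
    groups = df["replicate_group"] if "replicate_group" in df.columns else None
    return DesignMatrix(factors, coded, groups)


def load_table(path, schema: str):
    """Read and validate one of the pipeline's input tables.

    ``schema`` is one of ``design``, ``responses``, ``spectra``, ``dpph``.
    """
    if schema == "design":
        return load_design(path)
    df = _read_csv(path)
    if schema == "responses":
        _require_columns(df, ["run_id"], path)
        if df["run_id"].duplicated().any():
            raise SchemaError(f"{path}: duplicated run_id")
        df = df.set_index("run_id")
        if df.shape[1] < 2 or len(df) < 2:
            raise SchemaError(f"{path}: need >=2 runs and >=2 responses")
        _require_numeric(df, list(df.columns), path)
        return df
    if schema == "spectra":
        _require_columns(df, ["wavelength_nm"], path)
        _require_numeric(df, list(df.columns), path)
        df = df.set_index("wavelength_nm")
        return df.T  # runs x wavelengths
    if schema == "dpph":
        cols = ["concentration_mg_per_ml", "t0", "t1"]
        _require_columns(df, cols, path)
        _require_numeric(df, cols, path)
        if (df["concentration_mg_per_ml"] <= 0).any():
            raise SchemaError(f"{path}: concentrations must be positive")
        return df
    raise ValueError(f"unknown schema {schema!r}")


def write_table(df: pd.DataFrame, path, config_hash: str = "", seeds=None, index=True):
    """Write a CSV with a traceability comment header."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# chemoextract {__version__}; config_hash={config_hash}; "
                 f"seeds={seeds}\n")
        df.to_csv(fh, index=index)


@dataclass
class RunConfig:
    """Declarative configuration of a full pipeline run."""

    design: str = ""
    responses: str = ""
    spectra: str = ""
    dpph: str = ""
    outdir: str = "chemoextract_out"
    alpha: float = 0.05
    reduce: bool = True
    grid_step: float = 0.05
    n_perm: int = 999
    n_boot: int = 1000
    seed: int = 0
    wavelength_window: tuple[float, float] = (220.0, 400.0)
    asca_terms: list[str] = field(default_factory=list)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise SchemaError(f"unknown config keys: {sorted(unknown)}")
        if "wavelength_window" in raw:
            raw["wavelength_window"] = tuple(raw["wavelength_window"])
        return cls(**raw)

    def to_yaml(self, path):
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["wavelength_window"] = list(d["wavelength_window"])
        return d

    def digest(self) -> str:
        return hashlib.sha256(json.dumps(self.to_dict(), sort_keys=True)
                              .encode()).hexdigest()[:12]


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages and write all result files.

    Stages (each optional, driven by which input paths are set):

    1. responses + design: autoscaled PCA, PC1 response, quadratic fit
       with hierarchical reduction, ANOVA, optimum.
    2. spectra + design: SNV + ASCA with permutation and bootstrap
       significance per term.
    3. dpph: calibration line and IC50.

    Returns the summary dict, which is also written as summary.json.
    """
    if not any([config.responses, config.spectra, config.dpph]):
        raise SchemaError("empty config: no input stage requested")
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    h = config.digest()
    seeds = {"seed": config.seed}
    summary: dict = {"config_hash": h, "version": __version__, "seeds": seeds}

    design = None
    if config.design:
        log.info("loading design from %s", config.design)
        design = load_table(config.design, "design")

    if config.responses:
        if design is None:
            raise SchemaError("responses stage requires a design file")
        _stage(summary, "rsm", _run_rsm, config, design, out, h)
    if config.spectra:
        if design is None:
            raise SchemaError("asca stage requires a design file")
        _stage(summary, "asca", _run_asca, config, design, out, h)
    if config.dpph:
        _stage(summary, "dpph", _run_dpph, config, design, out, h)

    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    return summary


def _stage(summary, name, fn, config, design, out, h):
    try:
        summary[name] = fn(config, design, out, h)
    except Exception as exc:
        raise RuntimeError(f"stage {name!r} failed: {exc}") from exc


def _run_rsm(config: RunConfig, design: DesignMatrix, out: Path, h: str) -> dict:
    table = load_table(config.responses, "responses").loc[design.run_ids]
    model = pca(autoscale(table))
    y = pc1_response(model)
    write_table(pd.DataFrame({"PC1": y}), out / "pc1_scores.csv", h)
    write_table(model.loadings, out / "pc1_loadings.csv", h)
    res = ResponseSurfaceModel(design, y.to_numpy()).fit(
        alpha=config.alpha, reduce=config.reduce)
    write_table(res.coef_table, out / "coefficients.csv", h)
    write_table(res.anova(), out / "anova.csv", h)
    grid, argmax, best = res.optimize(grid_step=config.grid_step)
    write_table(grid, out / "surface.csv", h, index=False)
    return {
        "pc1_variance_pct": float(model.explained_variance_pct.iloc[0]),
        "terms": res.terms,
        "adjusted_r2": res.rsquared_adj,
        "optimum": argmax,
        "optimum_prediction": best,
    }


def _run_asca(config: RunConfig, design: DesignMatrix, out: Path, h: str) -> dict:
    wide = load_table(config.spectra, "spectra").loc[design.run_ids]
    wide.columns = [float(c) for c in wide.columns]
    labels = design.natural.round(9).astype(str)
    terms = config.asca_terms or list(labels.columns)
    spectra = SpectraSet(wide, labels[terms])
    res = AscaModel(spectra, window=config.wavelength_window).fit()
    info = {"effect_variance_pct": res.effect_variance_pct.to_dict(),
            "permutation_p": {}, "n_perm": config.n_perm, "n_boot": config.n_boot}
    rows = []
    for term in terms:
        p = res.permutation_test(term, n_perm=config.n_perm, seed=config.seed)
        info["permutation_p"][term] = p
        boot = res.bootstrap_loadings(term, component=1, n_boot=config.n_boot,
                                      seed=config.seed)
        sc = res.effect_pca(term, 1)
        df = boot.copy()
        df.insert(0, "term", term)
        rows.append(df)
        write_table(sc.scores, out / f"asca_scores_{term}.csv", h,
                    seeds={"seed": config.seed})
    write_table(pd.concat(rows), out / "asca_loadings.csv", h,
                seeds={"seed": config.seed})
    write_table(res.effect_variance_pct.to_frame("variance_pct"),
                out / "asca_variance.csv", h)
    return info


def _run_dpph(config: RunConfig, design, out: Path, h: str) -> dict:
    records = load_table(config.dpph, "dpph")
    line = DpphCalibration(records).fit()
    write_table(pd.DataFrame([{
        "slope": line.slope, "intercept": line.intercept,
        "r_squared": line.r_squared, "ic50": line.ic50, "ic50_se": line.ic50_se,
    }]), out / "dpph_calibration.csv", h, index=False)
    return {"ic50": line.ic50, "ic50_se": line.ic50_se, "r_squared": line.r_squared}
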