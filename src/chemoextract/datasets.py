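"""Packaged reference tables from the chamomile extraction study.

Three small CSV fixtures ship with the package:

* ``antioxidant_ccd.csv`` — the 22-run face-centered CCD (natural factor levels
  Q in g, t in min, T in degC) with the DPPH absorbance-drop response Y
  and the replicate grouping (six duplicated "bis" conditions);
* ``dpph_inhibition.csv`` — five (concentration, mean inhibition %) points
  of the optimal-extract DPPH calibration, with their reported spreads;
* ``anova_components.csv`` — published SS/DF pairs of the factorial
  model's ANOVA (regression/residual and lack-of-fit/pure-error splits).
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .design import DesignMatrix, natural_to_coded
from .synthetic import ccd_factors

__all__ = ["load_antioxidant_ccd", "load_dpph_points", "load_anova_components"]


def _read(name: str) -> pd.DataFrame:
    with resources.files("chemoextract.fixtures").joinpath(name).open() as fh:
        return pd.read_csv(fh)


def load_antioxidant_ccd() -> tuple[DesignMatrix, pd.Series]:
    """The antioxidant CCD: (design with replicate groups, response Y)."""
    df = _read("antioxidant_ccd.csv").set_index("run_id")
    factors = ccd_factors()
    coded = natural_to_coded(df[[f.name for f in factors]], factors)
    design = DesignMatrix(factors, coded, df["replicate_group"])
    return design, df["Y"]


def load_dpph_points() -> pd.DataFrame:
    """Five mean inhibition points (concentration mg/mL, %, reported sd)."""
    return _read("dpph_inhibition.csv")


def load_anova_components() -> pd.DataFrame:
    """Published factorial ANOVA sums of squares, indexed by source."""
    return _read("anova_components.csv").set_index("source")
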