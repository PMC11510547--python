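"""Experimental-design construction for three-factor extraction studies.

Two designs are supported, both on coded levels in [-1, +1] with the
face-centered axial distance fixed at 1:

* the three-level full factorial (3^3 = 27 distinct points), optionally
  with replicate runs appended at the 8 vertices and the center;
* the face-centered central composite design (FCC/CCD): 8 vertices,
  6 face centers and 1 center point (15 distinct points).

Coded and natural units are linked by the affine map
``coded = (natural - mid) / half_range`` per factor, so coded -1/0/+1
correspond to the low/mid/high natural levels.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import OutOfDomainWarning, UnsupportedDesignError

__all__ = [
    "FactorSpec",
    "DesignMatrix",
    "build_full_factorial",
    "build_face_centered_ccd",
    "transform_levels",
    "coded_to_natural",
    "natural_to_coded",
    "max_variance_inflation",
]


@dataclass(frozen=True)
class FactorSpec:
    """One experimental factor with its studied natural-unit range."""

    name: str
    low: float
    high: float
    unit: str = ""

    def __post_init__(self):
        if not self.low < self.high:
            raise ValueError(f"factor {self.name!r}: low ({self.low}) must be < high ({self.high})")

    @property
    def mid(self) -> float:
        return 0.5 * (self.low + self.high)

    @property
    def half_range(self) -> float:
        return 0.5 * (self.high - self.low)


@dataclass
class DesignMatrix:
    """Runs of a coded design together with the factor specifications.

    Attributes
    ----------
    factors : list of FactorSpec
        Order fixes the X1, X2, X3 assignment of the quadratic model.
    coded : pandas.DataFrame
        Runs x factors matrix of coded levels, indexed by run_id.
    replicate_group : pandas.Series
        Label shared by runs that replicate the same condition.
    """

    factors: list[FactorSpec]
    coded: pd.DataFrame
    replicate_group: pd.Series = field(default=None)

    def __post_init__(self):
        names = [f.name for f in self.factors]
        if len(set(names)) != len(names):
            raise ValueError("factor names must be unique")
        self.coded = self.coded.loc[:, names].astype(float)
        if self.replicate_group is None:
            # default: condition-based grouping (identical coded levels)
            sig = self.coded.round(12).apply(lambda r: tuple(r), axis=1)
            self.replicate_group = sig.map({s: f"g{i}" for i, s in enumerate(dict.fromkeys(sig))})
        self.replicate_group = pd.Series(self.replicate_group, index=self.coded.index)
        if (self.coded.abs() > 1 + 1e-9).any().any():
            raise ValueError("coded levels must lie in [-1, +1]")

    @property
    def run_ids(self) -> list[str]:
        return list(self.coded.index)

    @property
    def n_runs(self) -> int:
        return len(self.coded)

    @property
    def natural(self) -> pd.DataFrame:
        return coded_to_natural(self.coded, self.factors)

    def n_distinct(self) -> int:
        return len(self.coded.round(12).drop_duplicates())

    def drop_points(self, coded_points: list[tuple]) -> "DesignMatrix":
        """Remove all runs at the given coded points (aborted runs)."""
        keep = np.ones(self.n_runs, bool)
        for pt in coded_points:
            hit = np.all(np.isclose(self.coded.to_numpy(), np.asarray(pt, float)), axis=1)
            keep &= ~hit
        return DesignMatrix(self.factors, self.coded.loc[keep], self.replicate_group.loc[keep])

    def to_frame(self) -> pd.DataFrame:
        """Natural-unit design table (run_id index, factor + replicate_group columns)."""
        out = self.natural.copy()
        out["replicate_group"] = self.replicate_group
        return out


def _check_three_factors(factors):
    if len(factors) != 3:
        raise UnsupportedDesignError(
            f"only 3-factor designs are supported, got {len(factors)} factors"
        )


def _assemble(factors, points, run_prefix, replicate_vertices, replicate_center, seed):
    names = [f.name for f in factors]
    ids = [f"{run_prefix}{i + 1}" for i in range(len(points))]
    groups = list(ids)
    rows = list(points)
    if replicate_vertices or replicate_center:
        for pid, pt in zip(list(ids), list(points)):
            is_vertex = all(abs(v) == 1 for v in pt)
            is_center = all(v == 0 for v in pt)
            if (replicate_vertices and is_vertex) or (replicate_center and is_center):
                ids.append(pid + "bis")
                groups.append(pid)
                rows.append(pt)
    coded = pd.DataFrame(rows, index=ids, columns=names, dtype=float)
    groups = pd.Series(groups, index=ids)
    if seed is not None:
        order = np.random.default_rng(seed).permutation(len(coded))
        coded, groups = coded.iloc[order], groups.iloc[order]
    return DesignMatrix(list(factors), coded, groups)


def build_full_factorial(factors, replicate_vertices=False, replicate_center=False,
                         drop=None, seed=None) -> DesignMatrix:
    """Three-level full factorial: 27 distinct coded points in {-1, 0, +1}^3.

    With both replicate flags, one replicate run is appended at each of the
    8 vertices and at the center (36 runs, 27 distinct conditions).
    ``drop`` removes aborted conditions given as coded tuples. ``seed``
    randomizes run order; default is deterministic standard order.
    """
    _check_three_factors(factors)
    points = list(itertools.product((-1.0, 0.0, 1.0), repeat=3))
    dm = _assemble(factors, points, "N", replicate_vertices, replicate_center, seed)
    if drop:
        dm = dm.drop_points(drop)
    return dm


def build_face_centered_ccd(factors, replicate_vertices=False, replicate_center=False,
                            drop=None, seed=None) -> DesignMatrix:
    """Face-centered CCD: 8 vertices, 6 face centers, 1 center (15 points)."""
    _check_three_factors(factors)
    vertices = list(itertools.product((-1.0, 1.0), repeat=3))
    faces = []
    for axis in range(3):
        for s in (-1.0, 1.0):
            pt = [0.0, 0.0, 0.0]
            pt[axis] = s
            faces.append(tuple(pt))
    points = vertices + faces + [(0.0, 0.0, 0.0)]
    dm = _assemble(factors, points, "C", replicate_vertices, replicate_center, seed)
    if drop:
        dm = dm.drop_points(drop)
    return dm


def coded_to_natural(coded: pd.DataFrame, factors) -> pd.DataFrame:
    out = {}
    for f in factors:
        out[f.name] = coded[f.name] * f.half_range + f.mid
    return pd.DataFrame(out, index=coded.index)


def natural_to_coded(natural: pd.DataFrame, factors) -> pd.DataFrame:
    out = {}
    for f in factors:
        vals = natural[f.name].astype(float)
        if ((vals < f.low - 1e-9) | (vals > f.high + 1e-9)).any():
            warnings.warn(
                f"natural values for factor {f.name!r} fall outside [{f.low}, {f.high}]",
                OutOfDomainWarning,
                stacklevel=2,
            )
        out[f.name] = (vals - f.mid) / f.half_range
    return pd.DataFrame(out, index=natural.index)


def transform_levels(design: DesignMatrix, values: pd.DataFrame, direction: str) -> pd.DataFrame:
    """Affine coded<->natural transform for arbitrary level tables.

    ``direction`` is ``"coded_to_natural"`` or ``"natural_to_coded"``;
    the round trip is the identity to numerical precision.
    """
    if direction == "coded_to_natural":
        return coded_to_natural(values, design.factors)
    if direction == "natural_to_coded":
        return natural_to_coded(values, design.factors)
    raise ValueError(f"unknown direction {direction!r}")


def max_variance_inflation(design: DesignMatrix) -> float:
    """Largest variance inflation factor among the coded linear columns.

    For a perfectly orthogonal design this is exactly 1; dropped runs
    inflate it. Used to check that aborted runs did not degrade the
    design's orthogonality.
    """
    X = design.coded.to_numpy()
    vifs = []
    for j in range(X.shape[1]):
        others = np.column_stack([np.ones(len(X)), np.delete(X, j, axis=1)])
        beta, *_ = np.linalg.lstsq(others, X[:, j], rcond=None)
        resid = X[:, j] - others @ beta
        ss_tot = ((X[:, j] - X[:, j].mean()) ** 2).sum()
        r2 = 1.0 - (resid ** 2).sum() / ss_tot if ss_tot > 0 else 0.0
        vifs.append(1.0 / (1.0 - r2) if r2 < 1 else np.inf)
    return float(max(vifs))
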