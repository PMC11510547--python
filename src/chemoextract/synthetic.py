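"""Design-linked synthetic data with known ground truth.

Every pipeline stage (PC1 scoring, response-surface fitting, ASCA,
DPPH calibration) is testable without external data by generating
responses from a known quadratic surface, spectra from known absorption
bands, and assay responses from a known concave surface. Defaults
emulate the cold-water chamomile extraction study conditions: a 3-level
factorial on T (15-25 degC), t (32-72 min), Q (1.5-2.5 g) with replicated
vertices/center and two aborted runs; and a 22-run face-centered CCD on
widened ranges (T 15-35, t 32-92, Q 0.5-2.5).

Spectral features are Gaussian bands placed where the polyphenol classes
absorb: hydroxybenzoic acids near 250 and 290 nm, hydroxycinnamic acids
around 320 nm, flavones/flavonols in 330-370 nm. Band amplitudes depend
on coded factor levels; multiplicative gain and additive baseline
offsets mimic the scatter that SNV is meant to remove. Gaussian band
shapes are adequate for testing band localization; no spectro-physical
realism is claimed.

All generators are bit-reproducible given a seed, and every generator
pairs its output with the :class:`GroundTruth` that produced it.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .design import DesignMatrix, FactorSpec, build_full_factorial
from .rsm import build_model_matrix
from .spectral_asca import SpectraSet

__all__ = [
    "Band",
    "GroundTruth",
    "simulate_areas",
    "simulate_spectra",
    "simulate_dpph",
    "factorial_factors",
    "ccd_factors",
    "default_factorial_design",
    "default_ccd_design",
    "default_area_truth",
    "default_spectra_truth",
    "default_dpph_truth",
]


def factorial_factors() -> list[FactorSpec]:
    return [FactorSpec("T", 15.0, 25.0, "C"),
            FactorSpec("t", 32.0, 72.0, "min"),
            FactorSpec("Q", 1.5, 2.5, "g")]


def ccd_factors() -> list[FactorSpec]:
    return [FactorSpec("T", 15.0, 35.0, "C"),
            FactorSpec("t", 32.0, 92.0, "min"),
            FactorSpec("Q", 0.5, 2.5, "g")]


def default_factorial_design(seed: int | None = None) -> DesignMatrix:
    """Replicated 3^3 factorial with the two aborted conditions removed."""
    return build_full_factorial(
        factorial_factors(), replicate_vertices=True, replicate_center=True,
        drop=[(0, -1, -1), (0, 1, 0)], seed=seed)


_CCD_LAYOUT = [
    # (run_id, group, T, t, Q) in coded levels; replication mirrors the
    # 22-run antioxidant CCD (six duplicated conditions named "bis",
    # one vertex run independently in duplicate)
    ("C1", "C1", -1, -1, -1), ("C1bis", "C1", -1, -1, -1),
    ("C2", "C2", 1, -1, -1), ("C2bis", "C2", 1, -1, -1),
    ("C3", "C3", -1, 1, -1), ("C3bis", "C3", -1, 1, -1),
    ("C4", "C4", 1, 1, -1),
    ("C5", "C5", 0, 0, -1),
    ("C6", "C6", 1, -1, 1), ("C6bis", "C6", 1, -1, 1),
    ("C7", "C7", -1, -1, 1), ("C8", "C8", -1, -1, 1),
    ("C9", "C9", -1, 1, 1), ("C9bis", "C9", -1, 1, 1),
    ("C10", "C10", 1, 1, 1),
    ("C11", "C11", 0, 0, 1),
    ("C12", "C12", 0, 0, 0), ("C12bis", "C12", 0, 0, 0),
    ("C14", "C14", 1, 0, 0),
    ("C15", "C15", -1, 0, 0),
    ("C16", "C16", 0, 1, 0),
    ("C17", "C17", 0, -1, 0),
]


def default_ccd_design() -> DesignMatrix:
    """22-run face-centered CCD layout of the antioxidant study."""
    ids = [r[0] for r in _CCD_LAYOUT]
    coded = pd.DataFrame([r[2:] for r in _CCD_LAYOUT], index=ids,
                         columns=["T", "t", "Q"], dtype=float)
    groups = pd.Series([r[1] for r in _CCD_LAYOUT], index=ids)
    return DesignMatrix(ccd_factors(), coded, groups)


@dataclass(frozen=True)
class Band:
    """One Gaussian absorption band whose amplitude depends on the design."""

    name: str
    center_nm: float
    width_nm: float
    amplitude: float
    factor_coeffs: dict = field(default_factory=dict)   # term -> amplitude change


@dataclass
class GroundTruth:
    """Known generating parameters for one synthetic dataset."""

    true_coefficients: dict          # term -> value (shared latent surface)
    noise_sd: float = 0.0
    band_spec: tuple = ()            # Bands, for spectra
    gain_sd: float = 0.0             # multiplicative scatter, gain = 1 + N(0, sd)
    baseline_sd: float = 0.0         # additive baseline offset sd
    seed: int = 0
    latent_loadings: tuple = ()      # per-response multipliers (areas)
    t0_mean: float = 0.532           # DPPH blank absorbance, clips the response

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    def to_dict(self) -> dict:
        return asdict(self)


def _surface(design: DesignMatrix, coefficients: dict) -> np.ndarray:
    terms = list(coefficients)
    M = build_model_matrix(design.coded, terms)
    return M @ np.array([coefficients[t] for t in terms], float)


def default_area_truth(seed: int = 0, n_responses: int = 18) -> GroundTruth:
    """Latent 'extract quality' surface feeding all peak areas.

    Signs mirror the optimization findings: quality rises with quantity,
    falls with time, and the temperature-time interaction makes high
    temperature pay off only at short times (optimum at T high, t low,
    Q high). Positive per-response loadings produce the all-positive-PC1
    correlation structure.
    """
    rng = np.random.default_rng(seed)
    coeffs = {"1": 10.0, "T": 0.0, "t": -0.8, "Q": 1.2,
              "T*t": -0.7, "T^2": 0.9}
    loadings = tuple(rng.uniform(0.5, 1.5, n_responses).round(4))
    return GroundTruth(true_coefficients=coeffs, noise_sd=0.5,
                       latent_loadings=loadings, seed=seed)


def default_spectra_truth(seed: int = 0) -> GroundTruth:
    """Polyphenol-class bands with factor-dependent amplitudes.

    Flavone/flavonol absorption (330-370 nm) is stronger at the low
    temperature level and shorter times; hydroxybenzoic (250/290 nm) and
    hydroxycinnamic (320 nm) bands grow with temperature.
    """
    bands = (
        Band("hydroxybenzoic_250", 250.0, 12.0, 1.00, {"T": 0.25}),
        Band("hydroxybenzoic_290", 290.0, 12.0, 0.90, {"T": 0.20}),
        Band("hydroxycinnamic_320", 320.0, 15.0, 0.80, {"T": 0.15, "t": -0.10}),
        Band("flavone_350", 350.0, 20.0, 1.00, {"T": -0.30, "t": -0.15}),
    )
    return GroundTruth(true_coefficients={}, noise_sd=0.01, band_spec=bands,
                       gain_sd=0.15, baseline_sd=0.05, seed=seed)


def default_dpph_truth(seed: int = 0) -> GroundTruth:
    """Concave antioxidant surface: negative quadratic T and Q terms,
    negative T*t interaction, strong positive Q linear term."""
    coeffs = {"1": 0.41, "T": -0.023, "t": -0.052, "Q": 0.145,
              "T*t": -0.015, "T*Q": -0.011, "t*Q": 0.003,
              "T^2": -0.024, "t^2": -0.017, "Q^2": -0.059}
    return GroundTruth(true_coefficients=coeffs, noise_sd=0.013, seed=seed)


def simulate_areas(design: DesignMatrix, truth: GroundTruth,
                   n_responses: int = 18) -> pd.DataFrame:
    """Peak-area table: latent quality surface x positive loadings + noise.

    With ``latent_loadings`` set (the default truth), response j is
    ``loading_j * quality(run) + noise``, which correlates all responses
    positively; without loadings each response uses the shared surface
    directly.
    """
    rng = np.random.default_rng(truth.seed)
    quality = _surface(design, truth.true_coefficients)
    if truth.latent_loadings:
        if len(truth.latent_loadings) < n_responses:
            raise ValueError("truth has fewer latent loadings than responses")
        load = np.asarray(truth.latent_loadings[:n_responses], float)
    else:
        load = np.ones(n_responses)
    base = quality[:, None] * load[None, :]
    noise = rng.normal(0.0, truth.noise_sd, base.shape) if truth.noise_sd else 0.0
    cols = [f"P{j + 1}" for j in range(n_responses)]
    return pd.DataFrame(base + noise, index=design.run_ids, columns=cols)


def simulate_spectra(design: DesignMatrix, truth: GroundTruth,
                     wl_lo: float = 220.0, wl_hi: float = 400.0,
                     step: float = 1.0) -> SpectraSet:
    """UV-Vis spectra from factor-dependent Gaussian bands.

    Each run's spectrum is sum_bands amplitude(run) * exp(-(wl-c)^2/2w^2),
    multiplied by a random gain and shifted by a random baseline (the
    scatter SNV removes), plus white noise.
    """
    if not truth.band_spec:
        raise ValueError("truth.band_spec is empty")
    rng = np.random.default_rng(truth.seed)
    wl = np.arange(wl_lo, wl_hi + step / 2, step)
    n = design.n_runs
    clean = np.zeros((n, len(wl)))
    for band in truth.band_spec:
        amp = np.full(n, band.amplitude)
        if band.factor_coeffs:
            amp = amp + _surface(design, band.factor_coeffs)
        shape = np.exp(-0.5 * ((wl - band.center_nm) / band.width_nm) ** 2)
        clean += amp[:, None] * shape[None, :]
    gain = 1.0 + rng.normal(0.0, truth.gain_sd, n) if truth.gain_sd else np.ones(n)
    gain = np.clip(gain, 0.2, None)
    baseline = rng.normal(0.0, truth.baseline_sd, n) if truth.baseline_sd else np.zeros(n)
    noise = rng.normal(0.0, truth.noise_sd, clean.shape) if truth.noise_sd else 0.0
    X = gain[:, None] * clean + baseline[:, None] + noise
    absorbance = pd.DataFrame(X, index=design.run_ids, columns=wl)
    labels = design.natural.astype(str)
    return SpectraSet(absorbance, labels)


def simulate_dpph(design: DesignMatrix, truth: GroundTruth) -> pd.Series:
    """Absorbance-drop responses Y from the truth surface, clipped to [0, t0]."""
    for q in ("T^2", "Q^2"):
        if truth.true_coefficients.get(q, 0.0) >= 0:
            raise ValueError(f"dpph truth requires a negative {q} coefficient")
    rng = np.random.default_rng(truth.seed)
    y = _surface(design, truth.true_coefficients)
    if truth.noise_sd:
        y = y + rng.normal(0.0, truth.noise_sd, len(y))
    y = np.clip(y, 0.0, truth.t0_mean)
    return pd.Series(y, index=design.run_ids, name="Y")
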