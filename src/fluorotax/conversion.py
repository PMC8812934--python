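"""Core conversion: fluorescence spectra → chemotaxonomic assemblages.

An unknown nine-channel excitation spectrum f (standardized to sum 1) is
expressed as a bounded linear combination of the reference spectra F_i,

    f = Σ α_i · F_i,      0 ≤ α_i ≤ 1,

with the coefficients chosen to minimise the Euclidean residual (bounded
least squares; no simplex constraint on Σα).  The assemblage is then
reconstructed from the reference compositions as p = Σ α_i · P_i and
renormalised to proportions of total chlorophyll a.  Total chlorophyll is
estimated separately from the raw 435 nm channel via the calibration model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import lsq_linear

from .calibration import CHANNELS, CalibrationModel, estimate_tchla
from .chemotax import (
    GROUPS,
    GroupComposition,
    PigmentSample,
    RatioMatrix,
    batch_estimate,
    load_default_ratio_matrix,
)

__all__ = [
    "FluorescenceSpectrum",
    "ReferenceRecord",
    "ReferenceDatabase",
    "DecompositionResult",
    "standardize_spectrum",
    "build_reference_database",
    "decompose_spectrum",
    "reconstruct_composition",
    "convert_spectrum",
]

#: α below this is treated as inactive in diagnostics.
ALPHA_ACTIVE_TOL = 1e-6


@dataclass(frozen=True)
class FluorescenceSpectrum:
    """Nine-channel excitation fluorescence, optionally sum-standardized."""

    channels: np.ndarray  # aligned with calibration.CHANNELS
    standardized: bool = False

    def __post_init__(self) -> None:
        values = np.asarray(self.channels, dtype=float)
        if values.shape != (len(CHANNELS),):
            raise ValueError(f"expected {len(CHANNELS)} channels, got {values.shape}")
        if (values < 0).any():
            raise ValueError("fluorescence must be non-negative")
        if self.standardized and abs(values.sum() - 1.0) > 1e-9:
            raise ValueError("standardized spectrum must sum to 1")
        object.__setattr__(self, "channels", values)

    def __getitem__(self, wavelength: int) -> float:
        return float(self.channels[CHANNELS.index(wavelength)])


def standardize_spectrum(raw: FluorescenceSpectrum) -> FluorescenceSpectrum:
    """Divide every channel by the nine-channel sum so the spectrum sums to 1."""
    total = raw.channels.sum()
    if total <= 0:
        raise ValueError("cannot standardize an all-zero spectrum")
    return FluorescenceSpectrum(raw.channels / total, standardized=True)


@dataclass(frozen=True)
class ReferenceRecord:
    """A paired standardized spectrum and pigment-based composition."""

    spectrum: FluorescenceSpectrum
    composition: GroupComposition
    tchla: float
    cruise: str = ""
    station: str = ""
    depth_m: float = np.nan
    area: str = ""
    season: str = ""
    outlier: bool = False

    def __post_init__(self) -> None:
        if not self.spectrum.standardized:
            raise ValueError("reference spectra must be standardized")

    @property
    def key(self) -> tuple[str, str, float]:
        return (self.cruise, self.station, float(self.depth_m))


class ReferenceDatabase:
    """Indexed reference pairs (F_i, P_i); the active view excludes outliers.

    Record indices are stable: filtered views carry the original indices so
    coefficients can always be traced back to records.
    """

    #: columns of the CSV serialization, in order
    SPECTRUM_COLS = tuple(f"f{ch}" for ch in CHANNELS)
    META_COLS = ("tchla", "cruise", "station", "depth_m", "area", "season", "outlier")

    def __init__(self, records: list[ReferenceRecord], provenance: str = ""):
        self.records = list(records)
        self.provenance = provenance

    def __len__(self) -> int:
        return len(self.records)

    @property
    def active_indices(self) -> np.ndarray:
        return np.array([i for i, r in enumerate(self.records) if not r.outlier],
                        dtype=int)

    @property
    def n_active(self) -> int:
        return len(self.active_indices)

    def active_view(self, keep: np.ndarray | None = None) -> "ReferenceDatabase":
        """Non-outlier records, optionally restricted to ``keep`` (original indices)."""
        idx = self.active_indices
        if keep is not None:
            idx = np.intersect1d(idx, np.asarray(keep, dtype=int))
        db = ReferenceDatabase([self.records[i] for i in idx], self.provenance)
        db._original_indices = idx
        return db

    def spectra_matrix(self) -> np.ndarray:
        """Active spectra stacked as (9, n_active) — columns are references."""
        idx = self.active_indices
        return np.column_stack([self.records[i].spectrum.channels for i in idx])

    def composition_matrix(self) -> np.ndarray:
        """Active compositions stacked as (n_active, 9 groups)."""
        idx = self.active_indices
        return np.vstack([self.records[i].composition.as_array() for i in idx])

    # ---- serialization -------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            row = dict(zip(self.SPECTRUM_COLS, r.spectrum.channels))
            row.update({g: r.composition.fractions[g] for g in GROUPS})
            row.update(tchla=r.tchla, cruise=r.cruise, station=r.station,
                       depth_m=r.depth_m, area=r.area, season=r.season,
                       outlier=r.outlier)
            rows.append(row)
        return pd.DataFrame(rows)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, provenance: str = "") -> "ReferenceDatabase":
        records = []
        for _, row in df.iterrows():
            spec = FluorescenceSpectrum(
                row[list(cls.SPECTRUM_COLS)].to_numpy(float), standardized=True)
            comp = GroupComposition({g: float(row[g]) for g in GROUPS})
            records.append(ReferenceRecord(
                spectrum=spec, composition=comp, tchla=float(row["tchla"]),
                cruise=str(row["cruise"]), station=str(row["station"]),
                depth_m=float(row["depth_m"]), area=str(row["area"]),
                season=str(row["season"]), outlier=bool(row["outlier"])))
        return cls(records, provenance)


@dataclass(frozen=True)
class DecompositionResult:
    """Bounded least-squares coefficients of a spectrum over the references."""

    alphas: np.ndarray
    residual_norm: float
    n_active: int

    def __post_init__(self) -> None:
        a = np.asarray(self.alphas, dtype=float)
        if (a < -1e-12).any() or (a > 1 + 1e-9).any():
            raise ValueError("coefficients must lie in [0, 1]")
        object.__setattr__(self, "alphas", np.clip(a, 0.0, 1.0))

    @property
    def alpha_sum(self) -> float:
        return float(self.alphas.sum())


def build_reference_database(
    samples: list[PigmentSample],
    raw_spectra: list[FluorescenceSpectrum],
    calibration: CalibrationModel,
    ratios: RatioMatrix | None = None,
    provenance: str = "",
) -> ReferenceDatabase:
    """Assemble the reference database from paired pigment/fluorescence samples.

    Compositions come from the chemotaxonomic inversion, spectra are
    standardized, and pairs flagged as outliers of the TChla calibration are
    kept in the database but excluded from the active view.
    """
    if len(samples) != len(raw_spectra):
        raise ValueError("samples and spectra must be paired")
    if len(samples) < 10:
        raise ValueError("need at least 10 pairs to build a reference database")
    if ratios is None:
        ratios = load_default_ratio_matrix()

    flags = calibration.outlier_flags
    if flags is None:
        flags = np.zeros(len(samples), dtype=bool)
    elif len(flags) != len(samples):
        raise ValueError("calibration flags do not align with the sample pairs")

    compositions = batch_estimate(samples, ratios)
    records = []
    seen_keys: set[tuple[str, str, float]] = set()
    for sample, raw, comp, flagged in zip(samples, raw_spectra, compositions, flags):
        if isinstance(comp, Exception):
            raise ValueError(
                f"composition failed for {sample.key}: {comp}") from comp
        if sample.key in seen_keys:
            import warnings
            warnings.warn(f"duplicate sampling key {sample.key}; keeping both")
        seen_keys.add(sample.key)
        records.append(ReferenceRecord(
            spectrum=standardize_spectrum(raw), composition=comp,
            tchla=sample.tchla, cruise=sample.cruise, station=sample.station,
            depth_m=sample.depth_m, area=sample.area, season=sample.season,
            outlier=bool(flagged)))
    db = ReferenceDatabase(records, provenance=provenance)
    if db.n_active == 0:
        raise ValueError("empty reference database: every pair was flagged")
    return db


def decompose_spectrum(f: FluorescenceSpectrum,
                       db: ReferenceDatabase) -> DecompositionResult:
    """Solve min ‖f − Σ α_i F_i‖₂ subject to 0 ≤ α_i ≤ 1 over active records."""
    if not f.standardized:
        raise ValueError("target spectrum must be standardized")
    F = db.spectra_matrix()
    if F.shape[1] == 0:
        raise ValueError("empty active reference database")
    sol = lsq_linear(F, f.channels, bounds=(0.0, 1.0), method="bvls",
                     tol=1e-12, max_iter=3 * F.shape[1])
    alphas = np.clip(sol.x, 0.0, 1.0)
    residual = float(np.linalg.norm(F @ alphas - f.channels))
    n_active = int(np.sum(alphas > ALPHA_ACTIVE_TOL))
    return DecompositionResult(alphas=alphas, residual_norm=residual,
                               n_active=n_active)


def reconstruct_composition(result: DecompositionResult,
                            db: ReferenceDatabase) -> GroupComposition:
    """Reconstruct p = Σ α_i P_i and renormalise to proportions of TChla."""
    P = db.composition_matrix()
    if len(result.alphas) != P.shape[0]:
        raise ValueError("coefficients do not align with active records")
    if result.alpha_sum <= 0:
        raise ValueError("no reference support: all coefficients are zero")
    p_raw = result.alphas @ P
    return GroupComposition.from_array(p_raw / p_raw.sum())


def convert_spectrum(
    raw: FluorescenceSpectrum,
    db: ReferenceDatabase,
    calibration: CalibrationModel,
) -> tuple[GroupComposition, float, dict]:
    """Full conversion of one raw spectrum: composition, TChla_MEX, diagnostics.

    The composition path standardizes the spectrum before decomposition, so
    it is invariant to overall intensity; TChla uses the raw 435 nm channel.
    Diagnostics report the decomposition residual, Σα, the number of active
    coefficients, and the maximum pairwise correlation among active
    reference spectra (a collinearity warning signal).
    """
    f = standardize_spectrum(raw)
    result = decompose_spectrum(f, db)
    composition = reconstruct_composition(result, db)
    tchla_mex = estimate_tchla(raw[435], calibration)

    active = np.flatnonzero(result.alphas > ALPHA_ACTIVE_TOL)
    max_corr = np.nan
    if active.size >= 2:
        spectra = db.spectra_matrix()[:, active]
        corr = np.corrcoef(spectra.T)
        iu = np.triu_indices(active.size, k=1)
        max_corr = float(np.nanmax(corr[iu]))
    diagnostics = {
        "residual_norm": result.residual_norm,
        "alpha_sum": result.alpha_sum,
        "n_active": result.n_active,
        "max_active_spectral_correlation": max_corr,
    }
    return composition, tchla_mex, diagnostics
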