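"""Synthetic reference databases and casts with the structure the method assumes.

The generator emulates the statistical skeleton of a multi-excitation
fluorometry field campaign:

* nine group-specific excitation "endmember" spectra over the instrument's
  nine LED channels.  These are smooth Gaussian-mixture shapes constrained
  by known pigment photophysics — every group excites broadly in the blue
  (435–470 nm); dinoflagellates (peridinin–chlorophyll protein) are
  elevated near 505 nm; cyanophytes and prochlorophytes (phycobilins) are
  elevated at 570/590 nm.  They are NOT measured excitation spectra and
  must never be mistaken for instrument truth;
* water samples whose group composition is Dirichlet-distributed with
  area-specific means (diatom-heavy subarctic areas, a picoplankton-heavy
  warm-current area, a small-eukaryote-heavy marginal sea), whose marker
  pigments follow the ratio-matrix forward model with multiplicative
  lognormal noise, and whose spectra are chlorophyll-weighted endmember
  mixtures with multiplicative channel noise;
* depth-structured 10 Hz casts with layered compositions, an optional
  Gaussian subsurface chlorophyll maximum, and spike contamination for
  exercising the median despiking.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .calibration import CHANNELS, fit_robust_zero_intercept
from .chemotax import GROUPS, PIGMENTS, PigmentSample, RatioMatrix, load_default_ratio_matrix
from .conversion import FluorescenceSpectrum, ReferenceDatabase, build_reference_database
from .profiles import CHANNEL_COLS, MexCast

__all__ = [
    "SimulationConfig",
    "AREA_DIRICHLET_MEANS",
    "make_endmember_spectra",
    "simulate_reference_db",
    "simulate_cast",
]

#: instrument gain: raw fluorescence units per (µg/L chlorophyll × unit mixture)
INSTRUMENT_GAIN = 2.0

#: area-specific Dirichlet mean compositions (rows sum to 1), echoing the
#: regional character of the study areas: a warm-current area dominated by
#: picocyanobacteria, a marginal sea rich in small eukaryotes, and two
#: diatom-heavy subarctic areas.
AREA_DIRICHLET_MEANS: dict[str, np.ndarray] = {
    "Kuroshio": np.array([0.10, 0.08, 0.07, 0.05, 0.05, 0.07, 0.08, 0.15, 0.35]),
    "JS":       np.array([0.12, 0.15, 0.13, 0.05, 0.08, 0.15, 0.18, 0.08, 0.06]),
    "Okhotsk":  np.array([0.45, 0.08, 0.07, 0.08, 0.08, 0.06, 0.07, 0.06, 0.05]),
    "Oyashio":  np.array([0.40, 0.10, 0.08, 0.10, 0.07, 0.08, 0.07, 0.05, 0.05]),
}

#: Gaussian-mixture endmember shapes: group -> [(weight, peak nm, width nm), ...]
_ENDMEMBER_SHAPES: dict[str, list[tuple[float, float, float]]] = {
    "diatoms":         [(1.00, 450, 28), (0.55, 525, 14)],
    "haptophytes3":    [(1.00, 465, 22), (0.55, 400, 16)],
    "haptophytes4":    [(1.00, 435, 20), (0.50, 375, 12)],
    "dinoflagellates": [(1.00, 440, 28), (0.90, 505, 13)],
    "cryptophytes":    [(1.00, 445, 28), (0.80, 565, 13)],
    "prasinophytes":   [(1.00, 422, 16), (0.45, 470, 14)],
    "chlorophytes":    [(1.00, 468, 16), (0.40, 420, 12)],
    "cyanophytes":     [(0.40, 435, 28), (1.00, 588, 12)],
    "prochlorophytes": [(1.00, 455, 18), (0.60, 375, 20), (0.35, 570, 10)],
}


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for a synthetic reference database.

    Defaults mirror a modest field campaign: 200 paired samples over four
    areas, 5% multiplicative spectral noise and 5% pigment noise
    (HPLC-like precision), chlorophyll spanning 0.05–5 µg/L log-uniformly.
    The Dirichlet concentration of 2.0 yields strongly dominance-structured
    assemblages (one or two leading groups per sample), the regime the
    contrasting study areas represent; recovery degrades for more even
    assemblages.
    """

    n_samples: int = 200
    n_areas: int = 4
    dirichlet_concentration: float = 2.0
    spectral_noise_sd: float = 0.05
    pigment_noise_sd: float = 0.05
    tchla_range: tuple[float, float] = (0.05, 5.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError("n_samples must be ≥ 1")
        if not (1 <= self.n_areas <= len(AREA_DIRICHLET_MEANS)):
            raise ValueError("n_areas out of range")
        if self.spectral_noise_sd < 0 or self.pigment_noise_sd < 0:
            raise ValueError("noise sds must be non-negative")


def make_endmember_spectra(seed: int = 0, jitter_sd: float = 0.03) -> pd.DataFrame:
    """Nine standardized group endmember spectra over the nine channels.

    Deterministic Gaussian-mixture base shapes receive a small seeded
    multiplicative jitter so repeated campaigns differ slightly; each
    spectrum is standardized to sum 1.  Pairwise correlations stay below
    0.999 (identifiability), dinoflagellates exceed diatoms in the
    505:435 ratio, and the cyanobacterial groups carry the 570/590
    phycobilin shoulder.
    """
    rng = np.random.default_rng(seed)
    wl = np.array(CHANNELS, dtype=float)
    rows = {}
    for group in GROUPS:
        shape = np.zeros_like(wl)
        for weight, mu, sigma in _ENDMEMBER_SHAPES[group]:
            shape += weight * np.exp(-0.5 * ((wl - mu) / sigma) ** 2)
        shape *= np.exp(rng.normal(0.0, jitter_sd, size=wl.size))
        rows[group] = shape / shape.sum()
    spectra = pd.DataFrame(rows, index=list(CHANNEL_COLS)).T
    corr = np.corrcoef(spectra.to_numpy())
    iu = np.triu_indices(len(GROUPS), k=1)
    if np.max(corr[iu]) >= 0.999:
        raise RuntimeError("endmember jitter produced near-duplicate spectra")
    return spectra


def _forward_spectrum(q: np.ndarray, tchla: float, endmembers: np.ndarray,
                      rng: np.random.Generator, noise_sd: float) -> np.ndarray:
    """Raw spectrum of a composition q at a given chlorophyll concentration."""
    mix = q @ endmembers  # (9 channels,) — sums to 1 since each endmember does
    raw = mix * tchla * INSTRUMENT_GAIN
    if noise_sd > 0:
        raw = raw * np.exp(rng.normal(0.0, noise_sd, size=raw.size))
    return raw


def simulate_reference_db(
    config: SimulationConfig,
    ratios: RatioMatrix | None = None,
) -> tuple[ReferenceDatabase, pd.DataFrame]:
    """Simulate paired pigment/fluorescence samples and build the database.

    Per sample: an area-specific Dirichlet composition q, marker pigments
    from the ratio-matrix forward model with lognormal noise, and a raw
    spectrum from the chlorophyll-weighted endmember mixture with
    multiplicative channel noise.  The TChla calibration is fitted on the
    435 nm channel of the simulated pairs and used to flag outliers, then
    the reference database is assembled exactly as it would be from field
    data.

    Returns the database and a ground-truth table (area, tchla and the
    true fractions) aligned with the database records.
    """
    if ratios is None:
        ratios = load_default_ratio_matrix()
    rng = np.random.default_rng(config.seed)
    endmembers = make_endmember_spectra(seed=config.seed).to_numpy()
    areas = list(AREA_DIRICHLET_MEANS)[: config.n_areas]

    samples: list[PigmentSample] = []
    spectra: list[FluorescenceSpectrum] = []
    truth_rows = []
    A = (ratios.values / 100.0)  # (groups, pigments)
    lo, hi = config.tchla_range
    for i in range(config.n_samples):
        area = areas[i % len(areas)]
        q = rng.dirichlet(AREA_DIRICHLET_MEANS[area] * config.dirichlet_concentration)
        tchla = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        pigments = (q * tchla) @ A
        if config.pigment_noise_sd > 0:
            pigments = pigments * np.exp(
                rng.normal(0.0, config.pigment_noise_sd, size=pigments.size))
        conc = dict(zip(PIGMENTS, map(float, pigments)))
        conc["Neo"] = 0.0
        conc["Lut"] = 0.0
        samples.append(PigmentSample(
            concentrations=conc, cruise=f"SIM{1 + i // 100}",
            station=f"S{i:03d}", depth_m=float(rng.uniform(10, 170)),
            area=area, season=("winter", "spring", "summer", "autumn")[i % 4]))
        spectra.append(FluorescenceSpectrum(
            _forward_spectrum(q, tchla, endmembers, rng, config.spectral_noise_sd)))
        truth_rows.append({"area": area, "tchla": tchla,
                           **dict(zip(GROUPS, map(float, q)))})

    f435 = np.array([s[435] for s in spectra])
    tchla_obs = np.array([s.tchla for s in samples])
    calibration = fit_robust_zero_intercept(f435, tchla_obs, channel=435)
    db = build_reference_database(samples, spectra, calibration, ratios,
                                  provenance=f"simulated(seed={config.seed})")
    truth = pd.DataFrame(truth_rows)
    return db, truth


def simulate_cast(
    layers: list[tuple[float, float, np.ndarray, float]],
    noise_sd: float = 0.02,
    seed: int = 0,
    descent_rate: float = 0.2,
    sample_hz: float = 10.0,
    scm: tuple[float, float, float] | None = None,
    spike_rate: float = 0.0,
    spike_factor: float = 100.0,
    station: str = "SIM",
) -> MexCast:
    """Simulate a 10 Hz descent through layered water.

    ``layers`` is a list of (top_m, bottom_m, composition fractions,
    TChla µg/L); ranges must not overlap.  ``scm`` optionally adds a
    Gaussian subsurface chlorophyll maximum as (peak depth m, added TChla
    µg/L, width m).  ``spike_rate`` replaces that fraction of records with
    ``spike_factor``× channel values, for testing the median despiking.
    The cast starts at the surface, so segmentation sees a shallow lead-in.
    """
    spans = sorted((top, bot) for top, bot, _, _ in layers)
    for (a0, a1), (b0, b1) in zip(spans, spans[1:]):
        if b0 < a1:
            raise ValueError("overlapping layers")
    rng = np.random.default_rng(seed)
    endmembers = make_endmember_spectra(seed=seed).to_numpy()
    max_depth = max(bot for _, bot, _, _ in layers)
    n = int(np.ceil(max_depth / descent_rate * sample_hz)) + 1
    t = np.arange(n) / sample_hz
    depth = descent_rate * t

    records = []
    for ti, z in zip(t, depth):
        q, tchla = None, 0.0
        for top, bot, comp, layer_tchla in layers:
            if top <= z < bot or (z == max_depth and bot == max_depth):
                q = np.asarray(comp, dtype=float)
                tchla = float(layer_tchla)
                break
        if q is None:  # above/below all layers: nearest layer's water
            top, bot, comp, layer_tchla = min(
                layers, key=lambda L: min(abs(z - L[0]), abs(z - L[1])))
            q, tchla = np.asarray(comp, dtype=float), float(layer_tchla)
        if scm is not None:
            z0, amp, width = scm
            tchla = tchla + amp * float(np.exp(-0.5 * ((z - z0) / width) ** 2))
        raw = _forward_spectrum(q / q.sum(), tchla, endmembers, rng, noise_sd)
        records.append({"time_s": ti, "depth_m": z, "temp_c": 20.0 - 0.1 * z,
                        **dict(zip(CHANNEL_COLS, raw))})
    df = pd.DataFrame(records)
    if spike_rate > 0:
        hit = rng.random(len(df)) < spike_rate
        df.loc[hit, list(CHANNEL_COLS)] *= spike_factor
    return MexCast(df, station=station, observation_id=station)
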