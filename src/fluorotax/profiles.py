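"""Field-cast processing: from 10 Hz sensor records to water-column summaries.

A deployment file may contain several stations' profiles back to back.
Contiguous stretches with the sensor at ≥ 2 m depth lasting ≥ 300 s are
treated as distinct observations.  Within an observation the 10 Hz records
are despiked to 1 Hz medians, averaged into 1-m depth bins, and each bin's
mean spectrum is converted to a chemotaxonomic composition and TChla_MEX.
Per-profile vertical heterogeneity of each group's proportion is scored by
the quartile coefficient of dispersion, and group biomass is integrated
over the water column (µg/L over m ≡ mg/m²).  Observations are compared by
Bray–Curtis dissimilarity of their integrated group shares, embedded in
two dimensions by non-metric multidimensional scaling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from sklearn.manifold import MDS

from .calibration import CHANNELS, CalibrationModel
from .chemotax import GROUPS
from .conversion import FluorescenceSpectrum, ReferenceDatabase, convert_spectrum

__all__ = [
    "MexCast",
    "BinnedProfile",
    "HeterogeneityReport",
    "segment_observations",
    "median_resample_1s",
    "bin_profile_1m",
    "qcod",
    "qcod_threshold",
    "heterogeneity_report",
    "integrate_water_column",
    "station_similarity",
]

CHANNEL_COLS = tuple(f"f{ch}" for ch in CHANNELS)
CAST_COLS = ("time_s", "depth_m", "temp_c") + CHANNEL_COLS

#: segmentation defaults: sensor below 2 m for at least 300 s
MIN_OBS_DEPTH_M = 2.0
MIN_OBS_DURATION_S = 300.0


@dataclass
class MexCast:
    """Time-ordered fluorometer records (time_s, depth_m, temp_c, 9 channels)."""

    data: pd.DataFrame
    station: str = ""
    observation_id: str = ""

    def __post_init__(self) -> None:
        missing = [c for c in CAST_COLS if c not in self.data.columns]
        if missing:
            raise ValueError(f"cast is missing columns: {missing}")
        t = self.data["time_s"].to_numpy()
        if len(t) == 0:
            raise ValueError("empty cast")
        if not np.all(np.diff(t) > 0):
            raise ValueError("timestamps must be strictly increasing")
        if (self.data["depth_m"].to_numpy() < 0).any():
            raise ValueError("negative depths")

    def __len__(self) -> int:
        return len(self.data)

    @property
    def duration_s(self) -> float:
        t = self.data["time_s"].to_numpy()
        return float(t[-1] - t[0])


def segment_observations(cast: MexCast,
                         min_depth: float = MIN_OBS_DEPTH_M,
                         min_duration: float = MIN_OBS_DURATION_S,
                         ) -> list[MexCast]:
    """Split a deployment into observations: runs at ≥ min_depth for ≥ min_duration.

    A run is broken by any record shallower than ``min_depth`` (no gap
    tolerance).  Runs shorter than ``min_duration`` are discarded.  May
    return an empty list.
    """
    deep = cast.data["depth_m"].to_numpy() >= min_depth
    out: list[MexCast] = []
    edges = np.flatnonzero(np.diff(np.concatenate(([0], deep.view(np.int8), [0]))))
    for k, (start, stop) in enumerate(zip(edges[::2], edges[1::2])):
        chunk = cast.data.iloc[start:stop]
        t = chunk["time_s"].to_numpy()
        if t[-1] - t[0] >= min_duration:
            out.append(MexCast(chunk.reset_index(drop=True), station=cast.station,
                               observation_id=f"{cast.observation_id or cast.station}"
                                              f"-obs{len(out)}"))
    return out


def median_resample_1s(cast: MexCast) -> MexCast:
    """Despike to 1 Hz: per whole-second window, the median of every column.

    Even-count windows use the midpoint-average median.  The window's
    timestamp is its start second.
    """
    df = cast.data
    window = np.floor(df["time_s"].to_numpy()).astype(int)
    agg = df.groupby(window).median()
    agg["time_s"] = agg.index.astype(float)
    return MexCast(agg.reset_index(drop=True), station=cast.station,
                   observation_id=cast.observation_id)


@dataclass
class BinnedProfile:
    """Per-1-m-bin composition and TChla_MEX for one observation.

    ``data`` columns: depth_m (bin lower edge), tchla_mex, one fraction
    column per group, n_samples; sorted by depth, bins non-overlapping.
    """

    data: pd.DataFrame
    observation_id: str = ""

    def __post_init__(self) -> None:
        d = self.data["depth_m"].to_numpy()
        if not np.all(np.diff(d) > 0):
            raise ValueError("bins must be sorted and non-overlapping")
        if (self.data["tchla_mex"].to_numpy() < 0).any():
            raise ValueError("negative TChla")

    def fractions(self) -> pd.DataFrame:
        return self.data.set_index("depth_m")[list(GROUPS)]


def bin_profile_1m(cast_1hz: MexCast, db: ReferenceDatabase,
                   calibration: CalibrationModel,
                   zmin: float = MIN_OBS_DEPTH_M) -> BinnedProfile:
    """Average 1 Hz records into half-open [k, k+1) m bins and convert each.

    Each bin's mean raw spectrum is converted to a composition and
    TChla_MEX; empty bins are simply absent from the output (interpolated
    later when integrating).
    """
    df = cast_1hz.data[cast_1hz.data["depth_m"] >= zmin]
    if df.empty:
        raise ValueError("no records at or below zmin")
    bins = np.floor(df["depth_m"].to_numpy()).astype(int)
    rows = []
    for depth, chunk in df.groupby(bins):
        mean_channels = chunk[list(CHANNEL_COLS)].mean().to_numpy()
        if mean_channels.sum() <= 0:
            continue
        raw = FluorescenceSpectrum(mean_channels)
        comp, tchla, _ = convert_spectrum(raw, db, calibration)
        row = {"depth_m": float(depth), "tchla_mex": tchla,
               "n_samples": len(chunk)}
        row.update(comp.fractions)
        rows.append(row)
    if not rows:
        raise ValueError("no usable depth bins")
    data = pd.DataFrame(rows).sort_values("depth_m").reset_index(drop=True)
    return BinnedProfile(data, observation_id=cast_1hz.observation_id)


def qcod(values: np.ndarray) -> float:
    """Quartile coefficient of dispersion, (Q3 − Q1)/(Q3 + Q1).

    Quartiles by linear interpolation between order statistics.  Returns
    NaN (undefined) when Q1 + Q3 = 0.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 4:
        raise ValueError("need at least 4 values")
    q1, q3 = np.percentile(v, [25, 75])
    denom = q3 + q1
    if denom == 0:
        return float("nan")
    return float((q3 - q1) / denom)


def qcod_threshold(mean: float, sd: float) -> float:
    """High-heterogeneity threshold: mean + 2·sd of a QCoD population."""
    return mean + 2.0 * sd


@dataclass(frozen=True)
class HeterogeneityReport:
    """QCoD per observation × group with a mean + 2·sd exceedance threshold."""

    qcod: pd.DataFrame    # rows: observation ids, cols: groups
    threshold: float
    flags: pd.DataFrame
    mean: float
    sd: float
    n_undefined: int


def heterogeneity_report(profiles: list[BinnedProfile]) -> HeterogeneityReport:
    """Score vertical heterogeneity of every profile and group by QCoD.

    The threshold is mean + 2·sd over all defined QCoD values; undefined
    entries (groups absent throughout a profile) are excluded from the
    summary and never flagged.
    """
    if len(profiles) < 2:
        raise ValueError("need at least 2 profiles")
    rows = {}
    for prof in profiles:
        fr = prof.fractions()
        rows[prof.observation_id] = {g: qcod(fr[g].to_numpy()) for g in GROUPS}
    table = pd.DataFrame.from_dict(rows, orient="index")
    flat = table.to_numpy().ravel()
    defined = flat[~np.isnan(flat)]
    mean = float(defined.mean())
    sd = float(defined.std(ddof=1)) if defined.size > 1 else 0.0
    threshold = qcod_threshold(mean, sd)
    flags = table > threshold
    return HeterogeneityReport(qcod=table, threshold=threshold, flags=flags,
                               mean=mean, sd=sd,
                               n_undefined=int(np.isnan(flat).sum()))


def integrate_water_column(profile: BinnedProfile,
                           zmin: float = MIN_OBS_DEPTH_M,
                           zmax: float | None = None) -> pd.DataFrame:
    """Trapezoidal water-column integral of group biomass (mg/m²).

    Integrates fraction × TChla_MEX per group over [zmin, zmax] on the
    1-m bin grid, linearly interpolating missing bins, and reports each
    group's share of the integrated total.  1 µg/L over 1 m ≡ 1 mg/m².
    """
    depth = profile.data["depth_m"].to_numpy(float)
    if zmax is None:
        zmax = float(depth.max())
    if zmin < depth.min() or zmax > depth.max() or zmax <= zmin:
        raise ValueError("integration range outside profile coverage")
    grid = np.arange(np.ceil(zmin), np.floor(zmax) + 1.0)
    grid = np.unique(np.concatenate(([zmin], grid[(grid > zmin) & (grid < zmax)],
                                     [zmax])))
    tchla = profile.data["tchla_mex"].to_numpy(float)
    out = {}
    for g in GROUPS:
        product = profile.data[g].to_numpy(float) * tchla
        out[g] = float(np.trapezoid(np.interp(grid, depth, product), grid))
    total = float(np.trapezoid(np.interp(grid, depth, tchla), grid))
    table = pd.DataFrame({
        "integrated_mg_m2": pd.Series(out),
        "share": pd.Series(out) / total if total > 0 else np.nan,
    })
    table.attrs["total_tchla_mg_m2"] = total
    table.attrs["zmin"], table.attrs["zmax"] = float(zmin), float(zmax)
    return table


def station_similarity(shares: pd.DataFrame, seed: int = 0,
                       n_restarts: int = 20) -> tuple[pd.DataFrame, float]:
    """Bray–Curtis NMDS of observations' integrated group shares.

    2-D non-metric MDS (Kruskal stress-1) with seeded random restarts;
    the best embedding is returned with its stress.  All-identical rows
    yield coincident points and stress 0.
    """
    if shares.shape[0] < 4:
        raise ValueError("need at least 4 observations")
    D = squareform(pdist(shares.to_numpy(float), metric="braycurtis"))
    if np.allclose(D, 0.0):
        coords = np.zeros((shares.shape[0], 2))
        return pd.DataFrame(coords, index=shares.index, columns=["NMDS1", "NMDS2"]), 0.0
    mds = MDS(n_components=2, metric_mds=False, n_init=n_restarts,
              init="random", max_iter=500, random_state=seed,
              metric="precomputed", normalized_stress=True)
    coords = mds.fit_transform(D)
    return (pd.DataFrame(coords, index=shares.index, columns=["NMDS1", "NMDS2"]),
            float(mds.stress_))
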