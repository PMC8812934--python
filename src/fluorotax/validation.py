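"""Cross-validation, bootstrap sensitivity and comparison statistics.

Two cross-validation designs probe the reference-based conversion:

* leave-one-out (LOOCV): every record is converted against the database
  minus all records sharing its (cruise, station, depth) sampling key,
  so replicate bottles never vouch for themselves;
* leave-area-out: every record is converted using only references from
  other geographic areas, probing spatial transferability.

Estimated and pigment-based proportions are compared per group by ordinary
regression, mean absolute difference and empirical 95% difference
intervals.  Bootstrap resampling of the reference set quantifies how much
a converted composition depends on particular reference records, as a
per-group coefficient of variation.  A sequential PERMANOVA on Bray–Curtis
distances quantifies how much of the compositional variance the nine
excitation channels explain.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform

from .calibration import CHANNELS
from .chemotax import GROUPS, GroupComposition
from .conversion import (
    ReferenceDatabase,
    decompose_spectrum,
    reconstruct_composition,
)

__all__ = [
    "PairedCompositions",
    "ComparisonStats",
    "BootstrapReport",
    "loocv_conversion",
    "leave_area_out_conversion",
    "comparison_stats",
    "bootstrap_sensitivity",
    "aggregate_groups",
    "permanova_fluorescence",
]

AGGREGATION_SCHEMES = ("eukaryotes_merge", "cyanobacteria_merge", "both")

#: groups pooled as "eukaryotes" (small flagellates hard to separate optically)
EUKARYOTE_MEMBERS = ("chlorophytes", "prasinophytes", "haptophytes3", "haptophytes4")
#: groups pooled as "cyanobacteria"
CYANOBACTERIA_MEMBERS = ("cyanophytes", "prochlorophytes")


@dataclass(frozen=True)
class PairedCompositions:
    """Aligned estimated vs pigment-based proportions for a set of records."""

    estimated: np.ndarray  # (n, 9)
    truth: np.ndarray      # (n, 9)
    indices: np.ndarray    # original db indices
    groups: tuple[str, ...] = GROUPS

    def __len__(self) -> int:
        return self.estimated.shape[0]


def _convert_against(db: ReferenceDatabase, target_idx: int,
                     keep: np.ndarray) -> np.ndarray:
    """Convert record ``target_idx``'s spectrum against a restricted view."""
    view = db.active_view(keep=keep)
    if view.n_active == 0:
        raise ValueError("reference exclusion left an empty database")
    f = db.records[target_idx].spectrum
    result = decompose_spectrum(f, view)
    return reconstruct_composition(result, view).as_array()


def loocv_conversion(db: ReferenceDatabase) -> PairedCompositions:
    """Leave-one-out conversion excluding same-(cruise, station, depth) records."""
    idx = db.active_indices
    keys = [db.records[i].key for i in idx]
    if len(set(keys)) < 2:
        raise ValueError("need at least two distinct sampling keys")
    est, truth = [], []
    for j, key in zip(idx, keys):
        keep = np.array([i for i, k in zip(idx, keys) if k != key])
        est.append(_convert_against(db, j, keep))
        truth.append(db.records[j].composition.as_array())
    return PairedCompositions(np.vstack(est), np.vstack(truth), idx)


def leave_area_out_conversion(db: ReferenceDatabase) -> PairedCompositions:
    """Convert each record using only references from other areas."""
    idx = db.active_indices
    areas = [db.records[i].area for i in idx]
    if len(set(areas)) < 2:
        raise ValueError("need at least two areas")
    est, truth = [], []
    for j, area in zip(idx, areas):
        keep = np.array([i for i, a in zip(idx, areas) if a != area])
        est.append(_convert_against(db, j, keep))
        truth.append(db.records[j].composition.as_array())
    return PairedCompositions(np.vstack(est), np.vstack(truth), idx)


@dataclass(frozen=True)
class ComparisonStats:
    """Per-group agreement statistics between estimated and true proportions.

    ``table`` columns: slope, t_value, p_value, r2, mean_abs_diff_pct,
    ci_halfwidth_pct (percentile-based), ci_halfwidth_normal_pct, n,
    skipped (zero-variance truth).  Differences are in percentage points.
    """

    table: pd.DataFrame

    def __getitem__(self, group: str) -> pd.Series:
        return self.table.loc[group]


def comparison_stats(pairs: PairedCompositions) -> ComparisonStats:
    """Regress estimated on true proportions per group and summarise differences."""
    if len(pairs) < 3:
        raise ValueError("need at least 3 pairs")
    rows = {}
    for m, group in enumerate(pairs.groups):
        x = pairs.truth[:, m]
        y = pairs.estimated[:, m]
        diff = (y - x) * 100.0
        row = {
            "mean_abs_diff_pct": float(np.mean(np.abs(diff))),
            "ci_halfwidth_pct": float(
                (np.percentile(diff, 97.5) - np.percentile(diff, 2.5)) / 2.0),
            "ci_halfwidth_normal_pct": float(1.96 * np.std(diff, ddof=1)),
            "n": len(pairs),
        }
        if np.ptp(x) == 0:
            row.update(slope=np.nan, t_value=np.nan, p_value=np.nan,
                       r2=np.nan, skipped=True)
        else:
            fit = stats.linregress(x, y)
            t = fit.slope / fit.stderr if fit.stderr > 0 else np.inf
            row.update(slope=fit.slope, t_value=t, p_value=fit.pvalue,
                       r2=fit.rvalue**2, skipped=False)
        rows[group] = row
    table = pd.DataFrame(rows).T
    table["skipped"] = table["skipped"].astype(bool)
    table["n"] = table["n"].astype(int)
    num = [c for c in table.columns if c not in ("skipped", "n")]
    table[num] = table[num].astype(float)
    return ComparisonStats(table)


@dataclass(frozen=True)
class BootstrapReport:
    """Reference-resampling sensitivity of converted compositions.

    cv_jm: per-record, per-group coefficient of variation (%) of the
    composition across bootstrap replicates of the reference set.
    cv_m summarises cv_jm per group (mean, sd, mean + 2·sd).
    """

    cv_jm: pd.DataFrame          # rows: record index, cols: groups
    cv_m: pd.DataFrame           # rows: groups; cols: mean, sd, upper95, n_defined
    R: int
    seed: int


def bootstrap_sensitivity(db: ReferenceDatabase, R: int = 1000,
                          seed: int = 0) -> BootstrapReport:
    """Bootstrap the leave-one-out reference set and measure composition CV.

    For every active record j, the same-key-excluded reference set is
    resampled with replacement R times; record j's spectrum is converted
    against each replicate.  CV_jm = 100·sd/mean of the resulting
    proportions per group (undefined where the mean proportion is 0).
    """
    if R < 2:
        raise ValueError("R must be at least 2")
    if db.n_active < 10:
        raise ValueError("need at least 10 active records")
    rng = np.random.default_rng(seed)
    idx = db.active_indices
    keys = [db.records[i].key for i in idx]
    F_all = db.spectra_matrix()      # (9, n)
    P_all = db.composition_matrix()  # (n, 9)

    cv_rows = {}
    for pos, (j, key) in enumerate(zip(idx, keys)):
        pool = np.array([q for q, k in enumerate(keys) if k != key])
        f = db.records[j].spectrum
        reps = np.empty((R, len(GROUPS)))
        for r in range(R):
            draw = rng.choice(pool, size=pool.size, replace=True)
            sub = _SubsetView(F_all[:, draw], P_all[draw])
            result = decompose_spectrum(f, sub)
            reps[r] = reconstruct_composition(result, sub).as_array()
        mean = reps.mean(axis=0)
        sd = reps.std(axis=0, ddof=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            cv = np.where(mean > 0, 100.0 * sd / mean, np.nan)
        cv_rows[j] = cv
    cv_jm = pd.DataFrame.from_dict(cv_rows, orient="index", columns=list(GROUPS))
    summary = pd.DataFrame({
        "mean": cv_jm.mean(skipna=True),
        "sd": cv_jm.std(ddof=1, skipna=True),
        "n_defined": cv_jm.notna().sum(),
    })
    summary["upper95"] = summary["mean"] + 2.0 * summary["sd"]
    return BootstrapReport(cv_jm=cv_jm, cv_m=summary, R=R, seed=seed)


class _SubsetView:
    """Duck-typed minimal reference view for resampled matrices."""

    def __init__(self, F: np.ndarray, P: np.ndarray):
        self._F, self._P = F, P

    def spectra_matrix(self) -> np.ndarray:
        return self._F

    def composition_matrix(self) -> np.ndarray:
        return self._P


def aggregate_groups(p: GroupComposition, scheme: str) -> GroupComposition:
    """Merge groups that the optical conversion cannot reliably separate.

    ``eukaryotes_merge`` pools chlorophytes, prasinophytes and both
    haptophyte types as "eukaryotes"; ``cyanobacteria_merge`` pools
    cyanophytes and prochlorophytes as "cyanobacteria"; ``both`` applies
    both.  Totals are preserved.
    """
    if scheme not in AGGREGATION_SCHEMES:
        raise ValueError(f"unknown aggregation scheme: {scheme!r}")
    merges: list[tuple[str, tuple[str, ...]]] = []
    if scheme in ("eukaryotes_merge", "both"):
        merges.append(("eukaryotes", EUKARYOTE_MEMBERS))
    if scheme in ("cyanobacteria_merge", "both"):
        merges.append(("cyanobacteria", CYANOBACTERIA_MEMBERS))
    merged_members = {g for _, members in merges for g in members}
    fractions = {g: v for g, v in p.fractions.items() if g not in merged_members}
    for name, members in merges:
        fractions[name] = float(sum(p.fractions[g] for g in members))
    return GroupComposition(fractions, undefined=p.undefined)


def permanova_fluorescence(db: ReferenceDatabase, n_perm: int = 1000,
                           seed: int = 0) -> pd.DataFrame:
    """Sequential PERMANOVA of compositions against the nine channels.

    Bray–Curtis distances among active compositions are partitioned against
    the standardized channel values as continuous predictors, added
    sequentially in wavelength order (Type-I sums of squares, as in the
    distance-based redundancy analysis of McArdle & Anderson).  Pseudo-F
    for each term uses the full-model residual; p-values come from
    permuting the distance matrix rows.

    Returns a table with one row per channel plus a ``Residual`` row:
    columns ``SS, R2, F, p_value, skipped``.
    """
    Y = db.composition_matrix()
    X = db.spectra_matrix().T  # (n, 9) standardized channel values
    names = [f"f{ch}" for ch in CHANNELS]
    return _sequential_permanova(Y, X, names, n_perm=n_perm, seed=seed)


def _sequential_permanova(Y: np.ndarray, X: np.ndarray, names: list[str],
                          n_perm: int = 1000, seed: int = 0) -> pd.DataFrame:
    n = Y.shape[0]
    if n < 10:
        raise ValueError("need at least 10 records")
    D = squareform(pdist(Y, metric="braycurtis"))
    G = _gower_center(D)
    ss_total = float(np.trace(G))

    # Gram–Schmidt of [1, x1, x2, ...]; constant/collinear columns are skipped.
    basis = [np.full(n, 1.0 / np.sqrt(n))]
    kept, skipped = [], []
    for k, name in enumerate(names):
        v = X[:, k].astype(float).copy()
        for q in basis:
            v -= (q @ v) * q
        norm = np.linalg.norm(v)
        if norm < 1e-10 * max(1.0, np.linalg.norm(X[:, k])):
            skipped.append(name)
            continue
        basis.append(v / norm)
        kept.append(name)
    Q = np.column_stack(basis[1:])  # (n, m) term directions
    m = Q.shape[1]
    df_resid = n - 1 - m

    ss_terms = np.einsum("nk,nm,mk->k", Q, G, Q)
    ss_resid = ss_total - ss_terms.sum()
    F_obs = (ss_terms / 1.0) / (ss_resid / df_resid)

    rng = np.random.default_rng(seed)
    perms = np.array([rng.permutation(n) for _ in range(n_perm)])
    Qp = Q[perms]  # (n_perm, n, m)
    t1 = np.einsum("nm,bmk->bnk", G, Qp)
    ss_p = np.einsum("bnk,bnk->bk", Qp, t1)
    ss_resid_p = ss_total - ss_p.sum(axis=1)
    F_p = ss_p / (ss_resid_p[:, None] / df_resid)
    p_values = (1.0 + np.sum(F_p >= F_obs[None, :] - 1e-12, axis=0)) / (n_perm + 1.0)

    rows = []
    it = iter(zip(ss_terms, F_obs, p_values))
    for name in names:
        if name in skipped:
            rows.append({"term": name, "SS": np.nan, "R2": np.nan, "F": np.nan,
                         "p_value": np.nan, "skipped": True})
        else:
            ss, f, p = next(it)
            rows.append({"term": name, "SS": ss, "R2": ss / ss_total, "F": f,
                         "p_value": p, "skipped": False})
    rows.append({"term": "Residual", "SS": ss_resid, "R2": ss_resid / ss_total,
                 "F": np.nan, "p_value": np.nan, "skipped": False})
    return pd.DataFrame(rows).set_index("term")


def _gower_center(D: np.ndarray) -> np.ndarray:
    """Gower-centered inner-product matrix of a squared distance matrix."""
    A = -0.5 * D**2
    n = A.shape[0]
    J = np.eye(n) - np.full((n, n), 1.0 / n)
    return J @ A @ J
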