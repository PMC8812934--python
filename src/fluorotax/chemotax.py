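"""Pigment-based chemotaxonomy: attribute chlorophyll-a biomass to algal groups.

The inversion follows the CHEMTAX logic with a fixed marker-pigment ratio
matrix: each of nine phytoplankton groups carries a characteristic set of
accessory pigments in (approximately) fixed proportion to its chlorophyll a.
Given an HPLC pigment profile of a water sample, the chlorophyll contribution
of each group is the non-negative least-squares solution of

    pigments  ≈  (R / 100)ᵀ · x,        x ≥ 0,

where R is the ratio matrix (pigment units per 100 units chlorophyll a) and
x the vector of per-group chlorophyll-a concentrations.  Fractions are
x / Σx.  The ratio matrix is held fixed; no iterative ratio re-optimisation
is performed.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy.optimize import nnls

__all__ = [
    "GROUPS",
    "PIGMENTS",
    "EXTRA_PIGMENTS",
    "RatioMatrix",
    "PigmentSample",
    "GroupComposition",
    "UndefinedCompositionError",
    "load_default_ratio_matrix",
    "estimate_composition",
    "batch_estimate",
]

#: Chemotaxonomic groups, in canonical order.
GROUPS: tuple[str, ...] = (
    "diatoms",
    "haptophytes3",
    "haptophytes4",
    "dinoflagellates",
    "cryptophytes",
    "prasinophytes",
    "chlorophytes",
    "cyanophytes",
    "prochlorophytes",
)

#: Marker pigments used by the ratio matrix, in canonical order.
PIGMENTS: tuple[str, ...] = (
    "Per", "But", "Fuc", "Hex", "Pra", "Vio",
    "All", "Zea", "Chlb", "MVChla", "DVChla",
)

#: Pigments measured by the HPLC protocol but carrying no chemotaxonomic
#: weight in the ratio matrix.
EXTRA_PIGMENTS: tuple[str, ...] = ("Neo", "Lut")


class UndefinedCompositionError(ValueError):
    """Raised when a sample has no pigment signal to attribute."""


@dataclass(frozen=True)
class RatioMatrix:
    """Pigment : chlorophyll-a ratio matrix (pigment per 100 units TChla).

    Rows are groups, columns marker pigments.  Every group's chlorophyll is
    carried either by monovinyl chlorophyll a (MVChla = 100) or, for
    prochlorophytes, by divinyl chlorophyll a (DVChla = 100).
    """

    groups: tuple[str, ...]
    pigments: tuple[str, ...]
    values: np.ndarray  # shape (n_groups, n_pigments)

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.shape != (len(self.groups), len(self.pigments)):
            raise ValueError("ratio matrix shape does not match labels")
        if (values < 0).any():
            raise ValueError("ratio matrix entries must be non-negative")
        object.__setattr__(self, "values", values)
        mv = values[:, self.pigments.index("MVChla")]
        dv = values[:, self.pigments.index("DVChla")]
        if not np.all((mv == 100) ^ (dv == 100)):
            raise ValueError(
                "each group must carry exactly one of MVChla, DVChla at 100"
            )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.groups),
                            columns=list(self.pigments))

    def row(self, group: str) -> np.ndarray:
        return self.values[self.groups.index(group)]


@dataclass(frozen=True)
class PigmentSample:
    """One water sample's HPLC pigment concentrations (µg/L) plus metadata."""

    concentrations: dict[str, float]
    cruise: str = ""
    station: str = ""
    depth_m: float = np.nan
    area: str = ""
    season: str = ""

    def __post_init__(self) -> None:
        for name, value in self.concentrations.items():
            if value < 0:
                raise ValueError(f"negative concentration for {name}: {value}")

    @property
    def tchla(self) -> float:
        """Total chlorophyll a: monovinyl + divinyl."""
        c = self.concentrations
        return c.get("MVChla", 0.0) + c.get("DVChla", 0.0)

    def vector(self, pigments: tuple[str, ...] = PIGMENTS) -> np.ndarray:
        return np.array([self.concentrations.get(p, 0.0) for p in pigments])

    @property
    def key(self) -> tuple[str, str, float]:
        """Sampling identity: (cruise, station, depth)."""
        return (self.cruise, self.station, float(self.depth_m))


@dataclass(frozen=True)
class GroupComposition:
    """Fraction of total chlorophyll a attributed to each group.

    Fractions sum to one unless the sample had no pigment signal, in which
    case ``undefined`` is set and the fractions are all zero.
    """

    fractions: dict[str, float]
    group_chla: dict[str, float] | None = None
    undefined: bool = False

    def __post_init__(self) -> None:
        vals = np.array([self.fractions[g] for g in self.fractions])
        if self.undefined:
            if not np.allclose(vals, 0.0):
                raise ValueError("undefined composition must have zero fractions")
        else:
            if (vals < -1e-12).any() or (vals > 1 + 1e-9).any():
                raise ValueError("fractions must lie in [0, 1]")
            if abs(vals.sum() - 1.0) > 1e-9:
                raise ValueError("fractions must sum to 1")

    def as_array(self, groups: tuple[str, ...] = GROUPS) -> np.ndarray:
        return np.array([self.fractions[g] for g in groups])

    @classmethod
    def from_array(cls, values: np.ndarray,
                   groups: tuple[str, ...] = GROUPS,
                   group_chla: np.ndarray | None = None) -> "GroupComposition":
        chla = None if group_chla is None else dict(zip(groups, map(float, group_chla)))
        return cls(dict(zip(groups, map(float, values))), group_chla=chla)


def load_default_ratio_matrix() -> RatioMatrix:
    """Load the packaged nine-group, eleven-pigment ratio matrix."""
    with resources.files("fluorotax").joinpath("data/ratio_matrix.csv").open() as fh:
        df = pd.read_csv(fh, index_col="group")
    return RatioMatrix(tuple(df.index), tuple(df.columns), df.to_numpy(float))


def estimate_composition(sample: PigmentSample,
                         ratios: RatioMatrix | None = None) -> GroupComposition:
    """Estimate a sample's nine-group chlorophyll-a composition.

    Solves the non-negative least-squares problem on the eleven marker
    pigments and renormalises the group chlorophyll contributions to
    fractions of their sum.

    Raises
    ------
    UndefinedCompositionError
        If every marker pigment concentration is zero.
    """
    if ratios is None:
        ratios = load_default_ratio_matrix()
    b = sample.vector(ratios.pigments)
    if not (b > 0).any():
        raise UndefinedCompositionError(
            "all marker pigments are zero; composition undefined"
        )
    # design matrix: pigments x groups, in per-unit-chlorophyll terms
    A = (ratios.values / 100.0).T
    x, _ = nnls(A, b)
    total = x.sum()
    if total <= 0:
        raise UndefinedCompositionError("no group can explain the pigment vector")
    return GroupComposition.from_array(x / total, ratios.groups, group_chla=x)


def batch_estimate(samples: list[PigmentSample],
                   ratios: RatioMatrix | None = None
                   ) -> list[GroupComposition | Exception]:
    """Element-wise :func:`estimate_composition`, isolating per-row failures.

    Returns a list aligned with ``samples``; entries are either a
    :class:`GroupComposition` or the exception raised for that row.
    """
    if not samples:
        raise ValueError("empty sample list")
    if ratios is None:
        ratios = load_default_ratio_matrix()
    out: list[GroupComposition | Exception] = []
    for s in samples:
        try:
            out.append(estimate_composition(s, ratios))
        except (UndefinedCompositionError, ValueError) as exc:
            out.append(exc)
    return out
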