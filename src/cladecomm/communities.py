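"""Plot x species cover matrices: loading, cover-class mapping, filtering.

Field covers recorded in eight ordinal abundance classes are converted to
their class-midpoint percentages; species are retained when seen strictly
more than a minimum number of times, and plots when the retained species
account for at least a minimum fraction of total vegetation cover.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "CommunityMatrix",
    "PlotMetadata",
    "COVER_CLASS_MIDPOINTS",
    "DEFAULT_ZONE_BREAKPOINTS",
    "ZONE_NAMES",
    "map_cover_classes",
    "filter_species_by_frequency",
    "filter_plots_by_relative_cover",
    "assign_vegetation_zones",
    "read_community_csv",
    "read_metadata_csv",
]

#: midpoint percent cover of the eight ordinal abundance classes
COVER_CLASS_MIDPOINTS: dict[int, float] = {
    1: 0.05, 2: 0.5, 3: 3.0, 4: 10.0, 5: 20.0, 6: 37.5, 7: 62.5, 8: 82.5,
}

#: elevation breakpoints (m) separating the four vegetation zones; these are
#: configuration defaults, not field-calibrated values
DEFAULT_ZONE_BREAKPOINTS: tuple[float, ...] = (900.0, 1500.0, 2200.0)
ZONE_NAMES: tuple[str, ...] = ("colline", "montane", "subalpine", "alpine")


@dataclass(frozen=True)
class CommunityMatrix:
    """Percent cover of each species in each plot (0 = absent)."""

    cover: pd.DataFrame  # index: plot_id, columns: species, values in [0, 100]

    def __post_init__(self) -> None:
        df = self.cover
        if df.index.has_duplicates:
            raise ValueError("duplicate plot_ids")
        if df.columns.has_duplicates:
            raise ValueError("duplicate species names")
        vals = df.to_numpy(dtype=float)
        if np.isnan(vals).any():
            raise ValueError("cover matrix contains missing values")
        if (vals < 0).any() or (vals > 100).any():
            raise ValueError("cover values must lie in [0, 100]")

    @property
    def plot_ids(self) -> tuple[str, ...]:
        return tuple(map(str, self.cover.index))

    @property
    def species(self) -> tuple[str, ...]:
        return tuple(map(str, self.cover.columns))

    @property
    def presence(self) -> pd.DataFrame:
        """Boolean presence/absence (cover > 0)."""
        return self.cover > 0

    @property
    def occurrences(self) -> pd.Series:
        """Number of plots each species occurs in."""
        return self.presence.sum(axis=0)

    def subset_species(self, species) -> "CommunityMatrix":
        return CommunityMatrix(self.cover.loc[:, list(species)])

    def subset_plots(self, plot_ids) -> "CommunityMatrix":
        return CommunityMatrix(self.cover.loc[list(plot_ids), :])


@dataclass(frozen=True)
class PlotMetadata:
    """Per-plot elevation (m a.s.l.) and optional vegetation zone."""

    table: pd.DataFrame  # index: plot_id; columns: elevation [, zone]
    valid_elevation: tuple[float, float] = (0.0, 5000.0)

    def __post_init__(self) -> None:
        if "elevation" not in self.table.columns:
            raise ValueError("metadata must have an 'elevation' column")
        if self.table.index.has_duplicates:
            raise ValueError("duplicate plot_ids in metadata")
        elev = self.table["elevation"].to_numpy(dtype=float)
        lo, hi = self.valid_elevation
        if np.isnan(elev).any() or (elev < lo).any() or (elev > hi).any():
            raise ValueError(
                f"elevations outside the valid range [{lo}, {hi}] m"
            )

    @property
    def elevations(self) -> pd.Series:
        return self.table["elevation"].astype(float)

    def check_covers(self, cm: CommunityMatrix) -> None:
        missing = set(cm.plot_ids) - set(map(str, self.table.index))
        if missing:
            raise ValueError(
                f"{len(missing)} plots lack metadata, e.g. {sorted(missing)[:5]}"
            )


def map_cover_classes(raw: pd.DataFrame) -> CommunityMatrix:
    """Convert an ordinal class matrix (0 = absent, 1..8) to percent cover."""
    vals = raw.to_numpy()
    as_float = np.asarray(vals, dtype=float)
    if not np.all(np.isin(as_float, [0, 1, 2, 3, 4, 5, 6, 7, 8])):
        bad = np.unique(as_float[~np.isin(as_float, np.arange(9))])
        raise ValueError(f"cover classes outside 0..8: {bad[:10]}")
    lut = np.array([0.0] + [COVER_CLASS_MIDPOINTS[k] for k in range(1, 9)])
    mapped = lut[as_float.astype(int)]
    return CommunityMatrix(
        pd.DataFrame(mapped, index=raw.index, columns=raw.columns)
    )


def filter_species_by_frequency(
    cm: CommunityMatrix, min_occurrences: int = 20
) -> CommunityMatrix:
    """Retain species occurring strictly more than ``min_occurrences`` times."""
    if min_occurrences < 1:
        raise ValueError("min_occurrences must be >= 1")
    counts = cm.occurrences
    keep = counts[counts > min_occurrences].index
    if len(keep) == 0:
        raise ValueError(
            "no species exceed the frequency threshold "
            f"(max occurrence count is {int(counts.max())})"
        )
    return cm.subset_species(keep)


def filter_plots_by_relative_cover(
    cm: CommunityMatrix, retained, min_fraction: float = 0.8
) -> CommunityMatrix:
    """Keep plots where ``retained`` species hold >= ``min_fraction`` of cover.

    The returned matrix contains only the retained species columns, since
    downstream analyses operate on that species set.  Plots with zero total
    cover are dropped with a warning.
    """
    if not 0 < min_fraction <= 1:
        raise ValueError("min_fraction must be in (0, 1]")
    retained = [s for s in cm.species if s in set(retained)]
    if not retained:
        raise ValueError("retained species set is empty")
    total = cm.cover.sum(axis=1)
    zero = total == 0
    if zero.any():
        warnings.warn(f"dropping {int(zero.sum())} plots with zero total cover")
    part = cm.cover.loc[:, retained].sum(axis=1)
    frac = part.where(~zero, 0.0) / total.where(~zero, 1.0)
    keep = cm.cover.index[(frac >= min_fraction) & ~zero]
    return CommunityMatrix(cm.cover.loc[keep, retained])


def assign_vegetation_zones(
    meta: PlotMetadata, breakpoints=DEFAULT_ZONE_BREAKPOINTS
) -> PlotMetadata:
    """Assign each plot to a zone by half-open elevation intervals [lo, hi).

    Elevations outside the metadata's valid range are labelled "unassigned"
    (they cannot occur if validation passed, but guard against config drift).
    """
    bp = tuple(float(b) for b in breakpoints)
    if len(bp) != len(ZONE_NAMES) - 1 or any(
        b2 <= b1 for b1, b2 in zip(bp, bp[1:])
    ):
        raise ValueError("breakpoints must be 3 strictly increasing elevations")
    elev = meta.elevations.to_numpy()
    idx = np.searchsorted(bp, elev, side="right")
    zones = np.array(ZONE_NAMES, dtype=object)[idx]
    lo, hi = meta.valid_elevation
    out_of_span = (elev < lo) | (elev > hi)
    if out_of_span.any():
        warnings.warn(
            f"{int(out_of_span.sum())} plots outside the configured elevation "
            "span left unassigned"
        )
        zones[out_of_span] = "unassigned"
    table = meta.table.copy()
    table["zone"] = zones
    return PlotMetadata(table, meta.valid_elevation)


def read_community_csv(path: str, cover: str = "percent") -> CommunityMatrix:
    """Read a plot x species CSV (first column plot_id).

    ``cover`` declares the encoding: ``percent`` (values already in [0, 100])
    or ``classes`` (ordinal 0..8, converted via the class midpoints).
    """
    df = pd.read_csv(path, index_col=0)
    df.index = df.index.astype(str)
    if cover == "classes":
        return map_cover_classes(df)
    if cover == "percent":
        return CommunityMatrix(df.astype(float))
    raise ValueError(f"unknown cover encoding: {cover!r}")


def read_metadata_csv(
    path: str, valid_elevation: tuple[float, float] = (0.0, 5000.0)
) -> PlotMetadata:
    df = pd.read_csv(path, index_col=0)
    df.index = df.index.astype(str)
    return PlotMetadata(df, valid_elevation)
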