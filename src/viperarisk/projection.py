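"""Scenario projection: thresholding, masking, dispersal and range change.

The continuous ensemble map is converted to a binary range (the AOO
surrogate) at the minimal-predicted-area (MPA) threshold — the minimum
ensemble suitability observed at the training occurrences, so that every
occurrence cell is classified suitable.  Developed cells (human footprint
> 50) are masked out of both current and future ranges.  Futures are
evaluated under two dispersal extremes: "none" (future range restricted to
currently suitable cells) and "unlimited" (all newly suitable cells count).
Change statistics are expressed relative to the current range size.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ThresholdingError
from .occurrences import OccurrenceSet
from .raster import RasterGrid

DISPERSAL_SCENARIOS = ("none", "unlimited")


@dataclass
class ScenarioPlan:
    """Cartesian projection design: algorithms × replicates × GCM × RCP × period."""

    algorithms: list[str]
    replicates: int
    gcms: list[str]
    rcps: list[str]
    periods: list[str]

    def __post_init__(self) -> None:
        if (not self.algorithms or not self.gcms or not self.rcps
                or not self.periods or self.replicates < 1):
            raise ConfigurationError("every scenario-plan component must be non-empty")

    @property
    def n_projections(self) -> int:
        return (len(self.algorithms) * self.replicates * len(self.gcms)
                * len(self.rcps) * len(self.periods))


@dataclass(frozen=True)
class ProjectionTask:
    algorithm: str
    replicate: int
    gcm: str
    rcp: str
    period: str


def enumerate_projections(plan: ScenarioPlan) -> list[ProjectionTask]:
    """All projection tasks in deterministic (algorithm, replicate, gcm, rcp,
    period) order; the full factorial design."""
    return [ProjectionTask(a, r, g, c, p)
            for a, r, g, c, p in product(plan.algorithms,
                                         range(1, plan.replicates + 1),
                                         plan.gcms, plan.rcps, plan.periods)]


@dataclass
class BinaryRangeMap:
    """Thresholded presence/absence grid aligned with its source suitability."""

    values: np.ndarray  # boolean
    geometry: RasterGrid
    threshold_used: float = float("nan")
    masked: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=bool)
        if self.values.shape != self.geometry.shape:
            raise ConfigurationError("binary map shape must match geometry")
        # nodata can never be suitable
        self.values = self.values & ~self.geometry.nodata_mask

    @property
    def n_suitable(self) -> int:
        return int(self.values.sum())

    def like(self, values: np.ndarray, **overrides) -> "BinaryRangeMap":
        kw = {"threshold_used": self.threshold_used, "masked": self.masked}
        kw.update(overrides)
        return BinaryRangeMap(values, self.geometry, **kw)

    def write_ascii(self, path) -> None:
        out = self.geometry.like(self.values.astype(float))
        out.write_ascii(path)


def mpa_threshold(suitability: RasterGrid, occs: OccurrenceSet) -> float:
    """Minimal-predicted-area threshold: min suitability over occurrence cells.

    No occurrence is discarded as marginal, so binarising at this threshold
    classifies every occurrence cell as suitable.
    """
    vals = []
    for lon, lat in occs.lonlat:
        r, c = suitability.cell_of(lon, lat)
        if 0 <= r < suitability.n_rows and 0 <= c < suitability.n_cols \
                and not suitability.nodata_mask[r, c]:
            vals.append(suitability.values[r, c])
    if not vals:
        raise ThresholdingError("no occurrence falls on a valid suitability cell")
    return float(min(vals))


def binarize(suitability: RasterGrid, threshold: float) -> BinaryRangeMap:
    """Suitable iff suitability ≥ threshold; nodata is never suitable."""
    if not 0 <= threshold <= 1:
        raise ConfigurationError("threshold must be in [0, 1]")
    vals = suitability.values >= threshold
    return BinaryRangeMap(vals, suitability, threshold_used=threshold)


def apply_footprint_mask(binary: BinaryRangeMap, footprint: RasterGrid,
                         cutoff: float = 50.0) -> BinaryRangeMap:
    """Remove developed cells (footprint strictly greater than ``cutoff``).

    The same static mask is applied to current and future ranges alike.
    """
    binary.geometry.require_aligned(footprint)
    keep = ~(footprint.values > cutoff)
    return binary.like(binary.values & keep, masked=True)


def average_over_gcms(maps: list[RasterGrid]) -> RasterGrid:
    """Cellwise unweighted mean of aligned suitability maps (consensus map).

    Used for display/consensus output; change statistics are computed per GCM
    and then summarised (mean, SD) across GCMs.
    """
    if not maps:
        raise ConfigurationError("need at least one map to average")
    ref = maps[0]
    for m in maps[1:]:
        ref.require_aligned(m)
    return ref.like(np.mean([m.values for m in maps], axis=0))


def apply_dispersal(current: BinaryRangeMap, future: BinaryRangeMap,
                    scenario: str = "none") -> BinaryRangeMap:
    """Apply a dispersal extreme to a projected future range.

    ``none``: no colonisation — future range is intersected with the current
    range.  ``unlimited``: the projected future range stands as-is.
    """
    current.geometry.require_aligned(future.geometry)
    if scenario == "none":
        return future.like(future.values & current.values)
    if scenario == "unlimited":
        return future.like(future.values.copy())
    raise ConfigurationError(f"unknown dispersal scenario {scenario!r}")


@dataclass
class RangeChangeSummary:
    """Stable/loss/gain percentages of one clade × scenario, plus altitude."""

    clade: str = ""
    gcm: str = ""
    rcp: str = ""
    period: str = ""
    dispersal: str = "none"
    stable_pct: float = float("nan")
    loss_pct: float = float("nan")
    gain_pct: float = float("nan")
    net_change_pct: float = float("nan")
    current_cells: int = 0
    future_cells: int = 0
    mean_altitude_m: float = float("nan")

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def range_change(current: BinaryRangeMap, future: BinaryRangeMap,
                 **meta) -> RangeChangeSummary:
    """Stable/loss/gain percentages relative to the current range.

    loss = |current ∖ future| / |current| × 100, gain = |future ∖ current| /
    |current| × 100, stable = |current ∩ future| / |current| × 100; stable +
    loss = 100 and net change = gain − loss by construction.
    """
    current.geometry.require_aligned(future.geometry)
    n_cur = current.n_suitable
    if n_cur == 0:
        raise ConfigurationError("current range is empty; percentages undefined")
    cur, fut = current.values, future.values
    stable = int((cur & fut).sum())
    lost = int((cur & ~fut).sum())
    gained = int((fut & ~cur).sum())
    loss_pct = 100.0 * lost / n_cur
    gain_pct = 100.0 * gained / n_cur
    return RangeChangeSummary(
        stable_pct=100.0 * stable / n_cur,
        loss_pct=loss_pct,
        gain_pct=gain_pct,
        net_change_pct=gain_pct - loss_pct,
        current_cells=n_cur,
        future_cells=future.n_suitable,
        **meta,
    )


def mean_range_altitude(binary: BinaryRangeMap, dem: RasterGrid) -> float:
    """Unweighted mean elevation (m) over suitable cells."""
    binary.geometry.require_aligned(dem)
    if binary.n_suitable == 0:
        raise ConfigurationError("empty range: mean altitude undefined")
    return float(dem.values[binary.values].mean())


def summarize_over_gcms(summaries: list[RangeChangeSummary]) -> pd.DataFrame:
    """Mean and SD of the change statistics across GCMs.

    Grouped by (clade, rcp, period, dispersal); the SD columns quantify
    between-GCM uncertainty, zero when all GCMs agree.
    """
    df = pd.DataFrame([s.as_dict() for s in summaries])
    stats = ["stable_pct", "loss_pct", "gain_pct", "net_change_pct",
             "mean_altitude_m"]
    grouped = df.groupby(["clade", "rcp", "period", "dispersal"])[stats]
    out = grouped.agg(["mean", "std"])
    out.columns = [f"{c}_{s}" for c, s in out.columns]
    return out.fillna({c: 0.0 for c in out.columns if c.endswith("_std")}).reset_index()
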