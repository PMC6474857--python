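"""Threat classification and landscape-configuration metrics.

Projected AOO losses are mapped onto a four-level, loss-based threat scale
patterned on IUCN Red List reduction thresholds (level 1: 100% loss,
level 2: ≥80%, level 3: ≥50%, level 4: ≥30%; losses under 30% fall below the
assessment thresholds and are reported as level 0).  Landscape configuration
of a binary range map is summarised by the FRAGSTATS-style class metrics NP
(number of patches), PL (proportion of landscape), AI (aggregation index)
and SI (splitting index).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import ConfigurationError
from .projection import BinaryRangeMap, RangeChangeSummary

_ROOK = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])
_QUEEN = np.ones((3, 3), dtype=int)


def threat_level(loss_pct: float) -> int:
    """Loss-based threat category.

    1 iff loss = 100; 2 iff 80 ≤ loss < 100; 3 iff 50 ≤ loss < 80;
    4 iff 30 ≤ loss < 50; 0 (below assessment thresholds) iff loss < 30.
    """
    if not 0 <= loss_pct <= 100:
        raise ConfigurationError("loss_pct must be within [0, 100]")
    if loss_pct == 100:
        return 1
    if loss_pct >= 80:
        return 2
    if loss_pct >= 50:
        return 3
    if loss_pct >= 30:
        return 4
    return 0


def _structure(connectivity: str) -> np.ndarray:
    if connectivity == "rook":
        return _ROOK
    if connectivity == "queen":
        return _QUEEN
    raise ConfigurationError(f"unknown connectivity {connectivity!r}")


def label_patches(binary: BinaryRangeMap, connectivity: str = "rook"
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Connected components of suitable cells.

    Returns (label grid with ids 1..NP, array of patch sizes in cells).
    """
    labels, n = ndimage.label(binary.values, structure=_structure(connectivity))
    sizes = np.bincount(labels.ravel())[1:] if n else np.array([], dtype=int)
    return labels, sizes


def np_pl(binary: BinaryRangeMap, connectivity: str = "rook") -> tuple[int, float]:
    """Number of patches and proportion of the (valid) landscape suitable."""
    _, sizes = label_patches(binary, connectivity)
    n_valid = int((~binary.geometry.nodata_mask).sum())
    if n_valid < 1:
        raise ConfigurationError("landscape has no valid cells")
    return len(sizes), binary.n_suitable / n_valid


def _max_like_adjacencies(area: int) -> int:
    """Largest possible count of shared edges among ``area`` cells.

    Achieved by the most compact (quasi-square) arrangement: with
    n = ⌊√A⌋ and m = A − n², the maximum is 2n(n−1), plus 2m−1 if
    0 < m ≤ n, plus 2m−2 if m > n.
    """
    n = math.isqrt(area)
    m = area - n * n
    g = 2 * n * (n - 1)
    if m == 0:
        return g
    if m <= n:
        return g + 2 * m - 1
    return g + 2 * m - 2


def aggregation_index(binary: BinaryRangeMap) -> float:
    """Class-level aggregation index, 100 · g / g_max ∈ [0, 100].

    g counts rook adjacencies between suitable cells (each shared edge once);
    g_max is the compact-arrangement maximum for the class area.  Undefined
    (NaN) for a single-cell class, where g_max = 0.
    """
    area = binary.n_suitable
    if area == 0:
        raise ConfigurationError("aggregation index undefined for an empty class")
    v = binary.values
    g = int((v[:, :-1] & v[:, 1:]).sum() + (v[:-1, :] & v[1:, :]).sum())
    g_max = _max_like_adjacencies(area)
    if g_max == 0:
        return float("nan")
    return 100.0 * g / g_max


def splitting_index(binary: BinaryRangeMap, connectivity: str = "rook",
                    denominator: str = "landscape") -> float:
    """Splitting index SI = A² / Σ aᵢ² — effective number of equal patches.

    ``denominator`` chooses A: the total valid landscape cell count
    (FRAGSTATS class-level SPLIT, the default) or the suitable class area.
    """
    _, sizes = label_patches(binary, connectivity)
    if sizes.size == 0:
        raise ConfigurationError("splitting index undefined for an empty class")
    if denominator == "landscape":
        A = int((~binary.geometry.nodata_mask).sum())
    elif denominator == "class":
        A = int(sizes.sum())
    else:
        raise ConfigurationError(f"unknown SI denominator {denominator!r}")
    return float(A) ** 2 / float((sizes.astype(float) ** 2).sum())


@dataclass
class LandscapeMetrics:
    """NP/PL/AI/SI of one binary range map; AI and SI are NaN when undefined."""

    np: int
    pl: float
    ai: float
    si: float

    @classmethod
    def of(cls, binary: BinaryRangeMap, connectivity: str = "rook",
           si_denominator: str = "landscape") -> "LandscapeMetrics":
        n_patches, pl = np_pl(binary, connectivity)
        if n_patches == 0:
            return cls(0, 0.0, float("nan"), float("nan"))
        return cls(
            n_patches, pl,
            aggregation_index(binary),
            splitting_index(binary, connectivity, si_denominator),
        )


def assess(summaries: list[RangeChangeSummary],
           metrics: dict[tuple, LandscapeMetrics] | None = None) -> pd.DataFrame:
    """Join range change, threat level and landscape metrics per scenario.

    ``metrics`` maps (clade, gcm, rcp, period, dispersal) keys to the
    landscape metrics of the corresponding future range; scenarios without
    metrics are reported with empty metric fields rather than failing.
    """
    rows = []
    for s in summaries:
        row = s.as_dict()
        row["threat_level"] = threat_level(min(max(s.loss_pct, 0.0), 100.0))
        key = (s.clade, s.gcm, s.rcp, s.period, s.dispersal)
        m = (metrics or {}).get(key)
        row["np"] = m.np if m else None
        row["pl"] = m.pl if m else None
        row["ai"] = m.ai if m else None
        row["si"] = m.si if m else None
        rows.append(row)
    return pd.DataFrame(rows)
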