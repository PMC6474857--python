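"""Training-table assembly and collinearity screening.

Presence-only niche models need background contrast: pseudo-absences sampled
uniformly over the valid study grid.  Presences and pseudo-absences are
joined into a weighted training table (classes balanced to equal total
weight), and predictors are screened for collinearity with a pairwise
Pearson pre-filter followed by iterative VIF elimination.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, SamplingError, SelectionError
from .raster import PredictorStack

logger = logging.getLogger(__name__)


@dataclass
class TrainingTable:
    """Model-ready rows: label (1/0), weight, one column per predictor."""

    data: pd.DataFrame
    predictor_names: list[str]

    def __post_init__(self) -> None:
        for col in ("label", "weight", *self.predictor_names):
            if col not in self.data.columns:
                raise ConfigurationError(f"training table missing column {col!r}")
        if self.data[self.predictor_names].isna().any().any():
            raise ConfigurationError("training table contains missing predictor values")
        labels = set(self.data["label"].unique())
        if not labels <= {0, 1} or len(labels) < 2:
            raise ConfigurationError("need both presence (1) and absence (0) rows")

    @property
    def X(self) -> pd.DataFrame:
        return self.data[self.predictor_names]

    @property
    def y(self) -> np.ndarray:
        return self.data["label"].to_numpy(dtype=int)

    @property
    def w(self) -> np.ndarray:
        return self.data["weight"].to_numpy(dtype=float)

    def subset(self, names: Sequence[str]) -> "TrainingTable":
        missing = [n for n in names if n not in self.predictor_names]
        if missing:
            raise ConfigurationError(f"unknown predictors {missing}")
        cols = ["label", "weight", *names]
        return TrainingTable(self.data[cols].copy(), list(names))

    def write_csv(self, path: str | Path) -> None:
        self.data.to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path: str | Path) -> "TrainingTable":
        df = pd.read_csv(path)
        names = [c for c in df.columns if c not in ("label", "weight")]
        return cls(df, names)


def sample_pseudo_absences(stack: PredictorStack, n: int = 10_000,
                           seed: int = 0) -> np.ndarray:
    """Uniformly sample ``n`` distinct valid-cell centres as (lon, lat).

    Background points cover the whole study grid, presence cells included,
    to provide an unbiased environmental contrast.
    """
    valid = np.flatnonzero(~stack.nodata_mask.ravel())
    if n > valid.size:
        raise SamplingError(f"requested {n} pseudo-absences but only {valid.size} valid cells")
    rng = np.random.default_rng(seed)
    chosen = rng.choice(valid, size=n, replace=False)
    ref = stack.reference
    rows, cols = np.unravel_index(chosen, ref.shape)
    pts = np.array([ref.cell_center(int(r), int(c)) for r, c in zip(rows, cols)])
    return pts


def extract_values(stack: PredictorStack, points: np.ndarray) -> pd.DataFrame:
    """Layer values at each point's containing cell.

    Points outside the extent or on nodata cells are dropped with a warning;
    the returned frame keeps the surviving points' order and carries their
    original positional index in ``point_index``.
    """
    ref = stack.reference
    rows_out: list[dict] = []
    dropped = 0
    for i, (lon, lat) in enumerate(np.asarray(points, dtype=float)):
        r, c = ref.cell_of(lon, lat)
        if not (0 <= r < ref.n_rows and 0 <= c < ref.n_cols):
            dropped += 1
            continue
        if stack.nodata_mask[r, c]:
            dropped += 1
            continue
        rec = {"point_index": i, "lon": lon, "lat": lat}
        for name in stack.names:
            rec[name] = stack[name].values[r, c]
        rows_out.append(rec)
    if dropped:
        logger.warning("extract_values dropped %d point(s) outside extent or on nodata", dropped)
    return pd.DataFrame(rows_out, columns=["point_index", "lon", "lat", *stack.names])


def build_training_table(stack: PredictorStack, presences: np.ndarray,
                         absences: np.ndarray) -> TrainingTable:
    """Assemble a weighted presence/pseudo-absence table from a stack."""
    pres = extract_values(stack, presences)
    absn = extract_values(stack, absences)
    if pres.empty or absn.empty:
        raise ConfigurationError("need at least one valid presence and absence point")
    frames = []
    for label, df in ((1, pres), (0, absn)):
        block = df[stack.names].copy()
        block.insert(0, "label", label)
        block.insert(1, "weight", 1.0)
        frames.append(block)
    table = TrainingTable(pd.concat(frames, ignore_index=True), list(stack.names))
    return case_weights(table)


def case_weights(table: TrainingTable) -> TrainingTable:
    """Balance the two classes: presences weigh 1, absences n_pres/n_abs.

    Total presence weight then equals total absence weight, so the fitted
    models see a 50:50 prior regardless of how many background points were
    drawn.
    """
    data = table.data.copy()
    n_pres = int((data["label"] == 1).sum())
    n_abs = int((data["label"] == 0).sum())
    data.loc[data["label"] == 1, "weight"] = 1.0
    data.loc[data["label"] == 0, "weight"] = n_pres / n_abs
    return TrainingTable(data, table.predictor_names)


def vif(table: TrainingTable, predictor_subset: Sequence[str] | None = None
        ) -> dict[str, float]:
    """Variance inflation factor per predictor, 1/(1 − R²).

    R²_j comes from an ordinary (unweighted) least-squares regression of
    predictor j on all others plus an intercept.  Perfect collinearity is
    reported as ``inf`` rather than raised.
    """
    names = list(predictor_subset) if predictor_subset is not None \
        else list(table.predictor_names)
    if len(names) < 2:
        raise ConfigurationError("VIF needs at least two predictors")
    X = table.data[names].to_numpy(dtype=float)
    if X.shape[0] <= len(names):
        raise ConfigurationError("need more rows than predictors for VIF")
    out: dict[str, float] = {}
    for j, name in enumerate(names):
        y = X[:, j]
        others = np.delete(X, j, axis=1)
        A = np.column_stack([np.ones(len(y)), others])
        coef, *_ = np.linalg.lstsq(A, y, rcond=None)
        resid = y - A @ coef
        sst = float(((y - y.mean()) ** 2).sum())
        if sst == 0:
            out[name] = float("inf")
            continue
        r2 = 1.0 - float((resid**2).sum()) / sst
        out[name] = float("inf") if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return out


def select_predictors(table: TrainingTable, vif_threshold: float = 6.0,
                      cor_threshold: float = 0.75
                      ) -> tuple[list[str], list[dict]]:
    """Two-stage collinearity screen; returns (retained names, removal log).

    Stage A drops, from the worst-correlated pair, the member with the higher
    mean absolute correlation to all remaining predictors, until every
    pairwise |Pearson r| ≤ ``cor_threshold``.  Stage B then drops the
    max-VIF predictor until all VIF ≤ ``vif_threshold``.  Ties break
    lexicographically by name so the result does not depend on column order.
    """
    if vif_threshold <= 0 or cor_threshold <= 0:
        raise ConfigurationError("thresholds must be positive")
    names = sorted(table.predictor_names)
    log: list[dict] = []

    # stage A: pairwise correlation pre-filter
    while len(names) >= 2:
        corr = table.data[names].corr().abs()
        np.fill_diagonal(corr.values, 0.0)
        worst = corr.stack().idxmax()
        r = float(corr.loc[worst])
        if r <= cor_threshold:
            break
        a, b = sorted(worst)
        mean_a = float(corr.loc[a].drop(index=a).mean())
        mean_b = float(corr.loc[b].drop(index=b).mean())
        drop = a if (mean_a, a) > (mean_b, b) else b
        log.append({"dropped": drop, "stage": "correlation", "value": r,
                    "pair": [a, b]})
        names.remove(drop)

    # stage B: iterative VIF elimination
    while len(names) >= 2:
        vifs = vif(table, names)
        worst_name = max(sorted(vifs), key=lambda n: vifs[n])
        if vifs[worst_name] <= vif_threshold:
            break
        log.append({"dropped": worst_name, "stage": "vif",
                    "value": vifs[worst_name]})
        names.remove(worst_name)

    if not names:
        raise SelectionError("collinearity screening removed every predictor")
    # preserve the table's original predictor order in the output
    retained = [n for n in table.predictor_names if n in names]
    return retained, log
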