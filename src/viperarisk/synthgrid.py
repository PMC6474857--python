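"""Synthetic climate grids, terrain, footprint and virtual species.

This module manufactures inputs with the statistical structure the range-loss
analysis assumes — spatially autocorrelated and partially collinear climate
layers, a smooth mountainous DEM, a clustered 0–100 human-footprint index,
and a virtual species whose habitat suitability is a known quadratic-logistic
function of the climate — so that every downstream stage (model fitting,
thresholding, projection, risk scoring) can be verified against ground truth
without any external raster downloads.

All generators are pure functions of their seed and arguments.  Random fields
are smoothed white noise (Gaussian kernel), which is the simplest construction
giving a controllable autocorrelation range.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.special import expit

from .errors import ConfigurationError, SamplingError
from .occurrences import OccurrenceSet
from .raster import PredictorStack, RasterGrid

#: Names given to the first six generated layers, mirroring the bioclim
#: variables a climate-only niche model typically retains (annual mean
#: temperature, temperature seasonality, max temperature of warmest month,
#: annual precipitation, precipitation of driest month, precipitation
#: seasonality).
BIOCLIM_NAMES = ("bio1", "bio4", "bio5", "bio12", "bio14", "bio15")


def _rng(seed: int, *context: object) -> np.random.Generator:
    """Deterministic generator from a seed plus free-form context tokens."""
    token = ":".join([str(seed), *map(str, context)])
    digest = hashlib.sha256(token.encode()).digest()
    return np.random.default_rng(int.from_bytes(digest[:4], "big"))


def _smooth_field(rng: np.random.Generator, n_rows: int, n_cols: int,
                  sigma: float) -> np.ndarray:
    """Unit-variance Gaussian random field via kernel-smoothed white noise."""
    field_ = gaussian_filter(rng.standard_normal((n_rows, n_cols)), sigma=sigma,
                             mode="reflect")
    sd = field_.std()
    return field_ / sd if sd > 0 else field_


@dataclass
class VirtualSpeciesSpec:
    """Ground-truth niche of a virtual species.

    Suitability is ``logistic(intercept + Σ_j lin_j·x_j + quad_j·x_j²)`` with
    non-positive quadratic coefficients, i.e. a unimodal response along each
    climate axis.  If ``prevalence_target`` is set, the intercept is
    re-calibrated at evaluation time so mean suitability over valid cells hits
    the target (within ``0.02``).
    """

    coefficients: dict[str, tuple[float, float]]
    intercept: float = 0.0
    prevalence_target: float | None = None

    def __post_init__(self) -> None:
        if not any(l != 0 or q != 0 for l, q in self.coefficients.values()):
            raise ConfigurationError("virtual species needs a nonzero coefficient")
        for name, (_, quad) in self.coefficients.items():
            if quad > 0:
                raise ConfigurationError(
                    f"quadratic coefficient for {name!r} must be <= 0 (unimodal niche)"
                )
        if self.prevalence_target is not None and not 0 < self.prevalence_target < 1:
            raise ConfigurationError("prevalence_target must be in (0, 1)")


@dataclass
class ScenarioPerturbation:
    """Phenomenological future-climate perturbation for one GCM/RCP/period.

    ``additive_shift`` moves named layers by a constant (layer units);
    ``noise_sd`` adds a smooth zero-mean field per layer emulating between-GCM
    spatial disagreement.
    """

    gcm_name: str = "GCM1"
    rcp_name: str = "RCP4.5"
    period: str = "2050"
    additive_shift: dict[str, float] = field(default_factory=dict)
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be non-negative")


def make_climate_stack(seed: int, n_layers: int = 6, n_rows: int = 100,
                       n_cols: int = 100, autocorr_range_cells: float = 10.0,
                       collinear_pairs: int = 2,
                       names: tuple[str, ...] | None = None,
                       gradient_strength: float = 0.7,
                       origin_lon: float = 30.0, origin_lat: float = 40.0,
                       cell_size: float = 0.01) -> PredictorStack:
    """Generate a stack of autocorrelated, partially collinear climate layers.

    The first ``n_layers - collinear_pairs`` layers are independent smoothed
    Gaussian fields plus a north–south gradient (emulating the latitudinal
    trend of temperature-like variables).  Each of the last
    ``collinear_pairs`` layers is a copy of one base layer plus small noise,
    guaranteeing ``collinear_pairs`` layer pairs with |Pearson r| > 0.8.
    """
    if n_rows <= 0 or n_cols <= 0:
        raise ConfigurationError("grid dimensions must be positive")
    if n_layers < 2:
        raise ConfigurationError("need at least two layers")
    if autocorr_range_cells < 1:
        raise ConfigurationError("autocorr_range_cells must be >= 1")
    if not 0 <= collinear_pairs <= n_layers - 1:
        raise ConfigurationError("collinear_pairs must be in [0, n_layers-1]")

    if names is None:
        names = tuple(BIOCLIM_NAMES[:n_layers]) if n_layers <= len(BIOCLIM_NAMES) \
            else tuple(f"bio{i + 1}" for i in range(n_layers))
    if len(names) != n_layers:
        raise ConfigurationError("names length must equal n_layers")

    lat_gradient = np.linspace(1.0, -1.0, n_rows)[:, None] * np.ones((1, n_cols))
    n_base = n_layers - collinear_pairs
    layers: dict[str, RasterGrid] = {}
    base_values: list[np.ndarray] = []
    for i in range(n_base):
        rng = _rng(seed, "climate", i)
        vals = _smooth_field(rng, n_rows, n_cols, autocorr_range_cells) \
            + gradient_strength * lat_gradient
        base_values.append(vals)
        layers[names[i]] = RasterGrid(vals, origin_lon, origin_lat, cell_size)
    for k in range(collinear_pairs):
        rng = _rng(seed, "collinear", k)
        base = base_values[k % n_base]
        vals = base + 0.1 * _smooth_field(rng, n_rows, n_cols, autocorr_range_cells)
        layers[names[n_base + k]] = RasterGrid(vals, origin_lon, origin_lat, cell_size)
    return PredictorStack(layers)


def collinear_partners(n_layers: int, collinear_pairs: int,
                       names: tuple[str, ...] | None = None) -> dict[str, list[str]]:
    """Base-layer → collinear-copy names for a ``make_climate_stack`` call.

    Mirrors the stack construction (copy k duplicates base layer k mod
    n_base).  Used to perturb a base layer and its copies coherently, the way
    physically correlated climate variables shift together.
    """
    if names is None:
        names = tuple(BIOCLIM_NAMES[:n_layers]) if n_layers <= len(BIOCLIM_NAMES) \
            else tuple(f"bio{i + 1}" for i in range(n_layers))
    n_base = n_layers - collinear_pairs
    out: dict[str, list[str]] = {}
    for k in range(collinear_pairs):
        out.setdefault(names[k % n_base], []).append(names[n_base + k])
    return out


def make_dem(seed: int, n_rows: int = 100, n_cols: int = 100,
             relief_m: float = 3000.0, autocorr_range_cells: float = 8.0,
             origin_lon: float = 30.0, origin_lat: float = 40.0,
             cell_size: float = 0.01) -> RasterGrid:
    """Smooth mountainous elevation model in metres.

    Elevations are non-negative with max − min equal to ``relief_m``; ridges
    arise from folding a smooth field about its median (absolute value), which
    produces connected high-elevation crests rather than isolated bumps.
    """
    if n_rows <= 0 or n_cols <= 0:
        raise ConfigurationError("grid dimensions must be positive")
    if relief_m <= 0:
        raise ConfigurationError("relief_m must be positive")
    rng = _rng(seed, "dem")
    f = _smooth_field(rng, n_rows, n_cols, autocorr_range_cells)
    ridges = np.abs(f - np.median(f))
    elev = relief_m * (ridges - ridges.min()) / (ridges.max() - ridges.min())
    return RasterGrid(elev, origin_lon, origin_lat, cell_size)


def make_footprint(seed: int, geometry: RasterGrid,
                   developed_fraction: float = 0.1,
                   autocorr_range_cells: float = 6.0) -> RasterGrid:
    """Clustered human-footprint index on the grid of ``geometry``.

    Integer values 0–100; exactly ``round(fraction × n_cells)`` cells exceed
    50 (the conventional "developed" cutoff), placed where a smooth latent
    field is highest so that developed areas form spatial clusters, as cities
    and road corridors do.
    """
    if not 0 <= developed_fraction <= 1:
        raise ConfigurationError("developed_fraction must be in [0, 1]")
    rng = _rng(seed, "footprint")
    n_rows, n_cols = geometry.shape
    latent = _smooth_field(rng, n_rows, n_cols, autocorr_range_cells)
    # tiny jitter breaks rank ties so the developed count is exact
    latent = latent + 1e-9 * rng.standard_normal(latent.shape)
    order = np.argsort(latent, axis=None)
    ranks = np.empty(latent.size, dtype=float)
    ranks[order] = np.arange(latent.size)
    ranks /= max(latent.size - 1, 1)
    n_dev = int(round(developed_fraction * latent.size))
    cut = 1.0 - n_dev / latent.size
    vals = np.empty(latent.size, dtype=float)
    low = ranks < cut if n_dev > 0 else np.ones(latent.size, dtype=bool)
    vals[low] = np.floor(50 * ranks[low] / max(cut, 1e-12))
    vals[~low] = 51 + np.floor(49 * (ranks[~low] - cut) / max(1 - cut, 1e-12))
    vals = np.clip(vals, 0, 100).reshape(geometry.shape)
    return geometry.like(vals)


def _linear_predictor(stack: PredictorStack, spec: VirtualSpeciesSpec) -> np.ndarray:
    eta = np.zeros(stack.reference.shape)
    for name, (lin, quad) in spec.coefficients.items():
        if name not in stack:
            raise ConfigurationError(f"virtual species references missing layer {name!r}")
        x = stack[name].values
        eta += lin * x + quad * x**2
    return eta


def true_suitability(stack: PredictorStack, spec: VirtualSpeciesSpec) -> RasterGrid:
    """Ground-truth habitat suitability of the virtual species on a stack.

    Cellwise ``logistic(intercept + Σ lin·x + quad·x²)`` in (0, 1).  When the
    species declares a prevalence target, the intercept is adjusted by 1-D
    bisection so that mean suitability over valid cells is within 0.02 of the
    target; because the logistic is strictly increasing in its intercept the
    bisection always converges.
    """
    eta = _linear_predictor(stack, spec)
    valid = ~stack.nodata_mask
    if spec.prevalence_target is None:
        suit = expit(spec.intercept + eta)
    else:
        target = spec.prevalence_target
        lo, hi = -50.0, 50.0
        while expit(hi + eta[valid]).mean() < target and hi < 1e6:
            hi *= 2
        while expit(lo + eta[valid]).mean() > target and lo > -1e6:
            lo *= 2
        for _ in range(200):
            mid = 0.5 * (lo + hi)
            mean = expit(mid + eta[valid]).mean()
            if abs(mean - target) <= 1e-4:
                break
            if mean < target:
                lo = mid
            else:
                hi = mid
        suit = expit(mid + eta)
    suit = np.clip(suit, 1e-12, 1 - 1e-12)
    out = stack.reference.like(suit)
    out.values[stack.nodata_mask] = 0.0
    return out


def sample_occurrences(suitability: RasterGrid, n: int, seed: int,
                       clade: str = "virtual") -> OccurrenceSet:
    """Sample ``n`` distinct occurrence cells ∝ suitability.

    One occurrence per cell (without replacement), mimicking spatially thinned
    field records; points are returned at cell centres.
    """
    if n < 1:
        raise ConfigurationError("n must be >= 1")
    probs = suitability.values.astype(float).ravel().copy()
    probs[suitability.nodata_mask.ravel()] = 0.0
    positive = int((probs > 0).sum())
    if n > positive:
        raise SamplingError(
            f"requested {n} occurrences but only {positive} cells have positive suitability"
        )
    rng = _rng(seed, "occurrences")
    idx = rng.choice(probs.size, size=n, replace=False, p=probs / probs.sum())
    rows, cols = np.unravel_index(idx, suitability.shape)
    records = []
    for i, (r, c) in enumerate(zip(rows, cols)):
        lon, lat = suitability.cell_center(int(r), int(c))
        records.append((f"occ{i:04d}", clade, lon, lat))
    return OccurrenceSet.from_records(records, provenance="synthetic")


def make_future_stack(current: PredictorStack, pert: ScenarioPerturbation,
                      seed: int) -> PredictorStack:
    """Perturb a climate stack into one GCM × RCP × period future.

    Each layer named in ``additive_shift`` is moved by its constant and, when
    ``noise_sd`` > 0, by an independent smooth zero-mean field with standard
    deviation ``noise_sd``.  Noise fields are seeded by (seed, gcm, rcp,
    period, layer), so two GCMs disagree spatially even at the same seed.
    Geometry and nodata mask are preserved.
    """
    unknown = set(pert.additive_shift) - set(current.names)
    if unknown:
        raise ConfigurationError(f"perturbation names absent from stack: {sorted(unknown)}")
    layers: dict[str, RasterGrid] = {}
    for name in current.names:
        layer = current[name]
        vals = layer.values.copy()
        if name in pert.additive_shift:
            vals = vals + pert.additive_shift[name]
            if pert.noise_sd > 0:
                rng = _rng(seed, "future", pert.gcm_name, pert.rcp_name,
                           pert.period, name)
                vals = vals + pert.noise_sd * _smooth_field(
                    rng, layer.n_rows, layer.n_cols, 6.0)
        layers[name] = layer.like(vals)
    return PredictorStack(layers)


def true_mpa_cutoff(suitability: RasterGrid, occs: OccurrenceSet) -> float:
    """Operational truth cutoff: min true suitability over occurrence cells.

    Applies the minimal-predicted-area rule to the *true* suitability field,
    so the virtual species' ground-truth range is defined by the same
    operational rule the pipeline uses for its estimate (every occurrence
    cell counts as occupied, marginal habitat included).
    """
    vals = [suitability.values[suitability.cell_of(lon, lat)]
            for lon, lat in occs.lonlat]
    if not vals:
        raise ConfigurationError("no occurrences to derive a truth cutoff from")
    return float(min(vals))


def true_range_loss(stack: PredictorStack, future: PredictorStack,
                    spec: VirtualSpeciesSpec, cutoff: float = 0.5) -> float:
    """True no-dispersal range loss (%) between two climates.

    The species' true range under a climate is the set of cells whose true
    suitability is ≥ ``cutoff`` (the intercept calibrated on the *current*
    stack is reused for the future so both ranges live on the same scale).
    """
    cur_suit = true_suitability(stack, spec)
    if spec.prevalence_target is not None:
        # recover the calibrated intercept implied by the current-climate map
        eta = _linear_predictor(stack, spec)
        valid = ~stack.nodata_mask
        logit = np.log(cur_suit.values[valid] / (1 - cur_suit.values[valid]))
        intercept = float(np.median(logit - eta[valid]))
        frozen = VirtualSpeciesSpec(spec.coefficients, intercept, None)
    else:
        frozen = spec
    fut_suit = true_suitability(future, frozen)
    valid = ~stack.nodata_mask
    cur = cur_suit.values >= cutoff
    fut = fut_suit.values >= cutoff
    cur &= valid
    fut &= valid
    n_cur = int(cur.sum())
    if n_cur == 0:
        raise ConfigurationError("true current range is empty at this cutoff")
    lost = int((cur & ~fut).sum())
    return 100.0 * lost / n_cur


def calibrate_shift_for_loss(stack: PredictorStack, spec: VirtualSpeciesSpec,
                             layer: str, target_loss_pct: float,
                             cutoff: float = 0.5, max_shift: float = 20.0,
                             tol_pct: float = 0.5) -> float:
    """Find the additive shift on one layer producing a target true loss.

    Bisection on the shift magnitude; assumes loss is non-decreasing in the
    shift (true for a unimodal niche pushed off its optimum), which holds for
    the generator's default virtual species.
    """
    if layer not in stack:
        raise ConfigurationError(f"no layer named {layer!r}")

    def loss(delta: float) -> float:
        pert = ScenarioPerturbation(additive_shift={layer: delta})
        return true_range_loss(stack, make_future_stack(stack, pert, 0), spec, cutoff)

    lo, hi = 0.0, max_shift
    if loss(hi) < target_loss_pct:
        raise ConfigurationError(
            f"target loss {target_loss_pct}% unreachable with shift <= {max_shift}")
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        l_mid = loss(mid)
        if abs(l_mid - target_loss_pct) <= tol_pct:
            return mid
        if l_mid < target_loss_pct:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)
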