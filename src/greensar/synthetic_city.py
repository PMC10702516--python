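"""Synthetic study inputs with known ground truth.

Emulates a drive-by air-quality campaign on an urban road network: points
spaced ~50 m apart (jittered grid), spatially smooth greenspace fields with
street-level (GVI) and overhead (NDVI) components, positive smooth covariate
fields (temperature, precipitation, population density, traffic in passenger
car units), segmented street-view label masks and NIR/red band rasters that
round-trip exactly through the metric computations, and pollutant
concentrations generated by a simultaneous-autoregressive (SAR) process

    log y = (I - rho W)^(-1) (X beta + eps),   eps ~ N(0, sigma_eps^2 I)

with configurable spatial feedback rho and a negative greenspace coefficient
beta1, so that every downstream estimator can be validated against the truth.

Smooth fields are produced by Gaussian-kernel smoothing of white noise over
neighboring points (a cheap Gaussian-process stand-in: O(n k) instead of
O(n^3), with the same qualitative distance-decaying correlation).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy.spatial import cKDTree

from greensar.points import PointSet
from greensar.rasters import BandRaster, GeoTransform
from greensar.weights import SpatialWeightMatrix, build_kernel_weights

POLLUTANTS = ("pm25", "no2", "no", "co", "co2")

# marginal levels the generator aims at (means in ug/m3 for pm25/no2/no,
# mg/m3 for co/co2) — typical urban drive-by campaign magnitudes
DEFAULT_POLLUTANT_MEANS = {
    "pm25": 6.49, "no2": 17.62, "no": 24.56, "co": 809.0, "co2": 0.37,
}


@dataclass
class SyntheticCityConfig:
    """Ground-truth parameters of the synthetic city.

    ``beta_true`` orders coefficients as (intercept adjustment, greenspace
    GVI in %, temperature, precipitation, population density, traffic),
    acting on the standardized covariates but on raw GVI, with the pollutant
    modeled on the natural-log scale.  Per-pollutant intercepts are derived
    from ``pollutant_log_means`` so concentrations land near realistic urban
    levels.
    """

    n_points: int = 2000
    extent: tuple = (10000.0, 10000.0)    # meters; city-scale domain so the
                                          # largest buffer stays local
    spacing: float = 50.0                 # target inter-point distance, m
    field_range: float = 400.0            # correlation length of fields, m
    gvi_mean: float = 14.15               # %
    gvi_sd: float = 9.94                  # %
    ndvi_mean: float = 0.12
    ndvi_sd: float = 0.07
    ndvi_gvi_corr: float = 0.7            # latent correlation of the two fields
    rho_true: float = 0.5
    beta_true: tuple = (0.0, -0.02, 0.05, -0.02, 0.08, 0.12)
    sigma_eps: float = 0.3                # SD of the log-scale SAR innovation
    k_weights: int = 15
    pollutant_means: dict = dc_field(default_factory=lambda: dict(DEFAULT_POLLUTANT_MEANS))
    seed: int = 0

    def __post_init__(self):
        if abs(self.rho_true) >= 1:
            raise ValueError("|rho_true| must be < 1 for a stationary SAR process")
        if self.sigma_eps < 0:
            raise ValueError("sigma_eps must be nonnegative")
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")
        if len(self.beta_true) != 6:
            raise ValueError("beta_true must have 6 entries "
                             "(intercept, greenspace, 4 covariates)")


def _rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def generate_points(config: SyntheticCityConfig) -> PointSet:
    """Jittered-grid road midpoints with minimum pairwise distance >= spacing/2.

    Grid cells of size ``spacing`` are sampled without replacement and each
    point is jittered uniformly within +/- spacing/4 per axis, which bounds
    the minimum pairwise distance below by spacing/2.
    """
    s = config.spacing
    nx = int(config.extent[0] // s)
    ny = int(config.extent[1] // s)
    if config.n_points < 2:
        raise ValueError("n_points must be at least 2")
    if nx * ny < config.n_points:
        raise ValueError(
            f"extent {config.extent} holds only {nx * ny} cells at spacing {s}; "
            f"cannot place {config.n_points} points")
    rng = np.random.default_rng(config.seed)
    cells = rng.choice(nx * ny, size=config.n_points, replace=False)
    cx = (cells % nx + 0.5) * s
    cy = (cells // nx + 0.5) * s
    jitter = rng.uniform(-s / 4, s / 4, size=(config.n_points, 2))
    return PointSet(np.arange(config.n_points), cx + jitter[:, 0], cy + jitter[:, 1])


def smooth_field(points: PointSet, field_range: float,
                 rng: np.random.Generator) -> np.ndarray:
    """Unit-variance spatially smooth field by kernel smoothing of white noise.

    z_i = sum_j k(d_ij) eps_j / sqrt(sum_j k(d_ij)^2) with a Gaussian kernel
    of length scale field_range/2 truncated at 2*field_range, giving each
    point marginal variance one and correlation decaying with distance.
    """
    if field_range <= 0:
        raise ValueError("field_range must be positive")
    eps = rng.standard_normal(points.n)
    tree = cKDTree(points.coords)
    ell = field_range / 2.0
    pairs = tree.sparse_distance_matrix(tree, max_distance=2 * field_range,
                                        output_type="coo_matrix")
    k = np.exp(-(pairs.data / ell) ** 2)
    K = sp.csr_matrix((k, (pairs.row, pairs.col)), shape=(points.n, points.n))
    num = K @ eps
    norm = np.sqrt(np.asarray(K.power(2).sum(axis=1)).ravel())
    return num / norm


def generate_greenspace_field(points: PointSet, config: SyntheticCityConfig,
                              rng=None):
    """Per-point GVI (%) and NDVI with spatial correlation and shared structure.

    Returns (gvi, ndvi).  GVI is clipped to [0, 100] and NDVI to [-1, 1];
    the two share a latent field (correlation ``ndvi_gvi_corr``) so
    street-level and overhead greenery agree where they should.
    """
    rng = _rng(config.seed + 1 if rng is None else rng)
    z1 = smooth_field(points, config.field_range, rng)
    z2 = smooth_field(points, config.field_range, rng)
    c = config.ndvi_gvi_corr
    z_ndvi = c * z1 + np.sqrt(1 - c ** 2) * z2
    gvi = np.clip(config.gvi_mean + config.gvi_sd * z1, 0.0, 100.0)
    ndvi = np.clip(config.ndvi_mean + config.ndvi_sd * z_ndvi, -1.0, 1.0)
    return gvi, ndvi


def render_segmented_images(gvi_value: float, image_shape=(100, 100),
                            seed: int = 0):
    """Six binary label masks whose pooled green fraction encodes gvi_value.

    The pooled green-pixel count is gvi_value/100 of the total pixel count
    across the six views, rounded to the nearest whole pixel, so
    compute_gvi recovers gvi_value to within the pixel quantum
    100/(6*H*W).
    """
    if not 0.0 <= gvi_value <= 100.0:
        raise ValueError("gvi_value must lie in [0, 100]")
    h, w = image_shape
    total = 6 * h * w
    n_green = int(round(gvi_value / 100.0 * total))
    rng = np.random.default_rng(seed)
    flat = np.zeros(total, dtype=np.uint8)
    flat[rng.choice(total, size=n_green, replace=False)] = 1
    return [flat[i * h * w:(i + 1) * h * w].reshape(h, w) for i in range(6)]


def render_band_rasters(points: PointSet, ndvi_values, cell_size: float = 10.0,
                        background_ndvi: float = 0.1):
    """NIR and red band rasters that reproduce the given NDVI at each point.

    At the cell containing each point, NIR = (1+v)/2 and Red = (1-v)/2 so
    (NIR-R)/(NIR+R) = v exactly.  Values at +/-1 would force a zero band
    and are clipped to +/-(1 - 1e-6) with a warning.  Remaining cells carry
    a uniform background.  Returns a BandRaster (georeferenced so the
    point-to-cell lookup is exact).
    """
    v = np.asarray(ndvi_values, float)
    if np.any(np.abs(v) >= 1.0):
        warnings.warn("NDVI values at +/-1 clipped to +/-(1 - 1e-6)", stacklevel=2)
        v = np.clip(v, -1 + 1e-6, 1 - 1e-6)
    x0 = points.x.min() - cell_size
    y1 = points.y.max() + cell_size
    ncols = int(np.ceil((points.x.max() + cell_size - x0) / cell_size)) + 1
    nrows = int(np.ceil((y1 - (points.y.min() - cell_size)) / cell_size)) + 1
    gt = GeoTransform(x0, y1, cell_size, -cell_size)
    nir = np.full((nrows, ncols), (1 + background_ndvi) / 2)
    red = np.full((nrows, ncols), (1 - background_ndvi) / 2)
    row, col = gt.rowcol(points.x, points.y)
    occupied = {}
    for i, (r, c) in enumerate(zip(row, col)):
        if (r, c) in occupied:
            raise ValueError(
                f"points {occupied[(r, c)]} and {points.ids[i]} share raster cell "
                f"{(r, c)}; decrease cell_size")
        occupied[(r, c)] = points.ids[i]
        nir[r, c] = (1 + v[i]) / 2
        red[r, c] = (1 - v[i]) / 2
    return BandRaster(nir=nir, red=red, transform=gt)


def generate_covariates(points: PointSet, seed: int = 0, field_range: float = 400.0,
                        variances=(1.0, 1.0, 1.0, 1.0)) -> pd.DataFrame:
    """Four spatially smooth, strictly positive covariate fields.

    temperature (deg C) and precipitation (mm) are Gaussian around urban
    levels; population density (persons/km^2) and traffic (passenger car
    units/h) are log-normal, all sharing the smoothing kernel of the
    greenspace fields.  ``variances`` scale the four fields' variability
    (zeros give constant fields).
    """
    rng = np.random.default_rng(seed)
    z = [smooth_field(points, field_range, rng) for _ in range(4)]
    v = np.sqrt(np.asarray(variances, float))
    temp = np.maximum(10.6 + 1.2 * v[0] * z[0], 0.1)
    precip = np.maximum(62.0 + 12.0 * v[1] * z[1], 0.1)
    popden = np.exp(np.log(3500.0) + 0.5 * v[2] * z[2])
    traffic = np.exp(np.log(500.0) + 0.6 * v[3] * z[3])
    return pd.DataFrame({
        "temperature": temp, "precipitation": precip,
        "population_density": popden, "traffic_pcu": traffic,
    })


def simulate_pollution(swm: SpatialWeightMatrix, X: np.ndarray, beta,
                       rho: float, sigma_eps: float, seed: int = 0) -> np.ndarray:
    """Draw one SAR-process field y = (I - rho W)^(-1) (X beta + eps).

    Uses a sparse direct solve (never a dense inverse).  W must be
    row-standardized and |rho| < 1 for stationarity; X must include an
    intercept column.
    """
    if abs(rho) >= 1:
        raise ValueError("|rho| must be < 1 for a stationary SAR process")
    swm.require_standardized()
    X = np.asarray(X, float)
    if not any(np.ptp(X[:, j]) == 0 and X[0, j] != 0 for j in range(X.shape[1])):
        raise ValueError("X must include an intercept column")
    rng = _rng(seed)
    n = X.shape[0]
    eps = rng.standard_normal(n) * sigma_eps
    rhs = X @ np.asarray(beta, float) + eps
    A = (sp.identity(n) - rho * swm.W).tocsc()
    return spla.spsolve(A, rhs)


@dataclass
class SyntheticCity:
    """A complete simulated study with its generating truth."""

    config: SyntheticCityConfig
    points: PointSet
    gvi: np.ndarray
    ndvi: np.ndarray
    covariates: pd.DataFrame
    weights: SpatialWeightMatrix
    pollutants: pd.DataFrame       # concentrations (exp of the SAR log-field)
    design: np.ndarray             # the X actually used by the SAR process
    design_names: list

    def tables(self):
        """(points, greenspace, covariates, pollutants) as tidy DataFrames."""
        green = pd.DataFrame({"id": self.points.ids, "gvi": self.gvi,
                              "ndvi": self.ndvi})
        return self.points.to_frame(), green, self.covariates, self.pollutants


def generate_city(config: SyntheticCityConfig) -> SyntheticCity:
    """Generate the full synthetic study deterministically from config.seed.

    The SAR design matrix is (1, GVI %, standardized covariates); the
    per-pollutant intercept is chosen so the mean log-concentration sits
    near log of the configured pollutant mean.
    """
    points = generate_points(config)
    gvi, ndvi = generate_greenspace_field(points, config)
    cov = generate_covariates(points, seed=config.seed + 2,
                              field_range=config.field_range)
    swm = build_kernel_weights(points, k=config.k_weights)

    covz = (cov - cov.mean()) / cov.std(ddof=0)
    X = np.column_stack([np.ones(points.n), gvi, covz.to_numpy()])
    names = ["intercept", "gvi", *cov.columns]
    beta = np.asarray(config.beta_true, float)

    poll = {}
    for j, (name, mean_level) in enumerate(config.pollutant_means.items()):
        b = beta.copy()
        # center the log-field at log(mean_level): E[y] ~ mean(X beta)/(1-rho)
        b[0] = beta[0] + np.log(mean_level) * (1 - config.rho_true) - beta[1] * gvi.mean()
        logy = simulate_pollution(swm, X, b, config.rho_true, config.sigma_eps,
                                  seed=config.seed + 100 + j)
        poll[name] = np.exp(logy)
    pollutants = pd.DataFrame(poll)
    return SyntheticCity(config=config, points=points, gvi=gvi, ndvi=ndvi,
                         covariates=cov, weights=swm, pollutants=pollutants,
                         design=X, design_names=names)
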