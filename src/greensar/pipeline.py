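"""Full-study orchestration: simulate or ingest, screen, fit, report.

One run analyses every pollutant x greenspace-metric x spatial-scale
combination (5 x 3 x 6 = 90 by default) on a shared unit set: pollution
points that survive the outlier screen and have complete greenspace metrics
at every scale.  All fits at every scale share one spatial weight matrix —
the regression units are the same points throughout; only the greenspace
aggregation changes — so the log-determinant machinery is built once.

Effect estimates come from the spatial lag model (with the spillover total
effect alongside); the SLM-vs-SEM choice by residual Moran's I is recorded
per fit in the diagnostics bundle.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from greensar.diagnostics import lm_tests, morans_i, screen_outliers
from greensar.greenspace import (BUFFER_RADII_M, build_greenspace_table,
                                 compute_iqr, scale_label)
from greensar.points import PointSet
from greensar.sar import LogDeterminant, fit_sem, fit_slm, pct_per_iqr, select_model
from greensar.synthetic_city import SyntheticCity, SyntheticCityConfig, generate_city
from greensar.weights import build_kernel_weights

logger = logging.getLogger("greensar")

DEFAULT_METRICS = ("gvi", "ndvi", "ratio")
DEFAULT_COVARIATES = ("temperature", "precipitation", "population_density",
                      "traffic_pcu")


@dataclass
class StudyConfig:
    """Configuration of a full study run.

    Either ``simulate`` (a synthetic-city block) or ``input_dir`` (a
    directory of points.csv, greenspace.csv, covariates.csv,
    pollutants.csv) must be provided.  ``seed``, when set, overrides the
    simulate block's seed so one integer drives the whole run.
    """

    simulate: SyntheticCityConfig | None = None
    input_dir: str | None = None
    radii_m: tuple = BUFFER_RADII_M
    k_weights: int = 15
    pollutants: tuple | None = None        # default: every pollutant column
    metrics: tuple = DEFAULT_METRICS
    covariates: tuple = DEFAULT_COVARIATES
    z_thresh: float = 3.0
    maha_quantile: float = 0.975
    n_perm: int = 999
    alpha: float = 0.05
    log_scale: bool = True
    use_total: bool = False                # report T_ef instead of beta1
    seed: int | None = None

    def __post_init__(self):
        radii = tuple(float(r) for r in self.radii_m)
        if len(set(radii)) != len(radii):
            raise ValueError("config key radii_m: radii must be unique")
        if any(r < 0 for r in radii):
            raise ValueError("config key radii_m: radii must be nonnegative")
        self.radii_m = radii
        if not 0 < self.alpha < 1:
            raise ValueError("config key alpha: must lie in (0, 1)")
        if self.simulate is None and self.input_dir is None:
            raise ValueError("config: provide either 'simulate' or 'input_dir'")
        if isinstance(self.simulate, dict):
            self.simulate = SyntheticCityConfig(**self.simulate)
        if self.simulate is not None and self.seed is not None:
            self.simulate.seed = int(self.seed)

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


@dataclass
class StudyResult:
    """Everything a run produced: effects, diagnostics, screening, provenance."""

    effects: pd.DataFrame
    moran: pd.DataFrame
    lm: pd.DataFrame
    selection: pd.DataFrame
    outliers: pd.DataFrame
    greenspace: pd.DataFrame
    skips: list
    manifest: dict


def _load_inputs(input_dir: str):
    d = Path(input_dir)
    for name in ("points.csv", "greenspace.csv", "covariates.csv", "pollutants.csv"):
        if not (d / name).exists():
            raise FileNotFoundError(f"missing input file {d / name}")
    points = PointSet.from_csv(d / "points.csv")
    green = pd.read_csv(d / "greenspace.csv")
    cov = pd.read_csv(d / "covariates.csv")
    poll = pd.read_csv(d / "pollutants.csv")
    return points, green["gvi"].to_numpy(), green["ndvi"].to_numpy(), cov, poll


def run_study(config: StudyConfig) -> StudyResult:
    """Execute the complete analysis chain deterministically from the config."""
    rng_seed = int(config.seed if config.seed is not None
                   else (config.simulate.seed if config.simulate else 0))

    if config.simulate is not None:
        logger.info("simulating city: n=%d seed=%d", config.simulate.n_points, rng_seed)
        city = generate_city(config.simulate)
        points, gvi, ndvi = city.points, city.gvi, city.ndvi
        cov, poll = city.covariates, city.pollutants
    else:
        points, gvi, ndvi, cov, poll = _load_inputs(config.input_dir)

    pollutants = tuple(config.pollutants) if config.pollutants else tuple(poll.columns)
    missing = [p for p in pollutants if p not in poll.columns]
    if missing:
        raise ValueError(f"config key pollutants: not in data: {missing}")
    missing = [c for c in config.covariates if c not in cov.columns]
    if missing:
        raise ValueError(f"config key covariates: not in data: {missing}")

    # outlier screen on the pollutant concentrations
    report, kept = screen_outliers(poll[list(pollutants)], z_thresh=config.z_thresh,
                                   maha_quantile=config.maha_quantile)
    keep_mask = ~report.flagged
    logger.info("outlier screen: flagged %d of %d rows", report.n_flagged, len(poll))

    # greenspace metrics at every scale, normalized within scale
    gs = build_greenspace_table(points, gvi, ndvi, points, radii_m=config.radii_m)

    # analysis set: unflagged rows with complete metrics at every usable
    # scale; metric-scale combinations that are entirely missing (e.g. a
    # buffer radius exceeding the study extent) are skipped outright
    complete = keep_mask.copy()
    dead_combos = []
    for r in config.radii_m:
        sub = gs[gs["scale"] == scale_label(r)].set_index("unit_id")
        for m in config.metrics:
            col = np.isfinite(sub[m].reindex(points.ids).to_numpy())
            if not col.any():
                dead_combos.append((m, scale_label(r)))
            else:
                complete &= col
    idx = np.flatnonzero(complete)
    n_drop = points.n - idx.size
    logger.info("analysis set: %d units (%d dropped)", idx.size, n_drop)
    if idx.size < len(config.covariates) + 4:
        raise ValueError("too few complete units for regression; check radii "
                         "against the study extent and the outlier thresholds")

    sub_points = PointSet(points.ids[idx], points.x[idx], points.y[idx])
    swm = build_kernel_weights(sub_points, k=config.k_weights)
    logdet = LogDeterminant(swm.W, mode="eig")   # shared across all 90 fits

    Y = poll[list(pollutants)].iloc[idx]
    if config.log_scale:
        Y = np.log(Y)
    C = cov[list(config.covariates)].iloc[idx].to_numpy()

    moran_rows = []
    for j, p in enumerate(pollutants):
        mr = morans_i(Y[p].to_numpy(), swm, n_perm=config.n_perm,
                      seed=rng_seed + 1000 + j)
        moran_rows.append({"pollutant": p, "I": mr.I, "expectation": mr.expectation,
                           "z": mr.z, "p_analytic": mr.p_analytic,
                           "p_perm": mr.p_perm, "interpretation": mr.interpretation})
    moran_df = pd.DataFrame(moran_rows)

    effect_rows, lm_rows, sel_rows, skips = [], [], [], []
    for r in config.radii_m:
        slab = scale_label(r)
        sub = gs[gs["scale"] == slab].set_index("unit_id")
        for m in config.metrics:
            if (m, slab) in dead_combos:
                for p in pollutants:
                    skips.append({"fit": f"{p}/{m}/{slab}",
                                  "reason": "metric entirely missing at this scale"})
                continue
            v = sub[m].reindex(sub_points.ids).to_numpy()
            X = np.column_stack([np.ones(idx.size), v, C])
            iqr = compute_iqr(v)
            for p in pollutants:
                y = Y[p].to_numpy()
                tag = f"{p}/{m}/{slab}"
                try:
                    lm = lm_tests(y, X, swm)
                    lm_rows.append({"pollutant": p, "metric": m, "scale": slab,
                                    **lm.to_series().to_dict()})
                    slm = fit_slm(y, X, swm, logdet=logdet)
                    sem = fit_sem(y, X, swm, logdet=logdet)
                    sel = select_model(slm, sem, swm, alpha=config.alpha)
                    sel_rows.append({
                        "pollutant": p, "metric": m, "scale": slab,
                        "choice": sel.choice,
                        "slm_resid_I": sel.moran_slm.I, "slm_resid_p": sel.moran_slm.p_analytic,
                        "sem_resid_I": sel.moran_sem.I, "sem_resid_p": sel.moran_sem.p_analytic,
                        "rationale": sel.rationale,
                    })
                    eff = pct_per_iqr(slm, iqr, use_total=config.use_total,
                                      alpha=config.alpha, pollutant=p, metric=m,
                                      scale_label=slab)
                    effect_rows.append({
                        "pollutant": p, "metric": m, "scale": slab,
                        "beta1": eff.beta1, "se_beta1": eff.se_beta1,
                        "iqr": eff.iqr, "pct_diff": eff.pct_diff,
                        "ci_low": eff.ci_low, "ci_high": eff.ci_high,
                        "p": eff.p_value, "rho": eff.rho,
                        "total_effect": eff.total_effect,
                        "total_ci_low": eff.total_ci_low,
                        "total_ci_high": eff.total_ci_high,
                        "model": sel.choice,
                    })
                    logger.info("fit %s: rho=%.3f beta1=%.4g pct=%.2f%% [%s]",
                                tag, eff.rho, eff.beta1, eff.pct_diff, sel.choice)
                except Exception as exc:       # recorded, never silent
                    skips.append({"fit": tag, "reason": str(exc)})
                    logger.warning("skipped %s: %s", tag, exc)

    effects = pd.DataFrame(effect_rows)
    expected = len(pollutants) * len(config.metrics) * len(config.radii_m)
    assert len(effects) + len(skips) == expected

    outlier_df = pd.DataFrame({
        "unit_id": points.ids, "flag_z": report.flag_z,
        "flag_mahalanobis": report.flag_maha, "flagged": report.flagged,
        "mahalanobis_sq": report.mahalanobis_sq,
    })

    import greensar

    manifest = {
        "config_hash": StudyConfig.config_hash(config),
        "seed": rng_seed,
        "n_units": int(idx.size),
        "n_dropped": int(n_drop),
        "n_effects": len(effects),
        "n_skips": len(skips),
        "versions": {"greensar": greensar.__version__,
                     "numpy": np.__version__, "pandas": pd.__version__},
        "skewness": report.skewness.round(6).to_dict(),
        "excess_kurtosis": report.excess_kurtosis.round(6).to_dict(),
    }
    return StudyResult(effects=effects, moran=moran_df, lm=pd.DataFrame(lm_rows),
                       selection=pd.DataFrame(sel_rows), outliers=outlier_df,
                       greenspace=gs, skips=skips, manifest=manifest)


FLOAT_FMT = "%.12g"


def write_report(result: StudyResult, outdir) -> dict:
    """Write the study outputs as tabular text plus a machine-readable manifest.

    Returns the mapping of artifact name to path.  Float formatting is fixed
    so a rerun with identical config and seed is byte-identical.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    tables = {
        "effects": result.effects, "moran": result.moran, "lm_tests": result.lm,
        "model_selection": result.selection, "outliers": result.outliers,
        "greenspace": result.greenspace,
    }
    for name, df in tables.items():
        p = out / f"{name}.csv"
        df.to_csv(p, index=False, float_format=FLOAT_FMT)
        paths[name] = p
    p = out / "manifest.json"
    with open(p, "w") as fh:
        json.dump({**result.manifest, "skips": result.skips}, fh, indent=2,
                  sort_keys=True)
        fh.write("\n")
    paths["manifest"] = p
    return paths
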