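"""Rejection and regression-adjusted ABC over a simulated reference table.

The engine standardises each summary column by its median and median absolute
deviation (robust to the heavy tails of statistics like MaxChi), ranks
simulations by Euclidean distance to the observed summary vector, accepts the
closest fraction ``tolerance`` with Epanechnikov kernel weights, and optionally
applies the classic ABC weighted local-linear regression correction: each
estimated parameter is (optionally transformed and) regressed on the
standardised accepted summaries, and the accepted draws are projected to the
observed summary point by adding their residuals to the local fit, with an
optional heteroscedasticity correction that rescales residuals by the fitted
conditional spread.  The logit transform maps through the parameter's uniform
prior bounds, which guarantees adjusted draws stay inside the prior support.

Posterior point estimates are the mode of a weighted Gaussian kernel density
(Silverman bandwidth) on a 512-point grid over the prior range; interval
estimates are weighted 2.5% / 97.5% quantiles.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

from .sumstats import SUMMARY_NAMES, SummaryVector

__all__ = [
    "ReferenceTable",
    "PosteriorResult",
    "standardize_and_distance",
    "reject",
    "regression_adjust",
    "summarize_posterior",
    "estimate",
]

logger = logging.getLogger(__name__)

PARAM_NAMES = ("rho", "theta", "omega")


@dataclass
class ReferenceTable:
    """Simulated (parameters, nuisance, summaries) triplets plus prior bounds."""

    parameters: np.ndarray          # (S, 3): rho, theta, omega
    summaries: np.ndarray           # (S, 26)
    prior_bounds: dict[str, tuple[float, float]]
    nuisance: np.ndarray | None = None   # (S, k), recorded but never estimated
    nuisance_names: tuple[str, ...] = ()

    def __post_init__(self):
        self.parameters = np.asarray(self.parameters, dtype=float)
        self.summaries = np.asarray(self.summaries, dtype=float)
        if self.parameters.ndim != 2 or self.parameters.shape[1] != 3:
            raise ValueError("parameters must be (S, 3)")
        if self.summaries.shape != (self.parameters.shape[0], 26):
            raise ValueError("summaries must be (S, 26)")
        if not np.isfinite(self.summaries).all():
            raise ValueError("summaries must be finite")
        for k, name in enumerate(PARAM_NAMES):
            lo, hi = self.prior_bounds[name]
            col = self.parameters[:, k]
            if ((col < lo) | (col > hi)).any():
                raise ValueError(f"{name} draws outside prior bounds [{lo}, {hi}]")
        if self.nuisance is not None:
            self.nuisance = np.asarray(self.nuisance, dtype=float)
            if self.nuisance.shape[0] != self.parameters.shape[0]:
                raise ValueError("nuisance rows must match parameter rows")

    @property
    def n_simulations(self) -> int:
        return self.parameters.shape[0]

    def to_dataframe(self) -> pd.DataFrame:
        cols = {name: self.parameters[:, k] for k, name in enumerate(PARAM_NAMES)}
        for k, name in enumerate(self.nuisance_names):
            cols[name] = self.nuisance[:, k]
        for k, name in enumerate(SUMMARY_NAMES):
            cols[name] = self.summaries[:, k]
        return pd.DataFrame(cols)

    def to_tsv(self, path: str | Path) -> None:
        df = self.to_dataframe()
        with open(path, "w") as fh:
            for name in PARAM_NAMES:
                lo, hi = self.prior_bounds[name]
                fh.write(f"# prior {name} uniform {lo} {hi}\n")
            df.to_csv(fh, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ReferenceTable":
        bounds = {}
        with open(path) as fh:
            for line in fh:
                if not line.startswith("#"):
                    break
                _, _, name, _, lo, hi = line.split()
                bounds[name] = (float(lo), float(hi))
        df = pd.read_csv(path, sep="\t", comment="#")
        params = df[list(PARAM_NAMES)].to_numpy()
        summaries = df[list(SUMMARY_NAMES)].to_numpy()
        nuis_cols = [c for c in df.columns
                     if c not in PARAM_NAMES and c not in SUMMARY_NAMES]
        nuis = df[nuis_cols].to_numpy() if nuis_cols else None
        return cls(params, summaries, bounds, nuis, tuple(nuis_cols))

    def concatenate(self, other: "ReferenceTable") -> "ReferenceTable":
        """Append-safe merge of two tables built with disjoint seed ranges."""
        if self.prior_bounds != other.prior_bounds:
            raise ValueError("cannot concatenate tables with different priors")
        if self.nuisance_names != other.nuisance_names:
            raise ValueError("cannot concatenate tables with different nuisance sets")
        nuis = None
        if self.nuisance is not None and other.nuisance is not None:
            nuis = np.vstack([self.nuisance, other.nuisance])
        return ReferenceTable(
            np.vstack([self.parameters, other.parameters]),
            np.vstack([self.summaries, other.summaries]),
            dict(self.prior_bounds),
            nuis,
            self.nuisance_names,
        )


@dataclass
class PosteriorResult:
    """Accepted (and optionally regression-adjusted) draws with weights and
    per-parameter mode / 95% credible interval."""

    accepted_raw: np.ndarray            # (m, 3)
    weights: np.ndarray                 # (m,)
    tolerance: float
    transform: str
    accepted_adjusted: np.ndarray | None = None
    accepted_indices: np.ndarray | None = None
    modes: dict[str, float] = field(default_factory=dict)
    intervals: dict[str, tuple[float, float]] = field(default_factory=dict)

    @property
    def draws(self) -> np.ndarray:
        """Adjusted draws when available, raw otherwise."""
        return (self.accepted_adjusted
                if self.accepted_adjusted is not None else self.accepted_raw)

    def report(self) -> dict:
        return {
            "tolerance": self.tolerance,
            "transform": self.transform,
            "n_accepted": int(self.accepted_raw.shape[0]),
            "adjusted": self.accepted_adjusted is not None,
            "parameters": {
                name: {
                    "mode": self.modes[name],
                    "ci95": list(self.intervals[name]),
                }
                for name in PARAM_NAMES
            },
        }


def _mad_scales(summaries: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    center = np.median(summaries, axis=0)
    scale = np.median(np.abs(summaries - center), axis=0)
    scale = np.where(scale > 0, scale, 1.0)  # constant columns: scale 1
    return center, scale


def standardize_and_distance(observed: SummaryVector | np.ndarray,
                             table: ReferenceTable) -> np.ndarray:
    """Euclidean distance of each table row to the observed vector, after
    median/MAD standardisation of every summary column."""
    obs = observed.values if isinstance(observed, SummaryVector) else \
        np.asarray(observed, dtype=float)
    if obs.shape != (26,):
        raise ValueError("observed summary vector must have 26 entries")
    if table.n_simulations == 0:
        raise ValueError("reference table is empty")
    center, scale = _mad_scales(table.summaries)
    z = (table.summaries - center) / scale
    zo = (obs - center) / scale
    return np.sqrt(((z - zo) ** 2).sum(axis=1))


def reject(distances: np.ndarray, table: ReferenceTable,
           tolerance: float) -> tuple[np.ndarray, np.ndarray]:
    """Accept the closest ``round(tolerance * S)`` rows (at least one).

    Ties are broken by table row order.  Weights are Epanechnikov,
    w_i = 1 - (d_i/d_max)^2, uniform when all accepted distances are equal.
    """
    if not 0.0 < tolerance <= 1.0:
        raise ValueError("tolerance must be in (0, 1]")
    s = table.n_simulations
    m = max(1, int(np.floor(tolerance * s + 0.5)))
    m = min(m, s)
    order = np.argsort(distances, kind="stable")
    accepted = order[:m]
    d = distances[accepted]
    dmax = d.max()
    if dmax > 0:
        weights = 1.0 - (d / dmax) ** 2
    else:
        weights = np.ones(m)
    if weights.max() <= 0:
        weights = np.ones(m)
    return accepted, weights


def _transform(x: np.ndarray, transform: str, lo: float, hi: float) -> np.ndarray:
    if transform == "none":
        return x
    if transform == "log":
        if (x <= 0).any():
            raise ValueError(
                "log transform requires positive parameter values; "
                "use 'logit' or 'none'"
            )
        return np.log(x)
    if transform == "logit":
        eps = 1e-8 * (hi - lo)
        xc = np.clip(x, lo + eps, hi - eps)
        p = (xc - lo) / (hi - lo)
        return np.log(p / (1.0 - p))
    raise ValueError(f"unknown transform {transform!r}")


def _back_transform(y: np.ndarray, transform: str, lo: float, hi: float) -> np.ndarray:
    if transform == "none":
        return y
    if transform == "log":
        return np.exp(y)
    # clip so the inverse logit stays strictly inside (lo, hi) in floats
    p = 1.0 / (1.0 + np.exp(-np.clip(y, -30.0, 30.0)))
    return lo + (hi - lo) * p


def _wls(x: np.ndarray, y: np.ndarray, w: np.ndarray) -> np.ndarray:
    sw = np.sqrt(w)
    beta, *_ = np.linalg.lstsq(x * sw[:, None], y * sw, rcond=None)
    return beta


def regression_adjust(accepted_params: np.ndarray, accepted_summaries: np.ndarray,
                      observed: np.ndarray, weights: np.ndarray,
                      transform: str = "none",
                      prior_bounds: dict | None = None,
                      hetero_correction: bool = False) -> np.ndarray:
    """Weighted local-linear regression adjustment of the accepted draws.

    ``accepted_summaries`` and ``observed`` must be on the same (standardised)
    scale.  Returns the adjusted (m, p) parameter draws on the natural scale.
    """
    params = np.atleast_2d(np.asarray(accepted_params, dtype=float))
    if params.shape[0] == 1 and np.asarray(accepted_params).ndim == 1:
        params = params.T
    m, n_par = params.shape
    s = np.asarray(accepted_summaries, dtype=float)
    obs = np.asarray(observed, dtype=float)

    # centre the design at the observed point: the intercept is then the
    # local fit at the observation
    x = s - obs
    spread = x.std(axis=0)
    keep = spread > 1e-12
    if not keep.all():
        logger.warning("dropping %d constant summary columns from regression",
                       int((~keep).sum()))
    x = x[:, keep]
    if m < max(3 * x.shape[1], x.shape[1] + 2):
        logger.warning(
            "only %d accepted points for %d regressors; falling back to "
            "rejection-only", m, x.shape[1])
        return params.copy()
    design = np.column_stack([np.ones(m), x])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        logger.warning("collinear summary columns in regression design "
                       "(rank %d < %d); dropping via pivoted QR",
                       rank, design.shape[1])
        from scipy.linalg import qr
        _, _, piv = qr(design, mode="economic", pivoting=True)
        keep_cols = np.sort(piv[:rank])
        if 0 not in keep_cols:
            keep_cols = np.concatenate([[0], keep_cols[:-1]])
        design = design[:, keep_cols]

    bounds = prior_bounds or {}
    out = np.empty_like(params)
    for k in range(n_par):
        name = PARAM_NAMES[k] if n_par == len(PARAM_NAMES) else str(k)
        lo, hi = bounds.get(name, (0.0, 1.0))
        phi = _transform(params[:, k], transform, lo, hi)
        beta = _wls(design, phi, weights)
        fitted = design @ beta
        resid = phi - fitted
        fit_at_obs = beta[0]
        if hetero_correction:
            # second weighted regression models log residual variance
            log_r2 = np.log(resid ** 2 + 1e-30)
            gamma = _wls(design, log_r2, weights)
            log_var = design @ gamma
            ratio = np.exp(0.5 * (gamma[0] - log_var))
            ratio = np.clip(ratio, 1e-6, 1e6)
            resid = resid * ratio
        out[:, k] = _back_transform(fit_at_obs + resid, transform, lo, hi)
    return out


def _weighted_quantile(x: np.ndarray, w: np.ndarray, q: float) -> float:
    order = np.argsort(x)
    xs, ws = x[order], w[order]
    cw = np.cumsum(ws)
    cw /= cw[-1]
    return float(np.interp(q, cw, xs))


def summarize_posterior(draws: np.ndarray, weights: np.ndarray,
                        prior_bounds: dict[str, tuple[float, float]],
                        names: tuple[str, ...] = PARAM_NAMES
                        ) -> tuple[dict[str, float], dict[str, tuple[float, float]]]:
    """Weighted-KDE mode and weighted 95% interval for each parameter."""
    draws = np.atleast_2d(np.asarray(draws, dtype=float))
    if draws.shape[0] == 1 and len(names) != draws.shape[1]:
        draws = draws.T
    if draws.shape[0] < 2:
        raise ValueError("need at least 2 draws to summarise a posterior")
    w = np.asarray(weights, dtype=float)
    w = np.where(w > 0, w, 0.0)
    if w.sum() <= 0:
        w = np.ones_like(w)
    modes: dict[str, float] = {}
    intervals: dict[str, tuple[float, float]] = {}
    for k, name in enumerate(names):
        x = draws[:, k]
        lo, hi = prior_bounds[name]
        wvar = np.cov(x, aweights=w) if x.size > 1 else 0.0
        if float(wvar) <= 1e-300:
            v = float(_weighted_quantile(x, w, 0.5))
            modes[name] = v
            intervals[name] = (v, v)
            continue
        kde = gaussian_kde(x, bw_method="silverman", weights=w)
        grid = np.linspace(lo, hi, 512)
        dens = kde(grid)
        modes[name] = float(grid[np.argmax(dens)])
        ci = (_weighted_quantile(x, w, 0.025), _weighted_quantile(x, w, 0.975))
        intervals[name] = (float(np.clip(ci[0], lo, hi)),
                           float(np.clip(ci[1], lo, hi)))
    return modes, intervals


def estimate(observed: SummaryVector | np.ndarray, table: ReferenceTable,
             tolerance: float = 0.002, method: str = "loclinear",
             transform: str = "logit",
             hetero_correction: bool = False) -> PosteriorResult:
    """End-to-end rejection (+ optional regression adjustment) estimation."""
    if method not in ("rejection", "loclinear"):
        raise ValueError("method must be 'rejection' or 'loclinear'")
    distances = standardize_and_distance(observed, table)
    accepted, weights = reject(distances, table, tolerance)
    raw = table.parameters[accepted]
    adjusted = None
    if method == "loclinear":
        obs = observed.values if isinstance(observed, SummaryVector) else \
            np.asarray(observed, dtype=float)
        center, scale = _mad_scales(table.summaries)
        adjusted = regression_adjust(
            raw,
            (table.summaries[accepted] - center) / scale,
            (obs - center) / scale,
            weights,
            transform=transform,
            prior_bounds=table.prior_bounds,
            hetero_correction=hetero_correction,
        )
        if adjusted.shape == raw.shape and np.array_equal(adjusted, raw):
            adjusted = None  # regression fell back to rejection
    result = PosteriorResult(
        accepted_raw=raw,
        weights=weights,
        tolerance=tolerance,
        transform=transform if method == "loclinear" else "none",
        accepted_adjusted=adjusted,
        accepted_indices=accepted,
    )
    modes, intervals = summarize_posterior(result.draws, weights,
                                           table.prior_bounds)
    result.modes = modes
    result.intervals = intervals
    return result
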