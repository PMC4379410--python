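"""Orchestration: prior sampling, parallel simulation, table assembly and
end-to-end estimation.

One simulation draws (rho, theta, omega) and the nuisance parameters from
their priors, simulates an ancestral recombination graph for the observed
alignment's dimensions, evolves codon sequences along it, and computes the
26-statistic summary vector.  Reproducibility contract: every simulation gets
a child seed derived deterministically from (root seed, simulation index), so
reference tables are identical row-for-row regardless of the number of worker
processes, and tables built from disjoint index ranges can be concatenated.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from joblib import Parallel, delayed

from .abc_engine import PARAM_NAMES, PosteriorResult, ReferenceTable, estimate
from .alignment import CodingAlignment, read_alignment
from .codon_evolver import (
    SubstitutionParams,
    equal_codon_frequencies,
    evolve_alignment,
    f1x4_codon_frequencies,
)
from .genealogy_sim import CoalescentConfig, simulate_arg
from .sumstats import SUMMARY_NAMES, compute_summary_vector

__all__ = [
    "PriorSpec",
    "ParameterDraw",
    "RunConfig",
    "sample_prior",
    "simulate_dataset",
    "build_reference_table",
    "run_estimation",
]

logger = logging.getLogger(__name__)

Bound = tuple[float, float]


@dataclass(frozen=True)
class PriorSpec:
    """Priors for the three estimated parameters and the nuisance parameters.

    The estimated parameters use uniform priors given as (low, high).  Each
    nuisance entry is either a fixed value or a (low, high) uniform prior.
    ``codon_freq_scheme`` is one of "equal", "empirical" (F1x4 from the
    observed alignment) or "dirichlet" (a fresh symmetric Dirichlet draw per
    simulation).  ``gamma_shape=None`` disables among-site rate variation.
    """

    rho: Bound = (0.0, 50.0)
    theta: Bound = (0.0, 300.0)
    omega: Bound = (0.0, 2.0)
    kappa: float | Bound = 0.5
    gtr_rates: tuple | None = None  # six fixed exchangeabilities, replaces kappa
    codon_freq_scheme: str = "equal"
    dirichlet_concentration: float = 1.0
    gamma_shape: float | Bound | None = None
    prop_invariable: float | Bound = 0.0

    def __post_init__(self):
        for name in ("rho", "theta", "omega"):
            lo, hi = getattr(self, name)
            if not (np.isfinite(lo) and np.isfinite(hi)):
                raise ValueError(f"prior bounds for {name} must be finite")
            if not lo < hi:
                raise ValueError(f"prior for {name}: lower bound must be < upper")
            if lo < 0:
                raise ValueError(f"prior for {name}: lower bound must be >= 0")
        if self.codon_freq_scheme not in ("equal", "empirical", "dirichlet"):
            raise ValueError(
                f"unknown codon_freq_scheme {self.codon_freq_scheme!r}")

    @property
    def bounds(self) -> dict[str, Bound]:
        return {"rho": self.rho, "theta": self.theta, "omega": self.omega}

    def nuisance_names(self) -> tuple[str, ...]:
        names = ["kappa"]
        if self.gamma_shape is not None:
            names.append("gamma_shape")
        names.append("prop_invariable")
        return tuple(names)


@dataclass(frozen=True)
class ParameterDraw:
    """One point from the joint prior, with its per-simulation seed."""

    rho: float
    theta: float
    omega: float
    kappa: float
    codon_freqs: np.ndarray
    gamma_shape: float | None
    prop_invariable: float
    gtr_rates: tuple | None = None
    seed: tuple[int, ...] | None = None

    def nuisance_values(self, spec: PriorSpec) -> list[float]:
        vals = [self.kappa]
        if spec.gamma_shape is not None:
            vals.append(self.gamma_shape)
        vals.append(self.prop_invariable)
        return vals


@dataclass(frozen=True)
class RunConfig:
    """Settings of one ABC run; alignment dimensions always follow the data."""

    n_simulations: int
    n_samples: int
    n_codons: int
    tolerance: float = 0.002
    method: str = "loclinear"
    transform: str = "logit"
    hetero_correction: bool = False
    n_workers: int = 1
    seed: int = 0
    intracodon: str = "nucleotide"

    def __post_init__(self):
        if self.n_simulations < 1:
            raise ValueError("n_simulations must be >= 1")
        if self.n_samples < 2:
            raise ValueError("n_samples must be >= 2")
        if self.n_codons < 1:
            raise ValueError("n_codons must be >= 1")


def _draw(value: float | Bound, rng: np.random.Generator) -> float:
    if isinstance(value, (tuple, list)):
        lo, hi = value
        return float(rng.uniform(lo, hi))
    return float(value)


def sample_prior(spec: PriorSpec, rng: np.random.Generator,
                 observed_nt_freqs: np.ndarray | None = None,
                 seed: tuple[int, ...] | None = None) -> ParameterDraw:
    """Draw one parameter point from the joint prior."""
    rho = float(rng.uniform(*spec.rho))
    theta = float(rng.uniform(*spec.theta))
    omega = float(rng.uniform(*spec.omega))
    kappa = _draw(spec.kappa, rng)
    if spec.codon_freq_scheme == "equal":
        freqs = equal_codon_frequencies()
    elif spec.codon_freq_scheme == "empirical":
        if observed_nt_freqs is None:
            raise ValueError(
                "codon_freq_scheme='empirical' requires observed nucleotide "
                "frequencies")
        freqs = f1x4_codon_frequencies(observed_nt_freqs)
    else:
        freqs = rng.dirichlet(np.full(61, spec.dirichlet_concentration))
        freqs = freqs / freqs.sum()
    gamma = None if spec.gamma_shape is None else _draw(spec.gamma_shape, rng)
    p_inv = _draw(spec.prop_invariable, rng)
    return ParameterDraw(rho, theta, omega, kappa, freqs, gamma, p_inv,
                         gtr_rates=spec.gtr_rates, seed=seed)


def child_rng(root_seed: int, *key: int) -> np.random.Generator:
    """Deterministic per-simulation stream: child seed = f(root seed, index)."""
    return np.random.default_rng(np.random.SeedSequence((root_seed,) + key))


def simulate_dataset(draw: ParameterDraw, n_samples: int, n_codons: int,
                     rng: np.random.Generator,
                     intracodon: str = "nucleotide") -> CodingAlignment:
    """Simulate one coding alignment under one parameter draw."""
    config = CoalescentConfig(n_samples=n_samples, l_nt=3 * n_codons,
                              rho=draw.rho)
    genealogies = simulate_arg(config, rng)
    params = SubstitutionParams(
        theta=draw.theta,
        omega=draw.omega,
        kappa=draw.kappa,
        codon_freqs=draw.codon_freqs,
        gamma_shape=draw.gamma_shape,
        prop_invariable=draw.prop_invariable,
        gtr_rates=draw.gtr_rates,
        n_codons=n_codons,
    )
    return evolve_alignment(genealogies, params, rng, intracodon=intracodon)


def _simulate_one(spec: PriorSpec, config: RunConfig, index: int,
                  observed_nt_freqs: np.ndarray | None):
    """One reference-table row; retried once with a fresh child seed."""
    for attempt in (0, 1):
        try:
            rng = child_rng(config.seed, index, attempt)
            draw = sample_prior(spec, rng, observed_nt_freqs,
                                seed=(config.seed, index, attempt))
            aln = simulate_dataset(draw, config.n_samples, config.n_codons,
                                   rng, config.intracodon)
            vec = compute_summary_vector(aln)
            return (draw.rho, draw.theta, draw.omega,
                    draw.nuisance_values(spec), vec.values)
        except Exception:  # noqa: BLE001 - logged and retried by contract
            if attempt == 1:
                logger.exception("simulation %d failed twice; excluded", index)
                return None
            logger.warning("simulation %d failed; retrying with fresh seed",
                           index)
    return None


def build_reference_table(spec: PriorSpec, config: RunConfig,
                          observed_nt_freqs: np.ndarray | None = None,
                          index_offset: int = 0) -> ReferenceTable:
    """Run ``config.n_simulations`` simulations and assemble the table.

    Deterministic in (seed, n_simulations, index_offset) regardless of
    ``n_workers``.  Simulations failing twice are excluded; more than 1%
    failures aborts.
    """
    indices = range(index_offset, index_offset + config.n_simulations)
    if config.n_workers > 1:
        rows = Parallel(n_jobs=config.n_workers, batch_size="auto")(
            delayed(_simulate_one)(spec, config, i, observed_nt_freqs)
            for i in indices
        )
    else:
        rows = [_simulate_one(spec, config, i, observed_nt_freqs)
                for i in indices]
    failures = sum(r is None for r in rows)
    if failures > 0.01 * config.n_simulations:
        raise RuntimeError(
            f"{failures}/{config.n_simulations} simulations failed; aborting")
    if failures:
        logger.warning("%d/%d simulations failed and were excluded",
                       failures, config.n_simulations)
    rows = [r for r in rows if r is not None]
    params = np.array([r[:3] for r in rows])
    nuisance = np.array([r[3] for r in rows])
    summaries = np.vstack([r[4] for r in rows])
    return ReferenceTable(params, summaries, spec.bounds, nuisance,
                          spec.nuisance_names())


def write_simulated_alignment(aln: CodingAlignment, draw: ParameterDraw,
                              path: str | Path) -> None:
    """Write a simulated alignment as FASTA plus an adjacent ``.params.tsv``
    sidecar recording the generating parameter draw (never inside the FASTA).
    """
    from .alignment import write_fasta

    path = Path(path)
    write_fasta(aln, path)
    sidecar = path.with_suffix(path.suffix + ".params.tsv")
    fields = {
        "rho": draw.rho, "theta": draw.theta, "omega": draw.omega,
        "kappa": draw.kappa, "gamma_shape": draw.gamma_shape,
        "prop_invariable": draw.prop_invariable, "seed": draw.seed,
    }
    with open(sidecar, "w") as fh:
        fh.write("# generating parameter draw\n")
        fh.write("\t".join(fields) + "\n")
        fh.write("\t".join(str(v) for v in fields.values()) + "\n")


def _prior_predictive_check(observed: np.ndarray, table: ReferenceTable) -> int:
    """Number of observed summaries outside the [0.5%, 99.5%] table envelope."""
    lo = np.quantile(table.summaries, 0.005, axis=0)
    hi = np.quantile(table.summaries, 0.995, axis=0)
    return int(((observed < lo) | (observed > hi)).sum())


def run_estimation(observed: CodingAlignment | str | Path, spec: PriorSpec,
                   config: RunConfig, table: ReferenceTable | None = None,
                   output_dir: str | Path | None = None) -> PosteriorResult:
    """Observed summaries -> reference table -> rejection/regression ABC.

    ``config.n_samples``/``n_codons`` must match the observed alignment; they
    are overwritten from the data if they differ (summaries are
    dimension-sensitive, so simulations always copy the observed dimensions).
    """
    if not isinstance(observed, CodingAlignment):
        observed = read_alignment(observed)
    if (config.n_samples, config.n_codons) != (observed.n_sequences,
                                               observed.n_codons):
        logger.info("taking alignment dimensions from the observed data: "
                    "%d sequences x %d codons",
                    observed.n_sequences, observed.n_codons)
        config = replace(config, n_samples=observed.n_sequences,
                         n_codons=observed.n_codons)
    obs_vec = compute_summary_vector(observed)
    nt = observed.nts
    counts = np.bincount(nt[nt >= 0], minlength=4).astype(float)
    nt_freqs = counts / counts.sum()
    if table is None:
        table = build_reference_table(spec, config, nt_freqs)
    n_outside = _prior_predictive_check(obs_vec.values, table)
    if n_outside > 8:
        logger.warning(
            "prior-predictive mismatch: %d of 26 observed summaries fall "
            "outside the [0.5%%, 99.5%%] envelope of the reference table; "
            "estimates may be unreliable", n_outside)
    result = estimate(obs_vec, table, tolerance=config.tolerance,
                      method=config.method, transform=config.transform,
                      hetero_correction=config.hetero_correction)
    if output_dir is not None:
        output_dir = Path(output_dir)
        output_dir.mkdir(parents=True, exist_ok=True)
        report = result.report()
        report["prior_predictive_outside_envelope"] = n_outside
        report["observed_summaries"] = dict(zip(SUMMARY_NAMES,
                                                map(float, obs_vec.values)))
        with open(output_dir / "estimate.json", "w") as fh:
            json.dump(report, fh, indent=2)
        _write_draws_tsv(output_dir / "accepted_draws.tsv", result)
        table.to_tsv(output_dir / "reference_table.tsv")
    return result


def _write_draws_tsv(path: Path, result: PosteriorResult) -> None:
    with open(path, "w") as fh:
        cols = [f"{p}_raw" for p in PARAM_NAMES] + ["weight"]
        if result.accepted_adjusted is not None:
            cols += [f"{p}_adjusted" for p in PARAM_NAMES]
        fh.write("\t".join(cols) + "\n")
        for i in range(result.accepted_raw.shape[0]):
            vals = list(result.accepted_raw[i]) + [result.weights[i]]
            if result.accepted_adjusted is not None:
                vals += list(result.accepted_adjusted[i])
            fh.write("\t".join(f"{v:.6g}" for v in vals) + "\n")
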