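"""GY94 codon substitution along coalescent genealogies.

The instantaneous rate between two sense codons that differ at exactly one
nucleotide position is proportional to the target codon's stationary frequency
times kappa for transitions and omega for amino-acid-changing moves; all other
off-diagonal rates are zero.  The matrix is normalised so the expected number
of substitutions per codon per unit branch length is 1; an alignment-wide rate
theta = 4*N*mu*L then translates into a per-codon rate theta/(2L) on branches
measured in units of 2N generations.

Sequences are evolved by exact stochastic (Gillespie) sampling of the
continuous-time Markov chain, forward in time down the ancestral recombination
graph: the grand ancestor draws its codons from the stationary distribution,
recombination nodes splice the two parental sequences at the breakpoint
(including mid-codon), and coalescence nodes copy the parental sequence into
both descendant branches.  Because every lineage carries a full sequence, the
substitution rates of a nucleotide whose codon is split by a breakpoint are
always conditioned on the current states of its two partner nucleotides on the
same lineage, which is the forward-process behaviour the intracodon
recombination model calls for.  A simpler whole-codon approximation (each
codon follows the marginal tree of its first nucleotide) is available via
``intracodon="first_tree"``.

Rate variation among codon sites uses continuous gamma multipliers (mean 1,
shape alpha) plus an independent probability ``prop_invariable`` of a site
being completely invariable.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._codes import (
    CODON_NT,
    DIFF_ONE,
    IS_NONSYN,
    IS_TRANSITION,
    N_CODONS,
    NT3_TO_CODON,
)
from ._kernels import evolve_codon_sites, seed_rng
from .alignment import CodingAlignment
from .genealogy_sim import MarginalGenealogySet

__all__ = [
    "SubstitutionParams",
    "CodonRateMatrix",
    "build_gy94_matrix",
    "assign_site_rates",
    "evolve_alignment",
    "equal_codon_frequencies",
    "f1x4_codon_frequencies",
]


def equal_codon_frequencies() -> np.ndarray:
    return np.full(N_CODONS, 1.0 / N_CODONS)


def f1x4_codon_frequencies(nt_freqs: np.ndarray) -> np.ndarray:
    """Codon frequencies as the product of position-independent base frequencies,
    renormalised over the 61 sense codons (F1x4)."""
    nt_freqs = np.asarray(nt_freqs, dtype=float)
    if nt_freqs.shape != (4,) or not np.isclose(nt_freqs.sum(), 1.0):
        raise ValueError("nt_freqs must be 4 frequencies summing to 1")
    f = nt_freqs[CODON_NT].prod(axis=1)
    return f / f.sum()


@dataclass
class SubstitutionParams:
    """Parameters of the codon substitution process.

    theta  : scaled codon substitution rate for the whole alignment (4*N*mu*L)
    omega  : nonsynonymous/synonymous rate ratio (dN/dS)
    kappa  : transition/transversion rate ratio (HKY-style)
    gtr_rates : optional six exchangeabilities (AC, AG, AT, CG, CT, GT)
                replacing the kappa parameterisation
    codon_freqs : stationary frequencies of the 61 sense codons
    gamma_shape : shape of the continuous gamma rate variation (None = off)
    prop_invariable : probability a codon site never changes, in [0, 1)
    n_codons : number of codon sites L
    """

    theta: float
    omega: float
    n_codons: int
    kappa: float = 1.0
    gtr_rates: np.ndarray | None = None
    codon_freqs: np.ndarray = field(default_factory=equal_codon_frequencies)
    gamma_shape: float | None = None
    prop_invariable: float = 0.0

    def __post_init__(self):
        self.codon_freqs = np.asarray(self.codon_freqs, dtype=float)
        if self.theta < 0:
            raise ValueError("theta must be >= 0")
        if self.omega < 0:
            raise ValueError("omega must be >= 0")
        if self.kappa <= 0:
            raise ValueError("kappa must be > 0")
        if self.n_codons < 1:
            raise ValueError("n_codons must be >= 1")
        if self.codon_freqs.shape != (N_CODONS,) or (self.codon_freqs < 0).any():
            raise ValueError(f"codon_freqs must be {N_CODONS} nonnegative values")
        if abs(self.codon_freqs.sum() - 1.0) > 1e-12:
            raise ValueError("codon_freqs must sum to 1 within 1e-12")
        if self.gamma_shape is not None and self.gamma_shape <= 0:
            raise ValueError("gamma_shape must be > 0 (or None to disable)")
        if not 0.0 <= self.prop_invariable < 1.0:
            raise ValueError("prop_invariable must be in [0, 1)")
        if self.gtr_rates is not None:
            self.gtr_rates = np.asarray(self.gtr_rates, dtype=float)
            if self.gtr_rates.shape != (6,) or (self.gtr_rates <= 0).any():
                raise ValueError("gtr_rates must be 6 positive exchangeabilities")


@dataclass
class CodonRateMatrix:
    """Normalised 61x61 GY94 generator plus sampling tables."""

    q: np.ndarray
    scale: float  # expected substitutions per codon per unit branch length
    exit_rates: np.ndarray = field(repr=False)  # -diag(q)
    cum_trans: np.ndarray = field(repr=False)   # row-cumulative jump probabilities


# map (from_nt, to_nt) -> GTR exchangeability index
_GTR_PAIR = np.zeros((4, 4), dtype=np.int64)
for _k, (_a, _b) in enumerate([(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]):
    _GTR_PAIR[_a, _b] = _GTR_PAIR[_b, _a] = _k
del _k, _a, _b

# per ordered codon pair (i,j) with one difference: the nucleotide pair involved
_pos = np.where(DIFF_ONE, np.argmax(CODON_NT[:, None, :] != CODON_NT[None, :, :], axis=2), 0)
_ii, _jj = np.indices((N_CODONS, N_CODONS))
_FROM_NT = CODON_NT[_ii, _pos]
_TO_NT = CODON_NT[_jj, _pos]
del _pos, _ii, _jj


def build_gy94_matrix(params: SubstitutionParams) -> CodonRateMatrix:
    """Build the normalised GY94 rate matrix for ``params``."""
    pi = params.codon_freqs
    if params.gtr_rates is not None:
        exch = params.gtr_rates[_GTR_PAIR[_FROM_NT, _TO_NT]]
    else:
        exch = np.where(IS_TRANSITION, params.kappa, 1.0)
    q = np.where(DIFF_ONE, pi[None, :] * exch, 0.0)
    q[IS_NONSYN] *= params.omega
    np.fill_diagonal(q, 0.0)
    np.fill_diagonal(q, -q.sum(axis=1))
    mean_rate = -float(np.dot(pi, np.diag(q)))
    if mean_rate <= 0:
        raise ValueError("degenerate rate matrix: no permitted substitutions")
    q /= mean_rate
    exit_rates = -np.diag(q).copy()
    with np.errstate(invalid="ignore", divide="ignore"):
        jump = np.where(exit_rates[:, None] > 0, q / exit_rates[:, None], 0.0)
    np.fill_diagonal(jump, 0.0)
    cum = np.cumsum(jump, axis=1)
    # guard against rounding so sampling never falls off the row end
    cum[cum[:, -1] > 0, -1] = 1.0
    return CodonRateMatrix(q=q, scale=1.0, exit_rates=exit_rates, cum_trans=cum)


def assign_site_rates(params: SubstitutionParams, L: int,
                      rng: np.random.Generator) -> np.ndarray:
    """Per-codon-site rate multipliers for gamma + invariable-sites variation.

    Variable sites draw Gamma(shape alpha, mean 1) multipliers scaled by
    1/(1 - p_inv), so the expected mean multiplier over all sites is 1.
    """
    if params.gamma_shape is not None:
        a = params.gamma_shape
        rates = rng.gamma(a, 1.0 / a, size=L)
    else:
        rates = np.ones(L)
    p = params.prop_invariable
    if p > 0.0:
        invariable = rng.random(L) < p
        rates[invariable] = 0.0
        rates[~invariable] /= 1.0 - p
    return rates


def _evolve_seq(seq: np.ndarray, duration: float, site_rate: np.ndarray,
                matrix: CodonRateMatrix) -> np.ndarray:
    """Exact CTMC (Gillespie jump chain) sampling of all codon sites over one
    branch.  Sites are independent given their rate multipliers.  Randomness
    comes from the numba thread-local stream seeded per alignment."""
    seq = seq.copy()
    evolve_codon_sites(seq, float(duration), site_rate, matrix.exit_rates,
                       matrix.cum_trans)
    return seq


def _splice(left: np.ndarray, right: np.ndarray, bp: int) -> np.ndarray:
    """Recombine two codon sequences at nucleotide breakpoint ``bp``.

    Mid-codon breakpoints build a hybrid codon from the two parents; in the
    rare case the hybrid is a stop codon the left parent's codon is kept
    (the state space has no stop states).
    """
    cb, off = divmod(bp, 3)
    out = np.concatenate([left[:cb], right[cb:]])
    if off:
        lnt = CODON_NT[left[cb]]
        rnt = CODON_NT[right[cb]]
        packed = 0
        for k in range(3):
            packed = packed * 4 + int(lnt[k] if k < off else rnt[k])
        hybrid = NT3_TO_CODON[packed]
        out[cb] = hybrid if hybrid >= 0 else left[cb]
    return out


def evolve_alignment(genealogies: MarginalGenealogySet, params: SubstitutionParams,
                     rng: np.random.Generator,
                     intracodon: str = "nucleotide") -> CodingAlignment:
    """Evolve codon sequences along the simulated genealogies.

    ``intracodon="nucleotide"`` (default) runs the forward pass down the full
    ARG with mid-codon splicing; ``"first_tree"`` approximates by evolving
    each codon along the marginal tree of its first nucleotide.
    """
    L = params.n_codons
    if genealogies.l_nt != 3 * L:
        raise ValueError(
            f"genealogy length {genealogies.l_nt} != 3 x {L} codons"
        )
    matrix = build_gy94_matrix(params)
    site_rate = assign_site_rates(params, L, rng) * (params.theta / (2.0 * L))
    seed_rng(int(rng.integers(2**31)))

    if intracodon == "first_tree":
        codons = _evolve_by_marginal_trees(genealogies, params, matrix, site_rate, rng)
    elif intracodon == "nucleotide":
        codons = _evolve_down_arg(genealogies, params, matrix, site_rate, rng)
    else:
        raise ValueError("intracodon must be 'nucleotide' or 'first_tree'")
    return CodingAlignment.from_codon_matrix(codons)


def _evolve_down_arg(gen: MarginalGenealogySet, params: SubstitutionParams,
                     matrix: CodonRateMatrix, site_rate: np.ndarray,
                     rng: np.random.Generator) -> np.ndarray:
    n, L = gen.n_samples, params.n_codons
    birth = gen.birth_times
    root = gen.events[-1][4]  # parent created by the final coalescence
    seq_bottom: dict[int, np.ndarray] = {
        root: rng.choice(N_CODONS, size=L, p=params.codon_freqs).astype(np.int64)
    }
    for ev in reversed(gen.events):
        t = ev[1]
        if ev[0] == "c":
            _, _, a, b, par = ev
            top = seq_bottom.pop(par)
            seq_bottom[a] = _evolve_seq(top, t - birth[a], site_rate, matrix)
            seq_bottom[b] = _evolve_seq(top, t - birth[b], site_rate, matrix)
        else:
            _, _, child, lp, rp, bp = ev
            top = _splice(seq_bottom.pop(lp), seq_bottom.pop(rp), bp)
            seq_bottom[child] = _evolve_seq(top, t - birth[child], site_rate,
                                            matrix)
    return np.stack([seq_bottom[i] for i in range(n)])


def _evolve_by_marginal_trees(gen: MarginalGenealogySet, params: SubstitutionParams,
                              matrix: CodonRateMatrix, site_rate: np.ndarray,
                              rng: np.random.Generator) -> np.ndarray:
    n, L = gen.n_samples, params.n_codons
    out = np.empty((n, L), dtype=np.int64)
    # group codons by the segment containing their first nucleotide
    seg_of = np.searchsorted(np.asarray(gen.breakpoints), 3 * np.arange(L),
                             side="right")
    for seg in np.unique(seg_of):
        sites = np.flatnonzero(seg_of == seg)
        tree = gen.tree(int(seg))
        rates = site_rate[sites]
        root = 2 * n - 2
        states = {root: rng.choice(N_CODONS, size=sites.size,
                                   p=params.codon_freqs).astype(np.int64)}
        for node in range(root, n - 1, -1):
            parent_seq = states.pop(node)
            for child in tree.children[node - n]:
                branch = tree.times[node] - tree.times[child]
                states[child] = _evolve_seq(parent_seq, branch, rates, matrix)
        for tip in range(n):
            out[tip, sites] = states[tip]
    return out
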