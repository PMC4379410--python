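"""The 26-statistic summary vector for coding alignments.

The vector concatenates, in a frozen canonical order:

1-3    three recombination test statistics: PHI (pairwise homoplasy index),
       NSS (neighbor similarity score) and MaxChi (maximum chi-squared),
       reported as raw statistics rather than permutation p-values;
4-11   mean, SD, skewness and excess kurtosis of pairwise diversity at the
       codon and amino-acid levels;
12-19  the same four moments of per-site expected heterozygosity at the codon
       and amino-acid levels;
20-22  segregating-site counts at the nucleotide, codon and amino-acid levels;
23-26  joint codon/amino-acid statistics: the aa/codon mean-diversity ratio,
       the number of codon sites variable only synonymously, the number
       variable at both levels, and the aa/codon segregating-site ratio.

Any statistic that is undefined on a degenerate input (monomorphic data, zero
denominator) takes the sentinel value 0, never NaN, so that ABC distances are
always computable.  Missing data (gaps/ambiguities in observed alignments) are
handled by pairwise deletion; simulated alignments are always complete.
"""
from __future__ import annotations

from dataclasses import dataclass
import numpy as np

from ._codes import N_CODONS
from ._kernels import maxchi_scan, phi_mean_score
from .alignment import CodingAlignment

__all__ = [
    "SUMMARY_NAMES",
    "SummaryVector",
    "phi_statistic",
    "nss_statistic",
    "maxchi_statistic",
    "diversity_moments",
    "heterozygosity_moments",
    "segregating_sites",
    "joint_codon_aa_stats",
    "compute_summary_vector",
]

PHI_WINDOW = 100   # nucleotide window of the original PHI test
MAXCHI_HALF_WINDOW = 30  # polymorphic sites each side of a candidate breakpoint

_MOMENT_SUFFIXES = ("mean", "sd", "skew", "kurt")
SUMMARY_NAMES: tuple[str, ...] = (
    ("phi", "nss", "maxchi")
    + tuple(f"div_codon_{s}" for s in _MOMENT_SUFFIXES)
    + tuple(f"div_aa_{s}" for s in _MOMENT_SUFFIXES)
    + tuple(f"het_codon_{s}" for s in _MOMENT_SUFFIXES)
    + tuple(f"het_aa_{s}" for s in _MOMENT_SUFFIXES)
    + ("seg_nt", "seg_codon", "seg_aa")
    + ("div_ratio_aa_codon", "n_syn_only_sites", "n_both_var_sites",
       "seg_ratio_aa_codon")
)
assert len(SUMMARY_NAMES) == 26


@dataclass(frozen=True)
class SummaryVector:
    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.shape != (26,):
            raise ValueError("summary vector must have exactly 26 entries")
        if not np.isfinite(v).all():
            raise ValueError("summary vector entries must be finite")
        object.__setattr__(self, "values", v)

    names = SUMMARY_NAMES

    def __len__(self) -> int:
        return 26

    def __getitem__(self, key: str | int) -> float:
        if isinstance(key, str):
            key = SUMMARY_NAMES.index(key)
        return float(self.values[key])

    def to_dict(self) -> dict[str, float]:
        return dict(zip(SUMMARY_NAMES, map(float, self.values)))


# ---------------------------------------------------------------- internals

def _moments(x: np.ndarray) -> tuple[float, float, float, float]:
    """Population mean/SD/skewness/excess kurtosis; skew & kurtosis are 0
    when the SD is 0."""
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        return 0.0, 0.0, 0.0, 0.0
    m = float(x.mean())
    d = x - m
    m2 = float(np.mean(d * d))
    if m2 <= 1e-180:  # guard m2**2 against underflow to zero
        return m, 0.0, 0.0, 0.0
    sd = float(np.sqrt(m2))
    skew = float(np.mean(d ** 3)) / m2 ** 1.5
    kurt = float(np.mean(d ** 4)) / (m2 * m2) - 3.0
    return m, sd, skew, kurt


def _informative_columns(mat: np.ndarray) -> np.ndarray:
    """Indices of parsimony-informative nucleotide columns (>=2 states with
    count >=2), ignoring missing (-1) entries.  ``mat`` is (n_seq, n_sites)
    over states 0..3."""
    n, s = mat.shape
    counts = np.zeros((s, 4), dtype=np.int64)
    site_idx = np.broadcast_to(np.arange(s), (n, s))
    valid = mat >= 0
    np.add.at(counts, (site_idx[valid], mat[valid]), 1)
    return np.flatnonzero((counts >= 2).sum(axis=1) >= 2)


def _variable_columns(mat: np.ndarray) -> np.ndarray:
    """Boolean mask of columns with >=2 observed states (missing ignored)."""
    n, s = mat.shape
    first = np.full(s, -1, dtype=mat.dtype)
    var = np.zeros(s, dtype=bool)
    for i in range(n):
        row = mat[i]
        valid = row >= 0
        unset = (first == -1) & valid
        first[unset] = row[unset]
        var |= valid & (first != -1) & (row != first)
    return var


# ---------------------------------------------------------- recombination tests

def phi_statistic(alignment: CodingAlignment, window: int = PHI_WINDOW) -> float:
    """Pairwise homoplasy index: mean refined incompatibility score over pairs
    of parsimony-informative nucleotide sites within ``window`` nucleotides.
    Lower values indicate less homoplasy, hence less recombination."""
    if alignment.n_sequences < 4:
        return 0.0
    nts = alignment.nts
    idx = _informative_columns(nts)
    if idx.size < 2:
        return 0.0
    cols = np.ascontiguousarray(nts[:, idx].T)
    return float(phi_mean_score(cols, idx, window))


def nss_statistic(alignment: CodingAlignment) -> float:
    """Neighbor similarity score: the fraction of adjacent parsimony-informative
    site pairs that are compatible under the four-gamete test on binarised
    (major state vs rest) patterns."""
    nts = alignment.nts
    idx = _informative_columns(nts)
    if idx.size < 2:
        return 0.0
    cols = nts[:, idx]  # (n, S)
    # binarise: major allele (smallest code on ties) -> 0, other states -> 1
    n, s = cols.shape
    counts = np.zeros((s, 4), dtype=np.int64)
    site_idx = np.broadcast_to(np.arange(s), (n, s))
    valid = cols >= 0
    np.add.at(counts, (site_idx[valid], cols[valid]), 1)
    major = counts.argmax(axis=1).astype(cols.dtype)
    binar = np.where(valid, (cols != major[None, :]).astype(np.int8), -1)
    a, b = binar[:, :-1], binar[:, 1:]
    valid = (a >= 0) & (b >= 0)
    gametes = np.zeros(idx.size - 1, dtype=np.int64)
    for x in (0, 1):
        for y in (0, 1):
            gametes += ((a == x) & (b == y) & valid).any(axis=0)
    compatible = gametes < 4
    return float(compatible.mean())


def maxchi_statistic(alignment: CodingAlignment,
                     half_window: int = MAXCHI_HALF_WINDOW) -> float:
    """Maximum chi-squared statistic over all sequence pairs and candidate
    breakpoints.

    For each pair, alignment-wide segregating nucleotide columns are scored
    match/mismatch; every boundary between consecutive such columns is a
    candidate breakpoint, contrasted by a 2x2 chi-squared on the
    ``half_window`` polymorphic sites each side (truncated at the ends)."""
    if alignment.n_sequences < 2:
        return 0.0
    nts = alignment.nts
    seg = np.flatnonzero(_variable_columns(nts))
    if seg.size < 2:
        return 0.0
    sub = np.ascontiguousarray(nts[:, seg])
    return float(maxchi_scan(sub, half_window))


# ------------------------------------------------------------- diversity family

def _level_matrix(alignment: CodingAlignment, level: str) -> np.ndarray:
    if level == "codon":
        return alignment.codons
    if level in ("aa", "amino-acid"):
        return alignment.amino_acids
    if level in ("nt", "nucleotide"):
        return alignment.nts
    raise ValueError(f"unknown level {level!r}")


def pairwise_diversity(alignment: CodingAlignment, level: str) -> np.ndarray:
    """Proportion of differing sites for each unordered sequence pair
    (pairwise deletion of missing data)."""
    x = _level_matrix(alignment, level)
    n = x.shape[0]
    neq = x[:, None, :] != x[None, :, :]
    valid = (x[:, None, :] >= 0) & (x[None, :, :] >= 0)
    diff = (neq & valid).sum(axis=2).astype(float)
    tot = valid.sum(axis=2).astype(float)
    iu = np.triu_indices(n, 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(tot[iu] > 0, diff[iu] / tot[iu], 0.0)
    return frac


def diversity_moments(alignment: CodingAlignment,
                      level: str) -> tuple[float, float, float, float]:
    """Four moments of the pairwise-diversity distribution at one level."""
    return _moments(pairwise_diversity(alignment, level))


def site_heterozygosity(alignment: CodingAlignment, level: str) -> np.ndarray:
    """Per-site expected heterozygosity 1 - sum(f^2), with the n/(n-1)
    small-sample correction; 0 for sites with fewer than two valid states."""
    x = _level_matrix(alignment, level)
    n, s = x.shape
    n_states = N_CODONS if level == "codon" else int(x.max()) + 2
    counts = np.zeros((s, max(n_states, 1)), dtype=np.int64)
    site_idx = np.broadcast_to(np.arange(s), (n, s))
    valid = x >= 0
    np.add.at(counts, (site_idx[valid], x[valid]), 1)
    tot = counts.sum(axis=1).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        sumsq = (counts.astype(float) ** 2).sum(axis=1)
        h = np.where(tot >= 2, (1.0 - sumsq / tot ** 2) * tot / (tot - 1.0), 0.0)
    return h


def heterozygosity_moments(alignment: CodingAlignment,
                           level: str) -> tuple[float, float, float, float]:
    return _moments(site_heterozygosity(alignment, level))


def segregating_sites(alignment: CodingAlignment, level: str) -> int:
    """Number of columns with >=2 observed states at the given level."""
    return int(_variable_columns(_level_matrix(alignment, level)).sum())


def joint_codon_aa_stats(alignment: CodingAlignment) -> tuple[float, int, int, float]:
    """Statistics contrasting codon-level and amino-acid-level variation.

    Returns (aa/codon mean-diversity ratio, number of codon sites variable
    only synonymously, number variable at both levels, aa/codon
    segregating-site ratio); ratios are 0 when their denominator is 0.
    """
    div_codon = pairwise_diversity(alignment, "codon").mean() \
        if alignment.n_sequences > 1 else 0.0
    div_aa = pairwise_diversity(alignment, "aa").mean() \
        if alignment.n_sequences > 1 else 0.0
    ratio_div = float(div_aa / div_codon) if div_codon > 0 else 0.0
    var_codon = _variable_columns(alignment.codons)
    var_aa = _variable_columns(alignment.amino_acids)
    n_syn_only = int((var_codon & ~var_aa).sum())
    n_both = int((var_codon & var_aa).sum())
    seg_codon = int(var_codon.sum())
    seg_aa = int(var_aa.sum())
    ratio_seg = float(seg_aa / seg_codon) if seg_codon > 0 else 0.0
    return ratio_div, n_syn_only, n_both, ratio_seg


def permutation_pvalues(alignment: CodingAlignment, n_permutations: int = 200,
                        rng: np.random.Generator | None = None
                        ) -> dict[str, float]:
    """Permutation p-values for PHI / NSS / MaxChi (diagnostics only).

    Site order is permuted to destroy spatial signal; the p-value is the
    fraction of permutations at least as extreme as the observation in the
    direction indicating recombination (PHI: nearby sites more compatible
    than a random arrangement, so low observed values are extreme; NSS and
    MaxChi: high observed values are extreme).  The ABC summary vector uses
    the raw statistics, never these p-values.
    """
    if rng is None:
        rng = np.random.default_rng()
    obs = {
        "phi": phi_statistic(alignment),
        "nss": nss_statistic(alignment),
        "maxchi": maxchi_statistic(alignment),
    }
    hits = {"phi": 0, "nss": 0, "maxchi": 0}
    n, l = alignment.nts.shape
    for _ in range(n_permutations):
        perm = rng.permutation(l)
        # permute whole nucleotide columns; codon structure is irrelevant to
        # the three site-pattern tests
        shuffled = CodingAlignment(alignment.nts[:, perm].copy(),
                                   list(alignment.labels))
        shuffled._codons = alignment.codons  # skip stop revalidation
        hits["phi"] += phi_statistic(shuffled) <= obs["phi"]
        hits["nss"] += nss_statistic(shuffled) >= obs["nss"]
        hits["maxchi"] += maxchi_statistic(shuffled) >= obs["maxchi"]
    return {k: (hits[k] + 1) / (n_permutations + 1) for k in obs}


def compute_summary_vector(alignment: CodingAlignment) -> SummaryVector:
    """All 26 statistics in the canonical order (see module docstring)."""
    values = [
        phi_statistic(alignment),
        nss_statistic(alignment),
        maxchi_statistic(alignment),
        *diversity_moments(alignment, "codon"),
        *diversity_moments(alignment, "aa"),
        *heterozygosity_moments(alignment, "codon"),
        *heterozygosity_moments(alignment, "aa"),
        segregating_sites(alignment, "nt"),
        segregating_sites(alignment, "codon"),
        segregating_sites(alignment, "aa"),
        *joint_codon_aa_stats(alignment),
    ]
    return SummaryVector(np.asarray(values, dtype=float))
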