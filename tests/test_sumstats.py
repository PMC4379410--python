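"""Summary statistics: hand-enumerated toys, brute-force oracles, invariances.

The PHI oracle enumerates all unrooted trees on six taxa and counts Fitch
parsimony steps, which is an independent route to the minimum number of extra
steps ("homoplasies") a site pair forces; the MaxChi oracle re-scans all
pairs and breakpoints with plain Python loops.
"""
import itertools

import numpy as np
import pytest

from coalabc import CoalescentConfig, SubstitutionParams, evolve_alignment, simulate_arg
from coalabc._codes import CODON_INDEX
from coalabc._kernels import pair_incompatibility
from coalabc.alignment import CodingAlignment
from coalabc.sumstats import (
    SUMMARY_NAMES,
    SummaryVector,
    compute_summary_vector,
    diversity_moments,
    heterozygosity_moments,
    joint_codon_aa_stats,
    maxchi_statistic,
    nss_statistic,
    phi_statistic,
    segregating_sites,
)
from conftest import make_alignment


def binary_sites_alignment(site_patterns: list[list[int]]) -> CodingAlignment:
    """Alignment with one two-state site (A/C at codon position 1, G filler)
    per pattern; AGG/CGG are both arginine, so the frame stays stop-free."""
    n = len(site_patterns[0])
    rows = []
    for i in range(n):
        rows.append("".join(("A" if pat[i] == 0 else "C") + "GG"
                            for pat in site_patterns))
    return make_alignment(rows)


# ------------------------------------------------------------------ PHI oracle

def _all_unrooted_trees(n: int):
    """All unrooted binary topologies on taxa 0..n-1, as edge lists."""
    trees = [[(0, -1), (1, -1), (2, -1)]]
    for taxon in range(3, n):
        new_internal = -(taxon - 1)
        grown = []
        for edges in trees:
            for k, (u, v) in enumerate(edges):
                rest = edges[:k] + edges[k + 1:]
                grown.append(rest + [(u, new_internal), (v, new_internal),
                                     (taxon, new_internal)])
        trees = grown
    return trees


def _min_joint_extra_steps(col_a, col_b):
    """Minimum extra steps (homoplasies) a site pair requires on a common
    tree, by exhaustive search over all 6-taxon topologies."""
    n = len(col_a)
    best = None
    for edges in _all_unrooted_trees(n):
        total = 0
        for states in (col_a, col_b):
            adj = {}
            for u, v in edges:
                adj.setdefault(u, []).append(v)
                adj.setdefault(v, []).append(u)
            steps = 0

            def post(node, parent):
                nonlocal steps
                if node >= 0:
                    return {states[node]}
                sets = [post(c, node) for c in adj[node] if c != parent]
                out = sets[0]
                for s in sets[1:]:
                    inter = out & s
                    if inter:
                        out = inter
                    else:
                        out = out | s
                        steps += 1
                return out

            root_set = post(adj[0][0], 0)
            if states[0] not in root_set:
                steps += 1
            total += steps
        best = total if best is None else min(best, total)
    min_steps = (len(set(col_a)) - 1) + (len(set(col_b)) - 1)
    return best - min_steps


class TestPhi:
    def test_identical_sequences_give_zero(self):
        aln = make_alignment(["AAAGGG"] * 5)
        assert phi_statistic(aln) == 0.0

    def test_compatible_pair_scores_zero(self):
        # two sites generated by one clean bipartition: no homoplasy
        aln = binary_sites_alignment([[0, 0, 0, 1, 1, 1], [0, 0, 0, 1, 1, 1]])
        assert phi_statistic(aln) == 0.0

    def test_engineered_incompatible_pair_matches_parsimony_oracle(self):
        a = [0, 0, 0, 1, 1, 1]
        b = [0, 1, 1, 0, 0, 1]
        aln = binary_sites_alignment([a, b])
        expected = _min_joint_extra_steps(a, b)
        assert expected == 1
        assert phi_statistic(aln) == pytest.approx(expected)

    @pytest.mark.parametrize("seed", range(8))
    def test_pair_score_equals_exhaustive_parsimony(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.integers(0, 3, size=6)
        b = rng.integers(0, 3, size=6)
        kernel = pair_incompatibility(a.astype(np.int8), b.astype(np.int8))
        oracle = _min_joint_extra_steps(list(a), list(b))
        assert kernel == oracle

    def test_fewer_than_four_sequences_sentinel(self):
        aln = make_alignment(["AAAGGG", "AAAGGC", "AAAGGT"])
        assert phi_statistic(aln) == 0.0


class TestNss:
    def test_all_compatible_gives_one(self):
        aln = binary_sites_alignment([[0, 0, 1, 1]] * 4)
        assert nss_statistic(aln) == 1.0

    def test_alternating_compatibility_toy(self):
        a = [0, 0, 1, 1]
        b = [0, 1, 0, 1]
        # adjacent pairs (a,b) incompatible, (b,b) compatible, (b,a) incompatible
        aln = binary_sites_alignment([a, b, b, a])
        assert nss_statistic(aln) == pytest.approx(1.0 / 3.0)

    def test_single_informative_site_sentinel(self):
        aln = binary_sites_alignment([[0, 0, 1, 1]])
        assert nss_statistic(aln) == 0.0


def _maxchi_bruteforce(aln: CodingAlignment, k: int = 30) -> float:
    """Plain-loop reimplementation of the MaxChi scan."""
    nts = aln.nts
    seg_cols = [j for j in range(nts.shape[1])
                if len({v for v in nts[:, j] if v >= 0}) >= 2]
    best = 0.0
    n = nts.shape[0]
    for i in range(n - 1):
        for j in range(i + 1, n):
            d = [1 if nts[i, c] != nts[j, c] else 0
                 for c in seg_cols if nts[i, c] >= 0 and nts[j, c] >= 0]
            for bp in range(1, len(d)):
                left = d[max(0, bp - k):bp]
                right = d[bp:bp + k]
                a1, n1 = sum(left), len(left)
                a2, n2 = sum(right), len(right)
                tot, c1 = n1 + n2, a1 + a2
                denom = n1 * n2 * c1 * (tot - c1)
                if denom:
                    chi = tot * (a1 * (n2 - a2) - (n1 - a1) * a2) ** 2 / denom
                    best = max(best, chi)
    return best


class TestMaxChi:
    def test_identical_sequences_give_zero(self):
        aln = make_alignment(["AAAGGG"] * 4)
        assert maxchi_statistic(aln) == 0.0

    def _mosaic(self):
        rng = np.random.default_rng(42)
        L = 100
        codes = np.array(sorted(CODON_INDEX.values()))
        parent_a = rng.choice(codes, L)
        parent_b = parent_a.copy()
        flip = rng.random(L) < 0.45  # ~20% nucleotide divergence
        parent_b[flip] = rng.choice(codes, int(flip.sum()))
        child = np.concatenate([parent_a[:L // 2], parent_b[L // 2:]])
        return CodingAlignment.from_codon_matrix(
            np.stack([parent_a, parent_b, child]))

    def test_mosaic_matches_bruteforce(self):
        aln = self._mosaic()
        assert maxchi_statistic(aln) == pytest.approx(_maxchi_bruteforce(aln))
        assert maxchi_statistic(aln) > 10.0

    def test_uniform_divergence_scores_below_mosaic(self):
        rng = np.random.default_rng(43)
        codes = np.array(sorted(CODON_INDEX.values()))
        rows = rng.choice(codes, (3, 100))
        uniform = CodingAlignment.from_codon_matrix(rows)
        assert maxchi_statistic(uniform) < maxchi_statistic(self._mosaic())


class TestDiversityMoments:
    def test_identical_sequences(self):
        aln = make_alignment(["AAAGGG"] * 4)
        assert diversity_moments(aln, "codon") == (0.0, 0.0, 0.0, 0.0)

    def test_two_sequences_three_of_300_codons(self):
        codons = np.zeros((2, 300), dtype=int)
        codons[1, :3] = 1  # three differing codon sites
        aln = CodingAlignment.from_codon_matrix(codons)
        mean, sd, skew, kurt = diversity_moments(aln, "codon")
        assert mean == pytest.approx(0.01)
        assert (sd, skew, kurt) == (0.0, 0.0, 0.0)

    def test_four_sequence_toy_matches_hand_enumeration(self):
        rng = np.random.default_rng(7)
        codes = np.array(sorted(CODON_INDEX.values()))
        codons = rng.choice(codes, (4, 20))
        aln = CodingAlignment.from_codon_matrix(codons)
        pair_divs = [np.mean(codons[i] != codons[j])
                     for i, j in itertools.combinations(range(4), 2)]
        mean, sd, skew, kurt = diversity_moments(aln, "codon")
        x = np.array(pair_divs)
        assert mean == pytest.approx(x.mean())
        assert sd == pytest.approx(x.std())


class TestHeterozygosity:
    def test_monomorphic(self):
        aln = make_alignment(["AAAGGG"] * 4)
        assert heterozygosity_moments(aln, "codon") == (0.0, 0.0, 0.0, 0.0)

    def test_fifty_fifty_site_with_correction(self):
        # two states at 2:2 among 4 sequences: (1 - 0.5) * 4/3 = 2/3
        codons = np.zeros((4, 2), dtype=int)
        codons[2:, 0] = 1
        aln = CodingAlignment.from_codon_matrix(codons)
        mean, sd, *_ = heterozygosity_moments(aln, "codon")
        assert mean == pytest.approx((2.0 / 3.0 + 0.0) / 2.0)

    def test_equal_heterozygosity_sites_have_zero_sd(self):
        codons = np.zeros((4, 3), dtype=int)
        codons[2:, :] = 1  # every site 2:2
        aln = CodingAlignment.from_codon_matrix(codons)
        _, sd, skew, kurt = heterozygosity_moments(aln, "codon")
        assert (sd, skew, kurt) == (0.0, 0.0, 0.0)


class TestSegregatingSites:
    def test_identical_sequences(self):
        aln = make_alignment(["AAAGGG"] * 3)
        for level in ("nt", "codon", "aa"):
            assert segregating_sites(aln, level) == 0

    def test_synonymous_third_position_change(self):
        aln = make_alignment(["AAAGGA", "AAAGGG"])  # GGA/GGG both glycine
        assert segregating_sites(aln, "nt") == 1
        assert segregating_sites(aln, "codon") == 1
        assert segregating_sites(aln, "aa") == 0

    def test_level_ordering_invariant(self, small_simulated_alignment):
        aln = small_simulated_alignment
        assert (segregating_sites(aln, "aa")
                <= segregating_sites(aln, "codon")
                <= segregating_sites(aln, "nt"))


class TestJointStats:
    def test_monomorphic_sentinels(self):
        aln = make_alignment(["AAAGGG"] * 4)
        assert joint_codon_aa_stats(aln) == (0.0, 0, 0, 0.0)

    def test_synonymous_only_data(self):
        aln = make_alignment(["AAAGGA", "AAAGGG"])
        ratio_div, n_syn, n_both, ratio_seg = joint_codon_aa_stats(aln)
        assert ratio_div == 0.0
        assert n_both == 0
        assert n_syn == 1

    def test_hand_enumerated_site_classes(self):
        # codon sites: syn (GGA/GGG), syn (CTT/CTC), nonsyn (AAA/GAA), constant
        aln = make_alignment(["GGACTTAAAGGG", "GGGCTCGAAGGG"])
        _, n_syn, n_both, ratio_seg = joint_codon_aa_stats(aln)
        assert n_syn == 2
        assert n_both == 1
        assert ratio_seg == pytest.approx(1.0 / 3.0)


class TestSummaryVector:
    def test_arity_and_names(self, small_simulated_alignment):
        vec = compute_summary_vector(small_simulated_alignment)
        assert len(vec) == 26
        assert len(SUMMARY_NAMES) == 26
        assert np.isfinite(vec.values).all()

    def test_monomorphic_alignment_all_zero(self):
        aln = make_alignment(["AAAGGGCCC"] * 5)
        assert np.all(compute_summary_vector(aln).values == 0.0)

    def test_composition_matches_individual_operations(self,
                                                       small_simulated_alignment):
        aln = small_simulated_alignment
        vec = compute_summary_vector(aln)
        assert vec["phi"] == phi_statistic(aln)
        assert vec["nss"] == nss_statistic(aln)
        assert vec["maxchi"] == maxchi_statistic(aln)
        assert vec["div_codon_mean"] == diversity_moments(aln, "codon")[0]
        assert vec["het_aa_kurt"] == heterozygosity_moments(aln, "aa")[3]
        assert vec["seg_nt"] == segregating_sites(aln, "nt")
        assert vec["div_ratio_aa_codon"] == joint_codon_aa_stats(aln)[0]

    def test_wrong_arity_rejected(self):
        with pytest.raises(ValueError):
            SummaryVector(np.zeros(25))

    def test_taxon_permutation_invariance(self, small_simulated_alignment):
        aln = small_simulated_alignment
        base = compute_summary_vector(aln).values
        rng = np.random.default_rng(3)
        for _ in range(3):
            perm = rng.permutation(aln.n_sequences)
            shuffled = CodingAlignment.from_codon_matrix(aln.codons[perm])
            assert np.allclose(compute_summary_vector(shuffled).values, base)


class TestRecombinationSignal:
    def test_statistics_shift_with_recombination(self):
        """rho=30 should raise PHI and MaxChi and lower NSS relative to rho=0."""
        means = {}
        for rho in (0.0, 30.0):
            rng = np.random.default_rng(int(rho) + 11)
            vals = []
            for _ in range(150):
                gen = simulate_arg(CoalescentConfig(10, 180, rho), rng)
                params = SubstitutionParams(theta=60.0, omega=0.5, kappa=0.5,
                                            n_codons=60)
                aln = evolve_alignment(gen, params, rng)
                vec = compute_summary_vector(aln)
                vals.append([vec["phi"], vec["nss"], vec["maxchi"]])
            means[rho] = np.mean(vals, axis=0)
        assert means[30.0][0] > means[0.0][0]   # PHI up
        assert means[30.0][1] < means[0.0][1]   # NSS down
        assert means[30.0][2] > means[0.0][2]   # MaxChi up

    def test_diversity_ratio_increases_with_omega(self):
        means = []
        for level, omega in enumerate((0.1, 0.7, 1.8)):
            rng = np.random.default_rng(500 + level)
            vals = []
            for _ in range(200):
                gen = simulate_arg(CoalescentConfig(8, 120, 0.0), rng)
                params = SubstitutionParams(theta=40.0, omega=omega,
                                            n_codons=40)
                aln = evolve_alignment(gen, params, rng)
                vals.append(joint_codon_aa_stats(aln)[0])
            means.append(np.mean(vals))
        assert means[0] < means[1] < means[2]


class TestPermutationDiagnostics:
    def test_pvalues_in_unit_interval_and_sensitive_to_recombination(self):
        from coalabc.sumstats import permutation_pvalues
        rng = np.random.default_rng(9)
        gen = simulate_arg(CoalescentConfig(10, 300, 30.0), rng)
        params = SubstitutionParams(theta=120.0, omega=0.5, kappa=0.5,
                                    n_codons=100)
        aln = evolve_alignment(gen, params, rng)
        pv = permutation_pvalues(aln, n_permutations=50,
                                 rng=np.random.default_rng(1))
        assert set(pv) == {"phi", "nss", "maxchi"}
        assert all(0.0 < p <= 1.0 for p in pv.values())
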