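"""Neutral constant-size coalescent with recombination.

Simulates the ancestral recombination graph (ARG) of a sample of sequences and
exposes it both as an event list (consumed by the sequence evolver, which runs
forward in time down the graph) and as marginal trees, one per non-recombining
nucleotide segment.

Time is measured backward in units of 2N generations (Hudson scaling): each
pair of lineages coalesces at rate 1, and a lineage whose ancestral material
spans ``s`` of the ``l_nt - 1`` inter-nucleotide links recombines at rate
``(rho / 2) * s / (l_nt - 1)``, so that the total scaled recombination rate for
the whole alignment is rho = 4*N*r*l.  Breakpoints fall on nucleotide
boundaries drawn uniformly over the active span of the chosen lineage, so
intracodon breakpoints arise naturally.

Ancestral material that has reached its most recent common ancestor is trimmed
(it can no longer generate effective recombination); lineages are nevertheless
retained until a single grand ancestor remains, which gives the forward
sequence pass a unique root.
"""
from __future__ import annotations

import bisect
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CoalescentConfig",
    "MarginalTree",
    "MarginalGenealogySet",
    "simulate_arg",
    "marginal_tree_at",
]


@dataclass(frozen=True)
class CoalescentConfig:
    """Sample size, alignment length and scaled recombination rate.

    ``rho`` is the population-scaled recombination rate 4*N*r*l for the whole
    alignment (N effective size, r per-nucleotide recombination rate, l the
    alignment length in nucleotides).  ``effective_size_N`` is bookkeeping
    only: all internal times are already scaled.
    """

    n_samples: int
    l_nt: int
    rho: float
    effective_size_N: int = 1000
    seed: int | None = None

    def __post_init__(self):
        if self.n_samples < 2:
            raise ValueError("n_samples must be >= 2")
        if self.l_nt < 3 or self.l_nt % 3 != 0:
            raise ValueError("l_nt must be >= 3 and divisible by 3")
        if self.rho < 0:
            raise ValueError("rho must be >= 0")


class MarginalTree:
    """Rooted binary coalescent tree with tips 0..n-1.

    Nodes are numbered 0..2n-2: tips first, then internal nodes in coalescence
    order (the root is node 2n-2).  ``times`` are node ages in coalescent
    units; a branch length is the age difference parent - child.
    """

    __slots__ = ("n_tips", "times", "parent", "children")

    def __init__(self, n_tips: int, times: np.ndarray, parent: np.ndarray,
                 children: np.ndarray):
        self.n_tips = n_tips
        self.times = times
        self.parent = parent
        self.children = children  # (n_tips-1, 2) children of internal nodes

    @property
    def tmrca(self) -> float:
        return float(self.times[-1])

    @property
    def total_length(self) -> float:
        return float(np.sum(self.times[self.parent[:-1]] - self.times[:-1]))

    def branch_length(self, node: int) -> float:
        if node == 2 * self.n_tips - 2:
            return 0.0
        return float(self.times[self.parent[node]] - self.times[node])

    def tip_depths(self) -> np.ndarray:
        """Root-to-tip path lengths; equal for all tips (ultrametric)."""
        depths = np.zeros(2 * self.n_tips - 1)
        for node in range(2 * self.n_tips - 3, -1, -1):
            depths[node] = depths[self.parent[node]] + self.branch_length(node)
        return depths[: self.n_tips]

    def to_newick(self, labels: list[str] | None = None) -> str:
        labels = labels or [str(i) for i in range(self.n_tips)]

        def fmt(node: int) -> str:
            if node < self.n_tips:
                name = labels[node]
            else:
                a, b = self.children[node - self.n_tips]
                name = f"({fmt(a)},{fmt(b)})"
            return f"{name}:{self.branch_length(node):.6f}"

        a, b = self.children[-1]
        return f"({fmt(a)},{fmt(b)});"


@dataclass
class MarginalGenealogySet:
    """ARG of one simulation, viewed as per-segment marginal trees.

    ``breakpoints`` are the recombination breakpoints that occurred in
    ancestral material, as 0-based nucleotide positions splitting
    ``[0, l_nt)`` into half-open segments ``[0,b1), [b1,b2), ...``.
    ``events`` is the time-ordered ARG event list:

    - ``("c", t, child_a, child_b, parent)``  coalescence
    - ``("r", t, child, left_parent, right_parent, bp)``  recombination

    Lineage ids: 0..n-1 are the sampled tips (time 0); every event creates
    fresh ids.  Trees are built lazily from the event list.
    """

    n_samples: int
    l_nt: int
    rho: float
    breakpoints: list[int]
    events: list[tuple]
    n_recomb_events: int
    birth_times: dict[int, float]
    _trees: list[MarginalTree | None] = field(default=None, repr=False)

    def __post_init__(self):
        if self._trees is None:
            self._trees = [None] * (len(self.breakpoints) + 1)

    @property
    def n_segments(self) -> int:
        return len(self.breakpoints) + 1

    @property
    def trees(self) -> list[MarginalTree]:
        return [self.tree(i) for i in range(self.n_segments)]

    def segment_bounds(self, seg: int) -> tuple[int, int]:
        lo = 0 if seg == 0 else self.breakpoints[seg - 1]
        hi = self.l_nt if seg == len(self.breakpoints) else self.breakpoints[seg]
        return lo, hi

    def tree(self, seg: int) -> MarginalTree:
        if self._trees[seg] is None:
            pos = self.segment_bounds(seg)[0]
            self._trees[seg] = _build_marginal_tree(self, pos)
        return self._trees[seg]

    def to_newick(self) -> str:
        """One tree per line, prefixed with its segment range as a comment."""
        lines = []
        for seg in range(self.n_segments):
            lo, hi = self.segment_bounds(seg)
            lines.append(f"[{lo},{hi}) {self.tree(seg).to_newick()}")
        return "\n".join(lines)


def _build_marginal_tree(gen: MarginalGenealogySet, pos: int) -> MarginalTree:
    """Replay the event list, following position ``pos`` through the ARG."""
    n = gen.n_samples
    node_of = {i: i for i in range(n)}  # lineage id -> tree node
    times = np.zeros(2 * n - 1)
    parent = np.full(2 * n - 1, -1, dtype=np.int64)
    children = np.zeros((n - 1, 2), dtype=np.int64)
    next_node = n
    for ev in gen.events:
        if ev[0] == "c":
            _, t, a, b, par = ev
            in_a, in_b = a in node_of, b in node_of
            if in_a and in_b:
                na, nb = node_of.pop(a), node_of.pop(b)
                times[next_node] = t
                parent[na] = parent[nb] = next_node
                children[next_node - n] = (na, nb)
                node_of[par] = next_node
                next_node += 1
                if next_node == 2 * n - 1:
                    break
            elif in_a:
                node_of[par] = node_of.pop(a)
            elif in_b:
                node_of[par] = node_of.pop(b)
        else:
            _, t, child, lp, rp, bp = ev
            if child in node_of:
                node_of[lp if pos < bp else rp] = node_of.pop(child)
    return MarginalTree(n, times, parent, children)


def simulate_arg(config: CoalescentConfig,
                 rng: np.random.Generator | None = None) -> MarginalGenealogySet:
    """Simulate one ARG under the neutral constant-size coalescent.

    Runs backward in time until every nucleotide position has found its MRCA
    and the remaining lineages have merged into a single grand ancestor.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n, l_nt, rho = config.n_samples, config.l_nt, config.rho
    n_links = l_nt - 1

    # per-lineage state
    anc: dict[int, np.ndarray] = {}      # ancestral-material mask
    span: dict[int, tuple[int, int]] = {}  # (first, last+1) ancestral position
    birth: dict[int, float] = {}
    for i in range(n):
        anc[i] = np.ones(l_nt, dtype=bool)
        span[i] = (0, l_nt)
        birth[i] = 0.0
    counts = np.full(l_nt, n, dtype=np.int64)  # lineages carrying each position

    active = list(range(n))
    links = [float(n_links)] * n  # recombination weight per active lineage
    events: list[tuple] = []
    breakpoints: set[int] = set()
    next_id = n
    t = 0.0
    n_rec = 0
    per_link = rho / (2.0 * n_links)

    while len(active) > 1:
        k = len(active)
        coal_rate = k * (k - 1) / 2.0
        links_sum = sum(links) if rho > 0.0 else 0.0
        rec_total = per_link * links_sum
        total = coal_rate + rec_total
        t += rng.exponential(1.0 / total)

        if rng.random() * total < coal_rate:
            ia = int(rng.integers(k))
            ib = int(rng.integers(k - 1))
            if ib >= ia:
                ib += 1
            a, b = active[ia], active[ib]
            anc_a, anc_b = anc.pop(a), anc.pop(b)
            span.pop(a), span.pop(b)
            both = anc_a & anc_b
            if both.any():
                counts[both] -= 1
            new = anc_a | anc_b
            done = new & (counts == 1)
            if done.any():
                new &= ~done
                counts[done] = 0
            par = next_id
            next_id += 1
            anc[par] = new
            if new.any():
                span[par] = (int(new.argmax()), l_nt - int(new[::-1].argmax()))
            else:
                span[par] = (0, 0)
            birth[par] = t
            events.append(("c", t, a, b, par))
            for ix in sorted((ia, ib), reverse=True):
                active.pop(ix)
                links.pop(ix)
            active.append(par)
            links.append(float(max(span[par][1] - span[par][0] - 1, 0)))
        else:
            target = rng.random() * links_sum
            acc = 0.0
            ix = k - 1
            for pos_i, w in enumerate(links):
                acc += w
                if target < acc:
                    ix = pos_i
                    break
            child = active[ix]
            lo, hi = span[child]
            bp = int(rng.integers(lo + 1, hi))  # breakpoint in [lo+1, hi-1]
            mask = anc.pop(child)
            span.pop(child)
            left = mask.copy()
            left[bp:] = False
            right = mask
            right[:bp] = False
            lp, rp = next_id, next_id + 1
            next_id += 2
            anc[lp], anc[rp] = left, right
            # left keeps the old lower end; right keeps the old upper end
            span[lp] = (lo, bp - int(left[lo:bp][::-1].argmax()))
            span[rp] = (bp + int(right[bp:hi].argmax()), hi)
            birth[lp] = birth[rp] = t
            events.append(("r", t, child, lp, rp, bp))
            breakpoints.add(bp)
            n_rec += 1
            active.pop(ix)
            links.pop(ix)
            active.extend((lp, rp))
            links.append(float(max(span[lp][1] - span[lp][0] - 1, 0)))
            links.append(float(max(span[rp][1] - span[rp][0] - 1, 0)))

    return MarginalGenealogySet(
        n_samples=n,
        l_nt=l_nt,
        rho=rho,
        breakpoints=sorted(breakpoints),
        events=events,
        n_recomb_events=n_rec,
        birth_times=birth,
    )


def marginal_tree_at(genealogies: MarginalGenealogySet, nt_position: int) -> MarginalTree:
    """Tree of the segment containing ``nt_position`` (half-open convention)."""
    if not 0 <= nt_position < genealogies.l_nt:
        raise IndexError(f"position {nt_position} outside [0, {genealogies.l_nt})")
    seg = bisect.bisect_right(genealogies.breakpoints, nt_position)
    return genealogies.tree(seg)
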