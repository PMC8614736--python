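"""Sequence-level analysis: per-species consensus sequences, Kimura
2-parameter distances, neighbor-joining tree construction, maximum-likelihood
species delimitation under the Poisson Tree Processes model, partition
quality summaries, and IUPAC-aware degenerate-primer matching.

The delimitation model treats the number of substitutions accumulating on a
branch as exponentially distributed, with one rate for between-species
(speciation) branches and another for within-species (coalescent) branches.
A delimitation assigns every leaf to a species clade; branches inside species
clades are within-species, all others between-species.  Rates are profiled
out at their maximum-likelihood values and the best delimitation is found by
best-improvement hill climbing over split/merge moves from several starting
states; the two-rate model is compared against a one-rate null by AIC.  This
is a deterministic, maximum-likelihood counterpart of the Bayesian/MCMC
implementations in common use; per-cluster posterior support values are not
produced.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np

from .errors import (
    ConfigError,
    DegenerateInputError,
    SaturationError,
    TaxonLookupError,
    ValidationError,
)
from .tables_io import (
    AlignedSequences,
    CODE_FOR_BASES,
    GAP,
    IUPAC_BASES,
    IUPAC_CODES,
)

logger = logging.getLogger(__name__)

#: Marker distance for saturated pairs (K2P log argument <= 0).
SATURATED = math.inf

_PURINES = {"A", "G"}
_PYRIMIDINES = {"C", "T"}
_ACGT = frozenset("ACGT")

_COMPLEMENT = {
    "A": "T", "C": "G", "G": "C", "T": "A",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D", "N": "N", GAP: GAP,
}

# branches at or below this length carry no substitutions at any realistic
# alignment length; they are excluded from the delimitation likelihood so
# that zero-length edges (identical sequences) cannot drive a rate to
# infinity.  Config-exposed via ptp_delimit(min_branch=...).
_MIN_BRANCH = 1e-7


def reverse_complement(seq: str) -> str:
    return "".join(_COMPLEMENT[c] for c in reversed(seq.upper()))


# ---------------------------------------------------------------------------
# Consensus
# ---------------------------------------------------------------------------

def consensus(seqs: AlignedSequences | Sequence[str],
              majority_threshold: float = 0.5) -> str:
    """Column-wise consensus of an aligned set of sequences.

    Per column: the unique most frequent non-gap symbol wins when its
    frequency (among non-gap symbols) exceeds the majority threshold; ties at
    the maximum are resolved to the minimal IUPAC ambiguity code covering the
    tied symbols' base sets.  All-gap columns are removed.  A single sequence
    returns itself (minus gap columns).
    """
    if isinstance(seqs, AlignedSequences):
        rows = seqs.sequences
    else:
        rows = [s.upper() for s in seqs]
    if not rows:
        raise ValidationError("consensus of an empty sequence set")
    if len({len(r) for r in rows}) > 1:
        raise ValidationError("consensus requires equal-length sequences")
    out = []
    for col in zip(*rows):
        symbols = [c for c in col if c != GAP]
        if not symbols:
            continue
        counts: dict[str, int] = {}
        for c in symbols:
            counts[c] = counts.get(c, 0) + 1
        top = max(counts.values())
        winners = sorted(c for c, n in counts.items() if n == top)
        if len(winners) == 1 and top / len(symbols) > majority_threshold:
            out.append(winners[0])
        else:
            bases = frozenset().union(*(IUPAC_BASES[c] for c in winners))
            out.append(CODE_FOR_BASES[bases])
    return "".join(out)


# ---------------------------------------------------------------------------
# K2P distances
# ---------------------------------------------------------------------------

def k2p(seq1: str, seq2: str) -> float:
    """Kimura 2-parameter distance between two aligned sequences.

    Sites where either sequence has a gap or an ambiguity code are excluded
    pairwise.  With P and Q the transition and transversion proportions over
    the retained sites, K = -0.5 * ln((1 - 2P - Q) * sqrt(1 - 2Q)); when a
    log argument is non-positive the distance is saturated and the
    :data:`SATURATED` marker is returned.
    """
    a, b = seq1.upper(), seq2.upper()
    if len(a) != len(b):
        raise ValidationError("k2p requires equal-length sequences")
    n = ts = tv = 0
    for x, y in zip(a, b):
        if x not in _ACGT or y not in _ACGT:
            continue
        n += 1
        if x == y:
            continue
        if (x in _PURINES) == (y in _PURINES):
            ts += 1
        else:
            tv += 1
    if n == 0:
        raise ValidationError("no comparable sites between sequences")
    p, q = ts / n, tv / n
    w1 = 1.0 - 2.0 * p - q
    w2 = 1.0 - 2.0 * q
    if w1 <= 0 or w2 <= 0:
        return SATURATED
    return -0.5 * math.log(w1 * math.sqrt(w2))


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distance matrix with saturated pairs flagged."""

    labels: list[str]
    d: np.ndarray = field(repr=False)
    undefined_pairs: set[tuple[str, str]] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise ValidationError("distance matrix shape mismatch")
        if not np.allclose(np.diag(self.d), 0):
            raise ValidationError("distance matrix diagonal must be zero")
        finite = self.d[np.isfinite(self.d)]
        if (finite < 0).any():
            raise ValidationError("distances must be non-negative")
        if not np.allclose(self.d, self.d.T, equal_nan=True):
            raise ValidationError("distance matrix must be symmetric")


def k2p_matrix(sequences: Mapping[str, str]) -> DistanceMatrix:
    """Pairwise K2P distances for a label -> aligned-sequence map."""
    labels = list(sequences)
    n = len(labels)
    d = np.zeros((n, n))
    undefined: set[tuple[str, str]] = set()
    for i in range(n):
        for j in range(i + 1, n):
            dist = k2p(sequences[labels[i]], sequences[labels[j]])
            if dist == SATURATED:
                undefined.add((labels[i], labels[j]))
            d[i, j] = d[j, i] = dist
    return DistanceMatrix(labels, d, undefined)


# ---------------------------------------------------------------------------
# Neighbor joining
# ---------------------------------------------------------------------------

def nj(dm: DistanceMatrix) -> dendropy.Tree:
    """Saitou-Nei neighbor joining with the standard Q-criterion.

    Exact on additive matrices (recovers topology and branch lengths).
    Negative branch-length estimates are clamped to zero with the deficit
    transferred to the sibling branch, so each joined pair keeps its pairwise
    distance.  Ties in the Q-criterion are broken by the lowest (i, j) pair
    of original label indices.  The result is unrooted (trifurcating root
    node) for four or more taxa.
    """
    if dm.undefined_pairs:
        raise SaturationError(
            "cannot build a tree over saturated pairs: "
            + ", ".join(f"{a}~{b}" for a, b in sorted(dm.undefined_pairs)))
    n0 = len(dm.labels)
    if n0 < 2:
        raise ValidationError("neighbor joining needs at least 2 taxa")

    taxa = dendropy.TaxonNamespace(dm.labels)
    tree = dendropy.Tree(taxon_namespace=taxa)
    nodes = []
    for label in dm.labels:
        node = dendropy.Node(taxon=taxa.get_taxon(label))
        nodes.append(node)

    D = dm.d.copy()
    active = list(range(n0))  # indices into `nodes`
    all_nodes = list(nodes)

    def join(i_pos: int, j_pos: int, li: float, lj: float) -> None:
        """Join active positions i_pos/j_pos under a new internal node."""
        nonlocal D, active, all_nodes
        ni, nj_ = all_nodes[active[i_pos]], all_nodes[active[j_pos]]
        parent = dendropy.Node()
        parent.add_child(ni)
        parent.add_child(nj_)
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        ni.edge.length = max(li, 0.0)
        nj_.edge.length = max(lj, 0.0)
        all_nodes.append(parent)
        m = D.shape[0]
        keep = [p for p in range(m) if p not in (i_pos, j_pos)]
        new_row = 0.5 * (D[i_pos, keep] + D[j_pos, keep] - D[i_pos, j_pos])
        D2 = np.zeros((len(keep) + 1, len(keep) + 1))
        D2[:-1, :-1] = D[np.ix_(keep, keep)]
        D2[-1, :-1] = new_row
        D2[:-1, -1] = new_row
        D = D2
        active = [active[p] for p in keep] + [len(all_nodes) - 1]

    while len(active) > 3:
        m = len(active)
        r = D.sum(axis=1)
        Q = (m - 2) * D - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        best = None
        for i_pos in range(m):
            for j_pos in range(i_pos + 1, m):
                key = (Q[i_pos, j_pos], active[i_pos], active[j_pos])
                if best is None or key < best[0]:
                    best = (key, i_pos, j_pos)
        _, i_pos, j_pos = best
        dij = D[i_pos, j_pos]
        li = 0.5 * dij + (r[i_pos] - r[j_pos]) / (2.0 * (m - 2))
        join(i_pos, j_pos, li, dij - li)

    root = dendropy.Node()
    if len(active) == 2:
        dij = D[0, 1]
        for pos in (0, 1):
            child = all_nodes[active[pos]]
            root.add_child(child)
            child.edge.length = dij / 2.0
    else:
        d01, d02, d12 = D[0, 1], D[0, 2], D[1, 2]
        lengths = (0.5 * (d01 + d02 - d12),
                   0.5 * (d01 + d12 - d02),
                   0.5 * (d02 + d12 - d01))
        for pos, length in zip(range(3), lengths):
            child = all_nodes[active[pos]]
            root.add_child(child)
            child.edge.length = max(0.0, length)
    tree.seed_node = root
    tree.is_rooted = False
    return tree


def tree_path_distances(tree: dendropy.Tree) -> DistanceMatrix:
    """Leaf-to-leaf path-length distances of a tree (patristic matrix)."""
    pdm = tree.phylogenetic_distance_matrix()
    labels = sorted(t.label for t in tree.taxon_namespace)
    n = len(labels)
    d = np.zeros((n, n))
    tax = {t.label: t for t in tree.taxon_namespace}
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = pdm.patristic_distance(tax[labels[i]],
                                                       tax[labels[j]])
    return DistanceMatrix(labels, d)


# ---------------------------------------------------------------------------
# ML Poisson Tree Processes delimitation
# ---------------------------------------------------------------------------

@dataclass
class SpeciesPartition:
    """A delimitation of a tree's leaves into putative species."""

    assignment: dict[str, int]
    n_clusters: int
    log_likelihood: float
    null_log_likelihood: float
    aic: float
    null_aic: float
    null_preferred: bool
    per_cluster_support: dict[int, float] | None = None

    def clusters(self) -> dict[int, set[str]]:
        out: dict[int, set[str]] = {}
        for leaf, cid in self.assignment.items():
            out.setdefault(cid, set()).add(leaf)
        return out


def _rate_class_loglik(n: int, total: float) -> float:
    """Max log-likelihood of n iid exponential lengths summing to `total`."""
    if n == 0:
        return 0.0
    return n * (math.log(n / total) - 1.0)


class _PtpTree:
    """Indexed view of a rooted binary tree for delimitation search.

    A state is a frozenset of node ids forming an antichain that covers all
    leaves; the edges strictly below a state node are within-species.
    Edges of length <= min_branch are excluded from the likelihood (they
    carry no substitutions and would otherwise drive a rate to infinity).
    """

    def __init__(self, tree: dendropy.Tree, min_branch: float = _MIN_BRANCH):
        self.nodes = list(tree.preorder_node_iter())
        self.index = {id(nd): i for i, nd in enumerate(self.nodes)}
        self.children: list[list[int]] = [[] for _ in self.nodes]
        self.lengths = np.zeros(len(self.nodes))
        self.leaf_labels: list[str | None] = [None] * len(self.nodes)
        for i, nd in enumerate(self.nodes):
            for ch in nd.child_nodes():
                self.children[i].append(self.index[id(ch)])
            self.lengths[i] = max(float(nd.edge.length or 0.0), 0.0)
            if nd.is_leaf():
                self.leaf_labels[i] = (nd.taxon.label if nd.taxon
                                       else str(i))
        self.root = 0
        self.min_branch = min_branch
        # subtree edge counts/sums over included edges strictly below a node
        self.sub_n = np.zeros(len(self.nodes), dtype=int)
        self.sub_s = np.zeros(len(self.nodes))
        for i in reversed(range(len(self.nodes))):
            for c in self.children[i]:
                include = self.lengths[c] > min_branch
                self.sub_n[i] += self.sub_n[c] + include
                self.sub_s[i] += self.sub_s[c] + (
                    self.lengths[c] if include else 0.0)
        self.total_n = int(self.sub_n[self.root])
        self.total_s = float(self.sub_s[self.root])
        self.parent = np.full(len(self.nodes), -1, dtype=int)
        for i in range(len(self.nodes)):
            for c in self.children[i]:
                self.parent[c] = i

    def leaves_under(self, i: int) -> list[str]:
        stack, out = [i], []
        while stack:
            j = stack.pop()
            if self.leaf_labels[j] is not None:
                out.append(self.leaf_labels[j])
            stack.extend(reversed(self.children[j]))
        return out

    def loglik(self, state: frozenset[int]) -> float:
        n_within = int(sum(self.sub_n[i] for i in state))
        s_within = float(sum(self.sub_s[i] for i in state))
        n_between = self.total_n - n_within
        s_between = self.total_s - s_within
        return (_rate_class_loglik(n_within, s_within)
                + _rate_class_loglik(n_between, s_between))

    def null_loglik(self) -> float:
        return _rate_class_loglik(self.total_n, self.total_s)

    def singleton_state(self) -> frozenset[int]:
        return frozenset(i for i, lab in enumerate(self.leaf_labels)
                         if lab is not None)

    def root_state(self) -> frozenset[int]:
        return frozenset({self.root})

    def random_state(self, rng: np.random.Generator,
                     p_stop: float = 0.5) -> frozenset[int]:
        state: set[int] = set()
        stack = [self.root]
        while stack:
            i = stack.pop()
            if not self.children[i] or rng.random() < p_stop:
                state.add(i)
            else:
                stack.extend(self.children[i])
        return frozenset(state)

    def moves(self, state: frozenset[int]) -> Iterable[frozenset[int]]:
        # split a species clade at its crown
        for i in sorted(state):
            if self.children[i]:
                yield state - {i} | set(self.children[i])
        # merge two sibling species into their parent
        for i in sorted(state):
            p = self.parent[i]
            if p >= 0 and all(c in state for c in self.children[p]):
                if i == min(self.children[p]):  # emit each merge once
                    yield state - set(self.children[p]) | {p}


def _dp_best_state(view: _PtpTree, rate_within: float,
                   rate_between: float) -> frozenset[int]:
    """Exact best delimitation for FIXED rates.

    With the rates fixed, each included edge contributes log(rate) - rate*b
    under its class, classes are decoupled, and the antichain-constrained
    optimum decomposes over the tree: a node either becomes a species crown
    (all edges below it within-species) or delegates to its children (their
    stem edges between-species).  Solved bottom-up in O(n).
    """
    lw, lb = math.log(rate_within), math.log(rate_between)

    def edge_cost(j: int, within: bool) -> float:
        b = view.lengths[j]
        if b <= view.min_branch:
            return 0.0
        return (lw - rate_within * b) if within else (lb - rate_between * b)

    n = len(view.nodes)
    best = np.zeros(n)
    take = np.zeros(n, dtype=bool)  # True: node is a species crown
    within_sum = np.zeros(n)  # cost of making everything below within
    for i in reversed(range(n)):
        within_sum[i] = sum(within_sum[c] + edge_cost(c, True)
                            for c in view.children[i])
        if not view.children[i]:
            best[i], take[i] = 0.0, True
            continue
        split = sum(best[c] + edge_cost(c, False)
                    for c in view.children[i])
        crown = within_sum[i]
        # >= so that ties prefer lumping (fewer clusters)
        take[i] = crown >= split
        best[i] = max(crown, split)
    state: set[int] = set()
    stack = [view.root]
    while stack:
        i = stack.pop()
        if take[i]:
            state.add(i)
        else:
            stack.extend(view.children[i])
    return frozenset(state)


def _profile_search(view: _PtpTree) -> tuple[frozenset[int], float]:
    """Coordinate ascent on the profile likelihood over rate pairs induced
    by every split of the sorted edge lengths, followed by EM-style
    alternation (rates -> exact DP state -> MLE rates) to a fixpoint."""
    lengths = np.sort([view.lengths[i] for i in range(len(view.nodes))
                       if i != view.root
                       and view.lengths[i] > view.min_branch])
    total_n, total_s = len(lengths), float(lengths.sum())
    best_state, best_ll = None, -math.inf

    def consider(state: frozenset[int]) -> None:
        nonlocal best_state, best_ll
        ll = view.loglik(state)
        if ll > best_ll + 1e-12 or (
                best_state is not None and abs(ll - best_ll) <= 1e-12
                and sorted(state) < sorted(best_state)):
            best_state, best_ll = state, ll

    def refine(rw: float, rb: float) -> None:
        seen = set()
        for _ in range(50):
            state = _dp_best_state(view, rw, rb)
            consider(state)
            if state in seen:
                break
            seen.add(state)
            n_w = int(sum(view.sub_n[i] for i in state))
            s_w = float(sum(view.sub_s[i] for i in state))
            n_b, s_b = total_n - n_w, total_s - s_w
            if n_w == 0 or n_b == 0 or s_w <= 0 or s_b <= 0:
                break
            rw, rb = n_w / s_w, n_b / s_b

    for k in range(1, total_n):
        s_w = float(lengths[:k].sum())
        s_b = float(lengths[k:].sum())
        if s_w <= 0 or s_b <= 0:
            continue
        rw, rb = k / s_w, (total_n - k) / s_b
        if rw <= rb:
            continue
        refine(rw, rb)
    return best_state, best_ll


def _hill_climb(view: _PtpTree, state: frozenset[int],
                max_iter: int) -> tuple[frozenset[int], float]:
    current, current_ll = state, view.loglik(state)
    for _ in range(max_iter):
        best_move, best_ll = None, current_ll
        for cand in view.moves(current):
            ll = view.loglik(cand)
            key_better = ll > best_ll + 1e-12
            tie = (best_move is not None and abs(ll - best_ll) <= 1e-12
                   and sorted(cand) < sorted(best_move))
            if key_better or tie:
                best_move, best_ll = cand, ll
        if best_move is None:
            break
        current, current_ll = best_move, best_ll
    return current, current_ll


def midpoint_root(tree: dendropy.Tree) -> dendropy.Tree:
    """Midpoint-root a copy of the tree (delimitation depends on rooting)."""
    rooted = tree.clone(depth=1)
    rooted.reroot_at_midpoint(update_bipartitions=False)
    rooted.is_rooted = True
    return rooted


def ptp_delimit(tree: dendropy.Tree, max_iter: int = 500, seed: int = 0,
                n_restarts: int = 8, min_branch: float = _MIN_BRANCH,
                collapse_if_null: bool = True) -> SpeciesPartition:
    """Maximum-likelihood species delimitation under the two-rate
    branching-process model.

    Starts hill climbing from the all-singletons and the single-species
    states plus seeded random restarts, keeps the best two-rate delimitation,
    and compares it against the one-rate null by AIC.  When the null wins and
    ``collapse_if_null`` is set, the returned assignment is a single cluster;
    the best two-rate partition remains available by passing
    ``collapse_if_null=False``.  Unrooted input is midpoint-rooted with a
    logged notice; a zero-total-length tree is rejected.
    """
    work = tree.clone(depth=1)
    if sum(float(nd.edge.length or 0.0)
           for nd in work.preorder_node_iter()) <= 0:
        raise DegenerateInputError("tree has zero total branch length")
    if not work.is_rooted or len(work.seed_node.child_nodes()) > 2:
        logger.info("unrooted input: midpoint-rooting before delimitation")
        work = midpoint_root(work)
    if any(len(nd.child_nodes()) > 2 for nd in work.preorder_node_iter()):
        work.resolve_polytomies()
    view = _PtpTree(work, min_branch=min_branch)
    n_leaves = sum(1 for lab in view.leaf_labels if lab is not None)
    if n_leaves < 3:
        raise ValidationError("delimitation needs at least 3 leaves")
    if view.total_s <= 0:
        raise DegenerateInputError("tree has zero total branch length")

    rng = np.random.default_rng(seed)
    best_state, best_ll = _profile_search(view)
    starts = [view.singleton_state(), view.root_state()]
    if best_state is not None:
        starts.append(best_state)
    starts += [view.random_state(rng) for _ in range(n_restarts)]
    for start in starts:
        state, ll = _hill_climb(view, start, max_iter)
        if best_state is None or ll > best_ll + 1e-12 or (
                abs(ll - best_ll) <= 1e-12
                and sorted(state) < sorted(best_state)):
            best_state, best_ll = state, ll

    # AIC with change-point counting: the two-rate model spends 2 rate
    # parameters plus one boundary parameter per cluster beyond the first
    # (the delimitation itself is fitted, so its complexity must be paid
    # for); the null has a single rate and no boundaries.
    null_ll = view.null_loglik()
    k_alt = 2 + (len(best_state) - 1)
    aic = 2 * k_alt - 2 * best_ll
    null_aic = 2 * 1 - 2 * null_ll
    null_preferred = null_aic <= aic

    if null_preferred and collapse_if_null:
        chosen = view.root_state()
        chosen_ll = null_ll
    else:
        chosen, chosen_ll = best_state, best_ll

    assignment: dict[str, int] = {}
    next_id = 1
    for i in sorted(chosen):
        for leaf in view.leaves_under(i):
            assignment[leaf] = next_id
        next_id += 1
    return SpeciesPartition(
        assignment=assignment,
        n_clusters=len(chosen),
        log_likelihood=chosen_ll,
        null_log_likelihood=null_ll,
        aic=aic,
        null_aic=null_aic,
        null_preferred=null_preferred,
    )


# ---------------------------------------------------------------------------
# Partition quality
# ---------------------------------------------------------------------------

@dataclass
class PartitionSummary:
    n_species: int
    n_separated: int
    merges: list[tuple[str, ...]]
    splits: list[str]

    @property
    def percent_separated(self) -> float:
        return 100.0 * self.n_separated / self.n_species


def partition_summary(partition: SpeciesPartition,
                      truth: Mapping[str, str]) -> PartitionSummary:
    """Score a delimitation against the true leaf -> species map.

    A species is *separated* iff its leaves form exactly one cluster that
    contains no other species' leaves.  Species sharing a cluster are
    enumerated as merges; species spread over several clusters as splits.
    """
    missing = set(partition.assignment) - set(truth)
    if missing:
        raise TaxonLookupError(
            "leaves missing from truth map: " + ", ".join(sorted(missing)))
    clusters = partition.clusters()
    species_leaves: dict[str, set[str]] = {}
    for leaf, sp in truth.items():
        if leaf in partition.assignment:
            species_leaves.setdefault(sp, set()).add(leaf)

    n_separated = 0
    merges: list[tuple[str, ...]] = []
    splits: list[str] = []
    seen_merge: set[tuple[str, ...]] = set()
    for sp, leaves in sorted(species_leaves.items()):
        cids = {partition.assignment[leaf] for leaf in leaves}
        if len(cids) > 1:
            splits.append(sp)
            continue
        cid = next(iter(cids))
        if clusters[cid] == leaves:
            n_separated += 1
        else:
            members = tuple(sorted({truth[l] for l in clusters[cid]}))
            if members not in seen_merge:
                seen_merge.add(members)
                merges.append(members)
    return PartitionSummary(len(species_leaves), n_separated, merges, splits)


# ---------------------------------------------------------------------------
# Degenerate primer matching
# ---------------------------------------------------------------------------

@dataclass
class PrimerPair:
    """A forward/reverse primer pair in IUPAC nucleotide code."""

    forward: str
    reverse: str
    name: str = ""

    def __post_init__(self) -> None:
        for which, seq in (("forward", self.forward),
                           ("reverse", self.reverse)):
            bad = set(seq.upper()) - IUPAC_CODES
            if bad:
                raise ValidationError(
                    f"{which} primer contains non-IUPAC characters "
                    f"{sorted(bad)}")
        self.forward = self.forward.upper()
        self.reverse = self.reverse.upper()


@dataclass
class PrimerHit:
    found: bool
    positions: list[int]
    mismatches: int | None


@dataclass
class PrimerMatchResult:
    found: bool
    forward: PrimerHit
    reverse: PrimerHit


def _compatible(a: str, b: str) -> bool:
    sa, sb = IUPAC_BASES.get(a), IUPAC_BASES.get(b)
    return bool(sa and sb and (sa & sb))


def match_primer(target: str, primer: str,
                 max_mismatch: int = 3) -> PrimerHit:
    """Scan one primer along a target; IUPAC-aware (codes match iff their
    base sets intersect).  Reports the best (lowest-mismatch) offsets with
    mismatch count <= max_mismatch; a primer longer than the target yields a
    no-match result."""
    t, p = target.upper(), primer.upper()
    if len(p) > len(t):
        logger.info("primer (%d nt) longer than target (%d nt): no match",
                    len(p), len(t))
        return PrimerHit(False, [], None)
    best = None
    hits: list[int] = []
    for off in range(len(t) - len(p) + 1):
        mm = sum(1 for a, b in zip(p, t[off:off + len(p)])
                 if not _compatible(a, b))
        if best is None or mm < best:
            best, hits = mm, [off]
        elif mm == best:
            hits.append(off)
    if best is None or best > max_mismatch:
        return PrimerHit(False, [], None)
    return PrimerHit(True, hits, best)


def primer_match(target: str, primers: PrimerPair,
                 max_mismatch: int = 3) -> PrimerMatchResult:
    """Match a primer pair against a target sequence.

    The forward primer is scanned against the target, the reverse primer
    against the target's reverse complement; the pair counts as found when
    both primers hit within the mismatch budget.
    """
    if not target:
        raise ValidationError("empty target sequence")
    fwd = match_primer(target, primers.forward, max_mismatch)
    rev = match_primer(reverse_complement(target), primers.reverse,
                       max_mismatch)
    return PrimerMatchResult(fwd.found and rev.found, fwd, rev)
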