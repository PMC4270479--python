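"""Ordering the focal substitutions on a fixed, time-annotated phylogeny.

Given a rooted tree, a taxa × sites character matrix of amino-acid states and
a focal tip (e.g. human), each focal site is reconstructed by small parsimony
and the substitution toward the focal tip's state is placed on the branch(es)
of the root-to-focal-tip path where the most-parsimonious state changes.
Sites placed on the same branch form a group whose internal order is unknown;
the branch sequence root→tip induces a partial order over the sites, whose
linear extensions are the substitution orderings consistent with the
phylogeny.

Parsimony machinery: the bottom-up pass uses Hartigan state counts (identical
to Fitch intersection/union on bifurcating trees and exact on polytomies);
the top-down resolution computes, for every node and state, the minimum number
of changes over the whole tree conditional on that assignment (unit-cost
Sankoff down/up recursion), so the reported per-node state sets are exactly
the states attainable in some most-parsimonious reconstruction.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from math import factorial, prod
from typing import Dict, FrozenSet, Iterable, Iterator, List, Mapping, Optional, Sequence, Tuple

import dendropy
import pandas as pd


class OrderingError(ValueError):
    """Raised for invalid trees, character matrices or partial orders."""


# ---------------------------------------------------------------------------
# partial orders and linear extensions
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PartialOrder:
    """Ordered groups of mutation labels, root-most branch first.

    Within a group the order is unknown; across groups it is fixed.
    """

    groups: Tuple[FrozenSet[str], ...]

    def __post_init__(self) -> None:
        groups = tuple(frozenset(g) for g in self.groups)
        object.__setattr__(self, "groups", groups)
        seen: set[str] = set()
        for g in groups:
            if not g:
                raise OrderingError("empty group in partial order")
            if seen & g:
                raise OrderingError(f"overlapping groups: {sorted(seen & g)}")
            seen |= g

    @property
    def labels(self) -> FrozenSet[str]:
        return frozenset().union(*self.groups) if self.groups else frozenset()

    @classmethod
    def from_lists(cls, groups: Iterable[Iterable[str]]) -> "PartialOrder":
        return cls(tuple(frozenset(g) for g in groups))


def linear_extensions(partial_order: PartialOrder,
                      enumerate_orderings: bool = False):
    """Count (and optionally list) total orders consistent with the groups.

    The count is Π over groups of (group size)!.  Enumerated orderings run
    groups root-most first, with each group's internal permutations in sorted
    lexicographic order for reproducibility.
    """
    count = prod(factorial(len(g)) for g in partial_order.groups)
    if not enumerate_orderings:
        return count
    per_group = [sorted(itertools.permutations(sorted(g)))
                 for g in partial_order.groups]
    orderings = [tuple(itertools.chain.from_iterable(combo))
                 for combo in itertools.product(*per_group)]
    assert len(orderings) == count
    return count, orderings


# ---------------------------------------------------------------------------
# trees and characters
# ---------------------------------------------------------------------------


@dataclass
class TimedTree:
    """A rooted tree with a designated focal tip and optional node ages (My).

    Ages, when given, map node labels (tips or internal) to ages and must be
    non-increasing along every root→tip walk of the focal path; they annotate
    reports only and play no role in the parsimony inference.
    """

    tree: dendropy.Tree
    focal_tip: str
    ages: Optional[Dict[str, float]] = None

    def __post_init__(self) -> None:
        if self.tree.seed_node is None:
            raise OrderingError("tree has no root")
        if self._find_tip(self.focal_tip) is None:
            raise OrderingError(f"focal tip {self.focal_tip!r} not in tree")
        if self.ages:
            path = self.focal_path_nodes()
            prev = None
            for node in path:
                lab = _node_label(node)
                if lab in self.ages:
                    age = self.ages[lab]
                    if prev is not None and age > prev + 1e-9:
                        raise OrderingError(
                            f"node ages increase toward the tips at {lab!r}"
                        )
                    prev = age

    @classmethod
    def from_newick(cls, newick: str, focal_tip: str,
                    ages: Optional[Dict[str, float]] = None) -> "TimedTree":
        tree = dendropy.Tree.get(data=newick, schema="newick",
                                 preserve_underscores=True)
        return cls(tree=tree, focal_tip=focal_tip, ages=ages)

    def _find_tip(self, label: str):
        for leaf in self.tree.leaf_node_iter():
            if _node_label(leaf) == label:
                return leaf
        return None

    def tip_labels(self) -> List[str]:
        return [_node_label(leaf) for leaf in self.tree.leaf_node_iter()]

    def focal_path_nodes(self) -> List[dendropy.Node]:
        """Nodes from the root down to the focal tip, inclusive."""
        tip = self._find_tip(self.focal_tip)
        path = []
        node = tip
        while node is not None:
            path.append(node)
            node = node.parent_node
        return list(reversed(path))


def _node_label(node: dendropy.Node) -> Optional[str]:
    if node.taxon is not None:
        return node.taxon.label
    return node.label


@dataclass
class CharacterMatrix:
    """Taxa × sites single-letter amino-acid states."""

    data: pd.DataFrame  # index: taxon labels; columns: site labels

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            raise OrderingError("duplicate taxa in character matrix")
        if self.data.columns.has_duplicates:
            raise OrderingError("duplicate site labels in character matrix")

    @classmethod
    def from_csv(cls, path) -> "CharacterMatrix":
        return cls(pd.read_csv(path, index_col=0, dtype=str))

    @property
    def sites(self) -> List[str]:
        return list(self.data.columns)

    def state(self, taxon: str, site: str) -> str:
        try:
            val = self.data.at[taxon, site]
        except KeyError:
            raise OrderingError(f"taxon {taxon!r} has no state at {site!r}")
        if not isinstance(val, str) or not val or val in ("?", "-"):
            raise OrderingError(f"taxon {taxon!r} unscored at site {site!r}")
        return val


# ---------------------------------------------------------------------------
# small parsimony
# ---------------------------------------------------------------------------


@dataclass
class FitchResult:
    """Per-node state sets from small parsimony at one site."""

    site: str
    score: int
    preliminary: Dict[int, FrozenSet[str]]   # keyed by id(node); bottom-up sets
    final: Dict[int, FrozenSet[str]]         # states in ≥1 MP reconstruction
    root_states: FrozenSet[str]


def _tip_states(tree: dendropy.Tree, characters: CharacterMatrix,
                site: str) -> Dict[int, str]:
    states: Dict[int, str] = {}
    for leaf in tree.leaf_node_iter():
        lab = _node_label(leaf)
        states[id(leaf)] = characters.state(lab, site)
    return states


def _sankoff_costs(tree: dendropy.Tree, states: Sequence[str],
                   tip_state: Mapping[int, str]):
    """Unit-cost Sankoff: subtree (down) and rest-of-tree (up) cost tables."""
    sidx = {s: i for i, s in enumerate(states)}
    ns = len(states)
    INF = 10 ** 9
    down: Dict[int, List[int]] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            vec = [INF] * ns
            vec[sidx[tip_state[id(node)]]] = 0
        else:
            vec = [0] * ns
            for child in node.child_nodes():
                cvec = down[id(child)]
                best = min(cvec)
                for i in range(ns):
                    vec[i] += min(cvec[i], best + 1)
        down[id(node)] = vec

    up: Dict[int, List[int]] = {id(tree.seed_node): [0] * ns}
    for node in tree.preorder_node_iter():
        uvec = up[id(node)]
        children = node.child_nodes()
        for child in children:
            # cost outside child's subtree, given child's state s:
            #   min over parent state t of up[node][t] + [s≠t]
            #   + siblings' min_r(down[sib][r] + [r≠t])
            cvec = [0] * ns
            for t in range(ns):
                total = uvec[t]
                for sib in children:
                    if sib is child:
                        continue
                    svec = down[id(sib)]
                    sbest = min(svec)
                    total += min(svec[t], sbest + 1)
                cvec[t] = total
            out = [INF] * ns
            for s in range(ns):
                out[s] = min(cvec[t] + (0 if s == t else 1) for t in range(ns))
            up[id(child)] = out
    return down, up, sidx


def fitch_parsimony(tree_or_timed, characters: CharacterMatrix,
                    site: str) -> FitchResult:
    """Small parsimony at one site: state sets and the minimum change count.

    ``preliminary`` holds the bottom-up (Fitch/Hartigan) sets; ``final`` holds,
    for every node, the states realised by at least one most-parsimonious
    reconstruction (the resolved sets of the top-down pass).
    """
    tree = tree_or_timed.tree if isinstance(tree_or_timed, TimedTree) else tree_or_timed
    tip_state = _tip_states(tree, characters, site)
    states = sorted(set(tip_state.values()))

    # bottom-up pass (Hartigan counts; = Fitch on bifurcating trees)
    preliminary: Dict[int, FrozenSet[str]] = {}
    score = 0
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            preliminary[id(node)] = frozenset({tip_state[id(node)]})
        else:
            counts: Dict[str, int] = {}
            children = node.child_nodes()
            for child in children:
                for s in preliminary[id(child)]:
                    counts[s] = counts.get(s, 0) + 1
            k = max(counts.values())
            preliminary[id(node)] = frozenset(s for s, c in counts.items() if c == k)
            score += len(children) - k

    # top-down resolution via exact conditional minima
    down, up, sidx = _sankoff_costs(tree, states, tip_state)
    root = tree.seed_node
    best = min(down[id(root)])
    assert best == score, "bottom-up score and Sankoff minimum disagree"
    final: Dict[int, FrozenSet[str]] = {}
    for node in tree.preorder_node_iter():
        tot = [down[id(node)][i] + up[id(node)][i] for i in range(len(states))]
        final[id(node)] = frozenset(s for s, i in sidx.items() if tot[i] == best)
    return FitchResult(site=site, score=score, preliminary=preliminary,
                       final=final, root_states=final[id(root)])


# ---------------------------------------------------------------------------
# substitution placement on the focal path
# ---------------------------------------------------------------------------


@dataclass
class SubstitutionPlacement:
    """Candidate focal-path branches per changed site.

    Branch i joins focal-path node i−1 to node i (node 0 = root).  Sites whose
    state does not change on the focal path are excluded, with a note.
    """

    path_labels: List[Optional[str]]            # labels of focal-path nodes
    branches: Dict[str, Tuple[int, ...]]        # site -> candidate branch indices
    notes: Dict[str, str]

    def is_ambiguous(self) -> bool:
        return any(len(b) > 1 for b in self.branches.values())


def place_substitutions(timed: TimedTree, characters: CharacterMatrix,
                        focal_sites: Optional[Sequence[str]] = None
                        ) -> SubstitutionPlacement:
    """Assign each changed site to the focal-path branch(es) where it occurred.

    A branch (u, v) on the root→focal-tip path is a candidate for a site iff
    some most-parsimonious reconstruction assigns u a non-derived state and v
    the focal tip's (derived) state — i.e. the substitution can lie on that
    branch without extra changes.  Ambiguous reconstructions yield
    multi-branch candidate sets rather than a silent ACCTRAN/DELTRAN choice.
    """
    tree = timed.tree
    sites = list(focal_sites) if focal_sites is not None else characters.sites
    path = timed.focal_path_nodes()
    branches: Dict[str, Tuple[int, ...]] = {}
    notes: Dict[str, str] = {}
    for site in sites:
        tip_state = _tip_states(tree, characters, site)
        states = sorted(set(tip_state.values()))
        derived = characters.state(timed.focal_tip, site)
        if len(states) == 1:
            notes[site] = "invariant site; no change on focal path"
            continue
        down, up, sidx = _sankoff_costs(tree, states, tip_state)
        score = min(down[id(tree.seed_node)])
        d = sidx[derived]
        cands: List[int] = []
        for i in range(1, len(path)):
            u, v = path[i - 1], path[i]
            others = [w for w in u.child_nodes() if w is not v]
            for t_state, t in sidx.items():
                if t_state == derived:
                    continue
                cost = up[id(u)][t] + 1 + down[id(v)][d]
                for w in others:
                    wvec = down[id(w)]
                    wbest = min(wvec)
                    cost += min(wvec[t], wbest + 1)
                if cost == score:
                    cands.append(i)
                    break
        if not cands:
            notes[site] = "no change on the root-to-focal-tip path"
            continue
        branches[site] = tuple(cands)
        if len(cands) > 1:
            notes[site] = (f"ambiguous placement: {len(cands)} candidate "
                           "branches under equally parsimonious reconstructions")
    return SubstitutionPlacement(
        path_labels=[_node_label(n) for n in path],
        branches=branches, notes=notes,
    )


def partial_orders(placement: SubstitutionPlacement) -> List[PartialOrder]:
    """All partial orders consistent with a placement (one if unambiguous)."""
    sites = sorted(placement.branches)
    choices = [placement.branches[s] for s in sites]
    orders: List[PartialOrder] = []
    seen: set[Tuple[FrozenSet[str], ...]] = set()
    for combo in itertools.product(*choices):
        groups: Dict[int, set] = {}
        for site, br in zip(sites, combo):
            groups.setdefault(br, set()).add(site)
        key = tuple(frozenset(groups[b]) for b in sorted(groups))
        if key not in seen:
            seen.add(key)
            orders.append(PartialOrder(key))
    return orders


def unique_partial_order(placement: SubstitutionPlacement) -> PartialOrder:
    """The single consistent partial order; error if placement is ambiguous."""
    orders = partial_orders(placement)
    if len(orders) != 1:
        raise OrderingError(
            f"placement is ambiguous ({len(orders)} partial orders); "
            "inspect SubstitutionPlacement.branches"
        )
    return orders[0]
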