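"""Exhaustive enumeration and classification of mutational trajectories.

A trajectory is an ordering in which the L mutations accumulate, visiting the
nested genotypes g_1 ⊂ g_2 ⊂ … ⊂ g_L.  A trajectory terminates at the first
intermediate that is not a functional pigment; it is accessible when every
intermediate and the endpoint are functional.  λ profiles use measured λ_max
only — imputed values are bookkeeping for the effect decomposition and never
enter a path's phenotype sequence; termination depends solely on the
functional flag.

Accessible counts are computed two ways: a subset dynamic programme over the
functional sub-lattice (O(2^L · L)), and — for verification and for the full
per-path listings — brute-force enumeration of all L! orderings.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from math import factorial
from typing import Dict, Iterable, Iterator, List, Optional, Sequence, Tuple

import numpy as np

from .landscape import (
    EffectTable,
    Landscape,
    LandscapeError,
    bit_count,
    decompose,
    reconstruct,
)
from .ordering import PartialOrder, linear_extensions

BRUTE_FORCE_LIMIT = 10

COMPLETE = "complete"
TERMINATED = "terminated"


class TrajectoryError(ValueError):
    pass


@dataclass(frozen=True)
class Trajectory:
    """One ordering of the mutations, possibly cut short."""

    order: Tuple[str, ...]
    status: str
    terminated_at: Optional[int] = None   # 1-based step of first nonfunctional

    @property
    def is_complete(self) -> bool:
        return self.status == COMPLETE


@dataclass(frozen=True)
class StepProfile:
    """λ_max sequence and per-step shifts over a trajectory's functional prefix."""

    lambdas: Tuple[float, ...]
    deltas: Tuple[float, ...]
    max_abs_delta: float
    variance: Optional[float]   # variance of deltas; None if < 2 steps

    @classmethod
    def from_lambdas(cls, lambdas: Sequence[float], ddof: int = 1) -> "StepProfile":
        lam = tuple(float(x) for x in lambdas)
        deltas = tuple(lam[i + 1] - lam[i] for i in range(len(lam) - 1))
        max_abs = max((abs(d) for d in deltas), default=0.0)
        if len(deltas) > ddof and len(deltas) >= 2:
            var = float(np.var(deltas, ddof=ddof))
        else:
            var = None
        return cls(lambdas=lam, deltas=deltas, max_abs_delta=max_abs, variance=var)


@dataclass
class TrajectorySummary:
    total: int
    accessible: int
    terminated: int
    fraction_accessible: float
    per_first_mutation: Dict[str, int]
    step_class_counts: Optional[Dict[str, int]] = None

    def __post_init__(self) -> None:
        assert self.accessible + self.terminated == self.total
        assert sum(self.per_first_mutation.values()) == self.accessible


# ---------------------------------------------------------------------------
# enumeration
# ---------------------------------------------------------------------------


def walk_ordering(landscape: Landscape, ordering: Sequence[str],
                  ddof: int = 1) -> Tuple[Trajectory, StepProfile]:
    """Follow one ordering, stopping at the first nonfunctional genotype."""
    sites = landscape.sites
    mask = 0
    lambdas: List[float] = [landscape.lambda_anc]
    terminated_at: Optional[int] = None
    for step, label in enumerate(ordering, start=1):
        mask |= 1 << sites.index(label)
        if not landscape.is_functional(mask):
            terminated_at = step
            break
        lambdas.append(landscape.records[mask].lambda_max)
    status = COMPLETE if terminated_at is None else TERMINATED
    traj = Trajectory(order=tuple(ordering), status=status,
                      terminated_at=terminated_at)
    return traj, StepProfile.from_lambdas(lambdas, ddof=ddof)


def enumerate_trajectories(landscape: Landscape, ddof: int = 1
                           ) -> Iterator[Tuple[Trajectory, StepProfile]]:
    """All L! orderings, in lexicographic order of the site labels."""
    sites = landscape.sites
    if sites.L > BRUTE_FORCE_LIMIT:
        raise TrajectoryError(
            f"L={sites.L}: {factorial(sites.L):,} orderings is beyond the "
            f"brute-force limit ({BRUTE_FORCE_LIMIT}); use count_accessible "
            "(subset DP) for counts"
        )
    for ordering in itertools.permutations(sites.labels):
        yield walk_ordering(landscape, ordering, ddof=ddof)


def _functional_array(landscape: Landscape) -> np.ndarray:
    n = landscape.sites.n_genotypes
    func = np.zeros(n, dtype=bool)
    func[0] = True
    for mask in range(1, n):
        func[mask] = landscape.is_functional(mask)
    return func


def count_accessible(landscape: Landscape,
                     threshold_nm: Optional[float] = 25.0,
                     strict: bool = True,
                     ddof: int = 1) -> TrajectorySummary:
    """Accessible/terminated counts by subset DP over the functional lattice.

    f(S) = number of ways to extend S to the full genotype through functional
    genotypes only; accessible = f(∅), and the per-first-mutation counts are
    the first-step terms of that sum.  ``threshold_nm`` additionally splits
    accessible paths by whether every |Δλ| stays below it (brute force, only
    for L within the enumeration limit; pass None to skip).
    """
    sites = landscape.sites
    L = sites.L
    n = sites.n_genotypes
    full = n - 1
    func = _functional_array(landscape)

    f = np.zeros(n, dtype=object)   # object: exact big-int path counts
    f[full] = 1
    for mask in sorted(range(n), key=bit_count, reverse=True):
        if mask == full:
            continue
        tot = 0
        for b in range(L):
            bit = 1 << b
            if not mask & bit and func[mask | bit]:
                tot += f[mask | bit]
        f[mask] = tot

    accessible = int(f[0])
    total = factorial(L)
    per_first = {
        label: int(f[1 << i]) if func[1 << i] else 0
        for i, label in enumerate(sites.labels)
    }

    step_counts = None
    if threshold_nm is not None and L <= BRUTE_FORCE_LIMIT:
        cls = classify_by_step(landscape, threshold_nm=threshold_nm,
                               strict=strict, ddof=ddof, keep_paths=False)
        step_counts = {"within": cls.n_within, "exceeding": cls.n_exceeding}

    return TrajectorySummary(
        total=total,
        accessible=accessible,
        terminated=total - accessible,
        fraction_accessible=accessible / total,
        per_first_mutation=per_first,
        step_class_counts=step_counts,
    )


def brute_force_accessible(landscape: Landscape) -> int:
    """Independent accessible count by scanning every permutation's prefixes."""
    sites = landscape.sites
    func = _functional_array(landscape)
    prefixes = _prefix_masks(sites.L)
    return int(func[prefixes].all(axis=1).sum())


_PREFIX_CACHE: Dict[int, np.ndarray] = {}


def _prefix_masks(L: int) -> np.ndarray:
    """(L!, L) array: cumulative genotype masks of every permutation."""
    if L not in _PREFIX_CACHE:
        if L > BRUTE_FORCE_LIMIT:
            raise TrajectoryError(f"L={L} beyond brute-force limit")
        perms = np.array(list(itertools.permutations(range(L))), dtype=np.int64)
        _PREFIX_CACHE[L] = np.bitwise_or.accumulate(1 << perms, axis=1)
    return _PREFIX_CACHE[L]


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------


@dataclass
class StepClassification:
    """Accessible paths split by the per-step |Δλ| criterion."""

    threshold_nm: float
    strict: bool
    n_within: int
    n_exceeding: int
    within: Optional[List[Tuple[Trajectory, StepProfile]]] = None
    exceeding: Optional[List[Tuple[Trajectory, StepProfile]]] = None


def classify_by_step(landscape: Landscape, threshold_nm: float = 25.0,
                     strict: bool = True, ddof: int = 1,
                     keep_paths: bool = True) -> StepClassification:
    """Partition accessible paths by max |Δλ| < threshold (or ≤ if not strict)."""
    if not threshold_nm > 0:
        raise TrajectoryError("threshold must be positive")
    within: List[Tuple[Trajectory, StepProfile]] = []
    exceeding: List[Tuple[Trajectory, StepProfile]] = []
    for traj, prof in enumerate_trajectories(landscape, ddof=ddof):
        if not traj.is_complete:
            continue
        ok = (prof.max_abs_delta < threshold_nm if strict
              else prof.max_abs_delta <= threshold_nm)
        (within if ok else exceeding).append((traj, prof))
    return StepClassification(
        threshold_nm=threshold_nm, strict=strict,
        n_within=len(within), n_exceeding=len(exceeding),
        within=within if keep_paths else None,
        exceeding=exceeding if keep_paths else None,
    )


@dataclass
class VarianceSplit:
    """Per-path Δλ variances split by presence of a large single step."""

    split_threshold_nm: float
    without_large_step: np.ndarray
    with_large_step: np.ndarray


def path_variance_distribution(landscape: Landscape,
                               split_threshold_nm: float = 30.0,
                               ddof: int = 1) -> VarianceSplit:
    """Variance of each accessible path's step shifts, split at Δλ > threshold.

    The split criterion is a signed, strict greater-than on any single step,
    mirroring a "contains a step larger than 30 nm" classification.
    """
    small: List[float] = []
    large: List[float] = []
    for traj, prof in enumerate_trajectories(landscape, ddof=ddof):
        if not traj.is_complete or prof.variance is None:
            continue
        has_large = any(d > split_threshold_nm for d in prof.deltas)
        (large if has_large else small).append(prof.variance)
    return VarianceSplit(
        split_threshold_nm=split_threshold_nm,
        without_large_step=np.asarray(small, dtype=float),
        with_large_step=np.asarray(large, dtype=float),
    )


# ---------------------------------------------------------------------------
# phylogeny-constrained paths
# ---------------------------------------------------------------------------


@dataclass
class ConstrainedPath:
    """A trajectory consistent with a branch-wise partial order."""

    trajectory: Trajectory
    profile: StepProfile
    epistasis_only: Tuple[float, ...]   # predicted λ using interaction terms only


def constrained_paths(landscape: Landscape, partial_order: PartialOrder,
                      effects: Optional[EffectTable] = None,
                      ddof: int = 1) -> List[ConstrainedPath]:
    """All complete orderings consistent with the partial order.

    Each path carries its observed λ profile and the epistasis-only predicted
    profile (reconstruction from interaction terms alone, i.e. dropping main
    effects), which shows how much of the phenotype change epistasis explains.
    """
    sites = landscape.sites
    if partial_order.labels != frozenset(sites.labels):
        missing = frozenset(sites.labels) - partial_order.labels
        extra = partial_order.labels - frozenset(sites.labels)
        raise TrajectoryError(
            f"partial order must cover exactly the site set "
            f"(missing {sorted(missing)}, extraneous {sorted(extra)})"
        )
    if effects is None:
        effects, _ = decompose(landscape)
    _, orderings = linear_extensions(partial_order, enumerate_orderings=True)
    out: List[ConstrainedPath] = []
    for ordering in orderings:
        traj, prof = walk_ordering(landscape, ordering, ddof=ddof)
        mask = 0
        epi = [reconstruct(effects, 0, min_order=2)]
        for label in ordering:
            mask |= 1 << sites.index(label)
            epi.append(reconstruct(effects, mask, min_order=2))
        out.append(ConstrainedPath(trajectory=traj, profile=prof,
                                   epistasis_only=tuple(epi)))
    return out
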