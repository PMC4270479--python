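"""Phenotype landscapes on the subset lattice and their factorial decomposition.

A landscape assigns a spectral phenotype (λ_max, in nm) to every combination of
L candidate mutations away from an ancestral pigment.  Writing λ(g) for the
phenotype of genotype g ⊆ {1..L}, the factorial model is

    λ(g) = λ_anc + Σ_{∅ ≠ T ⊆ g} θ_T

where θ_T for |T| = 1 are main (single-mutation) effects and θ_T for |T| ≥ 2
are epistatic interaction terms.  With all 2^L genotypes observed the system is
exactly determined: the incidence matrix C (C[g, T] = 1 iff T ⊆ g) is unit
lower-triangular once genotypes and subsets are sorted by size then bitmask, so
the θ are obtained by forward substitution — exact for integer-valued λ.

Genotypes that fail to form a functional pigment carry no λ_max.  Their effects
are imputed by the rule that a mutation which cannot form a pigment cannot
shift λ_max: the highest-order term for such a genotype is set to zero and its
λ_max is reconstructed from the lower-order terms already estimated
(processing genotypes in increasing order of size makes this cascade well
defined when nonfunctional genotypes nest).

Genotypes are represented as integer bitmasks over a :class:`SiteSet`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from math import isfinite
from typing import Dict, FrozenSet, Iterable, Iterator, List, Mapping, Optional, Tuple

import numpy as np
from scipy import linalg, stats

MAX_SITES = 20

MEASURED = "measured"
IMPUTED = "imputed"


class LandscapeError(ValueError):
    """Raised for structurally invalid landscapes or decomposition inputs."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SiteSet:
    """An ordered set of L uniquely labelled biallelic sites (mutations).

    Labels name the forward mutation in the ancestral frame, e.g. ``"F46T"``.
    Genotypes are bitmasks: bit i set ⇔ mutation ``labels[i]`` present.
    """

    labels: Tuple[str, ...]

    def __post_init__(self) -> None:
        labels = tuple(self.labels)
        object.__setattr__(self, "labels", labels)
        if not labels:
            raise LandscapeError("SiteSet needs at least one site label")
        if len(labels) > MAX_SITES:
            raise LandscapeError(
                f"L={len(labels)} sites would need a 2^{len(labels)} lattice; "
                f"limit is {MAX_SITES}"
            )
        if len(set(labels)) != len(labels):
            raise LandscapeError("site labels must be unique")
        if any(not lab for lab in labels):
            raise LandscapeError("site labels must be non-empty")

    @property
    def L(self) -> int:
        return len(self.labels)

    @property
    def n_genotypes(self) -> int:
        return 1 << self.L

    @property
    def full_mask(self) -> int:
        return (1 << self.L) - 1

    def index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise LandscapeError(f"unknown site label {label!r}") from None

    def mask_of(self, labels: Iterable[str]) -> int:
        mask = 0
        for lab in labels:
            bit = 1 << self.index(lab)
            if mask & bit:
                raise LandscapeError(f"duplicate label {lab!r} in genotype")
            mask |= bit
        return mask

    def labels_of(self, mask: int) -> Tuple[str, ...]:
        self.check_mask(mask)
        return tuple(lab for i, lab in enumerate(self.labels) if mask >> i & 1)

    def check_mask(self, mask: int) -> None:
        if not 0 <= mask < self.n_genotypes:
            raise LandscapeError(
                f"genotype mask {mask} outside the 2^{self.L} lattice"
            )

    def iter_masks(self, include_empty: bool = True) -> Iterator[int]:
        """All genotype masks sorted by subset size, then bitmask value."""
        for mask in lattice_order(self.L):
            if mask or include_empty:
                yield mask


def lattice_order(L: int) -> List[int]:
    """All masks of an L-site lattice sorted by (popcount, value)."""
    return sorted(range(1 << L), key=lambda m: (bit_count(m), m))


def bit_count(mask: int) -> int:
    return int(mask).bit_count()


def iter_submasks(mask: int, proper: bool = True, nonempty: bool = True) -> Iterator[int]:
    """Submasks of ``mask`` (descending); optionally excluding itself and ∅."""
    sub = mask
    while True:
        if not (proper and sub == mask) and not (nonempty and sub == 0):
            yield sub
        if sub == 0:
            break
        sub = (sub - 1) & mask


@dataclass(frozen=True)
class PhenotypeRecord:
    """One genotype's phenotype: λ_max in nm, or a nonfunctional flag."""

    mask: int
    lambda_max: Optional[float]
    functional: bool
    source: str = MEASURED

    def __post_init__(self) -> None:
        if self.source not in (MEASURED, IMPUTED):
            raise LandscapeError(f"bad record source {self.source!r}")
        if self.source == MEASURED:
            if self.functional != (self.lambda_max is not None):
                raise LandscapeError(
                    f"measured record {self.mask}: functional flag must match "
                    "presence of lambda_max"
                )
        else:  # imputed records always carry the reconstructed λ
            if self.lambda_max is None:
                raise LandscapeError("imputed record must carry a lambda_max")
        if self.lambda_max is not None and not isfinite(self.lambda_max):
            raise LandscapeError(f"non-finite lambda_max for genotype {self.mask}")

    @property
    def order(self) -> int:
        return bit_count(self.mask)


@dataclass
class Landscape:
    """λ_max over (a subset of) the 2^L genotype lattice of ``sites``."""

    sites: SiteSet
    lambda_anc: float
    records: Dict[int, PhenotypeRecord]

    def __post_init__(self) -> None:
        for mask in self.records:
            self.sites.check_mask(mask)
            if self.records[mask].mask != mask:
                raise LandscapeError(f"record keyed {mask} carries mask "
                                     f"{self.records[mask].mask}")
        anc = self.records.get(0)
        if anc is None:
            raise LandscapeError("missing ancestor (empty genotype) record")
        if not anc.functional:
            raise LandscapeError("nonfunctional ancestor: decomposition has no origin")
        if abs(anc.lambda_max - self.lambda_anc) > 1e-9:
            raise LandscapeError(
                f"ancestor record λ={anc.lambda_max} disagrees with "
                f"lambda_anc={self.lambda_anc}"
            )

    @property
    def complete(self) -> bool:
        return len(self.records) == self.sites.n_genotypes

    def missing_masks(self) -> List[int]:
        return [m for m in lattice_order(self.sites.L) if m not in self.records]

    def lambda_of(self, mask: int) -> Optional[float]:
        rec = self.records.get(mask)
        return None if rec is None else rec.lambda_max

    def is_functional(self, mask: int) -> bool:
        """Functional = a measured, pigment-forming genotype.

        Absent records and imputed records count as nonfunctional: an imputed
        λ is a bookkeeping value, not evidence of a folded pigment.
        """
        rec = self.records.get(mask)
        return rec is not None and rec.functional and rec.source == MEASURED

    def n_nonfunctional(self) -> int:
        return sum(1 for r in self.records.values()
                   if not (r.functional and r.source == MEASURED))


@dataclass
class EffectTable:
    """θ for every non-empty mutation subset; θ_∅ is the ancestral λ."""

    sites: SiteSet
    theta: Dict[int, float]
    theta_empty: float
    imputed: FrozenSet[int] = frozenset()
    se: Optional[Dict[int, float]] = None
    pvalue: Optional[Dict[int, float]] = None

    def theta_of(self, mask: int) -> float:
        if mask == 0:
            return self.theta_empty
        return self.theta[mask]

    def subsets(self) -> List[int]:
        return sorted(self.theta, key=lambda m: (bit_count(m), m))

    def stars(self, mask: int) -> str:
        if self.pvalue is None or mask not in self.pvalue:
            return ""
        p = self.pvalue[mask]
        return "**" if p < 0.01 else "*" if p < 0.05 else ""


@dataclass
class DesignSystem:
    """The C·X = Y system: genotype×subset incidence matrix and observations."""

    sites: SiteSet
    order: List[int]          # masks, sorted by (size, bitmask); rows and columns
    C: np.ndarray             # 0/1 incidence, unit lower-triangular
    Y: np.ndarray             # observed λ_max in row order
    V: np.ndarray             # observation variance-covariance (default identity)


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def build_design_system(landscape: Landscape,
                        V: Optional[np.ndarray] = None) -> DesignSystem:
    """Build the full 2^L × 2^L incidence system for a complete landscape.

    Rows are genotypes and columns are effect subsets, both sorted by subset
    size then bitmask, which makes C unit lower-triangular.  Requires every
    genotype to carry a λ (i.e. run after imputation).
    """
    sites = landscape.sites
    masks = lattice_order(sites.L)
    missing = [m for m in masks
               if m not in landscape.records
               or landscape.records[m].lambda_max is None]
    if missing:
        names = ", ".join("+".join(sites.labels_of(m)) or "ancestor"
                          for m in missing[:8])
        more = "" if len(missing) <= 8 else f" (+{len(missing) - 8} more)"
        raise LandscapeError(f"missing phenotypes for genotypes: {names}{more}")

    n = len(masks)
    row = np.asarray(masks)
    C = ((row[:, None] & row[None, :]) == row[None, :]).astype(float)
    Y = np.array([landscape.records[m].lambda_max for m in masks], dtype=float)
    if V is None:
        V = np.eye(n)
    else:
        V = np.asarray(V, dtype=float)
        if V.shape != (n, n):
            raise LandscapeError(f"V must be {n}x{n}")
    return DesignSystem(sites=sites, order=masks, C=C, Y=Y, V=V)


def decompose(landscape: Landscape) -> Tuple[EffectTable, Landscape]:
    """Solve for all θ by forward substitution, imputing nonfunctional λ.

    Genotypes are processed in increasing order of size.  A functional
    genotype g yields θ_g = λ(g) − λ_anc − Σ_{∅≠T⊊g} θ_T.  A nonfunctional
    genotype gets θ_g := 0 and its λ reconstructed from lower-order terms
    (recorded as an imputed phenotype); nested nonfunctional genotypes
    cascade, each using the already-imputed values below it.

    Returns the effect table and a completed landscape in which every
    nonfunctional genotype carries its imputed λ.
    """
    sites = landscape.sites
    missing = landscape.missing_masks()
    if missing:
        names = ", ".join("+".join(sites.labels_of(m)) or "ancestor"
                          for m in missing[:8])
        raise LandscapeError(
            f"landscape is incomplete; decompose needs every genotype listed "
            f"(missing: {names}{' …' if len(missing) > 8 else ''})"
        )

    theta: Dict[int, float] = {}
    imputed: set[int] = set()
    new_records: Dict[int, PhenotypeRecord] = {0: landscape.records[0]}
    lam: Dict[int, float] = {0: landscape.lambda_anc}

    for mask in lattice_order(sites.L):
        if mask == 0:
            continue
        rec = landscape.records[mask]
        sub_sum = sum(theta[t] for t in iter_submasks(mask))
        if rec.functional and rec.source == MEASURED:
            theta[mask] = rec.lambda_max - landscape.lambda_anc - sub_sum
            lam[mask] = rec.lambda_max
            new_records[mask] = rec
        else:
            theta[mask] = 0.0
            imputed.add(mask)
            lam[mask] = landscape.lambda_anc + sub_sum
            new_records[mask] = PhenotypeRecord(
                mask=mask, lambda_max=lam[mask], functional=False, source=IMPUTED
            )

    table = EffectTable(sites=sites, theta=theta,
                        theta_empty=landscape.lambda_anc,
                        imputed=frozenset(imputed))
    completed = Landscape(sites=sites, lambda_anc=landscape.lambda_anc,
                          records=new_records)
    return table, completed


def mobius_decompose(landscape: Landscape) -> EffectTable:
    """Möbius inversion over the subset lattice (independent of decompose).

    θ_S = Σ_{T ⊆ S} (−1)^{|S|−|T|} λ(T), with λ(∅) = λ_anc, computed by the
    in-place per-bit difference transform.  Requires every genotype to carry a
    λ (run after imputation).
    """
    sites = landscape.sites
    n = sites.n_genotypes
    vals = np.empty(n, dtype=float)
    for mask in range(n):
        lam = landscape.lambda_anc if mask == 0 else landscape.lambda_of(mask)
        if lam is None:
            raise LandscapeError(
                "mobius_decompose needs a λ for every genotype "
                f"({'+'.join(sites.labels_of(mask))} has none); impute first"
            )
        vals[mask] = lam
    idx = np.arange(n)
    for b in range(sites.L):
        bit = 1 << b
        hi = (idx & bit) > 0
        vals[hi] -= vals[idx[hi] ^ bit]
    theta = {mask: float(vals[mask]) for mask in range(1, n)}
    return EffectTable(sites=sites, theta=theta, theta_empty=float(vals[0]))


def reconstruct(effects: EffectTable, genotype: int | Iterable[str],
                min_order: int = 1) -> float:
    """λ_anc + Σ_{T ⊆ g, |T| ≥ min_order} θ_T.

    ``min_order=2`` gives the epistasis-only prediction (interaction terms
    alone, main effects dropped).
    """
    sites = effects.sites
    mask = genotype if isinstance(genotype, int) else sites.mask_of(genotype)
    sites.check_mask(mask)
    total = effects.theta_empty
    for t in iter_submasks(mask, proper=False):
        if bit_count(t) >= min_order:
            total += effects.theta[t]
    return total


def standard_errors(system: DesignSystem) -> Dict[int, float]:
    """SEs from the diagonal of C⁻¹ V (C⁻¹)ᵀ.

    With V = I (unit λ_max variance, zero covariance) the inverse has signed
    Möbius coefficients ±1, so SE_S = 2^{|S|/2}.
    """
    C = system.C
    n = C.shape[0]
    if not np.allclose(np.tril(C), C) or not np.allclose(np.diag(C), 1.0):
        # cannot occur for the full lattice under (size, bitmask) ordering
        if abs(np.linalg.det(C)) < 1e-12:
            raise LandscapeError("singular design matrix")
        Cinv = np.linalg.inv(C)
    else:
        Cinv = linalg.solve_triangular(C, np.eye(n), lower=True,
                                       unit_diagonal=True)
    S = Cinv @ system.V @ Cinv.T
    diag = np.diag(S)
    if np.any(diag < -1e-9):
        raise LandscapeError("V is not positive semidefinite")
    se = np.sqrt(np.clip(diag, 0.0, None))
    return {mask: float(se[i]) for i, mask in enumerate(system.order)}


def significance(effects: EffectTable,
                 bh_adjust: bool = False) -> Tuple[Dict[int, float], Dict[int, str]]:
    """Two-sided normal z-test per θ; stars at P<0.05 (*) and P<0.01 (**).

    Requires ``effects.se`` to be populated.  ``bh_adjust`` applies a
    Benjamini–Hochberg correction across all terms (off by default; the
    per-term assessment is the primary report).
    """
    if effects.se is None:
        raise LandscapeError("compute standard errors before significance")
    pvals: Dict[int, float] = {}
    for mask in effects.subsets():
        th = effects.theta[mask]
        se = effects.se[mask]
        if se == 0.0:
            if th == 0.0:
                pvals[mask] = 1.0
            else:
                warnings.warn(
                    f"zero SE with nonzero θ for "
                    f"{'+'.join(effects.sites.labels_of(mask))}; p set to 0",
                    RuntimeWarning,
                )
                pvals[mask] = 0.0
        else:
            z = th / se
            pvals[mask] = float(2.0 * stats.norm.sf(abs(z)))
    if bh_adjust:
        pvals = _benjamini_hochberg(pvals)
    effects.pvalue = pvals
    stars = {m: ("**" if p < 0.01 else "*" if p < 0.05 else "")
             for m, p in pvals.items()}
    return pvals, stars


def _benjamini_hochberg(pvals: Mapping[int, float]) -> Dict[int, float]:
    items = sorted(pvals.items(), key=lambda kv: kv[1])
    m = len(items)
    adj: Dict[int, float] = {}
    running = 1.0
    for rank in range(m, 0, -1):
        mask, p = items[rank - 1]
        running = min(running, p * m / rank)
        adj[mask] = running
    return adj


def attach_uncertainty(effects: EffectTable, landscape: Landscape,
                       V: Optional[np.ndarray] = None,
                       bh_adjust: bool = False) -> EffectTable:
    """Convenience: fill ``se`` and ``pvalue`` on an effect table in place."""
    system = build_design_system(landscape, V=V)
    effects.se = standard_errors(system)
    effects.se.pop(0, None)
    significance(effects, bh_adjust=bh_adjust)
    return effects


def decompose_stable_only(landscape: Landscape) -> EffectTable:
    """Decompose using only functional (structurally stable) genotypes.

    Runs the same size-ordered recursion but over measured functional
    genotypes alone; θ terms whose subset is nonfunctional are skipped (they
    contribute 0, exactly as the imputation forces them to in the full
    analysis).  Returns θ only for the estimable subsets; every returned value
    equals the full imputed decomposition's.  Tolerates absent nonfunctional
    rows, so it also serves partial (stable-only) data files.
    """
    sites = landscape.sites
    theta: Dict[int, float] = {}
    for mask in lattice_order(sites.L):
        if mask == 0:
            continue
        if not landscape.is_functional(mask):
            continue
        lam = landscape.records[mask].lambda_max
        sub_sum = sum(theta.get(t, 0.0) for t in iter_submasks(mask))
        theta[mask] = lam - landscape.lambda_anc - sub_sum
    return EffectTable(sites=sites, theta=theta,
                       theta_empty=landscape.lambda_anc)
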