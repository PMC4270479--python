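"""Synthetic genotype–phenotype landscapes, trees and character matrices.

The generator emulates the statistical structure of a combinatorial
mutagenesis study of spectral tuning: an ultraviolet ancestor near 357 nm,
near-zero single-mutation effects, sparse but large (|θ| ≥ 5 nm) epistatic
interactions, a configurable set of nonfunctional genotypes whose λ_max is
withheld, and additive unit-variance measurement noise.  Two fixed fixtures
accompany it: the three-locus landscape of the middle-wavelength pigment
(fully determined by its published effect terms) and a seven-site instance —
synthetic, not measured data — shaped like the short-wavelength pigment study
end to end (lethal-if-early site, blue 411-nm endpoint, a 15-taxon mammal
tree and character matrix yielding a four-branch substitution order).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .landscape import (
    IMPUTED,
    Landscape,
    LandscapeError,
    MEASURED,
    PhenotypeRecord,
    SiteSet,
    bit_count,
    iter_submasks,
    lattice_order,
)
from .ordering import CharacterMatrix, PartialOrder, TimedTree


@dataclass
class LandscapeSpec:
    """Parameters of the synthetic landscape generator.

    Defaults are the study conditions being emulated: seven sites, a 357-nm
    ancestor, main effects ~ N(0, 2) nm, interactions nonzero with probability
    0.28 and magnitude ~ N(0, 10) nm (≈17% of interaction terms end up with
    |θ| ≥ 5 nm), 60/127 of mutant genotypes nonfunctional, and unit-SD
    Gaussian measurement noise (the V = I assumption of the error model).
    """

    L: int = 7
    lambda_anc: float = 357.0
    main_mean: float = 0.0
    main_sd: float = 2.0
    interaction_sparsity: Union[float, Mapping[int, float]] = 0.28
    interaction_sd: float = 10.0
    nonfunctional: Union[None, float, Sequence[Iterable[str]]] = 60 / 127
    noise_sd: float = 1.0
    fix_anchor: bool = False          # measure the ancestor without noise
    round_lambda: Optional[float] = None   # e.g. 1.0 to emit integer λ
    labels: Optional[Tuple[str, ...]] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise SD must be >= 0")
        if isinstance(self.nonfunctional, float) and not 0 <= self.nonfunctional < 1:
            raise ValueError("nonfunctional fraction must be in [0, 1)")
        if self.seed is None:
            raise ValueError("a seed is mandatory for reproducibility")

    def sparsity_for(self, order: int) -> float:
        if isinstance(self.interaction_sparsity, Mapping):
            s = float(self.interaction_sparsity.get(order, 0.0))
        else:
            s = float(self.interaction_sparsity)
        if not 0 <= s <= 1:
            raise ValueError(f"sparsity for order {order} outside [0, 1]")
        return s

    def site_labels(self) -> Tuple[str, ...]:
        if self.labels is not None:
            if len(self.labels) != self.L:
                raise ValueError("labels length must equal L")
            return tuple(self.labels)
        return tuple(f"m{i + 1}" for i in range(self.L))


@dataclass
class GroundTruth:
    """The θ table and nonfunctional set a landscape was generated from."""

    sites: SiteSet
    lambda_anc: float
    theta: Dict[int, float]
    nonfunctional: FrozenSet[int]
    noise_sd: float


def generate_landscape(spec: LandscapeSpec) -> Tuple[Landscape, GroundTruth]:
    """Draw a landscape from the spec; deterministic under ``spec.seed``.

    Draw order (stable contract): θ terms in (size, bitmask) order — each
    single is one normal draw; each interaction is one uniform (inclusion)
    plus one normal (magnitude, drawn regardless of inclusion so sparsity does
    not shift the stream); then one noise draw per genotype in mask order
    (ancestor first); then one uniform per mutant genotype for the
    nonfunctional rule when it is a random fraction.
    """
    rng = np.random.default_rng(spec.seed)
    sites = SiteSet(spec.site_labels())
    n = sites.n_genotypes

    theta: Dict[int, float] = {}
    for mask in lattice_order(spec.L):
        if mask == 0:
            continue
        order = bit_count(mask)
        if order == 1:
            theta[mask] = float(rng.normal(spec.main_mean, spec.main_sd))
        else:
            keep = rng.random() < spec.sparsity_for(order)
            mag = float(rng.normal(0.0, spec.interaction_sd))
            theta[mask] = mag if keep else 0.0

    noise = rng.normal(0.0, spec.noise_sd, size=n) if spec.noise_sd > 0 \
        else np.zeros(n)
    if spec.fix_anchor:
        noise[0] = 0.0

    nonfunc: set[int] = set()
    if isinstance(spec.nonfunctional, float):
        if spec.nonfunctional > 0:
            draws = rng.random(n - 1)
            nonfunc = {m for m in range(1, n) if draws[m - 1] < spec.nonfunctional}
        # a random fraction can never mark the ancestor
    elif spec.nonfunctional is not None:
        for pattern in spec.nonfunctional:
            pmask = sites.mask_of(pattern)
            if pmask == 0:
                raise LandscapeError("nonfunctional rule would mark the ancestor")
            for m in range(1, n):
                if m & pmask == pmask:
                    nonfunc.add(m)

    lambda_anc = spec.lambda_anc + float(noise[0])
    records: Dict[int, PhenotypeRecord] = {}
    truth_theta = dict(theta)
    for mask in range(n):
        if mask in nonfunc:
            records[mask] = PhenotypeRecord(mask=mask, lambda_max=None,
                                            functional=False)
            continue
        base = spec.lambda_anc + sum(theta[t] for t in iter_submasks(mask, proper=False))
        lam = base + float(noise[mask]) if mask else lambda_anc
        if spec.round_lambda:
            lam = round(lam / spec.round_lambda) * spec.round_lambda
            if mask == 0:
                lambda_anc = lam
        records[mask] = PhenotypeRecord(mask=mask, lambda_max=lam, functional=True)

    landscape = Landscape(sites=sites, lambda_anc=lambda_anc, records=records)
    truth = GroundTruth(sites=sites, lambda_anc=spec.lambda_anc,
                        theta=truth_theta, nonfunctional=frozenset(nonfunc),
                        noise_sd=spec.noise_sd)
    return landscape, truth


# ---------------------------------------------------------------------------
# fixed fixtures
# ---------------------------------------------------------------------------

HUMAN_M_SITES = ("S180A", "Y277F", "T285A")

# Effect terms of the middle-wavelength pigment's three spectral-tuning
# mutations away from the 560-nm ancestral long-wavelength pigment.
HUMAN_M_THETA = {
    ("S180A",): -5.0,
    ("Y277F",): -10.0,
    ("T285A",): -17.0,
    ("S180A", "Y277F"): 0.0,
    ("S180A", "T285A"): -2.0,
    ("Y277F", "T285A"): 1.0,
    ("S180A", "Y277F", "T285A"): 4.0,
}


def human_m_fixture() -> Landscape:
    """The 3-locus, 8-genotype landscape implied by the published θ table.

    λ_anc = 560 nm; singles 555, 550, 543 nm; doubles 545, 536, 534 nm;
    triple 531 nm (= 560 − 29).  All genotypes functional.
    """
    sites = SiteSet(HUMAN_M_SITES)
    theta = {sites.mask_of(k): v for k, v in HUMAN_M_THETA.items()}
    records: Dict[int, PhenotypeRecord] = {}
    for mask in range(sites.n_genotypes):
        lam = 560.0 + sum(theta[t] for t in iter_submasks(mask, proper=False))
        records[mask] = PhenotypeRecord(mask=mask, lambda_max=lam, functional=True)
    return Landscape(sites=sites, lambda_anc=560.0, records=records)


S1_SITES = ("F46T", "F49L", "T52F", "F86L", "T93P", "A114G", "S118T")

# Hand-set ground truth of the synthetic seven-site instance.  Mains mirror
# the published single effects (−2, −3, 0, 0, 2, 1, 1 nm); six interaction
# terms carry the 55 nm that take the full mutant from 357 to 411 nm.
_S1_THETA = {
    ("F46T",): -2.0,
    ("F49L",): -3.0,
    ("T52F",): 0.0,
    ("F86L",): 0.0,
    ("T93P",): 2.0,
    ("A114G",): 1.0,
    ("S118T",): 1.0,
    ("F86L", "T93P"): 15.0,
    ("F86L", "T93P", "A114G"): 2.0,
    ("F49L", "F86L"): 10.0,
    ("F86L", "S118T"): 12.0,
    ("F46T", "F86L"): 5.0,
    ("F46T", "T52F"): 11.0,
}

# Synthetic lethality rule: T52F dehydrates the pigment unless at least four
# companion mutations have restored the water network — so any genotype
# carrying T52F with total order ≤ 4 is nonfunctional (a trajectory starting
# with T52F terminates immediately).
_S1_LETHAL_SITE = "T52F"
_S1_LETHAL_MAX_ORDER = 4

S1_PARTIAL_ORDER = PartialOrder.from_lists(
    [("T93P", "A114G"), ("F86L",), ("F49L", "S118T"), ("F46T", "T52F")]
)

# 15-taxon mammal tree (ultrametric, branch lengths in My).  SYNTHETIC: the
# topology and dates follow standard mammalian relationships, but it is a
# constructed stand-in, not a published alignment-derived tree.
S1_NEWICK = (
    "((((((((((human:6,chimpanzee:6):2,gorilla:8):7,orangutan:15):5,"
    "gibbon:20):10,macaque:30):15,(squirrel_monkey:35,marmoset:35):10):30,"
    "tarsier:75):5,aye_aye:80):10,((mouse:30,rat:30):45,squirrel:75):15):8,"
    "(bovine:95,elephant:95):3);"
)

# ancestral / derived states per site (ancestral frame: F46 F49 T52 F86 T93
# A114 S118; focal tip carries the derived state of every site)
_S1_ANC = {"F46T": "F", "F49L": "F", "T52F": "T", "F86L": "F",
           "T93P": "T", "A114G": "A", "S118T": "S"}
_S1_DER = {"F46T": "T", "F49L": "L", "T52F": "F", "F86L": "L",
           "T93P": "P", "A114G": "G", "S118T": "T"}

# which taxa carry the derived state, per substitution group (derived states
# are shared by everything inside the focal clade below the branch they map to)
_S1_DERIVED_TAXA = {
    "T93P": {"human", "chimpanzee", "gorilla", "orangutan", "gibbon",
             "macaque", "squirrel_monkey", "marmoset", "tarsier"},
    "A114G": {"human", "chimpanzee", "gorilla", "orangutan", "gibbon",
              "macaque", "squirrel_monkey", "marmoset", "tarsier"},
    "F86L": {"human", "chimpanzee", "gorilla", "orangutan", "gibbon",
             "macaque", "squirrel_monkey", "marmoset"},
    "F49L": {"human", "chimpanzee", "gorilla", "orangutan", "gibbon",
             "macaque"},
    "S118T": {"human", "chimpanzee", "gorilla", "orangutan", "gibbon",
              "macaque"},
    "F46T": {"human", "chimpanzee", "gorilla", "orangutan", "gibbon"},
    "T52F": {"human", "chimpanzee", "gorilla", "orangutan", "gibbon"},
}

S1_TAXA = ("human", "chimpanzee", "gorilla", "orangutan", "gibbon", "macaque",
           "squirrel_monkey", "marmoset", "tarsier", "aye_aye", "mouse",
           "rat", "squirrel", "bovine", "elephant")


def s1_like_fixture() -> Tuple[Landscape, PartialOrder, TimedTree, CharacterMatrix]:
    """A fixed seven-site instance exercising the whole pipeline.

    SYNTHETIC DATA: λ values are computed from a hand-set effect table (not
    measurements), chosen so the instance behaves like the short-wavelength
    pigment study — 357-nm ancestor, 411-nm full mutant, a site that is lethal
    unless it arrives late, and a tree/character matrix whose parsimony
    placement gives the four-branch partial order with 8 linear extensions.
    """
    sites = SiteSet(S1_SITES)
    theta = {sites.mask_of(k): v for k, v in _S1_THETA.items()}
    lethal_bit = 1 << sites.index(_S1_LETHAL_SITE)
    records: Dict[int, PhenotypeRecord] = {}
    for mask in range(sites.n_genotypes):
        if mask & lethal_bit and bit_count(mask) <= _S1_LETHAL_MAX_ORDER:
            records[mask] = PhenotypeRecord(mask=mask, lambda_max=None,
                                            functional=False)
            continue
        lam = 357.0 + sum(theta.get(t, 0.0)
                          for t in iter_submasks(mask, proper=False, nonempty=True))
        records[mask] = PhenotypeRecord(mask=mask, lambda_max=lam, functional=True)
    landscape = Landscape(sites=sites, lambda_anc=357.0, records=records)

    rows = {}
    for taxon in S1_TAXA:
        rows[taxon] = {
            site: (_S1_DER[site] if taxon in _S1_DERIVED_TAXA[site]
                   else _S1_ANC[site])
            for site in S1_SITES
        }
    matrix = CharacterMatrix(pd.DataFrame.from_dict(rows, orient="index",
                                                    columns=list(S1_SITES)))
    tree = TimedTree.from_newick(S1_NEWICK, focal_tip="human")
    return landscape, S1_PARTIAL_ORDER, tree, matrix


def s1_ground_truth_theta() -> Dict[Tuple[str, ...], float]:
    """The hand-set θ table behind :func:`s1_like_fixture` (synthetic)."""
    return dict(_S1_THETA)
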