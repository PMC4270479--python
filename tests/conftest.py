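import numpy as np
import pytest

from spectune import (
    Landscape,
    PhenotypeRecord,
    SiteSet,
    human_m_fixture,
    s1_like_fixture,
)


@pytest.fixture
def human_m() -> Landscape:
    return human_m_fixture()


@pytest.fixture(scope="session")
def s1_like():
    return s1_like_fixture()


def make_landscape(labels, lambda_anc, lam_by_labels, nonfunctional=()):
    """Build a complete landscape from {label-tuple: λ}; missing → NF."""
    sites = SiteSet(tuple(labels))
    nf_masks = {sites.mask_of(g) for g in nonfunctional}
    records = {}
    lam_by_mask = {sites.mask_of(g): v for g, v in lam_by_labels.items()}
    for mask in range(sites.n_genotypes):
        if mask in nf_masks:
            records[mask] = PhenotypeRecord(mask=mask, lambda_max=None,
                                            functional=False)
        else:
            lam = lambda_anc if mask == 0 else lam_by_mask[mask]
            records[mask] = PhenotypeRecord(mask=mask, lambda_max=lam,
                                            functional=True)
    return Landscape(sites=sites, lambda_anc=lambda_anc, records=records)


def random_functional_landscape(rng: np.random.Generator, L: int,
                                lambda_anc: float = 357.0) -> Landscape:
    """A complete, fully functional landscape with integer-ish random λ."""
    sites = SiteSet(tuple(f"s{i}" for i in range(L)))
    records = {0: PhenotypeRecord(mask=0, lambda_max=lambda_anc, functional=True)}
    for mask in range(1, sites.n_genotypes):
        lam = lambda_anc + float(rng.integers(-30, 31))
        records[mask] = PhenotypeRecord(mask=mask, lambda_max=lam, functional=True)
    return Landscape(sites=sites, lambda_anc=lambda_anc, records=records)


def random_lethality_landscape(rng: np.random.Generator, L: int,
                               p_nonfunctional: float = 0.4) -> Landscape:
    """Random complete landscape with a random nonfunctional pattern."""
    sites = SiteSet(tuple(f"s{i}" for i in range(L)))
    records = {0: PhenotypeRecord(mask=0, lambda_max=357.0, functional=True)}
    for mask in range(1, sites.n_genotypes):
        if rng.random() < p_nonfunctional:
            records[mask] = PhenotypeRecord(mask=mask, lambda_max=None,
                                            functional=False)
        else:
            lam = 357.0 + float(rng.integers(-30, 31))
            records[mask] = PhenotypeRecord(mask=mask, lambda_max=lam,
                                            functional=True)
    return Landscape(sites=sites, lambda_anc=357.0, records=records)
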