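"""Unit and property tests for the factorial effect decomposition."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from spectune import (
    LandscapeError,
    PhenotypeRecord,
    SiteSet,
    attach_uncertainty,
    build_design_system,
    decompose,
    decompose_stable_only,
    mobius_decompose,
    reconstruct,
    significance,
    standard_errors,
)
from spectune.landscape import IMPUTED, bit_count, lattice_order

from conftest import make_landscape, random_functional_landscape, \
    random_lethality_landscape


# ---------------------------------------------------------------------------
# design system
# ---------------------------------------------------------------------------


def test_design_matrix_small_lattices():
    """C is the subset-incidence matrix: ∅ is in every genotype; the row of a
    genotype has ones exactly at its subsets."""
    one = make_landscape(["a"], 100.0, {("a",): 105.0})
    sys1 = build_design_system(one)
    assert sys1.C.tolist() == [[1, 0], [1, 1]]

    two = make_landscape(["a", "b"], 100.0,
                         {("a",): 101.0, ("b",): 102.0, ("a", "b"): 104.0})
    sys2 = build_design_system(two)
    ab_row = sys2.order.index(3)
    assert sys2.C[ab_row].tolist() == [1, 1, 1, 1]
    a_row = sys2.order.index(1)
    assert sys2.C[a_row].tolist() == [1, 1, 0, 0]


@pytest.mark.parametrize("L", [3, 5, 7])
def test_design_matrix_unit_lower_triangular(L):
    """Under size-then-bitmask ordering C is unit lower-triangular, so the
    seven-site instance is a 128x128 forward-substitution solve."""
    rng = np.random.default_rng(0)
    land = random_functional_landscape(rng, L)
    system = build_design_system(land)
    n = 2 ** L
    assert system.C.shape == (n, n)
    assert np.allclose(np.triu(system.C, 1), 0.0)
    assert np.allclose(np.diag(system.C), 1.0)


def test_design_system_rejects_missing_lambda():
    land = make_landscape(["a", "b"], 100.0,
                          {("a",): 101.0, ("b",): 102.0},
                          nonfunctional=[("a", "b")])
    with pytest.raises(LandscapeError, match="missing phenotypes.*a\\+b"):
        build_design_system(land)


# ---------------------------------------------------------------------------
# decomposition and imputation
# ---------------------------------------------------------------------------


def test_decompose_recovers_human_m_effect_table(human_m):
    """The 3-locus fixture decomposes to its defining θ values exactly."""
    eff, _ = decompose(human_m)
    s = human_m.sites
    assert eff.theta[s.mask_of(["S180A"])] == -5.0
    assert eff.theta[s.mask_of(["Y277F"])] == -10.0
    assert eff.theta[s.mask_of(["T285A"])] == -17.0
    assert eff.theta[s.mask_of(["S180A", "Y277F"])] == 0.0
    assert eff.theta[s.mask_of(["S180A", "T285A"])] == -2.0
    assert eff.theta[s.mask_of(["Y277F", "T285A"])] == 1.0
    assert eff.theta[s.full_mask] == 4.0
    assert eff.imputed == frozenset()


def test_nonfunctional_single_imputes_zero_shift():
    """A nonfunctional single mutant cannot shift λ: θ := 0 and its imputed
    λ equals the ancestral value."""
    land = make_landscape(
        ["T52F", "T93P"], 357.0,
        {("T93P",): 359.0, ("T52F", "T93P"): 360.0},
        nonfunctional=[("T52F",)],
    )
    eff, completed = decompose(land)
    m52 = land.sites.mask_of(["T52F"])
    assert eff.theta[m52] == 0.0
    assert m52 in eff.imputed
    rec = completed.records[m52]
    assert rec.source == IMPUTED and rec.lambda_max == 357.0
    # the double now absorbs the residual as pure interaction
    assert eff.theta[land.sites.full_mask] == 360.0 - 357.0 - 2.0 - 0.0


def test_nonfunctional_double_imputed_from_singles():
    """θ_46=−2 and θ_114=1 with a nonfunctional double ⇒ θ_46×114 = 0 and an
    imputed λ of 357 − 2 + 1 = 356 nm."""
    land = make_landscape(
        ["F46T", "A114G"], 357.0,
        {("F46T",): 355.0, ("A114G",): 358.0},
        nonfunctional=[("F46T", "A114G")],
    )
    eff, completed = decompose(land)
    full = land.sites.full_mask
    assert eff.theta[full] == 0.0
    assert completed.records[full].lambda_max == 356.0
    assert completed.records[full].source == IMPUTED


def test_imputation_cascades_through_nested_nonfunctional():
    """A nonfunctional genotype above another nonfunctional one uses the
    already-imputed values below it."""
    land = make_landscape(
        ["a", "b", "c"], 100.0,
        {("a",): 102.0, ("b",): 103.0, ("c",): 101.0,
         ("a", "c"): 103.0, ("b", "c"): 104.0},
        nonfunctional=[("a", "b"), ("a", "b", "c")],
    )
    eff, completed = decompose(land)
    s = land.sites
    mab = s.mask_of(["a", "b"])
    # λ(ab) = 100 + 2 + 3 = 105; triple sums every θ below it
    assert completed.records[mab].lambda_max == 105.0
    assert eff.theta[s.full_mask] == 0.0
    lam_abc = completed.records[s.full_mask].lambda_max
    assert lam_abc == 100.0 + sum(
        eff.theta[t] for t in range(1, 8) if t != s.full_mask)


def test_decompose_rejects_incomplete_and_bad_ancestor():
    sites = SiteSet(("a", "b"))
    records = {
        0: PhenotypeRecord(mask=0, lambda_max=100.0, functional=True),
        1: PhenotypeRecord(mask=1, lambda_max=101.0, functional=True),
    }
    partial = {"sites": sites, "lambda_anc": 100.0, "records": records}
    from spectune import Landscape
    with pytest.raises(LandscapeError, match="incomplete"):
        decompose(Landscape(**partial))
    with pytest.raises(LandscapeError, match="ancestor"):
        Landscape(sites=sites, lambda_anc=100.0, records={
            0: PhenotypeRecord(mask=0, lambda_max=None, functional=False)})


# ---------------------------------------------------------------------------
# reconstruction
# ---------------------------------------------------------------------------


def test_reconstruct_examples(human_m):
    eff, _ = decompose(human_m)
    s = human_m.sites
    assert reconstruct(eff, s.mask_of(["S180A", "Y277F"])) == 545.0
    assert reconstruct(eff, s.full_mask) == 531.0          # 560 − 29
    assert reconstruct(eff, 0) == 560.0
    assert reconstruct(eff, 0, min_order=2) == 560.0       # empty sum either way


def test_reconstruct_min_order_drops_main_effects(human_m):
    """min_order=2 keeps interaction terms only (epistasis-only prediction)."""
    eff, _ = decompose(human_m)
    s = human_m.sites
    full = s.full_mask
    epi = reconstruct(eff, full, min_order=2)
    mains = sum(eff.theta[1 << i] for i in range(s.L))
    assert epi == pytest.approx(531.0 - mains)
    with pytest.raises(LandscapeError):
        reconstruct(eff, 1 << s.L)


def test_roundtrip_reconstruction_is_exact():
    """For every genotype, measured or imputed, reconstruction from the effect
    table reproduces its λ to machine precision."""
    rng = np.random.default_rng(7)
    for _ in range(20):
        land = random_lethality_landscape(rng, L=int(rng.integers(2, 6)))
        eff, completed = decompose(land)
        for mask, rec in completed.records.items():
            assert reconstruct(eff, mask) == pytest.approx(rec.lambda_max,
                                                           abs=1e-9)


# ---------------------------------------------------------------------------
# Möbius oracle
# ---------------------------------------------------------------------------


def test_mobius_trivial_cases():
    one = make_landscape(["a"], 100.0, {("a",): 107.0})
    eff = mobius_decompose(one)
    assert eff.theta[1] == 7.0
    flat = make_landscape(["a", "b"], 50.0,
                          {("a",): 50.0, ("b",): 50.0, ("a", "b"): 50.0})
    eff = mobius_decompose(flat)
    assert all(v == 0.0 for v in eff.theta.values())


@settings(max_examples=60, deadline=None, derandomize=True)
@given(L=st.integers(2, 6), seed=st.integers(0, 2 ** 31 - 1))
def test_mobius_equals_linear_decomposition(L, seed):
    """Subset-lattice Möbius inversion and the triangular-system recursion are
    the same linear map; they must agree exactly on random landscapes."""
    rng = np.random.default_rng(seed)
    land = random_functional_landscape(rng, L)
    eff, _ = decompose(land)
    orc = mobius_decompose(land)
    for mask in eff.theta:
        assert orc.theta[mask] == pytest.approx(eff.theta[mask], abs=1e-8)


def test_mobius_requires_all_lambda():
    land = make_landscape(["a", "b"], 100.0,
                          {("a",): 101.0, ("b",): 102.0},
                          nonfunctional=[("a", "b")])
    with pytest.raises(LandscapeError, match="impute"):
        mobius_decompose(land)


# ---------------------------------------------------------------------------
# standard errors and significance
# ---------------------------------------------------------------------------


@pytest.mark.parametrize("L", [1, 2, 4, 6])
def test_standard_errors_closed_form(L):
    """With V = I the SE of θ_S is 2^{|S|/2} (2^{|S|} signed unit Möbius
    coefficients over unit-variance observations)."""
    rng = np.random.default_rng(1)
    land = random_functional_landscape(rng, L)
    system = build_design_system(land)
    se = standard_errors(system)
    for mask in lattice_order(L):
        assert se[mask] == pytest.approx(2 ** (bit_count(mask) / 2), rel=1e-12)


def test_standard_errors_zero_variance():
    land = make_landscape(["a", "b"], 100.0,
                          {("a",): 101.0, ("b",): 102.0, ("a", "b"): 104.0})
    system = build_design_system(land, V=np.zeros((4, 4)))
    assert all(v == 0.0 for v in standard_errors(system).values())


def test_significance_star_flags(human_m):
    """A 17-nm single effect under SE √2 is overwhelming evidence (z ≈ −12,
    two stars); a zero θ has p = 1 and no star."""
    eff, completed = decompose(human_m)
    attach_uncertainty(eff, completed)
    s = human_m.sites
    m285 = s.mask_of(["T285A"])
    assert eff.se[m285] == pytest.approx(np.sqrt(2))
    assert eff.pvalue[m285] < 0.01
    assert eff.stars(m285) == "**"
    m_pair = s.mask_of(["S180A", "Y277F"])   # θ = 0
    assert eff.pvalue[m_pair] == 1.0
    assert eff.stars(m_pair) == ""


def test_significance_zero_se_nonzero_theta_warns():
    land = make_landscape(["a"], 100.0, {("a",): 105.0})
    eff, completed = decompose(land)
    system = build_design_system(completed, V=np.zeros((2, 2)))
    eff.se = standard_errors(system)
    with pytest.warns(RuntimeWarning):
        pvals, _ = significance(eff)
    assert pvals[1] == 0.0


# ---------------------------------------------------------------------------
# stable-only reduced analysis
# ---------------------------------------------------------------------------


def test_stable_only_matches_full_when_all_functional(human_m):
    eff_full, _ = decompose(human_m)
    eff_red = decompose_stable_only(human_m)
    assert eff_red.theta == eff_full.theta


def test_stable_only_drops_inestimable_terms():
    """With a nonfunctional single, its θ is absent from the reduced analysis
    and every estimable θ matches the full imputed decomposition."""
    land = make_landscape(
        ["T52F", "T93P"], 357.0,
        {("T93P",): 359.0, ("T52F", "T93P"): 360.0},
        nonfunctional=[("T52F",)],
    )
    full, _ = decompose(land)
    red = decompose_stable_only(land)
    m52 = land.sites.mask_of(["T52F"])
    assert m52 not in red.theta
    for mask, th in red.theta.items():
        assert th == pytest.approx(full.theta[mask], abs=1e-9)


@settings(max_examples=40, deadline=None, derandomize=True)
@given(L=st.integers(2, 6), seed=st.integers(0, 2 ** 31 - 1))
def test_stable_only_consistency_property(L, seed):
    """Every θ the reduced (stable-only) analysis returns equals the full
    decomposition's value, for random landscapes and lethality patterns."""
    rng = np.random.default_rng(seed)
    land = random_lethality_landscape(rng, L)
    full, _ = decompose(land)
    red = decompose_stable_only(land)
    for mask, th in red.theta.items():
        assert th == pytest.approx(full.theta[mask], abs=1e-9)


def test_stable_only_tolerates_absent_nonfunctional_rows():
    from spectune import Landscape
    sites = SiteSet(("a", "b"))
    records = {
        0: PhenotypeRecord(mask=0, lambda_max=100.0, functional=True),
        2: PhenotypeRecord(mask=2, lambda_max=103.0, functional=True),
        3: PhenotypeRecord(mask=3, lambda_max=110.0, functional=True),
    }
    land = Landscape(sites=sites, lambda_anc=100.0, records=records)
    red = decompose_stable_only(land)
    assert red.theta[2] == 3.0
    assert red.theta[3] == 110.0 - 100.0 - 3.0   # θ_a treated as 0
    assert 1 not in red.theta
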