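"""Binding-model tests: closed forms, solver vs oracle, isotherm fits."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from mlle_pam2 import binding
from mlle_pam2.binding import (
    EquilibriumSystem,
    Ligand,
    TitrationDataset,
    TwoSiteAffinity,
    bound_fraction_exclusive,
    cooperativity_factor,
    effective_kd_half_saturation,
    effective_kd_independent,
    fit_kd,
    isotherm,
    max_stoichiometry,
    solve_competition,
)
from mlle_pam2.synthetic import generate_titration
from oracles import oracle_bound_per_ligand, oracle_free_mlle

MEASURED = TwoSiteAffinity(kd_n=3.9, kd_c=3.1, kd_obs=1.3)


def test_effective_kd_harmonic_combination():
    # oracle: 1/(1/3.9 + 1/3.1)
    expected = 1.0 / (1.0 / 3.9 + 1.0 / 3.1)
    assert effective_kd_independent(MEASURED) == pytest.approx(expected, rel=1e-12)
    assert round(effective_kd_independent(MEASURED), 2) == 1.73


def test_cooperativity_factor_prints_1_3():
    factor = cooperativity_factor(MEASURED)
    assert factor == pytest.approx(effective_kd_independent(MEASURED) / 1.3, rel=1e-12)
    assert round(factor, 1) == 1.3
    with pytest.raises(ValueError, match="kd_obs"):
        cooperativity_factor(TwoSiteAffinity(3.9, 3.1))


@given(st.floats(0.01, 100), st.floats(0.01, 100))
def test_effective_kd_symmetry_and_bounds(kn, kc):
    aff = TwoSiteAffinity(kn, kc)
    swapped = TwoSiteAffinity(kc, kn)
    k_eff = effective_kd_independent(aff)
    assert k_eff == pytest.approx(effective_kd_independent(swapped), rel=1e-12)
    # tighter than either single site, no tighter than half the best
    assert k_eff < min(kn, kc) + 1e-15
    assert k_eff >= min(kn, kc) / 2 - 1e-12


def test_half_saturation_definition_solves_its_equation():
    for kn, kc in [(3.9, 3.1), (1.0, 10.0), (0.2, 0.3)]:
        m = effective_kd_half_saturation(TwoSiteAffinity(kn, kc))
        assert m == pytest.approx(math.sqrt(kn * kc), rel=1e-12)
        assert m / (kn + m) + m / (kc + m) == pytest.approx(1.0, rel=1e-12)


def test_exclusive_half_saturation_at_harmonic_kd():
    k_eff = effective_kd_independent(MEASURED)
    assert bound_fraction_exclusive(k_eff, MEASURED) == pytest.approx(0.5, rel=1e-12)


@given(st.floats(0.01, 50), st.floats(0.01, 50),
       st.floats(0.0, 1000), st.floats(0.0, 1000))
def test_bound_fraction_monotone_and_bounded(kn, kc, m1, m2):
    aff = TwoSiteAffinity(kn, kc)
    lo, hi = sorted((m1, m2))
    f_lo, f_hi = bound_fraction_exclusive(lo, aff), bound_fraction_exclusive(hi, aff)
    assert 0.0 <= f_lo <= f_hi <= 1.0
    assert bound_fraction_exclusive(0.0, aff) == 0.0


def test_max_stoichiometry_analytic_limits():
    assert max_stoichiometry(MEASURED, exclusive=True) == 1.0
    assert max_stoichiometry(MEASURED, exclusive=False) == 2.0


def test_affinity_validation():
    for bad in (0.0, -1.0, float("nan"), float("inf")):
        with pytest.raises(ValueError):
            TwoSiteAffinity(bad, 3.1)
    with pytest.raises(ValueError):
        Ligand("x", total=-1.0, kd_sites=(1.0,))
    with pytest.raises(ValueError):
        Ligand("x", total=1.0, kd_sites=())
    with pytest.raises(ValueError, match="unique"):
        EquilibriumSystem(1.0, (Ligand("a", 1, (1.0,)), Ligand("a", 1, (2.0,))))


def test_single_site_competition_matches_quadratic():
    """One single-site ligand: free MLLE solves the textbook quadratic."""
    total_m, total_l, kd = 10.0, 5.0, 2.0
    system = EquilibriumSystem(total_m, (Ligand("L", total_l, (kd,)),))
    table = solve_competition(system)
    m_free = float(table.loc[table.species == "MLLE", "free_ligand_uM"].iloc[0])
    # m^2 + (kd + total_l - total_m) m - kd total_m = 0
    b, c = kd + total_l - total_m, -kd * total_m
    root = (-b + math.sqrt(b * b - 4 * c)) / 2
    assert m_free == pytest.approx(root, rel=1e-10)


def test_competition_solver_matches_bisection_oracle():
    rng = np.random.default_rng(42)
    for _ in range(120):
        total_m = float(rng.uniform(0.0, 50.0))
        ligands = []
        for i in range(int(rng.integers(1, 4))):
            n_sites = int(rng.integers(1, 3))
            ligands.append(
                Ligand(
                    name=f"L{i}",
                    total=float(rng.uniform(0.0, 50.0)),
                    kd_sites=tuple(float(k) for k in rng.uniform(0.01, 100.0, n_sites)),
                    mutually_exclusive=bool(rng.integers(0, 2)),
                )
            )
        system = EquilibriumSystem(total_m, tuple(ligands))
        table = solve_competition(system)
        m_free = float(table.loc[table.species == "MLLE", "free_ligand_uM"].iloc[0])
        oracle = oracle_free_mlle(
            total_m, [(l.total, l.kd_sites, l.mutually_exclusive) for l in ligands]
        )
        # agreement to better than 4 significant figures
        assert m_free == pytest.approx(oracle, rel=1e-6, abs=1e-9)
        # per-ligand bound amounts follow from the same free concentration
        for lig in ligands:
            row = table.loc[table.species == lig.name].iloc[0]
            expect = lig.total * oracle_bound_per_ligand(
                m_free, lig.kd_sites, lig.mutually_exclusive
            )
            assert row.bound_mlle_uM == pytest.approx(expect, rel=1e-9, abs=1e-12)
        # MLLE conservation
        bound_total = float(
            table.loc[table.species != "MLLE", "bound_mlle_uM"].sum()
        )
        assert bound_total + m_free == pytest.approx(total_m, rel=1e-9, abs=1e-9)


def test_competitor_displaces_erf3():
    def erf3_bound(competitor_total: float) -> float:
        system = EquilibriumSystem(
            10.0,
            (
                Ligand("eRF3", 5.0, (3.9, 3.1), mutually_exclusive=True),
                Ligand("adaptor", competitor_total, (1.0,)),
            ),
        )
        table = solve_competition(system)
        return float(table.loc[table.species == "eRF3", "bound_mlle_uM"].iloc[0])

    amounts = [erf3_bound(t) for t in (0.0, 1.0, 5.0, 20.0, 100.0)]
    assert all(a > b for a, b in zip(amounts, amounts[1:]))


def test_fit_recovers_kd_noiseless():
    for kd in (0.05, 1.3, 7.0, 40.0):
        dataset = generate_titration(kd=kd, noise_sd=0.0)
        fitted = fit_kd(dataset)
        assert fitted.kd_estimate == pytest.approx(kd, rel=1e-6)


def test_fit_median_of_noisy_replicates_within_10_percent():
    estimates = [
        fit_kd(generate_titration(kd=1.3, noise_sd=0.02, seed=seed)).kd_estimate
        for seed in range(1, 101)
    ]
    median = float(np.median(estimates))
    assert abs(median - 1.3) / 1.3 < 0.10


def test_fit_input_validation():
    conc = tuple(np.geomspace(0.13, 13.0, 5))
    with pytest.raises(ValueError, match="at least 6"):
        fit_kd(TitrationDataset(conc, tuple(isotherm(np.array(conc), 1.3))))
    flat_conc = tuple(np.geomspace(0.13, 13.0, 8))
    with pytest.raises(ValueError, match="flat response"):
        fit_kd(TitrationDataset(flat_conc, (0.5,) * 8))
    with pytest.raises(ValueError, match="strictly increasing"):
        TitrationDataset((1.0, 1.0, 2.0), (0.1, 0.2, 0.3))
    with pytest.raises(ValueError, match="equal length"):
        TitrationDataset((1.0, 2.0), (0.1,))


def test_fit_summary_format():
    result = fit_kd(generate_titration(kd=1.3, noise_sd=0.0))
    assert "Kd = 1.3" in result.summary()
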