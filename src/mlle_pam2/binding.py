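"""Mass-action equilibria for MLLE binding to overlapping PAM2 sites.

eRF3 presents two PAM2 sites to the MLLE domain of PABPC1, but the sites
overlap (they share Phe76) and therefore cannot be occupied at the same
time.  For such a ligand the law of mass action gives an apparent
dissociation constant obtained by adding the per-site association
constants,

    Kd_indep = (1/Kd_N + 1/Kd_C)^-1,

which for the measured site constants of 3.9 and 3.1 µM is 1.73 µM.  The
measured constant of the overlapped peptide (1.3 µM) is tighter than that
by a factor of ~1.3 — a small degree of cooperativity between the sites —
while mutual exclusivity caps the stoichiometry at one MLLE per eRF3.

The module also solves competition between an arbitrary set of PAM2
ligands (eRF3 versus the deadenylase adaptors PAN3 and Tob) for a shared
pool of MLLE, and fits 1:1 saturation isotherms to recover Kd from
titration data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import sympy
from scipy import optimize

__all__ = [
    "TwoSiteAffinity",
    "Ligand",
    "EquilibriumSystem",
    "TitrationDataset",
    "KdFit",
    "effective_kd_independent",
    "effective_kd_half_saturation",
    "cooperativity_factor",
    "bound_fraction_exclusive",
    "max_stoichiometry",
    "solve_competition",
    "fit_kd",
]


def _check_positive(name: str, value: float) -> None:
    if not (math.isfinite(value) and value > 0):
        raise ValueError(f"{name} must be a positive finite concentration, got {value!r}")


@dataclass(frozen=True)
class TwoSiteAffinity:
    """Dissociation constants (µM) of the two overlapping PAM2 sites.

    ``kd_obs`` is the measured constant of the overlapped (two-site)
    peptide, when available.
    """

    kd_n: float
    kd_c: float
    kd_obs: float | None = None

    def __post_init__(self) -> None:
        _check_positive("kd_n", self.kd_n)
        _check_positive("kd_c", self.kd_c)
        if self.kd_obs is not None:
            _check_positive("kd_obs", self.kd_obs)


@dataclass(frozen=True)
class Ligand:
    """A PAM2-carrying species competing for MLLE.

    ``kd_sites`` lists the per-site dissociation constants (µM); with
    ``mutually_exclusive`` the sites overlap, so at most one MLLE binds
    per ligand molecule (eRF3); otherwise sites fill independently
    (hypothetical tandem arrangement).  Single-site adaptors such as PAN3
    or Tob carry one entry.
    """

    name: str
    total: float
    kd_sites: tuple[float, ...]
    mutually_exclusive: bool = True

    def __post_init__(self) -> None:
        if self.total < 0:
            raise ValueError(f"total concentration of {self.name} must be >= 0")
        if not self.kd_sites:
            raise ValueError(f"ligand {self.name} needs at least one site")
        for kd in self.kd_sites:
            _check_positive(f"kd of {self.name}", kd)

    def bound_mlle_per_ligand(self, m_free: float) -> float:
        """Average number of MLLE molecules bound per ligand molecule."""
        if self.mutually_exclusive:
            s = m_free * sum(1.0 / kd for kd in self.kd_sites)
            return s / (1.0 + s)
        return sum(m_free / (kd + m_free) for kd in self.kd_sites)


@dataclass(frozen=True)
class EquilibriumSystem:
    """A pool of MLLE shared by competing PAM2 ligands (all µM)."""

    total_mlle: float
    ligands: tuple[Ligand, ...]

    def __post_init__(self) -> None:
        if self.total_mlle < 0:
            raise ValueError("total_mlle must be >= 0")
        names = [lig.name for lig in self.ligands]
        if len(set(names)) != len(names):
            raise ValueError("ligand names must be unique")


@dataclass(frozen=True)
class TitrationDataset:
    """A 1:1 saturation-binding titration (concentrations in µM)."""

    titrant_concentrations: tuple[float, ...]
    response: tuple[float, ...]
    noise_sd: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        conc = np.asarray(self.titrant_concentrations, dtype=float)
        resp = np.asarray(self.response, dtype=float)
        if conc.ndim != 1 or conc.size != resp.size:
            raise ValueError("concentrations and response must be 1-D and equal length")
        if np.any(conc < 0):
            raise ValueError("concentrations must be non-negative")
        if np.any(np.diff(conc) <= 0):
            raise ValueError("concentrations must be strictly increasing")
        if not np.all(np.isfinite(resp)):
            raise ValueError("response must be finite")


@dataclass(frozen=True)
class KdFit:
    """Result of a 1:1 isotherm fit."""

    kd_estimate: float
    stderr: float
    residual_sd: float = field(default=float("nan"), compare=False)

    def summary(self) -> str:
        return (
            f"Kd = {self.kd_estimate:.3g} µM (± {self.stderr:.2g}), "
            f"residual sd {self.residual_sd:.3g}"
        )


def effective_kd_independent(affinity: TwoSiteAffinity) -> float:
    """Apparent Kd of two independent sites under the law of mass action.

    Association constants of independent sites add, so the apparent
    dissociation constant is the harmonic combination
    ``(1/kd_n + 1/kd_c)^-1``.  This equals the low-concentration initial
    slope of total site occupancy and, for mutually exclusive sites, the
    exact half-saturation point of the single-bound fraction.
    """
    return 1.0 / (1.0 / affinity.kd_n + 1.0 / affinity.kd_c)


def effective_kd_half_saturation(affinity: TwoSiteAffinity) -> float:
    """Alternative definition: free-MLLE concentration at which total
    occupancy of a hypothetical independent-tandem ligand reaches half of
    its saturation value (one of two sites filled).

    Exposed for comparison with :func:`effective_kd_independent`; it does
    not reproduce the observed ~1.3-fold cooperativity factor.  Solves
    m/(kn+m) + m/(kc+m) = 1 in closed form.
    """
    # m/(kn+m) + m/(kc+m) = 1 reduces to m^2 = kn*kc
    return math.sqrt(affinity.kd_n * affinity.kd_c)


def cooperativity_factor(affinity: TwoSiteAffinity) -> float:
    """Ratio of the independent-sites apparent Kd to the measured Kd.

    Values above 1 mean the overlapped pair binds more tightly than two
    independent sites would, i.e. positive cooperativity.  For the
    measured constants (3.9, 3.1; observed 1.3 µM) the factor is ~1.3.
    """
    if affinity.kd_obs is None:
        raise ValueError("cooperativity factor requires a measured kd_obs")
    return effective_kd_independent(affinity) / affinity.kd_obs


def bound_fraction_exclusive(mlle_free: float, affinity: TwoSiteAffinity) -> float:
    """Fraction of two-site ligand with an MLLE bound, sites mutually exclusive.

    Partition function over {empty, N-bound, C-bound}:
    ``(m/kn + m/kc) / (1 + m/kn + m/kc)``.  Monotone in ``m`` and → 1 at
    saturation — exactly one MLLE per ligand.
    """
    if mlle_free < 0:
        raise ValueError("free MLLE concentration must be >= 0")
    s = mlle_free / affinity.kd_n + mlle_free / affinity.kd_c
    return s / (1.0 + s)


def max_stoichiometry(affinity: TwoSiteAffinity, exclusive: bool = True) -> float:
    """MLLE molecules bound per ligand at saturation.

    Computed as the m → ∞ limit of the mean occupancy derived from the
    respective partition function (taken symbolically), not hard-coded:
    mutually exclusive overlapping sites saturate at 1, an independent
    tandem at 2.
    """
    m = sympy.symbols("m", positive=True)
    kn, kc = sympy.symbols("k_n k_c", positive=True)
    if exclusive:
        occupancy = (m / kn + m / kc) / (1 + m / kn + m / kc)
    else:
        occupancy = m / (kn + m) + m / (kc + m)
    return float(sympy.limit(occupancy, m, sympy.oo))


def _free_mlle_residual(m_free: float, system: EquilibriumSystem) -> float:
    bound = sum(
        lig.total * lig.bound_mlle_per_ligand(m_free) for lig in system.ligands
    )
    return m_free + bound - system.total_mlle


def solve_competition(system: EquilibriumSystem) -> pd.DataFrame:
    """Solve the competition equilibrium for free and bound concentrations.

    Conservation of MLLE reduces the problem to one scalar equation in
    free MLLE, which is monotone on [0, total_mlle] and solved by
    bracketed root finding (relative tolerance 1e-12, deterministic).

    Returns a table with one row per ligand (free/bound concentrations
    and per-site occupancies) plus a ``free MLLE`` row; every conservation
    law holds to relative tolerance 1e-9.
    """
    total = system.total_mlle
    if total == 0 or not system.ligands:
        m_free = total
    else:
        lo, hi = 0.0, total
        if _free_mlle_residual(hi, system) < 0:  # pragma: no cover - impossible
            raise RuntimeError("no root bracketed in [0, total_mlle]")
        m_free = optimize.brentq(
            _free_mlle_residual, lo, hi, args=(system,), xtol=1e-15, rtol=1e-13
        )
    rows = []
    for lig in system.ligands:
        per_ligand = lig.bound_mlle_per_ligand(m_free)
        bound = lig.total * per_ligand
        rows.append(
            {
                "species": lig.name,
                "total_uM": lig.total,
                "bound_mlle_uM": bound,
                "free_ligand_uM": lig.total * (1.0 - per_ligand)
                if lig.mutually_exclusive or len(lig.kd_sites) == 1
                else lig.total * math.prod(kd / (kd + m_free) for kd in lig.kd_sites),
                "occupancy_per_ligand": per_ligand,
            }
        )
    rows.append(
        {
            "species": "MLLE",
            "total_uM": total,
            "bound_mlle_uM": total - m_free,
            "free_ligand_uM": m_free,
            "occupancy_per_ligand": float("nan"),
        }
    )
    table = pd.DataFrame(rows)
    # internal consistency: MLLE conservation
    resid = abs(_free_mlle_residual(m_free, system))
    scale = max(total, 1.0)
    if resid > 1e-9 * scale:  # pragma: no cover - solver guarantee
        raise RuntimeError(f"conservation residual {resid} exceeds tolerance")
    return table


def isotherm(m: np.ndarray, kd: float) -> np.ndarray:
    """1:1 saturation isotherm, fraction bound = m / (Kd + m)."""
    m = np.asarray(m, dtype=float)
    return m / (kd + m)


def fit_kd(dataset: TitrationDataset) -> KdFit:
    """Least-squares fit of the 1:1 isotherm to a titration.

    Requires at least six concentration points and a visible binding
    signal; on noiseless data the generating constant is recovered to
    relative error below 1e-6.
    """
    conc = np.asarray(dataset.titrant_concentrations, dtype=float)
    resp = np.asarray(dataset.response, dtype=float)
    if conc.size < 6:
        raise ValueError("need at least 6 titration points to fit a Kd")
    if np.ptp(resp) < 0.05:
        raise ValueError(
            "flat response (range < 0.05 fraction bound): no binding signal to fit"
        )
    # initial guess: concentration closest to half-saturation
    p0 = conc[int(np.argmin(np.abs(resp - 0.5)))] or np.median(conc[conc > 0])
    try:
        popt, pcov = optimize.curve_fit(
            isotherm, conc, resp, p0=[p0], bounds=(1e-12, np.inf), maxfev=10000
        )
    except RuntimeError as exc:
        raise ValueError(f"isotherm fit did not converge: {exc}") from exc
    kd = float(popt[0])
    stderr = float(np.sqrt(pcov[0, 0]))
    dof = max(conc.size - 1, 1)
    residual_sd = float(np.sqrt(np.sum((resp - isotherm(conc, kd)) ** 2) / dof))
    return KdFit(kd_estimate=kd, stderr=stderr, residual_sd=residual_sd)
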