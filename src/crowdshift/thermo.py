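"""State-level crowding thermodynamics: ensemble Δμ, ΔΔG, κ and rate factors.

All energies are in units of k_BT unless noted. The ensemble chemical
potential of a state is the exponential (f-space) average of the
per-conformation values, −ln⟨e^{−βΔμ_i}⟩: transferring the whole state into
the crowded solution weights each conformation by its insertion probability,
so the state value must reproduce the ensemble-mean f.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

__all__ = [
    "KCAL_PER_MOL_PER_K",
    "kt_in_kcal_per_mol",
    "StateChemicalPotential",
    "CrowdingEffect",
    "boltzmann_average_delta_mu",
    "state_chemical_potential",
    "delta_delta_g",
    "population_ratio_change",
    "rate_change_from_barrier_shift",
]

#: Boltzmann constant in kcal/mol/K.
KCAL_PER_MOL_PER_K = 0.0019872041


def kt_in_kcal_per_mol(temperature: float = 300.0) -> float:
    """k_BT in kcal/mol at the given temperature (0.5961 at 300 K)."""
    return KCAL_PER_MOL_PER_K * temperature


@dataclass(frozen=True)
class StateChemicalPotential:
    """Ensemble crowding chemical potential of one conformational state."""

    state_label: str
    per_conformation: tuple[float, ...]
    beta_delta_mu: float

    @property
    def effective_f(self) -> float:
        return math.exp(-self.beta_delta_mu)


@dataclass(frozen=True)
class CrowdingEffect:
    """Effect of crowding on the open-to-closed population ratio.

    ``kappa`` is the relative change of the ratio (negative when crowding
    favours the closed state); ``fold_change`` is the dilute/crowded ratio of
    ratios, exp(βΔΔG).
    """

    beta_ddg: float
    kappa: float
    fold_change: float

    @property
    def percent_reduction(self) -> float:
        """−100 κ when κ < 0 (the ratio is reduced); 0 otherwise."""
        return -100.0 * self.kappa if self.kappa < 0 else 0.0


def boltzmann_average_delta_mu(
    per_conformation, arithmetic: bool = False
) -> float:
    """Ensemble βΔμ = −ln( mean_i exp(−βΔμ_i) ), via log-sum-exp.

    Equivalent to averaging the per-conformation insertion probabilities f_i.
    ``arithmetic=True`` instead returns the plain mean of the βΔμ values
    (sensitivity analysis only; it does not reproduce the ensemble f).
    """
    vals = np.asarray(list(per_conformation), dtype=float)
    if vals.size == 0:
        raise ValueError("need at least one per-conformation value")
    if not np.all(np.isfinite(vals)):
        raise ValueError("per-conformation values must be finite")
    if arithmetic:
        return float(np.mean(vals))
    return float(-(logsumexp(-vals) - math.log(vals.size)))


def state_chemical_potential(
    per_conformation, state_label: str = "", arithmetic: bool = False
) -> StateChemicalPotential:
    value = boltzmann_average_delta_mu(per_conformation, arithmetic=arithmetic)
    return StateChemicalPotential(
        state_label=state_label,
        per_conformation=tuple(float(v) for v in per_conformation),
        beta_delta_mu=value,
    )


def delta_delta_g(mu_open: float, mu_closed: float) -> float:
    """Crowding-induced shift of the open/closed free-energy difference:
    βΔΔG = βΔμ_open − βΔμ_closed."""
    if not (math.isfinite(mu_open) and math.isfinite(mu_closed)):
        raise ValueError("chemical potentials must be finite")
    return mu_open - mu_closed


def population_ratio_change(beta_ddg: float) -> CrowdingEffect:
    """κ = exp(−βΔΔG) − 1 and the equivalent fold change exp(βΔΔG)."""
    if not math.isfinite(beta_ddg):
        raise ValueError("beta_ddg must be finite")
    return CrowdingEffect(
        beta_ddg=beta_ddg,
        kappa=math.expm1(-beta_ddg),
        fold_change=math.exp(beta_ddg),
    )


def rate_change_from_barrier_shift(delta_barrier: float, direction: str) -> float:
    """Percent change of a transition rate for a barrier shifted by
    ``delta_barrier`` k_BT (>= 0), quoted as 100·(e^Δ − 1).

    ``direction`` is ``"lowered"`` (rate increase) or ``"raised"`` (rate
    decrease); the sign of the shift is carried by the direction, and the
    magnitude is quoted as |factor − 1| in percent either way.
    """
    if delta_barrier < 0:
        raise ValueError("delta_barrier must be >= 0; use direction for the sign")
    if direction not in ("lowered", "raised"):
        raise ValueError("direction must be 'lowered' or 'raised'")
    return 100.0 * math.expm1(delta_barrier)
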