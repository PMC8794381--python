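"""Evolutionary-game classification of the inferred interaction regime.

In a growing tumor, where resources are replenished and waste removed,
frequency-dependent dynamics are the more natural description, and the
two-subclone interaction can be summarized by the 2x2 payoff matrix

    rows: focal strategy, columns: opponent  (L first, then W)

        (beta_L - gamma    alpha_L - gamma)
        (beta_W - delta    alpha_W - delta)

where ``alpha_L, alpha_W < 0`` are the harms inflicted by the winner on each
type, ``beta_L, beta_W > 0`` the benefits bestowed by the loser on each type,
``gamma > 0`` the difference between the intrinsic exponential growth rates
(the loser pays a production cost), and ``delta >= 0`` a reduction of the
winner's intrinsic rate in a degraded (resource-poor) environment.

The relative ordering of the entries determines which classical game the
dynamics are equivalent to: a prisoner's dilemma with the winner as the sole
evolutionarily stable strategy (the regime the in-vitro inference supports),
a hawk-dove game with a mixed ESS permitting coexistence, or a prisoner's
dilemma with the loser as the ESS.  No automatic numeric mapping from the
Lotka-Volterra coefficients to payoff entries is asserted: the matrix takes
explicit entries (an illustrative heuristic is documented in
:func:`heuristic_payoff_from_lv`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import NamedTuple, Optional

import numpy as np

__all__ = [
    "PayoffMatrix",
    "GameClassification",
    "MixedESS",
    "classify_game",
    "mixed_ess_proportion",
    "apply_resource_poor",
    "replicator_trajectory",
    "heuristic_payoff_from_lv",
]


@dataclass(frozen=True)
class PayoffMatrix:
    """Payoff entries with the sign conventions of the two-subclone game."""

    alpha_L: float
    alpha_W: float
    beta_L: float
    beta_W: float
    gamma: float
    delta: float = 0.0

    def __post_init__(self) -> None:
        checks = [
            (self.alpha_L < 0, "alpha_L < 0 (harm inflicted by W on L)"),
            (self.alpha_W < 0, "alpha_W < 0 (harm inflicted by W on W)"),
            (self.beta_L > 0, "beta_L > 0 (benefit bestowed by L on L)"),
            (self.beta_W > 0, "beta_W > 0 (benefit bestowed by L on W)"),
            (self.gamma > 0, "gamma > 0 (intrinsic growth-rate difference)"),
            (self.delta >= 0, "delta >= 0 (resource-poor rate reduction)"),
        ]
        for ok, constraint in checks:
            if not ok:
                raise ValueError(f"payoff sign constraint violated: {constraint}")

    def effective(self) -> np.ndarray:
        """Effective 2x2 matrix, rows/columns ordered (L, W)."""
        return np.array(
            [
                [self.beta_L - self.gamma, self.alpha_L - self.gamma],
                [self.beta_W - self.delta, self.alpha_W - self.delta],
            ]
        )


class MixedESS(NamedTuple):
    """Two candidate mixed-ESS winner proportions.

    ``printed`` is the published closed-form expression
    ``(alpha_W - delta - alpha_L + gamma) / (alpha_W - alpha_L + beta_L - beta_W)``;
    ``equal_fitness`` is the root of the equal-fitness condition of the
    effective matrix.  The two are exact complements (they sum to 1); the
    discrepancy is surfaced as two named values, never averaged.
    """

    printed: float
    equal_fitness: float


@dataclass(frozen=True)
class GameClassification:
    """Outcome of the inequality chain on the effective payoff matrix."""

    game: str  # PD_W_ESS | HAWK_DOVE | PD_L_ESS | BISTABLE | BOUNDARY
    pure_ess: tuple
    mixed_ess: Optional[MixedESS]
    chain: str


def classify_game(m: PayoffMatrix, tol: float = 1e-12) -> GameClassification:
    """Classify the 2x2 game defined by the effective payoff matrix.

    The winner is a strict pure ESS iff ``alpha_W - delta > alpha_L - gamma``
    (W resists invasion by L); the loser iff ``beta_L - gamma > beta_W - delta``.
    Exactly one of four strict regimes holds — winner-ESS prisoner's
    dilemma, loser-ESS prisoner's dilemma, hawk-dove (neither pure strategy
    stable, interior mixed ESS) or a bistable coordination game (both pure
    strategies stable) — and any equality within ``tol`` is BOUNDARY.
    """
    E = m.effective()
    dW = E[1, 1] - E[0, 1]  # stability of W against invading L
    dL = E[0, 0] - E[1, 0]  # stability of L against invading W
    chain = (
        f"alpha_W - delta {'>' if dW > 0 else '<'} alpha_L - gamma; "
        f"beta_L - gamma {'>' if dL > 0 else '<'} beta_W - delta"
    )
    if abs(dW) <= tol or abs(dL) <= tol:
        return GameClassification("BOUNDARY", (), None, chain)
    if dW > 0 and dL < 0:
        return GameClassification("PD_W_ESS", ("W",), None, chain)
    if dW < 0 and dL > 0:
        return GameClassification("PD_L_ESS", ("L",), None, chain)
    if dW > 0 and dL > 0:
        return GameClassification("BISTABLE", ("L", "W"), None, chain)
    return GameClassification("HAWK_DOVE", (), mixed_ess_proportion(m), chain)


def mixed_ess_proportion(m: PayoffMatrix) -> MixedESS:
    """Mixed-ESS winner proportion, computed two ways.

    Returns the published closed form and the equal-fitness root of
    ``x E_WW + (1-x) E_WL = x E_LW + (1-x) E_LL``; the two candidates are
    complementary (``printed + equal_fitness = 1``).
    """
    den = m.alpha_W - m.alpha_L + m.beta_L - m.beta_W
    if den == 0:
        raise ValueError("mixed-ESS denominator is zero (degenerate payoffs)")
    printed = (m.alpha_W - m.delta - m.alpha_L + m.gamma) / den
    return MixedESS(printed=printed, equal_fitness=1.0 - printed)


def apply_resource_poor(m: PayoffMatrix, delta: float) -> PayoffMatrix:
    """Payoff matrix of the resource-poor environment (winner rate reduced by delta).

    Increasing ``delta`` lowers the winner's whole row, so the classification
    can only move away from the winner: the set of ``delta`` for which W is a
    pure ESS is a downward-closed interval.
    """
    if delta < 0:
        raise ValueError("delta must be >= 0")
    return replace(m, delta=delta)


def replicator_trajectory(
    E: np.ndarray, x0: float, t_end: float = 2000.0, n: int = 400
) -> np.ndarray:
    """Replicator dynamics of the winner proportion on an effective 2x2 matrix.

    ``dx/dt = x (1 - x) (f_W - f_L)`` with the mean-field fitnesses of the
    two strategies; used as a brute-force oracle for the classifier.
    """
    from scipy.integrate import solve_ivp

    E = np.asarray(E, dtype=float)

    def rhs(t, y):
        x = y[0]
        f_W = x * E[1, 1] + (1 - x) * E[1, 0]
        f_L = x * E[0, 1] + (1 - x) * E[0, 0]
        return [x * (1 - x) * (f_W - f_L)]

    sol = solve_ivp(
        rhs, (0.0, t_end), [x0], t_eval=np.linspace(0.0, t_end, n),
        rtol=1e-9, atol=1e-12,
    )
    return sol.y[0]


def heuristic_payoff_from_lv(
    params, benefit_L: float, benefit_W: float
) -> PayoffMatrix:
    """Illustrative mapping from Lotka-Volterra coefficients to payoff entries.

    The harms scale the winner's density effects by its carrying capacity
    (``alpha_L = b K_W``, ``alpha_W = d K_W``) and ``gamma`` is the phase-2
    intrinsic-rate difference; the benefit entries are not identified by the
    in-vitro data and must be supplied.  This mapping is a heuristic for
    exploration, not an asserted result.
    """
    from .model import derived_quantities

    K_W = derived_quantities(params).K_W
    return PayoffMatrix(
        alpha_L=params.b * K_W,
        alpha_W=params.d * K_W,
        beta_L=benefit_L,
        beta_W=benefit_W,
        gamma=params.r_W2 - params.r_L2,
        delta=0.0,
    )
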