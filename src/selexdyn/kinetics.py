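"""Closed-form reaction, recovery and enrichment formulas.

In vitro selection enriches catalytic RNAs because a catalyst reacts
(and is therefore recovered) with higher probability than a background
sequence during the reaction step of each round.  For a first-order
reaction the probability that a sequence with relative rate ``k`` and
amplitude ``A`` has reacted after scaled time ``tau`` is

    r(tau) = A * (1 - exp(-tau * k))

where time is nondimensionalized by the best catalyst's rate and the
substrate concentration (``tau = kcat * Csub * t``), so all rates here
are stored relative to that reference rate (``k = 1`` for the best
catalyst).  The amplitude ``A`` is the fraction of copies that ever
react: misfolded molecules are trapped and never do, so ``A <= 1``.
A reacted sequence survives the separation/processing steps with
probability ``Q``, giving the combined recovery probability
``R(tau) = Q * r(tau)``.

The per-round enrichment factor of a species is ``E = R / R_mean``
where ``R_mean`` is the population-averaged recovery probability.
Early in a selection nearly every molecule is background, so
``R_mean ~ R_back`` and the catalyst's enrichment approaches the hard
ceiling ``E_max = A * kcat / kback`` as ``tau -> 0``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import DegenerateRoundError

__all__ = [
    "ReactionParams",
    "RecoveryModel",
    "reaction_probability",
    "recovery_probability",
    "enrichment_factor",
    "max_enrichment",
    "scaled_time",
]


@dataclass(frozen=True)
class ReactionParams:
    """Kinetic parameters of one species.

    Parameters
    ----------
    label:
        Identifier used in pools, trajectories and output tables.
    A:
        Amplitude, the maximum fraction of copies that react at long
        times; in (0, 1].  Background sequences use ``A = 1`` because
        the uncatalysed reaction does not depend on folding.
    k:
        First-order rate relative to the reference catalyst rate
        ``kcat`` (dimensionless, > 0).  A typical background sequence
        has ``k = kback / kcat ~ 1e-3``.
    """

    label: str
    A: float
    k: float

    def __post_init__(self) -> None:
        if not (0.0 < self.A <= 1.0):
            raise ValueError(f"amplitude A must be in (0, 1], got {self.A!r}")
        if not self.k > 0.0:
            raise ValueError(f"relative rate k must be > 0, got {self.k!r}")


@dataclass(frozen=True)
class RecoveryModel:
    """Recovery-step parameters shared by a selection round.

    ``Q`` is the probability that a *reacted* sequence survives the
    separation and processing steps (gel purification, enzymatic
    steps, ...); it is the same for catalysts and background.  ``Rart``
    is the recovery probability of an artefact — a sequence captured by
    the separation step without reacting — and is independent of the
    reaction time.  ``Rart = 0`` means no artefact channel.
    """

    Q: float
    Rart: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 < self.Q <= 1.0):
            raise ValueError(f"Q must be in (0, 1], got {self.Q!r}")
        if not (0.0 <= self.Rart <= 1.0):
            raise ValueError(f"Rart must be in [0, 1], got {self.Rart!r}")


def _check_tau(tau):
    arr = np.asarray(tau, dtype=float)
    if np.any(arr < 0.0) or np.any(np.isnan(arr)):
        raise ValueError(f"scaled time tau must be >= 0, got {tau!r}")
    return arr


def scaled_time(k_cat: float, c_sub: float, t: float) -> float:
    """Convert physical reaction conditions to scaled time tau = kcat*Csub*t.

    For self-cleaving ribozymes without an external substrate use
    ``c_sub = 1``.
    """
    if k_cat <= 0 or c_sub <= 0 or t < 0:
        raise ValueError("require k_cat > 0, c_sub > 0, t >= 0")
    return k_cat * c_sub * t


def reaction_probability(params: ReactionParams, tau):
    """Probability that one copy has reacted after scaled time ``tau``.

    ``A * (1 - exp(-tau * k))``, evaluated with ``expm1`` so the small-tau
    regime (r ~ A*k*tau) keeps full relative precision.  ``tau = inf`` is
    accepted as a saturation sentinel and returns ``A``.
    """
    tau = _check_tau(tau)
    out = -params.A * np.expm1(-tau * params.k)
    return float(out) if out.ndim == 0 else out


def recovery_probability(params: ReactionParams, Q: float, tau):
    """Combined reaction-and-recovery probability R(tau) = Q * A * (1 - exp(-tau*k))."""
    if not (0.0 <= Q <= 1.0):
        raise ValueError(f"Q must be in [0, 1], got {Q!r}")
    out = Q * np.asarray(reaction_probability(params, tau))
    return float(out) if out.ndim == 0 else out


def enrichment_factor(R_species, R_mean: float):
    """Per-round enrichment E = R_species / R_mean.

    ``R_mean`` is the population mean recovery probability; E is the
    factor by which the species' frequency is multiplied in one round.
    """
    if R_mean < 0:
        raise ValueError("R_mean must be >= 0")
    if R_mean == 0.0:
        raise DegenerateRoundError("mean recovery probability is zero: no sequence recovered")
    out = np.asarray(R_species, dtype=float) / R_mean
    return float(out) if out.ndim == 0 else out


def max_enrichment(A: float, k_cat: float, k_back: float) -> float:
    """Ceiling on the early-round enrichment factor, A * kcat / kback.

    This is the tau -> 0 limit of Ecat(tau) = A(1-e^-tau)/(1-e^-tau*kback/kcat):
    at high stringency both exponentials linearize and the ratio of rates is
    all that remains.  Raising tau lets background sequences react too and
    pulls E below this ceiling.
    """
    if k_back <= 0:
        raise ValueError(f"k_back must be > 0, got {k_back!r}")
    if k_cat <= 0:
        raise ValueError(f"k_cat must be > 0, got {k_cat!r}")
    if not (0.0 < A <= 1.0):
        raise ValueError(f"amplitude A must be in (0, 1], got {A!r}")
    return A * k_cat / k_back
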