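"""Deterministic multi-round selection dynamics.

Each round multiplies every species' frequency by its recovery
probability and renormalizes:

    p_i(n) = p_i(n-1) * R_i(tau_n) / R_mean(n),
    R_mean(n) = sum_j p_j(n-1) * R_j(tau_n),

where the sum runs over catalysts, background and (optionally) an
artefact whose recovery probability ``Rart`` does not depend on the
reaction time.  The stringency schedule assigns a scaled reaction time
``tau_n`` to every round; decreasing tau in later rounds discriminates
by the product A*k instead of by the amplitude A alone, which can make
frequency curves cross — and can hand the population to an artefact if
tau drops below the point where ``Rart`` beats every catalyst.

Counter-selection for cofactor-dependent ribozymes runs each round in
two steps: sequences recovered *without* the cofactor are discarded,
then the survivors are selected *with* it.  The per-round pass
probability is (1 - R_without(tau_counter)) * R_with(tau_positive).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import DegenerateRoundError, TieError
from .kinetics import ReactionParams, recovery_probability

__all__ = [
    "SpeciesPool",
    "TauSchedule",
    "CofactorSpecies",
    "CofactorPool",
    "Trajectory",
    "species_recovery_probabilities",
    "round_update",
    "run_selection",
    "counter_selection_pass_probability",
    "run_counter_selection",
    "detect_dominant",
    "detect_crossings",
]

BACKGROUND_LABEL = "background"
ARTEFACT_LABEL = "artefact"


@dataclass(frozen=True)
class TauSchedule:
    """Per-round stringency schedule of scaled reaction times.

    Either an explicit list of tau values, or the stepped form
    (tau0, factor, first_decay_round): tau stays at ``tau0`` before
    ``first_decay_round`` and is divided by ``factor`` every round from
    then on.  Rounds are 1-based.  The shorthand is expanded once when a
    run begins.
    """

    taus: tuple[float, ...] | None = None
    tau0: float | None = None
    factor: float | None = None
    first_decay_round: int | None = None

    def __post_init__(self) -> None:
        explicit = self.taus is not None
        stepped = self.tau0 is not None
        if explicit == stepped:
            raise ValueError("give either an explicit tau list or (tau0, factor, first_decay_round)")
        if explicit:
            object.__setattr__(self, "taus", tuple(float(t) for t in self.taus))
            if any(t < 0 for t in self.taus):
                raise ValueError("all tau values must be >= 0")
        else:
            if self.factor is None or self.first_decay_round is None:
                raise ValueError("stepped schedule needs tau0, factor and first_decay_round")
            if self.tau0 < 0 or self.factor <= 0 or self.first_decay_round < 1:
                raise ValueError("invalid stepped schedule parameters")

    @classmethod
    def constant(cls, tau: float, n_rounds: int | None = None) -> "TauSchedule":
        # first_decay_round beyond any horizon makes this effectively constant
        return cls(tau0=float(tau), factor=1.0, first_decay_round=1)

    @classmethod
    def stepped(cls, tau0: float, factor: float, first_decay_round: int) -> "TauSchedule":
        return cls(tau0=float(tau0), factor=float(factor), first_decay_round=int(first_decay_round))

    def expand(self, n_rounds: int) -> np.ndarray:
        """Explicit tau value for rounds 1..n_rounds."""
        if n_rounds < 1:
            raise ValueError("n_rounds must be >= 1")
        if self.taus is not None:
            if len(self.taus) < n_rounds:
                raise ValueError(
                    f"schedule lists {len(self.taus)} rounds but {n_rounds} were requested"
                )
            return np.asarray(self.taus[:n_rounds], dtype=float)
        out = np.empty(n_rounds)
        tau = self.tau0
        for n in range(1, n_rounds + 1):
            if n >= self.first_decay_round:
                tau = tau / self.factor
            out[n - 1] = tau
        return out


@dataclass
class SpeciesPool:
    """Catalysts plus background (and optional artefact) entering a selection.

    ``p0`` holds one initial frequency per catalyst; the background
    absorbs the remaining probability mass.  Defaults Q = 0.2 and
    kback = 0.001 (relative to kcat = 1) are the running values used for
    the worked examples throughout this package.
    """

    catalysts: Sequence[ReactionParams]
    p0: Sequence[float]
    Q: float = 0.2
    kback: float = 0.001
    artefact_Rart: float | None = None
    artefact_p0: float = 0.0

    def __post_init__(self) -> None:
        self.catalysts = tuple(self.catalysts)
        self.p0 = tuple(float(p) for p in self.p0)
        if len(self.catalysts) != len(self.p0):
            raise ValueError("need one initial frequency per catalyst")
        if any(p < 0 for p in self.p0) or self.artefact_p0 < 0:
            raise ValueError("initial frequencies must be >= 0")
        if not (0.0 < self.Q <= 1.0):
            raise ValueError(f"Q must be in (0, 1], got {self.Q!r}")
        if self.kback <= 0:
            raise ValueError(f"kback must be > 0, got {self.kback!r}")
        if self.artefact_Rart is not None and not (0.0 <= self.artefact_Rart <= 1.0):
            raise ValueError("artefact Rart must be in [0, 1]")
        if self.artefact_Rart is None and self.artefact_p0 > 0:
            raise ValueError("artefact_p0 given without artefact_Rart")
        labels = [c.label for c in self.catalysts]
        if len(set(labels)) != len(labels):
            raise ValueError("catalyst labels must be unique")
        if self.background_p0 < -1e-12:
            raise ValueError("initial frequencies exceed 1; nothing left for background")

    @property
    def has_artefact(self) -> bool:
        return self.artefact_Rart is not None

    @property
    def background_p0(self) -> float:
        return 1.0 - sum(self.p0) - self.artefact_p0

    @property
    def labels(self) -> list[str]:
        out = [c.label for c in self.catalysts] + [BACKGROUND_LABEL]
        if self.has_artefact:
            out.append(ARTEFACT_LABEL)
        return out

    @property
    def roles(self) -> list[str]:
        out = ["catalyst"] * len(self.catalysts) + ["background"]
        if self.has_artefact:
            out.append("artefact")
        return out

    def initial_frequencies(self) -> np.ndarray:
        freqs = list(self.p0) + [max(self.background_p0, 0.0)]
        if self.has_artefact:
            freqs.append(self.artefact_p0)
        return np.asarray(freqs, dtype=float)


@dataclass
class Trajectory:
    """Round-by-round frequency history of one selection run.

    ``freqs`` has shape (n_rounds + 1, n_species); row 0 is the initial
    pool.  ``taus`` and ``mean_recovery`` have one entry per round.
    """

    labels: list[str]
    roles: list[str]
    taus: np.ndarray
    freqs: np.ndarray
    mean_recovery: np.ndarray

    @property
    def n_rounds(self) -> int:
        return self.freqs.shape[0] - 1

    def frequency(self, label: str) -> np.ndarray:
        """Frequency series (rounds 0..n) of one species."""
        return self.freqs[:, self.labels.index(label)]

    def enrichment(self, label: str) -> np.ndarray:
        """Per-round enrichment E(n) = p(n)/p(n-1) of one species (NaN where p(n-1)=0)."""
        p = self.frequency(label)
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(p[:-1] > 0, p[1:] / p[:-1], np.nan)

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: one row per (round, species)."""
        records = []
        for n in range(self.freqs.shape[0]):
            tau = np.nan if n == 0 else self.taus[n - 1]
            rbar = np.nan if n == 0 else self.mean_recovery[n - 1]
            for j, label in enumerate(self.labels):
                prev = self.freqs[n - 1, j] if n > 0 else np.nan
                enr = self.freqs[n, j] / prev if n > 0 and prev > 0 else np.nan
                records.append(
                    {
                        "round": n,
                        "tau": tau,
                        "species": label,
                        "role": self.roles[j],
                        "frequency": self.freqs[n, j],
                        "enrichment": enr,
                        "mean_recovery": rbar,
                    }
                )
        return pd.DataFrame.from_records(records)


def species_recovery_probabilities(pool: SpeciesPool, tau: float) -> np.ndarray:
    """Recovery probability of every pool species at scaled time tau.

    Order matches ``pool.labels``: catalysts, background, then the
    artefact if present.  The artefact entry equals ``Rart`` for every
    tau — artefacts are captured by the separation step itself, not by
    reacting.
    """
    back = ReactionParams(BACKGROUND_LABEL, A=1.0, k=pool.kback)
    R = [recovery_probability(c, pool.Q, tau) for c in pool.catalysts]
    R.append(recovery_probability(back, pool.Q, tau))
    if pool.has_artefact:
        R.append(pool.artefact_Rart)
    return np.asarray(R, dtype=float)


def round_update(freqs: np.ndarray, R: np.ndarray) -> tuple[np.ndarray, float]:
    """One selection round: multiply by recovery probabilities and renormalize.

    Returns the posterior frequencies and the mean recovery R_mean.
    """
    freqs = np.asarray(freqs, dtype=float)
    R = np.asarray(R, dtype=float)
    if freqs.shape != R.shape:
        raise ValueError("freqs and R must have matching shapes")
    r_mean = float(freqs @ R)
    if r_mean <= 0.0:
        raise DegenerateRoundError("mean recovery probability is zero: no sequence recovered")
    out = freqs * R / r_mean
    return out / out.sum(), r_mean


def run_selection(pool: SpeciesPool, schedule: TauSchedule, n_rounds: int) -> Trajectory:
    """Run the frequency recursion for ``n_rounds`` rounds of selection."""
    taus = schedule.expand(n_rounds)
    freqs = np.empty((n_rounds + 1, len(pool.labels)))
    freqs[0] = pool.initial_frequencies()
    rbar = np.empty(n_rounds)
    for n, tau in enumerate(taus, start=1):
        R = species_recovery_probabilities(pool, tau)
        freqs[n], rbar[n - 1] = round_update(freqs[n - 1], R)
    return Trajectory(pool.labels, pool.roles, taus, freqs, rbar)


# ---------------------------------------------------------------------------
# Counter-selection for cofactor-dependent ribozymes

COFACTOR_MODES = ("constitutive", "dependent", "leaky")


@dataclass(frozen=True)
class CofactorSpecies:
    """A catalyst classified by how it behaves without the cofactor.

    constitutive — same (A, k) with and without the cofactor.
    dependent    — strictly cofactor-dependent: behaves as a background
                   sequence (A = 1, rate kback) without it.
    leaky        — retains amplitude but reacts at ``k * leak_factor``
                   (default one half) without the cofactor.
    """

    label: str
    A: float
    k: float
    mode: str
    leak_factor: float = 0.5

    def __post_init__(self) -> None:
        ReactionParams(self.label, self.A, self.k)  # reuse validation
        if self.mode not in COFACTOR_MODES:
            raise ValueError(f"mode must be one of {COFACTOR_MODES}, got {self.mode!r}")
        if not (0.0 < self.leak_factor < 1.0):
            raise ValueError("leak_factor must be in (0, 1)")

    def params_with(self) -> ReactionParams:
        return ReactionParams(self.label, self.A, self.k)

    def params_without(self, kback: float) -> ReactionParams:
        if self.mode == "constitutive":
            return ReactionParams(self.label, self.A, self.k)
        if self.mode == "dependent":
            return ReactionParams(self.label, 1.0, kback)
        return ReactionParams(self.label, self.A, self.k * self.leak_factor)


@dataclass
class CofactorPool:
    """Species pool for a counter-selection experiment."""

    species: Sequence[CofactorSpecies]
    p0: Sequence[float]
    Q: float = 0.2
    kback: float = 0.001

    def __post_init__(self) -> None:
        self.species = tuple(self.species)
        self.p0 = tuple(float(p) for p in self.p0)
        if len(self.species) != len(self.p0):
            raise ValueError("need one initial frequency per species")
        if any(p < 0 for p in self.p0):
            raise ValueError("initial frequencies must be >= 0")
        if sum(self.p0) > 1 + 1e-12:
            raise ValueError("initial frequencies exceed 1")

    @property
    def labels(self) -> list[str]:
        return [s.label for s in self.species] + [BACKGROUND_LABEL]

    @property
    def roles(self) -> list[str]:
        return ["catalyst"] * len(self.species) + ["background"]

    def initial_frequencies(self) -> np.ndarray:
        return np.asarray(list(self.p0) + [1.0 - sum(self.p0)], dtype=float)


def counter_selection_pass_probability(
    species: CofactorSpecies,
    Q: float,
    kback: float,
    tau_counter: float,
    tau_positive: float,
) -> float:
    """Probability of surviving one counter-selection round.

    Counter step first (discard anything recovered without the
    cofactor), then positive step:
    (1 - R_without(tau_counter)) * R_with(tau_positive).
    The two steps may use different stringencies.
    """
    r_without = recovery_probability(species.params_without(kback), Q, tau_counter)
    r_with = recovery_probability(species.params_with(), Q, tau_positive)
    return (1.0 - r_without) * r_with


def _background_pass_probability(Q, kback, tau_counter, tau_positive) -> float:
    back = ReactionParams(BACKGROUND_LABEL, A=1.0, k=kback)
    return (1.0 - recovery_probability(back, Q, tau_counter)) * recovery_probability(
        back, Q, tau_positive
    )


def run_counter_selection(
    pool: CofactorPool,
    counter_schedule: TauSchedule,
    positive_schedule: TauSchedule,
    n_rounds: int,
) -> Trajectory:
    """Multi-round counter-selection using per-round pass probabilities."""
    taus_c = counter_schedule.expand(n_rounds)
    taus_p = positive_schedule.expand(n_rounds)
    freqs = np.empty((n_rounds + 1, len(pool.labels)))
    freqs[0] = pool.initial_frequencies()
    rbar = np.empty(n_rounds)
    for n in range(1, n_rounds + 1):
        tc, tp = taus_c[n - 1], taus_p[n - 1]
        R = np.asarray(
            [
                counter_selection_pass_probability(s, pool.Q, pool.kback, tc, tp)
                for s in pool.species
            ]
            + [_background_pass_probability(pool.Q, pool.kback, tc, tp)]
        )
        freqs[n], rbar[n - 1] = round_update(freqs[n - 1], R)
    # the positive-step tau is the stringency knob; record it
    return Trajectory(pool.labels, pool.roles, taus_p, freqs, rbar)


# ---------------------------------------------------------------------------
# Trajectory queries


def detect_dominant(trajectory: Trajectory, round: int) -> str:
    """Label of the most frequent species at a round; exact near-ties raise."""
    if not (0 <= round <= trajectory.n_rounds):
        raise ValueError(f"round {round} outside trajectory (0..{trajectory.n_rounds})")
    row = trajectory.freqs[round]
    order = np.argsort(row)
    top, second = row[order[-1]], row[order[-2]]
    if np.isclose(top, second, rtol=1e-9, atol=0.0):
        raise TieError(f"no unique dominant species at round {round}")
    return trajectory.labels[int(order[-1])]


def detect_crossings(trajectory: Trajectory) -> list[tuple[int, tuple[str, str]]]:
    """Rounds at which the frequency order of a catalyst pair flips.

    Returns (round, (label_a, label_b)) for every strict sign change of
    p_a - p_b between consecutive rounds; exact ties do not count as
    crossings.
    """
    idx = [j for j, role in enumerate(trajectory.roles) if role == "catalyst"]
    out: list[tuple[int, tuple[str, str]]] = []
    for ai in range(len(idx)):
        for bi in range(ai + 1, len(idx)):
            a, b = idx[ai], idx[bi]
            d = trajectory.freqs[:, a] - trajectory.freqs[:, b]
            s = np.sign(d)
            flips = np.nonzero(s[:-1] * s[1:] < 0)[0] + 1
            out.extend(
                (int(n), (trajectory.labels[a], trajectory.labels[b])) for n in flips
            )
    return sorted(out)
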