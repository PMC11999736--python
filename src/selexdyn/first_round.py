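"""Stochastic survival of rare functional sequences in the first round.

A random library samples sequence space so sparsely that each functional
sequence is typically present as a single DNA molecule.  After limited
PCR and transcription the mean RNA copy number per library sequence is
``c = N_RNA / N_DNA``; a given functional sequence enters the first round
with a Poisson-distributed number of copies, so the probability that at
least one copy both enters and is recovered is ``1 - exp(-QA*c)``.  With
``QA = 0.1`` (Q = 0.2, A = 0.5) about 30 RNA copies per DNA are needed to
recover 95% of the functional sequences.

Once ``N`` copies enter a round, the number recovered is binomial
(N, R(tau)).  At high stringency (small tau) the binomial mode drops to
zero even while the mean stays positive: the single most likely outcome
is to lose the sequence entirely.  This is the quantitative reason the
first round is run at low stringency.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "FirstRoundSetup",
    "survival_probability",
    "min_copies_for_confidence",
    "mean_copy_number",
    "recovery_count_pmf",
    "recovery_count_mode",
    "sample_recovery_count",
    "stochastic_enrichment",
]


@dataclass
class FirstRoundSetup:
    """Copy number and per-copy recovery probability of one functional sequence.

    Owns a private seeded random stream so that interleaved draws from
    other generators cannot perturb reproducibility.
    """

    N: int
    R: float
    seed: int | None = None
    _rng: np.random.Generator = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if self.N < 0 or self.N != int(self.N):
            raise ValueError(f"copy count N must be a nonnegative integer, got {self.N!r}")
        self.N = int(self.N)
        if not (0.0 <= self.R <= 1.0):
            raise ValueError(f"recovery probability R must be in [0, 1], got {self.R!r}")
        self._rng = np.random.default_rng(self.seed)


def survival_probability(c: float, QA: float = 1.0) -> float:
    """Probability 1 - exp(-QA*c) that >= 1 copy survives the first round.

    ``c`` is the mean copy number per library sequence and ``QA`` the
    combined recovery-times-amplitude probability; ``QA = 1`` gives the
    amplification-only case (does the sequence enter the round at all).
    """
    if c < 0:
        raise ValueError(f"mean copy number c must be >= 0, got {c!r}")
    if not (0.0 <= QA <= 1.0):
        raise ValueError(f"QA must be in [0, 1], got {QA!r}")
    return -math.expm1(-QA * c)


def min_copies_for_confidence(confidence: float, QA: float = 1.0) -> int:
    """Smallest integer mean copy number c with survival >= ``confidence``.

    Uses an integer search around the real-valued solution
    ``-ln(1-confidence)/QA`` rather than a bare ceiling, so exact
    boundaries do not produce off-by-one results.
    """
    if not (0.0 < confidence < 1.0):
        raise ValueError(f"confidence must be in (0, 1), got {confidence!r}")
    if not (0.0 < QA <= 1.0):
        raise ValueError(f"QA must be in (0, 1], got {QA!r}")
    c = max(1, math.floor(-math.log1p(-confidence) / QA))
    while survival_probability(c, QA) < confidence:
        c += 1
    while c > 1 and survival_probability(c - 1, QA) >= confidence:
        c -= 1
    return c


def mean_copy_number(n_rna: float, n_dna: float) -> float:
    """Mean RNA copies per library DNA sequence, c = N_RNA / N_DNA."""
    if n_dna <= 0:
        raise ValueError(f"n_dna must be > 0, got {n_dna!r}")
    if n_rna < 0:
        raise ValueError(f"n_rna must be >= 0, got {n_rna!r}")
    return n_rna / n_dna


def recovery_count_pmf(setup: FirstRoundSetup) -> np.ndarray:
    """Binomial(N, R) mass function over the recovered copy count 0..N."""
    counts = np.arange(setup.N + 1)
    return stats.binom.pmf(counts, setup.N, setup.R)


def recovery_count_mode(N: int, R: float) -> int:
    """Most likely number of recovered copies (argmax of binomial(N, R)).

    Adjacent ties are broken toward the smaller count, the conservative
    choice when the mode is used to flag probable loss of a sequence.
    """
    pmf = recovery_count_pmf(FirstRoundSetup(N=N, R=R))
    return int(np.argmax(pmf))  # argmax returns the first (smaller) tie


def sample_recovery_count(setup: FirstRoundSetup) -> int:
    """One reproducible draw of the recovered copy count from binomial(N, R)."""
    return int(setup._rng.binomial(setup.N, setup.R))


def stochastic_enrichment(Nrec: int, N: int, Rback: float) -> float:
    """Realized enrichment E = Nrec / (N * Rback) of a rare catalyst.

    With ``Nrec`` equal to its mean ``N * Rcat`` this reduces to the
    deterministic ``Rcat / Rback``; with ``Nrec = 0`` the sequence is lost.
    """
    if N <= 0:
        raise ValueError(f"N must be > 0, got {N!r}")
    if Rback <= 0:
        raise ValueError(f"Rback must be > 0, got {Rback!r}")
    if Nrec < 0 or Nrec > N:
        raise ValueError(f"Nrec must be in 0..N, got {Nrec!r}")
    return Nrec / (N * Rback)
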