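"""Cluster evolution with threshold-gated beneficial mutations.

Sequencing a selection experiment reveals clusters of related sequences,
each descended from one founder molecule in the initial pool.  Because
near-matches to a functional structure are vastly more common than exact
matches, founders are usually suboptimal, and PCR copying errors can
later produce the missing beneficial mutations within a cluster.

Each cluster carries three sequence classes at mutational distance
m = 0, 1, 2 from the optimum, with rates and amplitudes ordered
k0 >= k1 >= k2 and A0 >= A1 >= A2.  A round applies the usual selection
update per class,

    p'_im(n) = p_im(n-1) * R_im(tau) / R_mean,

then moves a fraction ``pben`` of mass one class upward (2 -> 1, 1 -> 0),
but only once the source class is frequent enough for a beneficial
mutation to be statistically expected among the N_tot * C copies made by
PCR: the gate opens when p' exceeds ``pmin = 1 / (N_tot * C * pben)``.

In the high-stringency limit R is proportional to A*k, so A*k acts as
the fitness.  Gated mutations make cluster fitnesses change in
mid-experiment, which is why final cluster frequencies correlate poorly
with fitness while per-round enrichment factors correlate strongly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as _sstats

from .errors import DegenerateRoundError
from .selection import TauSchedule

__all__ = [
    "ClusterRanges",
    "ClusterParams",
    "ClusterState",
    "MutationModel",
    "ClusterTrajectory",
    "CorrelationReport",
    "generate_clusters",
    "beneficial_mutation_probability",
    "amplification_factor",
    "mutation_threshold",
    "cluster_round_update",
    "run_cluster_simulation",
    "cluster_mean_fitness",
    "enrichment_series",
    "fitness_correlation_report",
]

N_LEVELS = 3  # mutational distance classes m = 0, 1, 2


@dataclass(frozen=True)
class ClusterRanges:
    """Sampling ranges for random cluster parameters.

    Defaults: founder-optimum rate k0 uniform in [0.5, 1.0] (so the best
    catalyst defines kcat = 1), amplitude A0 uniform in [0.8, 1.0], each
    mutational step divides the rate by a uniform [2, 4] factor and
    subtracts a uniform [0, 0.2] amplitude penalty.
    """

    k0: tuple[float, float] = (0.5, 1.0)
    A0: tuple[float, float] = (0.8, 1.0)
    rate_divisor: tuple[float, float] = (2.0, 4.0)
    amplitude_drop: tuple[float, float] = (0.0, 0.2)


@dataclass
class ClusterParams:
    """Rates ``k`` and amplitudes ``A``, each (n_clusters, 3), level-ordered."""

    k: np.ndarray
    A: np.ndarray

    def __post_init__(self) -> None:
        self.k = np.asarray(self.k, dtype=float)
        self.A = np.asarray(self.A, dtype=float)
        if self.k.shape != self.A.shape or self.k.ndim != 2 or self.k.shape[1] != N_LEVELS:
            raise ValueError(f"k and A must both be (n_clusters, {N_LEVELS}) arrays")
        if np.any(self.k <= 0):
            raise ValueError("all rates must be > 0")
        if np.any(self.A <= 0) or np.any(self.A > 1):
            raise ValueError("amplitudes must be in (0, 1]")
        if np.any(np.diff(self.k, axis=1) > 1e-12) or np.any(np.diff(self.A, axis=1) > 1e-12):
            raise ValueError("levels must satisfy k0 >= k1 >= k2 and A0 >= A1 >= A2")

    @property
    def n_clusters(self) -> int:
        return self.k.shape[0]

    @property
    def fitness(self) -> np.ndarray:
        """Per-level fitness A*k, shape (n_clusters, 3)."""
        return self.A * self.k


@dataclass
class ClusterState:
    """Frequencies per cluster and level plus the background frequency."""

    p: np.ndarray
    pback: float

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=float)
        if self.p.ndim != 2 or self.p.shape[1] != N_LEVELS:
            raise ValueError(f"p must be (n_clusters, {N_LEVELS})")
        if np.any(self.p < 0) or self.pback < 0:
            raise ValueError("frequencies must be >= 0")
        total = self.p.sum() + self.pback
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"frequencies sum to {total!r}, not 1")

    def cluster_frequencies(self) -> np.ndarray:
        return self.p.sum(axis=1)


@dataclass(frozen=True)
class MutationModel:
    """PCR copying-error model governing when beneficial mutations kick in.

    ``pben`` is the per-copy probability that a beneficial mutation is
    produced (approximately m1 * u / 3 for m1 correctable sites at error
    rate u per base); ``pmin`` is the frequency above which the expected
    number of beneficially mutated copies N_tot * C * p * pben exceeds 1.
    Defaults are the package's worked-example values pben = 1e-4 and
    pmin = 1e-10; ``from_experiment`` derives pmin from (Ntot, C, pben).
    """

    pben: float = 1e-4
    pmin: float = 1e-10
    u: float = 1e-5
    lam: float = 1.6
    ncyc: int = 14
    Ntot: float | None = None

    def __post_init__(self) -> None:
        if self.pben < 0 or self.pmin < 0:
            raise ValueError("pben and pmin must be >= 0")
        if not (0.0 < self.u < 1.0):
            raise ValueError("error rate u must be in (0, 1)")
        if self.lam <= 1.0 or self.ncyc < 0:
            raise ValueError("require amplification lam > 1 and ncyc >= 0")

    @classmethod
    def from_experiment(cls, Ntot: float, lam: float, ncyc: int, pben: float) -> "MutationModel":
        C = amplification_factor(lam, ncyc)
        return cls(pben=pben, pmin=mutation_threshold(Ntot, C, pben), lam=lam, ncyc=ncyc, Ntot=Ntot)


def beneficial_mutation_probability(m1: int, u: float, s: int) -> float:
    """Probability that one PCR copy gains a beneficial mutation.

    With m1 mismatched conserved sites out of s, a copy is improved if
    exactly one of the m1 sites reverts (probability u/3 each) and no
    other site mutates:
    m1 (u/3) (1 - u/3)^(m1-1) (1 - u)^(s-m1), approximately m1*u/3.
    """
    if not (0 <= m1 <= s):
        raise ValueError("require 0 <= m1 <= s")
    if not (0.0 < u < 1.0):
        raise ValueError("error rate u must be in (0, 1)")
    if m1 == 0:
        return 0.0
    return m1 * (u / 3.0) * (1.0 - u / 3.0) ** (m1 - 1) * (1.0 - u) ** (s - m1)


def amplification_factor(lam: float, ncyc: int) -> float:
    """Copies per input molecule after ncyc PCR cycles, C = lam**ncyc."""
    if lam <= 0:
        raise ValueError("lam must be > 0")
    if ncyc < 0:
        raise ValueError("ncyc must be >= 0")
    return lam**ncyc


def mutation_threshold(Ntot: float, C: float, pben: float) -> float:
    """Frequency pmin = 1/(Ntot*C*pben) above which mutations are expected."""
    if Ntot <= 0 or C <= 0:
        raise ValueError("Ntot and C must be > 0")
    if pben == 0:
        return math.inf
    if pben < 0:
        raise ValueError("pben must be >= 0")
    return 1.0 / (Ntot * C * pben)


def generate_clusters(
    n_clusters: int,
    seed: int | None = None,
    ranges: ClusterRanges = ClusterRanges(),
) -> ClusterParams:
    """Draw reproducible random (k, A) parameters for ``n_clusters`` clusters."""
    if n_clusters < 1:
        raise ValueError("n_clusters must be >= 1")
    rng = np.random.default_rng(seed)
    k0 = rng.uniform(*ranges.k0, n_clusters)
    A0 = rng.uniform(*ranges.A0, n_clusters)
    z1 = rng.uniform(*ranges.rate_divisor, n_clusters)
    z2 = rng.uniform(*ranges.rate_divisor, n_clusters)
    a1 = rng.uniform(*ranges.amplitude_drop, n_clusters)
    a2 = rng.uniform(*ranges.amplitude_drop, n_clusters)
    k = np.column_stack([k0, k0 / z1, k0 / z1 / z2])
    A = np.column_stack([A0, A0 - a1, A0 - a1 - a2])
    if np.any(A <= 0):  # only possible with user-widened ranges
        raise ValueError("amplitude_drop range drives an amplitude below zero")
    return ClusterParams(k=k, A=A)


def _recovery(params: ClusterParams, tau: float, Q: float) -> np.ndarray:
    return -Q * params.A * np.expm1(-tau * params.k)


def cluster_round_update(
    state: ClusterState,
    params: ClusterParams,
    tau: float,
    Q: float,
    kback: float,
    model: MutationModel,
) -> tuple[ClusterState, float]:
    """One round: selection on every level, then gated mutation flow.

    The mutation gate tests the post-selection frequencies p' (mass
    moves 2 -> 1 where p'_2 > pmin and 1 -> 0 where p'_1 > pmin); the
    update is a within-cluster stochastic-matrix reshuffle, so total
    frequency is conserved to rounding.
    """
    if tau < 0:
        raise ValueError("tau must be >= 0")
    R = _recovery(params, tau, Q)
    Rback = -Q * math.expm1(-tau * kback)
    r_mean = float((state.p * R).sum() + state.pback * Rback)
    if r_mean <= 0.0:
        raise DegenerateRoundError("mean recovery probability is zero: no sequence recovered")
    p = state.p * R / r_mean
    pback = state.pback * Rback / r_mean

    eps1 = np.where(p[:, 1] > model.pmin, model.pben, 0.0)
    eps2 = np.where(p[:, 2] > model.pmin, model.pben, 0.0)
    new = np.empty_like(p)
    new[:, 0] = p[:, 0] + eps1 * p[:, 1]
    new[:, 1] = (1.0 - eps1) * p[:, 1] + eps2 * p[:, 2]
    new[:, 2] = (1.0 - eps2) * p[:, 2]

    total = new.sum() + pback
    return ClusterState(p=new / total, pback=pback / total), r_mean


@dataclass
class ClusterTrajectory:
    """History of a cluster simulation.

    ``p`` has shape (n_rounds + 1, n_clusters, 3); round 0 is the
    initial pool.
    """

    p: np.ndarray
    pback: np.ndarray
    taus: np.ndarray
    params: ClusterParams
    model: MutationModel

    @property
    def n_rounds(self) -> int:
        return self.p.shape[0] - 1

    def cluster_frequencies(self) -> np.ndarray:
        """(n_rounds + 1, n_clusters) total frequency of each cluster."""
        return self.p.sum(axis=2)

    def state(self, round: int) -> ClusterState:
        return ClusterState(p=self.p[round], pback=float(self.pback[round]))


def run_cluster_simulation(
    params: ClusterParams,
    model: MutationModel,
    schedule: TauSchedule,
    n_rounds: int,
    init: str = "suboptimal",
    founder_frequency: float = 1e-14,
    Q: float = 0.2,
    kback: float = 0.001,
) -> ClusterTrajectory:
    """Run a multi-round cluster selection.

    ``init='suboptimal'`` founds every cluster with its distance-2
    sequence (the generic case: near-matches dominate the pool);
    ``init='optimal'`` founds with the distance-0 sequence, which paired
    with ``model.pben = 0`` gives the mutation-free control experiment.
    """
    if init not in ("suboptimal", "optimal"):
        raise ValueError("init must be 'suboptimal' or 'optimal'")
    n = params.n_clusters
    p0 = np.zeros((n, N_LEVELS))
    p0[:, 2 if init == "suboptimal" else 0] = founder_frequency
    state = ClusterState(p=p0, pback=1.0 - p0.sum())
    taus = schedule.expand(n_rounds)
    p_hist = np.empty((n_rounds + 1, n, N_LEVELS))
    pback_hist = np.empty(n_rounds + 1)
    p_hist[0], pback_hist[0] = state.p, state.pback
    for i, tau in enumerate(taus, start=1):
        state, _ = cluster_round_update(state, params, tau, Q, kback, model)
        p_hist[i], pback_hist[i] = state.p, state.pback
    return ClusterTrajectory(p=p_hist, pback=pback_hist, taus=taus, params=params, model=model)


def cluster_mean_fitness(state: ClusterState, params: ClusterParams, cluster: int | None = None):
    """Frequency-weighted mean fitness A*k within each cluster (or one cluster)."""
    totals = state.cluster_frequencies()
    if cluster is not None:
        if totals[cluster] <= 0:
            raise ValueError(f"cluster {cluster} has zero frequency")
        return float((state.p[cluster] * params.fitness[cluster]).sum() / totals[cluster])
    if np.any(totals <= 0):
        raise ValueError("all clusters must have positive frequency")
    return (state.p * params.fitness).sum(axis=1) / totals


def enrichment_series(trajectory: ClusterTrajectory, cluster: int) -> np.ndarray:
    """Per-round enrichment E(n) = p(n)/p(n-1) of one cluster, rounds 1..n."""
    p = trajectory.cluster_frequencies()[:, cluster]
    if np.any(p <= 0):
        raise ValueError("cluster frequency must stay positive for an enrichment series")
    return p[1:] / p[:-1]


@dataclass(frozen=True)
class CorrelationReport:
    """Correlations of cluster mean fitness with frequency and enrichment.

    Keys of both mappings: ``log10_frequency``, ``enrichment_current``
    (E at the report round) and ``enrichment_next`` (E one round later,
    present only if the trajectory extends that far).  ``degenerate``
    flags zero-variance inputs for which a correlation is undefined.
    """

    round: int
    pearson: dict
    spearman: dict
    degenerate: bool


def fitness_correlation_report(trajectory: ClusterTrajectory, round: int) -> CorrelationReport:
    """Correlate cluster fitnesses at a round with frequencies and enrichment."""
    if not (2 <= round <= trajectory.n_rounds):
        raise ValueError(f"round must be in 2..{trajectory.n_rounds}")
    fitness = cluster_mean_fitness(trajectory.state(round), trajectory.params)
    freqs = trajectory.cluster_frequencies()
    covariates = {
        "log10_frequency": np.log10(freqs[round]),
        "enrichment_current": freqs[round] / freqs[round - 1],
    }
    if round + 1 <= trajectory.n_rounds:
        covariates["enrichment_next"] = freqs[round + 1] / freqs[round]

    degenerate = float(np.ptp(fitness)) == 0.0
    pearson, spearman = {}, {}
    for key, x in covariates.items():
        if degenerate or float(np.ptp(x)) == 0.0:
            degenerate = True
            pearson[key] = spearman[key] = float("nan")
            continue
        pearson[key] = float(_sstats.pearsonr(fitness, x).statistic)
        spearman[key] = float(_sstats.spearmanr(fitness, x).statistic)
    return CorrelationReport(round=round, pearson=pearson, spearman=spearman, degenerate=degenerate)
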