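"""Combinatorics of sequences matching a ribozyme structure constraint.

A ribozyme motif is abstracted as a set of constraints on a window of
``Lstr`` nucleotides: ``s`` conserved sites that each require one
specific base, and ``b`` base pairs whose two (variable) sides must form
a canonical pair (GC, CG, AU, UA, GU or UG).  For uniform random
sequence the probability of satisfying one conserved site is 1/4 and one
pair 6/16 = 3/8, so an exact match in a single frame has probability

    q = (1/4)**s * (3/8)**b.

The motif may be split by break points into ``M`` modules that can move
independently (insertions at break points are tolerated), so within a
randomized region of length ``Lran`` it can be placed in

    W = C(Lran - Lstr + M, M)

frames (gaps before/between/after modules; a motif anchored at the 5'
end loses the leading gap, giving C(Lran - Lstr + M - 1, M - 1)).
Treating frames as independent, the chance of a match in at least one
frame is ``PW = 1 - (1 - q)**W ~ W*q``.

The mutational distance ``m`` of a sequence is the smallest number of
violated constraints over all frames.  Near-matches are vastly more
common than exact matches; the distributions below quantify by how
much, and the scanners measure the same quantity directly on sequences
so the independence approximation can be tested by brute force.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "StructureConstraint",
    "DistanceDistribution",
    "parse_structure",
    "load_structure",
    "format_structure",
    "exact_match_probability",
    "frame_count",
    "multi_frame_exact_probability",
    "mismatch_joint_probability",
    "single_frame_distribution",
    "multi_frame_distribution",
    "min_distance_scan",
    "scan_pool",
    "sample_min_distance_distribution",
    "exhaustive_distance_distribution",
    "encode_sequence",
]

RNA_BASES = "ACGU"
_BASE_CODE = {"A": 0, "C": 1, "G": 2, "U": 3, "T": 3}
# with A=0,C=1,G=2,U=3 the canonical pairs are exactly those whose codes
# sum to 3 (AU, UA, CG, GC) or 5 (GU, UG)
_CANONICAL_SUMS = (3, 5)


def encode_sequence(sequence: str) -> np.ndarray:
    """Encode an RNA string as int8 codes (A=0, C=1, G=2, U=3); T maps to U."""
    try:
        return np.asarray([_BASE_CODE[c] for c in sequence.upper()], dtype=np.int8)
    except KeyError as exc:
        raise ValueError(f"invalid base {exc.args[0]!r}; alphabet is A, C, G, U (or T)") from None


def _is_canonical(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    s = x.astype(np.int16) + y
    return (s == 3) | (s == 5)


@dataclass
class StructureConstraint:
    """Sequence/pairing constraints of a ribozyme motif.

    Coordinates are 1-based over 1..length.  ``conserved`` maps position
    to its required base; ``pairs`` holds unordered position pairs whose
    two sides are both variable (a conserved base inside a stem is
    entered as two conserved sites instead — the sequence constraint
    already enforces the pairing, so it must not be double counted).
    ``breaks`` lists positions after which a module boundary falls;
    pseudoknotted pairs need no special treatment and may cross breaks.
    """

    length: int
    conserved: dict[int, str] = field(default_factory=dict)
    pairs: tuple[tuple[int, int], ...] = ()
    breaks: tuple[int, ...] = ()
    anchored5: bool = False
    name: str = "structure"

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError("structure length must be >= 1")
        conserved = {}
        for pos, base in dict(self.conserved).items():
            pos = int(pos)
            base = str(base).upper().replace("T", "U")
            if not (1 <= pos <= self.length):
                raise ValueError(f"conserved position {pos} outside 1..{self.length}")
            if base not in RNA_BASES:
                raise ValueError(f"invalid conserved base {base!r} at position {pos}")
            conserved[pos] = base
        self.conserved = dict(sorted(conserved.items()))

        seen: set[int] = set()
        pairs = []
        for i, j in self.pairs:
            i, j = int(i), int(j)
            if i == j:
                raise ValueError(f"pair {i}:{j} uses one position twice")
            i, j = min(i, j), max(i, j)
            if not (1 <= i and j <= self.length):
                raise ValueError(f"pair {i}:{j} outside 1..{self.length}")
            for p in (i, j):
                if p in self.conserved:
                    raise ValueError(
                        f"position {p} is both conserved and paired; enter a conserved "
                        "stem base as two conserved sites instead"
                    )
                if p in seen:
                    raise ValueError(f"position {p} appears in two pairs")
                seen.add(p)
            pairs.append((i, j))
        self.pairs = tuple(sorted(pairs))

        breaks = tuple(sorted(int(p) for p in self.breaks))
        if len(set(breaks)) != len(breaks):
            raise ValueError("duplicate break points")
        if any(not (1 <= p <= self.length - 1) for p in breaks):
            raise ValueError(f"break points must lie in 1..{self.length - 1}")
        self.breaks = breaks
        if self.s + 2 * self.b > self.length:
            raise ValueError("more constrained positions than structure length")

    @property
    def s(self) -> int:
        """Number of conserved sites."""
        return len(self.conserved)

    @property
    def b(self) -> int:
        """Number of base-pair constraints."""
        return len(self.pairs)

    @property
    def n_modules(self) -> int:
        return len(self.breaks) + 1

    @property
    def modules(self) -> list[tuple[int, int]]:
        """1-based inclusive (start, end) of each module."""
        bounds = (0,) + self.breaks + (self.length,)
        return [(bounds[i] + 1, bounds[i + 1]) for i in range(self.n_modules)]

    def module_of(self, pos: int) -> int:
        for m, (start, end) in enumerate(self.modules):
            if start <= pos <= end:
                return m
        raise ValueError(f"position {pos} outside structure")

    def frame_count(self, Lran: int) -> int:
        return frame_count(Lran, self.length, self.n_modules, self.anchored5)


# ---------------------------------------------------------------------------
# Directive file format


def parse_structure(text: str) -> StructureConstraint:
    """Parse the line-oriented directive format into a StructureConstraint.

    Directives: ``NAME``, ``LENGTH``, ``CONS pos=base ...``,
    ``PAIR i:j ...``, ``BREAK pos ...``, ``ANCHOR5 true|false``;
    ``#`` starts a comment.  Coordinates are 1-based.
    """
    name = "structure"
    length = None
    conserved: dict[int, str] = {}
    pairs: list[tuple[int, int]] = []
    breaks: list[int] = []
    anchored5 = False
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        key, *args = line.split()
        key = key.upper()
        try:
            if key == "NAME":
                name = " ".join(args)
            elif key == "LENGTH":
                (length,) = args
                length = int(length)
            elif key == "CONS":
                for item in args:
                    pos, base = item.split("=")
                    pos = int(pos)
                    if pos in conserved:
                        raise ValueError(f"position {pos} conserved twice")
                    conserved[pos] = base
            elif key == "PAIR":
                for item in args:
                    i, j = item.split(":")
                    pairs.append((int(i), int(j)))
            elif key == "BREAK":
                breaks.extend(int(p) for p in args)
            elif key == "ANCHOR5":
                (flag,) = args
                if flag.lower() not in ("true", "false"):
                    raise ValueError(f"ANCHOR5 takes true or false, got {flag!r}")
                anchored5 = flag.lower() == "true"
            else:
                raise ValueError(f"unknown directive {key!r}")
        except ValueError as exc:
            raise ValueError(f"line {lineno}: {exc}") from None
    if length is None:
        raise ValueError("missing LENGTH directive")
    return StructureConstraint(
        length=length,
        conserved=conserved,
        pairs=tuple(pairs),
        breaks=tuple(breaks),
        anchored5=anchored5,
        name=name,
    )


def format_structure(structure: StructureConstraint) -> str:
    """Write a StructureConstraint back to the directive dialect (stable order)."""
    lines = [f"NAME {structure.name}", f"LENGTH {structure.length}"]
    if structure.conserved:
        lines.append("CONS " + " ".join(f"{p}={b}" for p, b in structure.conserved.items()))
    if structure.pairs:
        lines.append("PAIR " + " ".join(f"{i}:{j}" for i, j in structure.pairs))
    if structure.breaks:
        lines.append("BREAK " + " ".join(str(p) for p in structure.breaks))
    lines.append(f"ANCHOR5 {'true' if structure.anchored5 else 'false'}")
    return "\n".join(lines) + "\n"


def load_structure(path) -> StructureConstraint:
    with open(path) as fh:
        return parse_structure(fh.read())


# ---------------------------------------------------------------------------
# Closed-form frequencies


def exact_match_probability(s: int, b: int) -> float:
    """Probability q = (1/4)^s (3/8)^b of an exact match in one frame."""
    if s < 0 or b < 0:
        raise ValueError("s and b must be >= 0")
    return 0.25**s * 0.375**b


def frame_count(Lran: int, Lstr: int, M: int = 1, anchored5: bool = False) -> int:
    """Number of frames W in which an M-module motif fits a region of length Lran.

    The Lran - Lstr spare bases are distributed over the M + 1 gaps
    around and between the modules (all >= 0), giving
    C(Lran - Lstr + M, M); anchoring the first module at the 5' end
    forces the leading gap to zero, giving C(Lran - Lstr + M - 1, M - 1).
    With M = 1 the unanchored count reduces to the sliding-window
    Lran - Lstr + 1.
    """
    if M < 1:
        raise ValueError("M must be >= 1")
    if Lran < Lstr:
        raise ValueError(f"randomized length {Lran} shorter than structure {Lstr}")
    gap = Lran - Lstr
    if anchored5:
        return math.comb(gap + M - 1, M - 1)
    return math.comb(gap + M, M)


def multi_frame_exact_probability(q: float, W: int) -> tuple[float, float]:
    """(PW, Wq): exact-match probability over W independent frames.

    Returns both the exact ``1 - (1 - q)**W`` and the first-order
    approximation ``W*q`` that is customarily quoted.
    """
    if not (0.0 <= q <= 1.0):
        raise ValueError("q must be in [0, 1]")
    if W < 1:
        raise ValueError("W must be >= 1")
    return -math.expm1(W * math.log1p(-q)) if q < 1 else 1.0, W * q


def mismatch_joint_probability(m1: int, m2: int, s: int, b: int) -> float:
    """P(m1 conserved-site misses, m2 non-canonical pairs) for random sequence.

    Product of two binomials with per-site miss probabilities 3/4
    (conserved site) and 5/8 (pair).
    """
    if not (0 <= m1 <= s) or not (0 <= m2 <= b):
        raise ValueError("require 0 <= m1 <= s and 0 <= m2 <= b")
    return float(stats.binom.pmf(m1, s, 0.75) * stats.binom.pmf(m2, b, 0.625))


@dataclass(frozen=True)
class DistanceDistribution:
    """Probability vector over mutational distance m = 0..s+b.

    ``frames`` records the frame context: 1 for a single-frame
    distribution, W for the distribution of the best of W frames.
    ``kind`` distinguishes formula-based from measured distributions.
    """

    probs: np.ndarray
    frames: int = 1
    kind: str = "formula"

    def __post_init__(self) -> None:
        probs = np.asarray(self.probs, dtype=float)
        if np.any(probs < -1e-15):
            raise ValueError("distance probabilities must be >= 0")
        if abs(probs.sum() - 1.0) > 1e-9:
            raise ValueError(f"distance probabilities sum to {probs.sum()!r}, not 1")
        object.__setattr__(self, "probs", probs)

    def __len__(self) -> int:
        return len(self.probs)

    def __getitem__(self, m):
        return self.probs[m]

    @property
    def max_distance(self) -> int:
        return len(self.probs) - 1


def single_frame_distribution(s: int, b: int) -> DistanceDistribution:
    """Distribution of the mutational distance m = m1 + m2 in one frame.

    Convolution of binomial(s, 3/4) conserved-site misses with
    binomial(b, 5/8) pair misses; mass at 0 equals q exactly.
    """
    if s < 0 or b < 0:
        raise ValueError("s and b must be >= 0")
    p1 = stats.binom.pmf(np.arange(s + 1), s, 0.75)
    p2 = stats.binom.pmf(np.arange(b + 1), b, 0.625)
    probs = np.convolve(p1, p2)
    # pin the m=0 mass to q exactly and spread rounding error over the rest
    q = exact_match_probability(s, b)
    probs[0] = q
    tail = probs[1:].sum()
    if tail > 0:
        probs[1:] *= (1.0 - q) / tail
    return DistanceDistribution(probs, frames=1)


def multi_frame_distribution(single: DistanceDistribution, W: int) -> DistanceDistribution:
    """Distribution of the minimum distance over W independent frames.

    With tail g(m) = P(distance >= m in one frame), the best of W
    frames has P(m) = g(m)^W - g(m+1)^W; the m = 0 mass is
    1 - (1 - q)^W.
    """
    if W < 1:
        raise ValueError("W must be >= 1")
    if W == 1:
        return single
    g = np.concatenate([np.cumsum(single.probs[::-1])[::-1], [0.0]])
    g = np.minimum(g, 1.0)
    probs = g[:-1] ** W - g[1:] ** W
    return DistanceDistribution(probs / probs.sum(), frames=W)


# ---------------------------------------------------------------------------
# Brute-force scanners


def _placements(structure: StructureConstraint, Lran: int):
    """Yield per-module offset tuples (cumulative gaps, nondecreasing).

    Position p of module m maps to 0-based sequence index p - 1 + o[m].
    The number of tuples equals frame_count(Lran, Lstr, M, anchored5).
    """
    gap = Lran - structure.length
    M = structure.n_modules
    if structure.anchored5:
        if M == 1:
            yield (0,)
        else:
            for rest in itertools.combinations_with_replacement(range(gap + 1), M - 1):
                yield (0,) + rest
    else:
        yield from itertools.combinations_with_replacement(range(gap + 1), M)


def min_distance_scan(sequence, structure: StructureConstraint) -> int:
    """Smallest number of violated constraints over all frames.

    ``sequence`` is an RNA string (or an already-encoded int8 vector) of
    length >= Lstr.  Every module placement consistent with the break
    points (order preserving, non-overlapping, honouring 5' anchoring)
    is enumerated; the distance of a placement is the count of conserved
    sites with the wrong base plus the count of non-canonical pairs.
    """
    codes = encode_sequence(sequence) if isinstance(sequence, str) else np.asarray(sequence)
    if codes.ndim != 1:
        raise ValueError("expected a single sequence")
    if len(codes) < structure.length:
        raise ValueError(
            f"sequence length {len(codes)} shorter than structure length {structure.length}"
        )
    module_idx = {p: structure.module_of(p) for p in range(1, structure.length + 1)}
    cons = [(p, module_idx[p], _BASE_CODE[b]) for p, b in structure.conserved.items()]
    prs = [(i, module_idx[i], j, module_idx[j]) for i, j in structure.pairs]
    best = structure.s + structure.b
    for offs in _placements(structure, len(codes)):
        m = 0
        for p, mod, req in cons:
            if codes[p - 1 + offs[mod]] != req:
                m += 1
        for i, mi, j, mj in prs:
            si = codes[i - 1 + offs[mi]]
            sj = codes[j - 1 + offs[mj]]
            if (si + sj) not in _CANONICAL_SUMS:
                m += 1
        if m < best:
            best = m
            if best == 0:
                break
    return int(best)


def _module_constraint_arrays(structure: StructureConstraint):
    """Per-module constraint arrays, or None if a pair crosses modules."""
    M = structure.n_modules
    cons_pos: list[list[int]] = [[] for _ in range(M)]
    cons_req: list[list[int]] = [[] for _ in range(M)]
    pair_i: list[list[int]] = [[] for _ in range(M)]
    pair_j: list[list[int]] = [[] for _ in range(M)]
    for p, b in structure.conserved.items():
        m = structure.module_of(p)
        cons_pos[m].append(p - 1)
        cons_req[m].append(_BASE_CODE[b])
    for i, j in structure.pairs:
        mi, mj = structure.module_of(i), structure.module_of(j)
        if mi != mj:
            return None
        pair_i[mi].append(i - 1)
        pair_j[mi].append(j - 1)
    return [
        (
            np.asarray(cons_pos[m], dtype=int),
            np.asarray(cons_req[m], dtype=np.int8),
            np.asarray(pair_i[m], dtype=int),
            np.asarray(pair_j[m], dtype=int),
        )
        for m in range(M)
    ]


def scan_pool(seqs: np.ndarray, structure: StructureConstraint) -> np.ndarray:
    """Minimum mutational distance of every sequence in an encoded pool.

    ``seqs`` is an (n, Lran) int8 array of base codes.  When all pairs
    lie within single modules the minimum over placements factorizes:
    per-module mismatch costs depend only on that module's offset, and
    the offsets form a nondecreasing chain, so a prefix-minimum dynamic
    programme over offsets replaces explicit placement enumeration.
    Pairs crossing module boundaries fall back to the per-placement
    loop (still vectorized across sequences).  Both paths agree with
    ``min_distance_scan`` exactly.
    """
    seqs = np.asarray(seqs)
    if seqs.ndim != 2:
        raise ValueError("seqs must be a 2-D (n, Lran) array of base codes")
    n, Lran = seqs.shape
    if Lran < structure.length:
        raise ValueError("sequences shorter than the structure")
    per_module = _module_constraint_arrays(structure)
    if per_module is None:
        return _scan_pool_generic(seqs, structure)

    gap = Lran - structure.length
    G = gap + 1
    big = np.int16(4096)
    f = None
    for m, (cpos, creq, pi, pj) in enumerate(per_module):
        cost = np.zeros((n, G), dtype=np.int16)
        for g in range(G):
            if cpos.size:
                cost[:, g] += (seqs[:, cpos + g] != creq).sum(axis=1, dtype=np.int16)
            if pi.size:
                cost[:, g] += (~_is_canonical(seqs[:, pi + g], seqs[:, pj + g])).sum(
                    axis=1, dtype=np.int16
                )
        if f is None:
            f = cost
            if structure.anchored5 and G > 1:
                f = f.copy()
                f[:, 1:] = big
        else:
            f = np.minimum.accumulate(f, axis=1) + cost
    return f.min(axis=1).astype(np.int64)


def _scan_pool_generic(seqs: np.ndarray, structure: StructureConstraint) -> np.ndarray:
    n, Lran = seqs.shape
    module_idx = {p: structure.module_of(p) for p in range(1, structure.length + 1)}
    best = np.full(n, structure.s + structure.b, dtype=np.int16)
    for offs in _placements(structure, Lran):
        m = np.zeros(n, dtype=np.int16)
        for p, b in structure.conserved.items():
            m += seqs[:, p - 1 + offs[module_idx[p]]] != _BASE_CODE[b]
        for i, j in structure.pairs:
            si = seqs[:, i - 1 + offs[module_idx[i]]]
            sj = seqs[:, j - 1 + offs[module_idx[j]]]
            m += ~_is_canonical(si, sj)
        np.minimum(best, m, out=best)
    return best.astype(np.int64)


def sample_min_distance_distribution(
    structure: StructureConstraint,
    Lran: int,
    n_samples: int,
    seed: int | None = None,
    chunk_size: int = 200_000,
) -> DistanceDistribution:
    """Empirical minimum-distance distribution over uniform random sequences.

    Draws ``n_samples`` iid uniform sequences of length ``Lran`` and
    scans each.  Distances rarer than a few times 1/n_samples are not
    resolvable — at the default desk scale of 1e6 samples the exact-match
    tail (q ~ 1e-12) is far out of reach; only the bulk of the
    distribution can be compared with the formulas.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    rng = np.random.default_rng(seed)
    counts = np.zeros(structure.s + structure.b + 1, dtype=np.int64)
    remaining = n_samples
    while remaining > 0:
        take = min(chunk_size, remaining)
        seqs = rng.integers(0, 4, size=(take, Lran), dtype=np.int8)
        d = scan_pool(seqs, structure)
        counts += np.bincount(d, minlength=len(counts))
        remaining -= take
    return DistanceDistribution(
        counts / n_samples, frames=structure.frame_count(Lran), kind="empirical"
    )


def exhaustive_distance_distribution(
    structure: StructureConstraint, Lran: int, chunk_size: int = 1 << 16
) -> DistanceDistribution:
    """Exact minimum-distance distribution over all 4**Lran sequences.

    Independent oracle for the closed-form distributions; enumeration is
    guarded at Lran <= 12 (16.8M sequences).
    """
    if Lran > 12:
        raise ValueError("exhaustive enumeration is guarded at Lran <= 12")
    if Lran < structure.length:
        raise ValueError("Lran shorter than the structure")
    total = 4**Lran
    counts = np.zeros(structure.s + structure.b + 1, dtype=np.int64)
    shifts = 2 * np.arange(Lran, dtype=np.int64)[::-1]
    for start in range(0, total, chunk_size):
        idx = np.arange(start, min(start + chunk_size, total), dtype=np.int64)
        seqs = ((idx[:, None] >> shifts) & 3).astype(np.int8)
        d = scan_pool(seqs, structure)
        counts += np.bincount(d, minlength=len(counts))
    return DistanceDistribution(
        counts / total, frames=structure.frame_count(Lran), kind="exhaustive"
    )
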