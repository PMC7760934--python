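"""Synthetic inputs: canonical fixtures, sequence realizations, simulations.

The worked examples this engine must reproduce are stated as pairwise
*distances*, not sequences, so the canonical fixtures are capped-line
metrics: individuals sit at real coordinates on a line and the distance
between two of them is ``min(|x_i − x_j|, cap)``. A capped line metric is
symmetric, hollow, and satisfies the triangle inequality, and it is the
simplest geometry that realizes every constraint the examples state
(pairwise gaps, per-cluster spans, and a global maximum).

``realize_sequences`` turns any small realizable distance matrix into
actual DNA sequences whose alignment distances reproduce the matrix
*exactly* (or fails loudly); ``simulate_community`` plants a known
partition with controlled within- and between-group distances for
parameter-recovery tests.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy.optimize import Bounds, LinearConstraint, milp

from .distancekit import DistanceMatrix, DISTANCE_TOL
from .records import Individual

__all__ = [
    "CappedLineMetric",
    "fixture_fig1",
    "fixture_fig3",
    "realize_sequences",
    "simulate_community",
]


@dataclass(frozen=True)
class CappedLineMetric:
    """Individuals on a line with distances capped at a maximum.

    ``d(i, j) = min(|x_i − x_j|, cap)`` in percent units. The triangle
    inequality is asserted exhaustively on instantiation (fixture sizes are
    small), so every matrix this produces is a valid metric.
    """

    coordinates: dict[str, float]
    cap: float

    def __post_init__(self) -> None:
        if self.cap <= 0:
            raise ValueError("cap must be positive")
        m = self.to_matrix()
        d = m.data
        n = d.shape[0]
        for i, j, k in itertools.permutations(range(n), 3):
            if d[i, j] > d[i, k] + d[k, j] + DISTANCE_TOL:
                raise AssertionError("capped line metric violated the triangle inequality")

    def to_matrix(self) -> DistanceMatrix:
        pids = sorted(self.coordinates)
        x = np.array([self.coordinates[p] for p in pids])
        d = np.abs(x[:, None] - x[None, :])
        d = np.minimum(d, self.cap)
        np.fill_diagonal(d, 0.0)
        return DistanceMatrix(np.round(d, 4), ids=pids)


def fixture_fig1() -> DistanceMatrix:
    """Four individuals whose delimitation changes with the threshold.

    Coordinates 0.0 / 1.6 / 3.0 / 4.7 with cap 2.6 give adjacent distances
    1.6, 1.4, 1.7 and all remaining pairs 2.6. Single linkage yields four
    singletons at ≤1.0%, three clusters at ≤1.5% (ind2+ind3 merge with an
    intraspecific variation of 1.4%), and one chained cluster of all four
    at ≤2.0% with variation 2.6% — although some pairs inside it are
    farther apart than the threshold.
    """
    metric = CappedLineMetric(
        coordinates={"ind1": 0.0, "ind2": 1.6, "ind3": 3.0, "ind4": 4.7},
        cap=2.6,
    )
    return metric.to_matrix()


#: Group coordinates behind the 32-individual fixture. Group a spans
#: [0, 2.6] with adjacent gaps ≤ 0.25; group b spans [3.7, 4.9] (closest
#: approach to a: 1.1); group c spans [−3.6, −1.7] (closest approach to a:
#: 1.7); cap 5.2 is the farthest pair (b's right end to c's left end).
_FIG3_COORDS = {
    # SHa: 12 individuals
    **{f"a{i+1:02d}": x for i, x in enumerate(
        [0.0, 0.25, 0.5, 0.75, 1.0, 1.25, 1.5, 1.75, 2.0, 2.2, 2.4, 2.6]
    )},
    # SHb: 12 individuals
    **{f"b{i+1:02d}": x for i, x in enumerate(
        [3.7, 3.8, 3.9, 4.0, 4.1, 4.2, 4.3, 4.4, 4.5, 4.6, 4.7, 4.9]
    )},
    # SHc: 8 individuals
    **{f"c{i+1:02d}": x for i, x in enumerate(
        [-3.6, -3.3, -3.0, -2.7, -2.4, -2.1, -1.9, -1.7]
    )},
}


def fixture_fig3() -> DistanceMatrix:
    """Thirty-two individuals in three planted species hypotheses.

    At ≤1.0% the three groups a/b/c stay separate (a's internal variation
    is 2.6%); at ≤1.5% a and b merge (their closest members are 1.1%
    apart; variation of ab is 4.9%, of c 1.9%); at ≤2.0% c joins as well
    (closest approach 1.7%) and the single cluster's variation is 5.2%.
    """
    return CappedLineMetric(coordinates=dict(_FIG3_COORDS), cap=5.2).to_matrix()


def fig3_groups() -> dict[str, tuple[str, ...]]:
    """The planted partition of the 32-individual fixture."""
    groups: dict[str, list[str]] = {"a": [], "b": [], "c": []}
    for pid in sorted(_FIG3_COORDS):
        groups[pid[0]].append(pid)
    return {g: tuple(p) for g, p in groups.items()}


# ---------------------------------------------------------------------------
# sequence realization


def _set_partitions(n: int, max_blocks: int = 4):
    """All partitions of range(n) into 2..max_blocks blocks."""

    def rec(items):
        if not items:
            yield []
            return
        first, rest = items[0], items[1:]
        for p in rec(rest):
            for i in range(len(p)):
                yield p[:i] + [p[i] + [first]] + p[i + 1 :]
            if len(p) < max_blocks:
                yield [[first]] + p

    for p in rec(list(range(n))):
        if len(p) > 1:
            yield [sorted(b) for b in p]


_MAX_REALIZE_N = 8  # partition count grows as Bell(n); keep the solve exact and fast


def realize_sequences(matrix: DistanceMatrix, length: int, seed: int) -> list[Individual]:
    """Construct sequences whose pairwise distances reproduce ``matrix`` exactly.

    Each alignment column is assigned a *pattern* — a partition of the
    individuals into at most four blocks, one nucleotide per block — and a
    column contributes one mismatch to exactly the pairs its pattern
    separates. The required integer column counts per pattern are solved
    exactly (integer linear program over all patterns); the remaining
    columns share one seeded random background base. The result is verified
    against the matrix through the alignment pipeline and returned only on
    an exact match; an unrealizable matrix is an explicit failure, never a
    silent approximation.

    Preconditions: ``matrix entry × length / 100`` integral for every pair;
    at most 8 individuals (the pattern space is enumerated exhaustively).
    """
    pids = list(matrix.ids)
    n = len(pids)
    if n > _MAX_REALIZE_N:
        raise ValueError(f"realize_sequences supports at most {_MAX_REALIZE_N} individuals")
    rng = np.random.default_rng(seed)
    if n == 1:
        seq = "".join(rng.choice(list("ACGT"), size=length))
        return [Individual(pid=pids[0], sequence=seq)]

    pairs = list(itertools.combinations(range(n), 2))
    mismatches = []
    for i, j in pairs:
        m = matrix.data[i, j] * length / 100.0
        if abs(m - round(m)) > 1e-6:
            raise ValueError(
                f"distance {matrix.data[i, j]} not realizable at length {length}: "
                "mismatch count must be integral"
            )
        mismatches.append(int(round(m)))

    parts = list(_set_partitions(n))
    A = np.zeros((len(pairs), len(parts)))
    for col, p in enumerate(parts):
        block_of = {i: k for k, block in enumerate(p) for i in block}
        for row, (i, j) in enumerate(pairs):
            if block_of[i] != block_of[j]:
                A[row, col] = 1.0
    target = np.array(mismatches, dtype=float)
    res = milp(
        c=np.ones(len(parts)),
        constraints=LinearConstraint(A, target, target),
        integrality=np.ones(len(parts)),
        bounds=Bounds(0, np.inf),
    )
    if res.x is None:
        raise ValueError("matrix is not realizable as equal-length sequences")
    weights = np.round(res.x).astype(int)
    total_variable = int(weights.sum())
    if total_variable > length:
        raise ValueError(
            f"matrix needs {total_variable} variable columns but length is {length}"
        )

    letters = "ACGT"
    columns = np.empty((length, n), dtype="<U1")
    background = rng.choice(list(letters), size=length - total_variable)
    cursor = 0
    for k in range(len(background)):
        columns[cursor] = background[k]
        cursor += 1
    for col_idx, w in enumerate(weights):
        if w == 0:
            continue
        p = parts[col_idx]
        bases = np.empty(n, dtype="<U1")
        for block_idx, block in enumerate(p):
            for i in block:
                bases[i] = letters[block_idx]
        for _ in range(w):
            columns[cursor] = bases
            cursor += 1
    rng.shuffle(columns, axis=0)

    individuals = [
        Individual(pid=pid, sequence="".join(columns[:, i])) for i, pid in enumerate(pids)
    ]

    from .distancekit import build_matrix

    realized = build_matrix(individuals)
    realized = realized.filter(pids)
    if not np.allclose(realized.data, matrix.data, atol=1e-9):
        raise ValueError("realized sequences failed exact verification against the matrix")
    return individuals


def simulate_community(
    k: int,
    n_per: int,
    intra_max: float,
    inter_min: float,
    seed: int,
) -> tuple[DistanceMatrix, list[tuple[str, ...]]]:
    """Plant ``k`` groups of ``n_per`` individuals with a known partition.

    Groups sit on a line: within-group spans are at most ``intra_max`` and
    the gap between consecutive groups is at least ``inter_min``, so any
    single-linkage threshold strictly between the two recovers the planted
    partition exactly. Returns the distance matrix and the true partition;
    the same seed always reproduces the same matrix.
    """
    if k < 1 or n_per < 1:
        raise ValueError("k and n_per must be positive")
    if intra_max >= inter_min:
        raise ValueError("requires intra_max < inter_min")
    span_needed = k * intra_max + (k - 1) * inter_min
    if span_needed > 100.0:
        raise ValueError(
            f"geometry infeasible: {k} groups at these scales span {span_needed} > 100 percent"
        )
    rng = np.random.default_rng(seed)
    coords: dict[str, float] = {}
    partition: list[tuple[str, ...]] = []
    start = 0.0
    for g in range(k):
        pids = [f"g{g+1:02d}_i{i+1:02d}" for i in range(n_per)]
        if n_per == 1:
            offsets = np.array([0.0])
        else:
            # anchor both ends so the group is connected at any t > intra_max
            interior = np.sort(rng.uniform(0.0, intra_max, size=n_per - 2))
            offsets = np.concatenate([[0.0], interior, [intra_max]])
        for pid, off in zip(pids, offsets):
            coords[pid] = round(start + off, 4)
        partition.append(tuple(pids))
        start += intra_max + inter_min + rng.uniform(0.0, inter_min * 0.1)
    cap = max(coords.values()) - min(coords.values())
    metric = CappedLineMetric(coordinates=coords, cap=max(cap, inter_min) + 1e-6)
    return metric.to_matrix(), partition
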