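"""Pairwise percent distances between individuals.

Species hypotheses are delimited in a trait space of pairwise distances.
For marker sequences the distance is ``100 − percent identity`` under a
global alignment; worked examples and fixtures are stated directly as
distance matrices, so every delimitation operation also accepts a matrix
without ever touching sequences.

The matrix container is :class:`skbio.DistanceMatrix` (symmetric, hollow,
id-labelled), re-exported here as the canonical type.
"""

from __future__ import annotations

import itertools
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import Align
from skbio import DistanceMatrix

from .records import Individual

__all__ = [
    "DistanceMatrix",
    "pairwise_distance",
    "build_matrix",
    "read_matrix",
    "write_matrix",
    "identity_of",
    "DISTANCE_TOL",
]

#: Absolute tolerance for comparing percent distances against thresholds.
DISTANCE_TOL = 1e-9

_MATCHABLE = frozenset("ACGT")


def _aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -1
    aligner.extend_gap_score = -1
    return aligner


def pairwise_distance(a: str, b: str) -> float:
    """Percent distance between two sequences under global alignment.

    Scoring is +1 match / −1 mismatch / −1 per gap position; the first
    optimal traceback reported by the aligner is the canonical alignment.
    Identity is the fraction of exactly matching columns over all alignment
    columns after discarding terminal-gap columns; ambiguity symbols never
    match, not even against themselves. Returns ``100 × (1 − identity)``
    rounded to 4 decimals.
    """
    a = a.strip().upper()
    b = b.strip().upper()
    if not a or not b:
        raise ValueError("pairwise_distance requires two non-empty sequences")
    # canonical argument order makes the chosen optimal traceback, and hence
    # the identity, independent of which sequence is passed first
    if b < a:
        a, b = b, a
    alignment = _aligner().align(a, b)[0]
    row_a, row_b = str(alignment[0]), str(alignment[1])
    start = max(_first_residue(row_a), _first_residue(row_b))
    stop = min(_last_residue(row_a), _last_residue(row_b)) + 1
    if stop <= start:
        raise ValueError("alignment has no overlapping columns after trimming terminal gaps")
    matches = sum(
        1
        for x, y in zip(row_a[start:stop], row_b[start:stop])
        if x == y and x in _MATCHABLE
    )
    identity = matches / (stop - start)
    return round(100.0 * (1.0 - identity), 4)


def _first_residue(row: str) -> int:
    return len(row) - len(row.lstrip("-"))


def _last_residue(row: str) -> int:
    return len(row.rstrip("-")) - 1


def build_matrix(individuals: list[Individual]) -> DistanceMatrix:
    """All-pairs percent distance matrix over individuals with sequences."""
    missing = [ind.pid for ind in individuals if ind.sequence is None]
    if missing:
        raise ValueError(f"individuals without sequences: {missing}")
    pids = [ind.pid for ind in individuals]
    n = len(pids)
    data = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        d = pairwise_distance(individuals[i].sequence, individuals[j].sequence)
        data[i, j] = data[j, i] = d
    return DistanceMatrix(data, ids=pids)


def write_matrix(matrix: DistanceMatrix, path: str | Path) -> None:
    """Write a labelled TSV: header row of pids, one labelled row per pid.

    Values are printed with at least 4 decimals and such that reading the
    file back reproduces the matrix exactly.
    """
    ids = list(matrix.ids)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join([""] + ids) + "\n")
        for i, pid in enumerate(ids):
            cells = [_fmt(v) for v in matrix.data[i]]
            fh.write("\t".join([pid] + cells) + "\n")


def _fmt(v: float) -> str:
    fixed = f"{v:.4f}"
    return fixed if float(fixed) == v else repr(float(v))


def read_matrix(path: str | Path) -> DistanceMatrix:
    """Read a labelled square TSV distance matrix.

    Raises ``ValueError`` on asymmetry beyond 1e-9, a nonzero diagonal,
    negative or non-finite entries, or mismatched labels.
    """
    frame = pd.read_csv(path, sep="\t", index_col=0)
    ids = [str(i) for i in frame.index]
    cols = [str(c) for c in frame.columns]
    if ids != cols:
        raise ValueError("distance matrix row and column labels differ")
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate labels in distance matrix")
    data = frame.to_numpy(dtype=float)
    if not np.all(np.isfinite(data)):
        raise ValueError("distance matrix contains non-finite entries")
    if np.any(data < 0):
        raise ValueError("distance matrix contains negative entries")
    if np.any(np.abs(np.diag(data)) > 0):
        raise ValueError("distance matrix diagonal must be zero")
    if np.max(np.abs(data - data.T)) > DISTANCE_TOL:
        raise ValueError("distance matrix is asymmetric beyond 1e-9")
    data = (data + data.T) / 2.0
    return DistanceMatrix(data, ids=ids)


def identity_of(threshold: float) -> float:
    """Percent identity corresponding to a percent-distance threshold.

    A 3.0% distance threshold corresponds to 97% identity; the delimitation
    span 0.5–3.0% distance maps to 99.5–97% identity.
    """
    if not 0.0 <= threshold <= 100.0:
        raise ValueError(f"distance threshold out of [0, 100]: {threshold}")
    return 100.0 - threshold
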