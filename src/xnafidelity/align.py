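"""Affine-gap global alignment of clones to the design template.

Clones are full amplicons of a known template, so alignment is global
(end-to-end) Needleman-Wunsch with Gotoh's affine gap states.  A gap of
length k costs ``gap_open + k * gap_extend``.  N (base-caller ambiguity)
aligned against anything scores 0 — it is never a match or a mismatch.

Traceback is deterministic: on ties, a diagonal step is preferred over a gap
in the clone (deletion), which is preferred over a gap in the template
(insertion).  Indel placement within homopolymers is additionally made
reproducible by :func:`left_normalize_indels`.

The dynamic-programming fill and traceback run in a numba-compiled kernel;
the first call in a process pays a one-off JIT cost.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
from numba import njit

from .design import revcomp

__all__ = [
    "ScoringScheme",
    "Alignment",
    "DEFAULT_SCORING",
    "align_global",
    "orient_clone",
    "left_normalize_indels",
]

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}
_NEG = -(10**9)


@dataclass(frozen=True)
class ScoringScheme:
    """Alignment parameters; penalties are stored as magnitudes and applied
    subtractively.  The default (+1/-2, gap open 4, extend 1) favours
    substitution calls over spurious compensating indel pairs at the per-site
    error rates this assay operates at (around 2% and below)."""

    match: int = 1
    mismatch: int = 2
    gap_open: int = 4
    gap_extend: int = 1

    def __post_init__(self) -> None:
        if self.match <= 0:
            raise ValueError("match reward must be positive")
        if min(self.mismatch, self.gap_open, self.gap_extend) < 0:
            raise ValueError("penalties are magnitudes and must be >= 0")
        if self.gap_open < self.gap_extend:
            raise ValueError("gap_open must be >= gap_extend")


DEFAULT_SCORING = ScoringScheme()


@dataclass(frozen=True)
class Alignment:
    """A gapped pairing of clone to template.

    ``column_map[k]`` is the template coordinate consumed in column k, or -1
    for insertion columns (gap in the template row).  ``identity`` is the
    matching fraction of columns where both rows carry a base.
    """

    aligned_template: str
    aligned_clone: str
    score: int
    identity: float
    column_map: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.aligned_template) != len(self.aligned_clone):
            raise ValueError("aligned rows differ in length")


def _encode(seq: str, label: str) -> np.ndarray:
    try:
        return np.fromiter((_CODE[c] for c in seq), dtype=np.uint8, count=len(seq))
    except KeyError as exc:
        raise ValueError(f"{label} contains non-ACGTN character {exc.args[0]!r}")


@njit(cache=False)
def _gotoh(t, c, match, mismatch, gap_open, gap_ext):  # pragma: no cover - jitted
    n = t.shape[0]
    m = c.shape[0]
    M = np.full((n + 1, m + 1), _NEG, np.int64)
    X = np.full((n + 1, m + 1), _NEG, np.int64)  # gap in clone (consumes template)
    Y = np.full((n + 1, m + 1), _NEG, np.int64)  # gap in template (consumes clone)
    M[0, 0] = 0
    for i in range(1, n + 1):
        X[i, 0] = -(gap_open + i * gap_ext)
    for j in range(1, m + 1):
        Y[0, j] = -(gap_open + j * gap_ext)
    oe = gap_open + gap_ext
    for i in range(1, n + 1):
        a = t[i - 1]
        for j in range(1, m + 1):
            b = c[j - 1]
            if a == 4 or b == 4:
                s = 0
            elif a == b:
                s = match
            else:
                s = -mismatch
            best = M[i - 1, j - 1]
            if X[i - 1, j - 1] > best:
                best = X[i - 1, j - 1]
            if Y[i - 1, j - 1] > best:
                best = Y[i - 1, j - 1]
            M[i, j] = best + s
            vx = M[i - 1, j] - oe
            if Y[i - 1, j] - oe > vx:
                vx = Y[i - 1, j] - oe
            if X[i - 1, j] - gap_ext > vx:
                vx = X[i - 1, j] - gap_ext
            X[i, j] = vx
            vy = M[i, j - 1] - oe
            if X[i, j - 1] - oe > vy:
                vy = X[i, j - 1] - oe
            if Y[i, j - 1] - gap_ext > vy:
                vy = Y[i, j - 1] - gap_ext
            Y[i, j] = vy

    # traceback; state preference on ties: M (diagonal) > X (gap in clone)
    # > Y (gap in template)
    moves = np.empty(n + m, np.uint8)
    k = 0
    i, j = n, m
    score = M[n, m]
    state = 0
    if X[n, m] > score:
        score, state = X[n, m], 1
    if Y[n, m] > score:
        score, state = Y[n, m], 2
    while i > 0 or j > 0:
        if state == 0:
            moves[k] = 0
            k += 1
            target = M[i, j]
            i -= 1
            j -= 1
            a = t[i]
            b = c[j]
            if a == 4 or b == 4:
                s = 0
            elif a == b:
                s = match
            else:
                s = -mismatch
            if M[i, j] + s == target:
                state = 0
            elif X[i, j] + s == target:
                state = 1
            else:
                state = 2
        elif state == 1:
            moves[k] = 1
            k += 1
            target = X[i, j]
            i -= 1
            if i == 0 and j == 0:
                state = 0
            elif M[i, j] - oe == target:
                state = 0
            elif X[i, j] - gap_ext == target:
                state = 1
            else:
                state = 2
        else:
            moves[k] = 2
            k += 1
            target = Y[i, j]
            j -= 1
            if i == 0 and j == 0:
                state = 0
            elif M[i, j] - oe == target:
                state = 0
            elif X[i, j] - oe == target:
                state = 1
            else:
                state = 2
    return score, moves[:k][::-1].copy()


def _build_alignment(template: str, clone: str, score: int, moves: np.ndarray) -> Alignment:
    t_row: list[str] = []
    c_row: list[str] = []
    col_map: list[int] = []
    i = j = 0
    for mv in moves:
        if mv == 0:
            t_row.append(template[i])
            c_row.append(clone[j])
            col_map.append(i)
            i += 1
            j += 1
        elif mv == 1:
            t_row.append(template[i])
            c_row.append("-")
            col_map.append(i)
            i += 1
        else:
            t_row.append("-")
            c_row.append(clone[j])
            col_map.append(-1)
            j += 1
    return Alignment(
        aligned_template="".join(t_row),
        aligned_clone="".join(c_row),
        score=int(score),
        identity=_identity(t_row, c_row),
        column_map=tuple(col_map),
    )


def _identity(t_row, c_row) -> float:
    paired = matched = 0
    for a, b in zip(t_row, c_row):
        if a != "-" and b != "-":
            paired += 1
            if a == b:
                matched += 1
    return matched / paired if paired else 0.0


def align_global(
    template: str, clone: str, scoring: ScoringScheme = DEFAULT_SCORING
) -> Alignment:
    """Optimal affine-gap global alignment of ``clone`` against ``template``."""
    if not template or not clone:
        raise ValueError("cannot align an empty sequence")
    t = _encode(template, "template")
    c = _encode(clone, "clone")
    score, moves = _gotoh(
        t, c, scoring.match, scoring.mismatch, scoring.gap_open, scoring.gap_extend
    )
    return _build_alignment(template, clone, score, moves)


def orient_clone(
    clone: str, template: str, scoring: ScoringScheme = DEFAULT_SCORING
) -> tuple[str, str]:
    """Return the better-aligning of clone / revcomp(clone) and its strand.

    TOPO-TA inserts ligate in either orientation, so each clone is tried both
    ways; ties go to the forward strand.  Strand is ``"forward"`` or
    ``"reverse"``.
    """
    fwd = align_global(template, clone, scoring)
    rc = revcomp(clone)
    rev = align_global(template, rc, scoring)
    if rev.score > fwd.score:
        return rc, "reverse"
    return clone, "forward"


def _shift_gaps_left(gapped: list[str], other: list[str]) -> bool:
    """One left-shift pass of every gap run in ``gapped``; True if changed."""
    changed = False
    n = len(gapped)
    i = 0
    while i < n:
        if gapped[i] != "-":
            i += 1
            continue
        start = i
        while i < n and gapped[i] == "-":
            i += 1
        end = i  # run is [start, end)
        if (
            start > 0
            and gapped[start - 1] != "-"
            and other[start - 1] != "-"
            and other[start - 1] == other[end - 1]
            # a hop that would merge two gap runs changes the affine cost
            and (start < 2 or gapped[start - 2] != "-")
        ):
            gapped[end - 1] = gapped[start - 1]
            gapped[start - 1] = "-"
            changed = True
            i = end - 1  # re-scan the shifted run
    return changed


def left_normalize_indels(alignment: Alignment) -> Alignment:
    """Shift every gap run to its leftmost score-equivalent position.

    A run may move left one column whenever the non-gapped row carries the
    same base on both sides of the hop (a homopolymer), which leaves both the
    score and the matched fraction unchanged.  The operation is idempotent.
    """
    t_row = list(alignment.aligned_template)
    c_row = list(alignment.aligned_clone)
    changed = True
    while changed:
        changed = _shift_gaps_left(c_row, t_row) | _shift_gaps_left(t_row, c_row)
    col_map: list[int] = []
    i = 0
    for a in t_row:
        if a == "-":
            col_map.append(-1)
        else:
            col_map.append(i)
            i += 1
    return Alignment(
        aligned_template="".join(t_row),
        aligned_clone="".join(c_row),
        score=alignment.score,
        identity=alignment.identity,
        column_map=tuple(col_map),
    )
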