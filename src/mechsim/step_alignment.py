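"""Mechanism-level comparison.

Per-step Tanimoto coefficients are stored in a similarity matrix; the best
global alignment of steps (dynamic programming with zero gap penalties)
yields a score from which a mechanism-level Tanimoto coefficient is
computed.  Reaction reversibility (bond-change inversion plus step-order
reversal) and, where curation allows it, circular permutation of steps are
searched explicitly and the maximum over all configurations is reported.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from mechsim.reaction_model import (
    BondChangeSet,
    MechanisticStep,
    ReactionEntry,
    reverse_changes,
    reverse_entry,
)
from mechsim.simcore import max_possible_tanimoto, normalize, tanimoto

logger = logging.getLogger(__name__)

Direction = Literal["forward", "reversed"]
RotationPolicy = Literal["none", "whitelist", "all"]


@dataclass(frozen=True)
class StepAlignment:
    """Result of aligning two step sequences.

    ``matched`` holds 1-based (i, j) position pairs, strictly increasing in
    both coordinates; zero-similarity matches are excluded since they carry
    no similarity.  ``score`` is the full dynamic-programming optimum (the
    sum over the maximum-match pathway).
    """

    matched: tuple[tuple[int, int], ...]
    score: float
    mode: Literal["global", "local"]
    direction: Direction = "forward"
    rotation_1: int = 0
    rotation_2: int = 0


def step_matrix(m1: Sequence[MechanisticStep], m2: Sequence[MechanisticStep]) -> np.ndarray:
    """Tanimoto coefficients between all pairs of steps, shape (n1, n2).

    Steps with empty bond-change sets score 0 against everything.
    """
    if not m1 or not m2:
        raise ValueError("cannot build a step similarity matrix for an empty mechanism")
    mat = np.zeros((len(m1), len(m2)))
    for i, s1 in enumerate(m1):
        for j, s2 in enumerate(m2):
            if not s1.changes or not s2.changes:
                logger.debug("empty step scored 0: (%d, %d)", i + 1, j + 1)
                continue
            mat[i, j] = tanimoto(s1.changes, s2.changes)
    return mat


def global_align(mat: np.ndarray) -> StepAlignment:
    """Best global (Needleman-Wunsch style) alignment with zero gap penalties.

    Recurrence: H(i,j) = max(H(i-1,j-1) + M(i,j), H(i-1,j), H(i,j-1)).
    Traceback ties prefer diagonal, then up, then left, which makes the
    matched path deterministic (the score is unique regardless).
    """
    mat = np.asarray(mat, dtype=float)
    if mat.ndim != 2 or 0 in mat.shape:
        raise ValueError(f"similarity matrix must be 2-D and non-empty, got {mat.shape}")
    n1, n2 = mat.shape
    h = np.zeros((n1 + 1, n2 + 1))
    for i in range(1, n1 + 1):
        for j in range(1, n2 + 1):
            h[i, j] = max(h[i - 1, j - 1] + mat[i - 1, j - 1], h[i - 1, j], h[i, j - 1])
    matched: list[tuple[int, int]] = []
    i, j = n1, n2
    while i > 0 and j > 0:
        if h[i, j] == h[i - 1, j - 1] + mat[i - 1, j - 1]:
            if mat[i - 1, j - 1] > 0:
                matched.append((i, j))
            i -= 1
            j -= 1
        elif h[i, j] == h[i - 1, j]:
            i -= 1
        else:
            j -= 1
    matched.reverse()
    return StepAlignment(matched=tuple(matched), score=float(h[n1, n2]), mode="global")


def local_align(mat: np.ndarray, mismatch_offset: float = 0.5, gap_penalty: float = 0.0) -> StepAlignment:
    """Best local (Smith-Waterman style) alignment block.

    Cell scores are shifted by ``mismatch_offset`` so that dissimilar step
    pairs score negatively and terminate blocks; the DP floor is 0.
    """
    mat = np.asarray(mat, dtype=float)
    if mat.ndim != 2 or 0 in mat.shape:
        raise ValueError(f"similarity matrix must be 2-D and non-empty, got {mat.shape}")
    if mismatch_offset < 0 or gap_penalty < 0:
        raise ValueError("mismatch_offset and gap_penalty must be >= 0")
    n1, n2 = mat.shape
    s = mat - mismatch_offset
    h = np.zeros((n1 + 1, n2 + 1))
    for i in range(1, n1 + 1):
        for j in range(1, n2 + 1):
            h[i, j] = max(
                0.0,
                h[i - 1, j - 1] + s[i - 1, j - 1],
                h[i - 1, j] - gap_penalty,
                h[i, j - 1] - gap_penalty,
            )
    best = float(h.max())
    if best <= 0:
        return StepAlignment(matched=(), score=0.0, mode="local")
    i, j = np.unravel_index(int(h.argmax()), h.shape)
    matched: list[tuple[int, int]] = []
    while i > 0 and j > 0 and h[i, j] > 0:
        if h[i, j] == h[i - 1, j - 1] + s[i - 1, j - 1]:
            matched.append((int(i), int(j)))
            i -= 1
            j -= 1
        elif h[i, j] == h[i - 1, j] - gap_penalty:
            i -= 1
        else:
            j -= 1
    matched.reverse()
    return StepAlignment(matched=tuple(matched), score=best, mode="local")


def mechanistic_tanimoto(score: float, n1: int, n2: int) -> float:
    """Mechanism-level Tanimoto: S / (n1 + n2 - S) for alignment score S."""
    if n1 < 1 or n2 < 1:
        raise ValueError("step counts must be >= 1")
    if score < -1e-12 or score > min(n1, n2) + 1e-9:
        raise ValueError(f"alignment score {score} out of range for ({n1}, {n2}) steps")
    score = min(max(score, 0.0), float(min(n1, n2)))
    return score / (n1 + n2 - score)


def max_possible_mechanistic(n1: int, n2: int) -> float:
    """Maximum mechanistic Tanimoto for mechanisms of n1 and n2 steps.

    Assumes every step of the shorter mechanism matches a step of the
    longer one perfectly: m/(n1 + n2 - m) with m = min(n1, n2).
    """
    if n1 < 1 or n2 < 1:
        raise ValueError("step counts must be >= 1")
    m = min(n1, n2)
    return m / (n1 + n2 - m)


def rotations(mechanism: Sequence[MechanisticStep]) -> list[tuple[MechanisticStep, ...]]:
    """All circular permutations of a step sequence; offset 0 first.

    Each step keeps its original ``index`` so matched pairs can be mapped
    back to the un-rotated mechanism.
    """
    if not mechanism:
        raise ValueError("cannot rotate an empty mechanism")
    steps = tuple(mechanism)
    n = len(steps)
    return [steps[k:] + steps[:k] for k in range(n)]


def _rotate(mechanism: Sequence[MechanisticStep], k: int) -> tuple[MechanisticStep, ...]:
    steps = tuple(mechanism)
    k %= len(steps)
    return steps[k:] + steps[:k]


def find_identical_steps(
    m1: Sequence[MechanisticStep], m2: Sequence[MechanisticStep]
) -> set[tuple[int, int, Direction]]:
    """All step pairs with Tanimoto coefficient exactly 1.

    Pairs are searched in the forward direction and against the reversed
    second mechanism (step order reversed, bond changes inverted); indices
    reported are the original 1-based step indices of each mechanism.
    Empty-step pairs are never reported.
    """
    hits: set[tuple[int, int, Direction]] = set()
    for s1 in m1:
        if not s1.changes:
            continue
        inv = reverse_changes(s1.changes)
        for s2 in m2:
            if not s2.changes:
                continue
            if s1.changes == s2.changes:
                hits.add((s1.index, s2.index, "forward"))
            if inv == s2.changes:
                hits.add((s1.index, s2.index, "reversed"))
    return hits


@dataclass(frozen=True)
class PairComparison:
    """Full result of comparing two reaction entries."""

    id_1: str
    id_2: str
    overall_raw: float
    overall_normalized: float
    mechanistic_raw: float
    mechanistic_normalized: float
    overall_direction: Direction
    best_direction: Direction
    best_rotations: tuple[int, int]
    alignment: StepAlignment
    identical_steps_all: frozenset[tuple[int, int, Direction]]
    identical_steps_in_alignment: frozenset[tuple[int, int]]


def _rotation_offsets(entry: ReactionEntry, policy: RotationPolicy) -> range:
    if policy == "all" or (policy == "whitelist" and entry.permutation_allowed):
        return range(entry.n_steps)
    return range(1)


def compare_pair(
    e1: ReactionEntry,
    e2: ReactionEntry,
    rotation_policy: RotationPolicy = "whitelist",
    direction: Literal["auto", "forward", "reversed"] = "auto",
) -> PairComparison:
    """Compare two preprocessed entries in overall reaction and mechanism.

    Overall similarity is the maximum Tanimoto over the forward orientation
    and the orientation with the second entry's overall reaction inverted.
    Mechanistic similarity is the maximum over direction x allowed circular
    permutations of the mechanism-level Tanimoto; normalized variants are
    computed for the winning configuration.  Ties prefer forward direction
    and zero rotation offsets (iteration order), making results
    deterministic.  ``direction`` other than "auto" pins both searches to
    one orientation of the second entry.
    """
    # --- overall reaction, direction-maximized ---
    t_fwd = tanimoto(e1.overall, e2.overall)
    t_rev = tanimoto(e1.overall, reverse_changes(e2.overall))
    if direction == "forward":
        overall_raw, overall_direction = t_fwd, "forward"
    elif direction == "reversed":
        overall_raw, overall_direction = t_rev, "reversed"
    elif t_rev > t_fwd:
        overall_raw, overall_direction = t_rev, "reversed"
    else:
        overall_raw, overall_direction = t_fwd, "forward"
    if e1.overall and e2.overall:
        overall_normalized = normalize(overall_raw, len(e1.overall), len(e2.overall))
    else:
        # One change-free overall reaction: similarity is 0 in any direction
        # and no size normalization is defined.
        logger.warning(
            "%s vs %s: change-free overall reaction, normalized overall set to 0",
            e1.id,
            e2.id,
        )
        overall_normalized = 0.0

    # --- mechanism, direction x rotation maximized ---
    if not e1.mechanism or not e2.mechanism:
        raise ValueError(f"cannot compare mechanisms of {e1.id} and {e2.id}: empty mechanism")
    n1, n2 = e1.n_steps, e2.n_steps
    e2_reversed = reverse_entry(e2)
    orientations: tuple[tuple[Direction, tuple[MechanisticStep, ...]], ...] = (
        ("forward", e2.mechanism),
        ("reversed", e2_reversed.mechanism),
    )
    if direction != "auto":
        orientations = tuple(o for o in orientations if o[0] == direction)
    best: tuple[float, Direction, int, int, StepAlignment, np.ndarray] | None = None
    for mech_direction, m2 in orientations:
        for r1 in _rotation_offsets(e1, rotation_policy):
            rot1 = _rotate(e1.mechanism, r1)
            for r2 in _rotation_offsets(e2, rotation_policy):
                rot2 = _rotate(m2, r2)
                mat = step_matrix(rot1, rot2)
                aln = global_align(mat)
                if best is None or aln.score > best[0] + 1e-12:
                    best = (aln.score, mech_direction, r1, r2, aln, mat)
    assert best is not None
    score, won_direction, r1, r2, aln, mat = best
    alignment = StepAlignment(
        matched=aln.matched,
        score=score,
        mode="global",
        direction=won_direction,
        rotation_1=r1,
        rotation_2=r2,
    )
    mech_raw = mechanistic_tanimoto(score, n1, n2)
    mech_norm = min(mech_raw / max_possible_mechanistic(n1, n2), 1.0)

    # --- identical steps ---
    identical_all = frozenset(find_identical_steps(e1.mechanism, e2.mechanism))
    rot1 = _rotate(e1.mechanism, r1)
    m2_dir = e2.mechanism if won_direction == "forward" else e2_reversed.mechanism
    rot2 = _rotate(m2_dir, r2)
    in_alignment = set()
    for i, j in aln.matched:
        if mat[i - 1, j - 1] == 1.0:
            s1, s2 = rot1[i - 1], rot2[j - 1]
            # Map the reversed mechanism's positional index back to the
            # original step numbering of e2.
            orig_j = s2.index if won_direction == "forward" else n2 + 1 - s2.index
            in_alignment.add((s1.index, orig_j))
    return PairComparison(
        id_1=e1.id,
        id_2=e2.id,
        overall_raw=overall_raw,
        overall_normalized=overall_normalized,
        mechanistic_raw=mech_raw,
        mechanistic_normalized=mech_norm,
        overall_direction=overall_direction,
        best_direction=won_direction,
        best_rotations=(r1, r2),
        alignment=alignment,
        identical_steps_all=identical_all,
        identical_steps_in_alignment=frozenset(in_alignment),
    )


def render_alignment(comparison: PairComparison, m1=None, m2=None) -> str:
    """Human-readable listing of the winning step alignment."""
    lines = [
        f"{comparison.id_1} vs {comparison.id_2} "
        f"(direction={comparison.best_direction}, "
        f"rotations={comparison.best_rotations})",
        f"alignment score: {comparison.alignment.score:.4f}",
        f"mechanistic similarity: {comparison.mechanistic_raw:.4f} "
        f"(normalized {comparison.mechanistic_normalized:.4f})",
    ]
    for i, j in comparison.alignment.matched:
        tag = " *" if any(p == (i, j) for p in comparison.identical_steps_in_alignment) else ""
        lines.append(f"  step {i:>2} ~ step {j:>2}{tag}")
    if not comparison.alignment.matched:
        lines.append("  (no matched steps)")
    return "\n".join(lines)
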