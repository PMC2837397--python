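from __future__ import annotations

import numpy as np
import pytest

from mechsim.reaction_model import (
    BondChange,
    MechanisticStep,
    ReactionEntry,
    changes_from_tokens,
)


def changes(*tokens: str):
    """Shorthand: changes("f:C-O", "c:O-H") -> BondChangeSet."""
    return changes_from_tokens(tokens)


def make_entry(
    entry_id: str = "E1",
    ec: str = "1.1.1.1",
    superfamilies=("1.10.10.10",),
    overall=("f:C-O",),
    steps=(("f:C-O",),),
    spontaneous=(),
    permutation_allowed: bool = False,
) -> ReactionEntry:
    """Build a ReactionEntry from compact bond-change tokens."""
    mechanism = tuple(
        MechanisticStep(
            index=i,
            changes=changes(*step),
            spontaneous=i in spontaneous,
        )
        for i, step in enumerate(steps, start=1)
    )
    return ReactionEntry(
        id=entry_id,
        ec=ec,
        superfamilies=frozenset(superfamilies),
        overall=changes(*overall),
        mechanism=mechanism,
        permutation_allowed=permutation_allowed,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


def brute_force_monotone_score(mat: np.ndarray) -> float:
    """Independent oracle: max total score over all monotone matchings."""
    n1, n2 = mat.shape
    best = 0.0

    def rec(i: int, j: int, acc: float) -> None:
        nonlocal best
        if acc > best:
            best = acc
        for a in range(i, n1):
            for b in range(j, n2):
                rec(a + 1, b + 1, acc + mat[a, b])

    rec(0, 0, 0.0)
    return best
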