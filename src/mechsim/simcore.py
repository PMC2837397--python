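"""Set-level similarity: Tanimoto coefficient and size normalization.

Scores are plain floats in [0, 1]; "raw" vs "normalized" is tracked by the
field names of the result records that carry them.
"""

from __future__ import annotations

from mechsim.reaction_model import BondChangeSet

#: Number of decimal places used when rendering scores in reports.
REPORT_PRECISION = 4


class UndefinedSimilarityError(ValueError):
    """Similarity of two empty sets is undefined (change-free reactions
    are excluded from every comparison, mirroring their removal from the
    background dataset)."""


def tanimoto(a: BondChangeSet, b: BondChangeSet) -> float:
    """Tanimoto (Jaccard) coefficient |A∩B| / |A∪B| of two bond-change sets.

    Raises
    ------
    UndefinedSimilarityError
        If both sets are empty.
    """
    if not a and not b:
        raise UndefinedSimilarityError("similarity of two empty bond-change sets")
    inter = len(a & b)
    union = len(a) + len(b) - inter
    return inter / union


def max_possible_tanimoto(n_a: int, n_b: int) -> float:
    """Maximum Tanimoto attainable between sets of sizes ``n_a`` and ``n_b``.

    Assuming every change of the smaller set also occurs in the larger one,
    the best coefficient is ``min/(min + max - min) = min/max``; it is used
    as the divisor for size-normalized similarity.
    """
    if n_a < 1 or n_b < 1:
        raise ValueError(f"set cardinalities must be >= 1, got ({n_a}, {n_b})")
    lo, hi = min(n_a, n_b), max(n_a, n_b)
    return lo / (lo + hi - lo)


def normalize(score: float, n_a: int, n_b: int) -> float:
    """Divide a raw score by the maximum attainable for these set sizes.

    The result is 1 exactly when the smaller set is a (possibly improper)
    subset of the larger one.
    """
    bound = max_possible_tanimoto(n_a, n_b)
    if score > bound + 1e-12:
        raise ValueError(
            f"score {score} exceeds maximum attainable {bound} for sizes ({n_a}, {n_b})"
        )
    return min(score / bound, 1.0)
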