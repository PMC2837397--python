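"""Synthetic reaction generator.

Produces schema-conformant reaction entries with controlled structure:
steps drawn from a weighted repertoire of common enzyme bond types, overall
reactions derived from the mechanism by cancelling transient changes, and
configurable perturbations for building analog pairs and background
ensembles.  Everything is deterministic under a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from mechsim.reaction_model import (
    BondChange,
    BondChangeSet,
    ChangeKind,
    MechanisticStep,
    ReactionEntry,
)

#: Common enzyme bond types, weighted roughly by their prevalence in
#: catalysis (O-H, C-O, N-H, C-C, C-N, C-H, P-O head the list).
DEFAULT_REPERTOIRE: tuple[tuple[tuple[str, str], float], ...] = (
    (("H", "O"), 10.0),
    (("C", "O"), 9.0),
    (("H", "N"), 8.0),
    (("C", "C"), 7.0),
    (("C", "N"), 6.0),
    (("C", "H"), 5.0),
    (("O", "P"), 4.0),
    (("H", "S"), 2.0),
    (("C", "S"), 1.5),
    (("C", "Cl"), 0.5),
)

_CANCEL = {
    ChangeKind.FORMED: ChangeKind.CLEAVED,
    ChangeKind.CLEAVED: ChangeKind.FORMED,
    ChangeKind.ORDER_INCREASED: ChangeKind.ORDER_DECREASED,
    ChangeKind.ORDER_DECREASED: ChangeKind.ORDER_INCREASED,
}

_KINDS = tuple(ChangeKind)


@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs for the synthetic generator.

    Perturbation rates are probabilities per opportunity: ``p_step_delete``
    and ``p_step_insert`` per step, ``p_change_swap`` per bond change.
    """

    repertoire: tuple[tuple[tuple[str, str], float], ...] = DEFAULT_REPERTOIRE
    n_steps: tuple[int, int] = (2, 6)
    changes_per_step: tuple[int, int] = (1, 4)
    p_step_insert: float = 0.0
    p_step_delete: float = 0.0
    p_change_swap: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.repertoire or any(w <= 0 for _, w in self.repertoire):
            raise ValueError("repertoire must be non-empty with positive weights")
        lo, hi = self.n_steps
        if lo < 1 or hi < lo:
            raise ValueError(f"invalid n_steps range: {self.n_steps}")
        lo, hi = self.changes_per_step
        if lo < 1 or hi < lo:
            raise ValueError(f"invalid changes_per_step range: {self.changes_per_step}")
        if hi > 4 * len(self.repertoire):
            raise ValueError(
                "repertoire too small to draw "
                f"{hi} distinct bond changes ({len(self.repertoire)} bond types)"
            )
        for rate in (self.p_step_insert, self.p_step_delete, self.p_change_swap):
            if not (0 <= rate <= 1):
                raise ValueError("perturbation rates must be in [0, 1]")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def _bond_probs(cfg: GeneratorConfig) -> tuple[list[tuple[str, str]], np.ndarray]:
    bonds = [b for b, _ in cfg.repertoire]
    w = np.array([w for _, w in cfg.repertoire], dtype=float)
    return bonds, w / w.sum()


def _random_changes(cfg: GeneratorConfig, rng: np.random.Generator, n: int) -> BondChangeSet:
    """Draw n distinct (kind, bond) pairs, bond types weighted."""
    bonds, probs = _bond_probs(cfg)
    out: set[BondChange] = set()
    while len(out) < n:
        bond = bonds[int(rng.choice(len(bonds), p=probs))]
        kind = _KINDS[int(rng.integers(4))]
        out.add(BondChange(kind=kind, bond=bond))
    return frozenset(out)


def derive_overall(steps: tuple[MechanisticStep, ...]) -> BondChangeSet:
    """Net overall bond-change set of a mechanism.

    A change and its inverse on the same bond (formed/cleaved, or
    increased/decreased order) cancel pairwise across steps, so transient
    intermediates leave no net change.
    """
    union: set[BondChange] = set()
    for s in steps:
        union |= s.changes
    net = {
        c for c in union if BondChange(kind=_CANCEL[c.kind], bond=c.bond) not in union
    }
    return frozenset(net)


def random_entry(
    cfg: GeneratorConfig,
    rng: np.random.Generator,
    entry_id: str,
    ec: str,
    superfamilies,
) -> ReactionEntry:
    """One synthetic reaction entry with overall derived from its mechanism."""
    n_steps = int(rng.integers(cfg.n_steps[0], cfg.n_steps[1] + 1))
    steps = tuple(
        MechanisticStep(
            index=i,
            changes=_random_changes(
                cfg, rng, int(rng.integers(cfg.changes_per_step[0], cfg.changes_per_step[1] + 1))
            ),
        )
        for i in range(1, n_steps + 1)
    )
    return ReactionEntry(
        id=entry_id,
        ec=ec,
        superfamilies=frozenset(superfamilies),
        overall=derive_overall(steps),
        mechanism=steps,
    )


def perturbed_analog(
    entry: ReactionEntry,
    cfg: GeneratorConfig,
    rng: np.random.Generator,
    new_id: str | None = None,
) -> tuple[ReactionEntry, int]:
    """Copy of ``entry`` with controlled perturbations; returns (entry, count).

    Per step: deleted with probability ``p_step_delete`` (never below one
    surviving step) or followed by a freshly sampled inserted step with
    probability ``p_step_insert``.  Per bond change in surviving steps:
    replaced by a fresh random change with probability ``p_change_swap``.
    The perturbation count is the ground-truth number of edits applied.
    The overall reaction is re-derived from the perturbed mechanism.
    """
    edits = 0
    steps: list[BondChangeSet] = []
    for pos, s in enumerate(entry.mechanism):
        remaining_after = len(entry.mechanism) - pos - 1
        can_delete = bool(steps) or remaining_after > 0
        if cfg.p_step_delete > 0 and can_delete and rng.random() < cfg.p_step_delete:
            edits += 1
            continue
        changes = set(s.changes)
        if cfg.p_change_swap > 0:
            for c in sorted(s.changes):
                if rng.random() < cfg.p_change_swap:
                    changes.discard(c)
                    replacement = next(iter(_random_changes(cfg, rng, 1)))
                    changes.add(replacement)
                    edits += 1
        if not changes:  # swap collisions could empty the step; resample one
            changes = set(_random_changes(cfg, rng, 1))
        steps.append(frozenset(changes))
        if cfg.p_step_insert > 0 and rng.random() < cfg.p_step_insert:
            n = int(rng.integers(cfg.changes_per_step[0], cfg.changes_per_step[1] + 1))
            steps.append(_random_changes(cfg, rng, n))
            edits += 1
    if not steps:
        steps = [entry.mechanism[0].changes]
    mechanism = tuple(
        MechanisticStep(index=i, changes=ch) for i, ch in enumerate(steps, start=1)
    )
    out = replace(
        entry,
        id=new_id or f"{entry.id}-analog",
        overall=derive_overall(mechanism),
        mechanism=mechanism,
    )
    return out, edits


def delete_step(entry: ReactionEntry, position: int, new_id: str | None = None) -> ReactionEntry:
    """Deterministic single-step deletion (1-based position), re-indexed.

    Useful as ground truth: deleting one step from an n-step mechanism whose
    remaining steps still match their counterparts exactly yields a
    mechanistic similarity of (n-1)/n against the original.
    """
    if not 1 <= position <= len(entry.mechanism):
        raise ValueError(f"step position {position} out of range")
    if len(entry.mechanism) < 2:
        raise ValueError("cannot delete the only step of a mechanism")
    kept = [s for s in entry.mechanism if s.index != position]
    mechanism = tuple(
        MechanisticStep(index=i, changes=s.changes, spontaneous=s.spontaneous)
        for i, s in enumerate(kept, start=1)
    )
    return replace(
        entry,
        id=new_id or f"{entry.id}-del{position}",
        overall=derive_overall(mechanism),
        mechanism=mechanism,
    )


def background_ensemble(cfg: GeneratorConfig, k: int) -> list[ReactionEntry]:
    """k entries with pairwise-distinct sub-subclasses and superfamilies.

    Chemistry is sampled independently, so any similarity between ensemble
    members arises only from the limited repertoire of bond types: a null
    model for significance calibration.
    """
    if k < 2:
        raise ValueError("background ensemble needs k >= 2 entries")
    rng = cfg.rng()
    out = []
    for i in range(k):
        ec = f"{1 + i % 6}.{1 + i // 6}.{1 + i}.{1 + i}"
        out.append(
            random_entry(
                cfg,
                rng,
                entry_id=f"B{i:04d}",
                ec=ec,
                superfamilies={f"9.{i}.{i}.10"},
            )
        )
    return out


def analog_dataset(
    cfg: GeneratorConfig, n_pairs: int
) -> list[tuple[ReactionEntry, ReactionEntry]]:
    """n_pairs (original, perturbed analog) pairs sharing a sub-subclass.

    Each pair gets its own sub-subclass and disjoint superfamilies, so the
    pairs are valid functional analogs under the dataset-building rules.
    """
    rng = cfg.rng()
    pairs = []
    for i in range(n_pairs):
        ec = f"{1 + i % 6}.{1 + i // 6}.{100 + i}"
        a = random_entry(cfg, rng, f"D{i:04d}a", f"{ec}.1", {f"1.{i}.1.10"})
        b, _ = perturbed_analog(a, cfg, rng, new_id=f"D{i:04d}b")
        b = replace(b, ec=f"{ec}.2", superfamilies=frozenset({f"2.{i}.2.20"}))
        pairs.append((a, b))
    return pairs
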