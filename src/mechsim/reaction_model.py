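"""Canonical representation of bond changes, reactions and mechanisms.

A bond change is an elementary chemical event: a bond formed (``f``),
cleaved (``c``), increased in order (``i``) or decreased in order (``d``),
identified by the unordered pair of element symbols it connects.  Atom
types are not differentiated beyond the element symbol, so e.g. an
aromatic and an aliphatic carbon are identical for comparison purposes.

This module also implements the preprocessing rules applied before any
similarity computation: dropping stereochemistry-only records, removing
spontaneous (non-enzymatic) steps together with their contribution to the
overall reaction, and the reversibility transform (formed <-> cleaved,
increased <-> decreased, step order reversed).
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field, replace

logger = logging.getLogger(__name__)


class ValidationError(ValueError):
    """Raised when an input record violates the reaction schema."""


class ChangeKind(str, enum.Enum):
    """The four elementary bond-change kinds, serialized as single letters."""

    FORMED = "f"
    CLEAVED = "c"
    ORDER_INCREASED = "i"
    ORDER_DECREASED = "d"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: Letter used on input for stereochemistry-change records; accepted by
#: :func:`strip_stereo` but never stored.
STEREO_KIND = "involved"

_REVERSE_KIND = {
    ChangeKind.FORMED: ChangeKind.CLEAVED,
    ChangeKind.CLEAVED: ChangeKind.FORMED,
    ChangeKind.ORDER_INCREASED: ChangeKind.ORDER_DECREASED,
    ChangeKind.ORDER_DECREASED: ChangeKind.ORDER_INCREASED,
}

#: All IUPAC element symbols (1..118).
ELEMENT_SYMBOLS = frozenset(
    """
    H He Li Be B C N O F Ne Na Mg Al Si P S Cl Ar K Ca Sc Ti V Cr Mn Fe Co Ni
    Cu Zn Ga Ge As Se Br Kr Rb Sr Y Zr Nb Mo Tc Ru Rh Pd Ag Cd In Sn Sb Te I
    Xe Cs Ba La Ce Pr Nd Pm Sm Eu Gd Tb Dy Ho Er Tm Yb Lu Hf Ta W Re Os Ir Pt
    Au Hg Tl Pb Bi Po At Rn Fr Ra Ac Th Pa U Np Pu Am Cm Bk Cf Es Fm Md No Lr
    Rf Db Sg Bh Hs Mt Ds Rg Cn Nh Fl Mc Lv Ts Og
    """.split()
)

#: Mechanisms for which circular permutation of steps is accepted by curation
#: (simple proton transfers at either end of the sequence).
PERMUTATION_WHITELIST = frozenset(
    {"M0010", "M0043", "M0047", "M0049", "M0055", "M0093", "M0097", "M0098", "M0216"}
)


def canonicalize_bond(e1: str, e2: str) -> tuple[str, str]:
    """Return the unordered element pair ``(e1, e2)`` in canonical order.

    The canonical order is lexicographic by element symbol, so
    ``canonicalize_bond("O", "C") == canonicalize_bond("C", "O") == ("C", "O")``.

    Raises
    ------
    ValidationError
        If either symbol is empty or not a known element symbol.
    """
    for sym in (e1, e2):
        if not sym:
            raise ValidationError("empty element symbol in bond")
        if sym not in ELEMENT_SYMBOLS:
            raise ValidationError(f"unknown element symbol: {sym!r}")
    return (e1, e2) if e1 <= e2 else (e2, e1)


@dataclass(frozen=True, order=True)
class BondChange:
    """One elementary bond change: a kind and a canonical element pair."""

    kind: ChangeKind
    bond: tuple[str, str]

    @classmethod
    def of(cls, kind: ChangeKind | str, e1: str, e2: str) -> "BondChange":
        """Build a validated, canonicalized bond change."""
        if not isinstance(kind, ChangeKind):
            try:
                kind = ChangeKind(kind)
            except ValueError:
                raise ValidationError(f"unknown bond-change kind: {kind!r}") from None
        return cls(kind=kind, bond=canonicalize_bond(e1, e2))

    @classmethod
    def parse(cls, token: str) -> "BondChange":
        """Parse a compact token like ``"f:C-O"``."""
        try:
            kind, bond = token.split(":", 1)
            e1, e2 = bond.split("-", 1)
        except ValueError:
            raise ValidationError(f"malformed bond-change token: {token!r}") from None
        return cls.of(kind.strip(), e1.strip(), e2.strip())

    def __str__(self) -> str:
        return f"{self.kind.value}:{self.bond[0]}-{self.bond[1]}"


#: A reaction or step is represented as a set of distinct bond changes.
BondChangeSet = frozenset[BondChange]


def changes_from_tokens(tokens) -> BondChangeSet:
    """Parse and deduplicate an iterable of ``"f:C-O"``-style tokens."""
    parsed = [BondChange.parse(t) for t in tokens]
    out = frozenset(parsed)
    if len(out) < len(parsed):
        logger.warning("duplicate bond changes merged: %s", sorted(map(str, parsed)))
    return out


def reverse_changes(changes: BondChangeSet) -> BondChangeSet:
    """Invert a bond-change set for the reverse reaction direction.

    Formations become cleavages and vice versa; order increases become
    order decreases and vice versa.  The transform is an involution.
    """
    return frozenset(BondChange(_REVERSE_KIND[c.kind], c.bond) for c in changes)


def strip_stereo(raw_changes) -> BondChangeSet:
    """Drop stereochemistry-only ("involved") records and deduplicate.

    ``raw_changes`` is a sequence of ``(kind, e1, e2)`` triples where ``kind``
    may additionally be ``"involved"``.  Stereochemistry changes are the
    result of combinations of the elementary kinds and carry no independent
    information; they are removed with a warning.
    """
    kept: list[BondChange] = []
    for kind, e1, e2 in raw_changes:
        if kind == STEREO_KIND:
            logger.warning("dropping stereochemistry record: involved %s-%s", e1, e2)
            continue
        kept.append(BondChange.of(kind, e1, e2))
    out = frozenset(kept)
    if len(out) < len(kept):
        logger.warning("duplicate bond changes merged during parsing")
    return out


@dataclass(frozen=True)
class MechanisticStep:
    """One elementary stage of a catalytic mechanism."""

    index: int
    changes: BondChangeSet
    spontaneous: bool = False


@dataclass(frozen=True)
class ReactionEntry:
    """A reaction record: identity, classification and chemistry.

    ``ec`` must have exactly four dot-separated components; the first three
    (the sub-subclass) define functional-analog grouping.  ``superfamilies``
    are structural-superfamily code strings (CATH-style); sharing any one of
    them marks two entries as homologous.
    """

    id: str
    ec: str
    superfamilies: frozenset[str]
    overall: BondChangeSet
    mechanism: tuple[MechanisticStep, ...]
    permutation_allowed: bool = False

    def __post_init__(self) -> None:
        parts = self.ec.split(".")
        if len(parts) != 4 or any(not p for p in parts):
            raise ValidationError(f"{self.id}: EC code must have 4 components: {self.ec!r}")
        for pos, step in enumerate(self.mechanism, start=1):
            if step.index != pos:
                raise ValidationError(
                    f"{self.id}: step indices must be consecutive from 1, "
                    f"got {step.index} at position {pos}"
                )
        if not self.overall:
            logger.warning("%s: overall reaction has no bond changes", self.id)

    @property
    def sub_subclass(self) -> str:
        """First three EC components, e.g. ``"3.1.3"``."""
        return ".".join(self.ec.split(".")[:3])

    @property
    def n_steps(self) -> int:
        return len(self.mechanism)

    def step_changes(self) -> list[BondChangeSet]:
        return [s.changes for s in self.mechanism]


def reverse_entry(entry: ReactionEntry) -> ReactionEntry:
    """Return ``entry`` oriented in the reverse reaction direction.

    The overall bond changes are inverted, the step order is reversed and
    each step's changes are inverted; step indices are renumbered 1..n.
    """
    steps = tuple(
        MechanisticStep(index=i, changes=reverse_changes(s.changes), spontaneous=s.spontaneous)
        for i, s in enumerate(reversed(entry.mechanism), start=1)
    )
    return replace(entry, overall=reverse_changes(entry.overall), mechanism=steps)


def strip_spontaneous(entry: ReactionEntry) -> ReactionEntry:
    """Remove spontaneous steps and their bond changes from ``entry``.

    Spontaneous steps are non-enzymatic (they form the enzyme's substrate or
    the final product) and obscure the real similarity between mechanisms.
    The surviving steps are re-indexed consecutively and the overall reaction
    is re-annotated by subtracting the union of the removed steps' changes.

    Raises
    ------
    ValidationError
        If every step is spontaneous (no mechanism left to compare).
    """
    if not any(s.spontaneous for s in entry.mechanism):
        return entry
    kept = [s for s in entry.mechanism if not s.spontaneous]
    if not kept:
        raise ValidationError(f"{entry.id}: all steps are spontaneous")
    removed_changes: set[BondChange] = set()
    for s in entry.mechanism:
        if s.spontaneous:
            removed_changes |= s.changes
    kept_union = frozenset().union(*(s.changes for s in kept)) if kept else frozenset()
    overlap = removed_changes & kept_union
    if overlap:
        # Conservative: changes occurring in both a spontaneous and a
        # non-spontaneous step are still subtracted from the overall set.
        logger.warning(
            "%s: bond changes shared between spontaneous and enzymatic steps "
            "removed from the overall reaction: %s",
            entry.id,
            sorted(map(str, overlap)),
        )
    steps = tuple(
        MechanisticStep(index=i, changes=s.changes, spontaneous=False)
        for i, s in enumerate(kept, start=1)
    )
    return replace(entry, overall=entry.overall - removed_changes, mechanism=steps)


# ---------------------------------------------------------------------------
# Schema (de)serialization.  The JSON shape is documented in
# ``schema/reaction.schema.json`` at the repository root.
# ---------------------------------------------------------------------------


def _changes_to_json(changes: BondChangeSet) -> list[dict]:
    return [{"kind": c.kind.value, "bond": list(c.bond)} for c in sorted(changes)]


def _changes_from_json(records, *, allow_stereo: bool) -> BondChangeSet:
    triples = []
    for rec in records:
        try:
            kind = rec["kind"]
            e1, e2 = rec["bond"]
        except (KeyError, TypeError, ValueError):
            raise ValidationError(f"malformed bond-change record: {rec!r}") from None
        triples.append((kind, e1, e2))
    if allow_stereo:
        return strip_stereo(triples)
    return frozenset(BondChange.of(k, a, b) for k, a, b in triples)


def entry_to_dict(entry: ReactionEntry) -> dict:
    """Serialize an entry to the canonical JSON-schema shape."""
    return {
        "id": entry.id,
        "ec": entry.ec,
        "superfamilies": sorted(entry.superfamilies),
        "overall": _changes_to_json(entry.overall),
        "mechanism": [
            {
                "index": s.index,
                "spontaneous": s.spontaneous,
                "changes": _changes_to_json(s.changes),
            }
            for s in entry.mechanism
        ],
        "permutation_allowed": entry.permutation_allowed,
    }


def entry_from_dict(data: dict) -> ReactionEntry:
    """Parse, validate and canonicalize one reaction record.

    Stereochemistry ("involved") records are accepted in the overall
    reaction only and stripped with a warning.
    """
    try:
        entry_id = data["id"]
        ec = data["ec"]
    except (KeyError, TypeError):
        raise ValidationError(f"record missing 'id'/'ec': {data!r}") from None
    steps = []
    for pos, raw in enumerate(data.get("mechanism", []), start=1):
        steps.append(
            MechanisticStep(
                index=int(raw.get("index", pos)),
                changes=_changes_from_json(raw.get("changes", []), allow_stereo=False),
                spontaneous=bool(raw.get("spontaneous", False)),
            )
        )
    return ReactionEntry(
        id=str(entry_id),
        ec=str(ec),
        superfamilies=frozenset(map(str, data.get("superfamilies", []))),
        overall=_changes_from_json(data.get("overall", []), allow_stereo=True),
        mechanism=tuple(steps),
        permutation_allowed=bool(
            data.get("permutation_allowed", entry_id in PERMUTATION_WHITELIST)
        ),
    )
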