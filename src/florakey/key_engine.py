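"""Matrix-based identification: multi-entry filtering and dichotomous keys.

Two query styles over a :class:`~florakey.flora_model.CharacterMatrix`:

* **multi-entry** — any subset of character states supplied at once filters
  the candidate list (:func:`multi_entry_filter`);
* **single-access (dichotomous)** — a binary decision tree asking for one
  character state at each step (:func:`build_dichotomous_key`,
  :func:`identify_stepwise`).

Missing-data semantics: a taxon scored UNKNOWN on a constrained or splitting
character is conservatively retained (filter) or routed down both branches
(key) — an identification tool must never lose the true taxon to an
unscored cell. Character usability is organ-based: a character is unusable
on a specimen iff its organ is unavailable (e.g. flower characters out of
the flowering period), which is what makes stepwise identification stall.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .flora_model import (
    UNKNOWN,
    CharacterMatrix,
    FloraValidationError,
    SpecimenProfile,
)


@dataclass(frozen=True)
class Filter:
    """Multi-entry query: each constrained character requires one state."""

    constraints: Mapping[str, str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "constraints", dict(self.constraints))

    def __len__(self) -> int:
        return len(self.constraints)

    def extended(self, char_id: str, state: str) -> "Filter":
        merged = dict(self.constraints)
        merged[char_id] = state
        return Filter(merged)


def multi_entry_filter(matrix: CharacterMatrix, query: Filter) -> tuple[str, ...]:
    """Taxa consistent with every constraint (UNKNOWN cells retained).

    Adding a constraint can never enlarge the result. Unknown characters or
    undeclared states raise; jointly unsatisfiable constraints simply yield
    an empty tuple.
    """
    for cid, state in query.constraints.items():
        c = matrix.character(cid)  # raises on unknown character
        if state not in c.states:
            raise FloraValidationError(
                f"character {cid!r}: state {state!r} is not one of {c.states}")
    kept = []
    for t in matrix.taxon_ids:
        ok = True
        for cid, state in query.constraints.items():
            scored = matrix.state(t, cid)
            if scored != UNKNOWN and scored != state:
                ok = False
                break
        if ok:
            kept.append(t)
    return tuple(kept)


@dataclass
class KeyNode:
    """A node of a binarized dichotomous key.

    Internal nodes ask "is *character* in state *split_state*?": ``matches``
    holds taxa answering yes, ``others`` the rest; taxa scored UNKNOWN on
    the character appear under both children. Leaves (``character is
    None``) hold a non-empty taxon tuple whose members the remaining usable
    characters cannot separate.
    """

    character: str | None = None
    split_state: str | None = None
    matches: "KeyNode | None" = None
    others: "KeyNode | None" = None
    taxa: tuple[str, ...] = ()

    @property
    def is_leaf(self) -> bool:
        return self.character is None

    def taxa_under(self) -> tuple[str, ...]:
        """All taxa reachable below this node (deduplicated, sorted)."""
        if self.is_leaf:
            return tuple(sorted(set(self.taxa)))
        out: set[str] = set()
        out.update(self.matches.taxa_under())
        out.update(self.others.taxa_under())
        return tuple(sorted(out))

    def leaves(self) -> list["KeyNode"]:
        if self.is_leaf:
            return [self]
        return self.matches.leaves() + self.others.leaves()

    def depth(self) -> int:
        if self.is_leaf:
            return 0
        return 1 + max(self.matches.depth(), self.others.depth())

    # -- JSON serialization ------------------------------------------------
    def to_dict(self) -> dict:
        if self.is_leaf:
            return {"taxa": list(self.taxa)}
        return {
            "character": self.character,
            "state": self.split_state,
            "matches": self.matches.to_dict(),
            "others": self.others.to_dict(),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "KeyNode":
        if "taxa" in d:
            return cls(taxa=tuple(d["taxa"]))
        return cls(character=d["character"], split_state=d["state"],
                   matches=cls.from_dict(d["matches"]),
                   others=cls.from_dict(d["others"]))

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)

    @classmethod
    def from_json(cls, text: str) -> "KeyNode":
        return cls.from_dict(json.loads(text))


def _best_split(matrix: CharacterMatrix, taxa: Sequence[str],
                usable: Sequence[str]) -> tuple[str, str, list[str], list[str]] | None:
    """Best one-state-vs-rest binary split: minimal |size difference|,
    ties broken by ascending (char_id, state). Both sides must be proper
    subsets so recursion always progresses."""
    best = None
    n = len(taxa)
    for cid in sorted(usable):
        c = matrix.character(cid)
        observed = [matrix.state(t, cid) for t in taxa]
        present_states = sorted({s for s in observed if s != UNKNOWN})
        if len(present_states) < 2:
            continue
        for state in present_states:
            yes = [t for t, s in zip(taxa, observed) if s == state or s == UNKNOWN]
            no = [t for t, s in zip(taxa, observed) if s != state or s == UNKNOWN]
            if not yes or not no or len(yes) == n or len(no) == n:
                continue
            score = abs(len(yes) - len(no))
            key = (score, cid, state)
            if best is None or key < best[0]:
                best = (key, cid, state, yes, no)
    if best is None:
        return None
    _, cid, state, yes, no = best
    return cid, state, yes, no


def build_dichotomous_key(
    matrix: CharacterMatrix,
    taxa_subset: Sequence[str] | None = None,
    usable_characters: Sequence[str] | None = None,
) -> KeyNode:
    """Greedy recursive construction of a binarized dichotomous key.

    At each node the usable character/state pair whose one-vs-rest split is
    most balanced is chosen (tie-break: ascending char_id, then state).
    Recursion stops when no usable character separates the set; leaves may
    then hold more than one taxon (honest indistinguishability).
    """
    taxa = list(taxa_subset) if taxa_subset is not None else list(matrix.taxon_ids)
    if not taxa:
        raise FloraValidationError("cannot build a key over an empty taxon set")
    for t in taxa:
        matrix.taxon(t)  # validate membership
    usable = list(usable_characters) if usable_characters is not None else list(matrix.char_ids)

    def recurse(current: list[str]) -> KeyNode:
        if len(current) == 1:
            return KeyNode(taxa=tuple(current))
        split = _best_split(matrix, current, usable)
        if split is None:
            return KeyNode(taxa=tuple(sorted(current)))
        cid, state, yes, no = split
        return KeyNode(character=cid, split_state=state,
                       matches=recurse(yes), others=recurse(no))

    return recurse(taxa)


class Outcome(enum.Enum):
    SUCCESS = "SUCCESS"
    AMBIGUOUS = "AMBIGUOUS"
    STALLED = "STALLED"
    NO_MATCH = "NO_MATCH"


@dataclass(frozen=True)
class IdentificationResult:
    """Outcome of an identification session.

    * SUCCESS — a single taxon (``taxon`` set).
    * AMBIGUOUS — a multi-taxon leaf was reached (``candidates``).
    * STALLED — the next question needs an unobservable character
      (``blocking_character``); ``candidates`` is the residual taxon set.
    * NO_MATCH — a barcode query fell outside the reference library
      (pipeline level only).
    """

    outcome: Outcome
    taxon: str | None = None
    candidates: tuple[str, ...] = ()
    blocking_character: str | None = None

    @property
    def succeeded(self) -> bool:
        return self.outcome is Outcome.SUCCESS


def identify_stepwise(key: KeyNode, specimen: SpecimenProfile) -> IdentificationResult:
    """Descend the key answering each question from the specimen profile.

    Stalls (rather than guessing) as soon as the node's character is absent
    from the profile, reporting the residual taxa under that node and the
    blocking character.
    """
    node = key
    while not node.is_leaf:
        state = specimen.observed.get(node.character)
        if state is None:
            return IdentificationResult(
                outcome=Outcome.STALLED,
                candidates=node.taxa_under(),
                blocking_character=node.character,
            )
        node = node.matches if state == node.split_state else node.others
    if len(set(node.taxa)) == 1:
        return IdentificationResult(outcome=Outcome.SUCCESS, taxon=node.taxa[0],
                                    candidates=tuple(node.taxa))
    return IdentificationResult(outcome=Outcome.AMBIGUOUS,
                                candidates=tuple(sorted(set(node.taxa))))


def usable_characters_for(matrix: CharacterMatrix,
                          specimen: SpecimenProfile) -> tuple[str, ...]:
    """Characters whose organ is available on the specimen."""
    return tuple(c.char_id for c in matrix.characters
                 if c.organ not in specimen.unavailable_organs)


def residual_key_for(
    matrix: CharacterMatrix,
    taxa_subset: Sequence[str],
    specimen: SpecimenProfile,
) -> KeyNode:
    """Dichotomous key over the residual candidates, restricted to the
    characters observable on the specimen (the morpho-anatomical key built
    only for the species a barcode filter could not separate)."""
    return build_dichotomous_key(matrix, taxa_subset,
                                 usable_characters_for(matrix, specimen))
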