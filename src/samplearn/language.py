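"""Artificial languages as item×slot matrices of grammaticality and frequency.

A language is a small grid: *items* (transitive verbs V1..Vn, or noun
modifiers M1..Mn) crossed with *slots* (sentence constructions C1..C3 for the
word-order family, or contraction positions P1/P2 for the contraction
family).  Each cell is labeled grammatical, ungrammatical, or withheld, and
carries the number of times it is presented during training.  Exactly one
cell per language is withheld — the *exception cell* — whose inferred
grammaticality diagnoses whether a learner treats absence as evidence.

Three languages ship as fixtures (``exp1``, ``exp2``, ``exp3``); new ones can
be defined in YAML without code changes.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping

import yaml

__all__ = [
    "Gram",
    "LanguageSpec",
    "SlotMapping",
    "Sentence",
    "WORD_ORDERS",
    "CONTRACTION_POSITIONS",
    "FIXTURES",
    "build_language",
    "validate_language",
    "realize_sentence",
]


class Gram(str, enum.Enum):
    """Grammaticality label of an item×slot cell."""

    GRAMMATICAL = "grammatical"
    UNGRAMMATICAL = "ungrammatical"
    WITHHELD = "withheld"


#: The three word orders with the subject before the object.
WORD_ORDERS: tuple[str, ...] = ("S-O-V", "S-V-O", "V-S-O")

#: Realizations of contraction slots.
CONTRACTION_POSITIONS: tuple[str, ...] = ("subject_position", "object_position")

FIXTURES: tuple[str, ...] = ("exp1", "exp2", "exp3")

_PARSE_LABEL = {
    "+": Gram.GRAMMATICAL,
    "-": Gram.UNGRAMMATICAL,
    "?": Gram.WITHHELD,
    "grammatical": Gram.GRAMMATICAL,
    "ungrammatical": Gram.UNGRAMMATICAL,
    "withheld": Gram.WITHHELD,
}


@dataclass(frozen=True)
class LanguageSpec:
    """Full declarative description of one artificial language.

    ``grammaticality`` and ``frequency`` are total maps over
    ``items × slots``; ``exception_cell`` names the single withheld cell.
    ``lexicon`` and ``nouns`` are cosmetic surface metadata — the learners
    operate on abstract (item, slot) identities only.
    """

    family: str  # "word_order" | "contraction"
    items: tuple[str, ...]
    slots: tuple[str, ...]
    grammaticality: Mapping[tuple[str, str], Gram]
    frequency: Mapping[tuple[str, str], int]
    nouns: tuple[str, ...]
    lexicon: Mapping[str, str]
    exception_cell: tuple[str, str]
    verb: str | None = None  # carrier verb of contraction-family sentences
    name: str = field(default="custom")

    def cells(self) -> list[tuple[str, str]]:
        return [(i, s) for i in self.items for s in self.slots]

    def item_total(self, item: str) -> int:
        return sum(self.frequency[(item, s)] for s in self.slots)

    def total_trials(self) -> int:
        return sum(self.frequency.values())

    def to_config(self) -> dict:
        """Serialize to the flat structured-config form (round-trips)."""
        cells = {
            item: {
                slot: {
                    "label": self.grammaticality[(item, slot)].value,
                    "freq": int(self.frequency[(item, slot)]),
                }
                for slot in self.slots
            }
            for item in self.items
        }
        cfg = {
            "name": self.name,
            "family": self.family,
            "items": list(self.items),
            "slots": list(self.slots),
            "cells": cells,
            "nouns": list(self.nouns),
            "lexicon": dict(self.lexicon),
            "exception_cell": list(self.exception_cell),
        }
        if self.verb is not None:
            cfg["verb"] = self.verb
        return cfg


@dataclass(frozen=True)
class SlotMapping:
    """Bijection from abstract slots to their surface realization.

    For the word-order family the image is the three S-before-O orders; for
    the contraction family it is {subject_position, object_position}.  The
    mapping is randomized across participants.
    """

    family: str
    mapping: Mapping[str, str]

    def __post_init__(self) -> None:
        values = tuple(self.mapping.values())
        if len(set(values)) != len(values):
            raise ValueError("slot mapping must be a bijection")
        allowed = WORD_ORDERS if self.family == "word_order" else CONTRACTION_POSITIONS
        bad = set(values) - set(allowed)
        if bad:
            raise ValueError(f"realizations {sorted(bad)} not allowed for {self.family}")

    def __getitem__(self, slot: str) -> str:
        return self.mapping[slot]


@dataclass(frozen=True)
class Sentence:
    """One realized surface sentence for an (item, slot) cell."""

    item: str
    slot: str
    subject: str
    object: str
    tokens: tuple[str, ...]
    label: Gram
    contracted_position: str | None = None  # contraction family only

    @property
    def surface(self) -> str:
        return " ".join(self.tokens)

    def subject_index(self) -> int:
        return next(i for i, t in enumerate(self.tokens) if t.startswith(self.subject))

    def object_index(self) -> int:
        subj = self.subject_index()
        return next(
            i
            for i, t in enumerate(self.tokens)
            if i != subj and t.startswith(self.object)
        )


def _load_fixture_config(fixture_id: str) -> dict:
    path = resources.files("samplearn.data").joinpath(f"{fixture_id}.yaml")
    return yaml.safe_load(path.read_text())


def build_language(source: str | Path | Mapping) -> LanguageSpec:
    """Build a :class:`LanguageSpec` from a fixture id, config path, or dict.

    Parameters
    ----------
    source
        One of the fixture ids ``exp1``/``exp2``/``exp3``, a path to a YAML
        config file, or an already-parsed config mapping.

    Raises
    ------
    ValueError
        Unknown fixture id, or a config that violates a language invariant
        (the message names the offending cell).
    """
    if isinstance(source, Mapping):
        cfg = dict(source)
    else:
        src = str(source)
        if src in FIXTURES:
            cfg = _load_fixture_config(src)
        elif Path(src).exists():
            cfg = yaml.safe_load(Path(src).read_text())
        else:
            raise ValueError(
                f"unknown fixture id or missing config file: {source!r} "
                f"(fixtures: {', '.join(FIXTURES)})"
            )

    required = {"family", "items", "slots", "cells", "nouns", "lexicon"}
    missing = required - set(cfg)
    if missing:
        raise ValueError(f"language config missing fields: {sorted(missing)}")

    items = tuple(cfg["items"])
    slots = tuple(cfg["slots"])
    gram: dict[tuple[str, str], Gram] = {}
    freq: dict[tuple[str, str], int] = {}
    for item in items:
        row = cfg["cells"].get(item)
        if row is None:
            raise ValueError(f"cells table has no row for item {item!r}")
        for slot in slots:
            cell = row.get(slot)
            if cell is None:
                raise ValueError(f"cells table missing cell ({item}, {slot})")
            gram[(item, slot)] = _PARSE_LABEL[str(cell["label"])]
            freq[(item, slot)] = int(cell["freq"])

    withheld = [c for c, g in gram.items() if g is Gram.WITHHELD]
    exception = tuple(cfg.get("exception_cell", withheld[0] if withheld else ("", "")))

    spec = LanguageSpec(
        family=str(cfg["family"]),
        items=items,
        slots=slots,
        grammaticality=gram,
        frequency=freq,
        nouns=tuple(cfg["nouns"]),
        lexicon=dict(cfg["lexicon"]),
        exception_cell=(exception[0], exception[1]),
        verb=cfg.get("verb"),
        name=str(cfg.get("name", "custom")),
    )
    violations = validate_language(spec)
    if violations:
        raise ValueError("invalid language config: " + "; ".join(violations))
    return spec


def validate_language(spec: LanguageSpec) -> list[str]:
    """Check all language invariants; return human-readable violations.

    Returns an empty list iff the spec is valid.  Never raises.
    """
    out: list[str] = []
    cells = spec.cells()
    for cell in cells:
        if cell not in spec.grammaticality:
            out.append(f"grammaticality missing for cell {cell}")
        if cell not in spec.frequency:
            out.append(f"frequency missing for cell {cell}")

    withheld = [c for c in cells if spec.grammaticality.get(c) is Gram.WITHHELD]
    if len(withheld) != 1:
        out.append(
            f"exactly one cell must be withheld (exception-cell uniqueness); "
            f"found {len(withheld)}: {withheld}"
        )
    elif withheld[0] != tuple(spec.exception_cell):
        out.append(
            f"exception_cell {spec.exception_cell} does not match the withheld "
            f"cell {withheld[0]}"
        )
    for cell in withheld:
        if spec.frequency.get(cell, 0) != 0:
            out.append(f"withheld cell {cell} has nonzero frequency {spec.frequency[cell]}")
    for cell, f in spec.frequency.items():
        if f < 0:
            out.append(f"cell {cell} has negative frequency {f}")

    if spec.family == "word_order" and len(spec.slots) != 3:
        out.append(f"word_order family requires 3 slots, got {len(spec.slots)}")
    if spec.family == "contraction":
        if len(spec.slots) != 2:
            out.append(f"contraction family requires 2 slots, got {len(spec.slots)}")
        if spec.verb is None:
            out.append("contraction family requires a carrier verb")
    if spec.family not in ("word_order", "contraction"):
        out.append(f"unknown family {spec.family!r}")

    for item in spec.items:
        if item not in spec.lexicon:
            out.append(f"lexicon missing surface form for item {item!r}")
    if len(spec.nouns) < 2:
        out.append("at least two nouns are required")
    return out


def _contract(noun: str, modifier: str) -> str:
    # noun + apostrophe + first vowel-bearing fragment of the modifier,
    # e.g. tombat + ka -> tombat'a
    for i, ch in enumerate(modifier):
        if ch in "aeiou":
            return f"{noun}'{modifier[i:]}"
    return f"{noun}'{modifier}"


def realize_sentence(
    spec: LanguageSpec,
    mapping: SlotMapping,
    item: str,
    slot: str,
    subject: str,
    object: str,
) -> Sentence:
    """Realize the abstract cell (item, slot) as a surface sentence.

    Word-order family: arranges subject noun, object noun and the item's verb
    according to the word order the mapping assigns to the slot.  Contraction
    family: both nouns carry the item's modifier and exactly one noun+modifier
    group — at the position the mapping assigns to the slot — is contracted.
    """
    if item not in spec.items:
        raise ValueError(f"unknown item {item!r}")
    if slot not in spec.slots:
        raise ValueError(f"unknown slot {slot!r}")
    if subject == object:
        raise ValueError("subject and object nouns must differ")
    for noun in (subject, object):
        if noun not in spec.nouns:
            raise ValueError(f"noun {noun!r} not in the language's noun inventory")

    # withheld cells keep the WITHHELD label; they appear only in test prompts
    label = spec.grammaticality[(item, slot)]

    if spec.family == "word_order":
        verb = spec.lexicon[item]
        order = mapping[slot]
        token_of = {"S": subject, "O": object, "V": verb}
        tokens = tuple(token_of[part] for part in order.split("-"))
        return Sentence(item, slot, subject, object, tokens, label)

    modifier = spec.lexicon[item]
    position = mapping[slot]
    if position == "subject_position":
        subj_group = (_contract(subject, modifier),)
        obj_group = (object, modifier)
    else:
        subj_group = (subject, modifier)
        obj_group = (_contract(object, modifier),)
    tokens = subj_group + (spec.verb,) + obj_group
    return Sentence(item, slot, subject, object, tokens, label, contracted_position=position)
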