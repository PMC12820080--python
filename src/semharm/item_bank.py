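"""Data model, I/O and text preprocessing for rating-scale items.

The unit of analysis throughout the package is a *scale item*: one named
symptom (e.g. ``TLC-10`` "Neologisms") with a free-text description drawn
from a psychopathology rating instrument.  An :class:`ItemBank` pools items
from several instruments into a single ordered corpus, which downstream
modules embed, cluster and score.

Scale texts themselves are copyrighted and never bundled; banks are loaded
from user-supplied CSV/JSON files (header ``scale_id,item_index,label,
description``) or generated synthetically (:mod:`semharm.synthetic`).
"""

from __future__ import annotations

import csv
import json
import re
from collections import Counter
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

__all__ = [
    "ScaleItem",
    "ItemBank",
    "ConstructDescription",
    "LengthSummary",
    "ItemBankError",
    "SchemaError",
    "DuplicateItemError",
    "EmptyBankError",
    "load_item_bank",
    "save_item_bank",
    "load_constructs",
    "preprocess_text",
    "preprocess_bank",
    "length_statistics",
]

REQUIRED_COLUMNS = ("scale_id", "item_index", "label", "description")

#: parenthetical groups whose content starts with one of these prefixes are
#: treated as illustrative examples and stripped during preprocessing
DEFAULT_ILLUSTRATIVE_PREFIXES = ("e.g.", "i.e.")


class ItemBankError(ValueError):
    """Base class for item-bank loading and validation failures."""


class SchemaError(ItemBankError):
    """A required column or key is missing from the input file."""


class DuplicateItemError(ItemBankError):
    """Two rows resolve to the same ``scale_id-item_index`` identifier."""


class EmptyBankError(ItemBankError):
    """The input file contains no items."""


@dataclass(frozen=True)
class ScaleItem:
    """A single rating-scale item.

    ``item_index`` is kept as a string so that alphanumeric labels such as
    PANSS "N7" or "P2" survive round-trips unchanged.
    """

    scale_id: str
    item_index: str
    label: str
    description: str
    clean_text: str = ""

    @property
    def item_id(self) -> str:
        return f"{self.scale_id}-{self.item_index}"

    @property
    def word_count(self) -> int:
        """Whitespace-token count of the *raw* description.

        Computed before any preprocessing, so it is invariant to the
        lowercase and illustrative-stripping flags.
        """
        return len(self.description.split())


@dataclass(frozen=True)
class ItemBank:
    """An ordered corpus of scale items with unique identifiers."""

    items: tuple[ScaleItem, ...]

    def __post_init__(self) -> None:
        ids = [it.item_id for it in self.items]
        dupes = sorted({i for i, c in Counter(ids).items() if c > 1})
        if dupes:
            raise DuplicateItemError(
                f"duplicate item_id(s): {', '.join(dupes)}"
            )

    @property
    def scales(self) -> tuple[str, ...]:
        """Scale ids in first-appearance order."""
        seen: dict[str, None] = {}
        for it in self.items:
            seen.setdefault(it.scale_id, None)
        return tuple(seen)

    @property
    def item_ids(self) -> tuple[str, ...]:
        return tuple(it.item_id for it in self.items)

    def __len__(self) -> int:
        return len(self.items)

    def __iter__(self):
        return iter(self.items)

    def __getitem__(self, item_id: str) -> ScaleItem:
        for it in self.items:
            if it.item_id == item_id:
                return it
        raise KeyError(item_id)

    def subset(self, scale_ids: Iterable[str]) -> "ItemBank":
        wanted = set(scale_ids)
        return ItemBank(tuple(it for it in self.items if it.scale_id in wanted))


@dataclass(frozen=True)
class ConstructDescription:
    """A free-text paragraph describing a clinical construct.

    Construct paragraphs (e.g. the classical positive / negative formal
    thought disorder definitions) are embedded whole, without the
    illustrative-parenthetical stripping applied to scale items.
    """

    construct_id: str
    text: str

    def __post_init__(self) -> None:
        if not self.text.strip():
            raise ItemBankError(
                f"construct {self.construct_id!r} has empty text"
            )


@dataclass(frozen=True)
class LengthSummary:
    """Per-scale mean and maximum raw word counts."""

    mean_words: Mapping[str, float]
    max_words: Mapping[str, int]

    def to_rows(self) -> list[tuple[str, float, int]]:
        return [(s, self.mean_words[s], self.max_words[s]) for s in self.mean_words]


def _rows_to_bank(rows: Sequence[Mapping[str, str]], source: str) -> ItemBank:
    if not rows:
        raise EmptyBankError(f"{source}: no items found")
    items = []
    for i, row in enumerate(rows):
        missing = [c for c in REQUIRED_COLUMNS if c not in row or row[c] is None]
        if missing:
            raise SchemaError(
                f"{source}: record {i} is missing column(s) {', '.join(missing)}"
            )
        items.append(
            ScaleItem(
                scale_id=str(row["scale_id"]),
                item_index=str(row["item_index"]),
                label=str(row["label"]),
                description=str(row["description"]),
            )
        )
    return ItemBank(tuple(items))


def load_item_bank(path: str | Path, format: str | None = None) -> ItemBank:
    """Load an item bank from CSV or JSON, preserving input order.

    ``format`` is inferred from the file suffix when not given.  The file
    must provide ``scale_id, item_index, label, description`` per record;
    ``item_id`` is synthesized as ``"<scale_id>-<item_index>"`` and must be
    unique across the bank.
    """
    path = Path(path)
    if format is None:
        format = "json" if path.suffix.lower() == ".json" else "csv"
    if format == "csv":
        with path.open(newline="", encoding="utf-8") as fh:
            reader = csv.DictReader(fh)
            if reader.fieldnames is None:
                raise EmptyBankError(f"{path}: file is empty")
            missing = [c for c in REQUIRED_COLUMNS if c not in reader.fieldnames]
            if missing:
                raise SchemaError(
                    f"{path}: header is missing column(s) {', '.join(missing)}"
                )
            rows = list(reader)
    elif format == "json":
        with path.open(encoding="utf-8") as fh:
            data = json.load(fh)
        if not isinstance(data, list):
            raise SchemaError(f"{path}: expected a JSON array of objects")
        rows = data
    else:
        raise ValueError(f"unknown format {format!r}")
    return _rows_to_bank(rows, str(path))


def save_item_bank(bank: ItemBank, path: str | Path, format: str | None = None) -> None:
    """Write a bank back to CSV or JSON (lossless round-trip)."""
    path = Path(path)
    if format is None:
        format = "json" if path.suffix.lower() == ".json" else "csv"
    records = [
        {
            "scale_id": it.scale_id,
            "item_index": it.item_index,
            "label": it.label,
            "description": it.description,
        }
        for it in bank
    ]
    if format == "csv":
        with path.open("w", newline="", encoding="utf-8") as fh:
            writer = csv.DictWriter(fh, fieldnames=list(REQUIRED_COLUMNS))
            writer.writeheader()
            writer.writerows(records)
    elif format == "json":
        path.write_text(json.dumps(records, indent=2), encoding="utf-8")
    else:
        raise ValueError(f"unknown format {format!r}")


def load_constructs(path: str | Path) -> tuple[ConstructDescription, ...]:
    """Load construct descriptions from a JSON object ``{construct_id: text}``."""
    data = json.loads(Path(path).read_text(encoding="utf-8"))
    if not isinstance(data, dict):
        raise SchemaError(f"{path}: expected a JSON object construct_id -> text")
    return tuple(ConstructDescription(k, v) for k, v in data.items())


def _illustrative_pattern(prefixes: Sequence[str]) -> re.Pattern[str]:
    alts = "|".join(re.escape(p) for p in prefixes)
    # non-nested parenthetical whose content begins with an illustrative prefix
    return re.compile(rf"\(\s*(?:{alts})[^()]*\)", re.IGNORECASE)


def preprocess_text(
    raw: str,
    strip_illustrative: bool = True,
    lowercase: bool = True,
    illustrative_prefixes: Sequence[str] = DEFAULT_ILLUSTRATIVE_PREFIXES,
) -> str:
    """Clean one description for embedding.

    Parenthetical groups whose content begins with ``e.g.`` or ``i.e.``
    (case-insensitive, optional leading whitespace) are removed together
    with their parentheses; other parentheticals — which often carry
    synonyms like "(Word salad, Jargon Aphasia)" — are kept.  Whitespace is
    collapsed to single spaces and trimmed.  Idempotent.
    """
    text = raw
    if strip_illustrative and illustrative_prefixes:
        pat = _illustrative_pattern(illustrative_prefixes)
        prev = None
        while prev != text:  # re-scan in case stripping exposes a nested group
            prev = text
            text = pat.sub(" ", text)
    if lowercase:
        text = text.lower()
    return " ".join(text.split())


def preprocess_bank(
    bank: ItemBank,
    strip_illustrative: bool = True,
    lowercase: bool = True,
    illustrative_prefixes: Sequence[str] = DEFAULT_ILLUSTRATIVE_PREFIXES,
    include_label: bool = False,
) -> ItemBank:
    """Return a bank with ``clean_text`` filled for every item.

    By default only the description is embedded; set ``include_label`` to
    prepend the item title.
    """
    items = []
    for it in bank:
        raw = f"{it.label}. {it.description}" if include_label else it.description
        clean = preprocess_text(
            raw, strip_illustrative, lowercase, illustrative_prefixes
        )
        if it.description.strip() and not clean:
            raise ItemBankError(
                f"{it.item_id}: preprocessing erased a nonempty description"
            )
        items.append(replace(it, clean_text=clean))
    return ItemBank(tuple(items))


def length_statistics(bank: ItemBank) -> LengthSummary:
    """Per-scale mean and maximum whitespace-token counts of raw descriptions."""
    if len(bank) == 0:
        raise EmptyBankError("cannot summarize an empty bank")
    mean: dict[str, float] = {}
    mx: dict[str, int] = {}
    for scale in bank.scales:
        counts = [it.word_count for it in bank if it.scale_id == scale]
        mean[scale] = sum(counts) / len(counts)
        mx[scale] = max(counts)
    return LengthSummary(mean_words=mean, max_words=mx)
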