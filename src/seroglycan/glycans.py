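"""Oligosaccharide composition parsing and decoration-subgroup classification.

Glycans on shotgun milk-oligosaccharide arrays are annotated only by
monosaccharide composition, written as counts of hexose (H), N-acetyl-
hexosamine (N), fucose (F) and N-acetylneuraminic/sialic acid (S), e.g.
``H4N2F3``.  Some features carry an alias in parentheses (``H2F1 (3-FL)``),
some are ambiguous between two compositions (``H6N4F4/H7N5F2``) and some are
simply ``unknown``.

This module parses such labels and classifies each glycan by its decoration
state (fucosylated and/or sialylated) and by fucose/sialic-acid count bands
(F1, F2-F4, S1, S2, ...), the subgroups over which reactivity summaries and
group comparisons are defined.
"""

from __future__ import annotations

import logging
import re
from collections import Counter
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, NamedTuple, Sequence

logger = logging.getLogger(__name__)

_MONOSACCHARIDE_ORDER = "HNFS"
_TOKEN_RE = re.compile(r"([A-Za-z])(\d*)")
_ALIAS_RE = re.compile(r"\s*\(([^()]*)\)\s*$")

__all__ = [
    "GlycanComposition",
    "CompositionSet",
    "DecorationClass",
    "FucoseBand",
    "SialicBand",
    "DecorationBands",
    "CompositionParseError",
    "parse_composition",
    "decoration_class",
    "decoration_bands",
    "partition_library",
    "LibraryPartition",
]


class CompositionParseError(ValueError):
    """Raised for malformed composition labels; reports token and position."""

    def __init__(self, message: str, label: str, token: str = "", position: int = -1):
        self.label = label
        self.token = token
        self.position = position
        detail = f"{message} in label {label!r}"
        if token:
            detail += f" (token {token!r} at position {position})"
        super().__init__(detail)


@dataclass(frozen=True, order=True)
class GlycanComposition:
    """Monosaccharide counts of one composition alternative.

    ``alias`` is descriptive metadata (a trivial name such as ``3-FL``) and
    never participates in classification or equality of counts.
    """

    hexose_count: int = 0
    hexnac_count: int = 0
    fucose_count: int = 0
    sialic_count: int = 0
    alias: str | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        counts = self.counts
        if any(c < 0 for c in counts.values()):
            raise ValueError(f"negative monosaccharide count in {counts}")
        if all(c == 0 for c in counts.values()):
            raise ValueError("a composition must contain at least one monosaccharide")

    @property
    def counts(self) -> dict[str, int]:
        return {
            "H": self.hexose_count,
            "N": self.hexnac_count,
            "F": self.fucose_count,
            "S": self.sialic_count,
        }

    def render(self, with_alias: bool = True) -> str:
        """Canonical label: letters in H, N, F, S order, zero counts omitted."""
        body = "".join(
            f"{letter}{count}" for letter, count in self.counts.items() if count > 0
        )
        if with_alias and self.alias:
            body += f" ({self.alias})"
        return body


@dataclass(frozen=True)
class CompositionSet:
    """All composition alternatives a label admits, or the unknown marker."""

    alternatives: tuple[GlycanComposition, ...]
    source_label: str
    unknown: bool = False

    def __post_init__(self) -> None:
        if self.unknown and self.alternatives:
            raise ValueError("unknown composition sets carry no alternatives")
        if not self.unknown and not self.alternatives:
            raise ValueError("a known composition set needs >= 1 alternative")

    @property
    def is_ambiguous(self) -> bool:
        return len(self.alternatives) > 1

    def render(self) -> str:
        if self.unknown:
            return "unknown"
        body = "/".join(a.render(with_alias=False) for a in self.alternatives)
        alias = self.alternatives[0].alias
        if alias:
            body += f" ({alias})"
        return body


class DecorationClass(str, Enum):
    UNDECORATED = "undecorated"
    FUCOSYLATED_ONLY = "fucosylated_only"
    SIALYLATED_ONLY = "sialylated_only"
    FUCOSYLATED_SIALYLATED = "fucosylated_sialylated"
    UNKNOWN = "unknown"
    AMBIGUOUS = "ambiguous"


class FucoseBand(str, Enum):
    F0 = "F0"
    F1 = "F1"
    F2TO4 = "F2to4"
    F_GT4 = "F_gt4"
    AMBIGUOUS = "ambiguous"


class SialicBand(str, Enum):
    S0 = "S0"
    S1 = "S1"
    S2 = "S2"
    S_GT2 = "S_gt2"
    AMBIGUOUS = "ambiguous"


class DecorationBands(NamedTuple):
    fucose_band: FucoseBand
    sialic_band: SialicBand


def _parse_alternative(alt: str, label: str, offset: int) -> GlycanComposition:
    counts: dict[str, int] = {letter: 0 for letter in _MONOSACCHARIDE_ORDER}
    pos = 0
    stripped = alt.strip()
    if not stripped:
        raise CompositionParseError("empty composition alternative", label)
    while pos < len(stripped):
        match = _TOKEN_RE.match(stripped, pos)
        if match is None:
            raise CompositionParseError(
                "unparseable token", label, stripped[pos], offset + pos
            )
        letter, digits = match.group(1), match.group(2)
        token = match.group(0)
        if letter.upper() not in counts:
            raise CompositionParseError(
                "unrecognized monosaccharide letter", label, token, offset + pos
            )
        if not digits:
            raise CompositionParseError(
                "monosaccharide letter without a count", label, token, offset + pos
            )
        value = int(digits)
        if value <= 0:
            raise CompositionParseError(
                "monosaccharide count must be positive", label, token, offset + pos
            )
        if counts[letter.upper()] != 0:
            raise CompositionParseError(
                "duplicate monosaccharide letter", label, token, offset + pos
            )
        counts[letter.upper()] = value
        pos = match.end()
    return GlycanComposition(
        hexose_count=counts["H"],
        hexnac_count=counts["N"],
        fucose_count=counts["F"],
        sialic_count=counts["S"],
    )


def parse_composition(label: str) -> CompositionSet:
    """Parse a composition label into its alternatives.

    Grammar: one or more ``{H,N,F,S}<positive int>`` tokens per alternative,
    alternatives separated by ``/``, an optional trailing ``(alias)``, or the
    literal ``unknown`` (case-insensitive).  Letter order within an
    alternative is irrelevant; absent letters mean count zero.

    Raises
    ------
    CompositionParseError
        For empty labels and malformed tokens (``H0``, ``X3``, a dangling
        digit); the error names the offending token and its position.
    """
    if not isinstance(label, str) or not label.strip():
        raise CompositionParseError("empty composition label", str(label))
    text = label.strip()
    if text.lower() == "unknown":
        return CompositionSet(alternatives=(), source_label=label, unknown=True)

    alias: str | None = None
    alias_match = _ALIAS_RE.search(text)
    if alias_match:
        alias = alias_match.group(1).strip() or None
        text = text[: alias_match.start()].strip()
        if not text:
            raise CompositionParseError("label contains only an alias", label)

    alternatives: list[GlycanComposition] = []
    offset = 0
    for part in text.split("/"):
        comp = _parse_alternative(part, label, offset)
        if alias is not None:
            comp = GlycanComposition(
                comp.hexose_count,
                comp.hexnac_count,
                comp.fucose_count,
                comp.sialic_count,
                alias=alias,
            )
        if comp not in alternatives:
            alternatives.append(comp)
        offset += len(part) + 1
    return CompositionSet(alternatives=tuple(alternatives), source_label=label)


def _single_class(comp: GlycanComposition) -> DecorationClass:
    fucosylated = comp.fucose_count > 0
    sialylated = comp.sialic_count > 0
    if fucosylated and sialylated:
        return DecorationClass.FUCOSYLATED_SIALYLATED
    if fucosylated:
        return DecorationClass.FUCOSYLATED_ONLY
    if sialylated:
        return DecorationClass.SIALYLATED_ONLY
    return DecorationClass.UNDECORATED


def decoration_class(comp: CompositionSet) -> DecorationClass:
    """Decoration state of a glycan; ambiguous sets must agree unanimously.

    A multi-alternative set is assigned a class only when every alternative
    lands in the same class — a glycan never joins a subgroup its annotation
    cannot guarantee.
    """
    if comp.unknown:
        return DecorationClass.UNKNOWN
    classes = {_single_class(a) for a in comp.alternatives}
    if len(classes) == 1:
        return classes.pop()
    return DecorationClass.AMBIGUOUS


def _fucose_band(count: int) -> FucoseBand:
    if count == 0:
        return FucoseBand.F0
    if count == 1:
        return FucoseBand.F1
    if count <= 4:
        return FucoseBand.F2TO4
    return FucoseBand.F_GT4


def _sialic_band(count: int) -> SialicBand:
    if count == 0:
        return SialicBand.S0
    if count == 1:
        return SialicBand.S1
    if count == 2:
        return SialicBand.S2
    return SialicBand.S_GT2


def decoration_bands(comp: CompositionSet) -> DecorationBands:
    """Fucose / sialic-acid count bands (F0, F1, F2-F4, ...; S0, S1, S2, ...).

    Bands beyond the classic figure range (more than four fucoses, more than
    two sialic acids) are kept distinct, never merged into F2to4/S2.  As for
    classes, a multi-alternative set gets a band only on unanimity.
    """
    if comp.unknown:
        return DecorationBands(FucoseBand.AMBIGUOUS, SialicBand.AMBIGUOUS)
    f_bands = {_fucose_band(a.fucose_count) for a in comp.alternatives}
    s_bands = {_sialic_band(a.sialic_count) for a in comp.alternatives}
    return DecorationBands(
        f_bands.pop() if len(f_bands) == 1 else FucoseBand.AMBIGUOUS,
        s_bands.pop() if len(s_bands) == 1 else SialicBand.AMBIGUOUS,
    )


@dataclass(frozen=True)
class LibraryPartition:
    """Classification of every glycan in an array library."""

    compositions: dict[str, CompositionSet]
    classes: dict[str, DecorationClass]
    bands: dict[str, DecorationBands]

    @property
    def class_counts(self) -> Counter:
        return Counter(self.classes.values())

    def __len__(self) -> int:
        return len(self.classes)

    def ids_in_class(self, cls: DecorationClass) -> list[str]:
        return [g for g, c in self.classes.items() if c is cls]

    def ids_in_fucose_band(self, band: FucoseBand) -> list[str]:
        return [g for g, b in self.bands.items() if b.fucose_band is band]

    def ids_in_sialic_band(self, band: SialicBand) -> list[str]:
        return [g for g, b in self.bands.items() if b.sialic_band is band]


def partition_library(
    labels: Mapping[str, str] | Sequence[str] | Iterable[str],
) -> LibraryPartition:
    """Classify a whole library; unparseable labels become ``unknown``.

    Accepts a mapping ``glycan_id -> composition_label`` or a plain sequence
    of labels (ids are then generated as ``g0001``...).  Parse failures are
    collected, logged as warnings and classified unknown — never fatal.
    The result is a partition: every id appears exactly once and class
    counts sum to the library size.
    """
    if isinstance(labels, Mapping):
        items = list(labels.items())
    else:
        items = [(f"g{i + 1:04d}", label) for i, label in enumerate(labels)]

    compositions: dict[str, CompositionSet] = {}
    classes: dict[str, DecorationClass] = {}
    bands: dict[str, DecorationBands] = {}
    for glycan_id, label in items:
        try:
            comp = parse_composition(label)
        except CompositionParseError as exc:
            logger.warning("glycan %s: %s; classified unknown", glycan_id, exc)
            comp = CompositionSet(alternatives=(), source_label=str(label), unknown=True)
        compositions[glycan_id] = comp
        classes[glycan_id] = decoration_class(comp)
        bands[glycan_id] = decoration_bands(comp)

    partition = LibraryPartition(compositions, classes, bands)
    logger.info(
        "classified %d glycans: %s",
        len(partition),
        dict(partition.class_counts),
    )
    return partition
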