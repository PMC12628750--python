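"""Motif algebra and repeat-configuration handling.

Motif identity is strand- and phase-free: two motifs are "the same" when one
is a rotation of the other or of its reverse complement.  The canonical key
of a motif is the lexicographically smallest string over all rotations of the
motif and of its reverse complement, giving every equivalence class a single
deterministic representative while the display spelling (the orientation a
motif is usually written in, e.g. ``TTTCA``) is preserved for reporting.

Repeat structures are written as ``(MOTIF)N-(MOTIF)N-...`` where ``N`` is a
positive copy count; :func:`parse_config` and :func:`format_config` are exact
inverses on valid configurations.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "PentaplexError",
    "InvalidAlphabetError",
    "RegionParseError",
    "ConfigParseError",
    "ConfigurationError",
    "RepeatMotif",
    "LocusSpec",
    "RepeatConfiguration",
    "reverse_complement",
    "rotations",
    "canonical_key",
    "parse_region",
    "format_region",
    "parse_config",
    "format_config",
    "config_to_sequence",
    "load_locus_json",
]


class PentaplexError(Exception):
    """Base class for all toolkit errors."""


class InvalidAlphabetError(PentaplexError, ValueError):
    """A sequence or motif contains characters outside A/C/G/T."""


class RegionParseError(PentaplexError, ValueError):
    """A ``contig:first-last`` region string is malformed."""


class ConfigParseError(PentaplexError, ValueError):
    """A ``(MOTIF)N-...`` configuration string is malformed."""


class ConfigurationError(PentaplexError, ValueError):
    """An operation was invoked with an inconsistent parameter set."""


_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_ACGT = frozenset("ACGT")


def reverse_complement(seq: str) -> str:
    """Reverse complement of an A/C/G/T/N string."""
    return seq.translate(_COMPLEMENT)[::-1]


def rotations(s: str) -> list[str]:
    """All cyclic rotations of ``s`` (length |s|, including ``s`` itself)."""
    return [s[i:] + s[:i] for i in range(len(s))]


def canonical_key(motif: str) -> str:
    """Canonical representative of a motif's rotation/reverse-complement class.

    Returns the lexicographically smallest string among all rotations of
    ``motif`` and all rotations of its reverse complement.  Idempotent:
    ``canonical_key(canonical_key(m)) == canonical_key(m)``.

    Raises
    ------
    InvalidAlphabetError
        If ``motif`` is empty or contains a character outside A/C/G/T.
    """
    if not motif or not _ACGT.issuperset(motif):
        raise InvalidAlphabetError(
            f"motif must be a non-empty A/C/G/T string, got {motif!r}"
        )
    return min(min(rotations(motif)), min(rotations(reverse_complement(motif))))


@dataclass(frozen=True)
class RepeatMotif:
    """A repeat motif with its strand/phase-free identity.

    ``display`` keeps the spelling the motif was supplied in; ``canonical_key``
    is shared by every rotation of ``display`` and of its reverse complement.
    """

    display: str
    canonical_key: str = field(init=False)
    length: int = field(init=False)

    def __post_init__(self) -> None:
        if not 1 <= len(self.display) <= 30:
            raise InvalidAlphabetError(
                f"motif length must be 1-30 bp, got {len(self.display)}"
            )
        object.__setattr__(self, "canonical_key", canonical_key(self.display))
        object.__setattr__(self, "length", len(self.display))

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.display

    def same_class(self, other: "RepeatMotif | str") -> bool:
        key = other.canonical_key if isinstance(other, RepeatMotif) else canonical_key(other)
        return self.canonical_key == key


def as_motif(m: "RepeatMotif | str") -> RepeatMotif:
    """Coerce a string to a :class:`RepeatMotif` (no-op on motif input)."""
    return m if isinstance(m, RepeatMotif) else RepeatMotif(m)


def check_distinct_motifs(motifs: Sequence[RepeatMotif]) -> None:
    """Raise :class:`ConfigurationError` unless canonical keys are pairwise distinct."""
    if not motifs:
        raise ConfigurationError("motif list must not be empty")
    keys = [m.canonical_key for m in motifs]
    if len(set(keys)) != len(keys):
        raise ConfigurationError(f"motifs must be distinct by canonical key: {keys}")


_REGION_RE = re.compile(r"^([^:\s]+):(\d+)-(\d+)$")


def parse_region(region: str) -> tuple[str, int, int]:
    """Parse ``contig:first-last`` (1-based inclusive) to 0-based half-open.

    ``"chr5:10356339-10356411"`` -> ``("chr5", 10356338, 10356411)`` (73 bp).
    """
    m = _REGION_RE.match(region.strip())
    if m is None:
        raise RegionParseError(f"malformed region string: {region!r}")
    contig, first, last = m.group(1), int(m.group(2)), int(m.group(3))
    if first < 1 or first > last:
        raise RegionParseError(f"invalid interval {first}-{last} in {region!r}")
    return contig, first - 1, last


def format_region(contig: str, start: int, end: int) -> str:
    """Inverse of :func:`parse_region` (back to 1-based inclusive)."""
    return f"{contig}:{start + 1}-{end}"


@dataclass(frozen=True)
class LocusSpec:
    """A named genomic interval with the motifs expected at the locus."""

    name: str
    contig: str
    start: int  # 0-based inclusive
    end: int  # 0-based exclusive
    target_motifs: tuple[RepeatMotif, ...]

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ConfigurationError(
                f"locus interval must satisfy 0 <= start < end, got [{self.start}, {self.end})"
            )
        check_distinct_motifs(self.target_motifs)
        object.__setattr__(self, "target_motifs", tuple(self.target_motifs))

    @property
    def region(self) -> str:
        return format_region(self.contig, self.start, self.end)


@dataclass(frozen=True)
class RepeatConfiguration:
    """Ordered (motif, copies) blocks with optional flanking sequence."""

    blocks: tuple[tuple[RepeatMotif, int], ...]
    left_flank: str = ""
    right_flank: str = ""

    def __post_init__(self) -> None:
        blocks = tuple((as_motif(m), int(c)) for m, c in self.blocks)
        for _, copies in blocks:
            if copies < 1:
                raise ConfigParseError(f"block copy count must be positive, got {copies}")
        for (a, _), (b, _) in zip(blocks, blocks[1:]):
            if a.canonical_key == b.canonical_key:
                raise ConfigParseError(
                    f"adjacent blocks must differ in canonical key ({a.display}, {b.display})"
                )
        for flank in (self.left_flank, self.right_flank):
            if flank and not set("ACGTN").issuperset(flank):
                raise InvalidAlphabetError("flank sequence must be A/C/G/T/N")
        object.__setattr__(self, "blocks", blocks)

    @property
    def total_repeat_bp(self) -> int:
        return sum(c * m.length for m, c in self.blocks)

    def with_flanks(self, left: str, right: str) -> "RepeatConfiguration":
        return RepeatConfiguration(self.blocks, left, right)


_BLOCK_RE = re.compile(r"^\(([ACGT]+)\)(-?\d+)$")


def parse_config(
    text: str, left_flank: str = "", right_flank: str = ""
) -> RepeatConfiguration:
    """Parse ``"(MOTIF)N-(MOTIF)N-..."`` into a :class:`RepeatConfiguration`.

    Copy counts must be positive integers; motifs must be A/C/G/T.  Round-trips
    through :func:`format_config`.
    """
    text = text.strip()
    if not text:
        raise ConfigParseError("empty configuration string")
    blocks: list[tuple[RepeatMotif, int]] = []
    # split on '-' only between a ')' digit run and a '('
    for part in re.split(r"(?<=\d)-(?=\()", text):
        m = _BLOCK_RE.match(part)
        if m is None:
            raise ConfigParseError(f"malformed block {part!r} in {text!r}")
        copies = int(m.group(2))
        if copies < 1:
            raise ConfigParseError(f"copy count must be positive in {part!r}")
        blocks.append((RepeatMotif(m.group(1)), copies))
    return RepeatConfiguration(tuple(blocks), left_flank, right_flank)


def format_config(config: RepeatConfiguration) -> str:
    """Inverse of :func:`parse_config` (flanks are not represented)."""
    return "-".join(f"({m.display}){c}" for m, c in config.blocks)


def config_to_sequence(config: RepeatConfiguration) -> str:
    """Materialize a configuration: left flank + blocks in order + right flank."""
    body = "".join(m.display * c for m, c in config.blocks)
    return config.left_flank + body + config.right_flank


def load_locus_json(path: str | Path) -> LocusSpec:
    """Load ``{name, region: "contig:first-last", motifs: [...]}`` from JSON."""
    with open(path) as fh:
        obj = json.load(fh)
    contig, start, end = parse_region(obj["region"])
    return LocusSpec(
        name=obj["name"],
        contig=contig,
        start=start,
        end=end,
        target_motifs=tuple(RepeatMotif(m) for m in obj["motifs"]),
    )


def motifs_from_strings(specs: Iterable[str]) -> tuple[RepeatMotif, ...]:
    """Build a distinct motif tuple from display strings (validates distinctness)."""
    motifs = tuple(RepeatMotif(s) for s in specs)
    check_distinct_motifs(motifs)
    return motifs
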