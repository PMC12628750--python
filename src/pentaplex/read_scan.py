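"""Per-read repeat-content profiling.

A *run* is a maximal substring that is an exact cyclic repetition of some
rotation of a target motif (or of its reverse complement when both-strand
scanning is enabled).  Runs shorter than ``min_run_bp`` (default: two full
motif copies) are discarded — a single motif occurrence is not a tandem
repeat.  ``N`` (or any non-ACGT character) never matches and breaks runs.

Per-read summaries report, for each motif, the union base-pair coverage of
that motif's runs, plus the union coverage over all runs of all motifs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Sequence

from .repeat_model import (
    RepeatMotif,
    as_motif,
    check_distinct_motifs,
    reverse_complement,
    rotations,
)

__all__ = ["RepeatRun", "ReadRepeatProfile", "find_runs", "profile_read", "repeat_fraction"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RepeatRun:
    """A maximal exact tandem run of one motif within a read."""

    start: int  # 0-based
    end: int  # exclusive
    motif: RepeatMotif

    @property
    def bp(self) -> int:
        return self.end - self.start

    @property
    def copies(self) -> Fraction:
        return Fraction(self.bp, self.motif.length)


@dataclass(frozen=True)
class ReadRepeatProfile:
    """Repeat content of one read: per-motif and total union coverage."""

    read_id: str
    read_length: int
    per_motif_bp: dict[str, int]  # canonical_key -> union bp
    total_repeat_bp: int
    runs: tuple[RepeatRun, ...] = field(default_factory=tuple)


def _match_units(motif: RepeatMotif, both_strands: bool) -> frozenset[str]:
    units = set(rotations(motif.display))
    if both_strands:
        units.update(rotations(reverse_complement(motif.display)))
    return frozenset(units)


def find_runs(
    seq: str,
    motifs: Sequence[RepeatMotif | str],
    min_run_bp: int | None = None,
    both_strands: bool = True,
) -> list[RepeatRun]:
    """Find all maximal exact tandem runs of the target motifs in ``seq``.

    Parameters
    ----------
    seq
        Read sequence (uppercased internally; non-ACGT never matches).
    motifs
        Target motifs, pairwise distinct by canonical key.
    min_run_bp
        Minimum run length in bp.  ``None`` means two full copies of each
        motif (10 bp for pentamers, 30 bp for a 15-mer).
    both_strands
        Also match rotations of each motif's reverse complement.

    Returns
    -------
    Runs sorted by start position, then by motif order in the input list.
    Deterministic.  Runs of motifs with different lengths may overlap; runs
    of the same motif arising from distinct periodic stretches may overlap by
    less than one motif length.
    """
    motifs = [as_motif(m) for m in motifs]
    check_distinct_motifs(motifs)
    seq = seq.upper()
    n = len(seq)
    ok = [c in "ACGT" for c in seq]
    runs: list[tuple[int, int, RepeatRun]] = []
    for order, motif in enumerate(motifs):
        L = motif.length
        threshold = 2 * L if min_run_bp is None else min_run_bp
        units = _match_units(motif, both_strands)
        # positions k where seq[k] == seq[k+L]: maximal True stretches [a, b)
        # yield maximal period-L substrings [a, b+L).
        k = 0
        limit = n - L
        while k < limit:
            if ok[k] and ok[k + L] and seq[k] == seq[k + L]:
                a = k
                while k < limit and ok[k] and ok[k + L] and seq[k] == seq[k + L]:
                    k += 1
                b = k
                unit = seq[a : a + L]
                if b + L - a >= threshold and unit in units:
                    runs.append((a, order, RepeatRun(a, b + L, motif)))
            else:
                k += 1
    runs.sort(key=lambda t: (t[0], t[1]))
    return [r for _, _, r in runs]


def _union_bp(intervals: Iterable[tuple[int, int]]) -> int:
    total = 0
    last_end = -1
    for start, end in sorted(intervals):
        if start > last_end:
            total += end - start
            last_end = end
        elif end > last_end:
            total += end - last_end
            last_end = end
    return total


def profile_read(
    read_id: str,
    seq: str,
    motifs: Sequence[RepeatMotif | str],
    min_run_bp: int | None = None,
    both_strands: bool = True,
) -> ReadRepeatProfile:
    """Profile one read: per-motif union bp, total union bp, and the run list."""
    motifs = [as_motif(m) for m in motifs]
    runs = find_runs(seq, motifs, min_run_bp=min_run_bp, both_strands=both_strands)
    per_motif: dict[str, int] = {m.canonical_key: 0 for m in motifs}
    for m in motifs:
        key = m.canonical_key
        per_motif[key] = _union_bp(
            (r.start, r.end) for r in runs if r.motif.canonical_key == key
        )
    total = _union_bp((r.start, r.end) for r in runs)
    return ReadRepeatProfile(
        read_id=read_id,
        read_length=len(seq),
        per_motif_bp=per_motif,
        total_repeat_bp=total,
        runs=tuple(runs),
    )


def repeat_fraction(profile: ReadRepeatProfile, motif: RepeatMotif | str) -> float:
    """Fraction of the read covered by runs of ``motif`` (0.0 for unknown motifs)."""
    key = as_motif(motif).canonical_key
    if key not in profile.per_motif_bp:
        logger.warning(
            "motif %s was not scanned for read %s; repeat_fraction -> 0.0",
            key,
            profile.read_id,
        )
        return 0.0
    if profile.read_length == 0:
        return 0.0
    return profile.per_motif_bp[key] / profile.read_length
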