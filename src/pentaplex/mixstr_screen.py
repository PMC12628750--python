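"""Read-pair classification and sample flagging for mixed-motif expansions.

A read pair is evidence of adjacent expansions of multiple motifs when both
mates are (nearly) pure repeat (strictly more than ``min_read_bp`` repeat
sequence in each read, default 125 bp) and every target motif reaches at
least ``min_motif_bp`` of repeat sequence summed across the pair (default
50 bp).  A sample is flagged when at least ``min_pairs`` (default 3) pairs
qualify.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass
from typing import Iterable, Iterator, Sequence

import pandas as pd

from .read_scan import ReadRepeatProfile, profile_read, repeat_fraction
from .repeat_model import (
    ConfigurationError,
    RepeatMotif,
    as_motif,
    check_distinct_motifs,
)

__all__ = [
    "Reason",
    "PairClassification",
    "SampleScreenResult",
    "classify_pair",
    "screen_sample",
    "screen_cohort",
]

logger = logging.getLogger(__name__)


class Reason(str, enum.Enum):
    OK = "ok"
    READ_BELOW_MIN = "read_below_min"
    MOTIF_BELOW_MIN = "motif_below_min"


@dataclass(frozen=True)
class PairClassification:
    pair_id: str
    qualifies: bool
    reason: Reason
    per_motif_pair_bp: dict[str, int]  # canonical_key -> bp summed across mates
    read1_total_bp: int
    read2_total_bp: int


@dataclass(frozen=True)
class SampleScreenResult:
    sample_id: str
    qualifying_pairs: int
    flagged: bool
    min_pairs: int = 3


def classify_pair(
    p1: ReadRepeatProfile,
    p2: ReadRepeatProfile,
    target_motifs: Sequence[RepeatMotif | str],
    min_read_bp: int = 125,
    min_motif_bp: int = 50,
    pair_id: str | None = None,
) -> PairClassification:
    """Classify one read pair against the mixed-motif criteria.

    Qualifies iff both reads have total repeat content strictly greater than
    ``min_read_bp`` AND, for EVERY target motif, the pair's summed per-motif
    content is at least ``min_motif_bp``.  Symmetric in (p1, p2).

    Raises
    ------
    ConfigurationError
        If either profile was not computed over all target motifs.
    """
    motifs = [as_motif(m) for m in target_motifs]
    check_distinct_motifs(motifs)
    keys = [m.canonical_key for m in motifs]
    for prof in (p1, p2):
        missing = [k for k in keys if k not in prof.per_motif_bp]
        if missing:
            raise ConfigurationError(
                f"profile {prof.read_id} lacks motifs {missing}; "
                "recompute profiles over the target motif set"
            )
    pair_bp = {k: p1.per_motif_bp[k] + p2.per_motif_bp[k] for k in keys}
    reads_ok = p1.total_repeat_bp > min_read_bp and p2.total_repeat_bp > min_read_bp
    motifs_ok = all(pair_bp[k] >= min_motif_bp for k in keys)
    if not reads_ok:
        reason = Reason.READ_BELOW_MIN
    elif not motifs_ok:
        reason = Reason.MOTIF_BELOW_MIN
    else:
        reason = Reason.OK
    return PairClassification(
        pair_id=pair_id or f"{p1.read_id}/{p2.read_id}",
        qualifies=reads_ok and motifs_ok,
        reason=reason,
        per_motif_pair_bp=pair_bp,
        read1_total_bp=p1.total_repeat_bp,
        read2_total_bp=p2.total_repeat_bp,
    )


def _iter_classifications(
    pair_stream: Iterable,
    motifs: Sequence[RepeatMotif],
    min_read_bp: int,
    min_motif_bp: int,
    min_run_bp: int | None,
    both_strands: bool,
) -> Iterator[PairClassification]:
    """Accept (pair_id, seq1, seq2) triples or (profile1, profile2) pairs."""
    for item in pair_stream:
        if len(item) == 3 and isinstance(item[1], str):
            pair_id, s1, s2 = item
            p1 = profile_read(f"{pair_id}/1", s1, motifs, min_run_bp, both_strands)
            p2 = profile_read(f"{pair_id}/2", s2, motifs, min_run_bp, both_strands)
        else:
            p1, p2 = item[0], item[1]
            pair_id = None
        yield classify_pair(p1, p2, motifs, min_read_bp, min_motif_bp, pair_id=pair_id)


def screen_sample(
    pair_stream: Iterable,
    target_motifs: Sequence[RepeatMotif | str],
    min_read_bp: int = 125,
    min_motif_bp: int = 50,
    min_pairs: int = 3,
    sample_id: str = "sample",
    min_run_bp: int | None = None,
    both_strands: bool = True,
    collect_pairs: bool = False,
) -> SampleScreenResult | tuple[SampleScreenResult, list[PairClassification]]:
    """Screen one sample's read pairs; flag it at ``min_pairs`` qualifying pairs.

    ``pair_stream`` yields either ``(pair_id, seq1, seq2)`` or precomputed
    ``(profile1, profile2)``.  Order-independent; an empty stream gives zero
    qualifying pairs and ``flagged=False``.
    """
    motifs = [as_motif(m) for m in target_motifs]
    check_distinct_motifs(motifs)
    qualifying = 0
    kept: list[PairClassification] = []
    for cls in _iter_classifications(
        pair_stream, motifs, min_read_bp, min_motif_bp, min_run_bp, both_strands
    ):
        if cls.qualifies:
            qualifying += 1
            if collect_pairs:
                kept.append(cls)
    result = SampleScreenResult(
        sample_id=sample_id,
        qualifying_pairs=qualifying,
        flagged=qualifying >= min_pairs,
        min_pairs=min_pairs,
    )
    return (result, kept) if collect_pairs else result


def screen_cohort(
    samples: Sequence[tuple[str, Iterable]],
    target_motifs: Sequence[RepeatMotif | str],
    min_read_bp: int = 125,
    min_motif_bp: int = 50,
    min_pairs: int = 3,
    min_run_bp: int | None = None,
    both_strands: bool = True,
) -> pd.DataFrame:
    """Screen several samples; one row per sample, sorted by sample id.

    ``samples`` is a sequence of ``(sample_id, pair_stream)``.  Duplicate
    sample ids are an error.
    """
    if not samples:
        raise ConfigurationError("cohort must contain at least one sample")
    ids = [sid for sid, _ in samples]
    if len(set(ids)) != len(ids):
        raise ConfigurationError(f"duplicate sample ids in cohort: {sorted(ids)}")
    rows = []
    for sample_id, stream in samples:
        res = screen_sample(
            stream,
            target_motifs,
            min_read_bp=min_read_bp,
            min_motif_bp=min_motif_bp,
            min_pairs=min_pairs,
            sample_id=sample_id,
            min_run_bp=min_run_bp,
            both_strands=both_strands,
        )
        rows.append(
            {
                "sample_id": res.sample_id,
                "qualifying_pairs": res.qualifying_pairs,
                "flagged": res.flagged,
                "min_pairs": res.min_pairs,
            }
        )
    table = pd.DataFrame(rows).sort_values("sample_id", kind="stable").reset_index(drop=True)
    logger.info("screened %d samples, %d flagged", len(table), int(table["flagged"].sum()))
    return table


def pair_fraction_qualifies(
    p1: ReadRepeatProfile,
    p2: ReadRepeatProfile,
    motif: RepeatMotif | str,
    min_fraction: float = 0.90,
) -> bool:
    """Alternative in-repeat-read style criterion: both mates exceed a per-motif
    repeat fraction (default >90% of read length). Combined with the bp
    criterion by union when screening for single-motif expansions."""
    return (
        repeat_fraction(p1, motif) > min_fraction
        and repeat_fraction(p2, motif) > min_fraction
    )
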