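"""Long-read repeat-locus characterization.

Pipeline: extract reads overlapping the locus (orienting everything to the
reference-forward strand), quantify per-motif repeat content, drop wild-type
alleles by a total-repeat-length threshold, flag strand-biased miscall
artifacts, segment each read into ordered motif blocks, and summarize block
structures across reads (consensus structure, waterfall rows).

Segmentation is windowed best-motif voting: every exact occurrence of a
rotation of a target motif votes for the positions it covers, each position
takes the motif with the most votes, and the resulting per-position labels
are run-length encoded and cleaned (sub-minimum segments become interruptions
or unassigned sequence, same-motif neighbours merge).  On error-free input
this reproduces the exact run decomposition; under a few percent of
substitutions and indels the votes of overlapping occurrences bridge isolated
errors.
"""

from __future__ import annotations

import enum
import logging
from collections import Counter
from dataclasses import dataclass, field
from fractions import Fraction
from statistics import median
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .read_scan import _union_bp, find_runs
from .repeat_model import (
    ConfigurationError,
    RepeatMotif,
    as_motif,
    check_distinct_motifs,
    parse_region,
    reverse_complement,
    rotations,
)

__all__ = [
    "Strand",
    "LongReadRecord",
    "MotifCountRecord",
    "Block",
    "BlockSegmentation",
    "ConsensusStructure",
    "WaterfallSummary",
    "extract_region_reads",
    "count_motifs",
    "filter_wildtype",
    "detect_miscall_artifact",
    "segment_read",
    "consensus_structure",
    "waterfall",
]

logger = logging.getLogger(__name__)


class Strand(str, enum.Enum):
    FORWARD = "forward"
    REVERSE = "reverse"
    UNKNOWN = "unknown"


_STRAND_ALIASES = {
    "+": Strand.FORWARD,
    "forward": Strand.FORWARD,
    "fwd": Strand.FORWARD,
    "-": Strand.REVERSE,
    "reverse": Strand.REVERSE,
    "rev": Strand.REVERSE,
    ".": Strand.UNKNOWN,
    "unknown": Strand.UNKNOWN,
}


@dataclass(frozen=True)
class LongReadRecord:
    """One long read, stored in reference-forward orientation."""

    read_id: str
    seq: str
    mapped_strand: Strand = Strand.UNKNOWN
    overlaps_region: bool = True

    def __post_init__(self) -> None:
        if not self.seq:
            raise ConfigurationError(f"read {self.read_id} has empty sequence")


@dataclass(frozen=True)
class MotifCountRecord:
    """Per-read motif copy counts (tandem-run copies, not isolated occurrences)."""

    read_id: str
    per_motif_copies: dict[str, Fraction]  # canonical_key -> copies
    total_repeat_bp: int
    mapped_strand: Strand = Strand.UNKNOWN


@dataclass(frozen=True)
class Block:
    motif: RepeatMotif
    bp: int

    @property
    def copies(self) -> int:
        return round(self.bp / self.motif.length)


@dataclass(frozen=True)
class BlockSegmentation:
    """Ordered motif blocks recovered from one read."""

    read_id: str
    blocks: tuple[Block, ...]
    unassigned_bp: int
    read_length: int
    interruptions: tuple[Block, ...] = field(default_factory=tuple)

    @property
    def total_block_bp(self) -> int:
        return sum(b.bp for b in self.blocks)

    @property
    def structure_string(self) -> str:
        return "-".join(f"({b.motif.display}){b.copies}" for b in self.blocks)

    @property
    def block_order(self) -> tuple[str, ...]:
        return tuple(b.motif.canonical_key for b in self.blocks)


def extract_region_reads(
    read_table: pd.DataFrame | Iterable[dict],
    region: str | tuple[str, int, int],
) -> list[LongReadRecord]:
    """Select reads whose alignment interval overlaps the region.

    ``read_table`` rows need ``read_id``, ``seq``, ``contig``, ``start``,
    ``end`` (0-based half-open) and ``strand``.  Whole reads are kept, never
    clipped: the repeat itself is typically absent from the reference and the
    alignment anchors in the flanks.  Reverse-strand reads are stored
    reverse-complemented so every record is reference-forward.
    """
    contig, start, end = parse_region(region) if isinstance(region, str) else region
    if not isinstance(read_table, pd.DataFrame):
        read_table = pd.DataFrame(list(read_table))
    if len(read_table) and contig not in set(read_table["contig"]):
        logger.warning("contig %s absent from read table; no reads extracted", contig)
        return []
    records: list[LongReadRecord] = []
    for row in read_table.itertuples(index=False):
        if row.contig != contig or row.start >= end or row.end <= start:
            continue
        strand = _STRAND_ALIASES.get(str(row.strand).lower(), Strand.UNKNOWN)
        seq = str(row.seq).upper()
        if strand is Strand.REVERSE:
            seq = reverse_complement(seq)
        records.append(LongReadRecord(str(row.read_id), seq, strand, True))
    logger.info("extracted %d reads overlapping %s:%d-%d", len(records), contig, start, end)
    return records


def count_motifs(
    rec: LongReadRecord,
    motifs: Sequence[RepeatMotif | str],
    min_run_bp: int | None = None,
    both_strands: bool = True,
) -> MotifCountRecord:
    """Quantify tandem-run motif copies in one read.

    Copies are run bp divided by motif length (exact rational); total repeat
    bp is the union coverage over all runs of all motifs.
    """
    motifs = [as_motif(m) for m in motifs]
    runs = find_runs(rec.seq, motifs, min_run_bp=min_run_bp, both_strands=both_strands)
    per_copies: dict[str, Fraction] = {}
    for m in motifs:
        bp = _union_bp((r.start, r.end) for r in runs if r.motif.canonical_key == m.canonical_key)
        per_copies[m.canonical_key] = Fraction(bp, m.length)
    total = _union_bp((r.start, r.end) for r in runs)
    return MotifCountRecord(rec.read_id, per_copies, total, rec.mapped_strand)


def filter_wildtype(
    records: Sequence[MotifCountRecord], min_total_bp: int = 800
) -> list[MotifCountRecord]:
    """Drop reads with total repeat length strictly below ``min_total_bp``.

    Removes wild-type alleles (short repeats) so only expanded-allele reads
    are summarized.  Order-preserving; the removed count is logged.
    """
    kept = [r for r in records if r.total_repeat_bp >= min_total_bp]
    logger.info(
        "wild-type filter (<%d bp): removed %d of %d reads",
        min_total_bp,
        len(records) - len(kept),
        len(records),
    )
    return kept


def detect_miscall_artifact(
    rec: LongReadRecord,
    motifs: Sequence[RepeatMotif | str] | None = None,
    min_fraction: float = 0.5,
    artifact_motif: RepeatMotif | str = "TTCCA",
    signal_motifs: Sequence[RepeatMotif | str] = ("TTTCA", "TTTTA"),
) -> bool:
    """Flag reverse-strand reads whose repeat tract is dominated by the
    basecaller miscall motif.

    True iff the read mapped to the reverse strand AND the artifact motif's
    run bp exceeds ``min_fraction`` of the combined artifact+signal run bp.
    Reads with unknown strand are never flagged (warned).  Flagged reads are
    reported by the caller, not silently dropped.
    """
    artifact = as_motif(artifact_motif)
    signals = [as_motif(m) for m in signal_motifs]
    if motifs is not None:
        keys = {as_motif(m).canonical_key for m in motifs}
        if artifact.canonical_key not in keys:
            raise ConfigurationError(
                f"artifact motif {artifact.display} missing from the supplied motif set"
            )
    if rec.mapped_strand is Strand.UNKNOWN:
        logger.warning("read %s has unknown strand; artifact filter skipped", rec.read_id)
        return False
    if rec.mapped_strand is not Strand.REVERSE:
        return False
    scan = [artifact] + signals
    runs = find_runs(rec.seq, scan, both_strands=True)
    art_bp = _union_bp(
        (r.start, r.end) for r in runs if r.motif.canonical_key == artifact.canonical_key
    )
    total_bp = _union_bp((r.start, r.end) for r in runs)
    if total_bp == 0:
        return False
    return art_bp > min_fraction * total_bp


# ---------------------------------------------------------------------------
# Segmentation


def _vote_matrix(
    seq: str, motifs: Sequence[RepeatMotif], both_strands: bool
) -> np.ndarray:
    """votes[m, i] = number of exact motif-rotation occurrences covering i."""
    n = len(seq)
    votes = np.zeros((len(motifs), n), dtype=np.int32)
    for mi, motif in enumerate(motifs):
        L = motif.length
        units = set(rotations(motif.display))
        if both_strands:
            units.update(rotations(reverse_complement(motif.display)))
        row = votes[mi]
        for i in range(n - L + 1):
            if seq[i : i + L] in units:
                row[i : i + L] += 1
    return votes


def _rle(labels: np.ndarray) -> list[tuple[int, int, int]]:
    """Run-length encode integer labels -> list of (label, start, end)."""
    segs = []
    start = 0
    for i in range(1, len(labels) + 1):
        if i == len(labels) or labels[i] != labels[start]:
            segs.append((int(labels[start]), start, i))
            start = i
    return segs


def segment_read(
    rec: LongReadRecord | str,
    motifs: Sequence[RepeatMotif | str],
    window_copies: int = 3,
    min_block_copies: int = 2,
    both_strands: bool = True,
    read_id: str = "read",
) -> BlockSegmentation:
    """Decompose one read into ordered motif blocks.

    Every position takes the motif with the most covering exact
    rotation-occurrences (ties broken by motif order in the input list;
    positions with no votes are unassigned).  The per-position labels are
    run-length encoded, then cleaned: segments shorter than
    ``min_block_copies`` motif copies are removed — kept in the
    ``interruptions`` list when they carry a motif label — and same-motif
    neighbours are merged, absorbing the removed bp between them; removed bp
    not absorbed by a merge counts as ``unassigned_bp``.  Reads shorter than
    ``window_copies`` copies of the smallest motif collapse to a single
    best-motif block (or an empty segmentation if nothing votes).

    On error-free synthesized configurations whose blocks all have at least
    ``min_block_copies`` copies, the recovered block order and rounded copy
    counts equal the input configuration.
    """
    if isinstance(rec, str):
        rec = LongReadRecord(read_id, rec)
    motifs = [as_motif(m) for m in motifs]
    check_distinct_motifs(motifs)
    seq = rec.seq.upper()
    n = len(seq)
    min_window = window_copies * min(m.length for m in motifs)
    votes = _vote_matrix(seq, motifs, both_strands)

    if n < min_window:
        totals = votes.sum(axis=1)
        if totals.max(initial=0) == 0:
            return BlockSegmentation(rec.read_id, (), n, n)
        mi = int(np.argmax(totals))
        bp = int((votes[mi] > 0).sum())
        return BlockSegmentation(rec.read_id, (Block(motifs[mi], bp),), n - bp, n)

    # majority smoothing: score each motif by its vote total in a centred
    # window of window_copies full copies; positions covered by no exact
    # occurrence of any motif stay unassigned (keeps flanks out and clean
    # input exact).
    smoothed = np.empty_like(votes, dtype=np.float64)
    for mi, motif in enumerate(motifs):
        w = max(1, window_copies * motif.length)
        kernel = np.ones(w) / w
        smoothed[mi] = np.convolve(votes[mi], kernel, mode="same")
    best_raw = votes.max(axis=0)
    winner = smoothed.argmax(axis=0)  # ties -> lowest motif index
    winner[best_raw == 0] = -1

    segs = _rle(winner)

    def is_kept(seg: tuple[int, int, int]) -> bool:
        label, start, end = seg
        if label < 0:
            return False
        if end - start < min_block_copies * motifs[label].length:
            return False
        # a true tandem tract is covered by ~L overlapping exact occurrences
        # per position; scattered chance hits (e.g. in flanking sequence) are
        # far sparser and must not become blocks
        mean_votes = float(votes[label, start:end].mean())
        return mean_votes >= 0.5 * motifs[label].length

    blocks: list[Block] = []
    unassigned = 0
    pending_gap = 0  # bp removed since the last kept segment
    for seg in segs:
        label, start, end = seg
        if is_kept(seg):
            if blocks and blocks[-1].motif.canonical_key == motifs[label].canonical_key:
                # merge across the removed gap, absorbing its bp
                blocks[-1] = Block(blocks[-1].motif, blocks[-1].bp + pending_gap + (end - start))
            else:
                unassigned += pending_gap
                blocks.append(Block(motifs[label], end - start))
            pending_gap = 0
        else:
            pending_gap += end - start
    unassigned += pending_gap

    # prune interruption-scale foreign blocks sandwiched between two blocks of
    # the same motif: a sub-window tract of a different motif inside a long
    # tract is stray-copy evidence (kept as an interruption), not structure
    demoted: list[Block] = []
    changed = True
    while changed:
        changed = False
        for i in range(1, len(blocks) - 1):
            b = blocks[i]
            if (
                b.bp < window_copies * b.motif.length
                and blocks[i - 1].motif.canonical_key == blocks[i + 1].motif.canonical_key
            ):
                demoted.append(b)
                merged = Block(
                    blocks[i - 1].motif, blocks[i - 1].bp + b.bp + blocks[i + 1].bp
                )
                blocks[i - 1 : i + 2] = [merged]
                changed = True
                break

    # interruptions: short runs of a different motif visible in the raw votes
    # but overruled by smoothing (e.g. a single embedded motif copy)
    raw_winner = votes.argmax(axis=0)
    raw_winner[best_raw == 0] = -1
    interruptions = demoted + [
        Block(motifs[label], end - start)
        for label, start, end in _rle(raw_winner)
        if label >= 0
        and end - start < min_block_copies * motifs[label].length
        and winner[(start + end) // 2] != label
    ]

    return BlockSegmentation(
        rec.read_id, tuple(blocks), unassigned, n, tuple(interruptions)
    )


@dataclass(frozen=True)
class ConsensusStructure:
    """Modal block order across reads with per-block copy statistics."""

    block_order: tuple[str, ...]  # motif display names, modal order
    structure_string: str
    median_copies: tuple[float, ...]
    median_bp: tuple[float, ...]
    mad_copies: tuple[float, ...]
    n_reads: int
    n_discordant: int


def consensus_structure(segs: Sequence[BlockSegmentation]) -> ConsensusStructure:
    """Modal block order across reads; per-block median bp/copies and MAD.

    Reads whose block order disagrees with the modal order are counted as
    discordant and excluded from the per-block statistics.
    """
    if not segs:
        raise ConfigurationError("consensus requires at least one segmentation")
    orders = Counter(s.block_order for s in segs)
    top = max(orders.values())
    modal = sorted(o for o, c in orders.items() if c == top)[0]
    concordant = [s for s in segs if s.block_order == modal]
    displays = tuple(b.motif.display for b in concordant[0].blocks)
    med_bp, med_cp, mad_cp = [], [], []
    for bi in range(len(modal)):
        bps = [s.blocks[bi].bp for s in concordant]
        cps = [s.blocks[bi].copies for s in concordant]
        med_bp.append(median(bps))
        mc = median(cps)
        med_cp.append(mc)
        mad_cp.append(median(abs(c - mc) for c in cps))
    structure = "-".join(f"({d}){round(c)}" for d, c in zip(displays, med_cp))
    return ConsensusStructure(
        block_order=displays,
        structure_string=structure,
        median_copies=tuple(med_cp),
        median_bp=tuple(med_bp),
        mad_copies=tuple(mad_cp),
        n_reads=len(segs),
        n_discordant=len(segs) - len(concordant),
    )


@dataclass(frozen=True)
class WaterfallSummary:
    """Per-read motif tracks sorted by repeat length, plus copy distributions."""

    rows: tuple[BlockSegmentation, ...]  # sorted by total block bp desc, ties by read_id
    distribution: pd.DataFrame  # per motif: n_reads, min/median/max copies


def waterfall(segs: Sequence[BlockSegmentation]) -> WaterfallSummary:
    """Order reads for a waterfall plot and summarize motif copy distributions."""
    if not segs:
        raise ConfigurationError("waterfall requires at least one segmentation")
    rows = tuple(sorted(segs, key=lambda s: (-s.total_block_bp, s.read_id)))
    per_motif: dict[str, dict] = {}
    copies: dict[str, list[int]] = {}
    for s in segs:
        seen: dict[str, int] = {}
        for b in s.blocks:
            seen[b.motif.display] = seen.get(b.motif.display, 0) + b.copies
        for disp, c in seen.items():
            copies.setdefault(disp, []).append(c)
    for disp, vals in sorted(copies.items()):
        per_motif[disp] = {
            "n_reads": len(vals),
            "min_copies": min(vals),
            "median_copies": median(vals),
            "max_copies": max(vals),
        }
    dist = pd.DataFrame.from_dict(per_motif, orient="index")
    dist.index.name = "motif"
    return WaterfallSummary(rows=rows, distribution=dist.reset_index())


def waterfall_table(summary: WaterfallSummary) -> pd.DataFrame:
    """Flatten waterfall rows to a table (one row per read)."""
    return pd.DataFrame(
        {
            "read_id": [s.read_id for s in summary.rows],
            "total_repeat_bp": [s.total_block_bp for s in summary.rows],
            "structure": [s.structure_string for s in summary.rows],
            "unassigned_bp": [s.unassigned_bp for s in summary.rows],
        }
    )


def plot_waterfall(summary: WaterfallSummary, path: str, colors: dict[str, str] | None = None) -> None:
    """Render the waterfall as horizontal motif-colored bars (optional)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    default_palette = ["#4477AA", "#EE6677", "#228833", "#CCBB44", "#66CCEE", "#AA3377"]
    displays: list[str] = []
    for s in summary.rows:
        for b in s.blocks:
            if b.motif.display not in displays:
                displays.append(b.motif.display)
    colors = colors or {
        d: default_palette[i % len(default_palette)] for i, d in enumerate(displays)
    }
    fig, ax = plt.subplots(figsize=(10, max(2, 0.18 * len(summary.rows))))
    for yi, s in enumerate(summary.rows):
        x = 0
        for b in s.blocks:
            ax.barh(yi, b.bp, left=x, color=colors[b.motif.display], height=0.8)
            x += b.bp
    handles = [plt.Rectangle((0, 0), 1, 1, color=c) for c in colors.values()]
    ax.legend(handles, list(colors), loc="lower right", fontsize=8)
    ax.set_xlabel("repeat length (bp)")
    ax.set_ylabel("reads")
    ax.set_yticks([])
    ax.invert_yaxis()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
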