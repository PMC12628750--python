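"""Synthetic diploid repeat alleles, Illumina-like read pairs, and noisy
long-read amplicons.

Every other stage of the toolkit is testable against this module's ground
truth: each emitted read carries full provenance (allele of origin, fragment
coordinates or drawn block structure), and identical seeds give identical
output.

The long-read model supports an optional strand-biased miscall artifact:
a fraction of reverse-strand reads has a large contiguous tract of its
TTTTA/TTTCA copies rewritten as TTCCA before sequencing noise is applied,
emulating a systematic basecaller failure mode.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
import numpy as np
import pandas as pd

from .repeat_model import (
    ConfigurationError,
    RepeatConfiguration,
    RepeatMotif,
    canonical_key,
    config_to_sequence,
    reverse_complement,
)

__all__ = [
    "AlleleModel",
    "ShortReadSimSpec",
    "LongReadSimSpec",
    "SimulatedRead",
    "random_flank",
    "simulate_allele",
    "simulate_short_pairs",
    "simulate_long_reads",
]

logger = logging.getLogger(__name__)

_BASES = np.array(list("ACGT"))


def random_flank(length: int = 500, gc: float = 0.4, rng: np.random.Generator | None = None) -> str:
    """Random flanking sequence with the given GC content (default 40%)."""
    rng = rng or np.random.default_rng(0)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(_BASES, size=length, p=p))


@dataclass(frozen=True)
class AlleleModel:
    """A repeat allele, optionally with one mosaic block whose copy number is
    redrawn per read template (modelling PCR bias and somatic mosaicism
    jointly, which amplicon data cannot distinguish)."""

    configuration: RepeatConfiguration
    mosaic_block: int | None = None
    # {"family": "lognormal", "mean_copies": float, "sigma": float}
    # or {"family": "discrete", "values": [...], "probs": [...]}
    mosaic_distribution: dict | None = None

    def __post_init__(self) -> None:
        if (self.mosaic_block is None) != (self.mosaic_distribution is None):
            raise ConfigurationError("mosaic_block and mosaic_distribution go together")
        if self.mosaic_block is not None and not (
            0 <= self.mosaic_block < len(self.configuration.blocks)
        ):
            raise ConfigurationError(
                f"mosaic_block {self.mosaic_block} out of range for "
                f"{len(self.configuration.blocks)} blocks"
            )

    def draw_copies(self, rng: np.random.Generator) -> list[int]:
        copies = [c for _, c in self.configuration.blocks]
        if self.mosaic_block is not None:
            dist = self.mosaic_distribution
            if dist["family"] == "lognormal":
                drawn = rng.lognormal(np.log(dist["mean_copies"]), dist["sigma"])
            elif dist["family"] == "discrete":
                drawn = rng.choice(dist["values"], p=dist.get("probs"))
            else:
                raise ConfigurationError(f"unknown mosaic family {dist['family']!r}")
            copies[self.mosaic_block] = max(1, int(round(drawn)))
        return copies


@dataclass(frozen=True)
class ShortReadSimSpec:
    read_length: int = 151
    fragment_mean: float = 350.0
    fragment_sd: float = 50.0
    coverage: float = 30.0
    substitution_rate: float = 0.001
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.substitution_rate < 1:
            raise ConfigurationError("substitution_rate must be in [0, 1)")
        if self.read_length > self.fragment_mean:
            raise ConfigurationError("read_length must not exceed mean fragment length")


@dataclass(frozen=True)
class LongReadSimSpec:
    coverage: float = 50.0  # reads per allele (full-length amplicons)
    substitution_rate: float = 0.0
    insertion_rate: float = 0.0
    deletion_rate: float = 0.0
    reverse_prob: float = 0.5
    artifact_rate: float = 0.0  # fraction of reverse-strand reads corrupted
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("substitution_rate", "insertion_rate", "deletion_rate",
                     "reverse_prob", "artifact_rate"):
            v = getattr(self, name)
            if not 0 <= v < 1 and not (name == "reverse_prob" and v == 1.0):
                raise ConfigurationError(f"{name} must be in [0, 1), got {v}")


@dataclass(frozen=True)
class SimulatedRead:
    read_id: str
    seq: str
    mate_seq: str | None = None  # short-read mode only
    strand: str = "+"


def simulate_allele(
    model: AlleleModel, rng: np.random.Generator
) -> tuple[str, pd.DataFrame]:
    """Materialize one allele template; mosaic block copies are drawn fresh.

    Returns the sequence and a ground-truth block table (motif, copies, bp).
    Without mosaicism this is exactly ``config_to_sequence``.
    """
    copies = model.draw_copies(rng)
    cfg = model.configuration
    body = "".join(m.display * c for (m, _), c in zip(cfg.blocks, copies))
    seq = cfg.left_flank + body + cfg.right_flank
    truth = pd.DataFrame(
        {
            "block_index": range(len(cfg.blocks)),
            "motif": [m.display for m, _ in cfg.blocks],
            "copies": copies,
            "bp": [m.length * c for (m, _), c in zip(cfg.blocks, copies)],
        }
    )
    return seq, truth


def _add_substitutions(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    hits = np.nonzero(rng.random(len(arr)) < rate)[0]
    for i in hits:
        cur = arr[i].decode()
        choices = [b for b in "ACGT" if b != cur]
        arr[i] = rng.choice(choices).encode()
    return arr.tobytes().decode()


def _add_indel_noise(
    seq: str, sub: float, ins: float, dele: float, rng: np.random.Generator
) -> str:
    """Apply i.i.d. per-base substitution/insertion/deletion noise."""
    if sub <= 0 and ins <= 0 and dele <= 0:
        return seq
    out: list[str] = []
    n = len(seq)
    # one uniform draw per base decides the event; insertions occur before bases
    u = rng.random(n)
    for i, base in enumerate(seq):
        if ins > 0 and u[i] < ins:
            out.append(str(rng.choice(_BASES)))
        r = rng.random()
        if r < dele:
            continue
        if r < dele + sub:
            out.append(str(rng.choice([b for b in "ACGT" if b != base])))
        else:
            out.append(base)
    return "".join(out)


def simulate_short_pairs(
    alleleA: str,
    alleleB: str,
    spec: ShortReadSimSpec,
) -> tuple[list[SimulatedRead], pd.DataFrame]:
    """Simulate paired 151 bp (default) reads from a diploid pair of alleles.

    Fragments are drawn uniformly along each allele at half the requested
    coverage per allele; R1 is the fragment's 5' end, R2 the reverse
    complement of its 3' end.  Deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    reads: list[SimulatedRead] = []
    truth_rows = []
    for allele_name, allele in (("A", alleleA), ("B", alleleB)):
        n = len(allele)
        if n < spec.read_length:
            raise ConfigurationError(f"allele {allele_name} shorter than read length")
        n_pairs = int(round((spec.coverage / 2) * n / (2 * spec.read_length)))
        for i in range(n_pairs):
            # resample until the fragment fits the allele
            for _ in range(1000):
                frag_len = int(round(rng.normal(spec.fragment_mean, spec.fragment_sd)))
                frag_len = max(frag_len, spec.read_length)
                if frag_len <= n:
                    break
            else:
                logger.warning("fragment resampling exhausted; clamping to allele length")
                frag_len = n
            start = int(rng.integers(0, n - frag_len + 1))
            frag = allele[start : start + frag_len]
            r1 = _add_substitutions(frag[: spec.read_length], spec.substitution_rate, rng)
            r2 = _add_substitutions(
                reverse_complement(frag)[: spec.read_length], spec.substitution_rate, rng
            )
            pair_id = f"sim_{allele_name}_{i}"
            reads.append(SimulatedRead(pair_id, r1, r2))
            truth_rows.append(
                {
                    "pair_id": pair_id,
                    "allele": allele_name,
                    "frag_start": start,
                    "frag_end": start + frag_len,
                }
            )
    return reads, pd.DataFrame(truth_rows)


def _corrupt_tract(
    blocks: list[tuple[RepeatMotif, int]],
    rng: np.random.Generator,
    artifact: str = "TTCCA",
    targets: tuple[str, ...] = ("TTTTA", "TTTCA"),
) -> tuple[list[tuple[str, int]], int]:
    """Rewrite a contiguous stretch of target-motif copies as the artifact motif.

    Returns (list of (unit, copies) segments, corrupted copy count).  The
    corrupted stretch covers 60-95% of the combined target copies, contiguous
    over the concatenated target-copy axis — large tracts, not scattered
    single copies.
    """
    target_keys = {canonical_key(t) for t in targets}
    spans = []  # (block_idx, n_copies) for target blocks, in order
    total = 0
    for bi, (m, c) in enumerate(blocks):
        if m.canonical_key in target_keys:
            spans.append((bi, c))
            total += c
    if total == 0:
        return [(m.display, c) for m, c in blocks], 0
    frac = rng.uniform(0.6, 0.95)
    n_corrupt = max(1, int(round(frac * total)))
    start = int(rng.integers(0, total - n_corrupt + 1))
    out: list[tuple[str, int]] = []
    cursor = 0  # position along concatenated target copies
    corrupted = 0
    for bi, (m, c) in enumerate(blocks):
        if m.canonical_key not in target_keys:
            out.append((m.display, c))
            continue
        # overlap of [cursor, cursor+c) with [start, start+n_corrupt)
        lo = max(cursor, start)
        hi = min(cursor + c, start + n_corrupt)
        if hi <= lo:
            out.append((m.display, c))
        else:
            pre, mid, post = lo - cursor, hi - lo, cursor + c - hi
            if pre:
                out.append((m.display, pre))
            out.append((artifact, mid))
            corrupted += mid
            if post:
                out.append((m.display, post))
        cursor += c
    return out, corrupted


def simulate_long_reads(
    modelA: AlleleModel,
    modelB: AlleleModel | None,
    spec: LongReadSimSpec,
    region: tuple[str, int, int] = ("chr5", 10356338, 10356411),
) -> tuple[list[SimulatedRead], pd.DataFrame, pd.DataFrame]:
    """Simulate full-length amplicon long reads from one or two allele models.

    Per read: draw the allele template (mosaic copies redrawn each time),
    optionally corrupt a reverse-strand read's TTTTA/TTTCA tract to TTCCA,
    apply i.i.d. substitution/indel noise, and emit reverse-strand reads
    reverse-complemented.  Returns (reads, alignment-like table, truth table).
    The alignment table rows (read_id, contig, start, end, strand) all overlap
    ``region``, mimicking flank-anchored mapping of the amplicon.
    """
    rng = np.random.default_rng(spec.seed)
    contig, rstart, rend = region
    models = [("A", modelA)] + ([("B", modelB)] if modelB is not None else [])
    reads: list[SimulatedRead] = []
    aln_rows = []
    truth_rows = []
    n_reads = int(round(spec.coverage))
    for allele_name, model in models:
        lflank = len(model.configuration.left_flank)
        for i in range(n_reads):
            read_id = f"lr_{allele_name}_{i}"
            copies = model.draw_copies(rng)
            blocks = [(m, c) for (m, _), c in zip(model.configuration.blocks, copies)]
            strand = "-" if rng.random() < spec.reverse_prob else "+"
            corrupted_copies = 0
            if strand == "-" and spec.artifact_rate > 0 and rng.random() < spec.artifact_rate:
                segments, corrupted_copies = _corrupt_tract(blocks, rng)
            else:
                segments = [(m.display, c) for m, c in blocks]
            body = "".join(unit * c for unit, c in segments)
            template = model.configuration.left_flank + body + model.configuration.right_flank
            noisy = _add_indel_noise(
                template,
                spec.substitution_rate,
                spec.insertion_rate,
                spec.deletion_rate,
                rng,
            )
            emitted = reverse_complement(noisy) if strand == "-" else noisy
            reads.append(SimulatedRead(read_id, emitted, strand=strand))
            aln_rows.append(
                {
                    "read_id": read_id,
                    "contig": contig,
                    "start": rstart - lflank,
                    "end": rstart - lflank + len(noisy),
                    "strand": strand,
                }
            )
            truth_rows.append(
                {
                    "read_id": read_id,
                    "allele": allele_name,
                    "strand": strand,
                    "corrupted": corrupted_copies > 0,
                    "corrupted_copies": corrupted_copies,
                    "structure": "-".join(
                        f"({m.display}){c}" for m, c in blocks
                    ),
                    "total_repeat_bp": sum(m.length * c for m, c in blocks),
                }
            )
    return reads, pd.DataFrame(aln_rows), pd.DataFrame(truth_rows)
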