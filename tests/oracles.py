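"""Independent brute-force references used to check the fast implementations.

These deliberately share no code with the package's scanners: runs are found
by greedy cyclic extension from every start position over every explicit
rotation, and pair decisions re-apply the thresholds by hand.
"""

from __future__ import annotations


def _revcomp(s: str) -> str:
    return s.translate(str.maketrans("ACGT", "TGCA"))[::-1]


def _rotations(s: str) -> list[str]:
    return [s[i:] + s[:i] for i in range(len(s))]


def brute_force_runs(
    seq: str,
    motifs: list[str],
    min_run_bp: int | None = None,
    both_strands: bool = True,
) -> set[tuple[int, int, str]]:
    """All maximal runs as (start, end, motif-display) via exhaustive search.

    For every start position and every explicit rotation of each motif (and of
    its reverse complement when ``both_strands``), extend greedily while the
    sequence matches the cyclic pattern; keep intervals meeting the length
    threshold that are not contained in a longer interval of the same motif.
    """
    out: set[tuple[int, int, str]] = set()
    n = len(seq)
    for motif in motifs:
        L = len(motif)
        threshold = 2 * L if min_run_bp is None else min_run_bp
        units = set(_rotations(motif))
        if both_strands:
            units.update(_rotations(_revcomp(motif)))
        intervals: set[tuple[int, int]] = set()
        for start in range(n):
            best_end = start
            for unit in units:
                e = start
                while e < n and seq[e] == unit[(e - start) % L]:
                    e += 1
                best_end = max(best_end, e)
            if best_end - start >= threshold:
                intervals.add((start, best_end))
        for a, b in intervals:
            if not any(
                (c <= a and b <= d and (c, d) != (a, b)) for c, d in intervals
            ):
                out.add((a, b, motif))
    return out


def brute_force_pair_decision(
    read1_motif_bp: dict[str, int],
    read2_motif_bp: dict[str, int],
    read1_total: int,
    read2_total: int,
    targets: list[str],
    min_read_bp: int = 125,
    min_motif_bp: int = 50,
) -> bool:
    """Hand-applied mixed-motif thresholds: strictly >min_read_bp per read,
    >=min_motif_bp per target motif summed across the pair."""
    if read1_total <= min_read_bp or read2_total <= min_read_bp:
        return False
    for m in targets:
        if read1_motif_bp.get(m, 0) + read2_motif_bp.get(m, 0) < min_motif_bp:
            return False
    return True
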