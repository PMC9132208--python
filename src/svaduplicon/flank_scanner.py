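"""Scanner for insertions flanked by large same-orientation direct repeats.

A hit is the maximum-scoring ungapped segment on a diagonal of the
self-comparison matrix (match +1, mismatch -p with p = id/(1-id), so a
segment scores >= 0 iff its identity >= the threshold), subject to the
segmental-duplication regime: repeat length >= min_len (>= 1 kb),
identity >= min_identity (>= 0.9), copies non-overlapping and separated
by at most ``max_insert``.  Candidate diagonals come from exact k-mer
seed pairs; each diagonal's optimum is computed exactly.  Inverted
repeats are out of scope by contract.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .core_model import Contig, Interval
from .junction_tsd import characterize_junction

MIN_REPEAT_LEN = 1_000
MIN_IDENTITY = 0.9
MAX_INSERT = 25_000
WINDOW_SIZE = 500_000
SEED_K = 14


@dataclass
class FlankHit:
    left_repeat: Interval
    right_repeat: Interval
    insert: Interval
    repeat_length: int
    identity: float
    n_mismatches: int
    score: float
    orientation: str = "direct"
    junctions: list = field(default_factory=list)
    predicted_nahr_product: dict | None = None

    def key(self) -> tuple:
        return (
            self.left_repeat.contig_id,
            self.left_repeat.start,
            self.left_repeat.end,
            self.right_repeat.start,
        )


def mismatch_penalty(min_identity: float) -> float:
    """Per-mismatch penalty making identity >= min_identity <=> score >= 0."""
    if min_identity >= 1.0:
        return 1e9
    return min_identity / (1.0 - min_identity)


def max_scoring_segment(match: np.ndarray, penalty: float):
    """Best-scoring contiguous segment of a boolean match vector.

    Returns (score, start, end); ties resolve to the first maximum prefix
    position (deterministic).  The optimal segment never starts or ends
    on a mismatch.
    """
    v = np.where(match, 1.0, -penalty)
    s = np.concatenate(([0.0], np.cumsum(v)))
    runmin = np.minimum.accumulate(s[:-1])
    gains = s[1:] - runmin
    b = int(np.argmax(gains)) + 1
    score = float(gains[b - 1])
    a = int(np.argmin(s[:b]))
    return score, a, b


def _as_id_seq(contig) -> tuple:
    if isinstance(contig, Contig):
        return contig.id, contig.seq
    if isinstance(contig, tuple):
        return contig
    return "contig", contig  # bare string


def _candidate_diagonals(seq: str, k: int, max_gap: int, max_kmer_freq: int) -> set:
    positions: dict = {}
    for i in range(len(seq) - k + 1):
        positions.setdefault(seq[i : i + k], []).append(i)
    diagonals = set()
    for kmer, pos in positions.items():
        if len(pos) < 2 or len(pos) > max_kmer_freq:
            continue
        for x in range(len(pos)):
            for y in range(x + 1, len(pos)):
                g = pos[y] - pos[x]
                if 0 < g <= max_gap:
                    diagonals.add(g)
    return diagonals


def _merge_hits(hits: list) -> list:
    """Overlapping hits collapse to the best (score, identity) maximal pair."""
    kept = []
    for h in sorted(hits, key=lambda h: (-h.score, -h.identity, h.left_repeat.start)):
        dup = any(
            h.left_repeat.overlaps(k.left_repeat)
            and h.right_repeat.overlaps(k.right_repeat)
            for k in kept
        )
        if not dup:
            kept.append(h)
    kept.sort(key=lambda h: h.left_repeat.start)
    return kept


def find_direct_repeat_flanks(
    contig,
    min_len: int = MIN_REPEAT_LEN,
    min_identity: float = MIN_IDENTITY,
    max_insert: int = MAX_INSERT,
    seed_k: int = SEED_K,
    max_kmer_freq: int = 64,
    max_repeat_length: int | None = None,
    offset: int = 0,
) -> list:
    """All direct-repeat pairs of length >= min_len flanking an insert.

    ``contig`` may be a Contig, (id, seq) tuple, or bare sequence string.
    ``offset`` shifts reported coordinates (used by the window scanner).
    """
    if min_len < 1_000:
        raise ValueError("min_len below the SD definition (1 kb)")
    if min_identity < 0.9:
        raise ValueError("min_identity below the SD definition (0.9)")
    cid, seq = _as_id_seq(contig)
    n = len(seq)
    if n < 2 * min_len:
        return []

    penalty = mismatch_penalty(min_identity)
    max_rep = max_repeat_length if max_repeat_length is not None else n
    max_gap = max_insert + max_rep
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)

    hits = []
    for g in sorted(_candidate_diagonals(seq, seed_k, max_gap, max_kmer_freq)):
        if g < min_len:  # repeat length <= g (non-overlap), so g >= min_len
            continue
        match = arr[:-g] == arr[g:]
        score, a, b = max_scoring_segment(match, penalty)
        length = b - a
        if length < min_len or length > g:
            continue
        insert_len = g - length
        if insert_len > max_insert:
            continue
        n_match = int(match[a:b].sum())
        identity = n_match / length
        if identity < min_identity:
            continue
        hits.append(
            FlankHit(
                left_repeat=Interval(cid, offset + a, offset + b),
                right_repeat=Interval(cid, offset + a + g, offset + b + g),
                insert=Interval(cid, offset + b, offset + a + g),
                repeat_length=length,
                identity=identity,
                n_mismatches=length - n_match,
                score=score,
                predicted_nahr_product={
                    "length": length,
                    "description": "single chimeric repeat copy, insert removed",
                    "seq": seq[a : a + length // 2] + seq[a + g + length // 2 : b + g],
                },
            )
        )
    return _merge_hits(hits)


def characterize_hit_junctions(
    hit: FlankHit,
    seq: str,
    insert_donor: str | None = None,
    window: int = 30,
) -> list:
    """Type the two repeat/insert junctions of a hit.

    Without the insert's donor sequence only junction positions are
    recorded; with it, microhomology/inserted bases are resolved through
    the junction classifier.
    """
    j5 = hit.left_repeat.end
    j3 = hit.right_repeat.start
    records = []
    if insert_donor is None:
        records.append({"junction": "5p", "position": j5})
        records.append({"junction": "3p", "position": j3})
    else:
        w = min(window, hit.repeat_length, len(insert_donor) // 2)
        obs5 = seq[j5 - w : j5 + w]
        call5 = characterize_junction(seq[j5 - w : j5], insert_donor[: 2 * w], obs5)
        obs3 = seq[j3 - w : j3 + w]
        call3 = characterize_junction(insert_donor[-2 * w :], seq[j3 : j3 + w], obs3)
        records.append({"junction": "5p", "position": j5, "call": call5})
        records.append({"junction": "3p", "position": j3, "call": call3})
    hit.junctions = records
    return records


def scan_windows(
    genome,
    sd_intervals: list | None = None,
    window_size: int = WINDOW_SIZE,
    seam_margin: int | None = None,
    min_len: int = MIN_REPEAT_LEN,
    min_identity: float = MIN_IDENTITY,
    max_insert: int = MAX_INSERT,
    **kwargs,
) -> list:
    """Apply the flank scanner in nonoverlapping windows (default 0.5 Mb).

    Windows are extended by a seam margin so hits straddling a boundary
    are found; duplicates across seams collapse by coordinate identity.
    When ``sd_intervals`` is given only windows near those intervals are
    scanned.
    """
    if window_size <= 2 * min_len:
        raise ValueError("window_size must exceed 2*min_len")
    if seam_margin is None:
        seam_margin = max_insert + 16_000

    if isinstance(genome, dict):
        items = list(genome.items())
    else:
        items = [(c.id, c.seq) for c in genome]

    hits: dict = {}
    for cid, seq in items:
        n = len(seq)
        for wstart in range(0, n, window_size):
            wend = min(n, wstart + window_size + seam_margin)
            if sd_intervals is not None:
                near = any(
                    iv.contig_id == cid
                    and iv.start < wend + seam_margin
                    and wstart - seam_margin < iv.end
                    for iv in sd_intervals
                )
                if not near:
                    continue
            for h in find_direct_repeat_flanks(
                (cid, seq[wstart:wend]),
                min_len=min_len,
                min_identity=min_identity,
                max_insert=max_insert,
                offset=wstart,
                **kwargs,
            ):
                hits.setdefault(h.key(), h)
    out = list(hits.values())
    out.sort(key=lambda h: (h.left_repeat.contig_id, h.left_repeat.start))
    return _merge_hits(out)


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------


def write_hits_bed(hits, path) -> None:
    """BED of left repeat / insert / right repeat per hit."""
    with open(path, "w") as fh:
        for i, h in enumerate(hits):
            for part, iv in (
                ("left_repeat", h.left_repeat),
                ("insert", h.insert),
                ("right_repeat", h.right_repeat),
            ):
                fh.write(
                    f"{iv.contig_id}\t{iv.start}\t{iv.end}\t"
                    f"hit{i}:{part}\t{round(h.identity * 1000)}\t+\n"
                )


def hit_to_dict(h: FlankHit) -> dict:
    return {
        "contig": h.left_repeat.contig_id,
        "left_repeat": [h.left_repeat.start, h.left_repeat.end],
        "right_repeat": [h.right_repeat.start, h.right_repeat.end],
        "insert": [h.insert.start, h.insert.end],
        "repeat_length": h.repeat_length,
        "identity": h.identity,
        "n_mismatches": h.n_mismatches,
        "orientation": h.orientation,
        "junction_positions": [h.left_repeat.end, h.right_repeat.start],
        "predicted_nahr_product_length": (
            h.predicted_nahr_product["length"] if h.predicted_nahr_product else None
        ),
    }


def write_hits_json(hits, path) -> None:
    with open(path, "w") as fh:
        json.dump([hit_to_dict(h) for h in hits], fh, indent=1, sort_keys=True)
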