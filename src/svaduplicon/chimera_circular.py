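"""Subfamily segmentation of composite elements, chimera detection, and the
circular-intermediate integration signature.

Subfamily affiliation along an element is diagnosed from diagnostic sites
only (robust inside the unalignable VNTR, which is excluded from scoring
by default), not from windowed similarity.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

from .core_model import ConsensusLibrary, Interval
from .junction_tsd import TSDCall, detect_tsd

MIN_SEGMENT_SUPPORT = 3


@dataclass
class ChimeraSegment:
    """Subfamily segmentation of one element along its consensus."""

    element: Interval | None
    segments: list  # (consensus start, consensus end, subfamily, support)
    switch_points: list  # consensus coordinates between adjacent segments
    site_calls: list  # (consensus position, called subfamily)
    n_suppressed: int = 0

    @property
    def subfamily_order(self) -> list:
        return [s[2] for s in self.segments]

    def is_chimeric(self) -> bool:
        return len(self.segments) >= 2


@dataclass
class CircularSignatureCall:
    locus: Interval
    element5: ChimeraSegment
    element3: ChimeraSegment
    outer_tsd: TSDCall | None
    inner_tsd: TSDCall | None
    verdict: str  # positive | partial | negative
    notes: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# consensus coordinate mapping
# ---------------------------------------------------------------------------


def _map_consensus_to_element(consensus: str, element_seq: str) -> dict:
    """consensus index -> element index.

    Equal lengths use the identity map (substitution-only divergence);
    otherwise a global pairwise alignment handles VNTR-length jitter.
    """
    if len(consensus) == len(element_seq):
        return {i: i for i in range(len(consensus))}
    from Bio import Align

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = -1.0
    aligner.open_gap_score = -4.0
    aligner.extend_gap_score = -0.5
    aln = aligner.align(consensus, element_seq)[0]
    cmap = {}
    target_blocks, query_blocks = aln.aligned
    for (ts, te), (qs, _qe) in zip(target_blocks, query_blocks):
        for k in range(te - ts):
            cmap[ts + k] = qs + k
    return cmap


# ---------------------------------------------------------------------------
# segmentation
# ---------------------------------------------------------------------------


def segment_by_subfamily(
    element_seq: str,
    library: ConsensusLibrary,
    pair: tuple,
    element: Interval | None = None,
    min_support: int = MIN_SEGMENT_SUPPORT,
    exclude_vntr: bool = True,
) -> ChimeraSegment:
    """Score diagnostic sites along an element and segment by subfamily.

    Maximal runs of same-state sites become segments; runs with fewer
    than ``min_support`` sites are merged into the better-supported
    neighbor (suppressed sites counted, with a warning).  The switch
    point between adjacent segments is the midpoint between their
    flanking diagnostic sites.
    """
    sub_a, sub_b = pair
    key = tuple(sorted(pair))
    if key not in library.diagnostic_sites:
        raise ValueError(f"no diagnostic sites for pair {pair}")
    sites = library.diagnostic_sites[key]
    if key != tuple(pair):
        sites = [(p, sb, sa) for p, sa, sb in sites]

    base = library.consensus(library.base) if library.base else library.consensus(sub_a)
    cmap = _map_consensus_to_element(base, element_seq.upper())
    vntr = None
    if exclude_vntr:
        entry = library.entries.get(library.base) or library.entries[sub_a]
        vntr = entry["domains"].get("VNTR")

    elem = element_seq.upper()
    calls = []
    for pos, sa, sb in sites:
        if vntr and vntr[0] <= pos < vntr[1]:
            continue
        idx = cmap.get(pos)
        if idx is None or idx >= len(elem):
            continue
        ch = elem[idx]
        if ch == sa:
            calls.append((pos, sub_a))
        elif ch == sb:
            calls.append((pos, sub_b))
        # other states (mutation) are unscorable at this site
    if len(calls) < 2:
        raise ValueError("unclassifiable: <2 scorable diagnostic sites")
    calls.sort()

    # maximal same-state runs
    runs = []  # [state, [positions]]
    for pos, st in calls:
        if runs and runs[-1][0] == st:
            runs[-1][1].append(pos)
        else:
            runs.append([st, [pos]])

    n_suppressed = 0
    while len(runs) > 1 and min(len(r[1]) for r in runs) < min_support:
        k = min(range(len(runs)), key=lambda i: (len(runs[i][1]), i))
        state, positions = runs.pop(k)
        left = runs[k - 1] if k > 0 else None
        right = runs[k] if k < len(runs) else None
        if left is not None and (right is None or len(left[1]) >= len(right[1])):
            target = left
        else:
            target = right
        n_suppressed += len(positions)
        target[1].extend(positions)
        target[1].sort()
        # re-merge neighbors that became same-state
        merged = []
        for st2, ps in runs:
            if merged and merged[-1][0] == st2:
                merged[-1][1].extend(ps)
                merged[-1][1].sort()
            else:
                merged.append([st2, list(ps)])
        runs = merged
    if n_suppressed:
        warnings.warn(f"mosaic below resolution: {n_suppressed} diagnostic sites suppressed")

    cons_len = len(base)
    switch_points = []
    for (s1, p1), (s2, p2) in zip(runs, runs[1:]):
        switch_points.append((p1[-1] + p2[0]) // 2)
    bounds = [0] + switch_points + [cons_len]
    segments = [
        (bounds[i], bounds[i + 1], runs[i][0], len(runs[i][1]))
        for i in range(len(runs))
    ]
    return ChimeraSegment(
        element=element,
        segments=segments,
        switch_points=switch_points,
        site_calls=calls,
        n_suppressed=n_suppressed,
    )


def detect_chimera(
    annotations,
    genome,
    library: ConsensusLibrary,
    pair: tuple | None = None,
    min_support: int = MIN_SEGMENT_SUPPORT,
    families=("SVA",),
) -> list:
    """Segment every annotated element; return multi-segment (chimeric) calls.

    Element sequences are read in consensus orientation (minus-strand
    annotations are reverse-complemented before scoring), so subfamily
    order is orientation-normalized.
    """
    if pair is None:
        subfams = library.subfamilies()
        if len(subfams) != 2:
            raise ValueError("pair required when library has != 2 subfamilies")
        pair = tuple(subfams)

    def _seq(contig_id: str) -> str:
        if isinstance(genome, dict):
            return genome[contig_id]
        for c in genome:
            if c.id == contig_id:
                return c.seq
        raise KeyError(contig_id)

    calls = []
    for a in annotations:
        if a.family not in families:
            continue
        seq = a.interval.slice(_seq(a.interval.contig_id))
        try:
            seg = segment_by_subfamily(
                seq, library, pair, element=a.interval, min_support=min_support
            )
        except ValueError:
            continue
        if seg.is_chimeric():
            calls.append(seg)
    return calls


# ---------------------------------------------------------------------------
# circular-intermediate signature
# ---------------------------------------------------------------------------


def _detect_edge_pair(
    seq: str,
    min_len: int,
    max_window: int,
    slack: int,
    max_mismatch_frac: float = 0.2,
):
    """Near-identical (prefix, suffix) pair of a segment — the inner-TSD
    geometry: copies start/end at the segment edges (small offsets allowed).

    Returns (length, mismatches, offset_left, offset_right) or None.
    """
    best = None
    w = min(max_window, len(seq) // 2)
    for l in range(w, min_len - 1, -1):
        for a in range(slack + 1):
            left = seq[a : a + l]
            if len(left) < l:
                continue
            for b in range(slack + 1):
                if b + l > len(seq):
                    continue
                right = seq[len(seq) - b - l : len(seq) - b]
                mm = sum(x != y for x, y in zip(left, right))
                if mm > int(max_mismatch_frac * l):
                    continue
                key = (l, -mm, -(a + b))
                if best is None or key > best[0]:
                    best = (key, (l, mm, a, b))
        if best is not None:
            break
    return best[1] if best else None


def detect_circular_signature(
    genome,
    chimeras: list,
    locus: Interval | None = None,
    tsd_max_window: int = 40,
    tsd_min_len: int = 8,
    adjacency_slack: int = 4,
) -> CircularSignatureCall:
    """Call the reciprocal-chimera circular-integration signature.

    Requires exactly two chimera calls flanking an interior segment.
    positive: reciprocal subfamily orders (X->Y / Y->X), an outer TSD pair
    flanking the whole cassette (copies adjacent to the X ends) and an
    inner TSD pair bordering the interior (copies adjacent to the Y ends);
    partial: exactly one TSD pair; negative otherwise.
    """
    if len(chimeras) != 2:
        raise ValueError("not a candidate cassette: need exactly 2 flanking chimeras")
    c5, c3 = sorted(chimeras, key=lambda c: c.element.start)
    contig_id = c5.element.contig_id
    if locus is None:
        locus = Interval(contig_id, c5.element.start, c3.element.end)

    notes = []
    order5, order3 = c5.subfamily_order, c3.subfamily_order
    reciprocal = (
        len(order5) == 2
        and len(order3) == 2
        and order5[0] == order3[1]
        and order5[1] == order3[0]
        and order5[0] != order5[1]
    )
    if not reciprocal:
        notes.append(f"subfamily orders not reciprocal: {order5} / {order3}")

    cassette = Interval(contig_id, c5.element.start, c3.element.end)
    interior = Interval(contig_id, c5.element.end, c3.element.start)

    def _tsd(insertion: Interval) -> TSDCall | None:
        try:
            call = detect_tsd(
                genome, insertion, max_window=tsd_max_window, min_len=tsd_min_len
            )
        except ValueError:
            return None
        if call is None:
            return None
        jdist = (insertion.start - call.left.end) + (call.right.start - insertion.end)
        if jdist > adjacency_slack:
            return None  # present but not junction-adjacent
        return call

    outer = _tsd(cassette)

    # inner TSD copies are the interior's near-identical edge pair (they
    # flank the circularly permuted donor segment, inside the cassette)
    inner = None
    if len(interior) > 2 * tsd_min_len:
        def _seq(cid):
            return genome[cid] if isinstance(genome, dict) else next(
                c.seq for c in genome if c.id == cid
            )
        iseq = _seq(contig_id)[interior.start : interior.end]
        found = _detect_edge_pair(iseq, tsd_min_len, tsd_max_window, adjacency_slack)
        if found is not None:
            l, mm, a, b = found
            inner = TSDCall(
                left=Interval(contig_id, interior.start + a, interior.start + a + l),
                right=Interval(contig_id, interior.end - b - l, interior.end - b),
                length=l,
                mismatches=mm,
            )
    if outer is None:
        notes.append("no outer TSD pair")
    if inner is None:
        notes.append("no inner TSD pair")

    if reciprocal and outer and inner:
        verdict = "positive"
        notes.append(
            f"outer TSDs adjacent to {order5[0]} ends; inner to {order5[1]} ends"
        )
    elif reciprocal and (outer or inner):
        verdict = "partial"
    else:
        verdict = "negative"

    return CircularSignatureCall(
        locus=locus,
        element5=c5,
        element3=c3,
        outer_tsd=outer,
        inner_tsd=inner,
        verdict=verdict,
        notes=notes,
    )


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------


def write_chimera_tsv(calls, path) -> None:
    with open(path, "w") as fh:
        fh.write("contig\tstart\tend\tstrand\tsegments\tswitch_points\tn_suppressed\n")
        for c in calls:
            iv = c.element
            seg = ";".join(f"{s}-{e}:{sf}({n})" for s, e, sf, n in c.segments)
            sw = ",".join(map(str, c.switch_points)) or "."
            loc = (
                f"{iv.contig_id}\t{iv.start}\t{iv.end}\t{iv.strand}"
                if iv is not None
                else ".\t.\t.\t."
            )
            fh.write(f"{loc}\t{seg}\t{sw}\t{c.n_suppressed}\n")


def signature_to_dict(call: CircularSignatureCall) -> dict:
    def _tsd(t):
        if t is None:
            return None
        return {
            "left": [t.left.start, t.left.end],
            "right": [t.right.start, t.right.end],
            "length": t.length,
            "mismatches": t.mismatches,
        }

    return {
        "locus": [call.locus.contig_id, call.locus.start, call.locus.end],
        "verdict": call.verdict,
        "order5": call.element5.subfamily_order,
        "order3": call.element3.subfamily_order,
        "switch_points5": call.element5.switch_points,
        "switch_points3": call.element3.switch_points,
        "outer_tsd": _tsd(call.outer_tsd),
        "inner_tsd": _tsd(call.inner_tsd),
        "notes": call.notes,
    }


def write_signature_json(calls, path) -> None:
    with open(path, "w") as fh:
        json.dump([signature_to_dict(c) for c in calls], fh, indent=1, sort_keys=True)
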