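"""Target-site duplications, junction typing, and breakpoint censuses."""

from __future__ import annotations

import json
import statistics
import warnings
from dataclasses import dataclass, field

import numpy as np

from .core_model import Interval, revcomp

TSD_MAX_WINDOW = 100
TSD_MIN_LEN = 5
TSD_MAX_MISMATCH_FRAC = 0.2
CLUSTER_TOLERANCE_BP = 20


@dataclass
class TSDCall:
    """A target-site duplication: near-identical copies on both flanks."""

    left: Interval
    right: Interval
    length: int
    mismatches: int

    def __post_init__(self) -> None:
        if len(self.left) != self.length or len(self.right) != self.length:
            raise ValueError("TSD copies differ in length")
        if self.mismatches > int(TSD_MAX_MISMATCH_FRAC * self.length):
            raise ValueError("mismatches exceed tolerated fraction")


@dataclass
class JunctionCall:
    """Characterized transition between two donor sequences.

    ``position`` is the unattributable interior span in observed-junction
    coordinates (zero-length for abutted/microhomologous junctions).
    """

    microhomology_len: int
    inserted_seq: str
    position: tuple
    left_match_len: int
    right_match_len: int
    overlap_class: str = "none"
    complexity: str = "simple"

    def __post_init__(self) -> None:
        if self.microhomology_len > 0 and self.inserted_seq:
            raise ValueError("microhomology and inserted sequence are exclusive")


@dataclass
class BreakpointCensus:
    side: str  # "5p" or "3p"
    clusters: list  # (coordinate, [member names])
    overlap_classes: list = field(default_factory=list)
    n_skipped: int = 0
    tolerance_bp: int = CLUSTER_TOLERANCE_BP


def _contig_seq(genome, contig_id: str) -> str:
    if isinstance(genome, str):
        return genome
    if isinstance(genome, dict):
        return genome[contig_id]
    for c in genome:  # list of Contig
        if c.id == contig_id:
            return c.seq
    raise KeyError(contig_id)


# ---------------------------------------------------------------------------
# TSD detection
# ---------------------------------------------------------------------------


def detect_tsd(
    genome,
    insertion: Interval,
    max_window: int = TSD_MAX_WINDOW,
    min_len: int = TSD_MIN_LEN,
    max_mismatch_frac: float = TSD_MAX_MISMATCH_FRAC,
):
    """Find the best TSD pair flanking ``insertion``, or None.

    Candidates are substring pairs — one inside the ``max_window`` bases
    left of the insertion, one inside the window right of it — scored by
    (longest, fewest mismatches, closest to the junction); mismatches are
    capped at ``floor(max_mismatch_frac * length)``.  Ties break toward
    the junction-proximal pair.
    """
    seq = _contig_seq(genome, insertion.contig_id)
    wl = min(max_window, insertion.start)
    wr = min(max_window, len(seq) - insertion.end)
    if wl <= 0 or wr <= 0:
        raise ValueError("insertion at contig edge: no flank to search")

    lw = np.frombuffer(seq[insertion.start - wl : insertion.start].encode(), dtype=np.uint8)
    rw = np.frombuffer(seq[insertion.end : insertion.end + wr].encode(), dtype=np.uint8)
    match = lw[:, None] == rw[None, :]

    best = None  # (length, -mism, -jdist, key...) -> call params
    for d in range(-(wl - 1), wr):
        diag = np.diagonal(match, offset=d)
        m = diag.size
        if m < min_len:
            continue
        i0 = max(0, -d)  # left-window index of diagonal start
        j0 = max(0, d)
        pref = np.concatenate(([0], np.cumsum(~diag)))
        for l in range(m, min_len - 1, -1):
            if best is not None and l < best[0][0]:
                break
            allowed = int(max_mismatch_frac * l)
            mism = pref[l:] - pref[:-l]
            ok = np.nonzero(mism <= allowed)[0]
            if ok.size == 0:
                continue
            for k in ok:
                le = insertion.start - wl + i0 + int(k) + l  # left chunk end
                rs = insertion.end + j0 + int(k)  # right chunk start
                jdist = (insertion.start - le) + (rs - insertion.end)
                key = (l, -int(mism[k]), -jdist, le, -rs)
                if best is None or key > best[0]:
                    best = (key, (le - l, le, rs, rs + l, int(mism[k])))
            break  # longer l dominates shorter on the same diagonal

    if best is None:
        return None
    ls, le, rs, re, mm = best[1]
    return TSDCall(
        left=Interval(insertion.contig_id, ls, le),
        right=Interval(insertion.contig_id, rs, re),
        length=le - ls,
        mismatches=mm,
    )


# ---------------------------------------------------------------------------
# junction characterization
# ---------------------------------------------------------------------------


def _lcp(a: str, b: str) -> int:
    n = min(len(a), len(b))
    for i in range(n):
        if a[i] != b[i]:
            return i
    return n


def characterize_junction(
    left_donor_seq: str,
    right_donor_seq: str,
    observed_junction_seq: str,
    extra_donors: dict | None = None,
    overlap_class: str = "none",
    min_fragment: int = 8,
) -> JunctionCall:
    """Type the junction in ``observed_junction_seq``.

    The left donor ends at its breakpoint, the right donor starts at its
    breakpoint; both retain any junction-shared bases.  The left match is
    the largest ``a`` with ``observed[:a] == left_donor[-a:]``; the
    transition ``t`` is the smallest offset with
    ``observed[t:] == right_donor[:n-t]``.  Overlap ``a - t`` is
    microhomology; a gap ``observed[a:t]`` becomes ``inserted_seq``.
    Interior fragments mappable to >=2 distinct ``extra_donors`` mark the
    junction complex.
    """
    obs = observed_junction_seq.upper()
    ld = left_donor_seq.upper()
    rd = right_donor_seq.upper()
    n = len(obs)
    x = max(
        (a for a in range(min(n, len(ld)) + 1) if obs[:a] == ld[len(ld) - a :]),
        default=0,
    )
    t = next((t for t in range(n) if obs[t:] == rd[: n - t]), n)
    if x == 0 or t == n:
        raise ValueError("donor sequences not found in observed junction")

    if x >= t:
        mh = x - t
        inserted = ""
        pos = (t, t)
    else:
        mh = 0
        inserted = obs[x:t]
        pos = (x, t)

    complexity = "simple"
    if inserted and extra_donors:
        hit_donors = set()
        for name, dseq in extra_donors.items():
            dseq = dseq.upper()
            for i in range(0, len(inserted) - min_fragment + 1):
                frag = inserted[i : i + min_fragment]
                if frag in dseq or frag in revcomp(dseq):
                    hit_donors.add(name)
                    break
        if len(hit_donors) >= 2:
            complexity = "complex"

    return JunctionCall(
        microhomology_len=mh,
        inserted_seq=inserted,
        position=pos,
        left_match_len=x,
        right_match_len=n - t,
        overlap_class=overlap_class,
        complexity=complexity,
    )


# ---------------------------------------------------------------------------
# breakpoint clustering and the repeat-overlap census
# ---------------------------------------------------------------------------


def cluster_breakpoints(copies, side: str, tolerance_bp: int = CLUSTER_TOLERANCE_BP) -> BreakpointCensus:
    """Single-linkage 1-D clustering of per-copy breakpoints.

    ``side`` selects ``bp5`` or ``bp3``; cluster coordinate is the median
    of its members.  Copies lacking the requested breakpoint are skipped
    with a warning and counted.
    """
    if side not in ("5p", "3p"):
        raise ValueError("side must be '5p' or '3p'")
    attr = "bp5" if side == "5p" else "bp3"
    points = []
    n_skipped = 0
    for c in copies:
        v = getattr(c, attr, None)
        if v is None:
            warnings.warn(f"copy {c.name} has no {side} breakpoint; skipped")
            n_skipped += 1
            continue
        points.append((int(v), c.name))
    points.sort()

    clusters = []
    current = []
    for coord, name in points:
        if current and coord - current[-1][0] > tolerance_bp:
            clusters.append(current)
            current = []
        current.append((coord, name))
    if current:
        clusters.append(current)

    out = [
        (float(statistics.median([c for c, _ in cl])), [n for _, n in cl])
        for cl in clusters
    ]
    return BreakpointCensus(side=side, clusters=out, n_skipped=n_skipped,
                            tolerance_bp=tolerance_bp)


def repeat_overlap_census(census: BreakpointCensus, annotations) -> dict:
    """Assign each independent breakpoint the class of its containing repeat.

    Point-in-interval is half-open; breakpoints outside every annotation
    count as "none".  Also fills ``census.overlap_classes``.
    """
    counts: dict = {}
    classes = []
    for coord, _members in census.clusters:
        cls = "none"
        for a in annotations:
            if a.interval.start <= coord < a.interval.end:
                cls = a.family
                break
        classes.append(cls)
        counts[cls] = counts.get(cls, 0) + 1
    census.overlap_classes = classes
    return counts


# ---------------------------------------------------------------------------
# insertion chaining (annotation -> candidate insertion spans)
# ---------------------------------------------------------------------------


def chain_insertions(annotations, max_gap: int = 5, seed_families=("SVA",)) -> list:
    """Chain an element annotation with abutting TD/polyA annotations.

    Returns candidate full-insertion Intervals (element + downstream
    transduction + polyA tail), the spans a TSD caller should flank.
    """
    by_contig: dict = {}
    for a in annotations:
        by_contig.setdefault(a.interval.contig_id, []).append(a)
    spans = []
    for contig_id, annots in by_contig.items():
        annots.sort(key=lambda a: a.interval.start)
        used = set()
        for i, a in enumerate(annots):
            if i in used or a.family not in seed_families:
                continue
            start, end = a.interval.start, a.interval.end
            j = i + 1
            while j < len(annots) and annots[j].interval.start - end <= max_gap:
                if annots[j].family in ("TD", "Simple_repeat"):
                    end = annots[j].interval.end
                    used.add(j)
                    j += 1
                else:
                    break
            spans.append(Interval(contig_id, start, end))
    return spans


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------


def write_tsd_calls_tsv(calls, path) -> None:
    with open(path, "w") as fh:
        fh.write("contig\tleft_start\tleft_end\tright_start\tright_end\tlength\tmismatches\n")
        for c in calls:
            if c is None:
                continue
            fh.write(
                f"{c.left.contig_id}\t{c.left.start}\t{c.left.end}\t"
                f"{c.right.start}\t{c.right.end}\t{c.length}\t{c.mismatches}\n"
            )


def write_junction_calls_tsv(calls, path) -> None:
    with open(path, "w") as fh:
        fh.write("microhomology_len\tinserted_seq\toverlap_class\tcomplexity\n")
        for c in calls:
            fh.write(
                f"{c.microhomology_len}\t{c.inserted_seq or '.'}\t"
                f"{c.overlap_class}\t{c.complexity}\n"
            )


def census_to_dict(census: BreakpointCensus, counts: dict | None = None) -> dict:
    doc = {
        "side": census.side,
        "tolerance_bp": census.tolerance_bp,
        "n_skipped": census.n_skipped,
        "clusters": [
            {
                "coordinate": coord,
                "members": members,
                "overlap_class": (
                    census.overlap_classes[i] if census.overlap_classes else None
                ),
            }
            for i, (coord, members) in enumerate(census.clusters)
        ],
    }
    if counts is not None:
        doc["class_counts"] = counts
    return doc


def write_census_json(census: BreakpointCensus, counts: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(census_to_dict(census, counts), fh, indent=1, sort_keys=True)


def write_census_tsv(census: BreakpointCensus, path) -> None:
    with open(path, "w") as fh:
        fh.write("side\tcoordinate\tn_members\tmembers\toverlap_class\n")
        for i, (coord, members) in enumerate(census.clusters):
            cls = census.overlap_classes[i] if census.overlap_classes else "."
            fh.write(
                f"{census.side}\t{coord}\t{len(members)}\t{','.join(members)}\t{cls}\n"
            )
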