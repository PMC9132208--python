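"""Domain types and readers/writers for the standard formats used throughout.

Coordinate convention: all internal coordinates are 0-based half-open
``[start, end)``.  1-based formats (RepeatMasker ``.out``, consensus
positions) are converted at the boundary and nowhere else.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

DNA_ALPHABET = frozenset("ACGTN")
_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N-safe, case preserved)."""
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class Contig:
    """A named DNA sequence over {A,C,G,T,N}."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValueError(f"contig {self.id!r}: empty sequence")
        bad = set(self.seq) - DNA_ALPHABET
        if bad:
            for off, ch in enumerate(self.seq):
                if ch in bad:
                    raise ValueError(
                        f"contig {self.id!r}: illegal character {ch!r} at offset {off}"
                    )

    def __len__(self) -> int:
        return len(self.seq)

    def reverse_complement(self) -> "Contig":
        return Contig(self.id, revcomp(self.seq))


@dataclass(frozen=True)
class Interval:
    """Half-open genomic interval ``[start, end)`` on a contig."""

    contig_id: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start < 0 or self.start > self.end:
            raise ValueError(f"bad interval [{self.start}, {self.end})")
        if self.strand not in ("+", "-"):
            raise ValueError(f"bad strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end

    def overlaps(self, other: "Interval") -> bool:
        return (
            self.contig_id == other.contig_id
            and self.start < other.end
            and other.start < self.end
        )

    def lift_revcomp(self, contig_length: int) -> "Interval":
        """Map through reverse-complement of the whole contig."""
        return Interval(
            self.contig_id,
            contig_length - self.end,
            contig_length - self.start,
            "-" if self.strand == "+" else "+",
        )

    def slice(self, seq: str) -> str:
        sub = seq[self.start : self.end]
        return revcomp(sub) if self.strand == "-" else sub


@dataclass
class RepeatAnnotation:
    """Annotated repeat interval with family/subfamily and consensus coords.

    ``consensus_start``/``consensus_end`` follow the RepeatMasker convention:
    1-based inclusive positions on the subfamily consensus.
    """

    interval: Interval
    family: str
    subfamily: str
    consensus_start: int = 1
    consensus_end: int = 1
    divergence_pct: float = 0.0

    def __post_init__(self) -> None:
        if self.consensus_start > self.consensus_end:
            raise ValueError("consensus_start > consensus_end")
        if not 0.0 <= self.divergence_pct <= 100.0:
            raise ValueError("divergence_pct outside [0, 100]")


@dataclass
class ConsensusLibrary:
    """Element consensus sequences with domain structure and diagnostic sites.

    ``entries``: subfamily -> dict with keys ``seq`` (consensus string),
    ``domains`` (name -> (start, end), 0-based half-open, tiling the
    consensus), and optional ``transduction`` (3' transduction sequence).
    ``diagnostic_sites``: (subfamA, subfamB) -> list of
    (0-based consensus position, stateA, stateB) with stateA != stateB.
    ``base``: name of the base consensus all subfamilies derive from.
    """

    entries: dict
    diagnostic_sites: dict
    base: str = ""

    def __post_init__(self) -> None:
        for name, ent in self.entries.items():
            spans = sorted(ent["domains"].values())
            for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
                if e1 > s2:
                    raise ValueError(f"{name}: overlapping domains")
            if spans and (spans[0][0] != 0 or spans[-1][1] != len(ent["seq"])):
                raise ValueError(f"{name}: domains do not tile the consensus")
        for (a, b), sites in self.diagnostic_sites.items():
            for pos, sa, sb in sites:
                if sa == sb:
                    raise ValueError(f"({a},{b}) site {pos}: identical states")
                for nm in (a, b):
                    if not 0 <= pos < len(self.entries[nm]["seq"]):
                        raise ValueError(f"({a},{b}) site {pos}: outside consensus")

    def subfamilies(self) -> list:
        return sorted(n for n in self.entries if n != self.base)

    def consensus(self, subfamily: str) -> str:
        return self.entries[subfamily]["seq"]

    def domain(self, subfamily: str, name: str):
        return self.entries[subfamily]["domains"][name]


@dataclass
class DuplicationCopy:
    """A duplicated copy of the ancestral locus with mapped breakpoints.

    ``bp5``/``bp3`` are coordinates of the copy's 5'/3' breakpoints on the
    ancestral locus; ``ancestral_map`` lists (copy Interval, ancestral
    Interval) alignment blocks.
    """

    name: str
    interval: Interval
    bp5: int
    bp3: int
    ancestral_map: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.bp5 >= self.bp3:
            raise ValueError(f"{self.name}: bp5 >= bp3")


@dataclass
class MultipleAlignment:
    """Gapped alignment rows with group labels and a designated outgroup."""

    rows: dict  # id -> gapped string (insertion-ordered)
    groups: dict  # id -> group label
    outgroup_id: str

    def __post_init__(self) -> None:
        lengths = {len(s) for s in self.rows.values()}
        if len(lengths) > 1:
            raise ValueError("alignment rows differ in length")
        if self.outgroup_id not in self.rows:
            raise ValueError(f"outgroup {self.outgroup_id!r} not in rows")
        missing = [rid for rid in self.rows if rid not in self.groups]
        if missing:
            raise ValueError(f"rows without group label: {missing}")

    @property
    def n_cols(self) -> int:
        return len(next(iter(self.rows.values())))

    @property
    def taxa(self) -> list:
        return list(self.rows)

    def ingroup_labels(self) -> list:
        out = self.groups[self.outgroup_id]
        seen = []
        for rid, g in self.groups.items():
            if rid != self.outgroup_id and g != out and g not in seen:
                seen.append(g)
        return seen

    def col_map(self, row_id: str) -> list:
        """Per-column ungapped coordinate for a row (-1 at gap columns)."""
        out, pos = [], 0
        for ch in self.rows[row_id]:
            if ch == "-":
                out.append(-1)
            else:
                out.append(pos)
                pos += 1
        return out

    def column(self, j: int) -> dict:
        return {rid: s[j] for rid, s in self.rows.items()}

    def subset_columns(self, cols) -> "MultipleAlignment":
        cols = list(cols)
        rows = {rid: "".join(s[j] for j in cols) for rid, s in self.rows.items()}
        return MultipleAlignment(rows, dict(self.groups), self.outgroup_id)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta(path) -> list:
    """Read a (multi-record) FASTA into Contigs.

    Case-folds to upper, maps U->T, rejects characters outside {A,C,G,T,N}
    with the in-record offset. Raises ``ValueError("no records")`` on input
    without any record.
    """
    contigs = []
    cur_id, parts = None, []

    def _flush():
        if cur_id is None:
            return
        seq = "".join(parts).upper().replace("U", "T")
        for off, ch in enumerate(seq):
            if ch not in DNA_ALPHABET:
                raise ValueError(
                    f"record {cur_id!r}: illegal character {ch!r} at offset {off}"
                )
        contigs.append(Contig(cur_id, seq))

    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                _flush()
                cur_id = line[1:].split()[0] if len(line) > 1 else ""
                parts = []
            else:
                if cur_id is None:
                    raise ValueError("sequence data before first FASTA header")
                parts.append(line)
    _flush()
    if not contigs:
        raise ValueError("no records")
    ids = [c.id for c in contigs]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate contig ids in FASTA")
    return contigs


def write_fasta(contigs, path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for c in contigs:
            fh.write(f">{c.id}\n")
            for i in range(0, len(c.seq), width):
                fh.write(c.seq[i : i + width] + "\n")


def read_alignment_fasta(path, groups: dict, outgroup_id: str) -> MultipleAlignment:
    """Read an aligned FASTA (gaps as ``-``) into a MultipleAlignment."""
    rows = {}
    cur_id, parts = None, []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                if cur_id is not None:
                    rows[cur_id] = "".join(parts).upper()
                cur_id = line[1:].split()[0]
                parts = []
            else:
                parts.append(line)
    if cur_id is not None:
        rows[cur_id] = "".join(parts).upper()
    if not rows:
        raise ValueError("no records")
    return MultipleAlignment(rows, groups, outgroup_id)


def write_alignment_fasta(aln: MultipleAlignment, path) -> None:
    with open(path, "w") as fh:
        for rid, seq in aln.rows.items():
            fh.write(f">{rid}\n{seq}\n")


# ---------------------------------------------------------------------------
# RepeatMasker .out
# ---------------------------------------------------------------------------

_RM_HEADER = (
    "   SW   perc perc perc  query     position in query"
    "     matching          repeat             position in repeat\n"
    "score   div. del. ins.  sequence  begin end    (left)   repeat"
    "     class/family      begin  end   (left)    ID\n"
    "\n"
)


def parse_repeatmasker_out(path) -> list:
    """Parse the standard RepeatMasker ``.out`` dialect (3 header lines).

    Converts 1-based inclusive query coordinates to 0-based half-open;
    orientation ``C`` maps to strand ``-`` (for which repeat begin/end
    columns are swapped and the (left) field is parenthesised).
    """
    annots = []
    with open(path) as fh:
        lines = fh.readlines()
    for lineno, line in enumerate(lines[3:], start=4):
        if not line.strip():
            continue
        f = line.split()
        if len(f) < 14:
            raise ValueError(f"line {lineno}: expected >=14 columns, got {len(f)}")
        div = float(f[1])
        qname, qbeg, qend = f[4], int(f[5]), int(f[6])
        orient = f[8]
        repeat, family = f[9], f[10]
        if orient == "+":
            strand = "+"
            cbeg, cend = int(f[11]), int(f[12])
        elif orient in ("C", "-"):
            strand = "-"
            # minus strand: fields are (left) end begin
            cbeg, cend = int(f[13]), int(f[12])
        else:
            raise ValueError(f"line {lineno}: bad orientation {orient!r}")
        annots.append(
            RepeatAnnotation(
                interval=Interval(qname, qbeg - 1, qend, strand),
                family=family,
                subfamily=repeat,
                consensus_start=cbeg,
                consensus_end=cend,
                divergence_pct=div,
            )
        )
    return annots


def write_repeatmasker_out(annots, path, contig_lengths: dict) -> None:
    """Write annotations in the RepeatMasker ``.out`` dialect."""
    with open(path, "w") as fh:
        fh.write(_RM_HEADER)
        for i, a in enumerate(annots, start=1):
            iv = a.interval
            qleft = contig_lengths[iv.contig_id] - iv.end
            if iv.strand == "+":
                orient = "+"
                r1, r2, r3 = str(a.consensus_start), str(a.consensus_end), "(0)"
            else:
                orient = "C"
                r1, r2, r3 = "(0)", str(a.consensus_end), str(a.consensus_start)
            fh.write(
                f"  500 {a.divergence_pct:4.1f}  0.0  0.0  {iv.contig_id} "
                f"{iv.start + 1} {iv.end} ({qleft}) {orient} {a.subfamily} "
                f"{a.family} {r1} {r2} {r3} {i}\n"
            )


# ---------------------------------------------------------------------------
# BED6
# ---------------------------------------------------------------------------


def write_bed(annots, path, contig_lengths: dict | None = None) -> None:
    """Write BED6: name=family:subfamily, score=round(divergence*10)."""
    with open(path, "w") as fh:
        for a in annots:
            iv = a.interval
            if contig_lengths is not None:
                if iv.end > contig_lengths.get(iv.contig_id, iv.end):
                    raise ValueError(
                        f"interval {iv} out of bounds for {iv.contig_id}"
                    )
            fh.write(
                f"{iv.contig_id}\t{iv.start}\t{iv.end}\t"
                f"{a.family}:{a.subfamily}\t{round(a.divergence_pct * 10)}\t"
                f"{iv.strand}\n"
            )


def read_bed(path) -> list:
    annots = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 3:
                raise ValueError(f"line {lineno}: fewer than 3 BED columns")
            name = f[3] if len(f) > 3 else "unknown:unknown"
            family, _, subfam = name.partition(":")
            score = float(f[4]) if len(f) > 4 and f[4] != "." else 0.0
            strand = f[5] if len(f) > 5 else "+"
            annots.append(
                RepeatAnnotation(
                    interval=Interval(f[0], int(f[1]), int(f[2]), strand),
                    family=family,
                    subfamily=subfam or family,
                    divergence_pct=score / 10.0,
                )
            )
    return annots


# ---------------------------------------------------------------------------
# DuplicationCopy TSV
# ---------------------------------------------------------------------------


def write_duplication_copies_tsv(copies, path) -> None:
    with open(path, "w") as fh:
        fh.write("name\tcontig\tstart\tend\tstrand\tbp5\tbp3\n")
        for c in copies:
            iv = c.interval
            fh.write(
                f"{c.name}\t{iv.contig_id}\t{iv.start}\t{iv.end}\t{iv.strand}\t"
                f"{c.bp5}\t{c.bp3}\n"
            )


def read_duplication_copies_tsv(path) -> list:
    copies = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {name: i for i, name in enumerate(header)}
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            try:
                copies.append(
                    DuplicationCopy(
                        name=f[idx["name"]],
                        interval=Interval(
                            f[idx["contig"]],
                            int(f[idx["start"]]),
                            int(f[idx["end"]]),
                            f[idx["strand"]],
                        ),
                        bp5=int(f[idx["bp5"]]),
                        bp3=int(f[idx["bp3"]]),
                    )
                )
            except (KeyError, IndexError) as exc:
                raise ValueError(f"line {lineno}: malformed copy row") from exc
    return copies
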