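"""Synthetic genomes with planted retroelement structures and a truth ledger.

Every structure the detectors look for can be planted with exact,
machine-readable coordinates: L1-mediated insertions with TSDs and 3'
transductions, duplication-block copies with junction microhomology,
reciprocal-chimera circular-integration cassettes, and segmental
duplications flanked by large direct repeats.  Substitutions are i.i.d.
per site with transitions weighted ``kappa:1`` over transversions; no
indels are introduced outside junction features, so ledger coordinates
are exact.  All randomness flows from explicit seeds.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .core_model import (
    Contig,
    ConsensusLibrary,
    Interval,
    RepeatAnnotation,
    revcomp,
)

_BASES = "ACGT"
_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
HEXAMER_UNIT = "TCTCCC"


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(list(_BASES))[rng.integers(0, 4, size=n)])


def mutate_sequence(seq: str, mu: float, kappa: float, rng: np.random.Generator):
    """Mutate ``seq`` at per-site rate ``mu`` under a two-rate model.

    Transitions occur with probability kappa/(kappa+2) per substitution,
    each transversion with 1/(kappa+2).  Returns (mutated, positions).
    N bases are never mutated.
    """
    if mu == 0.0 or not seq:
        return seq, []
    hits = np.nonzero(rng.random(len(seq)) < mu)[0]
    if hits.size == 0:
        return seq, []
    out = list(seq)
    positions = []
    p_ts = kappa / (kappa + 2.0)
    for i in hits:
        ref = out[i]
        if ref == "N":
            continue
        if rng.random() < p_ts:
            out[i] = _TRANSITION[ref]
        else:
            tv = [b for b in _BASES if b != ref and b != _TRANSITION[ref]]
            out[i] = tv[rng.integers(0, 2)]
        positions.append(int(i))
    return "".join(out), positions


# ---------------------------------------------------------------------------
# configuration / ledger
# ---------------------------------------------------------------------------


@dataclass
class SimulationConfig:
    seed: int
    n_contigs: int = 1
    contig_length: int = 400_000
    core_duplicon_length: int = 20_000
    mu: float = 0.0
    ts_tv_ratio: float = 2.0
    tsd_length_range: tuple = (4, 20)
    transduction_length_range: tuple = (150, 400)
    microhomology_range: tuple = (1, 4)
    direct_repeat_flank_length: int = 4_000
    direct_repeat_identity: float = 0.98
    n_l1_insertions: int = 0
    n_duplication_copies: int = 0
    n_bp5_clusters: int = 3
    n_bp3_clusters: int = 3
    n_circular_cassettes: int = 0
    n_direct_repeat_sds: int = 0
    n_subfamilies: int = 2
    n_diagnostic_sites: int = 24
    min_event_spacing: int = 40_000

    def __post_init__(self) -> None:
        if not 0.0 <= self.mu <= 0.2:
            raise ValueError("mu outside [0, 0.2]")
        if self.ts_tv_ratio <= 0:
            raise ValueError("ts_tv_ratio must be > 0")
        for name in ("tsd_length_range", "transduction_length_range", "microhomology_range"):
            lo, hi = getattr(self, name)
            if lo > hi or lo < 0:
                raise ValueError(f"{name} empty or negative")
        if self.direct_repeat_flank_length < 1_000:
            raise ValueError("direct_repeat_flank_length below SD minimum (1 kb)")
        if not 0.9 <= self.direct_repeat_identity <= 1.0:
            raise ValueError("direct_repeat_identity outside SD regime [0.9, 1.0]")


@dataclass
class TruthLedger:
    """Planted-event records; the acceptance surface for recovery scoring.

    Each event is a JSON-able dict with at least ``type`` and a
    ``features`` map of named {contig, start, end, seq} records whose
    coordinates index the emitted genome.
    """

    events: list = field(default_factory=list)

    def by_type(self, event_type: str) -> list:
        return [e for e in self.events if e["type"] == event_type]

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"events": self.events}, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "TruthLedger":
        with open(path) as fh:
            return cls(events=json.load(fh)["events"])


def _feature(contig: str, start: int, end: int, seq: str) -> dict:
    return {"contig": contig, "start": int(start), "end": int(end), "seq": seq}


def audit_ledger(contigs: dict, ledger: TruthLedger) -> None:
    """Check that every recorded feature reproduces its genome slice."""
    for i, ev in enumerate(ledger.events):
        for name, f in ev.get("features", {}).items():
            seq = contigs[f["contig"]][f["start"] : f["end"]]
            if seq != f["seq"]:
                raise AssertionError(
                    f"event {i} ({ev['type']}): feature {name} at "
                    f"{f['contig']}:{f['start']}-{f['end']} does not match ledger"
                )


# ---------------------------------------------------------------------------
# element library
# ---------------------------------------------------------------------------


def make_element_library(
    seed: int,
    n_subfamilies: int = 2,
    n_diagnostic_sites: int = 24,
    hexamer_copies: int = 5,
    alu_like_length: int = 300,
    vntr_unit_length: int = 36,
    vntr_units: int = 12,
    sine_r_length: int = 500,
    transduction_length: int = 250,
) -> ConsensusLibrary:
    """Build a composite-element consensus library.

    The base consensus has the canonical four-domain layout: hexamer
    repeats of TCTCCC, an Alu-like domain, a VNTR of near-identical units,
    and a SINE-R.  Subfamilies differ from the base (and from each other)
    at exactly ``n_diagnostic_sites`` non-VNTR positions; the differing
    states are recorded per subfamily pair.
    """
    if n_subfamilies < 2:
        raise ValueError("need at least 2 subfamilies")
    rng = np.random.default_rng(seed)

    hexamer = HEXAMER_UNIT * hexamer_copies
    alu_like = random_dna(rng, alu_like_length)
    unit = random_dna(rng, vntr_unit_length)
    vntr_parts = []
    for _ in range(vntr_units):
        u, _ = mutate_sequence(unit, 0.02, 2.0, rng)  # near-identical units
        vntr_parts.append(u)
    vntr = "".join(vntr_parts)
    sine_r = random_dna(rng, sine_r_length)

    base = hexamer + alu_like + vntr + sine_r
    b0 = 0
    b1 = len(hexamer)
    b2 = b1 + len(alu_like)
    b3 = b2 + len(vntr)
    b4 = len(base)
    domains = {
        "hexamer": (b0, b1),
        "alu_like": (b1, b2),
        "VNTR": (b2, b3),
        "SINE_R": (b3, b4),
    }

    non_vntr = list(range(b0, b2)) + list(range(b3, b4))
    if n_diagnostic_sites > len(non_vntr):
        raise ValueError("n_diagnostic_sites exceeds non-VNTR length")
    site_positions = sorted(
        int(p) for p in rng.choice(non_vntr, size=n_diagnostic_sites, replace=False)
    )

    names = [f"SVA_{chr(ord('A') + i)}" for i in range(n_subfamilies)]
    seqs = {}
    for k, name in enumerate(names):
        s = list(base)
        for pos in site_positions:
            ref = base[pos]
            alts = [b for b in _BASES if b != ref]
            s[pos] = alts[k % 3]
        seqs[name] = "".join(s)

    entries = {"base": {"seq": base, "domains": dict(domains), "transduction": None}}
    for name in names:
        entries[name] = {
            "seq": seqs[name],
            "domains": dict(domains),
            "transduction": random_dna(rng, transduction_length),
        }

    diagnostic_sites = {}
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            a, b = names[i], names[j]
            sites = [
                (pos, seqs[a][pos], seqs[b][pos])
                for pos in site_positions
                if seqs[a][pos] != seqs[b][pos]
            ]
            diagnostic_sites[(a, b)] = sites

    return ConsensusLibrary(entries=entries, diagnostic_sites=diagnostic_sites, base="base")


def save_library(library: ConsensusLibrary, path) -> None:
    doc = {
        "base": library.base,
        "entries": {
            name: {
                "seq": ent["seq"],
                "domains": {k: list(v) for k, v in ent["domains"].items()},
                "transduction": ent.get("transduction"),
            }
            for name, ent in library.entries.items()
        },
        "diagnostic_sites": {
            f"{a}|{b}": sites for (a, b), sites in library.diagnostic_sites.items()
        },
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1, sort_keys=True)


def load_library(path) -> ConsensusLibrary:
    with open(path) as fh:
        doc = json.load(fh)
    entries = {
        name: {
            "seq": ent["seq"],
            "domains": {k: tuple(v) for k, v in ent["domains"].items()},
            "transduction": ent.get("transduction"),
        }
        for name, ent in doc["entries"].items()
    }
    diagnostic_sites = {
        tuple(key.split("|")): [tuple(s) for s in sites]
        for key, sites in doc["diagnostic_sites"].items()
    }
    return ConsensusLibrary(entries=entries, diagnostic_sites=diagnostic_sites,
                            base=doc.get("base", ""))


# ---------------------------------------------------------------------------
# individual plant operations
#
# Each operation takes a genome (dict contig_id -> sequence string), returns
# (genome', event dict).  Coordinates recorded refer to the returned genome.
# ---------------------------------------------------------------------------


def plant_l1_insertion(
    genome: dict,
    library: ConsensusLibrary,
    site,
    with_transduction: bool = False,
    seed: int = 0,
    subfamily: str | None = None,
    tsd_length: int | None = None,
    tsd_mismatches: int = 0,
    truncate_5p: int = 0,
    polya_length: int | None = None,
    transduction_length: int | None = None,
    mu: float = 0.0,
    kappa: float = 2.0,
):
    """Plant an L1-mediated element insertion with a TSD pair.

    ``site`` is (contig_id, position).  The inserted sequence is
    element (optionally 5'-truncated) [+ 3' transduction] + polyA; the
    target-site bases are duplicated on both flanks.
    """
    contig_id, pos = site
    seq = genome[contig_id]
    rng = np.random.default_rng(seed)
    if subfamily is None:
        subfamily = rng.choice(library.subfamilies())
    if subfamily not in library.entries:
        raise ValueError(f"unknown subfamily {subfamily!r}")
    if tsd_length is None:
        tsd_length = int(rng.integers(4, 21))
    if polya_length is None:
        polya_length = int(rng.integers(8, 31))
    if pos < 0 or pos + tsd_length > len(seq):
        raise ValueError(f"site {pos} out of bounds for contig {contig_id}")

    elem = library.consensus(subfamily)[truncate_5p:]
    td = ""
    if with_transduction:
        td = library.entries[subfamily]["transduction"]
        if td is None:
            raise ValueError(f"subfamily {subfamily!r} has no transduction")
        if transduction_length is not None:
            td = td[:transduction_length]
    polya = "A" * polya_length
    insert = elem + td + polya

    tsd = seq[pos : pos + tsd_length]
    if "N" in tsd:
        raise ValueError("TSD would contain N")
    right_tsd = tsd
    if tsd_mismatches:
        idxs = rng.choice(tsd_length, size=tsd_mismatches, replace=False)
        r = list(right_tsd)
        for i in idxs:
            r[i] = _TRANSITION[r[i]]
        right_tsd = "".join(r)

    new_seq = seq[:pos] + tsd + insert + right_tsd + seq[pos + tsd_length :]

    # post-insertion neutral divergence over the whole planted region
    span_start, span_end = pos, pos + 2 * tsd_length + len(insert)
    region, mut_pos = mutate_sequence(new_seq[span_start:span_end], mu, kappa, rng)
    new_seq = new_seq[:span_start] + region + new_seq[span_end:]
    genome = dict(genome)
    genome[contig_id] = new_seq

    lt_s, lt_e = pos, pos + tsd_length
    ins_s, ins_e = lt_e, lt_e + len(insert)
    rt_s, rt_e = ins_e, ins_e + tsd_length
    elem_s, elem_e = ins_s, ins_s + len(elem)
    td_s, td_e = elem_e, elem_e + len(td)
    pa_s, pa_e = td_e, td_e + polya_length

    g = genome[contig_id]
    left_seq, right_seq = g[lt_s:lt_e], g[rt_s:rt_e]
    event = {
        "type": "L1_insertion",
        "contig": contig_id,
        "site": int(pos),
        "subfamily": subfamily,
        "truncate_5p": int(truncate_5p),
        "tsd_length": int(tsd_length),
        "tsd_mismatches": sum(a != b for a, b in zip(left_seq, right_seq)),
        "with_transduction": bool(with_transduction),
        "n_substitutions": len(mut_pos),
        "features": {
            "tsd_left": _feature(contig_id, lt_s, lt_e, left_seq),
            "tsd_right": _feature(contig_id, rt_s, rt_e, right_seq),
            "insert": _feature(contig_id, ins_s, ins_e, g[ins_s:ins_e]),
            "element": _feature(contig_id, elem_s, elem_e, g[elem_s:elem_e]),
            "polyA": _feature(contig_id, pa_s, pa_e, g[pa_s:pa_e]),
        },
    }
    if with_transduction:
        event["features"]["transduction"] = _feature(contig_id, td_s, td_e, g[td_s:td_e])

    annotations = [
        RepeatAnnotation(
            Interval(contig_id, elem_s, elem_e), "SVA", subfamily,
            consensus_start=truncate_5p + 1,
            consensus_end=len(library.consensus(subfamily)),
        ),
        RepeatAnnotation(
            Interval(contig_id, pa_s, pa_e), "Simple_repeat", "(A)n"
        ),
    ]
    if with_transduction:
        annotations.insert(
            1,
            RepeatAnnotation(
                Interval(contig_id, td_s, td_e), "TD", f"{subfamily}_TD"
            ),
        )
    event["annotations_idx"] = None  # filled by simulate()
    return genome, event, annotations


def plant_duplication_block(
    genome: dict,
    core_locus,
    bp5: int,
    bp3: int,
    target_site,
    mu: float = 0.0,
    seed: int = 0,
    kappa: float = 2.0,
    microhomology_range: tuple = (1, 4),
    name: str = "copy",
    junction_mode: str = "microhomology",
    insertion_nt_range: tuple = (1, 10),
):
    """Copy ``ancestral[bp5:bp3]`` to ``target_site`` with junction features.

    ``core_locus`` is (contig_id, locus_start): bp5/bp3 are ancestral-locus
    coordinates (offsets from locus_start).  The copy is mutated at rate
    ``mu``; each junction carries either sampled microhomology (target
    flank bases forced to match the copy end) or an inserted-nucleotide
    run, per ``junction_mode`` in {"microhomology", "insertion"}.
    """
    if bp3 - bp5 < 1_000:
        raise ValueError("duplication shorter than 1 kb is below the SD definition")
    anc_contig, locus_start = core_locus
    tgt_contig, tgt = target_site
    rng = np.random.default_rng(seed)

    ancestral = genome[anc_contig][locus_start + bp5 : locus_start + bp3]
    if len(ancestral) != bp3 - bp5:
        raise ValueError("breakpoint interval outside ancestral locus")
    copy, mut_pos = mutate_sequence(ancestral, mu, kappa, rng)

    seq = genome[tgt_contig]
    mh5 = mh3 = 0
    ins5 = ins3 = ""
    emitted = copy
    if junction_mode == "microhomology":
        mh5 = int(rng.integers(microhomology_range[0], microhomology_range[1] + 1))
        mh3 = int(rng.integers(microhomology_range[0], microhomology_range[1] + 1))
        # the shared junction bases live in the target flanks; the donor
        # copy retains them, the emitted copy is trimmed so they appear once
        if mh5:
            seq = seq[: tgt - mh5] + copy[:mh5] + seq[tgt:]
        if mh3:
            seq = seq[:tgt] + copy[-mh3:] + seq[tgt + mh3 :]
        emitted = copy[mh5 : len(copy) - mh3 if mh3 else len(copy)]
    elif junction_mode == "insertion":
        ins5 = random_dna(rng, int(rng.integers(*insertion_nt_range) + 1))
        ins3 = random_dna(rng, int(rng.integers(*insertion_nt_range) + 1))
    else:
        raise ValueError(f"unknown junction_mode {junction_mode!r}")

    new_seq = seq[:tgt] + ins5 + emitted + ins3 + seq[tgt:]
    genome = dict(genome)
    genome[tgt_contig] = new_seq

    c_s = tgt + len(ins5)
    c_e = c_s + len(emitted)
    g = genome[tgt_contig]
    event = {
        "type": "duplication_copy",
        "name": name,
        "contig": tgt_contig,
        "target_site": int(tgt),
        "ancestral_contig": anc_contig,
        "ancestral_locus_start": int(locus_start),
        "bp5": int(bp5),
        "bp3": int(bp3),
        "bp5_emitted": int(bp5 + mh5),
        "bp3_emitted": int(bp3 - mh3),
        "mh5": mh5,
        "mh3": mh3,
        "inserted5": ins5,
        "inserted3": ins3,
        "junction5_bases": copy[:mh5],
        "junction3_bases": copy[-mh3:] if mh3 else "",
        "donor_seq": copy,
        "n_substitutions": len(mut_pos),
        "features": {
            "copy": _feature(tgt_contig, c_s, c_e, g[c_s:c_e]),
        },
    }
    return genome, event


def plant_circular_integration(
    genome: dict,
    library: ConsensusLibrary,
    donor_locus,
    target_site=None,
    seed: int = 0,
    outer_subfamily: str | None = None,
    inner_subfamily: str | None = None,
    switch_point: int | None = None,
    tsd_length: int = 12,
    mu: float = 0.0,
    kappa: float = 2.0,
):
    """Plant the reciprocal-chimera circular-integration cassette.

    Emitted structure (X = outer subfamily, Y = inner subfamily)::

        [outerL TSD][X5'|Y3' chimera][innerL TSD][rotated donor segment]
        [innerR TSD][Y5'|X3' chimera][outerR TSD]

    The outer TSD pair duplicates the pre-integration target site; the
    inner pair is the donor Y-element's own TSD (donor bases at the
    circularization cut), so the donor segment appears circularly permuted
    at the Y insertion point.
    """
    rng = np.random.default_rng(seed)
    subfams = library.subfamilies()
    if outer_subfamily is None:
        outer_subfamily = subfams[0]
    if inner_subfamily is None:
        inner_subfamily = subfams[1]
    for sf in (outer_subfamily, inner_subfamily):
        if sf not in library.entries or sf == library.base:
            raise ValueError(f"donor lacks a {sf!r} element")
    if outer_subfamily == inner_subfamily:
        raise ValueError("outer and inner subfamilies must differ")

    key = tuple(sorted((outer_subfamily, inner_subfamily)))
    sites = library.diagnostic_sites[key]
    if len(sites) < 4:
        raise ValueError("too few diagnostic sites to place a switch point")
    if switch_point is None:
        # between two adjacent diagnostic sites in the element 3' half
        positions = [p for p, _, _ in sites]
        k = len(positions) // 2
        switch_point = (positions[k] + positions[k + 1]) // 2
    s = int(switch_point)

    d_contig, d_start, d_end = donor_locus
    donor = genome[d_contig][d_start:d_end]
    if len(donor) < 2 * tsd_length + 100:
        raise ValueError("donor locus too short")
    cut = len(donor) // 2
    inner_tsd = donor[cut : cut + tsd_length]
    rotated = donor[cut:] + donor[:cut]

    x = library.consensus(outer_subfamily)
    y = library.consensus(inner_subfamily)
    chim1 = x[:s] + y[s:]  # X5' | Y3'
    chim2 = y[:s] + x[s:]  # Y5' | X3'

    if target_site is None:
        raise ValueError("target_site required")
    t_contig, tgt = target_site
    seq = genome[t_contig]
    outer_tsd = seq[tgt : tgt + tsd_length]
    cassette = chim1 + inner_tsd + rotated + inner_tsd + chim2
    new_seq = seq[: tgt + tsd_length] + cassette + seq[tgt:]
    genome = dict(genome)
    genome[t_contig] = new_seq

    ol_s, ol_e = tgt, tgt + tsd_length
    c1_s, c1_e = ol_e, ol_e + len(chim1)
    il_s, il_e = c1_e, c1_e + tsd_length
    rot_s, rot_e = il_e, il_e + len(rotated)
    ir_s, ir_e = rot_e, rot_e + tsd_length
    c2_s, c2_e = ir_e, ir_e + len(chim2)
    or_s, or_e = c2_e, c2_e + tsd_length

    # neutral divergence across the whole cassette (incl. both TSD pairs)
    region, mut_pos = mutate_sequence(new_seq[ol_s:or_e], mu, kappa, rng)
    new_seq = new_seq[:ol_s] + region + new_seq[or_e:]
    genome[t_contig] = new_seq
    g = new_seq

    event = {
        "type": "circular_integration",
        "contig": t_contig,
        "site": int(tgt),
        "outer_subfamily": outer_subfamily,
        "inner_subfamily": inner_subfamily,
        "switch_point_5p": s,
        "switch_point_3p": s,
        "tsd_length": int(tsd_length),
        "n_substitutions": len(mut_pos),
        "cassette": [int(ol_s), int(or_e)],
        "features": {
            "outer_tsd_left": _feature(t_contig, ol_s, ol_e, g[ol_s:ol_e]),
            "outer_tsd_right": _feature(t_contig, or_s, or_e, g[or_s:or_e]),
            "inner_tsd_left": _feature(t_contig, il_s, il_e, g[il_s:il_e]),
            "inner_tsd_right": _feature(t_contig, ir_s, ir_e, g[ir_s:ir_e]),
            "chimera_5p": _feature(t_contig, c1_s, c1_e, g[c1_s:c1_e]),
            "interior": _feature(t_contig, rot_s, rot_e, g[rot_s:rot_e]),
            "chimera_3p": _feature(t_contig, c2_s, c2_e, g[c2_s:c2_e]),
        },
    }
    annotations = [
        RepeatAnnotation(
            Interval(t_contig, c1_s, c1_e), "SVA", outer_subfamily,
            consensus_start=1, consensus_end=len(chim1),
        ),
        RepeatAnnotation(
            Interval(t_contig, c2_s, c2_e), "SVA", inner_subfamily,
            consensus_start=1, consensus_end=len(chim2),
        ),
    ]
    return genome, event, annotations


def plant_direct_repeat_sd(
    genome: dict,
    insert: str,
    flank_length: int = 4_000,
    identity: float = 1.0,
    seed: int = 0,
    target_site=None,
    kappa: float = 2.0,
    microhomology_range: tuple = (1, 4),
    junction_mode: str = "microhomology",
    insertion_nt_range: tuple = (1, 10),
):
    """Plant ``[repeat L][insert][repeat R]`` with R a mutated copy of L.

    L is the target-locus sequence immediately left of the integration
    point (mirrors flanks derived from target-chromosome sequence); R is a
    copy mutated down to the stated identity.  Junctions carry either
    sampled microhomology or an unrelated-nucleotide insertion.
    Inverted-orientation structures are never emitted.
    """
    if flank_length < 1_000:
        raise ValueError("flank_length below SD minimum (1 kb)")
    if not 0.9 <= identity <= 1.0:
        raise ValueError("identity below the SD definition (>= 0.9)")
    t_contig, tgt = target_site
    rng = np.random.default_rng(seed)
    seq = genome[t_contig]
    if tgt < flank_length:
        raise ValueError("no room for the left repeat at target site")

    left = seq[tgt - flank_length : tgt]
    right, _ = mutate_sequence(left, 1.0 - identity, kappa, rng)
    donor = insert.upper()

    mh5 = mh3 = 0
    ins5 = ins3 = ""
    if junction_mode == "microhomology":
        mh5 = int(rng.integers(microhomology_range[0], microhomology_range[1] + 1))
        mh3 = int(rng.integers(microhomology_range[0], microhomology_range[1] + 1))
        # donor ends share bases with the flanks; emitted insert is trimmed
        # so the shared bases appear once in the genome
        d = list(donor)
        if mh5:
            d[:mh5] = left[-mh5:]
        if mh3:
            d[len(d) - mh3 :] = right[:mh3]
        donor = "".join(d)
        emitted = donor[mh5 : len(donor) - mh3 if mh3 else len(donor)]
    elif junction_mode == "insertion":
        ins5 = random_dna(rng, int(rng.integers(*insertion_nt_range) + 1))
        ins3 = random_dna(rng, int(rng.integers(*insertion_nt_range) + 1))
        emitted = donor
    else:
        raise ValueError(f"unknown junction_mode {junction_mode!r}")

    new_seq = seq[:tgt] + ins5 + emitted + ins3 + right + seq[tgt:]
    genome = dict(genome)
    genome[t_contig] = new_seq
    g = new_seq

    l_s, l_e = tgt - flank_length, tgt
    i_s = tgt + len(ins5)
    i_e = i_s + len(emitted)
    r_s = i_e + len(ins3)
    r_e = r_s + flank_length
    realized_identity = sum(a == b for a, b in zip(g[l_s:l_e], g[r_s:r_e])) / flank_length
    event = {
        "type": "direct_repeat_SD",
        "contig": t_contig,
        "site": int(tgt),
        "flank_length": int(flank_length),
        "identity": float(identity),
        "realized_identity": float(realized_identity),
        "mh5": mh5,
        "mh3": mh3,
        "inserted5": ins5,
        "inserted3": ins3,
        "donor_insert": donor,
        "features": {
            "left_repeat": _feature(t_contig, l_s, l_e, g[l_s:l_e]),
            "insert": _feature(t_contig, i_s, i_e, g[i_s:i_e]),
            "right_repeat": _feature(t_contig, r_s, r_e, g[r_s:r_e]),
        },
    }
    return genome, event


# ---------------------------------------------------------------------------
# ancestral core locus with embedded repeats (for breakpoint census truth)
# ---------------------------------------------------------------------------


def make_core_locus(
    rng: np.random.Generator,
    library: ConsensusLibrary,
    length: int = 20_000,
    contig_id: str = "ancestral_core",
):
    """Random core-duplicon sequence with embedded SVA/Alu annotations.

    Returns (seq, annotations); annotation coordinates are locus-relative.
    Elements are placed in the interior so breakpoints can be planted
    inside or outside them.
    """
    seq = random_dna(rng, length)
    annots = []
    sva = library.consensus(library.subfamilies()[0])
    alu = random_dna(rng, 300)  # Alu stand-in: fixed random 300-mer
    # repeats in both halves so both breakpoint sides can overlap them
    placements = [
        ("SVA", library.subfamilies()[0], sva, int(length * 0.08)),
        ("Alu", "AluY", alu, int(length * 0.25)),
        ("Alu", "AluY", alu, int(length * 0.60)),
        ("SVA", library.subfamilies()[0], sva, int(length * 0.80)),
    ]
    for family, subfam, elem, at in placements:
        seq = seq[:at] + elem + seq[at + len(elem) :]
        annots.append(
            RepeatAnnotation(
                Interval(contig_id, at, at + len(elem)), family, subfam,
                consensus_start=1, consensus_end=len(elem),
            )
        )
    return seq, annots


# ---------------------------------------------------------------------------
# composed simulation
# ---------------------------------------------------------------------------


@dataclass
class SimulationResult:
    config: SimulationConfig
    contigs: dict  # id -> sequence string
    ledger: TruthLedger
    annotations: list  # RepeatAnnotation in emitted coordinates
    library: ConsensusLibrary
    ancestral_annotations: list  # on the ancestral core locus (locus-relative)

    def contig_list(self) -> list:
        return [Contig(cid, seq) for cid, seq in self.contigs.items()]


def simulate(config: SimulationConfig) -> SimulationResult:
    """Run the full composed simulation for a configuration.

    Events are planted left-to-right at increasing coordinates with
    ``min_event_spacing`` so earlier coordinates stay valid as the contig
    grows.  A self-consistency audit runs before returning.
    """
    rng = np.random.default_rng(config.seed)
    library = make_element_library(
        seed=int(rng.integers(0, 2**31)),
        n_subfamilies=config.n_subfamilies,
        n_diagnostic_sites=config.n_diagnostic_sites,
    )

    genome = {}
    core_seq, anc_annots = make_core_locus(
        rng, library, config.core_duplicon_length, "ancestral_core"
    )
    genome["ancestral_core"] = core_seq
    for i in range(config.n_contigs):
        genome[f"chr{i + 1}"] = random_dna(rng, config.contig_length)

    # breakpoint clusters on the ancestral locus: a third inside the SVA, a
    # third inside an Alu, the rest in unique sequence (census ground truth)
    L = len(core_seq)

    def _pick_breakpoints(n: int, side: str) -> list:
        # 5' breakpoints live in the left 40% of the locus, 3' in the right
        # 45%, so every bp5 < every bp3 and intervals stay > 1 kb.
        lo, hi = (100, int(L * 0.38)) if side == "5p" else (int(L * 0.58), L - 100)
        svas = [a for a in anc_annots if a.family == "SVA"
                and lo <= a.interval.start and a.interval.end <= hi]
        alus = [a for a in anc_annots if a.family == "Alu"
                and lo <= a.interval.start and a.interval.end <= hi]
        n_sva = (n + 1) // 3 if side == "5p" else max(1, round(n * 5 / 9))
        n_alu = (n - n_sva + 1) // 2
        coords: list = []

        def _draw(dlo: int, dhi: int, unique: bool) -> None:
            for _ in range(10_000):
                p = int(rng.integers(dlo, dhi))
                if any(abs(p - c) < 100 for c in coords):
                    continue
                if unique and any(a.interval.contains(p) for a in anc_annots):
                    continue
                coords.append(p)
                return
            raise RuntimeError("could not place breakpoint")

        for k in range(n):
            if k < n_sva and svas:
                iv = svas[k % len(svas)].interval
                _draw(iv.start + 5, iv.end - 5, unique=False)
            elif k < n_sva + n_alu and alus:
                iv = alus[k % len(alus)].interval
                _draw(iv.start + 5, iv.end - 5, unique=False)
            else:
                _draw(lo, hi, unique=True)
        return sorted(coords)

    bp5s = _pick_breakpoints(config.n_bp5_clusters, "5p")
    bp3s = _pick_breakpoints(config.n_bp3_clusters, "3p")

    # plan events, then plant round-robin across contigs left-to-right
    plan = []
    for i in range(config.n_l1_insertions):
        plan.append(("L1", i))
    for i in range(config.n_duplication_copies):
        plan.append(("DUP", i))
    for i in range(config.n_circular_cassettes):
        plan.append(("CIRC", i))
    for i in range(config.n_direct_repeat_sds):
        plan.append(("SD", i))
    rng.shuffle(plan)

    contig_ids = [f"chr{i + 1}" for i in range(config.n_contigs)]
    spacing = config.min_event_spacing
    slots_per_contig = max(0, (config.contig_length - 25_000) // spacing)
    if slots_per_contig * config.n_contigs < len(plan):
        raise ValueError(
            f"{len(plan)} events need more room: increase contig_length or n_contigs"
        )

    cursor = {cid: 0 for cid in contig_ids}  # cumulative insertion shift
    slot = {cid: 0 for cid in contig_ids}
    ledger = TruthLedger()
    annotations = []

    def _next_site(cid: str) -> int:
        slot[cid] += 1
        return slot[cid] * spacing + cursor[cid]

    for k, (etype, idx) in enumerate(plan):
        cid = contig_ids[k % len(contig_ids)]
        site = _next_site(cid)
        before = len(genome[cid])
        ev_seed = int(rng.integers(0, 2**31))
        if etype == "L1":
            tsd_len = int(rng.integers(config.tsd_length_range[0],
                                       config.tsd_length_range[1] + 1))
            genome, event, annots = plant_l1_insertion(
                genome, library, (cid, site),
                with_transduction=bool(rng.random() < 0.5),
                seed=ev_seed,
                tsd_length=tsd_len,
                transduction_length=int(
                    rng.integers(config.transduction_length_range[0],
                                 config.transduction_length_range[1] + 1)
                ),
                mu=config.mu,
                kappa=config.ts_tv_ratio,
            )
            annotations.extend(annots)
        elif etype == "DUP":
            bp5 = bp5s[idx % len(bp5s)]
            bp3 = bp3s[idx % len(bp3s)]
            genome, event = plant_duplication_block(
                genome, ("ancestral_core", 0), bp5, bp3, (cid, site),
                mu=config.mu, seed=ev_seed, kappa=config.ts_tv_ratio,
                microhomology_range=config.microhomology_range,
                name=f"copy_{idx + 1}",
            )
        elif etype == "CIRC":
            # carve the donor segment out of untouched sequence downstream
            donor_len = 6_000
            d_start = site + spacing // 2
            genome, event, annots = plant_circular_integration(
                genome, library,
                donor_locus=(cid, d_start, d_start + donor_len),
                target_site=(cid, site),
                seed=ev_seed, tsd_length=12,
                mu=config.mu, kappa=config.ts_tv_ratio,
            )
            annotations.extend(annots)
        else:  # SD
            insert = random_dna(rng, 8_000)
            genome, event = plant_direct_repeat_sd(
                genome, insert,
                flank_length=config.direct_repeat_flank_length,
                identity=config.direct_repeat_identity,
                seed=ev_seed, target_site=(cid, site),
                kappa=config.ts_tv_ratio,
                microhomology_range=config.microhomology_range,
            )
        ledger.events.append(event)
        cursor[cid] += len(genome[cid]) - before

    audit_ledger(genome, ledger)
    return SimulationResult(
        config=config,
        contigs=genome,
        ledger=ledger,
        annotations=annotations,
        library=library,
        ancestral_annotations=anc_annots,
    )


def write_result(result: SimulationResult, outdir) -> None:
    """Write genome FASTA, annotations (.out + BED), ledger JSON, config."""
    import os

    from .core_model import write_bed, write_fasta, write_repeatmasker_out

    os.makedirs(outdir, exist_ok=True)
    write_fasta(result.contig_list(), os.path.join(outdir, "genome.fasta"))
    lengths = {cid: len(s) for cid, s in result.contigs.items()}
    write_repeatmasker_out(
        result.annotations, os.path.join(outdir, "annotations.out"), lengths
    )
    write_bed(result.annotations, os.path.join(outdir, "annotations.bed"), lengths)
    anc_lengths = {"ancestral_core": len(result.contigs["ancestral_core"])}
    write_repeatmasker_out(
        result.ancestral_annotations,
        os.path.join(outdir, "ancestral_annotations.out"),
        anc_lengths,
    )
    result.ledger.to_json(os.path.join(outdir, "truth.json"))
    save_library(result.library, os.path.join(outdir, "library.json"))
    with open(os.path.join(outdir, "config.txt"), "w") as fh:
        for key, val in sorted(asdict(result.config).items()):
            fh.write(f"{key} = {val}\n")


# ---------------------------------------------------------------------------
# sequence evolution on trees (for the phylogenetic modules' simulations)
# ---------------------------------------------------------------------------


def leaf(name: str) -> dict:
    return {"name": name, "children": []}


def node(children: list) -> dict:
    """Internal node: ``children`` is a list of (subtree, branch_length)."""
    return {"name": None, "children": children}


def tree_leaves(tree: dict) -> list:
    if not tree["children"]:
        return [tree["name"]]
    out = []
    for child, _ in tree["children"]:
        out.extend(tree_leaves(child))
    return out


def make_random_tree(taxa: list, rng: np.random.Generator, blen_range=(0.01, 0.05)) -> dict:
    """Random binary topology by sequential joining, U(blen_range) branches."""
    lo, hi = blen_range
    nodes = [leaf(t) for t in taxa]
    while len(nodes) > 2:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        a, b = nodes[i], nodes[j]
        merged = node([(a, float(rng.uniform(lo, hi))), (b, float(rng.uniform(lo, hi)))])
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [merged]
    return node([(nodes[0], float(rng.uniform(lo, hi))),
                 (nodes[1], float(rng.uniform(lo, hi)))])


def evolve_on_tree(tree: dict, root_seq: str, rng: np.random.Generator, kappa: float = 2.0) -> dict:
    """Evolve ``root_seq`` down a nested tree; substitutions only.

    Branch lengths are expected substitutions per site.  Returns
    leaf name -> sequence; all sequences share coordinates (no indels),
    so they form an alignment as-is.
    """
    out = {}

    def _walk(nd: dict, seq: str) -> None:
        if not nd["children"]:
            out[nd["name"]] = seq
            return
        for child, blen in nd["children"]:
            mutated, _ = mutate_sequence(seq, blen, kappa, rng)
            _walk(child, mutated)

    _walk(tree, root_seq)
    return out


def simulate_split_alignment(
    seed: int,
    n_per_group: int = 4,
    seg_len: int = 600,
    recombinant: bool = True,
    stem: float = 0.05,
    tip_range=(0.002, 0.006),
    outgroup_blen: float = 0.01,
    kappa: float = 2.0,
):
    """Two-group + outgroup alignment with an optional recombination switch.

    The 5' segment always evolves on a tree where the two in-groups stem
    independently from the root (no shared internal edge with respect to
    the outgroup).  The 3' segment evolves either on a fresh tree of the
    same shape (non-recombinant control) or on a tree whose two clades mix
    members of both groups (recombinant): group-specific substitutions
    then precede the switch and shared-derived ones follow it.

    Returns (MultipleAlignment, truth) with truth = {"switch": column,
    "groups": (labelA, labelB)}.
    """
    from .core_model import MultipleAlignment

    rng = np.random.default_rng(seed)
    a_taxa = [f"A{i + 1}" for i in range(n_per_group)]
    b_taxa = [f"B{i + 1}" for i in range(n_per_group)]

    def _three_clade_tree(left_taxa, right_taxa):
        return node(
            [
                (leaf("OUT"), outgroup_blen),
                (make_random_tree(left_taxa, rng, tip_range), stem),
                (make_random_tree(right_taxa, rng, tip_range), stem),
            ]
        )

    t5 = _three_clade_tree(a_taxa, b_taxa)
    if recombinant:
        half = n_per_group // 2
        mixed1 = a_taxa[:half] + b_taxa[:half]
        mixed2 = a_taxa[half:] + b_taxa[half:]
        t3 = _three_clade_tree(mixed1, mixed2)
    else:
        t3 = _three_clade_tree(a_taxa, b_taxa)

    left = evolve_on_tree(t5, random_dna(rng, seg_len), rng, kappa)
    right = evolve_on_tree(t3, random_dna(rng, seg_len), rng, kappa)
    rows = {t: left[t] + right[t] for t in a_taxa + b_taxa + ["OUT"]}
    groups = {t: "chr16" for t in a_taxa}
    groups.update({t: "chr13" for t in b_taxa})
    groups["OUT"] = "outgroup"
    aln = MultipleAlignment(rows, groups, "OUT")
    return aln, {"switch": seg_len, "groups": ("chr16", "chr13")}


def tree_path_distances(tree: dict) -> dict:
    """Leaf-to-leaf path-length distances (additive matrix) of a nested tree."""
    dists = {}

    def _walk(nd: dict, blen: float):
        if not nd["children"]:
            return {nd["name"]: blen}
        below = {}
        child_maps = []
        for child, b in nd["children"]:
            m = _walk(child, b)
            child_maps.append(m)
        for i in range(len(child_maps)):
            for j in range(i + 1, len(child_maps)):
                for la, da in child_maps[i].items():
                    for lb, db in child_maps[j].items():
                        dists[tuple(sorted((la, lb)))] = da + db
        for m in child_maps:
            for l_, d_ in m.items():
                below[l_] = d_ + blen
        return below

    _walk(tree, 0.0)
    return dists
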