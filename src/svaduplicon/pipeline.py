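"""End-to-end orchestration: simulate -> annotate -> detect -> score -> report.

The pipeline is deterministic under a fixed seed: identical configs
produce byte-identical output bundles, and the emitted manifest (config
hash + seed + versions) suffices to replay a run.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np

from . import __version__
from .core_model import Contig, DuplicationCopy, Interval, RepeatAnnotation
from .chimera_circular import (
    detect_chimera,
    detect_circular_signature,
    signature_to_dict,
    write_chimera_tsv,
    write_signature_json,
)
from .flank_scanner import (
    max_scoring_segment,
    mismatch_penalty,
    scan_windows,
    write_hits_bed,
    write_hits_json,
)
from .junction_tsd import (
    chain_insertions,
    cluster_breakpoints,
    detect_tsd,
    repeat_overlap_census,
    write_census_json,
    write_census_tsv,
    write_tsd_calls_tsv,
)
from .synthetic_genome import SimulationConfig, TruthLedger, simulate, write_result

log = logging.getLogger("svaduplicon")

DEFAULT_MATCH_TOLERANCE_BP = 20

# pipeline-level detector defaults (each exposed in the config's [detect])
DETECT_DEFAULTS = {
    "tsd_min_len": 8,
    "tsd_max_window": 60,
    "tsd_max_junction_dist": 4,
    "cluster_tolerance_bp": 20,
    "copy_min_len": 2000,
    "copy_min_identity": 0.9,
    "flank_min_len": 2000,
    "flank_min_identity": 0.9,
    "flank_max_insert": 10_000,
    "flank_window_size": 500_000,
    "cassette_max_span": 25_000,
    "chimera_min_support": 3,
}


# ---------------------------------------------------------------------------
# duplication-copy mapping (ancestral locus vs. genome diagonals)
# ---------------------------------------------------------------------------


def map_duplication_copies(
    contigs: dict,
    ancestral_id: str = "ancestral_core",
    min_len: int = 1000,
    min_identity: float = 0.9,
    seed_k: int = 14,
) -> list:
    """Find copies of the ancestral locus elsewhere in the genome.

    Seeded ungapped diagonal search between the ancestral sequence and
    each other contig; per diagonal the maximum-scoring segment is kept if
    it passes the SD length/identity regime.  Breakpoints bp5/bp3 are the
    ancestral coordinates of the matched segment.
    """
    anc = contigs[ancestral_id]
    penalty = mismatch_penalty(min_identity)
    anc_arr = np.frombuffer(anc.encode(), dtype=np.uint8)
    index: dict = {}
    for i in range(len(anc) - seed_k + 1):
        index.setdefault(anc[i : i + seed_k], []).append(i)

    copies = []
    n_copy = 0
    for cid, seq in sorted(contigs.items()):
        if cid == ancestral_id:
            continue
        diagonals = set()
        for t in range(len(seq) - seed_k + 1):
            for a in index.get(seq[t : t + seed_k], ()):
                diagonals.add(t - a)
        arr = np.frombuffer(seq.encode(), dtype=np.uint8)
        found = []
        for d in sorted(diagonals):
            a0 = max(0, -d)
            a1 = min(len(anc), len(seq) - d)
            if a1 - a0 < min_len:
                continue
            match = anc_arr[a0:a1] == arr[a0 + d : a1 + d]
            score, s, e = max_scoring_segment(match, penalty)
            length = e - s
            if length < min_len:
                continue
            n_match = int(match[s:e].sum())
            if n_match / length < min_identity:
                continue
            found.append((score, a0 + s, a0 + e, d))
        # merge overlapping target intervals, best score wins
        found.sort(key=lambda f: -f[0])
        kept = []
        for score, bp5, bp3, d in found:
            ts, te = bp5 + d, bp3 + d
            if any(ts < k_te and k_ts < te for _, k_ts, k_te in kept):
                continue
            kept.append((score, ts, te))
            n_copy += 1
            copies.append(
                DuplicationCopy(
                    name=f"copy_{n_copy}",
                    interval=Interval(cid, ts, te),
                    bp5=bp5,
                    bp3=bp3,
                    ancestral_map=[(Interval(cid, ts, te), Interval(ancestral_id, bp5, bp3))],
                )
            )
    copies.sort(key=lambda c: (c.interval.contig_id, c.interval.start))
    for i, c in enumerate(copies, 1):
        c.name = f"copy_{i}"
    return copies


# ---------------------------------------------------------------------------
# element annotation from a library scan (when no annotations are provided)
# ---------------------------------------------------------------------------


def annotate_elements(
    contigs: dict,
    library,
    min_len: int = 300,
    min_identity: float = 0.85,
    seed_k: int = 12,
    exclude=("ancestral_core",),
) -> list:
    """Annotate library-element matches by seeded diagonal search."""
    penalty = mismatch_penalty(min_identity)
    annots = []
    for subfam in library.subfamilies():
        cons = library.consensus(subfam)
        index: dict = {}
        for i in range(len(cons) - seed_k + 1):
            index.setdefault(cons[i : i + seed_k], []).append(i)
        cons_arr = np.frombuffer(cons.encode(), dtype=np.uint8)
        for cid, seq in sorted(contigs.items()):
            if cid in exclude:
                continue
            diagonals = set()
            for t in range(len(seq) - seed_k + 1):
                for a in index.get(seq[t : t + seed_k], ()):
                    diagonals.add(t - a)
            arr = np.frombuffer(seq.encode(), dtype=np.uint8)
            for d in sorted(diagonals):
                a0, a1 = max(0, -d), min(len(cons), len(seq) - d)
                if a1 - a0 < min_len:
                    continue
                match = cons_arr[a0:a1] == arr[a0 + d : a1 + d]
                score, s, e = max_scoring_segment(match, penalty)
                if e - s < min_len:
                    continue
                if int(match[s:e].sum()) / (e - s) < min_identity:
                    continue
                annots.append(
                    RepeatAnnotation(
                        Interval(cid, a0 + s + d, a0 + e + d),
                        "SVA",
                        subfam,
                        consensus_start=a0 + s + 1,
                        consensus_end=a0 + e,
                    )
                )
    # overlapping calls from different subfamilies: keep the longest
    annots.sort(key=lambda a: (a.interval.contig_id, a.interval.start, -len(a.interval)))
    kept = []
    for a in annots:
        if kept and a.interval.overlaps(kept[-1].interval):
            continue
        kept.append(a)
    return kept


# ---------------------------------------------------------------------------
# recovery scoring
# ---------------------------------------------------------------------------


@dataclass
class RecoveryScore:
    per_type: dict  # type -> {tp, fp, fn, precision, recall}
    tolerance_bp: int

    def to_dict(self) -> dict:
        return {"tolerance_bp": self.tolerance_bp, "per_type": self.per_type}


def ledger_truth_intervals(ledger: TruthLedger) -> dict:
    """Scoreable truth intervals per event type.

    ``recombinant_chimera`` truth derives from the two chimeric elements
    of every circular-integration cassette.
    """
    truth: dict = {}

    def _add(etype, contig, start, end):
        truth.setdefault(etype, []).append((contig, start, end))

    for ev in ledger.events:
        f = ev.get("features", {})
        if ev["type"] == "L1_insertion":
            x = f["insert"]
            _add("L1_insertion", x["contig"], x["start"], x["end"])
        elif ev["type"] == "duplication_copy":
            x = f["copy"]
            _add("duplication_copy", x["contig"], x["start"], x["end"])
        elif ev["type"] == "circular_integration":
            lo, hi = ev["cassette"]
            _add("circular_integration", ev["contig"], lo, hi)
            for name in ("chimera_5p", "chimera_3p"):
                x = f[name]
                _add("recombinant_chimera", x["contig"], x["start"], x["end"])
        elif ev["type"] == "direct_repeat_SD":
            lo = f["left_repeat"]["start"]
            hi = f["right_repeat"]["end"]
            _add("direct_repeat_SD", f["left_repeat"]["contig"], lo, hi)
    return truth


def score_recovery(
    calls: dict,
    ledger: TruthLedger,
    tolerance_bp: int = DEFAULT_MATCH_TOLERANCE_BP,
) -> RecoveryScore:
    """Greedy 1-to-1 best-overlap matching of calls against planted events.

    A call matches a planted event iff same type, same contig, and both
    boundaries agree within ``tolerance_bp``.  Unmatched calls are FP,
    unmatched events FN.
    """
    truth = ledger_truth_intervals(ledger)
    per_type = {}
    for etype in sorted(set(truth) | set(calls)):
        t_list = truth.get(etype, [])
        c_list = calls.get(etype, [])
        pairs = []
        for ti, (tc, ts, te) in enumerate(t_list):
            for ci, (cc, cs, ce) in enumerate(c_list):
                if tc != cc:
                    continue
                if abs(cs - ts) > tolerance_bp or abs(ce - te) > tolerance_bp:
                    continue
                overlap = min(te, ce) - max(ts, cs)
                if overlap <= 0:
                    continue
                pairs.append((overlap, ti, ci))
        pairs.sort(key=lambda p: (-p[0], p[1], p[2]))
        used_t, used_c = set(), set()
        tp = 0
        for _, ti, ci in pairs:
            if ti in used_t or ci in used_c:
                continue
            used_t.add(ti)
            used_c.add(ci)
            tp += 1
        fp = len(c_list) - tp
        fn = len(t_list) - tp
        per_type[etype] = {
            "tp": tp,
            "fp": fp,
            "fn": fn,
            "planted": len(t_list),
            "called": len(c_list),
            "precision": tp / (tp + fp) if (tp + fp) else 1.0,
            "recall": tp / (tp + fn) if (tp + fn) else 1.0,
        }
    return RecoveryScore(per_type=per_type, tolerance_bp=tolerance_bp)


# ---------------------------------------------------------------------------
# detection over an annotated genome
# ---------------------------------------------------------------------------


def run_detectors(
    contigs: dict,
    annotations: list,
    library,
    params: dict | None = None,
    ancestral_id: str = "ancestral_core",
    ancestral_annotations: list | None = None,
) -> dict:
    """Run every detector; return calls, intermediate objects, and spans.

    The calls dict (type -> list of (contig, start, end)) feeds
    ``score_recovery``; richer objects are returned alongside.
    """
    p = dict(DETECT_DEFAULTS)
    if params:
        p.update(params)

    out: dict = {"calls": {}}

    # --- chimeras and circular cassettes -----------------------------------
    chimeras = detect_chimera(
        annotations, contigs, library, min_support=p["chimera_min_support"]
    )
    out["chimeras"] = chimeras
    out["calls"]["recombinant_chimera"] = [
        (c.element.contig_id, c.element.start, c.element.end) for c in chimeras
    ]
    log.info("chimera: %d chimeric elements", len(chimeras))

    signatures = []
    by_contig: dict = {}
    for c in chimeras:
        by_contig.setdefault(c.element.contig_id, []).append(c)
    for cid, cl in sorted(by_contig.items()):
        cl.sort(key=lambda c: c.element.start)
        i = 0
        while i + 1 < len(cl):
            span = cl[i + 1].element.end - cl[i].element.start
            if span <= p["cassette_max_span"]:
                sig = detect_circular_signature(contigs, [cl[i], cl[i + 1]])
                signatures.append(sig)
                i += 2
            else:
                i += 1
    out["signatures"] = signatures
    out["calls"]["circular_integration"] = [
        (s.locus.contig_id, s.element5.element.start - (s.outer_tsd.length if s.outer_tsd else 0),
         s.element3.element.end + (s.outer_tsd.length if s.outer_tsd else 0))
        for s in signatures
        if s.verdict == "positive"
    ]
    log.info("circle: %d cassettes, %d positive", len(signatures),
             len(out["calls"]["circular_integration"]))

    # --- L1 insertions via TSDs --------------------------------------------
    chimera_spans = [c.element for c in chimeras]
    spans = chain_insertions(annotations)
    tsd_calls = []
    l1_calls = []
    windows = sorted({p["tsd_max_window"], 24, 16, 10}, reverse=True)
    for span in spans:
        if any(span.overlaps(iv) for iv in chimera_spans):
            continue
        accepted = None
        # cascade: spurious long flank matches die off in smaller windows
        # while a true junction-adjacent TSD keeps winning
        for w in windows:
            try:
                call = detect_tsd(
                    contigs, span, max_window=w, min_len=p["tsd_min_len"]
                )
            except ValueError:
                call = None
            if call is None:
                continue
            jdist = (span.start - call.left.end) + (call.right.start - span.end)
            if jdist <= p["tsd_max_junction_dist"]:
                accepted = call
                break
        if accepted is None:
            continue
        tsd_calls.append(accepted)
        l1_calls.append((span.contig_id, span.start, span.end))
    out["tsd_calls"] = tsd_calls
    out["calls"]["L1_insertion"] = l1_calls
    log.info("tsd: %d insertion spans tested, %d TSD-supported", len(spans), len(l1_calls))

    # --- duplication copies + breakpoint census ----------------------------
    copies = []
    censuses = {}
    if ancestral_id in contigs:
        copies = map_duplication_copies(
            contigs, ancestral_id,
            min_len=p["copy_min_len"],
            min_identity=p["copy_min_identity"],
        )
        out["calls"]["duplication_copy"] = [
            (c.interval.contig_id, c.interval.start, c.interval.end) for c in copies
        ]
        for side in ("5p", "3p"):
            census = cluster_breakpoints(copies, side, p["cluster_tolerance_bp"])
            counts = repeat_overlap_census(census, ancestral_annotations or [])
            censuses[side] = (census, counts)
        log.info("copies: %d mapped; %d 5p clusters, %d 3p clusters",
                 len(copies), len(censuses["5p"][0].clusters),
                 len(censuses["3p"][0].clusters))
    out["copies"] = copies
    out["censuses"] = censuses

    # --- direct-repeat flanked SDs -----------------------------------------
    flank_hits = scan_windows(
        {cid: s for cid, s in contigs.items() if cid != ancestral_id},
        window_size=p["flank_window_size"],
        min_len=p["flank_min_len"],
        min_identity=p["flank_min_identity"],
        max_insert=p["flank_max_insert"],
    )
    out["flank_hits"] = flank_hits
    out["calls"]["direct_repeat_SD"] = [
        (h.left_repeat.contig_id, h.left_repeat.start, h.right_repeat.end)
        for h in flank_hits
    ]
    log.info("flankscan: %d hits", len(flank_hits))

    return out


# ---------------------------------------------------------------------------
# config handling and the full pipeline
# ---------------------------------------------------------------------------


def validate_config(config: dict) -> None:
    if "simulate" not in config:
        raise ValueError("config missing required section: simulate")
    if "seed" not in config["simulate"]:
        raise ValueError("config missing required key: simulate.seed")


def config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()


def run_pipeline(config: dict, outdir: str) -> dict:
    """simulate -> annotate -> detect -> score -> write result bundle."""
    validate_config(config)
    os.makedirs(outdir, exist_ok=True)

    sim_conf = SimulationConfig(**{
        k: tuple(v) if isinstance(v, list) else v
        for k, v in config["simulate"].items()
    })
    result = simulate(sim_conf)
    write_result(result, outdir)
    log.info("simulate: %d contigs, %d planted events",
             len(result.contigs), len(result.ledger.events))

    detect_params = dict(config.get("detect", {}))
    use_annotations = result.annotations
    if detect_params.pop("annotate_from_library", False):
        use_annotations = annotate_elements(result.contigs, result.library)
        log.info("annotate: %d elements from library scan", len(use_annotations))

    det = run_detectors(
        result.contigs,
        use_annotations,
        result.library,
        params=detect_params,
        ancestral_annotations=result.ancestral_annotations,
    )

    tol = config.get("score", {}).get("tolerance_bp", DEFAULT_MATCH_TOLERANCE_BP)
    score = score_recovery(det["calls"], result.ledger, tolerance_bp=tol)
    for etype, s in sorted(score.per_type.items()):
        log.info("score %s: precision=%.3f recall=%.3f (tp=%d fp=%d fn=%d)",
                 etype, s["precision"], s["recall"], s["tp"], s["fp"], s["fn"])

    # ---- outputs ----------------------------------------------------------
    write_tsd_calls_tsv(det["tsd_calls"], os.path.join(outdir, "tsd_calls.tsv"))
    write_chimera_tsv(det["chimeras"], os.path.join(outdir, "chimeras.tsv"))
    write_signature_json(det["signatures"], os.path.join(outdir, "circular_signatures.json"))
    write_hits_bed(det["flank_hits"], os.path.join(outdir, "flank_hits.bed"))
    write_hits_json(det["flank_hits"], os.path.join(outdir, "flank_hits.json"))
    from .core_model import write_duplication_copies_tsv

    write_duplication_copies_tsv(det["copies"], os.path.join(outdir, "copies.tsv"))
    for side, (census, counts) in det["censuses"].items():
        write_census_tsv(census, os.path.join(outdir, f"census_{side}.tsv"))
        write_census_json(census, counts, os.path.join(outdir, f"census_{side}.json"))
    with open(os.path.join(outdir, "recovery.json"), "w") as fh:
        json.dump(score.to_dict(), fh, indent=1, sort_keys=True)

    manifest = {
        "version": __version__,
        "config_hash": config_hash(config),
        "seed": config["simulate"]["seed"],
        "n_events": len(result.ledger.events),
        "n_calls": {k: len(v) for k, v in sorted(det["calls"].items())},
    }
    with open(os.path.join(outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)

    return {"result": result, "detections": det, "score": score, "manifest": manifest}


def bundle_digest(outdir: str) -> str:
    """Order-independent digest of every file in a result bundle."""
    h = hashlib.sha256()
    for name in sorted(os.listdir(outdir)):
        path = os.path.join(outdir, name)
        if os.path.isfile(path):
            h.update(name.encode())
            with open(path, "rb") as fh:
                h.update(fh.read())
    return h.hexdigest()
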