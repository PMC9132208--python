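"""Independent brute-force oracles used by the test suite.

Each oracle is written against the problem definition, not against the
package implementation, and stays deliberately naive.
"""

from __future__ import annotations

import heapq
import itertools

import numpy as np


# ---------------------------------------------------------------------------
# TSD oracle: enumerate every flank substring pair
# ---------------------------------------------------------------------------


def brute_force_tsd(seq, ins_start, ins_end, max_window, min_len, max_mismatch_frac):
    """Best (left_start, left_end, right_start, right_end, mismatches) or None.

    Scored by (length desc, mismatches asc, junction distance asc,
    left end desc, right start asc) — the published scoring contract.
    """
    wl = min(max_window, ins_start)
    wr = min(max_window, len(seq) - ins_end)
    best_key, best = None, None
    for l in range(min(wl, wr), min_len - 1, -1):
        for le in range(ins_start, ins_start - wl + l - 1, -1):
            left = seq[le - l : le]
            for rs in range(ins_end, ins_end + wr - l + 1):
                right = seq[rs : rs + l]
                mm = sum(a != b for a, b in zip(left, right))
                if mm > int(max_mismatch_frac * l):
                    continue
                jdist = (ins_start - le) + (rs - ins_end)
                key = (l, -mm, -jdist, le, -rs)
                if best_key is None or key > best_key:
                    best_key = key
                    best = (le - l, le, rs, rs + l, mm)
        if best is not None:
            break  # longer lengths already exhausted
    return best


# ---------------------------------------------------------------------------
# junction oracle: overlap scan over all decompositions
# ---------------------------------------------------------------------------


def brute_force_junction(left_donor, right_donor, observed):
    """(microhomology_len, inserted_seq) by scanning every decomposition.

    Enumerates all (a, t): a = left-match length (observed prefix equal to
    the left donor's terminal a bases), t = transition offset with the
    observed tail equal to the right donor's prefix.  Takes the maximal a
    and minimal t.
    """
    n = len(observed)
    a_candidates = [
        a for a in range(n + 1)
        if a <= len(left_donor) and observed[:a] == left_donor[len(left_donor) - a :]
    ]
    t_candidates = [
        t for t in range(n)
        if n - t <= len(right_donor) and observed[t:] == right_donor[: n - t]
    ]
    if not t_candidates or max(a_candidates) == 0:
        raise ValueError("donors not found")
    a = max(a_candidates)
    t = min(t_candidates)
    if a >= t:
        return a - t, ""
    return 0, observed[a:t]


# ---------------------------------------------------------------------------
# direct-repeat flank oracle: every diagonal, exhaustively
# ---------------------------------------------------------------------------


def brute_force_flank_hits(seq, min_len, min_identity, max_insert):
    """Quadratic all-diagonal scan for direct-repeat pairs.

    Per diagonal keeps the maximum-scoring segment under match +1 /
    mismatch -(id/(1-id)) scoring (first-maximum tie rule), then applies
    the SD length/identity/insert constraints and the overlap-merge rule.
    Returns [(left_start, left_end, right_start, right_end, identity)].
    """
    n = len(seq)
    penalty = min_identity / (1.0 - min_identity) if min_identity < 1.0 else 1e9
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    raw = []
    for g in range(min_len, n - min_len + 1):
        match = arr[:-g] == arr[g:]
        if match.size < min_len:
            continue
        v = np.where(match, 1.0, -penalty)
        s = np.concatenate(([0.0], np.cumsum(v)))
        runmin = np.minimum.accumulate(s[:-1])
        gains = s[1:] - runmin
        b = int(np.argmax(gains)) + 1
        score = float(gains[b - 1])
        a = int(np.argmin(s[:b]))
        length = b - a
        if length < min_len or length > g:
            continue
        if g - length > max_insert:
            continue
        nm = int(match[a:b].sum())
        if nm / length < min_identity:
            continue
        raw.append((score, nm / length, a, b, g))
    # merge overlapping hits: best (score, identity) survives
    kept = []
    for score, ident, a, b, g in sorted(raw, key=lambda r: (-r[0], -r[1], r[2])):
        dup = False
        for ka, kb, krs, kre, _ in kept:
            if a < kb and ka < b and a + g < kre and krs < b + g:
                dup = True
                break
        if not dup:
            kept.append((a, b, a + g, b + g, ident))
    kept.sort()
    return kept


# ---------------------------------------------------------------------------
# Steiner-tree oracle (Dreyfus-Wagner on the Hamming hypercube)
# ---------------------------------------------------------------------------


def steiner_minimal_length(haplotypes):
    """Exact minimal Steiner length connecting haplotypes in Hamming space.

    Candidate vertices are all per-site combinations of observed states;
    edges join vectors at Hamming distance 1 (weight 1).  Dreyfus-Wagner
    dynamic program, exact for small instances.
    """
    haps = sorted(set(haplotypes))
    t = len(haps)
    if t <= 1:
        return 0
    sites = list(zip(*haps))
    alphabets = [sorted(set(col)) for col in sites]
    vertices = ["".join(v) for v in itertools.product(*alphabets)]
    vid = {v: i for i, v in enumerate(vertices)}
    n = len(vertices)

    def neighbors(i):
        v = vertices[i]
        for j, alpha in enumerate(alphabets):
            for st in alpha:
                if st != v[j]:
                    yield vid[v[:j] + st + v[j + 1 :]]

    terms = [vid[h] for h in haps]
    INF = float("inf")
    # D[mask][v]
    D = [[INF] * n for _ in range(1 << t)]

    def bfs_from(src):
        dist = [INF] * n
        dist[src] = 0
        queue = [src]
        while queue:
            nxt = []
            for u in queue:
                for w in neighbors(u):
                    if dist[w] == INF:
                        dist[w] = dist[u] + 1
                        nxt.append(w)
            queue = nxt
        return dist

    for k, term in enumerate(terms):
        D[1 << k] = bfs_from(term)

    full = (1 << t) - 1
    for mask in range(1, full + 1):
        if mask & (mask - 1) == 0:
            continue
        base = [INF] * n
        sub = (mask - 1) & mask
        while sub:
            other = mask ^ sub
            if 0 < sub < mask and sub < other:  # each split once
                ds, do = D[sub], D[other]
                for v in range(n):
                    c = ds[v] + do[v]
                    if c < base[v]:
                        base[v] = c
            sub = (sub - 1) & mask
        # Dijkstra relaxation over the graph (unit weights)
        heap = [(c, v) for v, c in enumerate(base) if c < INF]
        heapq.heapify(heap)
        dist = base[:]
        while heap:
            c, v = heapq.heappop(heap)
            if c > dist[v]:
                continue
            for w in neighbors(v):
                if c + 1 < dist[w]:
                    dist[w] = c + 1
                    heapq.heappush(heap, (c + 1, w))
        D[mask] = dist

    return int(min(D[full][v] for v in terms))


# ---------------------------------------------------------------------------
# K2P closed form (independent recomputation)
# ---------------------------------------------------------------------------


def k2p_closed_form(a, b):
    import math

    ts_pairs = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}
    n = ts = tv = 0
    for x, y in zip(a, b):
        if x in "-N?" or y in "-N?":
            continue
        n += 1
        if x == y:
            continue
        if (x, y) in ts_pairs:
            ts += 1
        else:
            tv += 1
    P, Q = ts / n, tv / n
    return -0.5 * math.log(1 - 2 * P - Q) - 0.25 * math.log(1 - 2 * Q), P, Q
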