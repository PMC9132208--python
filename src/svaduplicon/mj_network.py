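"""Median-joining haplotype networks with equal site weights and external
rooting.

The network is the epsilon-relaxed minimum spanning network (an edge is
kept iff its weight exceeds the minimax-path "connection cost" by at most
epsilon) over the observed haplotypes plus greedily added median (Steiner)
vectors; a median is kept only while it shortens the minimum spanning tree
over the node set.  Gap columns are excluded from distance scoring by
default.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

_DNA_STATES = set("ACGT")


@dataclass
class MJNet:
    nodes: list  # dicts: id, haplotype (scored columns), observed, multiplicity, names
    edges: list  # dicts: u, v, weight, changed_positions
    epsilon: int
    scored_columns: list  # scored-column index -> original alignment column
    root_id: int | None = None
    root_edge: dict | None = None  # distance to outgroup; drawn not-to-scale

    def node_by_id(self, nid: int) -> dict:
        return self.nodes[nid]

    def total_length(self) -> int:
        """Minimum spanning tree length over the node set."""
        haps = [n["haplotype"] for n in self.nodes]
        return mst_length(haps)

    def degree(self, nid: int) -> int:
        return sum(1 for e in self.edges if nid in (e["u"], e["v"]))


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def _changed_positions(a: str, b: str) -> list:
    return [i for i, (x, y) in enumerate(zip(a, b)) if x != y]


class _UnionFind:
    def __init__(self, n: int):
        self.p = list(range(n))

    def find(self, x: int) -> int:
        while self.p[x] != x:
            self.p[x] = self.p[self.p[x]]
            x = self.p[x]
        return x

    def union(self, a: int, b: int) -> bool:
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return False
        self.p[rb] = ra
        return True


def _kruskal(haps: list):
    """(MST length, MST edge list) over haplotypes under Hamming distance."""
    n = len(haps)
    edges = sorted(
        (_hamming(haps[i], haps[j]), i, j)
        for i in range(n)
        for j in range(i + 1, n)
    )
    uf = _UnionFind(n)
    total, used = 0, []
    for w, i, j in edges:
        if uf.union(i, j):
            total += w
            used.append((i, j, w))
    return total, used


def mst_length(haps: list) -> int:
    return _kruskal(haps)[0] if len(haps) > 1 else 0


def _bottlenecks(n: int, mst_edges: list):
    """Minimax path weight between all node pairs, via the MST."""
    adj = {i: [] for i in range(n)}
    for i, j, w in mst_edges:
        adj[i].append((j, w))
        adj[j].append((i, w))
    bn = [[0] * n for _ in range(n)]
    for src in range(n):
        stack = [(src, 0)]
        seen = {src}
        while stack:
            u, mx = stack.pop()
            for v, w in adj[u]:
                if v not in seen:
                    seen.add(v)
                    m2 = max(mx, w)
                    bn[src][v] = m2
                    stack.append((v, m2))
    return bn


def _median(a: str, b: str, c: str) -> str:
    out = []
    for x, y, z in zip(a, b, c):
        if x == y or x == z:
            out.append(x)
        elif y == z:
            out.append(y)
        else:
            out.append(min(x, y, z))  # 3-way tie: deterministic, order-free
    return "".join(out)


def build_mj_network(haplotypes: dict, epsilon: int = 0, weights=None,
                     include_gaps: bool = False) -> MJNet:
    """Median-joining network over aligned haplotype strings.

    ``haplotypes``: name -> aligned sequence.  Sites are equally weighted
    by default (``weights`` per alignment column otherwise; only columns
    with weight > 0 are scored).  Columns containing a gap are excluded
    from scoring unless ``include_gaps`` (gap becomes a fifth state).
    """
    if epsilon < 0:
        raise ValueError("epsilon must be >= 0")
    names = list(haplotypes)
    if len(names) < 2:
        raise ValueError("need >= 2 haplotypes")
    seqs = {n: haplotypes[n].upper() for n in names}
    lengths = {len(s) for s in seqs.values()}
    if len(lengths) != 1:
        raise ValueError("haplotypes differ in length")
    ncols = lengths.pop()

    allowed = _DNA_STATES | {"-"}
    for n, s in seqs.items():
        bad = set(s) - allowed
        if bad:
            raise ValueError(f"haplotype {n!r}: illegal states {sorted(bad)}")

    scored = []
    for j in range(ncols):
        if weights is not None and weights[j] <= 0:
            continue
        if not include_gaps and any(seqs[n][j] == "-" for n in names):
            continue
        scored.append(j)

    proj = {n: "".join(seqs[n][j] for j in scored) for n in names}

    # collapse duplicates -> observed nodes (canonical order by haplotype)
    by_hap: dict = {}
    for n in names:
        by_hap.setdefault(proj[n], []).append(n)
    observed = sorted(by_hap)
    if len(observed) < 2:
        raise ValueError("fewer than 2 distinct haplotypes over scored columns")

    # median phase: add Steiner vectors while they shorten the MST over the
    # node set; when single additions stall, try median pairs (a plateau
    # median can pay off only together with a second one)
    haps = list(observed)
    current = mst_length(haps)
    while True:
        seen = set(haps)
        cand = set()
        k = len(haps)
        for i in range(k):
            for j in range(i + 1, k):
                for l in range(j + 1, k):
                    m = _median(haps[i], haps[j], haps[l])
                    if m not in seen:
                        cand.add(m)
        cand = sorted(cand)
        best = None
        for m in cand:
            total = mst_length(haps + [m])
            if total < current and (best is None or total < best[0]):
                best = (total, [m])
        if best is None:
            # expand to a bounded median closure: optimal Steiner points can
            # be medians of medians, invisible to one-level candidates
            pool = sorted(set(haps) | set(cand))
            while len(pool) <= 256:
                new = set()
                for i in range(len(pool)):
                    for j in range(i + 1, len(pool)):
                        for l in range(j + 1, len(pool)):
                            m = _median(pool[i], pool[j], pool[l])
                            if m not in seen and m not in pool:
                                new.add(m)
                if not new:
                    break
                pool = sorted(set(pool) | new)
            cand = [m for m in pool if m not in seen]
            for m in cand:
                total = mst_length(haps + [m])
                if total < current and (best is None or total < best[0]):
                    best = (total, [m])
        if best is None and len(cand) <= 256:
            for i in range(len(cand)):
                for j in range(i + 1, len(cand)):
                    total = mst_length(haps + [cand[i], cand[j]])
                    if total < current and (best is None or total < best[0]):
                        best = (total, [cand[i], cand[j]])
        if best is None:
            break
        current = best[0]
        haps.extend(best[1])

    # prune medians that no longer shorten the tree
    changed = True
    while changed:
        changed = False
        for m in [h for h in haps if h not in by_hap]:
            rest = [h for h in haps if h != m]
            if mst_length(rest) <= current:
                haps = rest
                current = mst_length(haps)
                changed = True
                break

    haps = sorted(by_hap) + sorted(h for h in haps if h not in by_hap)
    nodes = []
    for nid, h in enumerate(haps):
        names_here = by_hap.get(h, [])
        nodes.append(
            {
                "id": nid,
                "haplotype": h,
                "observed": bool(names_here),
                "multiplicity": len(names_here),
                "names": sorted(names_here),
            }
        )

    # epsilon-relaxed minimum spanning network over the final node set
    n = len(haps)
    mst_total, mst_edges = _kruskal(haps)
    bn = _bottlenecks(n, mst_edges)
    edges = []
    for i in range(n):
        for j in range(i + 1, n):
            w = _hamming(haps[i], haps[j])
            if w <= bn[i][j] + epsilon:
                edges.append(
                    {
                        "u": i,
                        "v": j,
                        "weight": w,
                        "changed_positions": _changed_positions(haps[i], haps[j]),
                    }
                )

    return MJNet(
        nodes=nodes,
        edges=edges,
        epsilon=epsilon,
        scored_columns=scored,
    )


def root_network(net: MJNet, outgroup_haplotype: str, outgroup_id: str = "outgroup") -> MJNet:
    """Root on the node closest (Hamming) to the external outgroup.

    The outgroup attaches by an edge labeled with that distance, flagged
    not-to-scale.  Ties are all reported; the lowest-id node is chosen
    with a warning.
    """
    og_full = outgroup_haplotype.upper()
    if net.scored_columns and max(net.scored_columns) >= len(og_full):
        raise ValueError("outgroup haplotype not aligned to network haplotypes")
    og = "".join(og_full[j] for j in net.scored_columns)
    dists = [(_hamming(node["haplotype"], og), node["id"]) for node in net.nodes]
    dmin = min(d for d, _ in dists)
    candidates = sorted(nid for d, nid in dists if d == dmin)
    if len(candidates) > 1:
        warnings.warn(
            f"root tie between nodes {candidates}; choosing node {candidates[0]}"
        )
    net.root_id = candidates[0]
    net.root_edge = {
        "outgroup": outgroup_id,
        "distance": dmin,
        "to_scale": False,
        "tied_candidates": candidates,
    }
    return net


# ---------------------------------------------------------------------------
# exports
# ---------------------------------------------------------------------------


def network_to_dict(net: MJNet) -> dict:
    return {
        "epsilon": net.epsilon,
        "scored_columns": net.scored_columns,
        "nodes": net.nodes,
        "edges": net.edges,
        "root_id": net.root_id,
        "root_edge": net.root_edge,
        "total_length": net.total_length(),
    }


def write_network_json(net: MJNet, path) -> None:
    with open(path, "w") as fh:
        json.dump(network_to_dict(net), fh, indent=1, sort_keys=True)


def write_network_dot(net: MJNet, path) -> None:
    with open(path, "w") as fh:
        fh.write("graph mjnet {\n")
        for node in net.nodes:
            shape = "circle" if node["observed"] else "point"
            label = ",".join(node["names"]) if node["names"] else "median"
            extra = " peripheries=2" if node["id"] == net.root_id else ""
            fh.write(
                f'  n{node["id"]} [label="{label}" shape={shape}{extra}];\n'
            )
        for e in net.edges:
            fh.write(f'  n{e["u"]} -- n{e["v"]} [label="{e["weight"]}"];\n')
        if net.root_edge is not None:
            fh.write(
                f'  outgroup [label="{net.root_edge["outgroup"]}" shape=box];\n'
                f'  outgroup -- n{net.root_id} '
                f'[label="{net.root_edge["distance"]}" style=dashed];\n'
            )
        fh.write("}\n")


def write_network_tsv(net: MJNet, nodes_path, edges_path) -> None:
    with open(nodes_path, "w") as fh:
        fh.write("id\thaplotype\tobserved\tmultiplicity\tnames\tis_root\n")
        for node in net.nodes:
            fh.write(
                f'{node["id"]}\t{node["haplotype"]}\t{int(node["observed"])}\t'
                f'{node["multiplicity"]}\t{",".join(node["names"]) or "."}\t'
                f'{int(node["id"] == net.root_id)}\n'
            )
    with open(edges_path, "w") as fh:
        fh.write("u\tv\tweight\tchanged_positions\n")
        for e in net.edges:
            pos = ",".join(map(str, e["changed_positions"])) or "."
            fh.write(f'{e["u"]}\t{e["v"]}\t{e["weight"]}\t{pos}\n')
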