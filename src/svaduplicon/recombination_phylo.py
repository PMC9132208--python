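"""Distance phylogenetics and recombination-incongruence testing.

K2P distances, neighbor joining with column-resampling bootstrap,
Robinson-Foulds comparison, diagnostic-site partitioning relative to an
outgroup, recombination-interval bracketing, split-tree concordance, and
the downstream-segment gene-conversion control.

The source analyses used ML trees; the inference consumed from them is
purely topological (group monophyly), which NJ under K2P reproduces, so
NJ is used as the tree surrogate throughout.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .core_model import MultipleAlignment

_TRANSITION_PAIRS = {frozenset("AG"), frozenset("CT")}
_GAPLIKE = {"-", "N", "?"}

DEFAULT_BOOTSTRAP_REPLICATES = 10_000
MAX_GAP_COLUMN_FRAC = 0.5


# ---------------------------------------------------------------------------
# K2P
# ---------------------------------------------------------------------------


def k2p_distance(seq_a: str, seq_b: str):
    """Kimura two-parameter distance over pairwise non-gap columns.

    Returns (d, P, Q) with P/Q the transition/transversion proportions and
    d = -1/2 ln(1-2P-Q) - 1/4 ln(1-2Q).  Raises on saturated input.
    """
    if len(seq_a) != len(seq_b):
        raise ValueError("aligned rows differ in length")
    n = ts = tv = 0
    for a, b in zip(seq_a.upper(), seq_b.upper()):
        if a in _GAPLIKE or b in _GAPLIKE:
            continue
        n += 1
        if a == b:
            continue
        if frozenset((a, b)) in _TRANSITION_PAIRS:
            ts += 1
        else:
            tv += 1
    if n == 0:
        raise ValueError("no shared non-gap columns")
    P, Q = ts / n, tv / n
    w1, w2 = 1.0 - 2.0 * P - Q, 1.0 - 2.0 * Q
    if w1 <= 0 or w2 <= 0:
        raise ValueError("distance undefined (saturation)")
    d = -0.5 * math.log(w1) - 0.25 * math.log(w2)
    return d, P, Q


@dataclass
class DistanceMatrix:
    taxa: list
    d: np.ndarray
    P: np.ndarray
    Q: np.ndarray


def drop_gappy_columns(aln: MultipleAlignment, max_gap_frac: float = MAX_GAP_COLUMN_FRAC):
    """Column indices with gap fraction <= threshold (VNTR-mask surrogate)."""
    rows = list(aln.rows.values())
    n_rows = len(rows)
    keep = []
    for j in range(aln.n_cols):
        gaps = sum(1 for r in rows if r[j] in _GAPLIKE)
        if gaps / n_rows <= max_gap_frac:
            keep.append(j)
    return keep


def k2p_matrix(aln: MultipleAlignment, max_gap_frac: float = MAX_GAP_COLUMN_FRAC) -> DistanceMatrix:
    cols = drop_gappy_columns(aln, max_gap_frac)
    sub = {rid: "".join(s[j] for j in cols) for rid, s in aln.rows.items()}
    taxa = list(sub)
    n = len(taxa)
    d = np.zeros((n, n))
    P = np.zeros((n, n))
    Q = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            try:
                dij, pij, qij = k2p_distance(sub[taxa[i]], sub[taxa[j]])
            except ValueError as exc:
                raise ValueError(f"pair ({taxa[i]}, {taxa[j]}): {exc}") from exc
            d[i, j] = d[j, i] = dij
            P[i, j] = P[j, i] = pij
            Q[i, j] = Q[j, i] = qij
    return DistanceMatrix(taxa=taxa, d=d, P=P, Q=Q)


# ---------------------------------------------------------------------------
# trees
# ---------------------------------------------------------------------------


class Tree:
    """Unrooted tree: integer nodes, named leaves, branch lengths >= 0."""

    def __init__(self):
        self.adj: dict = {}  # node -> {nbr: length}
        self.leaf_of: dict = {}  # node -> leaf name
        self.supports: dict = {}  # frozenset(bipartition) -> percent
        self._next = 0

    def new_node(self, name: str | None = None) -> int:
        nid = self._next
        self._next += 1
        self.adj[nid] = {}
        if name is not None:
            self.leaf_of[nid] = name
        return nid

    def add_edge(self, u: int, v: int, length: float) -> None:
        self.adj[u][v] = float(length)
        self.adj[v][u] = float(length)

    def leaves(self) -> list:
        return sorted(self.leaf_of.values())

    def edges(self):
        seen = set()
        for u, nbrs in self.adj.items():
            for v, ln in nbrs.items():
                if frozenset((u, v)) not in seen:
                    seen.add(frozenset((u, v)))
                    yield u, v, ln

    def _side_leaves(self, u: int, v: int) -> frozenset:
        """Leaf names reachable from v without crossing edge (u, v)."""
        stack, seen, out = [v], {u, v}, []
        while stack:
            x = stack.pop()
            if x in self.leaf_of:
                out.append(self.leaf_of[x])
            for y in self.adj[x]:
                if y not in seen:
                    seen.add(y)
                    stack.append(y)
        return frozenset(out)

    def bipartitions(self) -> set:
        """Canonical non-trivial bipartitions (side without the min leaf)."""
        all_leaves = set(self.leaves())
        ref = min(all_leaves)
        out = set()
        for u, v, _ in self.edges():
            if u in self.leaf_of or v in self.leaf_of:
                continue  # pendant edge -> trivial split
            side = self._side_leaves(u, v)
            if ref in side:
                side = frozenset(all_leaves - side)
            if 2 <= len(side) <= len(all_leaves) - 2:
                out.add(side)
        return out

    def bipartition_of_edge(self, u: int, v: int) -> frozenset:
        all_leaves = set(self.leaves())
        ref = min(all_leaves)
        side = self._side_leaves(u, v)
        if ref in side:
            side = frozenset(all_leaves - side)
        return side

    def newick(self, root_leaf: str | None = None, with_supports: bool = True) -> str:
        """Serialize; arbitrarily rooted at the edge incident to a leaf."""
        name_to_node = {v: k for k, v in self.leaf_of.items()}
        if len(self.adj) == 1:
            only = next(iter(self.adj))
            return f"{self.leaf_of.get(only, '')};"
        if root_leaf is None:
            root_leaf = min(name_to_node)
        start = name_to_node[root_leaf]
        anchor = next(iter(self.adj[start]))

        def _fmt(u: int, parent: int) -> str:
            if u in self.leaf_of:
                return f"{self.leaf_of[u]}:{self.adj[u][parent]:.6f}"
            parts = [_fmt(v, u) for v in sorted(self.adj[u]) if v != parent]
            label = ""
            if with_supports:
                bip = self.bipartition_of_edge(parent, u)
                if bip in self.supports:
                    label = f"{self.supports[bip]:.0f}"
            return f"({','.join(parts)}){label}:{self.adj[u][parent]:.6f}"

        body = _fmt(anchor, start)
        return f"({self.leaf_of[start]}:{self.adj[start][anchor]:.6f},{body});"


def nj_tree(dm: DistanceMatrix) -> Tree:
    """Neighbor joining with deterministic tie-breaking.

    Negative branch lengths are clamped to 0 with the deficit moved to the
    sister edge.  Ties in the Q criterion break by the lexicographically
    smallest (cluster label, cluster label) pair.
    """
    n0 = len(dm.taxa)
    if n0 < 2:
        raise ValueError("need >= 2 taxa")
    tree = Tree()
    nodes = {}
    labels = {}
    for i, t in enumerate(dm.taxa):
        nodes[i] = tree.new_node(t)
        labels[i] = t
    D = {
        (i, j): float(dm.d[i, j])
        for i in range(n0)
        for j in range(n0)
        if i != j
    }
    active = list(range(n0))
    nxt = n0

    def _d(i, j):
        return D[(i, j)] if i != j else 0.0

    while len(active) > 2:
        m = len(active)
        r = {i: sum(_d(i, k) for k in active if k != i) for i in active}
        best = None
        for ai in range(m):
            for aj in range(ai + 1, m):
                i, j = active[ai], active[aj]
                q = (m - 2) * _d(i, j) - r[i] - r[j]
                tie = tuple(sorted((labels[i], labels[j])))
                key = (q, tie)
                if best is None or key < best[0]:
                    best = (key, i, j)
        _, i, j = best
        dij = _d(i, j)
        vi = 0.5 * dij + (r[i] - r[j]) / (2 * (m - 2))
        vj = dij - vi
        if vi < 0:
            vj += vi
            vi = 0.0
        if vj < 0:
            vi += vj
            vj = 0.0
        vi, vj = max(vi, 0.0), max(vj, 0.0)
        u = nxt
        nxt += 1
        nodes[u] = tree.new_node()
        tree.add_edge(nodes[i], nodes[u], vi)
        tree.add_edge(nodes[j], nodes[u], vj)
        labels[u] = min(labels[i], labels[j])
        for k in active:
            if k in (i, j):
                continue
            duk = 0.5 * (_d(i, k) + _d(j, k) - dij)
            D[(u, k)] = D[(k, u)] = max(duk, 0.0)
        active = [k for k in active if k not in (i, j)] + [u]

    i, j = active
    tree.add_edge(nodes[i], nodes[j], max(_d(i, j), 0.0))
    _contract_zero_internal_edges(tree)
    return tree


def _contract_zero_internal_edges(tree: Tree, eps: float = 1e-12) -> None:
    """Merge internal nodes joined by zero-length edges (unresolved splits)."""
    changed = True
    while changed:
        changed = False
        for u, v, ln in list(tree.edges()):
            if ln > eps or u in tree.leaf_of or v in tree.leaf_of:
                continue
            for w, wl in list(tree.adj[v].items()):
                if w != u:
                    tree.adj[u][w] = wl
                    tree.adj[w][u] = wl
                    del tree.adj[w][v]
            del tree.adj[v]
            del tree.adj[u][v]
            changed = True
            break


def rf_distance(t1: Tree, t2: Tree) -> int:
    """Count of non-trivial bipartitions present in exactly one tree."""
    if set(t1.leaves()) != set(t2.leaves()):
        raise ValueError("trees have different leaf sets")
    return len(t1.bipartitions() ^ t2.bipartitions())


def group_monophyletic(tree: Tree, members) -> bool:
    """True iff the member set is separated by some edge (trivial included)."""
    members = frozenset(members)
    all_leaves = set(tree.leaves())
    if not members <= all_leaves:
        raise ValueError("members not all present in tree")
    k = len(members)
    if k <= 1 or k >= len(all_leaves) - 1:
        return True
    ref = min(all_leaves)
    canon = frozenset(all_leaves - members) if ref in members else members
    return canon in tree.bipartitions()


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------


def bootstrap_support(
    aln: MultipleAlignment,
    groups: dict | None = None,
    n_replicates: int = DEFAULT_BOOTSTRAP_REPLICATES,
    seed: int = 0,
    max_gap_frac: float = MAX_GAP_COLUMN_FRAC,
) -> Tree:
    """NJ tree with column-resampling bootstrap supports (percent).

    Replicates whose distance matrix is undefined (saturation) are
    discarded and counted; more than 50% discarded raises.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    tree = nj_tree(k2p_matrix(aln, max_gap_frac))
    target = tree.bipartitions()
    if not target:
        tree.supports = {}
        return tree

    rng = np.random.default_rng(seed)
    ncols = aln.n_cols
    counts = {b: 0 for b in target}
    discarded = 0
    valid = 0
    for _ in range(n_replicates):
        cols = rng.integers(0, ncols, size=ncols)
        rep = aln.subset_columns(cols)
        try:
            rep_tree = nj_tree(k2p_matrix(rep, max_gap_frac))
        except ValueError:
            discarded += 1
            continue
        valid += 1
        reps = rep_tree.bipartitions()
        for b in target:
            if b in reps:
                counts[b] += 1
    if discarded > 0.5 * n_replicates:
        raise ValueError(f"saturated alignment: {discarded}/{n_replicates} replicates discarded")
    tree.supports = {b: 100.0 * c / valid for b, c in counts.items()} if valid else {}
    return tree


# ---------------------------------------------------------------------------
# diagnostic-site partition and the recombination interval
# ---------------------------------------------------------------------------


@dataclass
class SitePartition:
    column_classes: list  # per alignment column
    group_labels: tuple  # the two ingroup labels
    outgroup_id: str
    n_skipped: int  # outgroup-gap columns
    shared_support: list = field(default_factory=list)  # (nA, nB) per column

    def count(self, cls: str) -> int:
        return sum(1 for c in self.column_classes if c == cls)


def partition_diagnostic_sites(
    aln: MultipleAlignment, tolerate_missing_frac: float = 0.0
) -> SitePartition:
    """Classify columns into group-specific / shared-derived / other.

    The derived state of a column is defined relative to the outgroup.  A
    column is "<group>-specific" when all that group's members carry one
    common derived state and no other ingroup member carries any derived
    state; "shared-derived" when members of both groups share the same
    derived state and at least one ingroup member does not (a derived
    state fixed across every ingroup member is indistinguishable from an
    outgroup-private substitution, hence uninformative).  Up to
    ``tolerate_missing_frac`` of a group may be gap/missing.
    Outgroup-gap columns are skipped and counted.
    """
    labels = aln.ingroup_labels()
    if len(labels) != 2:
        raise ValueError(f"need exactly 2 ingroups, got {labels}")
    ga, gb = labels
    members = {
        g: [rid for rid, lbl in aln.groups.items() if lbl == g and rid != aln.outgroup_id]
        for g in labels
    }

    classes = []
    support = []
    n_skipped = 0
    for j in range(aln.n_cols):
        col = aln.column(j)
        og = col[aln.outgroup_id]
        if og in _GAPLIKE:
            classes.append("skipped")
            support.append((0, 0))
            n_skipped += 1
            continue

        state = {}
        missing = {}
        for g in labels:
            chars = [col[r] for r in members[g]]
            miss = sum(1 for c in chars if c in _GAPLIKE)
            present = [c for c in chars if c not in _GAPLIKE]
            missing[g] = miss / len(chars)
            state[g] = present

        cls = "uninformative"
        derived = {
            g: {c for c in state[g] if c != og}
            for g in labels
        }
        for g, other in ((ga, gb), (gb, ga)):
            if missing[g] > tolerate_missing_frac or missing[other] > tolerate_missing_frac:
                continue
            if (
                state[g]
                and len(set(state[g])) == 1
                and state[g][0] != og
                and not derived[other]
            ):
                cls = f"{g}-specific"
                break
        sup = (0, 0)
        if cls == "uninformative":
            all_states = state[ga] + state[gb]
            shared = {
                c
                for c in derived[ga] & derived[gb]
                if missing[ga] <= tolerate_missing_frac
                and missing[gb] <= tolerate_missing_frac
                and any(s != c for s in all_states)
            }
            if shared:
                cls = "shared-derived"
                best = max(
                    shared,
                    key=lambda c: sum(s == c for s in all_states),
                )
                sup = (
                    sum(s == best for s in state[ga]),
                    sum(s == best for s in state[gb]),
                )
        classes.append(cls)
        support.append(sup)

    return SitePartition(
        column_classes=classes,
        group_labels=(ga, gb),
        outgroup_id=aln.outgroup_id,
        n_skipped=n_skipped,
        shared_support=support,
    )


@dataclass
class RecombinationInterval:
    found: bool
    group: str | None = None
    start: int | None = None  # ungapped coord of last group-specific site
    end: int | None = None  # ungapped coord of first shared-derived site
    length: int | None = None
    last_specific_col: int | None = None
    first_shared_col: int | None = None


def locate_recombination_interval(
    partition: SitePartition,
    aln: MultipleAlignment,
    group: str | None = None,
    ref_id: str | None = None,
    min_group_support: int = 1,
) -> RecombinationInterval:
    """Bracket the crossover between the last group-specific and the first
    shared-derived substitution, in ungapped reference coordinates.

    With ``group=None`` both ingroups are tried in label order and the
    first yielding a valid ordering is reported; no valid ordering yields
    a not-found result (not an error).  ``min_group_support`` requires the
    shared-derived state in at least that many members of each group
    (>= 2 suppresses single-tip homoplasy when groups are large enough).
    """
    candidates = [group] if group else list(partition.group_labels)
    shared_cols = [
        j
        for j, c in enumerate(partition.column_classes)
        if c == "shared-derived"
        and (
            not partition.shared_support
            or min(partition.shared_support[j]) >= min_group_support
        )
    ]
    for g in candidates:
        spec_cols = [
            j for j, c in enumerate(partition.column_classes) if c == f"{g}-specific"
        ]
        if not spec_cols or not shared_cols:
            continue
        last_spec = max(j for j in spec_cols)
        first_shared_after = [j for j in shared_cols if j > last_spec]
        if not first_shared_after:
            continue
        first_shared = min(first_shared_after)

        if ref_id is None:
            ref_id = next(
                rid for rid, lbl in aln.groups.items()
                if lbl == g and rid != aln.outgroup_id
            )
        cmap = aln.col_map(ref_id)

        def _ungapped(j: int, direction: int) -> int:
            while cmap[j] < 0:
                j += direction
            return cmap[j]

        start = _ungapped(last_spec, -1)
        end = _ungapped(first_shared, +1)
        return RecombinationInterval(
            found=True,
            group=g,
            start=start,
            end=end,
            length=end - start,
            last_specific_col=last_spec,
            first_shared_col=first_shared,
        )
    return RecombinationInterval(found=False)


# ---------------------------------------------------------------------------
# split-tree incongruence and gene-conversion control
# ---------------------------------------------------------------------------


@dataclass
class SplitTestResult:
    tree5: Tree
    tree3: Tree
    rf: int
    verdict: str  # "concordant" | "discordant"
    monophyly: dict  # group -> (flag on 5' tree, flag on 3' tree)
    split_point: int
    split_col: int


def split_tree_test(
    aln: MultipleAlignment,
    split_point: int,
    ref_id: str | None = None,
    min_informative: int = 4,
    max_gap_frac: float = MAX_GAP_COLUMN_FRAC,
) -> SplitTestResult:
    """Build separate trees left/right of ``split_point`` and compare.

    ``split_point`` is an ungapped coordinate on the reference row
    (default: first row).  The verdict is discordant iff the per-group
    monophyly pattern differs between the two trees; RF distance is
    reported as auxiliary evidence.
    """
    if ref_id is None:
        ref_id = next(iter(aln.rows))
    cmap = aln.col_map(ref_id)
    ungapped_len = sum(1 for p in cmap if p >= 0)
    if not 0 < split_point < ungapped_len:
        raise ValueError("split_point outside the ungapped element span")
    split_col = next(j for j, p in enumerate(cmap) if p >= split_point)

    def _informative(sub: MultipleAlignment) -> int:
        count = 0
        for j in range(sub.n_cols):
            states = {c for c in sub.column(j).values() if c not in _GAPLIKE}
            if len(states) >= 2:
                count += 1
        return count

    left = aln.subset_columns(range(split_col))
    right = aln.subset_columns(range(split_col, aln.n_cols))
    for name, sub in (("5'", left), ("3'", right)):
        if _informative(sub) < min_informative:
            raise ValueError(f"segment too short: {name} side has <{min_informative} informative columns")

    t5 = nj_tree(k2p_matrix(left, max_gap_frac))
    t3 = nj_tree(k2p_matrix(right, max_gap_frac))

    groups_members: dict = {}
    for rid, lbl in aln.groups.items():
        if rid == aln.outgroup_id:
            continue
        groups_members.setdefault(lbl, set()).add(rid)
    mono = {
        g: (group_monophyletic(t5, mem), group_monophyletic(t3, mem))
        for g, mem in sorted(groups_members.items())
    }
    verdict = "concordant" if all(a == b for a, b in mono.values()) else "discordant"
    return SplitTestResult(
        tree5=t5,
        tree3=t3,
        rf=rf_distance(t5, t3),
        verdict=verdict,
        monophyly=mono,
        split_point=split_point,
        split_col=split_col,
    )


def segment_concordance_test(
    reference_aln: MultipleAlignment,
    segments: list,
    max_gap_frac: float = MAX_GAP_COLUMN_FRAC,
) -> dict:
    """Compare downstream-segment trees against the reference topology.

    ``reference_aln`` carries the 3'-element signal; each segment tree's
    per-group monophyly pattern is compared with the reference pattern.
    Overall verdict is "gene conversion not supported" iff every segment
    is concordant.
    """
    if not segments:
        raise ValueError("need >= 1 segment")
    taxa = set(reference_aln.rows)
    for k, seg in enumerate(segments):
        if set(seg.rows) != taxa:
            raise ValueError(f"segment {k}: taxa mismatch with reference")
    if len(segments) == 1:
        warnings.warn("single-segment control is weak")

    def _pattern(a: MultipleAlignment) -> dict:
        t = nj_tree(k2p_matrix(a, max_gap_frac))
        members: dict = {}
        for rid, lbl in a.groups.items():
            if rid == a.outgroup_id:
                continue
            members.setdefault(lbl, set()).add(rid)
        return {g: group_monophyletic(t, mem) for g, mem in sorted(members.items())}

    ref_pattern = _pattern(reference_aln)
    per_segment = []
    for seg in segments:
        pat = _pattern(seg)
        per_segment.append(
            {
                "verdict": "concordant" if pat == ref_pattern else "discordant",
                "monophyly": pat,
            }
        )
    all_conc = all(s["verdict"] == "concordant" for s in per_segment)
    return {
        "reference_monophyly": ref_pattern,
        "segments": per_segment,
        "overall": "gene conversion not supported" if all_conc else "gene conversion possible",
    }


# ---------------------------------------------------------------------------
# conversion from nested simulation trees
# ---------------------------------------------------------------------------


def tree_from_nested(nested: dict) -> Tree:
    """Build a Tree from the simulator's nested-dict representation."""
    tree = Tree()

    def _walk(nd: dict) -> int:
        if not nd["children"]:
            return tree.new_node(nd["name"])
        me = tree.new_node()
        for child, blen in nd["children"]:
            cid = _walk(child)
            tree.add_edge(me, cid, blen)
        return me

    root = _walk(nested)
    # suppress a degree-2 root so the tree is properly unrooted
    if len(tree.adj[root]) == 2:
        (a, la), (b, lb) = list(tree.adj[root].items())
        del tree.adj[root]
        del tree.adj[a][root]
        del tree.adj[b][root]
        tree.add_edge(a, b, la + lb)
    return tree
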