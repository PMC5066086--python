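"""Clonal partitioning and minimal-substitution lineage trees.

Transcripts are grouped by first-called V gene, J gene and junction length,
then single-linkage clustered on absolute (non-normalized) junction hamming
distance with an inclusive threshold (default 3); ambiguous bases match
anything (the minimal-distance rule).  Per clone, a lineage tree rooted at
the unmutated germline is built on the transcripts' mutation-presence sets:
clones with few unique members get an exact minimum-substitution (Steiner
parsimony) tree found by exhaustive topology search with Fitch scoring on
bit-packed characters; larger clones fall back to a greedy
shared-mutation-partition agglomeration, which is optimal whenever the
mutation sets are laminar (no homoplasy) but carries no optimality
guarantee in general.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import pandas as pd

from .germline import GermlineDatabase, default_germline_db
from .shm import Mutation, mutation_scan
from .types import Rearrangement

DEFAULT_MAX_DISTANCE = 3
#: Largest number of unique mutation profiles handled by exhaustive search.
EXACT_TREE_LIMIT = 8

_UNAMBIGUOUS = set("ACGT")


def junction_hamming(junction_a: str, junction_b: str) -> int:
    """Hamming distance between equal-length junctions; ambiguity costs 0."""
    if len(junction_a) != len(junction_b):
        raise ValueError("junction lengths differ")
    return sum(
        1
        for a, b in zip(junction_a, junction_b)
        if a != b and a in _UNAMBIGUOUS and b in _UNAMBIGUOUS
    )


@dataclass
class Clone:
    clone_id: str
    read_ids: list[str]
    v_gene: str
    j_gene: str
    junction_length: int
    subclasses: list[str]

    @property
    def n_members(self) -> int:
        return len(self.read_ids)


def partition_clones(
    transcripts: Sequence[Rearrangement], max_distance: int = DEFAULT_MAX_DISTANCE
) -> list[Clone]:
    """Single-linkage clone partition within (v_gene, j_gene, junction length).

    Only the first V/J calls feed clonality; clone ids are deterministic
    (derived from sorted member read ids).
    """
    groups: dict[tuple[str, str, int], list[Rearrangement]] = {}
    for r in transcripts:
        if not r.junction_nt:
            continue
        groups.setdefault((r.v_gene, r.j_gene, len(r.junction_nt)), []).append(r)

    clones: list[Clone] = []
    for (v_gene, j_gene, jlen), members in groups.items():
        members = sorted(members, key=lambda r: r.read_id)
        n = len(members)
        parent = list(range(n))

        def find(i: int) -> int:
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for i, j in itertools.combinations(range(n), 2):
            if junction_hamming(members[i].junction_nt, members[j].junction_nt) <= max_distance:
                parent[find(i)] = find(j)

        buckets: dict[int, list[Rearrangement]] = {}
        for i in range(n):
            buckets.setdefault(find(i), []).append(members[i])
        for bucket in buckets.values():
            ids = sorted(r.read_id for r in bucket)
            clones.append(
                Clone(
                    clone_id="",
                    read_ids=ids,
                    v_gene=v_gene,
                    j_gene=j_gene,
                    junction_length=jlen,
                    subclasses=sorted({r.subclass for r in bucket}),
                )
            )
    clones.sort(key=lambda c: c.read_ids[0])
    for k, clone in enumerate(clones):
        clone.clone_id = f"clone_{k:05d}"
    return clones


@dataclass
class ClonalitySummary:
    donor_id: str
    n_transcripts: int
    n_clones: int
    max_clone_pct: float
    pct_unique_clones: float


def clonality_summary(clones: Sequence[Clone], donor_id: str = "") -> ClonalitySummary:
    """Maximal clone size and singleton-clone percentage over a stratum."""
    if not clones:
        raise ValueError("no clones")
    n_total = sum(c.n_members for c in clones)
    n_singleton = sum(c.n_members for c in clones if c.n_members == 1)
    return ClonalitySummary(
        donor_id=donor_id,
        n_transcripts=n_total,
        n_clones=len(clones),
        max_clone_pct=100.0 * max(c.n_members for c in clones) / n_total,
        pct_unique_clones=100.0 * n_singleton / n_total,
    )


# --- lineage trees ---------------------------------------------------------

MutKey = tuple[int, str, str]  # (position, from_base, to_base)


@dataclass
class LineageNode:
    node_id: str
    mutations: frozenset[MutKey]
    read_ids: list[str] = field(default_factory=list)  # empty -> inferred
    children: list["LineageEdge"] = field(default_factory=list)

    @property
    def is_inferred(self) -> bool:
        return not self.read_ids and self.node_id != "germline"


@dataclass
class LineageEdge:
    child: LineageNode
    gained: frozenset[MutKey]
    lost: frozenset[MutKey]

    @property
    def length(self) -> int:
        return len(self.gained) + len(self.lost)


@dataclass
class LineageTree:
    clone_id: str
    germline_name: str
    root: LineageNode
    total_substitutions: int
    exact: bool

    def nodes(self) -> list[LineageNode]:
        out, stack = [], [self.root]
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(e.child for e in node.children)
        return out

    def to_newick(self) -> str:
        def label(node: LineageNode) -> str:
            if node.node_id == "germline":
                return self.germline_name.replace("*", "_")
            return "+".join(node.read_ids) if node.read_ids else node.node_id

        def render(node: LineageNode, length: int) -> str:
            if node.children:
                inner = ",".join(render(e.child, e.length) for e in node.children)
                return f"({inner}){label(node)}:{length}"
            return f"{label(node)}:{length}"

        inner = ",".join(render(e.child, e.length) for e in self.root.children)
        return f"({inner}){label(self.root)}:0;"


def _fitch_exact(profiles: list[frozenset[MutKey]]) -> tuple[int, list, dict]:
    """Exact Steiner parsimony via exhaustive rooted-topology enumeration.

    Characters (one per distinct mutation) are bit-packed so Fitch merging
    is O(1) per node; the germline (all-absent) is the fixed root.  Returns
    (min score, best rooted topology as nested tuples of leaf indices,
    reconstructed states keyed by topology node).
    """
    chars: list[MutKey] = sorted(set().union(*profiles)) if profiles else []
    idx = {c: i for i, c in enumerate(chars)}
    full = (1 << len(chars)) - 1

    # leaf state: (ok_when_absent, ok_when_present) bitmasks
    leaf_states = []
    for p in profiles:
        present = 0
        for c in p:
            present |= 1 << idx[c]
        leaf_states.append((full & ~present, present))

    def merge(a, b):
        i0, i1 = a[0] & b[0], a[1] & b[1]
        empty = full & ~(i0 | i1)
        cost = empty.bit_count()
        u0, u1 = a[0] | b[0], a[1] | b[1]
        return (i0 | (u0 & empty), i1 | (u1 & empty)), cost

    def score(tree) -> tuple[tuple[int, int], int]:
        if isinstance(tree, int):
            return leaf_states[tree], 0
        (left, right) = tree
        sl, cl = score(left)
        sr, cr = score(right)
        state, c = merge(sl, sr)
        return state, cl + cr + c

    def topologies(leaves: list[int]):
        if len(leaves) == 1:
            yield leaves[0]
            return
        first, rest = leaves[0], leaves[1:]
        for sub in topologies(rest):
            # insert `first` into every edge/subtree position
            for new in _insertions(sub, first):
                yield new

    def _insertions(tree, leaf):
        yield (leaf, tree)
        if not isinstance(tree, int):
            left, right = tree
            for nl in _insertions(left, leaf):
                yield (nl, right)
            for nr in _insertions(right, leaf):
                yield (left, nr)

    best_score, best_tree = None, None
    for tree in topologies(list(range(len(profiles)))):
        state, cost = score(tree)
        # root edge to germline: characters where "absent" is not allowed
        cost += (full & ~state[0]).bit_count()
        if best_score is None or cost < best_score:
            best_score, best_tree = cost, tree

    # reconstruct states top-down on the best topology (prefer parent state)
    states: dict = {}

    def assign(tree, parent_present: int):
        state, _ = score(tree)
        ok0, ok1 = state
        final = 0
        for i in range(len(chars)):
            bit = 1 << i
            p = parent_present & bit
            can0, can1 = ok0 & bit, ok1 & bit
            if p and can1:
                final |= bit
            elif not p and can0:
                pass
            elif can1:
                final |= bit
        states[id(tree) if not isinstance(tree, int) else ("leaf", tree)] = final
        if not isinstance(tree, int):
            for sub in tree:
                assign(sub, final)
        return final

    if best_tree is not None:
        assign(best_tree, 0)
    return best_score or 0, best_tree, {"states": states, "chars": chars}


def _tree_from_topology(
    topology,
    recon: dict,
    profiles: list[frozenset[MutKey]],
    labels: list[list[str]],
) -> tuple[LineageNode, int]:
    """Convert a scored topology into a LineageTree rooted at germline,
    collapsing zero-length edges and naming inferred intermediates."""
    chars = recon["chars"]
    states = recon["states"]
    counter = itertools.count()

    def mutset(present: int) -> frozenset[MutKey]:
        return frozenset(c for i, c in enumerate(chars) if present & (1 << i))

    def build(tree) -> LineageNode:
        if isinstance(tree, int):
            return LineageNode(
                node_id=f"n{next(counter)}",
                mutations=profiles[tree],
                read_ids=list(labels[tree]),
            )
        present = states[id(tree)]
        node = LineageNode(node_id=f"n{next(counter)}", mutations=mutset(present))
        for sub in tree:
            child = build(sub)
            node.children.append(
                LineageEdge(
                    child=child,
                    gained=child.mutations - node.mutations,
                    lost=node.mutations - child.mutations,
                )
            )
        return node

    root = LineageNode(node_id="germline", mutations=frozenset())
    top = build(topology)
    root.children.append(
        LineageEdge(child=top, gained=top.mutations, lost=frozenset())
    )
    _collapse_zero_edges(root)
    total = _total_substitutions(root)
    return root, total


def _collapse_zero_edges(node: LineageNode) -> None:
    """Merge inferred children connected by zero-length edges into the parent."""
    changed = True
    while changed:
        changed = False
        new_children: list[LineageEdge] = []
        for edge in node.children:
            child = edge.child
            if edge.length == 0 and child.mutations == node.mutations:
                # absorb: promote grandchildren; keep observed labels
                node.read_ids.extend(child.read_ids)
                new_children.extend(child.children)
                changed = True
            else:
                new_children.append(edge)
        node.children = new_children
    for edge in node.children:
        _collapse_zero_edges(edge.child)


def _total_substitutions(root: LineageNode) -> int:
    total = 0
    stack = [root]
    while stack:
        node = stack.pop()
        for e in node.children:
            total += e.length
            stack.append(e.child)
    return total


def _greedy_tree(
    profiles: list[frozenset[MutKey]], labels: list[list[str]]
) -> tuple[LineageNode, int]:
    """Greedy shared-mutation-partition agglomeration (optimal for laminar sets)."""
    nodes = [
        LineageNode(node_id=f"g{i}", mutations=p, read_ids=list(lab))
        for i, (p, lab) in enumerate(zip(profiles, labels))
    ]
    counter = itertools.count(len(nodes))

    def attach(parent: LineageNode, child: LineageNode) -> None:
        parent.children.append(
            LineageEdge(
                child=child,
                gained=child.mutations - parent.mutations,
                lost=parent.mutations - child.mutations,
            )
        )

    while len(nodes) > 1:
        best = None
        for i, j in itertools.combinations(range(len(nodes)), 2):
            inter = nodes[i].mutations & nodes[j].mutations
            key = (len(inter), -len(nodes[i].mutations | nodes[j].mutations))
            if best is None or key > best[0]:
                best = (key, i, j, inter)
        (shared_size, _), i, j, inter = best
        if shared_size == 0:
            break  # remaining nodes attach straight to germline
        a, b = nodes[i], nodes[j]
        if a.mutations == inter:
            parent = a
            attach(parent, b)
        elif b.mutations == inter:
            parent = b
            attach(parent, a)
        else:
            parent = LineageNode(node_id=f"i{next(counter)}", mutations=inter)
            attach(parent, a)
            attach(parent, b)
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [parent]

    root = LineageNode(node_id="germline", mutations=frozenset())
    for n in nodes:
        attach(root, n)
    return root, _total_substitutions(root)


def build_lineage_tree(
    clone: Clone,
    transcripts: dict[str, Rearrangement],
    db: Optional[GermlineDatabase] = None,
    exact_limit: int = EXACT_TREE_LIMIT,
) -> LineageTree:
    """Minimal-substitution lineage tree of a clone, rooted at the germline.

    Members must share a germline V assignment (error otherwise).  Identical
    mutation profiles are merged into a single node before tree building.
    """
    db = db if db is not None else default_germline_db()
    members = [transcripts[rid] for rid in clone.read_ids]
    v_names = {m.v_call[0] for m in members if m.v_call}
    if len(v_names) != 1:
        raise ValueError(
            f"clone {clone.clone_id}: conflicting V assignments {sorted(v_names)}"
        )
    v = db[next(iter(v_names))]

    by_profile: dict[frozenset[MutKey], list[str]] = {}
    for m in members:
        muts, _ = mutation_scan(m, v)
        profile = frozenset((mu.position, mu.from_base, mu.to_base) for mu in muts)
        by_profile.setdefault(profile, []).append(m.read_id)
    profiles = sorted(by_profile, key=lambda p: (len(p), sorted(p)))
    labels = [sorted(by_profile[p]) for p in profiles]

    if len(profiles) <= exact_limit:
        score, topology, recon = _fitch_exact(profiles)
        root, total = _tree_from_topology(topology, recon, profiles, labels)
        exact = True
    else:
        root, total = _greedy_tree(profiles, labels)
        exact = False
    return LineageTree(
        clone_id=clone.clone_id,
        germline_name=v.name,
        root=root,
        total_substitutions=total,
        exact=exact,
    )


def clone_frame(clones: Iterable[Clone], donor_of: Optional[dict[str, str]] = None) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "clone_id": c.clone_id,
                "donor_id": donor_of.get(c.read_ids[0], "") if donor_of else "",
                "v_gene": c.v_gene,
                "j_gene": c.j_gene,
                "junction_length": c.junction_length,
                "n_members": c.n_members,
                "subclasses": ",".join(c.subclasses),
                "read_ids": ",".join(c.read_ids),
            }
            for c in clones
        ]
    )


def mutation_matrix(
    clone: Clone,
    transcripts: dict[str, Rearrangement],
    db: Optional[GermlineDatabase] = None,
) -> pd.DataFrame:
    """Per-clone matrix (rows transcripts, columns mutated positions, R/S coded)."""
    db = db if db is not None else default_germline_db()
    rows = {}
    for rid in clone.read_ids:
        r = transcripts[rid]
        if not r.v_call:
            continue
        muts, _ = mutation_scan(r, db[r.v_call[0]])
        rows[rid] = {m.position: m.rs_class for m in muts}
    positions = sorted({p for row in rows.values() for p in row})
    return pd.DataFrame(
        {pos: {rid: rows[rid].get(pos, "") for rid in rows} for pos in positions}
    )
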