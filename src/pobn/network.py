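"""Bipartite regulator->gene network container and its interchange formats.

The network has two disjoint layers: a top layer of regulator nodes (hidden
protein activities) and a bottom layer of observed target genes.  Edges run
strictly regulator -> target, so the graph is acyclic by construction.  If an
input edge list names the same identifier in both roles (e.g. a transcription
factor that is itself a transcribed target), the regulator role is renamed to
``<name>:act`` to keep the layers disjoint: the top-layer node stands for the
unobserved *activity* of the regulator, not its mRNA.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field

logger = logging.getLogger(__name__)

ACTIVITY_SUFFIX = ":act"


@dataclass(frozen=True)
class BipartiteNetwork:
    """Immutable bipartite regulator->target network.

    Parameters
    ----------
    regulators : frozenset of str
        Top-layer (hidden) node identifiers.
    targets : frozenset of str
        Bottom-layer (observed) node identifiers; disjoint from regulators.
    edges : frozenset of (regulator, target) pairs
        Directed edges; every source must be a regulator, every sink a target.
    """

    regulators: frozenset = field(default_factory=frozenset)
    targets: frozenset = field(default_factory=frozenset)
    edges: frozenset = field(default_factory=frozenset)

    def __post_init__(self):
        object.__setattr__(self, "regulators", frozenset(self.regulators))
        object.__setattr__(self, "targets", frozenset(self.targets))
        object.__setattr__(self, "edges", frozenset(tuple(e) for e in self.edges))
        overlap = self.regulators & self.targets
        if overlap:
            raise ValueError(f"regulator/target namespaces overlap: {sorted(overlap)[:5]}")
        for r, t in self.edges:
            if r not in self.regulators:
                raise ValueError(f"edge source {r!r} is not a declared regulator")
            if t not in self.targets:
                raise ValueError(f"edge sink {t!r} is not a declared target")

    # -- queries ---------------------------------------------------------

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def parents_of(self, target: str) -> frozenset:
        """Regulators with an edge into ``target`` (possibly empty)."""
        if target not in self.targets:
            raise KeyError(f"unknown target {target!r}")
        return frozenset(r for r, t in self.edges if t == target)

    def children_of(self, regulator: str) -> frozenset:
        if regulator not in self.regulators:
            raise KeyError(f"unknown regulator {regulator!r}")
        return frozenset(t for r, t in self.edges if r == regulator)

    def active_counts(self) -> tuple:
        """(number of regulators with >= 1 child, number of targets).

        Parentless targets still count as targets; childless regulators are
        excluded from the first count.
        """
        with_child = {r for r, _ in self.edges}
        return (len(with_child), len(self.targets))

    # -- edits (value semantics) ----------------------------------------

    def remove_edge(self, edge) -> "BipartiteNetwork":
        """Return a copy of the network minus one edge.

        Orphaned targets are kept as parentless nodes; the receiver is
        unmodified.
        """
        edge = tuple(edge)
        if edge not in self.edges:
            raise KeyError(f"edge {edge!r} not in network")
        return BipartiteNetwork(self.regulators, self.targets, self.edges - {edge})

    def add_edges(self, new_edges) -> "BipartiteNetwork":
        """Return a copy with extra regulator->target edges (used by the
        synthetic spurious-edge injection; endpoints must already exist)."""
        new_edges = {tuple(e) for e in new_edges}
        return BipartiteNetwork(self.regulators, self.targets, self.edges | new_edges)

    def restrict_targets(self, keep) -> "BipartiteNetwork":
        """Return the sub-network whose targets are restricted to ``keep``.

        Regulators left childless are retained as nodes.
        """
        keep = set(keep)
        targets = self.targets & keep
        edges = frozenset((r, t) for r, t in self.edges if t in targets)
        return BipartiteNetwork(self.regulators, frozenset(targets), edges)

    def content_hash(self) -> str:
        """Stable hash of the node and edge sets (provenance tag)."""
        h = hashlib.sha1()
        for part in (sorted(self.regulators), sorted(self.targets), sorted(self.edges)):
            h.update(repr(part).encode())
        return h.hexdigest()[:12]


# ---------------------------------------------------------------------------
# module-level operation aliases


def parents_of(net: BipartiteNetwork, target: str) -> frozenset:
    return net.parents_of(target)


def remove_edge(net: BipartiteNetwork, edge) -> BipartiteNetwork:
    return net.remove_edge(edge)


def active_counts(net: BipartiteNetwork) -> tuple:
    return net.active_counts()


# ---------------------------------------------------------------------------
# I/O


def read_edge_list(path) -> BipartiteNetwork:
    """Read a two-column ``regulator<TAB>target`` TSV into a network.

    ``#`` comment lines and blank lines are ignored; a single optional header
    line (``regulator``/``target`` in any case) is skipped.  Duplicate edges
    are collapsed with a logged warning.  A name appearing in both roles has
    its regulator role suffixed with ``:act`` (hidden-activity convention).
    """
    raw_edges = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) == 1:
                fields = line.split()
            if len(fields) != 2:
                raise ValueError(f"{path}: line {lineno}: expected 2 columns, got {len(fields)}")
            a, b = fields[0].strip(), fields[1].strip()
            if lineno == 1 and a.lower() in ("regulator", "source", "tf") and b.lower() in ("target", "gene"):
                continue
            if not a or not b:
                raise ValueError(f"{path}: line {lineno}: empty node name")
            raw_edges.append((a, b))

    targets = {t for _, t in raw_edges}
    # resolve role collisions before building the edge set
    def reg_name(r):
        return r + ACTIVITY_SUFFIX if r in targets else r

    edges = []
    seen = set()
    n_dup = 0
    for r, t in raw_edges:
        e = (reg_name(r), t)
        if e in seen:
            n_dup += 1
            continue
        seen.add(e)
        edges.append(e)
    if n_dup:
        logger.warning("%s: collapsed %d duplicate edge line(s)", path, n_dup)
    regulators = {r for r, _ in edges}
    return BipartiteNetwork(frozenset(regulators), frozenset(targets), frozenset(edges))


def write_edge_list(net: BipartiteNetwork, path) -> None:
    """Write the canonical two-column TSV (sorted edges, with header)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("regulator\ttarget\n")
        for r, t in sorted(net.edges):
            fh.write(f"{r}\t{t}\n")
        # preserve isolated nodes as comments so round-trips keep them
        isolated_t = sorted(net.targets - {t for _, t in net.edges})
        isolated_r = sorted(net.regulators - {r for r, _ in net.edges})
        for t in isolated_t:
            fh.write(f"#node\ttarget\t{t}\n")
        for r in isolated_r:
            fh.write(f"#node\tregulator\t{r}\n")


def read_edge_list_full(path) -> BipartiteNetwork:
    """Like :func:`read_edge_list` but also restores isolated nodes written
    by :func:`write_edge_list` (``#node`` comment lines)."""
    net = read_edge_list(path)
    extra_t, extra_r = set(), set()
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            if line.startswith("#node\t"):
                _, role, name = line.rstrip("\n").split("\t")
                (extra_t if role == "target" else extra_r).add(name)
    if extra_t or extra_r:
        net = BipartiteNetwork(net.regulators | extra_r, net.targets | extra_t, net.edges)
    return net


def write_dot(net: BipartiteNetwork, path) -> None:
    """Export the network as a Graphviz ``dot`` digraph (export-only).

    One edge statement per edge, node names quoted; regulators drawn as
    boxes, targets as ellipses.
    """
    lines = ["digraph bipartite_regulatory_network {"]
    for r in sorted(net.regulators):
        lines.append(f'  "{r}" [shape=box];')
    for t in sorted(net.targets):
        lines.append(f'  "{t}" [shape=ellipse];')
    for r, t in sorted(net.edges):
        lines.append(f'  "{r}" -> "{t}";')
    lines.append("}")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines) + "\n")
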