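"""Median-joining haplotype networks.

Builds Bandelt-style median-joining networks (MJN) from equal-length
aligned haplotypes: starting from the epsilon-relaxed minimum spanning
network, quasi-median (Steiner) vectors of connected triples are inserted
greedily while they shorten the network, then obsolete medians are pruned.
With epsilon = 0 and no beneficial Steiner point the result is a minimum
spanning tree.

Two distance modes are available for the microsatellite fragment:
``character`` treats the gapped repeat-block alignment site by site with
gaps as fifth states; ``stepwise`` scores repeat-block run lengths by the
stepwise mutation model (|run-length difference|), which is how a
single-repeat contraction/expansion becomes a single mutational step.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import networkx as nx

from .repeats import encode_repeat_block
from .seqio import SequenceRecord

MAX_HAPLOTYPES = 10_000

Profile = tuple  # mixed tuple of single-char states and int run lengths


def truncate_to_common_length(
    records: Sequence[SequenceRecord],
) -> tuple[list[SequenceRecord], int]:
    """Cut primer-anchored sequences to the length of the shortest.

    Returns the truncated records and the common length.
    """
    if len(records) < 2:
        raise ValueError("truncation needs at least two records")
    common = min(len(r.bases) for r in records)
    out = []
    for r in records:
        clone = SequenceRecord(
            r.sample_id, r.population, r.source, r.locus, r.bases[:common]
        )
        out.append(clone)
    return out, common


def _profile_distance(a: Profile, b: Profile, weights: Sequence[float] | None) -> float:
    d = 0.0
    for i, (x, y) in enumerate(zip(a, b)):
        w = 1.0 if weights is None else weights[i]
        if isinstance(x, int) or isinstance(y, int):
            d += w * abs(int(x) - int(y))
        elif x != y:
            d += w
    return d


def _quasi_medians(u: Profile, v: Profile, w: Profile) -> list[Profile]:
    """Site-wise majority consensus; coordinates with three distinct states
    yield all three variants (capped); integer coordinates take the median."""
    options: list[tuple] = []
    n_ties = 0
    for x, y, z in zip(u, v, w):
        if isinstance(x, int):
            options.append((sorted((x, y, z))[1],))
        elif x == y or x == z:
            options.append((x,))
        elif y == z:
            options.append((y,))
        else:
            n_ties += 1
            options.append(tuple(sorted({x, y, z})))
    if n_ties > 3:  # combinatorial guard; such triples are never beneficial here
        return []
    return [tuple(p) for p in itertools.product(*options)]


def _mst_edges(
    nodes: Sequence[Profile], dist
) -> tuple[list[tuple[Profile, Profile, float]], float]:
    """Deterministic Kruskal MST (ties broken by sorted node order)."""
    order = {p: i for i, p in enumerate(sorted(nodes))}
    edges = sorted(
        (dist(a, b), min(order[a], order[b]), max(order[a], order[b]))
        for a, b in itertools.combinations(nodes, 2)
    )
    index = sorted(nodes)
    uf = nx.utils.UnionFind(nodes)
    out, total = [], 0.0
    for d, i, j in edges:
        a, b = index[i], index[j]
        if uf[a] != uf[b]:
            uf.union(a, b)
            out.append((a, b, d))
            total += d
    return out, total


def _feasible_edges(nodes: Sequence[Profile], dist, epsilon: float):
    """Epsilon-relaxed minimum spanning network: an edge is kept when its
    weight is within epsilon of the MST bottleneck distance of its ends."""
    mst, _ = _mst_edges(nodes, dist)
    tree = nx.Graph()
    tree.add_weighted_edges_from(mst)
    edges = []
    for a, b in itertools.combinations(nodes, 2):
        path = nx.shortest_path(tree, a, b)
        bottleneck = max(
            tree[u][v]["weight"] for u, v in zip(path, path[1:])
        )
        d = dist(a, b)
        if d <= bottleneck + epsilon:
            edges.append((a, b, d))
    return edges


@dataclass
class HaplotypeNetwork:
    """An MJN: observed haplotypes (with frequencies) plus median vectors."""

    graph: nx.Graph
    epsilon: float = 0.0

    @property
    def median_nodes(self) -> list[str]:
        return [n for n, d in self.graph.nodes(data=True) if d["is_median"]]

    @property
    def observed_nodes(self) -> list[str]:
        return [n for n, d in self.graph.nodes(data=True) if not d["is_median"]]

    def total_length(self) -> float:
        return sum(d["weight"] for _, _, d in self.graph.edges(data=True))


def _records_to_profiles(
    records: Sequence[SequenceRecord | str], mode: str
) -> tuple[list[Profile], list[str]]:
    seqs = [r.bases if isinstance(r, SequenceRecord) else str(r) for r in records]
    ids = [
        r.sample_id if isinstance(r, SequenceRecord) else f"seq{i + 1}"
        for i, r in enumerate(records)
    ]
    if len({len(s) for s in seqs}) != 1:
        raise ValueError("median-joining network requires equal-length sequences")
    if mode == "character":
        return [tuple(s) for s in seqs], ids
    # stepwise: replace the repeat-block columns with run-length integers
    first = records[0]
    locus = first.locus if isinstance(first, SequenceRecord) else None
    if locus is None or locus.repeat_region is None:
        raise ValueError("stepwise mode requires records of a microsatellite locus")
    start, end = locus.repeat_region
    profiles = []
    structure = None
    for s in seqs:
        block = s[start - 1 : end].replace("-", "")
        runs = encode_repeat_block(block).runs
        bases = tuple(b for _, b in runs)
        if structure is None:
            structure = bases
        elif bases != structure:
            raise ValueError(
                "stepwise mode requires a shared repeat-run structure; "
                "use character mode for rearranged alleles"
            )
        flank = tuple(s[: start - 1]) + tuple(s[end:])
        profiles.append(flank + tuple(length for length, _ in runs))
    return profiles, ids


def median_joining_network(
    records: Sequence[SequenceRecord | str],
    epsilon: float = 0.0,
    mode: Literal["character", "stepwise"] = "character",
    weights: Sequence[float] | None = None,
    max_iter: int = 200,
) -> HaplotypeNetwork:
    """Construct a median-joining network of the input haplotypes.

    Identical sequences are collapsed into one node whose frequency is the
    number of carriers; inferred median vectors carry zero frequency.
    Output is deterministic for a fixed input set (lexicographic
    tie-breaking throughout); the widely used desktop implementations may
    differ cosmetically in their tie-breaks.
    """
    if not records:
        raise ValueError("no records")
    profiles, ids = _records_to_profiles(records, mode)
    if weights is not None and len(weights) != len(profiles[0]):
        raise ValueError("weights length must match profile length")

    freq: dict[Profile, int] = {}
    carriers: dict[Profile, list[str]] = {}
    for p, sid in zip(profiles, ids):
        freq[p] = freq.get(p, 0) + 1
        carriers.setdefault(p, []).append(sid)
    if len(freq) > MAX_HAPLOTYPES:
        raise ValueError(f"refusing to build a network on {len(freq)} haplotypes")

    def dist(a: Profile, b: Profile) -> float:
        return _profile_distance(a, b, weights)

    nodes: set[Profile] = set(freq)
    if len(nodes) == 1:
        only = next(iter(nodes))
        g = nx.Graph()
        g.add_node(
            "H1", sequence=_profile_repr(only), frequency=freq[only],
            is_median=False, samples=",".join(carriers[only]),
        )
        return HaplotypeNetwork(g, epsilon)

    # --- median insertion loop -------------------------------------------
    for _ in range(max_iter):
        node_list = sorted(nodes)
        _, mst_len = _mst_edges(node_list, dist)
        feasible = _feasible_edges(node_list, dist, epsilon)
        adj = nx.Graph()
        adj.add_weighted_edges_from(feasible)
        best: tuple[float, Profile] | None = None
        seen: set[Profile] = set()
        for u, v, w in sorted(
            (t for t in itertools.combinations(node_list, 3)),
            key=lambda t: t
        ):
            if not (adj.has_edge(u, v) and adj.has_edge(u, w) and adj.has_edge(v, w)):
                continue
            for m in _quasi_medians(u, v, w):
                if m in nodes or m in seen:
                    continue
                seen.add(m)
                _, new_len = _mst_edges(node_list + [m], dist)
                gain = mst_len - new_len
                if gain > 1e-9 and (best is None or gain > best[0] + 1e-9
                                    or (abs(gain - best[0]) <= 1e-9 and m < best[1])):
                    best = (gain, m)
        if best is None:
            break
        nodes.add(best[1])

    # --- prune obsolete median vectors -----------------------------------
    changed = True
    while changed:
        changed = False
        _, cur_len = _mst_edges(sorted(nodes), dist)
        for m in sorted(nodes):
            if m in freq:
                continue
            rest = sorted(nodes - {m})
            _, rest_len = _mst_edges(rest, dist)
            if rest_len <= cur_len + 1e-9:
                nodes.discard(m)
                changed = True
                break

    # --- final graph -------------------------------------------------------
    node_list = sorted(nodes)
    observed_sorted = sorted(
        (p for p in node_list if p in freq), key=lambda p: (-freq[p], p)
    )
    names: dict[Profile, str] = {}
    for i, p in enumerate(observed_sorted):
        names[p] = f"H{i + 1}"
    m_i = 0
    for p in node_list:
        if p not in names:
            m_i += 1
            names[p] = f"mv{m_i}"
    g = nx.Graph(epsilon=epsilon)
    for p in node_list:
        g.add_node(
            names[p],
            sequence=_profile_repr(p),
            frequency=freq.get(p, 0),
            is_median=p not in freq,
            samples=",".join(carriers.get(p, [])),
        )
    for a, b, d in _feasible_edges(node_list, dist, epsilon):
        g.add_edge(names[a], names[b], weight=d)
    return HaplotypeNetwork(g, epsilon)


def _profile_repr(p: Profile) -> str:
    return "".join(str(x) if isinstance(x, int) else x for x in p)


def export_network(net: HaplotypeNetwork, path: str | Path, fmt: str | None = None) -> None:
    """Write the network as GML, DOT or a lossless TSV node/edge table."""
    path = Path(path)
    fmt = (fmt or path.suffix.lstrip(".")).lower()
    if fmt == "gml":
        g = net.graph.copy()
        for _, d in g.nodes(data=True):
            d["is_median"] = int(d["is_median"])
        nx.write_gml(g, str(path))
    elif fmt == "dot":
        lines = ["graph haplotypes {"]
        for n, d in net.graph.nodes(data=True):
            shape = "point" if d["is_median"] else "circle"
            lines.append(
                f'  "{n}" [label="{n} (n={d["frequency"]})", shape={shape}];'
            )
        for u, v, d in net.graph.edges(data=True):
            lines.append(f'  "{u}" -- "{v}" [label="{d["weight"]:g}"];')
        lines.append("}")
        path.write_text("\n".join(lines) + "\n")
    elif fmt == "tsv":
        rows = ["type\tid\tid2\tsequence\tfrequency\tis_median\tweight\tsamples"]
        for n, d in sorted(net.graph.nodes(data=True)):
            rows.append(
                f"node\t{n}\t\t{d['sequence']}\t{d['frequency']}"
                f"\t{int(d['is_median'])}\t\t{d['samples']}"
            )
        for u, v, d in sorted(net.graph.edges(data=True)):
            rows.append(f"edge\t{u}\t{v}\t\t\t\t{d['weight']:g}\t")
        path.write_text("\n".join(rows) + "\n")
    else:
        raise ValueError(f"unknown network export format {fmt!r}")


def read_network_tsv(path: str | Path) -> HaplotypeNetwork:
    """Read back a TSV written by :func:`export_network`."""
    g = nx.Graph()
    lines = Path(path).read_text().splitlines()[1:]
    for line in lines:
        parts = line.split("\t")
        if parts[0] == "node":
            g.add_node(
                parts[1],
                sequence=parts[3],
                frequency=int(parts[4]),
                is_median=bool(int(parts[5])),
                samples=parts[7] if len(parts) > 7 else "",
            )
        elif parts[0] == "edge":
            g.add_edge(parts[1], parts[2], weight=float(parts[6]))
    return HaplotypeNetwork(g)
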