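"""BCR somatic-hypermutation status, isotype composition and clone networks.

An IgH clone with at least one V-region nucleotide mismatch to germline is a
*mutated* clone; zero mismatches is *original*; a missing mismatch count is
*unknown* and excluded from percentage denominators. Mutated clones of one
sample (optionally one isotype) form a network: each mutated clone is a node,
and two nodes are connected when they plausibly belong to the same clonal
lineage — identical V gene, identical J gene, equal CDR3 amino-acid length
and CDR3aa Hamming distance at most 1 (threshold configurable). The summary
statistic is the average degree 2E/N, plus the EXd1 variant that first drops
all nodes with exactly one connection (a single simultaneous pass).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import pandas as pd

from .io import Clonotype, RepertoireSample

ISOTYPES = ("IgA", "IgG", "IgM")


class ChainError(ValueError):
    """SHM analysis applies to IGH samples only."""


def classify_mutated(clonotype: Clonotype) -> str:
    """Classify an IgH clone as ``original``, ``mutated`` or ``unknown``."""
    if clonotype.chain != "IGH":
        raise ChainError(f"SHM status requires an IGH clone, got chain {clonotype.chain!r}")
    if clonotype.v_mismatches is None:
        return "unknown"
    return "mutated" if clonotype.v_mismatches >= 1 else "original"


@dataclass(slots=True)
class SHMStats:
    """Percentages and network degrees for one (sample, isotype-view).

    ``original_pct``/``mutated_pct`` are clone-based percentages over clones
    with known mutation status (``None`` when no status is known);
    ``isotype_pct`` is the clone-share composition over the isotypes present.
    """

    original_pct: float | None
    mutated_pct: float | None
    avg_degree: float
    avg_degree_exd1: float
    isotype_pct: dict[str, float] = field(default_factory=dict)
    n_clones: int = 0
    n_known: int = 0
    n_mutated: int = 0


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def build_network(
    sample: RepertoireSample,
    isotype: str | None = None,
    max_aa_dist: int = 1,
) -> nx.Graph:
    """Mutated-clone network of one IGH sample (optionally one isotype).

    Nodes are the clone ids of mutated clones; an edge joins two clones with
    the same V gene, same J gene, equal CDR3aa length and CDR3aa Hamming
    distance <= ``max_aa_dist``. Node attributes carry isotype and CDR3aa.
    """
    if sample.chain != "IGH":
        raise ChainError(f"mutation network requires an IGH sample, got {sample.chain!r}")
    clones = [
        c
        for c in sample.clonotypes
        if (isotype is None or c.isotype == isotype) and classify_mutated(c) == "mutated"
    ]
    g = nx.Graph()
    for c in clones:
        g.add_node(c.clone_id, isotype=c.isotype, cdr3_aa=c.cdr3_aa, v_call=c.v_call)
    # bucket by (V, J, CDR3aa length) so only lineage candidates are paired
    buckets: dict[tuple[str, str, int], list[Clonotype]] = {}
    for c in clones:
        buckets.setdefault((c.v_call, c.j_call, len(c.cdr3_aa)), []).append(c)
    for members in buckets.values():
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                a, b = members[i], members[j]
                if _hamming(a.cdr3_aa, b.cdr3_aa) <= max_aa_dist:
                    g.add_edge(a.clone_id, b.clone_id)
    return g


def average_degree(net: nx.Graph) -> float:
    """Mean connections per node, sum(degree)/N = 2E/N; 0 for an empty graph."""
    n = net.number_of_nodes()
    if n == 0:
        return 0.0
    return 2.0 * net.number_of_edges() / n


def average_degree_exd1(net: nx.Graph) -> float:
    """Average degree after removing all degree-1 nodes in one pass.

    Nodes whose degree is exactly 1 are dropped simultaneously (not
    iteratively) together with their incident edges; isolated (degree-0)
    nodes are retained. Returns 0 for an empty pruned graph.
    """
    keep = [v for v, d in net.degree() if d != 1]
    return average_degree(net.subgraph(keep))


def shm_percentages(sample: RepertoireSample, isotype: str | None = None) -> SHMStats:
    """Clone-based SHM percentages and network degrees for one view.

    Percentages are over clones with known mutation status; when every clone
    has unknown status the percentage fields are ``None`` (missing), not 0.
    """
    if sample.chain != "IGH":
        raise ChainError(f"SHM percentages require an IGH sample, got {sample.chain!r}")
    clones = [c for c in sample.clonotypes if isotype is None or c.isotype == isotype]
    statuses = [classify_mutated(c) for c in clones]
    n_known = sum(s != "unknown" for s in statuses)
    n_mut = sum(s == "mutated" for s in statuses)
    if n_known:
        mutated_pct: float | None = 100.0 * n_mut / n_known
        original_pct: float | None = 100.0 - mutated_pct
    else:
        mutated_pct = original_pct = None
    iso_counts = {iso: sum(c.isotype == iso for c in clones) for iso in ISOTYPES}
    iso_total = sum(iso_counts.values())
    isotype_pct = (
        {iso: 100.0 * n / iso_total for iso, n in iso_counts.items() if n}
        if iso_total
        else {}
    )
    net = build_network(sample, isotype=isotype)
    return SHMStats(
        original_pct=original_pct,
        mutated_pct=mutated_pct,
        avg_degree=average_degree(net),
        avg_degree_exd1=average_degree_exd1(net),
        isotype_pct=isotype_pct,
        n_clones=len(clones),
        n_known=n_known,
        n_mutated=n_mut,
    )


def shm_table(samples) -> pd.DataFrame:
    """Tidy SHM summary over IGH samples: combined plus per-isotype rows."""
    rows = []
    for s in samples:
        if s.chain != "IGH":
            continue
        for iso in (None,) + ISOTYPES:
            stats = shm_percentages(s, isotype=iso)
            rows.append(
                {
                    "patient_id": s.patient_id,
                    "tissue": s.tissue,
                    "isotype": iso or "IGH",
                    "n_clones": stats.n_clones,
                    "original_pct": stats.original_pct,
                    "mutated_pct": stats.mutated_pct,
                    "avg_degree": stats.avg_degree,
                    "avg_degree_exd1": stats.avg_degree_exd1,
                    "isotype_clone_pct": stats.isotype_pct.get(iso) if iso else None,
                }
            )
    return pd.DataFrame(rows)


def write_edge_list(net: nx.Graph, path: str | Path) -> None:
    """Export a mutation network as an edge-list TSV with node attributes."""
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("source\ttarget\n")
        for u, v in sorted(net.edges()):
            fh.write(f"{u}\t{v}\n")
    node_path = path.with_suffix(".nodes.tsv")
    with open(node_path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("node\tdegree\tisotype\n")
        for v in sorted(net.nodes()):
            fh.write(f"{v}\t{net.degree(v)}\t{net.nodes[v].get('isotype', '')}\n")
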