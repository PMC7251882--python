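"""Paralog family delineation and node-weighted Ks estimation.

Takes the standard outputs of an external all-vs-all protein similarity
search (12-column tabular hits) and turns them into duplication events with
synonymous-distance ages:

1. build a sequence similarity graph and cluster it with Markov Clustering
   (MCL, inflation 2.0 by default),
2. back-thread a guide protein alignment onto CDS to get a gap-stripped
   codon alignment,
3. estimate pairwise Ks under GY94/F3x4 (:mod:`wgdsig.gy94`),
4. weight pairwise Ks values per duplication node of the family tree, so
   the resulting distribution counts duplication events rather than
   duplicate pairs, and
5. filter events to the usable Ks window (0, 5].
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from io import StringIO

import numpy as np
import pandas as pd
from Bio import Phylo
from Bio.Seq import Seq

from .gy94 import KsEstimate

logger = logging.getLogger(__name__)

DEFAULT_EVALUE_CUTOFF = 1e-10
RELAXED_EVALUE_CUTOFF = 1e-5


# ---------------------------------------------------------------------------
# Similarity graph and Markov clustering
# ---------------------------------------------------------------------------


@dataclass
class SimilarityGraph:
    """Undirected weighted graph of within-proteome similarity hits."""

    vertices: list[str]
    edges: dict[frozenset, float]  # pair -> weight (bit score)
    evalues: dict[frozenset, float] = field(default_factory=dict)

    @classmethod
    def from_hits(
        cls, hits: pd.DataFrame, evalue_cutoff: float = DEFAULT_EVALUE_CUTOFF
    ) -> "SimilarityGraph":
        """Build from 12-column tabular hits (query, subject, ..., evalue, bitscore).

        Self-hits are dropped; reciprocal hits are merged keeping the best
        bit score and E-value.
        """
        kept = hits[hits["evalue"] <= evalue_cutoff]
        qcol, scol = ("gene_a", "gene_b") if "gene_a" in hits.columns else ("query", "subject")
        edges: dict[frozenset, float] = {}
        evalues: dict[frozenset, float] = {}
        verts: set[str] = set()
        for q, s, ev, bs in zip(kept[qcol], kept[scol], kept["evalue"], kept["bitscore"]):
            if q == s:
                continue
            key = frozenset((q, s))
            verts.update(key)
            if key not in edges or bs > edges[key]:
                edges[key] = float(bs)
            evalues[key] = min(float(ev), evalues.get(key, np.inf))
        return cls(vertices=sorted(verts), edges=edges, evalues=evalues)


@dataclass
class ParalogFamily:
    """A clustered paralogous gene family."""

    family_id: str
    members: list[str]

    def __len__(self) -> int:
        return len(self.members)


class MclError(RuntimeError):
    pass


def cluster_paralogs_mcl(
    graph: SimilarityGraph,
    inflation: float = 2.0,
    prune_threshold: float = 1e-5,
    max_iter: int = 100,
    tol: float = 1e-8,
    min_size: int = 2,
) -> list[ParalogFamily]:
    """Markov clustering of the similarity graph.

    Implements the standard MCL iteration on the column-stochastic
    transition matrix: expansion (matrix squaring), inflation (entrywise
    power followed by column renormalization) and pruning of near-zero
    entries, run to convergence.  Clusters are read off the attractor rows
    of the limit matrix; attractors with overlapping supports are merged.
    Families smaller than ``min_size`` (singletons, by default) are
    discarded as they carry no duplication signal.
    """
    if not graph.vertices:
        raise ValueError("empty similarity graph")
    if inflation <= 1.0:
        raise ValueError("inflation must exceed 1")
    verts = graph.vertices
    idx = {v: i for i, v in enumerate(verts)}
    n = len(verts)
    M = np.zeros((n, n))
    for key, w in graph.edges.items():
        a, b = tuple(key)
        M[idx[a], idx[b]] = M[idx[b], idx[a]] = w
    # self-loops at each node's maximum incident weight regularize the flow
    loops = M.max(axis=0)
    loops[loops == 0] = 1.0
    np.fill_diagonal(M, loops)
    M = M / M.sum(axis=0, keepdims=True)

    for _ in range(max_iter):
        M_new = M @ M
        M_new = np.power(M_new, inflation)
        M_new[M_new < prune_threshold] = 0.0
        col = M_new.sum(axis=0, keepdims=True)
        col[col == 0] = 1.0
        M_new /= col
        diff = np.abs(M_new - M).max()
        M = M_new
        if diff < tol:
            break
    else:
        raise MclError(f"MCL did not converge within {max_iter} iterations")

    support_tol = 1e-6
    attractors = [i for i in range(n) if M[i, i] > support_tol]
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a, b):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[rb] = ra

    assigned = np.full(n, -1)
    for i in attractors:
        for j in np.nonzero(M[i] > support_tol)[0]:
            if assigned[j] >= 0:
                union(assigned[j], i)
            else:
                assigned[j] = i
    clusters: dict[int, list[str]] = {}
    for j in range(n):
        root = find(assigned[j]) if assigned[j] >= 0 else find(j)
        clusters.setdefault(root, []).append(verts[j])
    families = [
        ParalogFamily(family_id=f"fam{k}", members=sorted(members))
        for k, members in enumerate(
            sorted(clusters.values(), key=lambda m: (-len(m), m[0]))
        )
        if len(members) >= min_size
    ]
    return families


# ---------------------------------------------------------------------------
# Codon alignment back-threading
# ---------------------------------------------------------------------------


def backthread_codon_alignment(
    protein_alignment: dict[str, str], cds_sequences: dict[str, str]
) -> dict[str, str]:
    """Thread CDS onto a guide protein alignment; strip gapped columns.

    Every aligned amino-acid column is replaced by its source codon; columns
    containing a gap in any sequence are removed, so the result is a
    gap-stripped codon alignment with length divisible by 3.

    Raises if a CDS does not translate exactly to its (ungapped) protein
    under the standard code, or if lengths are inconsistent.
    """
    if not protein_alignment:
        raise ValueError("empty protein alignment")
    aln_len = {len(s) for s in protein_alignment.values()}
    if len(aln_len) != 1:
        raise ValueError("protein alignment rows differ in length")
    (n_cols,) = aln_len

    codons: dict[str, list[str]] = {}
    for name, aa_aln in protein_alignment.items():
        cds = cds_sequences[name].upper().replace("U", "T")
        if len(cds) % 3:
            raise ValueError(f"{name}: CDS length not divisible by 3")
        prot = str(Seq(cds).translate())
        if prot.endswith("*"):
            prot = prot[:-1]
            cds = cds[:-3]
        if "*" in prot:
            raise ValueError(f"{name}: internal stop codon in CDS")
        ungapped = aa_aln.replace("-", "")
        if prot != ungapped:
            raise ValueError(f"{name}: CDS translation does not match protein")
        triplets = [cds[3 * i : 3 * i + 3] for i in range(len(prot))]
        row, k = [], 0
        for aa in aa_aln:
            if aa == "-":
                row.append(None)
            else:
                row.append(triplets[k])
                k += 1
        codons[name] = row

    keep = [
        c for c in range(n_cols) if all(codons[name][c] is not None for name in codons)
    ]
    return {name: "".join(codons[name][c] for c in keep) for name in codons}


# ---------------------------------------------------------------------------
# Family trees and node weighting
# ---------------------------------------------------------------------------


def nj_family_tree(protein_alignment: dict[str, str]) -> "Phylo.BaseTree.Tree":
    """Neighbor-joining family tree on protein p-distances.

    Fallback for when no externally estimated family tree is supplied; only
    the topology's LCA structure is used downstream.
    """
    from Bio.Phylo.TreeConstruction import DistanceMatrix, DistanceTreeConstructor

    names = sorted(protein_alignment)
    matrix = []
    for i, a in enumerate(names):
        row = []
        for b in names[: i + 1]:
            if a == b:
                row.append(0.0)
                continue
            sa, sb = protein_alignment[a], protein_alignment[b]
            cols = [(x, y) for x, y in zip(sa, sb) if x != "-" and y != "-"]
            if not cols:
                row.append(1.0)
            else:
                row.append(sum(x != y for x, y in cols) / len(cols))
        matrix.append(row)
    dm = DistanceMatrix(names, matrix)
    return DistanceTreeConstructor().nj(dm)


@dataclass
class KsEvent:
    """One duplication event (internal node of a family tree).

    ``weight`` is the event's total weight (1 per node before filtering);
    ``pairs`` lists the contributing gene pairs with their per-pair weights
    1/(number of pairs coalescing at the node).
    """

    family_id: str
    node_id: str
    ks: float
    weight: float
    pairs: list[tuple[str, str, float, float]]  # (gene_a, gene_b, pair_ks, pair_weight)


def _as_phylo_tree(tree) -> "Phylo.BaseTree.Tree":
    if isinstance(tree, str):
        return Phylo.read(StringIO(tree), "newick")
    return tree


def weight_ks_by_node(
    family: ParalogFamily,
    pairwise_ks: dict[frozenset, "KsEstimate | float"],
    family_tree,
    exclude_saturated_before: bool = True,
    ks_ceiling: float = 5.0,
) -> list[KsEvent]:
    """Collapse pairwise Ks values into per-duplication-node events.

    Each internal node of the family tree is one duplication event; the
    pairs whose most recent common ancestor is that node contribute with
    weight 1/(number of pairs at the node), and the event's consensus Ks is
    their weighted mean.  Saturated pairs are excluded before averaging by
    default (set ``exclude_saturated_before=False`` to average first and let
    the Ks filter remove saturated events afterwards).
    """
    tree = _as_phylo_tree(family_tree)
    terminals = {t.name for t in tree.get_terminals()}
    if set(family.members) != terminals:
        raise ValueError(
            f"family tree leaves {sorted(terminals)} do not match members "
            f"{family.members}"
        )

    # map each leaf pair to its LCA clade
    clade_id: dict[int, str] = {}
    for k, clade in enumerate(tree.get_nonterminals()):
        clade_id[id(clade)] = f"node{k}"
    groups: dict[str, list[tuple[str, str, float]]] = {}
    members = family.members
    for i, a in enumerate(members):
        for b in members[i + 1 :]:
            key = frozenset((a, b))
            if key not in pairwise_ks:
                continue
            est = pairwise_ks[key]
            if isinstance(est, KsEstimate):
                if exclude_saturated_before and (est.saturated or est.ks > ks_ceiling):
                    continue
                ks_val = est.ks
            else:
                ks_val = float(est)
                if exclude_saturated_before and ks_val > ks_ceiling:
                    continue
            lca = tree.common_ancestor({"name": a}, {"name": b})
            groups.setdefault(clade_id[id(lca)], []).append((a, b, ks_val))

    events = []
    for node, rows in sorted(groups.items()):
        w = 1.0 / len(rows)
        consensus = float(np.mean([r[2] for r in rows]))
        events.append(
            KsEvent(
                family_id=family.family_id,
                node_id=node,
                ks=consensus,
                weight=1.0,
                pairs=[(a, b, ks, w) for a, b, ks in rows],
            )
        )
    return events


def filter_ks_events(
    events: list[KsEvent], ks_min: float = 0.0, ks_max: float = 5.0
) -> list[KsEvent]:
    """Keep events with consensus Ks in (ks_min, ks_max]."""
    kept = [e for e in events if ks_min < e.ks <= ks_max]
    removed = len(events) - len(kept)
    if removed:
        logger.info("filter_ks_events: removed %d of %d events", removed, len(events))
    if events and not kept:
        warnings.warn("all Ks events removed by the (0, 5] filter", stacklevel=2)
    return kept


def events_frame(events: list[KsEvent]) -> pd.DataFrame:
    """Tabular view (family, node, Ks, weight) of a KsEvent list."""
    return pd.DataFrame(
        [(e.family_id, e.node_id, e.ks, e.weight) for e in events],
        columns=["family", "node", "ks", "weight"],
    )
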