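"""Duplicate-pair classification and co-linear block chaining.

Within-genome homolog hits are placed on a gene-rank grid per scaffold pair
and chained by sparse dynamic programming into co-linear blocks, in both
parallel and inverted orientation.  Anchors (pairs inside blocks) are
labelled segmental/WGD-derived; remaining pairs are tandem if adjacent on
one scaffold, otherwise dispersed.  Block topology distinguishes
inter-scaffold blocks (the arrangement expected under WGD) from
intra-scaffold tandem arrays and palindromes (signatures of local segmental
duplication).

Chaining scores ``match_reward`` per anchor minus ``gap_penalty`` per unit
of rank-space Manhattan distance beyond the perfectly adjacent diagonal
step; extension is only allowed while the Manhattan distance between
consecutive anchors stays within ``max_gap``.  Two named presets mirror the
stringent and relaxed analysis regimes (seed 5 / gap 25 / E 1e-10 versus
seed 3 / gap 40 / E 1e-5).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class ChainingPreset:
    seed_size: int
    max_gap: int
    evalue_cutoff: float
    match_reward: float = 50.0
    gap_penalty: float = 1.0


STRINGENT = ChainingPreset(seed_size=5, max_gap=25, evalue_cutoff=1e-10)
RELAXED = ChainingPreset(seed_size=3, max_gap=40, evalue_cutoff=1e-5)


def rank_genes(genes: pd.DataFrame) -> pd.DataFrame:
    """Assign 0-based per-scaffold rank order by start coordinate.

    Ties on start are broken by gene id, lexicographically.  Input needs
    columns gene_id, scaffold, start, end (1-based closed), strand.
    """
    df = genes.copy()
    dup = df.duplicated(subset=["gene_id"], keep=False) & df.duplicated(
        subset=["scaffold", "start", "end"], keep=False
    )
    if dup.any():
        raise ValueError("overlapping identical coordinates with identical ids")
    df = df.sort_values(["scaffold", "start", "gene_id"], kind="mergesort")
    df["rank"] = df.groupby("scaffold").cumcount()
    return df.reset_index(drop=True)


@dataclass
class CollinearBlock:
    """A chained run of anchor pairs between two genomic segments."""

    block_id: int
    scaffold_a: str
    scaffold_b: str
    orientation: str  # parallel | inverted
    anchors: list[tuple[str, str]]
    score: float
    median_ks: float | None = None

    @property
    def anchor_count(self) -> int:
        return len(self.anchors)

    @property
    def topology(self) -> str:
        return classify_block_topology(self)


def classify_block_topology(block: CollinearBlock) -> str:
    """inter_scaffold if the copies sit on different scaffolds; otherwise
    palindrome when inverted, tandem_array when parallel."""
    if block.scaffold_a != block.scaffold_b:
        return "inter_scaffold"
    return "palindrome" if block.orientation == "inverted" else "tandem_array"


# ---------------------------------------------------------------------------
# Chaining dynamic programme
# ---------------------------------------------------------------------------


def _best_chain(hits, max_gap, match, gap_pen, inverted):
    """Best-scoring chain over ``hits`` = list of (q, t, key) in one
    orientation; returns (score, [hit positions]) or None.

    Hits are processed in sorted (q, t') order; ties in score are broken
    toward the smallest index, which makes the traceback the lexicographically
    smallest max-score chain (compared end-first) -- the same rule the
    exhaustive reference uses.
    """
    if not hits:
        return None
    pts = sorted(
        (q, -t if inverted else t, key) for q, t, key in hits
    )
    n = len(pts)
    score = np.empty(n)
    pred = np.full(n, -1)
    for i in range(n):
        qi, ti, _ = pts[i]
        best, bj = 0.0, -1
        for j in range(i):
            qj, tj, _ = pts[j]
            if qj >= qi or tj >= ti:
                continue
            d = (qi - qj) + (ti - tj)
            if d > max_gap:
                continue
            ext = score[j] - gap_pen * (d - 2)
            if ext > best + 1e-12:
                best, bj = ext, j
        score[i] = match + best
        pred[i] = bj
    end = int(np.argmax(score))  # argmax returns the first (smallest) index
    chain = []
    i = end
    while i >= 0:
        chain.append(pts[i][2])
        i = pred[i]
    chain.reverse()
    return float(score[end]), chain


def chain_collinear_blocks(
    pairs: pd.DataFrame,
    genes: pd.DataFrame,
    seed_size: int = STRINGENT.seed_size,
    max_gap: int = STRINGENT.max_gap,
    evalue_cutoff: float = STRINGENT.evalue_cutoff,
    match_reward: float = STRINGENT.match_reward,
    gap_penalty: float = STRINGENT.gap_penalty,
) -> list[CollinearBlock]:
    """Chain homolog pairs into co-linear blocks.

    For every scaffold pair (including self-pairs, with self-hits and the
    main diagonal masked) the highest-scoring chain among remaining hits is
    extracted repeatedly, in either orientation; chains with at least
    ``seed_size`` anchors are emitted.  Hits used by a sub-seed best chain
    are retired without emitting it, so overlapping chains resolve by score
    and then length.
    """
    ranked = genes if "rank" in genes.columns else rank_genes(genes)
    info = ranked.set_index("gene_id")[["scaffold", "rank"]]
    ks_col = pairs["ks"] if "ks" in pairs.columns else None

    by_pair: dict[tuple[str, str], list] = {}
    seen = set()
    for row_i, (a, b, ev) in enumerate(zip(pairs["gene_a"], pairs["gene_b"], pairs["evalue"])):
        if a == b or ev > evalue_cutoff:
            continue
        key = frozenset((a, b))
        if key in seen:
            continue
        seen.add(key)
        sa, ra = info.at[a, "scaffold"], int(info.at[a, "rank"])
        sb, rb = info.at[b, "scaffold"], int(info.at[b, "rank"])
        if (sb, rb, b) < (sa, ra, a):
            (a, sa, ra), (b, sb, rb) = (b, sb, rb), (a, sa, ra)
        ks = float(ks_col.iloc[row_i]) if ks_col is not None else np.nan
        by_pair.setdefault((sa, sb), []).append((ra, rb, (a, b, ks)))

    blocks: list[CollinearBlock] = []
    bid = 0
    for (sa, sb), hits in sorted(by_pair.items()):
        pool = list(hits)
        while pool:
            candidates = []
            for inverted in (False, True):
                res = _best_chain(pool, max_gap, match_reward, gap_penalty, inverted)
                if res is not None:
                    score, chain = res
                    candidates.append((score, len(chain), not inverted, chain))
            if not candidates:
                break
            score, length, is_par, chain = max(
                candidates, key=lambda c: (c[0], c[1], c[2])
            )
            chain_keys = set(id(k) for k in chain)
            pool = [h for h in pool if id(h[2]) not in chain_keys]
            if length >= seed_size:
                ks_vals = [k[2] for k in chain if np.isfinite(k[2])]
                blocks.append(
                    CollinearBlock(
                        block_id=bid,
                        scaffold_a=sa,
                        scaffold_b=sb,
                        orientation="parallel" if is_par else "inverted",
                        anchors=[(k[0], k[1]) for k in chain],
                        score=score,
                        median_ks=float(np.median(ks_vals)) if ks_vals else None,
                    )
                )
                bid += 1
    return blocks


# ---------------------------------------------------------------------------
# Pair classification and exports
# ---------------------------------------------------------------------------


def classify_duplicates(
    pairs: pd.DataFrame,
    blocks: list[CollinearBlock],
    genes: pd.DataFrame,
    tandem_rank_gap: int = 1,
) -> pd.DataFrame:
    """Label every homolog pair segmental_anchor / tandem / dispersed.

    Anchor pairs in co-linear blocks take precedence; non-anchor pairs on a
    single scaffold within ``tandem_rank_gap`` ranks are tandem; everything
    else is dispersed.
    """
    ranked = genes if "rank" in genes.columns else rank_genes(genes)
    info = ranked.set_index("gene_id")[["scaffold", "rank"]]
    anchor_keys = {frozenset(p) for b in blocks for p in b.anchors}
    labels = []
    for a, b in zip(pairs["gene_a"], pairs["gene_b"]):
        if frozenset((a, b)) in anchor_keys:
            labels.append("segmental_anchor")
            continue
        sa, sb = info.at[a, "scaffold"], info.at[b, "scaffold"]
        if sa == sb and abs(int(info.at[a, "rank"]) - int(info.at[b, "rank"])) <= tandem_rank_gap:
            labels.append("tandem")
        else:
            labels.append("dispersed")
    out = pairs.copy()
    out["classification"] = labels
    return out


def block_summary(blocks: list[CollinearBlock]) -> dict:
    """Topology tallies used by the signature decision framework."""
    topo = [b.topology for b in blocks]
    n = len(blocks)
    return {
        "n_blocks": n,
        "n_inter_scaffold": topo.count("inter_scaffold"),
        "n_tandem_array": topo.count("tandem_array"),
        "n_palindrome": topo.count("palindrome"),
        "inter_scaffold_fraction": (topo.count("inter_scaffold") / n) if n else 0.0,
        "n_anchor_pairs": sum(b.anchor_count for b in blocks),
    }


def macrosynteny_dotplot(
    pairs: pd.DataFrame,
    genes: pd.DataFrame,
    blocks: list[CollinearBlock] | None = None,
) -> pd.DataFrame:
    """Scaffold-concatenated scatter coordinates for every homolog pair.

    Scaffolds are laid end-to-end in deterministic order (descending length,
    then id); each pair becomes one row with the global bp midpoints of its
    two genes, anchors flagged.
    """
    ranked = genes if "rank" in genes.columns else rank_genes(genes)
    lengths = ranked.groupby("scaffold")["end"].max()
    order = sorted(lengths.index, key=lambda s: (-lengths[s], s))
    offset, cum = {}, 0
    for s in order:
        offset[s] = cum
        cum += int(lengths[s])
    info = ranked.set_index("gene_id")[["scaffold", "start", "end"]]
    anchor_keys = {frozenset(p) for b in (blocks or []) for p in b.anchors}
    rows = []
    for a, b in zip(pairs["gene_a"], pairs["gene_b"]):
        xa = offset[info.at[a, "scaffold"]] + (info.at[a, "start"] + info.at[a, "end"]) / 2
        yb = offset[info.at[b, "scaffold"]] + (info.at[b, "start"] + info.at[b, "end"]) / 2
        rows.append((a, b, xa, yb, frozenset((a, b)) in anchor_keys))
    return pd.DataFrame(rows, columns=["gene_a", "gene_b", "x", "y", "is_anchor"])


def block_link_table(blocks: list[CollinearBlock], genes: pd.DataFrame) -> pd.DataFrame:
    """Circos-style link table: the bp extent of both copies of every block."""
    info = genes.set_index("gene_id")
    rows = []
    for b in blocks:
        ext = []
        for side in (0, 1):
            members = [p[side] for p in b.anchors]
            scf = info.loc[members, "scaffold"].iloc[0]
            ext += [scf, int(info.loc[members, "start"].min()),
                    int(info.loc[members, "end"].max())]
        rows.append([b.block_id, b.topology] + ext)
    return pd.DataFrame(
        rows,
        columns=["block_id", "topology", "scaffold_a", "start_a", "end_a",
                 "scaffold_b", "start_b", "end_b"],
    )


def blocks_frame(blocks: list[CollinearBlock]) -> pd.DataFrame:
    rows = [
        (
            b.block_id, b.scaffold_a, b.scaffold_b, b.orientation, b.topology,
            b.anchor_count, b.score, b.median_ks,
        )
        for b in blocks
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "block_id", "scaffold_a", "scaffold_b", "orientation", "topology",
            "n_anchors", "score", "median_ks",
        ],
    )
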