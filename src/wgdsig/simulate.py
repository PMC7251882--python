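"""Synthetic genome-evolution generator.

Every downstream stage of the pipeline (paranome Ks distributions, co-linear
block chaining, the coverage test, and the duplication-loss + WGD count
model) is exercised against data produced here, where the ground truth is
known by construction:

* gene-family counts evolved along a dated species tree under a branch-wise
  linear birth-death process with optional WGD retention pulses,
* paranome Ks sets as a mixture of a decaying small-scale-duplication (SSD)
  background and Gaussian WGD pulses,
* genome layouts with planted co-linear blocks of chosen topology
  (inter-scaffold, tandem array, palindrome), and
* read-coverage tracks with half-depth haplotig segments.

All randomness flows from one user seed through ``numpy.random.SeedSequence``
spawning, so fixtures are reproducible and independent across stages.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .speciestree import DatedSpeciesTree, TreeError

__all__ = [
    "WgdHypothesis",
    "SimulatedFamilySet",
    "SyntheticGenomeLayout",
    "CoverageTrack",
    "simulate_family_counts",
    "replay_counts",
    "simulate_paranome_ks",
    "simulate_genome_layout",
    "simulate_coverage_track",
]


@dataclass(frozen=True)
class WgdHypothesis:
    """A hypothesized whole-genome duplication on a species-tree branch.

    ``age`` is measured in My before the branch's child node and must lie
    strictly inside the branch; ``q`` is the per-gene retention probability.
    """

    branch: str
    age: float
    q: float = 0.0
    name: str = ""

    def __post_init__(self):
        if not 0.0 <= self.q <= 1.0:
            raise ValueError(f"retention rate q={self.q} outside [0, 1]")
        if self.age <= 0:
            raise ValueError("WGD age must be positive")

    def validate_on(self, tree: DatedSpeciesTree) -> int:
        node = tree.node_by_label(self.branch)
        if not self.age < tree.length[node]:
            raise ValueError(
                f"WGD age {self.age} not strictly inside branch "
                f"{self.branch!r} of length {tree.length[node]}"
            )
        return node


@dataclass
class SimulatedFamilySet:
    """Realization of the DL+WGD generative model for many families.

    ``events`` holds one tuple ``(family, branch_label, time, kind, delta)``
    per event, where ``time`` is measured from the parent end of the branch
    and ``kind`` is ``dup``/``loss``/``wgd_retain``.  Replaying the log
    (:func:`replay_counts`) reproduces ``counts`` exactly.
    """

    counts: pd.DataFrame
    events: list[tuple]
    root_counts: np.ndarray
    seed: int


def _branch_rate_lookup(tree: DatedSpeciesTree, branch_rates):
    if isinstance(branch_rates, dict):
        table = {}
        for lbl, (lam, mu) in branch_rates.items():
            tree.node_by_label(lbl)
            table[lbl] = (float(lam), float(mu))
        missing = [
            tree.label[i]
            for i in range(tree.n_nodes)
            if i != tree.root and tree.label[i] not in table
        ]
        if missing:
            raise ValueError(f"branch_rates missing branches: {missing}")
        return table
    lam, mu = branch_rates
    return {tree.label[i]: (float(lam), float(mu)) for i in range(tree.n_nodes)}


def simulate_family_counts(
    tree: DatedSpeciesTree,
    branch_rates,
    wgds: list[WgdHypothesis] | None = None,
    root_prior_eta: float = 0.8,
    n_families: int = 1000,
    seed: int = 0,
) -> SimulatedFamilySet:
    """Simulate gene-family counts under the DL+WGD model.

    Each family starts with a geometric(eta) number of lineages at the root
    (support {1, 2, ...}, mean 1/eta).  Along every branch each lineage
    independently duplicates at rate lambda and is lost at rate mu (linear
    birth-death, exact Gillespie sampling).  At a WGD, every surviving
    lineage gains a retained extra copy with probability q.

    Parameters
    ----------
    branch_rates : (lam, mu) pair applied tree-wide, or dict branch-id -> (lam, mu)
    """
    wgds = list(wgds or [])
    if not 0.0 < root_prior_eta <= 1.0:
        raise ValueError("eta must lie in (0, 1]")
    if not tree.is_dated():
        raise TreeError("tree must be dated (positive branch lengths)")
    rates = _branch_rate_lookup(tree, branch_rates)
    if any(r < 0 for pair in rates.values() for r in pair):
        raise ValueError("rates must be non-negative")
    wgd_by_node: dict[int, list[WgdHypothesis]] = {}
    for w in wgds:
        node = w.validate_on(tree)
        wgd_by_node.setdefault(node, []).append(w)
    # order WGDs on a shared branch from the parent end downwards
    for node in wgd_by_node:
        wgd_by_node[node].sort(key=lambda w: -w.age)

    ss = np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss)
    root_counts = rng.geometric(root_prior_eta, size=n_families)

    order = tree.postorder()[::-1]  # preorder: parents first
    leaves = tree.leaves
    counts = np.zeros((n_families, len(leaves)), dtype=int)
    leaf_col = {node: j for j, node in enumerate(leaves)}
    events: list[tuple] = []

    for fam in range(n_families):
        node_count = {tree.root: int(root_counts[fam])}
        for node in order:
            if node == tree.root:
                continue
            lbl = tree.label[node]
            lam, mu = rates[lbl]
            t_total = tree.length[node]
            n = node_count[tree.parent[node]]
            # checkpoints: WGD times measured from the parent end
            checkpoints = [
                (t_total - w.age, w) for w in wgd_by_node.get(node, [])
            ] + [(t_total, None)]
            t = 0.0
            for t_stop, wgd in checkpoints:
                while n > 0:
                    total_rate = n * (lam + mu)
                    if total_rate == 0.0:
                        break
                    t_next = t + rng.exponential(1.0 / total_rate)
                    if t_next > t_stop:
                        break
                    t = t_next
                    if rng.random() < lam / (lam + mu):
                        n += 1
                        events.append((fam, lbl, t, "dup", +1))
                    else:
                        n -= 1
                        events.append((fam, lbl, t, "loss", -1))
                t = t_stop
                if wgd is not None and n > 0:
                    gained = int(rng.binomial(n, wgd.q))
                    if gained:
                        events.append((fam, lbl, t, "wgd_retain", gained))
                    n += gained
            node_count[node] = n
            if node in leaf_col:
                counts[fam, leaf_col[node]] = n

    df = pd.DataFrame(
        counts,
        index=[f"fam{f}" for f in range(n_families)],
        columns=[tree.label[i] for i in leaves],
    )
    return SimulatedFamilySet(
        counts=df, events=events, root_counts=root_counts, seed=seed
    )


def replay_counts(famset: SimulatedFamilySet, tree: DatedSpeciesTree) -> pd.DataFrame:
    """Recompute the leaf count matrix from the event log alone."""
    n_families = len(famset.root_counts)
    delta = np.zeros((n_families, tree.n_nodes), dtype=int)
    lbl_index = {lbl: i for i, lbl in enumerate(tree.label)}
    for fam, lbl, _t, _kind, d in famset.events:
        delta[fam, lbl_index[lbl]] += d
    node_counts = np.zeros((n_families, tree.n_nodes), dtype=int)
    for node in tree.postorder()[::-1]:
        if node == tree.root:
            node_counts[:, node] = famset.root_counts
        else:
            node_counts[:, node] = node_counts[:, tree.parent[node]] + delta[:, node]
    leaves = tree.leaves
    return pd.DataFrame(
        node_counts[:, leaves],
        index=famset.counts.index,
        columns=[tree.label[i] for i in leaves],
    )


# ---------------------------------------------------------------------------
# Paranome Ks mixtures
# ---------------------------------------------------------------------------

KS_MAX = 5.0


def simulate_paranome_ks(
    background_rate: float = 1.0,
    loss_hazard: float = 1.5,
    wgd_pulses: list[tuple[float, float, float]] | None = None,
    n_events: int = 5000,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw a synthetic node-weighted paranome Ks sample.

    The sample is a mixture of an SSD background whose density decays
    exponentially in Ks (duplicates are born continuously and survive with
    per-unit-Ks hazard ``loss_hazard``) and Gaussian WGD pulses truncated to
    (0, 5].  ``background_rate`` and each pulse's ``size`` are relative
    mixture weights.

    Returns ``(ks, weights)``; weights are 1 per event.
    """
    wgd_pulses = list(wgd_pulses or [])
    for mean, _sd, size in wgd_pulses:
        if not 0.0 < mean <= KS_MAX:
            raise ValueError(f"pulse mean {mean} outside (0, {KS_MAX}]")
        if size < 0:
            raise ValueError("pulse size must be >= 0")
    sizes = np.array([background_rate] + [p[2] for p in wgd_pulses], dtype=float)
    if background_rate < 0:
        raise ValueError("background_rate must be >= 0")
    if sizes.sum() <= 0:
        raise ValueError("all mixture component sizes are zero")

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    component_n = rng.multinomial(n_events, sizes / sizes.sum())
    draws = []
    if component_n[0] > 0:
        u = rng.random(component_n[0])
        if loss_hazard > 0:
            cdf_max = -np.expm1(-loss_hazard * KS_MAX)
            draws.append(-np.log1p(-u * cdf_max) / loss_hazard)
        else:
            draws.append(u * KS_MAX)
    for (mean, sd, _size), k in zip(wgd_pulses, component_n[1:]):
        if k == 0:
            continue
        a, b = (0.0 - mean) / sd, (KS_MAX - mean) / sd
        draws.append(
            stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=k, random_state=rng)
        )
    ks = np.concatenate(draws) if draws else np.empty(0)
    ks = np.clip(ks, np.nextafter(0.0, 1.0), KS_MAX)
    rng.shuffle(ks)
    return ks, np.ones_like(ks)


# ---------------------------------------------------------------------------
# Genome layouts with planted co-linear blocks
# ---------------------------------------------------------------------------

TOPOLOGIES = ("inter_scaffold", "tandem_array", "palindrome")


@dataclass
class SyntheticGenomeLayout:
    """Gene coordinates plus a ground-truth registry of planted features.

    ``genes``: gene_id, scaffold, start, end, strand, rank (per scaffold).
    ``pairs``: homolog pair list (gene_a, gene_b, evalue, bitscore, ks,
    true_class) -- exactly what a within-proteome similarity search would
    report for the planted features.
    ``blocks``: one row per planted anchor pair with block id and topology.
    """

    genes: pd.DataFrame
    pairs: pd.DataFrame
    blocks: pd.DataFrame
    scaffold_lengths: dict[str, int] = field(default_factory=dict)


class _SlotAllocator:
    """Hands out runs of consecutive gene slots, keeping planted features
    at least ``spacing`` ranks apart so they can never chain together."""

    def __init__(self, n_scaffolds: int, genes_per_scaffold: int, spacing: int):
        self.cursor = {f"scf{i + 1}": 0 for i in range(n_scaffolds)}
        self.cap = genes_per_scaffold
        self.spacing = spacing

    def scaffolds_with_room(self, k: int) -> list[str]:
        return [s for s, c in self.cursor.items() if c + k <= self.cap]

    def take(self, scaffold: str, k: int) -> list[int]:
        c = self.cursor[scaffold]
        if c + k > self.cap:
            raise ValueError("infeasible placement: scaffold capacity exceeded")
        self.cursor[scaffold] = c + k + self.spacing
        return list(range(c, c + k))


def simulate_genome_layout(
    n_scaffolds: int = 4,
    genes_per_scaffold: int = 400,
    planted_blocks: list[tuple[str, int, float]] | None = None,
    tandem_singletons: int = 0,
    dispersed_pairs: int = 0,
    seed: int = 0,
    background_ks_hazard: float = 1.0,
    anchor_ks_sd: float = 0.05,
    spacing: int = 45,
) -> SyntheticGenomeLayout:
    """Build a genome layout with planted duplicate structure.

    ``planted_blocks`` is a list of ``(topology, n_anchors, ks_mean)`` with
    topology one of ``inter_scaffold``, ``tandem_array``, ``palindrome``.
    Features are spaced > the relaxed chaining gap apart in rank space, so a
    chaining run recovers exactly the planted registry.
    """
    planted_blocks = list(planted_blocks or [])
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    alloc = _SlotAllocator(n_scaffolds, genes_per_scaffold, spacing)

    # slot -> (block assignments); gene ids assigned after layout is fixed
    anchor_rows = []  # (block_id, topology, scaffold_a, slot_a, scaffold_b, slot_b, inverted)
    for bid, (topology, k, ks_mean) in enumerate(planted_blocks):
        if topology not in TOPOLOGIES:
            raise ValueError(f"unknown topology {topology!r}")
        if k < 1:
            raise ValueError("block needs at least one anchor")
        if topology == "inter_scaffold":
            room = alloc.scaffolds_with_room(k)
            if len(room) < 2:
                raise ValueError("infeasible placement: need two scaffolds with room")
            sa, sb = rng.choice(room, size=2, replace=False)
            run_a, run_b = alloc.take(sa, k), alloc.take(sb, k)
            for i in range(k):
                anchor_rows.append((bid, topology, ks_mean, sa, run_a[i], sb, run_b[i], False))
        else:
            room = alloc.scaffolds_with_room(2 * k)
            if not room:
                raise ValueError("infeasible placement: no scaffold fits the block")
            s = rng.choice(room)
            run = alloc.take(s, 2 * k)
            for i in range(k):
                if topology == "tandem_array":
                    a, b = run[i], run[k + i]
                else:  # palindrome: second copy order-reversed
                    a, b = run[i], run[2 * k - 1 - i]
                anchor_rows.append((bid, topology, ks_mean, s, a, s, b, topology == "palindrome"))

    tandem_rows = []
    for _ in range(tandem_singletons):
        room = alloc.scaffolds_with_room(2)
        if not room:
            raise ValueError("infeasible placement for tandem singleton")
        s = rng.choice(room)
        a, b = alloc.take(s, 2)
        tandem_rows.append((s, a, s, b))

    dispersed_rows = []
    for _ in range(dispersed_pairs):
        room = alloc.scaffolds_with_room(1)
        if not room:
            raise ValueError("infeasible placement for dispersed pair")
        sa = rng.choice(room)
        a = alloc.take(sa, 1)[0]
        room = alloc.scaffolds_with_room(1)
        if not room:
            raise ValueError("infeasible placement for dispersed pair")
        sb = rng.choice(room)
        b = alloc.take(sb, 1)[0]
        dispersed_rows.append((sa, a, sb, b))

    # lay out every scaffold: coordinates 1-based closed, non-overlapping
    inverted_slots = {
        (row[5], row[6]) for row in anchor_rows if row[7]
    }  # second copies of palindromes get '-' strand
    gene_records = []
    gene_id = {}
    for s in alloc.cursor:
        pos = 1
        for slot in range(genes_per_scaffold):
            length = int(rng.integers(300, 1500))
            start, end = pos, pos + length - 1
            pos = end + 1 + int(rng.integers(200, 2000))
            gid = f"{s}_g{slot:04d}"
            strand = "-" if (s, slot) in inverted_slots else ("+" if rng.random() < 0.5 else "-")
            gene_records.append((gid, s, start, end, strand, slot))
            gene_id[(s, slot)] = gid
    genes = pd.DataFrame(
        gene_records, columns=["gene_id", "scaffold", "start", "end", "strand", "rank"]
    )
    scaffold_lengths = {
        s: int(genes.loc[genes.scaffold == s, "end"].max() + 1000) for s in alloc.cursor
    }

    def _ks_background(n):
        u = rng.random(n)
        cdf_max = -np.expm1(-background_ks_hazard * KS_MAX)
        return -np.log1p(-u * cdf_max) / background_ks_hazard

    pair_rows, block_rows = [], []
    for bid, topology, ks_mean, sa, a, sb, b, _inv in anchor_rows:
        ks = float(np.clip(rng.normal(ks_mean, anchor_ks_sd), 0.01, KS_MAX))
        ga, gb = gene_id[(sa, a)], gene_id[(sb, b)]
        pair_rows.append((ga, gb, 1e-50, 500.0, ks, "segmental_anchor"))
        block_rows.append((bid, topology, ga, gb, ks))
    for sa, a, sb, b in tandem_rows:
        ks = float(_ks_background(1)[0])
        pair_rows.append((gene_id[(sa, a)], gene_id[(sb, b)], 1e-30, 300.0, ks, "tandem"))
    for sa, a, sb, b in dispersed_rows:
        ks = float(_ks_background(1)[0])
        pair_rows.append((gene_id[(sa, a)], gene_id[(sb, b)], 1e-20, 200.0, ks, "dispersed"))

    pairs = pd.DataFrame(
        pair_rows, columns=["gene_a", "gene_b", "evalue", "bitscore", "ks", "true_class"]
    )
    blocks = pd.DataFrame(
        block_rows, columns=["block_id", "topology", "gene_a", "gene_b", "ks"]
    )
    return SyntheticGenomeLayout(
        genes=genes, pairs=pairs, blocks=blocks, scaffold_lengths=scaffold_lengths
    )


# ---------------------------------------------------------------------------
# Coverage tracks
# ---------------------------------------------------------------------------


@dataclass
class CoverageTrack:
    """Per-base integer read depth per scaffold, plus a haplotig registry."""

    depths: dict[str, np.ndarray]
    haplotigs: list[tuple[str, int, int, float]] = field(default_factory=list)

    def scaffold_length(self, scaffold: str) -> int:
        return len(self.depths[scaffold])


def _draw_depths(rng, n, mean, overdispersion):
    if overdispersion == 0.0:
        return np.full(n, int(round(mean)), dtype=np.int64)
    # negative binomial with var = m + alpha * m^2  (exceeds Poisson var)
    r = 1.0 / overdispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p, size=n)


def _windowed(rng, n, mean, overdispersion, window):
    n_win = int(np.ceil(n / window))
    draws = _draw_depths(rng, n_win, mean, overdispersion)
    return np.repeat(draws, window)[:n].astype(np.int32)


def simulate_coverage_track(
    scaffold_lengths: dict[str, int],
    base_depth: float = 100.0,
    overdispersion: float = 0.0,
    haplotig_segments: list[tuple[str, int, int, float]] | None = None,
    seed: int = 0,
    window: int = 1,
) -> CoverageTrack:
    """Simulate a per-base coverage track with optional haplotig segments.

    ``haplotig_segments`` entries are ``(scaffold, start, end, depth_fraction)``
    with 0-based half-open coordinates; inside a segment the mean depth is
    ``base_depth * depth_fraction``.  With ``overdispersion == 0`` depths are
    deterministic; otherwise they are negative-binomial with variance
    ``m + overdispersion * m**2``.  ``window`` > 1 draws one depth per
    fixed-size window (constant within it), which keeps run-length-encoded
    bedgraph exports compact; the track remains per-base indexed.
    """
    haplotig_segments = list(haplotig_segments or [])
    if any(l < 0 for l in scaffold_lengths.values()):
        raise ValueError("negative scaffold length")
    if window < 1:
        raise ValueError("window must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    depths = {
        s: _windowed(rng, n, base_depth, overdispersion, window)
        for s, n in scaffold_lengths.items()
    }
    for scf, start, end, frac in haplotig_segments:
        if not 0.0 < frac <= 1.0:
            raise ValueError("depth_fraction must be in (0, 1]")
        if scf not in depths or start < 0 or end > len(depths[scf]) or start >= end:
            raise ValueError(f"haplotig segment outside scaffold bounds: {scf}:{start}-{end}")
        depths[scf][start:end] = _windowed(
            rng, end - start, base_depth * frac, overdispersion, window
        )
    return CoverageTrack(depths=depths, haplotigs=haplotig_segments)
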