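"""Named synthetic scenario bundles.

Each scenario assembles generator outputs into the on-disk bundle the
pipeline consumes (GFF3 + tabular hits + per-pair Ks + bedgraph coverage,
or count matrix + dated tree + WGD hypotheses), with the statistical
structure of one of the archetypal duplication histories:

``wgd_like``
    a distinct paranome Ks peak (around Ks 0.8, as in a genome with a
    well-supported ancient WGD), anchor pairs clustered in that peak, and
    co-linear blocks residing on different scaffolds.
``segmental_burst``
    recent co-linear blocks, mostly intra-scaffold (palindromes and tandem
    arrays), whose anchor Ks values sit in the declining SSD background
    rather than in a distinct peak.
``ssd_only``
    the L-shaped distribution of continuous small-scale duplication, no
    co-linear blocks.
``haplotig``
    inter-scaffold blocks whose sequence coverage drops to half depth --
    uncollapsed haplotigs masquerading as segmental duplications.
``phylo``
    a 9-taxon dated tree with gene-family counts evolved under the DL+WGD
    model, for the reconciliation-surrogate stage.
"""

from __future__ import annotations

from pathlib import Path

import json

import numpy as np

from . import io as wio
from .simulate import (
    WgdHypothesis,
    simulate_coverage_track,
    simulate_family_counts,
    simulate_genome_layout,
    simulate_paranome_ks,
)
from .speciestree import balanced_dated_tree

GENOME_SCENARIOS = ("wgd_like", "segmental_burst", "ssd_only", "haplotig")
SCENARIOS = GENOME_SCENARIOS + ("phylo",)

#: default study conditions for the phylo scenario: tree-wide duplication
#: and loss rates of 0.002 events/gene lineage/My, geometric root prior
#: with eta = 0.8, 1000 families on a nine-taxon tree of ~350 My depth.
PHYLO_SPECIES = [
    "sp_dmel", "sp_bmor", "sp_tcas", "sp_amel", "sp_atum",
    "sp_cfel", "sp_phum", "sp_znev", "sp_fcan",
]
PHYLO_DEPTH_MY = 350.0
PHYLO_RATES = (0.002, 0.002)
PHYLO_ETA = 0.8
PHYLO_N_FAMILIES = 1000


def build_genome_scenario(name: str, seed: int = 0) -> dict:
    """Generator objects for one genome-bundle scenario."""
    if name == "wgd_like":
        ks, w = simulate_paranome_ks(
            background_rate=0.55, loss_hazard=1.5,
            wgd_pulses=[(0.8, 0.1, 0.45)], n_events=3000, seed=seed,
        )
        layout = simulate_genome_layout(
            n_scaffolds=10, genes_per_scaffold=250,
            planted_blocks=[("inter_scaffold", 6, 0.8)] * 6,
            tandem_singletons=4, dispersed_pairs=12, seed=seed + 1,
        )
        haplotigs = []
    elif name == "segmental_burst":
        ks, w = simulate_paranome_ks(
            background_rate=1.0, loss_hazard=1.5, wgd_pulses=[],
            n_events=3000, seed=seed,
        )
        layout = simulate_genome_layout(
            n_scaffolds=10, genes_per_scaffold=250,
            planted_blocks=[
                ("palindrome", 6, 0.2), ("palindrome", 5, 0.25),
                ("tandem_array", 5, 0.15), ("tandem_array", 6, 0.3),
                ("inter_scaffold", 5, 0.2),
            ],
            tandem_singletons=4, dispersed_pairs=12, seed=seed + 1,
        )
        haplotigs = []
    elif name == "ssd_only":
        ks, w = simulate_paranome_ks(
            background_rate=1.0, loss_hazard=1.5, wgd_pulses=[],
            n_events=3000, seed=seed,
        )
        layout = simulate_genome_layout(
            n_scaffolds=10, genes_per_scaffold=250, planted_blocks=[],
            tandem_singletons=6, dispersed_pairs=15, seed=seed + 1,
        )
        haplotigs = []
    elif name == "haplotig":
        ks, w = simulate_paranome_ks(
            background_rate=1.0, loss_hazard=1.5, wgd_pulses=[],
            n_events=3000, seed=seed,
        )
        layout = simulate_genome_layout(
            n_scaffolds=10, genes_per_scaffold=250,
            planted_blocks=[("inter_scaffold", 6, 0.1)] * 2,
            tandem_singletons=4, dispersed_pairs=12, seed=seed + 1,
        )
        haplotigs = _block_regions(layout, which=[0])
    else:
        raise ValueError(f"unknown genome scenario {name!r}")

    track = simulate_coverage_track(
        layout.scaffold_lengths, base_depth=100.0, overdispersion=0.05,
        haplotig_segments=haplotigs, seed=seed + 2, window=100,
    )
    return {"paranome_ks": ks, "paranome_weights": w, "layout": layout, "track": track}


def _block_regions(layout, which=None, depth_fraction=0.5):
    """Genomic extents (second copy) of planted blocks, as haplotig segments."""
    genes = layout.genes.set_index("gene_id")
    segs = []
    for bid, sub in layout.blocks.groupby("block_id"):
        if which is not None and bid not in which:
            continue
        members = sub["gene_b"]
        scf = genes.loc[members, "scaffold"].iloc[0]
        start = int(genes.loc[members, "start"].min()) - 1
        end = int(genes.loc[members, "end"].max())
        segs.append((scf, start, end, depth_fraction))
    return segs


def build_phylo_scenario(seed: int = 0, wgd_q: float | None = None) -> dict:
    """Counts + tree (+ optional planted WGD) for the DL+WGD stage."""
    tree = balanced_dated_tree(PHYLO_SPECIES, depth=PHYLO_DEPTH_MY)
    wgds = []
    if wgd_q is not None:
        branch = "sp_cfel"
        age = tree.length[tree.node_by_label(branch)] / 2.0
        wgds = [WgdHypothesis(branch=branch, age=age, q=wgd_q, name="wgd_test")]
    famset = simulate_family_counts(
        tree, PHYLO_RATES, wgds=wgds, root_prior_eta=PHYLO_ETA,
        n_families=PHYLO_N_FAMILIES, seed=seed,
    )
    return {"tree": tree, "famset": famset, "wgds": wgds}


def materialize(name: str, outdir, seed: int = 0) -> dict:
    """Write a named scenario bundle to disk; returns the file map."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if name == "phylo":
        sc = build_phylo_scenario(seed=seed, wgd_q=0.3)
        tree = sc["tree"]
        tree.write(outdir / "species_tree.nwk")
        wio.write_count_matrix(sc["famset"].counts, outdir / "counts.tsv")
        wgd_cfg = [
            {"branch": w.branch, "age": w.age, "name": w.name}
            for w in sc["wgds"]
        ]
        (outdir / "wgds.json").write_text(json.dumps(wgd_cfg, indent=1))
        return {
            "tree": str(outdir / "species_tree.nwk"),
            "counts": str(outdir / "counts.tsv"),
            "wgds": str(outdir / "wgds.json"),
        }
    if name not in GENOME_SCENARIOS:
        raise ValueError(f"unknown scenario {name!r}; choose from {SCENARIOS}")
    sc = build_genome_scenario(name, seed=seed)
    files = wio.write_layout_bundle(sc["layout"], outdir)
    np.savetxt(
        outdir / "paranome_ks.tsv",
        np.column_stack([sc["paranome_ks"], sc["paranome_weights"]]),
        delimiter="\t", header="ks\tweight", comments="",
    )
    wio.write_bedgraph(sc["track"], outdir / "coverage.bedgraph")
    files["paranome_ks"] = str(outdir / "paranome_ks.tsv")
    files["bedgraph"] = str(outdir / "coverage.bedgraph")
    return files
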