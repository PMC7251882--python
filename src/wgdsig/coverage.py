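"""Haplotig diagnostics from read-coverage resampling.

An apparent duplicated segment can be an assembly artefact: two haplotigs
(alternate haplotypes of one locus) that failed to collapse.  Such segments
show roughly half the background read depth.  The test compares each
block's mean per-base depth against the distribution of mean depths of
``n_random`` randomly sampled genome regions of the same length: a block
whose mean falls below the lower bound of the 95% confidence interval of
that distribution is flagged as a haplotig suspect.

The primary interval is the normal-assumption distributional CI
(mean +/- 1.96 sd of region means); the CI of the mean (sd/sqrt(n)) and the
empirical 2.5/97.5 percentiles are reported alongside for transparency.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .simulate import CoverageTrack


@dataclass
class CoverageVerdict:
    """Outcome of the resampling coverage test for one block region."""

    block_id: str
    scaffold: str
    start: int
    end: int
    block_mean: float
    background_mean: float
    ci_lower: float
    ci_upper: float
    sem_ci: tuple[float, float]
    empirical_ci: tuple[float, float]
    flag: str  # haplotig_suspect | normal


def _sample_contig_means(track, n_random, rng):
    names = sorted(track.depths)
    means_by_contig = np.array([track.depths[s].mean() for s in names])
    idx = rng.integers(0, len(names), size=n_random)
    return means_by_contig[idx]


def _sample_region_means(track, length, n_random, rng):
    eligible = {
        s: track.scaffold_length(s) - length
        for s in track.depths
        if track.scaffold_length(s) >= length
    }
    if not eligible:
        raise ValueError(f"block length {length} exceeds every scaffold")
    names = list(eligible)
    # scaffolds weighted by their number of eligible start positions
    weights = np.array([eligible[s] + 1 for s in names], dtype=float)
    weights /= weights.sum()
    means = np.empty(n_random)
    cum = {s: np.concatenate([[0], np.cumsum(track.depths[s])]) for s in names}
    choice = rng.choice(len(names), size=n_random, p=weights)
    for k, ci in enumerate(choice):
        s = names[ci]
        start = int(rng.integers(0, eligible[s] + 1))
        means[k] = (cum[s][start + length] - cum[s][start]) / length
    return means


def block_coverage_test(
    track: CoverageTrack,
    blocks: list[tuple[str, str, int, int]],
    n_random: int = 1000,
    seed: int = 0,
    mode: str = "regions",
) -> list[CoverageVerdict]:
    """Resampling coverage test for candidate duplicated regions.

    ``blocks`` entries are ``(block_id, scaffold, start, end)`` with 0-based
    half-open coordinates.  For every block, ``n_random`` same-length
    regions are sampled uniformly over start positions genome-wide (never
    crossing a scaffold end) and the block is flagged ``haplotig_suspect``
    when its mean depth falls below the lower bound of the 95% CI of the
    region-mean distribution.  ``mode='contigs'`` compares against the mean
    depths of randomly drawn whole contigs instead of length-matched
    regions (the coarser variant of the test).
    """
    if n_random < 100:
        raise ValueError("n_random must be at least 100")
    if mode not in ("regions", "contigs"):
        raise ValueError("mode must be 'regions' or 'contigs'")
    if not track.depths or all(len(d) == 0 for d in track.depths.values()):
        raise ValueError("empty coverage track")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    verdicts = []
    for block_id, scaffold, start, end in blocks:
        if scaffold not in track.depths or start < 0 or end > track.scaffold_length(scaffold) or start >= end:
            raise ValueError(f"block {block_id} outside track bounds")
        length = end - start
        block_mean = float(track.depths[scaffold][start:end].mean())
        if mode == "contigs":
            means = _sample_contig_means(track, n_random, rng)
        else:
            means = _sample_region_means(track, length, n_random, rng)
        bg_mean = float(means.mean())
        sd = float(means.std(ddof=1))
        lower, upper = bg_mean - 1.96 * sd, bg_mean + 1.96 * sd
        sem = sd / np.sqrt(n_random)
        emp = tuple(np.percentile(means, [2.5, 97.5]))
        verdicts.append(
            CoverageVerdict(
                block_id=block_id,
                scaffold=scaffold,
                start=start,
                end=end,
                block_mean=block_mean,
                background_mean=bg_mean,
                ci_lower=float(lower),
                ci_upper=float(upper),
                sem_ci=(float(bg_mean - 1.96 * sem), float(bg_mean + 1.96 * sem)),
                empirical_ci=(float(emp[0]), float(emp[1])),
                flag="haplotig_suspect" if block_mean < lower else "normal",
            )
        )
    return verdicts
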