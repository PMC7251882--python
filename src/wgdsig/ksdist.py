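"""Ks age distributions, peak detection and the WGD decision framework.

An ancient WGD leaves a distinct peak in the whole-paranome distribution of
node-weighted Ks values, coinciding with the Ks values of anchor pairs in
co-linear blocks that predominantly reside on different scaffolds.  A burst
of segmental duplication instead produces co-linear blocks whose anchor Ks
values are not clustered in a distinctive peak, or blocks that sit within
single scaffolds (tandem arrays, palindromes).  Continuous small-scale
duplication (SSD) alone produces the characteristic L-shaped distribution
with no interior peak and no blocks.  This module makes that qualitative
framework explicit: every threshold is a documented, configurable default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

KS_MAX = 5.0
#: peaks below this Ks are the L-shaped SSD boundary mode, never a WGD peak
BOUNDARY_EXCLUSION = 0.1


@dataclass
class KsHistogram:
    """Weighted histogram of duplication-event Ks values over (0, 5]."""

    bin_edges: np.ndarray
    counts: np.ndarray
    total_weight: float
    provenance: str = "whole-paranome"


def build_ks_histogram(
    ks: np.ndarray, weights: np.ndarray | None = None, bin_width: float = 0.1,
    provenance: str = "whole-paranome",
) -> KsHistogram:
    """Accumulate event weights (not pair counts) into fixed-width bins."""
    if bin_width <= 0:
        raise ValueError("bin width must be positive")
    ks = np.asarray(ks, dtype=float)
    weights = np.ones_like(ks) if weights is None else np.asarray(weights, dtype=float)
    n_bins = int(np.ceil(KS_MAX / bin_width))
    edges = np.arange(n_bins + 1) * bin_width
    # right-closed bins (0, w], (w, 2w], ... to match the (0, 5] filter
    idx = np.clip(np.ceil(ks / bin_width).astype(int) - 1, 0, n_bins - 1)
    counts = np.bincount(idx, weights=weights, minlength=n_bins)
    return KsHistogram(
        bin_edges=edges, counts=counts, total_weight=float(weights.sum()),
        provenance=provenance,
    )


@dataclass
class KsPeak:
    """A non-boundary mode in the Ks distribution."""

    location: float
    prominence: float
    mass_share: float
    interval: tuple[float, float]


def _weighted_silverman_bandwidth(ks, weights, floor):
    # total weight is the number of duplication events, which is the
    # relevant sample size; it is invariant under splitting an event's
    # weight across its contributing pairs
    n_events = weights.sum()
    mean = np.average(ks, weights=weights)
    sd = np.sqrt(np.average((ks - mean) ** 2, weights=weights))
    bw = 1.06 * sd * n_events ** (-1 / 5) if sd > 0 else floor
    return max(bw, floor)


def detect_ks_peaks(
    ks: np.ndarray,
    weights: np.ndarray | None = None,
    bandwidth: float | None = None,
    bandwidth_floor: float = 0.05,
    prominence_fraction: float = 0.1,
    boundary: float = BOUNDARY_EXCLUSION,
    min_total_weight: float = 200.0,
    grid_step: float = 0.005,
) -> list[KsPeak]:
    """Detect interior peaks in a weighted Ks sample.

    A Gaussian kernel density (Silverman bandwidth on the weighted sample,
    floored at 0.05 Ks) is evaluated on a fine grid; local maxima at
    Ks >= ``boundary`` with prominence at least ``prominence_fraction`` of
    the maximum interior density are reported, each with the weight share
    of events falling in its supporting interval (between the flanking
    density minima).  The boundary maximum at Ks -> 0 (the SSD L-shape) is
    never reported.
    """
    ks = np.asarray(ks, dtype=float)
    weights = np.ones_like(ks) if weights is None else np.asarray(weights, dtype=float)
    total = weights.sum()
    if total < min_total_weight:
        raise ValueError(
            f"insufficient events for peak detection: total weight {total:.1f} "
            f"< {min_total_weight}"
        )
    interior = ks >= boundary
    if not interior.any():
        return []
    bw = bandwidth if bandwidth is not None else _weighted_silverman_bandwidth(
        ks, weights, bandwidth_floor
    )
    grid = np.arange(0.0, KS_MAX + grid_step, grid_step)
    # weighted Gaussian KDE with reflection at Ks = 0, so the truncated
    # L-shaped SSD density keeps its boundary mode at 0 instead of being
    # smeared into a spurious interior maximum
    z = (grid[:, None] - ks[None, :]) / bw
    zr = (grid[:, None] + ks[None, :]) / bw
    dens = ((np.exp(-0.5 * z * z) + np.exp(-0.5 * zr * zr)) @ weights) / (
        total * bw * np.sqrt(2 * np.pi)
    )

    interior_mask = grid >= boundary
    max_interior = dens[interior_mask].max()
    if max_interior <= 0:
        return []
    idx, props = find_peaks(dens, prominence=prominence_fraction * max_interior)
    peaks = []
    for i, prom in zip(idx, props["prominences"]):
        loc = grid[i]
        if loc < boundary:
            continue
        # supporting interval: nearest density minima flanking the peak
        left = i
        while left > 0 and dens[left - 1] <= dens[left]:
            left -= 1
        right = i
        while right < len(dens) - 1 and dens[right + 1] <= dens[right]:
            right += 1
        lo, hi = grid[left], grid[right]
        mass = float(weights[(ks > lo) & (ks <= hi)].sum() / total)
        peaks.append(KsPeak(location=float(loc), prominence=float(prom),
                            mass_share=mass, interval=(float(lo), float(hi))))
    peaks.sort(key=lambda p: -p.prominence)
    return peaks


@dataclass
class SignatureVerdict:
    """Outcome of the duplication-signature decision framework."""

    label: str  # WGD_consistent | SSD_like | segmental_burst | inconclusive
    evidence: dict = field(default_factory=dict)


def assess_duplication_signature(
    paranome_peaks: list[KsPeak],
    anchor_ks: np.ndarray,
    anchor_weights: np.ndarray | None = None,
    n_blocks: int = 0,
    inter_scaffold_fraction: float = 0.0,
    anchor_concentration_threshold: float = 0.5,
    inter_scaffold_threshold: float = 0.5,
) -> SignatureVerdict:
    """Apply the WGD-vs-segmental-burst decision table.

    ``WGD_consistent`` requires (a) a non-boundary paranome peak, (b) at
    least ``anchor_concentration_threshold`` of the anchor-pair Ks mass
    inside that peak's supporting interval, and (c) at least
    ``inter_scaffold_threshold`` of the blocks on different scaffolds.
    ``segmental_burst``: blocks exist but (b) or (c) fails.  ``SSD_like``:
    no blocks and no peak.  Anything else is ``inconclusive``.
    """
    anchor_ks = np.asarray(anchor_ks, dtype=float)
    anchor_weights = (
        np.ones_like(anchor_ks) if anchor_weights is None
        else np.asarray(anchor_weights, dtype=float)
    )
    has_peak = len(paranome_peaks) > 0
    peak = paranome_peaks[0] if has_peak else None
    if has_peak and anchor_ks.size and anchor_weights.sum() > 0:
        lo, hi = peak.interval
        in_peak = (anchor_ks > lo) & (anchor_ks <= hi)
        anchor_conc = float(anchor_weights[in_peak].sum() / anchor_weights.sum())
    else:
        anchor_conc = 0.0
    anchors_clustered = has_peak and anchor_conc >= anchor_concentration_threshold
    inter_ok = inter_scaffold_fraction >= inter_scaffold_threshold

    evidence = {
        "has_interior_peak": has_peak,
        "peak_location": peak.location if peak else None,
        "anchor_peak_concentration": anchor_conc,
        "anchors_clustered_in_peak": anchors_clustered,
        "n_blocks": int(n_blocks),
        "inter_scaffold_fraction": float(inter_scaffold_fraction),
        "inter_scaffold_ok": inter_ok,
    }
    if n_blocks > 0:
        if has_peak and anchors_clustered and inter_ok:
            label = "WGD_consistent"
        else:
            label = "segmental_burst"
    else:
        label = "inconclusive" if has_peak else "SSD_like"
    return SignatureVerdict(label=label, evidence=evidence)
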