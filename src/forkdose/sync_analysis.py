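"""Analysis of synchronized-replication dosage profiles.

After a population-wide synchronized release, the dosage profile relative
to pre-initiation DNA is a two-plateau step per replichore: loci already
passed by the fork front sit at ``log2(1 + f)`` (``f`` = fraction of cells
that initiated) and loci beyond the front at 0.  Two quantities are read
off such a profile: the initiation fraction from the plateau height, and
the average fork position as the midpoint of the transition between the
replicated and unreplicated plateaus.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genome_profiles import (
    RIGHT,
    DosageProfile,
    GenomeMap,
    replichore_coordinate,
    rolling_average,
)
from .synthetic_data import VelocitySchedule


class NoTransitionError(ValueError):
    """No plateau-to-baseline transition is detectable in the profile."""


class InvertedProfileError(ValueError):
    """The origin-proximal region sits significantly below the distal one."""


@dataclass(frozen=True)
class SyncEstimate:
    replichore_id: str
    fork_position_mbp: float | None
    baseline_log2: float
    plateau_log2: float
    initiation_fraction: float


def _arm_track(profile, genome_map, replichore, window):
    """Smoothed (distance, value) track of one replichore, sorted by distance."""
    if window > 1:
        profile = rolling_average(profile, window)
    repl, dist = replichore_coordinate(profile.positions_bp, genome_map)
    sel = repl == replichore
    x, y = dist[sel], profile.log2_ratio[sel]
    order = np.argsort(x)
    return x[order], y[order]


def _plateau_baseline(x, y, proximal_region, distal_region, min_probes=20):
    if proximal_region is None:
        proximal_region = (x[0], x[int(0.1 * x.size)])
    if distal_region is None:
        distal_region = (x[int(0.9 * x.size) - 1], x[-1])
    prox = (x >= proximal_region[0]) & (x <= proximal_region[1])
    dist_sel = (x >= distal_region[0]) & (x <= distal_region[1])
    if prox.sum() < min_probes or dist_sel.sum() < min_probes:
        raise ValueError(
            f"proximal/distal regions need >= {min_probes} probes each"
        )
    plateau = float(np.median(y[prox]))
    baseline = float(np.median(y[dist_sel]))
    noise = float(np.std(y[dist_sel], ddof=1))
    return plateau, baseline, noise


def estimate_initiation_fraction(
    profile: DosageProfile,
    genome_map: GenomeMap,
    proximal_region: tuple | None = None,
    distal_region: tuple | None = None,
    replichore: str = RIGHT,
    window: int = 200,
) -> SyncEstimate:
    """Initiation fraction from the replicated-region plateau height.

    The baseline is the median smoothed log2 ratio over the distal
    (unreplicated) region and the plateau the median over the proximal
    (replicated) region; then ``f = 2**(plateau - baseline) - 1``, clipped
    to [0, 1].  Regions are (lo, hi) replichore distances in Mbp; defaults
    are the first and last 10% of the arm's probes.
    """
    x, y = _arm_track(profile, genome_map, replichore, window)
    plateau, baseline, noise = _plateau_baseline(
        x, y, proximal_region, distal_region
    )
    if plateau < baseline - 3.0 * noise:
        raise InvertedProfileError(
            "origin-proximal dosage below distal baseline (inverted profile)"
        )
    f = float(np.clip(2.0 ** (plateau - baseline) - 1.0, 0.0, 1.0))
    return SyncEstimate(replichore, None, baseline, plateau, f)


def estimate_fork_position(
    profile: DosageProfile,
    genome_map: GenomeMap,
    replichore: str = RIGHT,
    proximal_region: tuple | None = None,
    distal_region: tuple | None = None,
    window: int = 200,
) -> float:
    """Average fork position: the transition midpoint, in Mbp from oriC.

    Moving outward from oriC along the smoothed track, returns the first
    distance at which the log2 ratio crosses ``(baseline + plateau) / 2``,
    linearly interpolated between the flanking probes.
    """
    x, y = _arm_track(profile, genome_map, replichore, window)
    plateau, baseline, noise = _plateau_baseline(
        x, y, proximal_region, distal_region
    )
    if plateau - baseline <= 3.0 * noise:
        raise NoTransitionError(
            "no transition detected (plateau indistinguishable from baseline)"
        )
    level = 0.5 * (plateau + baseline)
    below = y < level
    if not below.any() or below[0]:
        raise NoTransitionError("no transition detected within probe coverage")
    i = int(np.argmax(below))  # first crossing moving away from oriC
    x0, x1 = x[i - 1], x[i]
    y0, y1 = y[i - 1], y[i]
    return float(x0 + (level - y0) / (y1 - y0) * (x1 - x0))


def analyze_sync_profile(
    profile: DosageProfile,
    genome_map: GenomeMap,
    replichore: str = RIGHT,
    window: int = 200,
) -> SyncEstimate:
    """Full per-replichore summary: plateau, baseline, f, fork position."""
    est = estimate_initiation_fraction(
        profile, genome_map, replichore=replichore, window=window
    )
    try:
        pos = estimate_fork_position(
            profile, genome_map, replichore=replichore, window=window
        )
    except NoTransitionError:
        pos = None
    return SyncEstimate(replichore, pos, est.baseline_log2, est.plateau_log2,
                        est.initiation_fraction)


def predicted_fork_position(
    velocity_schedule: VelocitySchedule,
    elapsed_min: float,
    replichore: str = RIGHT,
) -> float:
    """Fork position predicted by integrating a velocity schedule (Mbp)."""
    return velocity_schedule.front_position(elapsed_min, replichore)
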