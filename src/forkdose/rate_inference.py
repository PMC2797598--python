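"""Piecewise-linear fitting of asynchronous dosage profiles and conversion
of segment slopes to replication-fork velocities.

Under steady-state exponential growth the log2 gene dosage declines
linearly with replichore distance wherever fork velocity is constant, with
slope magnitude ``a = 1/(vT)`` (distance in Mbp, ``v`` in Mbp/min, mass
doubling time ``T`` in min).  Fitting straight segments between breakpoints
and inverting the slope therefore yields the local fork velocity:
``v = 1/(aT)``, reported in kb/min.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .genome_profiles import (
    LEFT,
    RIGHT,
    DosageProfile,
    GenomeMap,
    replichore_coordinate,
)
from .synthetic_data import GrowthLaw


class DataSufficiencyError(ValueError):
    """A segment contains too few probes (or no spatial extent) to fit."""


@dataclass(frozen=True)
class SegmentFit:
    """OLS fit of one dosage segment.

    ``slope`` is the positive magnitude of the log2 dosage decline per Mbp
    of replichore distance (the sign convention used for tabulated slopes);
    ``intercept`` is the fitted log2 ratio at the segment's oriC-proximal
    edge extrapolated to distance zero.
    """

    replichore_id: str
    start_mbp: float
    end_mbp: float
    slope: float
    slope_se: float
    intercept: float
    n_probes: int


@dataclass(frozen=True)
class VelocityEstimate:
    replichore_id: str
    start_mbp: float
    end_mbp: float
    velocity_kb_min: float
    velocity_se_kb_min: float


def _profile_to_arm_coords(profile: DosageProfile, genome_map: GenomeMap):
    repl, dist = replichore_coordinate(profile.positions_bp, genome_map)
    return repl, dist, profile.log2_ratio


def _ols_segment(x: np.ndarray, y: np.ndarray):
    if x.size < 2 or np.ptp(x) == 0:
        raise DataSufficiencyError("segment has no spatial extent")
    res = stats.linregress(x, y)
    return res.slope, res.stderr, res.intercept


def fit_segments(
    profile: DosageProfile,
    genome_map: GenomeMap,
    boundaries,
    continuity: str = "independent",
    min_probes: int = 10,
) -> list[SegmentFit]:
    """Fit piecewise-linear segments to a dosage profile per replichore.

    ``boundaries`` gives interior breakpoints as replichore distances in
    Mbp, either a single sequence applied to both arms (clipped to each
    arm's probe span) or a mapping ``{"left": [...], "right": [...]}``.
    ``continuity="independent"`` fits each segment by ordinary least
    squares; ``"continuous"`` fits a connected piecewise-linear function
    (hinge basis) forcing segments to meet at the breakpoints.
    """
    if continuity not in ("independent", "continuous"):
        raise ValueError(f"unknown continuity mode {continuity!r}")
    if isinstance(boundaries, dict):
        per_arm = {arm: sorted(float(b) for b in bs)
                   for arm, bs in boundaries.items()}
    else:
        bs = sorted(float(b) for b in boundaries)
        per_arm = {LEFT: bs, RIGHT: bs}

    repl, dist, values = _profile_to_arm_coords(profile, genome_map)
    fits: list[SegmentFit] = []
    for arm in (RIGHT, LEFT):
        sel = repl == arm
        if not np.any(sel) or arm not in per_arm:
            continue
        x, y = dist[sel], values[sel]
        order = np.argsort(x)
        x, y = x[order], y[order]
        interior = [b for b in per_arm[arm] if x.min() < b < x.max()]
        edges = [float(x.min())] + interior + [float(x.max())]
        if continuity == "independent":
            for lo, hi in zip(edges[:-1], edges[1:]):
                in_seg = (x >= lo) & (x <= hi)
                if in_seg.sum() < min_probes:
                    raise DataSufficiencyError(
                        f"segment [{lo:.3f}, {hi:.3f}] Mbp on the {arm} arm "
                        f"has {int(in_seg.sum())} probes (< {min_probes})"
                    )
                slope, se, icpt = _ols_segment(x[in_seg], y[in_seg])
                fits.append(SegmentFit(arm, lo, hi, -slope, se, icpt,
                                       int(in_seg.sum())))
        else:
            fits.extend(
                _fit_continuous(arm, x, y, interior, edges, min_probes)
            )
    return fits


def _fit_continuous(arm, x, y, interior, edges, min_probes):
    """Connected piecewise-linear OLS via a hinge (broken-stick) basis."""
    for lo, hi in zip(edges[:-1], edges[1:]):
        n_seg = int(((x >= lo) & (x <= hi)).sum())
        if n_seg < min_probes:
            raise DataSufficiencyError(
                f"segment [{lo:.3f}, {hi:.3f}] Mbp on the {arm} arm "
                f"has {n_seg} probes (< {min_probes})"
            )
    design = [np.ones_like(x), x]
    for b in interior:
        design.append(np.clip(x - b, 0.0, None))
    X = np.column_stack(design)
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    dof = max(x.size - X.shape[1], 1)
    sigma2 = float(resid @ resid) / dof
    cov = sigma2 * np.linalg.inv(X.T @ X)
    fits = []
    for i, (lo, hi) in enumerate(zip(edges[:-1], edges[1:])):
        # slope of segment i = beta_1 + sum of hinge coefficients up to i
        contrast = np.zeros(X.shape[1])
        contrast[1] = 1.0
        contrast[2 : 2 + i] = 1.0
        slope = float(contrast @ beta)
        se = float(np.sqrt(contrast @ cov @ contrast))
        in_seg = (x >= lo) & (x <= hi)
        # intercept of the fitted line over this segment, extrapolated to 0
        icpt = float(beta[0] - sum(beta[2 + j] * interior[j] for j in range(i)))
        fits.append(SegmentFit(arm, lo, hi, -slope, se, icpt, int(in_seg.sum())))
    return fits


# ---------------------------------------------------------------------------
# Changepoint detection
# ---------------------------------------------------------------------------

def detect_changepoints(
    profile: DosageProfile,
    genome_map: GenomeMap,
    penalty: float | None = None,
    min_segment_probes: int = 50,
    replichore: str = RIGHT,
) -> list[float]:
    """Locate slope changepoints on one replichore.

    The dosage track is continuous, so a slope change is a knot of a
    connected piecewise-linear (broken-stick) function rather than a jump.
    Breakpoints are found by forward knot selection: starting from a single
    straight line, the knot position whose hinge term most reduces the
    residual sum of squares is added, and the search stops when the best
    remaining reduction falls below ``penalty``.  Each accepted knot's
    position is then re-optimized given the others.  The default penalty is
    BIC-style, ``3 * sigma^2 * ln n``, with the noise variance estimated
    robustly from first differences (each knot spends ~3 parameters:
    position, slope change, and the maximization over candidate
    positions).  Candidate knots keep ``min_segment_probes`` probes on
    each side of every breakpoint.  Returns interior breakpoint positions
    as replichore distances (Mbp).
    """
    repl, dist, values = _profile_to_arm_coords(profile, genome_map)
    sel = repl == replichore
    x, y = dist[sel], values[sel]
    order = np.argsort(x)
    x, y = x[order], y[order]
    n = x.size
    if n < 2 * min_segment_probes:
        raise DataSufficiencyError(
            f"need at least {2 * min_segment_probes} probes, got {n}"
        )
    if penalty is None:
        sigma = 1.4826 * np.median(np.abs(np.diff(y))) / np.sqrt(2.0)
        penalty = 3.0 * sigma**2 * np.log(n)
    if penalty <= 0:
        raise ValueError("penalty must be positive")

    def hinges(knots):
        return [np.clip(x - b, 0.0, None) for b in knots]

    def candidates(knots):
        ok = np.ones(n, dtype=bool)
        ok[: min_segment_probes] = False
        ok[n - min_segment_probes :] = False
        for b in knots:
            k = int(np.searchsorted(x, b))
            ok[max(0, k - min_segment_probes) : k + min_segment_probes] = False
        return x[ok]

    def best_knot(knots, cand):
        """RSS reduction of each candidate hinge, given the current knots."""
        X0 = np.column_stack([np.ones_like(x), x] + hinges(knots))
        Q, _ = np.linalg.qr(X0)
        r = y - Q @ (Q.T @ y)
        H = np.clip(x[:, None] - cand[None, :], 0.0, None)
        Ht = H - Q @ (Q.T @ H)
        num = Ht.T @ r
        den = np.einsum("ij,ij->j", Ht, Ht)
        with np.errstate(divide="ignore", invalid="ignore"):
            gain = np.where(den > 1e-12, num**2 / np.maximum(den, 1e-300), 0.0)
        k = int(np.argmax(gain))
        return float(cand[k]), float(gain[k])

    knots: list[float] = []
    max_knots = n // min_segment_probes
    while len(knots) < max_knots:
        cand = candidates(knots)
        if cand.size == 0:
            break
        b, gain = best_knot(knots, cand)
        if gain <= penalty:
            break
        knots = sorted(knots + [b])
        # re-optimize each knot given the others: greedy placement of an
        # early knot between two true kinks would otherwise force extras
        for _ in range(2):
            for i in range(len(knots)):
                others = knots[:i] + knots[i + 1 :]
                cand_i = candidates(others)
                if cand_i.size:
                    knots[i], _ = best_knot(others, cand_i)
            knots.sort()
    if knots:
        knots = _refine_knots(x, y, knots)
        # backward elimination: drop knots whose hinge no longer earns the
        # penalty, then re-refine
        while knots:
            gains = []
            for i in range(len(knots)):
                others = knots[:i] + knots[i + 1 :]
                _, gain = best_knot(others, np.array([knots[i]]))
                gains.append(gain)
            worst = int(np.argmin(gains))
            if gains[worst] > penalty:
                break
            del knots[worst]
            if knots:
                knots = _refine_knots(x, y, knots)
    return knots


def _refine_knots(x, y, knots):
    """Jointly re-optimize knot positions by derivative-free least squares.

    Forward selection places knots on the candidate grid one at a time,
    which biases close pairs; a joint continuous refinement around the
    greedy solution removes that bias.
    """
    from scipy.optimize import minimize

    lo, hi = float(x[0]), float(x[-1])

    def rss(b):
        b = np.clip(np.sort(b), lo, hi)
        X = np.column_stack(
            [np.ones_like(x), x] + [np.clip(x - bi, 0.0, None) for bi in b]
        )
        beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
        r = y - X @ beta
        return float(r @ r)

    res = minimize(rss, np.asarray(knots), method="Nelder-Mead",
                   options={"xatol": 1e-5, "fatol": 1e-10, "maxiter": 2000})
    return sorted(float(b) for b in np.clip(res.x, lo, hi))


# ---------------------------------------------------------------------------
# Velocities and comparisons
# ---------------------------------------------------------------------------

def velocity_from_slope(fit: SegmentFit, growth: GrowthLaw) -> VelocityEstimate:
    """Convert a dosage slope to a fork velocity: v = 1/(aT), in kb/min.

    The standard error is propagated by the delta method,
    ``SE(v) = v * SE(a)/a``.
    """
    a = fit.slope
    if a <= 0:
        raise ValueError("non-declining dosage; velocity undefined")
    T = growth.doubling_time_min
    v_kb = 1000.0 / (a * T)
    se_kb = v_kb * fit.slope_se / a
    return VelocityEstimate(fit.replichore_id, fit.start_mbp, fit.end_mbp,
                            v_kb, se_kb)


def percent_speed_change(fit_test: SegmentFit, fit_reference: SegmentFit) -> float:
    """Percent fork-speed decrease of the test segment vs the reference.

    Velocity is inversely proportional to slope (the doubling time
    cancels), so the decrease is ``100 * (1 - a_ref / a_test)``.
    """
    if fit_test.slope <= 0 or fit_reference.slope <= 0:
        raise ValueError("speed change undefined for non-positive slopes")
    return 100.0 * (1.0 - fit_reference.slope / fit_test.slope)


def stall_segments(
    fits: list[SegmentFit], fold_threshold: float = 2.0
) -> list[SegmentFit]:
    """Flag segments whose slope exceeds ``fold_threshold`` times the
    median slope of the *other* segments on the same replichore —
    candidate sites where fork progression is strongly impeded or stalled.
    """
    flagged = []
    arms = {f.replichore_id for f in fits}
    for arm in arms:
        arm_fits = [f for f in fits if f.replichore_id == arm]
        if len(arm_fits) < 2:
            continue
        for f in arm_fits:
            others = [g.slope for g in arm_fits if g is not f]
            if f.slope > fold_threshold * float(np.median(others)):
                flagged.append(f)
    return flagged
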