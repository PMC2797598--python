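"""Generative models for replication-profiling data.

The raw measurements this package analyzes — asynchronous and synchronized
gene-dosage microarray tracks, fluctuation-assay mutant counts, growth
curves and head-to-head competitions — are emulated here from explicit
parametric models, so every estimator can be validated against a generator
whose ground truth is known.

The asynchronous model
----------------------
In a steady-state exponentially growing population with mass doubling time
``T``, the population gene dosage at chromosome position ``x`` (distance
from *oriC* along a replichore) is time-invariant up to overall exponential
growth.  If forks travel at a position-dependent speed ``v(x)``, the time
for a fork to reach ``x`` is ``t(x) = integral_0^x ds / v(s)`` and the log2
dosage relative to the origin is

    g(x) = -t(x) / T

so that a segment of constant velocity ``v`` (Mbp/min) appears as a
straight line of slope magnitude ``1/(vT)`` per Mbp.  The synchronized
model is a two-plateau step: a fraction ``f_init`` of cells initiated at
release, giving dosage ``1 + f_init`` behind the fork front and ``1``
beyond it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome_profiles import (
    LEFT,
    RIGHT,
    DosageProfile,
    GenomeMap,
    replichore_coordinate,
)


class ScheduleError(ValueError):
    """A velocity schedule does not cover the requested time interval."""


# ---------------------------------------------------------------------------
# Velocity fields and growth law
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SegmentedVelocity:
    """Piecewise-constant fork velocity along one replichore.

    ``breakpoints_mbp`` are the interior segment boundaries (strictly
    increasing, Mbp from oriC); ``velocities_kb_min`` has one entry per
    segment, i.e. ``len(breakpoints) + 1`` values.  The last segment
    extends to the end of the replichore.
    """

    breakpoints_mbp: tuple
    velocities_kb_min: tuple

    def __post_init__(self) -> None:
        bp = tuple(float(b) for b in self.breakpoints_mbp)
        v = tuple(float(x) for x in self.velocities_kb_min)
        if len(v) != len(bp) + 1:
            raise ValueError("need len(velocities) == len(breakpoints) + 1")
        if any(x <= 0 for x in v):
            raise ValueError("velocities must be positive")
        if any(b2 <= b1 for b1, b2 in zip(bp, bp[1:])) or (bp and bp[0] <= 0):
            raise ValueError("breakpoints must be positive and strictly increasing")
        object.__setattr__(self, "breakpoints_mbp", bp)
        object.__setattr__(self, "velocities_kb_min", v)

    @classmethod
    def uniform(cls, velocity_kb_min: float) -> "SegmentedVelocity":
        return cls((), (velocity_kb_min,))

    def velocity_at(self, x_mbp) -> np.ndarray:
        idx = np.searchsorted(self.breakpoints_mbp, np.asarray(x_mbp, dtype=float),
                              side="right")
        return np.asarray(self.velocities_kb_min)[idx]

    def time_to(self, x_mbp) -> np.ndarray:
        """Fork travel time (minutes) from oriC to ``x_mbp``."""
        x = np.atleast_1d(np.asarray(x_mbp, dtype=float))
        if np.any(x < 0):
            raise ValueError("replichore distance must be non-negative")
        edges = np.concatenate(([0.0], self.breakpoints_mbp, [np.inf]))
        v = np.asarray(self.velocities_kb_min) / 1000.0  # Mbp/min
        t = np.zeros_like(x)
        for lo, hi, vi in zip(edges[:-1], edges[1:], v):
            span = np.clip(x, lo, hi) - lo
            t += np.where(span > 0, span / vi, 0.0)
        return t if np.ndim(x_mbp) else float(t[0])

    def advance(self, x_mbp: float, dt_min: float) -> float:
        """Position reached after travelling ``dt_min`` starting at ``x_mbp``."""
        x, dt = float(x_mbp), float(dt_min)
        edges = list(self.breakpoints_mbp) + [np.inf]
        while dt > 0:
            idx = int(np.searchsorted(self.breakpoints_mbp, x, side="right"))
            v = self.velocities_kb_min[idx] / 1000.0
            t_to_edge = (edges[idx] - x) / v
            if t_to_edge >= dt:
                return x + dt * v
            x, dt = edges[idx], dt - t_to_edge
        return x


@dataclass(frozen=True)
class VelocityProfile:
    """Fork velocity field for both replichores."""

    left: SegmentedVelocity
    right: SegmentedVelocity

    @classmethod
    def uniform(cls, velocity_kb_min: float) -> "VelocityProfile":
        sv = SegmentedVelocity.uniform(velocity_kb_min)
        return cls(sv, sv)

    def arm(self, replichore_id: str) -> SegmentedVelocity:
        if replichore_id == LEFT:
            return self.left
        if replichore_id == RIGHT:
            return self.right
        raise ValueError(f"unknown replichore {replichore_id!r}")


@dataclass(frozen=True)
class GrowthLaw:
    """Exponential growth: N(t) = N(0) * 2**(t/T), T in minutes."""

    doubling_time_min: float

    def __post_init__(self) -> None:
        if self.doubling_time_min <= 0:
            raise ValueError("doubling time must be positive")


@dataclass(frozen=True)
class VelocitySchedule:
    """Time-resolved velocity field: list of (start_min, end_min, profile).

    Phases must be contiguous and non-overlapping; used for protocols in
    which the velocity field changes during the experiment (e.g. rifampicin
    addition a few minutes after synchronized release).
    """

    phases: tuple  # of (start_min, end_min, VelocityProfile)

    def __post_init__(self) -> None:
        phases = tuple(
            (float(s), float(e), p) for s, e, p in self.phases
        )
        if not phases:
            raise ScheduleError("schedule has no phases")
        for s, e, _ in phases:
            if e <= s:
                raise ScheduleError("phase end must exceed start")
        for (_, e1, _), (s2, _, _) in zip(phases, phases[1:]):
            if abs(s2 - e1) > 1e-9:
                raise ScheduleError("phases must be contiguous")
        object.__setattr__(self, "phases", phases)

    @classmethod
    def constant(cls, profile: VelocityProfile, until_min: float) -> "VelocitySchedule":
        return cls(((0.0, until_min, profile),))

    def front_position(self, elapsed_min: float, replichore_id: str = RIGHT) -> float:
        """Distance (Mbp) travelled by a fork released at t = 0."""
        if elapsed_min < 0:
            raise ScheduleError("elapsed time must be non-negative")
        if self.phases[0][0] > 0 or self.phases[-1][1] < elapsed_min - 1e-9:
            raise ScheduleError(
                f"schedule does not cover [0, {elapsed_min}] min"
            )
        x = 0.0
        for start, end, profile in self.phases:
            if start >= elapsed_min:
                break
            x = profile.arm(replichore_id).advance(x, min(end, elapsed_min) - start)
        return x


# ---------------------------------------------------------------------------
# Asynchronous (steady-state) profiles
# ---------------------------------------------------------------------------

def expected_async_profile(
    velocity: VelocityProfile,
    growth: GrowthLaw,
    genome_map: GenomeMap,
    probe_positions_bp,
    metadata: dict | None = None,
) -> DosageProfile:
    """Noise-free steady-state log2 dosage profile: g(x) = -t(x)/T.

    ``t(x)`` is the fork travel time to each probe's replichore distance and
    ``T`` the mass doubling time; the intercept is fixed by g(oriC) = 0.
    """
    pos = np.asarray(probe_positions_bp, dtype=np.int64)
    repl, dist = replichore_coordinate(pos, genome_map)
    g = np.empty(pos.shape, dtype=float)
    for arm in (LEFT, RIGHT):
        sel = repl == arm
        if np.any(sel):
            g[sel] = -velocity.arm(arm).time_to(dist[sel]) / growth.doubling_time_min
    meta = dict(metadata or {}, doubling_time_min=growth.doubling_time_min)
    return DosageProfile(pos, g, meta)


def sample_async_profile(
    velocity: VelocityProfile,
    growth: GrowthLaw,
    genome_map: GenomeMap,
    probe_positions_bp,
    noise_sd: float = 0.05,
    mode: str = "probe_noise",
    n_cells: int = 10_000,
    seed=None,
) -> DosageProfile:
    """Sample a noisy asynchronous profile.

    ``probe_noise`` adds i.i.d. Gaussian noise (sd ``noise_sd``, log2 units)
    to the closed-form expectation — an aCGH-like measurement-noise model.

    ``cell_sampling`` simulates the population explicitly: each of
    ``n_cells`` cells carries replication initiations at past times
    ``(phi + j) * T`` for j = 0, 1, 2, ..., with the cell-cycle phase
    ``phi`` drawn from the exponential-growth age density
    ``(2 ln 2) * 2**(-phi)`` on [0, 1).  A locus at fork travel time
    ``t(x)`` has been passed by every initiation of age >= t(x), and each
    passage doubles its copy number.  The per-probe population mean copy
    number, normalized to oriC, is returned in log2; it converges to the
    closed form as ``n_cells`` grows.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    rng = np.random.default_rng(seed)
    expected = expected_async_profile(velocity, growth, genome_map,
                                      probe_positions_bp)
    if mode == "probe_noise":
        noisy = expected.log2_ratio + rng.normal(0.0, noise_sd, len(expected))
        return DosageProfile(expected.positions_bp, noisy, dict(expected.metadata))
    if mode != "cell_sampling":
        raise ValueError(f"unknown mode {mode!r}")
    if n_cells < 100:
        raise ValueError("cell_sampling needs n_cells >= 100")
    # tau = t(x)/T in doublings; per-cell copy number relative to oriC is
    # 2**(-ceil(max(0, tau - phi))): initiations older than t(x) have passed x.
    tau = -expected.log2_ratio  # t(x)/T, >= 0
    u = rng.random(n_cells)
    phi = -np.log2(1.0 - u / 2.0)  # inverse CDF of (2 ln2) 2^-phi on [0,1)
    n_int = np.floor(tau).astype(int)
    frac = tau - n_int
    # copy factor is 2^-(n+1) for cells with phi < frac, else 2^-n
    phi_sorted = np.sort(phi)
    n_below = np.searchsorted(phi_sorted, frac, side="left")
    mean_rel = 2.0 ** (-n_int.astype(float)) * (
        (n_cells - n_below) + 0.5 * n_below
    ) / n_cells
    # exact-integer tau has frac == 0: all cells contribute 2^-n, consistent
    g = np.log2(mean_rel)
    if noise_sd > 0:
        g = g + rng.normal(0.0, noise_sd, g.size)
    return DosageProfile(expected.positions_bp, g, dict(expected.metadata))


# ---------------------------------------------------------------------------
# Synchronized-release profiles
# ---------------------------------------------------------------------------

def expected_sync_profile(
    velocity_schedule: VelocitySchedule,
    f_init: float,
    elapsed_min: float,
    genome_map: GenomeMap,
    probe_positions_bp,
    metadata: dict | None = None,
) -> DosageProfile:
    """Two-plateau profile after synchronized release.

    A fraction ``f_init`` of cells initiate at t = 0; sampling at
    ``elapsed_min`` relative to pre-initiation DNA gives dosage
    ``1 + f_init`` at loci the fork front has passed and 1 beyond it.
    The front position per replichore is the time integral of the
    velocity schedule.
    """
    if not 0.0 <= f_init <= 1.0:
        raise ValueError("f_init must be in [0, 1]")
    pos = np.asarray(probe_positions_bp, dtype=np.int64)
    repl, dist = replichore_coordinate(pos, genome_map)
    g = np.zeros(pos.shape, dtype=float)
    plateau = np.log2(1.0 + f_init)
    for arm in (LEFT, RIGHT):
        sel = repl == arm
        if np.any(sel):
            front = velocity_schedule.front_position(elapsed_min, arm)
            g[sel] = np.where(dist[sel] <= front, plateau, 0.0)
    meta = dict(metadata or {}, f_init=f_init, elapsed_min=elapsed_min)
    return DosageProfile(pos, g, meta)


def sample_sync_profile(
    velocity_schedule: VelocitySchedule,
    f_init: float,
    elapsed_min: float,
    genome_map: GenomeMap,
    probe_positions_bp,
    noise_sd: float = 0.1,
    seed=None,
) -> DosageProfile:
    """Synchronized profile with i.i.d. Gaussian probe noise."""
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    rng = np.random.default_rng(seed)
    expected = expected_sync_profile(
        velocity_schedule, f_init, elapsed_min, genome_map, probe_positions_bp
    )
    noisy = expected.log2_ratio + rng.normal(0.0, noise_sd, len(expected))
    return DosageProfile(expected.positions_bp, noisy, dict(expected.metadata))


# ---------------------------------------------------------------------------
# Fluctuation assays
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FluctuationAssay:
    """Mutant counts from parallel cultures grown N0 -> Nt cells each."""

    mutant_counts: tuple
    Nt: float
    N0: float = 1.0

    def __post_init__(self) -> None:
        counts = tuple(int(c) for c in self.mutant_counts)
        if any(c < 0 for c in counts):
            raise ValueError("mutant counts must be non-negative")
        if not self.Nt > self.N0 >= 1:
            raise ValueError("require Nt > N0 >= 1")
        object.__setattr__(self, "mutant_counts", counts)

    @property
    def n_cultures(self) -> int:
        return len(self.mutant_counts)

    @property
    def n_zero(self) -> int:
        return sum(1 for c in self.mutant_counts if c == 0)


def simulate_fluctuation_assay(
    mutation_rate: float,
    N0: float,
    Nt: float,
    n_cultures: int,
    seed=None,
) -> FluctuationAssay:
    """Luria-Delbrueck sampler with discrete generations (Lea-Coulson style).

    Each culture grows N0 -> Nt by doubling (the last generation may be
    partial when Nt/N0 is not a power of 2); in generation k the
    ``N_k - N_{k-1}`` new cells each mutate with probability
    ``mutation_rate``, and a mutation founds a clone that expands with the
    rest of the culture to final size ``~ Nt / N_k``.  Mutation
    opportunities total exactly ``Nt - N0``, so the zero-mutant probability
    is ``exp(-mu * (Nt - N0))``.  With rate 0 all counts are exactly zero.
    """
    if mutation_rate < 0:
        raise ValueError("mutation rate must be non-negative")
    generations = int(np.ceil(np.log2(Nt / N0)))
    if generations < 1:
        raise ValueError("Nt must exceed N0 by at least one doubling")
    if mutation_rate * Nt >= 10:
        warnings.warn(
            "mu * Nt >= 10: expect P0 ~ 0, outside the P0 method's regime",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    counts = np.zeros(n_cultures, dtype=np.int64)
    if mutation_rate > 0:
        n_prev = float(N0)
        for k in range(1, generations + 1):
            n_k = min(N0 * 2.0**k, float(Nt))
            muts = rng.poisson(mutation_rate * (n_k - n_prev), n_cultures)
            clone_size = max(1, int(round(Nt / n_k)))
            counts += muts * clone_size
            n_prev = n_k
    return FluctuationAssay(tuple(counts.tolist()), Nt=Nt, N0=N0)


# ---------------------------------------------------------------------------
# Competitions and growth curves
# ---------------------------------------------------------------------------

def simulate_competition(
    true_W: float,
    generations_ref: float = 10.0,
    N0_each: float = 1e6,
    count_noise_cv: float = 0.02,
    seed=None,
) -> pd.DataFrame:
    """Head-to-head competition between a test and a reference strain.

    The reference expands by ``generations_ref`` doublings; the test strain,
    with relative fitness ``true_W`` (ratio of Malthusian parameters),
    expands by ``true_W * generations_ref`` doublings.  Final counts carry
    multiplicative lognormal noise with coefficient of variation
    ``count_noise_cv`` (mean-one).
    """
    if true_W <= 0:
        raise ValueError("true_W must be positive")
    rng = np.random.default_rng(seed)
    final_ref = N0_each * 2.0 ** generations_ref
    final_test = N0_each * 2.0 ** (true_W * generations_ref)
    if count_noise_cv > 0:
        sigma = np.sqrt(np.log1p(count_noise_cv**2))
        noise = rng.lognormal(-(sigma**2) / 2.0, sigma, size=2)
        final_test *= noise[0]
        final_ref *= noise[1]
    return pd.DataFrame(
        {
            "strain": ["test", "reference"],
            "initial_count": [N0_each, N0_each],
            "final_count": [final_test, final_ref],
        }
    )


def simulate_growth_curve(
    doubling_time_min: float,
    od_start: float = 0.05,
    duration_min: float = 240.0,
    interval_min: float = 20.0,
    noise_cv: float = 0.0,
    seed=None,
):
    """Exponential OD600 time series with multiplicative lognormal noise."""
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, duration_min + 0.5 * interval_min, interval_min)
    od = od_start * 2.0 ** (t / doubling_time_min)
    if noise_cv > 0:
        sigma = np.sqrt(np.log1p(noise_cv**2))
        od = od * rng.lognormal(-(sigma**2) / 2.0, sigma, t.size)
    return t, od
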