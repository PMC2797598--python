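"""Mutation-rate estimation (P0 fluctuation method), growth-rate
extraction, the multiplicative fitness null model, and competition-based
relative fitness.

The P0 method uses only the fraction of parallel cultures with zero
mutants: if mutations arise at rate ``mu`` per cell per division, the
number of mutation events per culture is Poisson with mean
``m = mu * (Nt - N0)``, so ``P0 = exp(-m)`` and
``m = -ln(P0_hat)``, ``rate = m / Nt``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

from .synthetic_data import FluctuationAssay


@dataclass(frozen=True)
class RateEstimate:
    """Point estimate and CI for a mutation rate from a fluctuation assay."""

    m: float  # expected mutation events per culture
    rate: float  # mutations per cell (per culture growth)
    ci_low: float
    ci_high: float
    p0: float
    n_cultures: int


@dataclass(frozen=True)
class GrowthCurve:
    """OD600 time series of a growing culture."""

    time_min: np.ndarray
    od600: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.time_min, dtype=float)
        od = np.asarray(self.od600, dtype=float)
        if t.shape != od.shape or t.ndim != 1:
            raise ValueError("time and OD must be 1-D of equal length")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(od <= 0):
            raise ValueError("OD values must be positive")
        object.__setattr__(self, "time_min", t)
        object.__setattr__(self, "od600", od)


@dataclass(frozen=True)
class FitnessEstimate:
    W: float
    W_raw: float
    marker_control_W: float


def p0_mutation_rate(
    assay: FluctuationAssay,
    denominator: str = "Nt",
    alpha: float = 0.05,
) -> RateEstimate:
    """Estimate the mutation rate by the P0 method.

    ``P0_hat = n_zero / n_cultures``, ``m = -ln(P0_hat)`` and
    ``rate = m / Nt`` (or ``m / (Nt - N0)`` with
    ``denominator="Nt-N0"``; the difference is negligible when
    ``Nt >> N0``).  The CI is a Wilson binomial interval on P0 pushed
    through the monotone map ``-ln(.) / denominator``.
    """
    n, n_zero = assay.n_cultures, assay.n_zero
    if n_zero == 0:
        raise ValueError(
            "P0 method inapplicable: no zero-mutant cultures "
            "(mutation rate too high for this assay size)"
        )
    denom = assay.Nt if denominator == "Nt" else assay.Nt - assay.N0
    lo_p, hi_p = proportion_confint(n_zero, n, alpha=alpha, method="wilson")
    # -ln is decreasing: high P0 bound -> low rate bound
    ci_low = max(-np.log(hi_p) / denom, 0.0)
    ci_high = -np.log(lo_p) / denom
    if n_zero == n:
        # boundary: no mutants anywhere -> point estimate 0, one-sided CI
        return RateEstimate(0.0, 0.0, 0.0, ci_high, 1.0, n)
    p0 = n_zero / n
    m = -np.log(p0)
    return RateEstimate(float(m), float(m / denom), float(ci_low),
                        float(ci_high), float(p0), n)


def rate_ratio(
    assay_a: FluctuationAssay,
    assay_b: FluctuationAssay,
    n_bootstrap: int = 2000,
    seed=None,
    alpha: float = 0.05,
):
    """Fold change rate_A / rate_B with a percentile-bootstrap CI.

    Zero counts are resampled per assay (binomial with the observed P0);
    degenerate resamples are clamped one culture inside the boundary.
    """
    est_a = p0_mutation_rate(assay_a)
    est_b = p0_mutation_rate(assay_b)
    if est_b.rate == 0:
        raise ValueError("reference assay has zero estimated rate")
    point = est_a.rate / est_b.rate
    rng = np.random.default_rng(seed)

    def boot_rates(assay):
        n = assay.n_cultures
        nz = rng.binomial(n, assay.n_zero / n, n_bootstrap)
        nz = np.clip(nz, 1, n - 1)
        denom = assay.Nt
        return -np.log(nz / n) / denom

    ratios = boot_rates(assay_a) / boot_rates(assay_b)
    lo, hi = np.quantile(ratios, [alpha / 2.0, 1.0 - alpha / 2.0])
    return point, (float(lo), float(hi))


def doubling_time_from_od(
    curve: GrowthCurve, window: tuple | None = None
):
    """Doubling time (min) from OLS of ln(OD600) on time.

    ``window = (t_lo, t_hi)`` restricts the fit to the exponential range.
    Returns ``(T, SE)`` with ``T = ln2 / slope`` and the SE by the delta
    method.
    """
    t, od = curve.time_min, curve.od600
    if window is not None:
        sel = (t >= window[0]) & (t <= window[1])
        t, od = t[sel], od[sel]
    if t.size < 3:
        raise ValueError("need at least 3 points in the fitting window")
    res = stats.linregress(t, np.log(od))
    if res.slope <= 0:
        raise ValueError("no growth detected (non-positive log-OD slope)")
    T = np.log(2.0) / res.slope
    se = T * res.stderr / res.slope
    return float(T), float(se)


def multiplicative_expected_doubling(
    T_control: float, T_A: float, T_B: float
) -> float:
    """Expected doubling time of the A+B double mutant if the two
    perturbations combine multiplicatively on growth rate:
    ``(r_A/r_ctrl) * (r_B/r_ctrl) = r_AB/r_ctrl``, i.e.
    ``T_AB = T_A * T_B / T_control``.
    """
    if min(T_control, T_A, T_B) <= 0:
        raise ValueError("doubling times must be positive")
    return T_A * T_B / T_control


def relative_fitness(
    competition_counts,
    marker_control_W: float = 1.0,
) -> FitnessEstimate:
    """Relative fitness from initial/final counts of two competitors.

    ``W_raw = ln(test_final/test_initial) / ln(ref_final/ref_initial)``
    (ratio of realized Malthusian parameters over the competition), then
    corrected for the neutral-marker effect by dividing by
    ``marker_control_W``.

    ``competition_counts`` is either a DataFrame with columns
    ``strain`` ("test"/"reference"), ``initial_count``, ``final_count``
    (the layout produced by ``simulate_competition``), or a 4-tuple
    ``(test_initial, test_final, ref_initial, ref_final)``.
    """
    if hasattr(competition_counts, "columns"):
        df = competition_counts.set_index("strain")
        a0 = float(df.loc["test", "initial_count"])
        af = float(df.loc["test", "final_count"])
        b0 = float(df.loc["reference", "initial_count"])
        bf = float(df.loc["reference", "final_count"])
    else:
        a0, af, b0, bf = map(float, competition_counts)
    if min(a0, af, b0, bf) <= 0:
        raise ValueError("all counts must be positive")
    if marker_control_W <= 0:
        raise ValueError("marker_control_W must be positive")
    w_raw = np.log(af / a0) / np.log(bf / b0)
    return FitnessEstimate(float(w_raw / marker_control_W), float(w_raw),
                           marker_control_W)
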