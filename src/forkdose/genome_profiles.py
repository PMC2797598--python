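"""Genome coordinate model and gene-dosage profile handling.

A circular bacterial chromosome replicated bidirectionally from *oriC* is
described by a :class:`GenomeMap`: its length, the origin and terminus
positions, annotated features and an ordered list of rearrangements
(inversions/deletions) relative to the reference coordinate system.
Copy-number ("gene dosage") measurements are held in a
:class:`DosageProfile`, a track of (position in bp, log2 ratio) pairs.

Coordinates are 0-based base pairs; all intervals are half-open.  Degrees
(360 deg = one full chromosome) are a display/exchange convention only.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

#: Published genome length of B. subtilis 168, used as the default map size.
DEFAULT_GENOME_LENGTH_BP = 4_214_810

LEFT = "left"
RIGHT = "right"


class CoordinateError(ValueError):
    """A position falls outside the genome or inside a deleted interval."""


class ProfileFormatError(ValueError):
    """A profile table violates the format contract (sorting, parsing)."""


# ---------------------------------------------------------------------------
# Genome map
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Rearrangement:
    """A structural change of the chromosome relative to the reference.

    ``kind`` is ``"inversion"`` or ``"deletion"``; the interval
    ``[start_bp, end_bp)`` is half-open in the *pre*-rearrangement
    coordinate system.
    """

    kind: str
    start_bp: int
    end_bp: int

    def __post_init__(self) -> None:
        if self.kind not in ("inversion", "deletion"):
            raise ValueError(f"unknown rearrangement kind: {self.kind!r}")
        if not 0 <= self.start_bp < self.end_bp:
            raise ValueError("require 0 <= start_bp < end_bp")


@dataclass(frozen=True)
class GenomeMap:
    """Chromosome geometry: length, oriC/terC, features, rearrangements."""

    genome_length_bp: int = DEFAULT_GENOME_LENGTH_BP
    oriC_bp: int = 0
    terC_bp: int = 2_013_743  # 172 deg on the default length
    features: tuple = ()
    rearrangements: tuple = ()

    def __post_init__(self) -> None:
        L = self.genome_length_bp
        if L <= 0:
            raise ValueError("genome_length_bp must be positive")
        if not (0 <= self.oriC_bp < L and 0 <= self.terC_bp < L):
            raise ValueError("oriC/terC must lie within the genome")
        object.__setattr__(self, "features", tuple(self.features))
        object.__setattr__(self, "rearrangements", tuple(self.rearrangements))
        for name, start, end, strand in self.features:
            if not (0 <= start < end <= L):
                raise ValueError(f"feature {name!r} outside genome")
        ivals = sorted((r.start_bp, r.end_bp) for r in self.rearrangements)
        for (s1, e1), (s2, e2) in zip(ivals, ivals[1:]):
            if s2 < e1:
                raise ValueError("rearrangement intervals overlap")
        for r in self.rearrangements:
            if r.end_bp > L:
                raise ValueError("rearrangement extends beyond genome")

    # -- replichore geometry ------------------------------------------------

    @property
    def right_replichore_length_bp(self) -> int:
        """Clockwise arc oriC -> terC."""
        return (self.terC_bp - self.oriC_bp) % self.genome_length_bp

    @property
    def left_replichore_length_bp(self) -> int:
        return self.genome_length_bp - self.right_replichore_length_bp


def bp_to_degrees(position_bp, genome_map: GenomeMap):
    """Convert a bp position to chromosome degrees (0-360)."""
    pos = np.asarray(position_bp)
    L = genome_map.genome_length_bp
    if np.any((pos < 0) | (pos >= L)):
        raise CoordinateError("position outside genome")
    out = 360.0 * pos / L
    return out if out.ndim else float(out)


def degrees_to_bp(degrees, genome_map: GenomeMap):
    """Convert degrees to the nearest integer bp position."""
    deg = np.asarray(degrees, dtype=float)
    if np.any((deg < 0) | (deg > 360)):
        raise CoordinateError("degrees outside [0, 360]")
    out = np.rint(deg / 360.0 * genome_map.genome_length_bp).astype(np.int64)
    out = out % genome_map.genome_length_bp
    return out if out.ndim else int(out)


def replichore_coordinate(position_bp, genome_map: GenomeMap):
    """Map a genomic position onto (replichore, distance from oriC in Mbp).

    The right replichore is the clockwise arc oriC -> terC; the left
    replichore is the counterclockwise arc.  Distance is measured along the
    replication path of the fork serving that arm.  Vectorized; for array
    input returns (array of "left"/"right", array of Mbp distances).
    """
    pos = np.asarray(position_bp)
    L = genome_map.genome_length_bp
    if np.any((pos < 0) | (pos >= L)):
        raise CoordinateError("position outside genome")
    delta = (pos - genome_map.oriC_bp) % L
    right_len = genome_map.right_replichore_length_bp
    is_right = delta <= right_len
    dist_bp = np.where(is_right, delta, L - delta)
    repl = np.where(is_right, RIGHT, LEFT)
    dist_mbp = dist_bp / 1e6
    if pos.ndim == 0:
        return str(repl), float(dist_mbp)
    return repl, dist_mbp


def signed_coordinate(position_bp, genome_map: GenomeMap):
    """Signed plotting coordinate: +distance on the right arm, - on the left."""
    repl, dist = replichore_coordinate(position_bp, genome_map)
    sign = np.where(np.asarray(repl) == RIGHT, 1.0, -1.0)
    out = sign * dist
    return float(out) if np.ndim(position_bp) == 0 else out


def apply_rearrangements(position_bp, genome_map: GenomeMap):
    """Remap reference positions through the map's ordered rearrangements.

    An inversion ``[s, e)`` mirrors the interval (``x -> s + e - 1 - x``);
    a deletion ``[s, e)`` removes it, shifting downstream positions left by
    ``e - s``.  Rearrangements are applied in list order, which is
    authoritative.  Positions inside a deleted interval raise
    :class:`CoordinateError`.
    """
    pos = np.asarray(position_bp).astype(np.int64)
    scalar = pos.ndim == 0
    pos = np.atleast_1d(pos).copy()
    for r in genome_map.rearrangements:
        s, e = r.start_bp, r.end_bp
        inside = (pos >= s) & (pos < e)
        if r.kind == "inversion":
            pos[inside] = s + e - 1 - pos[inside]
        else:  # deletion
            if np.any(inside):
                raise CoordinateError(
                    f"position removed by rearrangement (deletion [{s}, {e}))"
                )
            pos[pos >= e] -= e - s
    return int(pos[0]) if scalar else pos


# ---------------------------------------------------------------------------
# Dosage profiles
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DosageProfile:
    """An ordered track of (probe position in bp, log2 dosage ratio).

    ``metadata`` carries condition/strain labels and, optionally, the
    measurement time ``t`` (minutes) and mass doubling time ``T`` (minutes)
    of the culture the profile was taken from.
    """

    positions_bp: np.ndarray
    log2_ratio: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions_bp, dtype=np.int64)
        val = np.asarray(self.log2_ratio, dtype=float)
        if pos.shape != val.shape or pos.ndim != 1:
            raise ProfileFormatError("positions and values must be 1-D, same length")
        if pos.size and np.any(np.diff(pos) <= 0):
            raise ProfileFormatError("probe positions must be strictly increasing")
        if not np.all(np.isfinite(val)):
            raise ProfileFormatError("log2 ratios must be finite")
        object.__setattr__(self, "positions_bp", pos)
        object.__setattr__(self, "log2_ratio", val)
        object.__setattr__(self, "metadata", dict(self.metadata))

    def __len__(self) -> int:
        return self.positions_bp.size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"position_bp": self.positions_bp, "log2_ratio": self.log2_ratio}
        )


def read_profile(path) -> DosageProfile:
    """Read a tab-separated profile (columns ``position_bp``, ``log2_ratio``).

    Extra columns are preserved in ``metadata["extra_columns"]``.
    """
    try:
        df = pd.read_csv(path, sep="\t")
    except (ValueError, pd.errors.ParserError) as exc:
        raise ProfileFormatError(f"cannot parse profile table: {exc}") from exc
    for col in ("position_bp", "log2_ratio"):
        if col not in df.columns:
            raise ProfileFormatError(f"missing required column {col!r}")
    try:
        pos = pd.to_numeric(df["position_bp"]).to_numpy()
        val = pd.to_numeric(df["log2_ratio"]).to_numpy(dtype=float)
    except (ValueError, TypeError) as exc:
        raise ProfileFormatError(f"non-numeric profile values: {exc}") from exc
    if np.any(pos != np.asarray(pos, dtype=np.int64)):
        raise ProfileFormatError("positions must be integers")
    meta = {}
    extra = [c for c in df.columns if c not in ("position_bp", "log2_ratio")]
    if extra:
        meta["extra_columns"] = {c: df[c].tolist() for c in extra}
    return DosageProfile(np.asarray(pos, dtype=np.int64), val, meta)


def write_profile(profile: DosageProfile, path) -> None:
    """Write a profile as TSV with full float precision (round-trip safe)."""
    df = profile.to_frame()
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def to_bedgraph(profile: DosageProfile, path=None, chrom: str = "chr") -> str:
    """Export as bedGraph lines ``chrom start start+1 value``."""
    buf = io.StringIO()
    for p, v in zip(profile.positions_bp, profile.log2_ratio):
        buf.write(f"{chrom}\t{p}\t{p + 1}\t{v:g}\n")
    text = buf.getvalue()
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


def rolling_average(profile: DosageProfile, window: int) -> DosageProfile:
    """Rolling mean over ``window`` consecutive probes.

    Matches the convention of averaging every ``window`` consecutive
    positions and plotting the mean against the midpoint of the window's
    first and last positions.  Only full windows are emitted, so the output
    has ``n - window + 1`` probes.
    """
    n = len(profile)
    if not 1 <= window <= n:
        raise ValueError(f"window must be in [1, {n}], got {window}")
    kernel = np.full(window, 1.0 / window)
    smoothed = np.convolve(profile.log2_ratio, kernel, mode="valid")
    pos = profile.positions_bp
    mid = (pos[: n - window + 1] + pos[window - 1 :]) // 2
    meta = dict(profile.metadata, smoothing_window=window)
    # midpoints of strictly increasing positions are strictly increasing
    return DosageProfile(mid, smoothed, meta)


def relative_profile(
    profile_a: DosageProfile,
    profile_b: DosageProfile,
    interpolate: bool = False,
) -> DosageProfile:
    """Per-position difference of log2 ratios (A minus B).

    By default the probe sets are intersected; with ``interpolate=True``,
    B is linearly interpolated onto A's positions (no extrapolation: A
    probes outside B's span are dropped).
    """
    if interpolate:
        pa = profile_a.positions_bp
        lo, hi = profile_b.positions_bp[0], profile_b.positions_bp[-1]
        keep = (pa >= lo) & (pa <= hi)
        pos = pa[keep]
        vb = np.interp(pos, profile_b.positions_bp, profile_b.log2_ratio)
        diff = profile_a.log2_ratio[keep] - vb
    else:
        pos, ia, ib = np.intersect1d(
            profile_a.positions_bp, profile_b.positions_bp, return_indices=True
        )
        if pos.size == 0:
            raise ValueError(
                "no shared probe positions; use interpolate=True to align"
            )
        diff = profile_a.log2_ratio[ia] - profile_b.log2_ratio[ib]
    meta = {
        "condition": "{}-vs-{}".format(
            profile_a.metadata.get("condition", "A"),
            profile_b.metadata.get("condition", "B"),
        )
    }
    return DosageProfile(pos, diff, meta)


def center_profile(
    profile: DosageProfile, reference_region: tuple | None = None
) -> DosageProfile:
    """Subtract the median log2 ratio over a reference region (default: all).

    log2 ratios have an arbitrary intercept set by the hybridization
    normalization; centering fixes it against a region assumed constant.
    """
    if reference_region is None:
        sel = np.ones(len(profile), dtype=bool)
    else:
        lo, hi = reference_region
        sel = (profile.positions_bp >= lo) & (profile.positions_bp < hi)
    if not np.any(sel):
        raise ValueError("reference region contains no probes")
    offset = float(np.median(profile.log2_ratio[sel]))
    return replace(profile, log2_ratio=profile.log2_ratio - offset)
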