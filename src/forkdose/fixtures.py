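"""Canonical genome maps and velocity configurations.

Constructors for the chromosome geometries of the strains this package is
aimed at — the B. subtilis wild type, the head-on transcription inversion
strain (HT, 0-94 deg inverted), the unequal-replichore strain (UR, oriC at
94 deg), a left-replichore inversion, and a strain with only the rrnIHG
rRNA cluster inverted — together with piecewise-constant velocity fields
matching the tabulated dosage slopes in minimal (Min) and casamino-acid
(CAA) media.

Locus positions are given in chromosome degrees (the field's convention;
oriC = 0, terC = 172) and converted to bp on the canonical 4,214,810 bp
genome.
"""

from __future__ import annotations

from .genome_profiles import (
    DEFAULT_GENOME_LENGTH_BP,
    GenomeMap,
    Rearrangement,
    degrees_to_bp,
)
from .synthetic_data import SegmentedVelocity, VelocityProfile

#: Landmark loci in chromosome degrees.
LANDMARKS_DEG = {
    "oriC": 0.0,
    "rrnD": 13.0,
    "rrnE": 40.0,
    "rrnGHI": 80.0,
    "aprE": 94.0,
    "pksE": 153.0,
    "terC": 172.0,
}

#: rrnIHG cluster bp coordinates (inversion interval of the rrn strain).
RRN_IHG_BP = (159_778, 176_408)

#: Tabulated slope magnitudes (log2 per Mbp) of the HT strain's
#: asynchronous dosage profiles, keyed by medium; right-replichore
#: segments are (start_deg, end_deg, slope), the left arm is one segment.
HT_SLOPES = {
    "Min": {
        "left": 0.408,
        "right": [
            (0.0, 94.0, 0.646),  # head-on (inverted) segment
            (94.0, 153.0, 0.462),  # co-directional
        ],
    },
    "CAA": {
        "left": 0.450,
        "right": [
            (0.0, 13.0, 0.640),
            (13.0, 40.0, 0.615),
            (40.0, 80.0, 0.654),
            (80.0, 94.0, 1.51),  # rRNA-dense stretch: near-stalled forks
            (94.0, 153.0, 0.456),
        ],
    },
}

#: Mass doubling times (min) of the stabilized HT strain used with the
#: slope tables above.
HT_DOUBLING_TIME_MIN = {"Min": 44.0, "CAA": 55.0}


def _deg_to_mbp(deg: float, length_bp: int = DEFAULT_GENOME_LENGTH_BP) -> float:
    return deg / 360.0 * length_bp / 1e6


def genome_map(strain: str = "wild_type") -> GenomeMap:
    """Genome map for one of the canonical strains.

    ``strain`` is one of ``wild_type``, ``HT`` (0-94 deg inversion, equal
    replichores), ``UR`` (oriC at 94 deg, no inversion), ``left_HT``
    (inversion of the oriC-proximal half of the left replichore,
    257-360 deg) or ``rrn_inversion`` (rrnIHG cluster inverted).
    """
    L = DEFAULT_GENOME_LENGTH_BP
    base = GenomeMap(genome_length_bp=L, oriC_bp=0,
                     terC_bp=degrees_to_bp(172.0, GenomeMap()))
    features = tuple(
        (name, degrees_to_bp(deg, base), degrees_to_bp(deg, base) + 1, "+")
        for name, deg in LANDMARKS_DEG.items()
    )
    inv_94 = Rearrangement("inversion", 0, degrees_to_bp(94.0, base))
    if strain == "wild_type":
        return GenomeMap(L, base.oriC_bp, base.terC_bp, features, ())
    if strain == "HT":
        return GenomeMap(L, base.oriC_bp, base.terC_bp, features, (inv_94,))
    if strain == "UR":
        return GenomeMap(L, degrees_to_bp(94.0, base), base.terC_bp,
                         features, ())
    if strain == "left_HT":
        inv = Rearrangement("inversion", degrees_to_bp(257.0, base), L)
        return GenomeMap(L, base.oriC_bp, base.terC_bp, features, (inv,))
    if strain == "rrn_inversion":
        inv = Rearrangement("inversion", *RRN_IHG_BP)
        return GenomeMap(L, base.oriC_bp, base.terC_bp, features, (inv,))
    raise ValueError(f"unknown strain {strain!r}")


def velocity_from_slopes(
    slopes: dict, doubling_time_min: float
) -> VelocityProfile:
    """Build a velocity field from slope magnitudes via v = 1/(aT).

    ``slopes`` has the layout of the entries in :data:`HT_SLOPES`:
    a uniform left-arm slope and (start_deg, end_deg, slope) right-arm
    segments; the last right-arm velocity extends to terC.
    """
    T = doubling_time_min
    left = SegmentedVelocity.uniform(1000.0 / (slopes["left"] * T))
    segs = slopes["right"]
    breakpoints = tuple(_deg_to_mbp(end) for _, end, _ in segs[:-1])
    velocities = tuple(1000.0 / (a * T) for _, _, a in segs)
    return VelocityProfile(left, SegmentedVelocity(breakpoints, velocities))


def ht_velocity_profile(medium: str = "Min") -> VelocityProfile:
    """Velocity field of the HT strain in ``medium`` ("Min" or "CAA")."""
    if medium not in HT_SLOPES:
        raise ValueError(f"unknown medium {medium!r}")
    return velocity_from_slopes(HT_SLOPES[medium],
                                HT_DOUBLING_TIME_MIN[medium])
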