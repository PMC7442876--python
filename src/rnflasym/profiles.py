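"""Core data containers for paired-eye circumpapillary RNFLT profiles.

Coordinate convention
---------------------
Every profile lives on a circle of ``N_LOCATIONS = 768`` equidistant A-scans.
Sample ``i`` sits at angle ``360 * i / 768`` degrees in the laterality-
normalized TSNIT frame: 0 deg = temporal pole, 90 = superior, 180 = nasal,
270 = inferior.  Right-eye (OD) scans are stored directly in this frame;
left-eye (OS) scans are stored in their native device orientation, which is
the mirror image about the temporal-nasal axis, and are mirrored into the
normalized frame by :func:`mirror_profile` before any cross-eye arithmetic.

Thickness arrays are float64 with ``NaN`` marking missing/unreliable
segmentations; ``missing_mask`` is the boolean image of those NaNs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "N_LOCATIONS",
    "DEG_PER_SAMPLE",
    "location_angles",
    "angle_to_index",
    "mirror_profile",
    "EyeProfile",
    "SubjectPair",
    "DifferenceProfile",
    "QCThresholds",
    "swap_eyes",
]

N_LOCATIONS = 768
DEG_PER_SAMPLE = 360.0 / N_LOCATIONS


def location_angles() -> np.ndarray:
    """Angles (degrees) of the 768 grid locations in the normalized frame."""
    return np.arange(N_LOCATIONS) * DEG_PER_SAMPLE


def angle_to_index(angle_deg: float) -> int:
    """Nearest grid index for a continuous angle in degrees."""
    return int(np.round((angle_deg % 360.0) / DEG_PER_SAMPLE)) % N_LOCATIONS


def mirror_profile(values: np.ndarray) -> np.ndarray:
    """Mirror a circular profile about the temporal-nasal axis.

    ``out[i] = values[(N - i) % N]``: index 0 (temporal) is fixed and the
    direction of traversal reverses, swapping superior and inferior halves.
    The transform is an involution.
    """
    values = np.asarray(values)
    idx = (-np.arange(len(values))) % len(values)
    return values[idx]


@dataclass
class EyeProfile:
    """One eye's 768-sample thickness circle plus scan metadata."""

    laterality: str  # "OD" or "OS"
    thickness: np.ndarray  # um, NaN where missing
    quality: float  # dB
    n_bscans: int
    scan_radius: float  # um, estimated true on-retina radius
    missing_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        if self.laterality not in ("OD", "OS"):
            raise ValueError(f"laterality must be 'OD' or 'OS', got {self.laterality!r}")
        self.thickness = np.asarray(self.thickness, dtype=float)
        if self.thickness.shape != (N_LOCATIONS,):
            raise ValueError(
                f"thickness must have {N_LOCATIONS} samples, got {self.thickness.shape}"
            )
        if self.missing_mask is None:
            self.missing_mask = np.isnan(self.thickness)
        else:
            self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
            if self.missing_mask.shape != (N_LOCATIONS,):
                raise ValueError("missing_mask must have 768 entries")
            if not np.array_equal(self.missing_mask, np.isnan(self.thickness)):
                raise ValueError("missing_mask must be true exactly where thickness is NaN")
        present = self.thickness[~self.missing_mask]
        if present.size and np.any(present < 0):
            raise ValueError("thickness values must be >= 0 where present")

    @property
    def missing_fraction(self) -> float:
        return float(self.missing_mask.mean())


@dataclass
class SubjectPair:
    """Age plus right- and left-eye profiles for one person."""

    subject_id: str
    age: float  # years
    od: EyeProfile
    os: EyeProfile

    def __post_init__(self):
        if self.od.laterality != "OD":
            raise ValueError("od field must hold an OD profile")
        if self.os.laterality != "OS":
            raise ValueError("os field must hold an OS profile")
        if not self.age > 0:
            raise ValueError(f"age must be > 0, got {self.age!r}")


@dataclass
class DifferenceProfile:
    """Left-minus-right thickness at 768 normalized locations.

    ``delta[i]`` is OS minus OD in the normalized TSNIT frame; ``rd`` is the
    signed interocular scanning-radius difference (OS minus OD, um).
    """

    subject_id: str
    age: float
    delta: np.ndarray
    rd: float
    abs_rd: float = None  # type: ignore[assignment]

    def __post_init__(self):
        self.delta = np.asarray(self.delta, dtype=float)
        if self.delta.shape != (N_LOCATIONS,):
            raise ValueError("delta must have 768 samples")
        if self.abs_rd is None:
            self.abs_rd = abs(self.rd)
        elif self.abs_rd != abs(self.rd):
            raise ValueError("abs_rd must equal |rd|")


@dataclass(frozen=True)
class QCThresholds:
    """Reliability criteria applied to each eye of a pair.

    Defaults follow the standard reliability rules for this scan protocol:
    signal quality of at least 20 dB, at least 50 averaged B-scans, and at
    most 2.5% missing or unreliable A-scan segmentations.  All three
    thresholds are inclusive.
    """

    min_quality: float = 20.0  # dB
    min_bscans: int = 50
    max_missing_frac: float = 0.025

    def __post_init__(self):
        if self.min_quality < 0 or self.min_bscans < 0:
            raise ValueError("thresholds must be nonnegative")
        if not 0.0 <= self.max_missing_frac <= 1.0:
            raise ValueError("max_missing_frac must lie in [0, 1]")


def swap_eyes(pair: SubjectPair) -> SubjectPair:
    """Exchange the physical eyes of a subject.

    The right eye's content becomes the left eye and vice versa.  Because
    the two lateralities are stored in mirrored orientations, the thickness
    arrays are mirrored when they change laterality; in the normalized frame
    this is an exact content swap, so every derived difference profile is
    exactly negated.
    """
    new_od = EyeProfile(
        laterality="OD",
        thickness=mirror_profile(pair.os.thickness),
        quality=pair.os.quality,
        n_bscans=pair.os.n_bscans,
        scan_radius=pair.os.scan_radius,
    )
    new_os = EyeProfile(
        laterality="OS",
        thickness=mirror_profile(pair.od.thickness),
        quality=pair.od.quality,
        n_bscans=pair.od.n_bscans,
        scan_radius=pair.od.scan_radius,
    )
    return SubjectPair(pair.subject_id, pair.age, od=new_od, os=new_os)
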