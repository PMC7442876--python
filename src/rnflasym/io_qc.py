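"""Profile table I/O, reliability filtering and difference formation.

CSV schema (wide format), one row per eye::

    subject_id, eye, age, quality_db, n_bscans, radius_um, t000, ..., t767

``eye`` is ``OD`` or ``OS``; thickness cells are um, empty where the
segmentation is missing.  The long format carries one row per
(eye, location) with columns ``subject_id, eye, age, quality_db, n_bscans,
radius_um, location, thickness``.

OS rows are stored in native device orientation (mirror of the normalized
TSNIT frame); :func:`normalize_and_difference` maps both eyes into the
normalized frame before differencing.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .profiles import (
    N_LOCATIONS,
    DifferenceProfile,
    EyeProfile,
    QCThresholds,
    SubjectPair,
    mirror_profile,
)

__all__ = [
    "read_profiles",
    "write_profiles",
    "qc_filter",
    "apply_qc",
    "normalize_and_difference",
    "normalized_thickness",
    "interpolate_missing_circular",
    "ProfileParseError",
]

logger = logging.getLogger(__name__)

_THICKNESS_COLS = [f"t{i:03d}" for i in range(N_LOCATIONS)]
_META_COLS = ["subject_id", "eye", "age", "quality_db", "n_bscans", "radius_um"]


class ProfileParseError(ValueError):
    """Raised when a profile table violates the CSV schema."""


def write_profiles(pairs: list[SubjectPair], path, format: str = "wide") -> None:
    """Write subject pairs to CSV (two rows per subject, one per eye)."""
    rows = []
    for pair in pairs:
        for eye in (pair.od, pair.os):
            meta = {
                "subject_id": pair.subject_id,
                "eye": eye.laterality,
                "age": pair.age,
                "quality_db": eye.quality,
                "n_bscans": eye.n_bscans,
                "radius_um": eye.scan_radius,
            }
            if format == "wide":
                meta.update(dict(zip(_THICKNESS_COLS, eye.thickness)))
                rows.append(meta)
            elif format == "long":
                for i, t in enumerate(eye.thickness):
                    rows.append({**meta, "location": i, "thickness": t})
            else:
                raise ValueError(f"unknown format {format!r}")
    pd.DataFrame(rows).to_csv(path, index=False)


def _eye_from_row(row: pd.Series, thickness: np.ndarray) -> EyeProfile:
    return EyeProfile(
        laterality=str(row["eye"]),
        thickness=thickness,
        quality=float(row["quality_db"]),
        n_bscans=int(row["n_bscans"]),
        scan_radius=float(row["radius_um"]),
    )


def read_profiles(path, format: str = "wide") -> list[SubjectPair]:
    """Read a profile table into SubjectPairs.

    Subjects with only one eye on file are logged and dropped (the analysis
    is defined on both-eye subjects only).  Malformed headers, non-numeric
    thickness cells and duplicate (subject, eye) rows raise
    :class:`ProfileParseError` naming the offending row.
    """
    try:
        df = pd.read_csv(
            path, dtype={"subject_id": str, "eye": str}, float_precision="round_trip"
        )
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise ProfileParseError(f"cannot parse {path}: {exc}") from exc

    if format == "wide":
        expected = _META_COLS + _THICKNESS_COLS
    elif format == "long":
        expected = _META_COLS + ["location", "thickness"]
    else:
        raise ValueError(f"unknown format {format!r}")
    missing_cols = [c for c in expected if c not in df.columns]
    if missing_cols:
        raise ProfileParseError(
            f"malformed header: missing columns {missing_cols[:4]}"
            + ("..." if len(missing_cols) > 4 else "")
        )

    if format == "long":
        df = _long_to_wide(df)

    eyes: dict[tuple[str, str], tuple[EyeProfile, float]] = {}
    for pos, (_, row) in enumerate(df.iterrows(), start=2):  # row 1 = header
        key = (row["subject_id"], row["eye"])
        if key in eyes:
            raise ProfileParseError(f"duplicate (subject, eye) {key} at row {pos}")
        thick = row[_THICKNESS_COLS].to_numpy()
        try:
            thick = thick.astype(float)
        except (TypeError, ValueError) as exc:
            raise ProfileParseError(f"non-numeric thickness at row {pos}: {exc}") from exc
        try:
            eyes[key] = (_eye_from_row(row, thick), float(row["age"]))
        except ValueError as exc:
            raise ProfileParseError(f"invalid row {pos}: {exc}") from exc

    subjects: dict[str, dict[str, tuple[EyeProfile, float]]] = {}
    order: list[str] = []
    for (sid, eye), val in eyes.items():
        if sid not in subjects:
            order.append(sid)
        subjects.setdefault(sid, {})[eye] = val

    pairs, dropped = [], 0
    for sid in order:
        by_eye = subjects[sid]
        if set(by_eye) != {"OD", "OS"}:
            dropped += 1
            continue
        od, age_od = by_eye["OD"]
        os_, age_os = by_eye["OS"]
        if age_od != age_os:
            raise ProfileParseError(f"subject {sid}: inconsistent ages between eyes")
        pairs.append(SubjectPair(sid, age_od, od=od, os=os_))
    if dropped:
        logger.warning("dropped %d subject(s) lacking a second eye", dropped)
    return pairs


def _long_to_wide(df: pd.DataFrame) -> pd.DataFrame:
    wide_rows = []
    for (sid, eye), grp in df.groupby(["subject_id", "eye"], sort=False):
        if len(grp) != N_LOCATIONS or set(grp["location"].astype(int)) != set(
            range(N_LOCATIONS)
        ):
            raise ProfileParseError(
                f"subject {sid} eye {eye}: expected {N_LOCATIONS} locations"
            )
        grp = grp.sort_values("location")
        row = grp.iloc[0][_META_COLS].to_dict()
        row.update(dict(zip(_THICKNESS_COLS, grp["thickness"].to_numpy(dtype=float))))
        wide_rows.append(row)
    return pd.DataFrame(wide_rows)


# ---------------------------------------------------------------------------
# Quality control


def qc_filter(pair: SubjectPair, thr: QCThresholds = QCThresholds()) -> tuple[bool, list[str]]:
    """Reliability predicate: both eyes must satisfy all three criteria.

    Thresholds are inclusive: quality >= min_quality, B-scans >= min_bscans,
    missing fraction <= max_missing_frac.  Returns (pass, reasons), with one
    reason per failed criterion per eye.
    """
    reasons = []
    for eye in (pair.od, pair.os):
        tag = eye.laterality
        if eye.quality < thr.min_quality:
            reasons.append(f"{tag}: quality {eye.quality:g} dB < {thr.min_quality:g} dB")
        if eye.n_bscans < thr.min_bscans:
            reasons.append(f"{tag}: {eye.n_bscans} B-scans < {thr.min_bscans}")
        frac = eye.missing_fraction
        if frac > thr.max_missing_frac:
            reasons.append(
                f"{tag}: missing fraction {frac:.4f} > {thr.max_missing_frac:g}"
            )
    return (not reasons, reasons)


def apply_qc(
    pairs: list[SubjectPair], thr: QCThresholds = QCThresholds()
) -> tuple[list[SubjectPair], dict[str, list[str]]]:
    """Filter a cohort; returns (passing pairs, {subject_id: reasons})."""
    kept, excluded = [], {}
    for pair in pairs:
        ok, reasons = qc_filter(pair, thr)
        if ok:
            kept.append(pair)
        else:
            excluded[pair.subject_id] = reasons
    if excluded:
        logger.info("QC excluded %d of %d subjects", len(excluded), len(pairs))
    return kept, excluded


# ---------------------------------------------------------------------------
# Coordinate normalization and differencing


def interpolate_missing_circular(values: np.ndarray) -> np.ndarray:
    """Fill NaN runs by linear interpolation around the circle.

    Non-missing samples are preserved bit-exactly.  Interpolation treats the
    profile as periodic, so runs that straddle index 0 are handled like any
    interior gap.
    """
    values = np.asarray(values, dtype=float)
    missing = np.isnan(values)
    if not missing.any():
        return values.copy()
    if missing.all():
        raise ValueError("cannot interpolate a fully missing profile")
    n = len(values)
    idx = np.arange(n)
    good = idx[~missing]
    # periodic extension of the known samples on both sides
    xp = np.concatenate([good - n, good, good + n])
    fp = np.tile(values[good], 3)
    out = values.copy()
    out[missing] = np.interp(idx[missing], xp, fp)
    return out


def normalized_thickness(eye: EyeProfile, interpolate: bool = True) -> np.ndarray:
    """Thickness in the normalized TSNIT frame (OS profiles are mirrored)."""
    t = eye.thickness
    if interpolate and eye.missing_mask.any():
        t = interpolate_missing_circular(t)
    if eye.laterality == "OS":
        t = mirror_profile(t)
    return np.asarray(t, dtype=float)


def normalize_and_difference(
    pair: SubjectPair, thr: QCThresholds = QCThresholds()
) -> DifferenceProfile:
    """Form the OS-minus-OD difference profile in normalized coordinates.

    Sub-threshold missing runs are filled by circular linear interpolation in
    each eye before differencing.  A pair whose missing fraction exceeds the
    QC threshold should have been filtered out and raises an error here.
    """
    for eye in (pair.od, pair.os):
        if eye.missing_fraction > thr.max_missing_frac:
            raise ValueError(
                f"{eye.laterality} missing fraction {eye.missing_fraction:.4f} "
                f"exceeds QC threshold {thr.max_missing_frac:g}"
            )
    od = normalized_thickness(pair.od)
    os_ = normalized_thickness(pair.os)
    rd = pair.os.scan_radius - pair.od.scan_radius
    return DifferenceProfile(
        subject_id=pair.subject_id, age=pair.age, delta=os_ - od, rd=rd
    )
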