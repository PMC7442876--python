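"""Smooth scalar fields on the peripapillary circle.

The synthetic-cohort generator parameterizes every angular quantity (the
baseline thickness profile, the interocular mean-difference field, the
dispersion field and its age/radius modulations) as an :class:`AngularField`:
a constant plus a sum of wrapped-Gaussian bumps and low-order circular
harmonics.  The representation is closed under serialization to plain JSON,
which keeps generator configurations reproducible from a parameter file.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["AngularField", "circular_distance_deg"]


def circular_distance_deg(a, b):
    """Smallest absolute angular distance in degrees between ``a`` and ``b``."""
    d = np.abs(np.asarray(a, dtype=float) - np.asarray(b, dtype=float)) % 360.0
    return np.minimum(d, 360.0 - d)


@dataclass(frozen=True)
class AngularField:
    """``f(theta) = constant + sum of Gaussian bumps + sum of harmonics``.

    Parameters
    ----------
    constant:
        Baseline value of the field (units of the field).
    bumps:
        Tuples ``(center_deg, width_deg, height)``.  Each contributes
        ``height * exp(-0.5 * (d(theta, center) / width)**2)`` where ``d`` is
        the circular angular distance; a wrapped bell centred on the circle.
    harmonics:
        Tuples ``(order, cos_amp, sin_amp)`` contributing
        ``cos_amp * cos(order * theta) + sin_amp * sin(order * theta)``.
    """

    constant: float = 0.0
    bumps: tuple[tuple[float, float, float], ...] = ()
    harmonics: tuple[tuple[int, float, float], ...] = ()

    def __post_init__(self):
        for center, width, _height in self.bumps:
            if width <= 0:
                raise ValueError(f"bump width must be > 0, got {width!r}")
            if not np.isfinite(center):
                raise ValueError("bump center must be finite")

    def __call__(self, theta_deg):
        theta = np.asarray(theta_deg, dtype=float)
        out = np.full(theta.shape, float(self.constant))
        for center, width, height in self.bumps:
            d = circular_distance_deg(theta, center)
            out += height * np.exp(-0.5 * (d / width) ** 2)
        rad = np.deg2rad(theta)
        for order, camp, samp in self.harmonics:
            out += camp * np.cos(order * rad) + samp * np.sin(order * rad)
        if np.isscalar(theta_deg):
            return float(out)
        return out

    def shifted(self, offset_deg: float) -> "AngularField":
        """Field with every bump center rotated by ``offset_deg``.

        Harmonics are phase-shifted equivalently.  Used to displace the
        nerve-fiber bundle humps of one eye relative to the other.
        """
        bumps = tuple(
            ((c + offset_deg) % 360.0, w, h) for c, w, h in self.bumps
        )
        off = np.deg2rad(offset_deg)
        harmonics = tuple(
            (
                k,
                ca * np.cos(k * off) + sa * np.sin(k * off),
                sa * np.cos(k * off) - ca * np.sin(k * off),
            )
            for k, ca, sa in self.harmonics
        )
        return AngularField(self.constant, bumps, harmonics)

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "constant": float(self.constant),
            "bumps": [list(map(float, b)) for b in self.bumps],
            "harmonics": [[int(k), float(c), float(s)] for k, c, s in self.harmonics],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AngularField":
        return cls(
            constant=float(d.get("constant", 0.0)),
            bumps=tuple(tuple(map(float, b)) for b in d.get("bumps", ())),
            harmonics=tuple(
                (int(k), float(c), float(s)) for k, c, s in d.get("harmonics", ())
            ),
        )

    @classmethod
    def coerce(cls, value) -> "AngularField":
        """Accept an AngularField, a plain number (constant field) or a dict."""
        if isinstance(value, cls):
            return value
        if isinstance(value, (int, float)):
            return cls(constant=float(value))
        if isinstance(value, dict):
            return cls.from_dict(value)
        raise TypeError(f"cannot interpret {value!r} as an AngularField")
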