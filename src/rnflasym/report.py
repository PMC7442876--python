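"""Sectoral summaries and personalized normative percentile plots.

The plot mirrors the familiar clinical printout: the patient's interocular
difference curve drawn over their personalized normative percentile bands
(default 1/5/95/99%), with the dark green normative median, TSNIT landmarks
on the angle axis, and a sector table (global mean G plus the standard six
clock sectors).  Both tails are colored abnormal, since an interocular
difference can be out of norm in either direction.
"""

from __future__ import annotations

from dataclasses import dataclass

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from scipy import stats

from .normative import NormativeAtlas
from .profiles import N_LOCATIONS, DifferenceProfile, location_angles

__all__ = ["SectorScheme", "PlotSpec", "sector_summaries", "render_normative_plot"]


@dataclass(frozen=True)
class SectorScheme:
    """Clinical 6-sector layout plus the global average.

    Extents are half-open ``[start, end)`` intervals in the normalized
    TSNIT frame; the six named sectors partition the circle (temporal and
    nasal span 90 deg, the oblique sectors 45 deg each).
    """

    sectors: tuple = (
        ("TMP", ((315.0, 360.0), (0.0, 45.0))),
        ("TS", ((45.0, 90.0),)),
        ("NS", ((90.0, 135.0),)),
        ("NAS", ((135.0, 225.0),)),
        ("NI", ((225.0, 270.0),)),
        ("TI", ((270.0, 315.0),)),
    )

    def __post_init__(self):
        counts = np.zeros(N_LOCATIONS, dtype=int)
        for name in self.names:
            counts[self.indices(name)] += 1
        if not np.all(counts == 1):
            raise ValueError("sectors must partition the 768 locations exactly")

    @property
    def names(self) -> list[str]:
        return [name for name, _ in self.sectors]

    def indices(self, name: str) -> np.ndarray:
        """Grid indices belonging to a named sector ('G' = all 768)."""
        if name == "G":
            return np.arange(N_LOCATIONS)
        angles = location_angles()
        for nm, intervals in self.sectors:
            if nm == name:
                mask = np.zeros(N_LOCATIONS, dtype=bool)
                for lo, hi in intervals:
                    mask |= (angles >= lo) & (angles < hi)
                return np.flatnonzero(mask)
        raise KeyError(name)


@dataclass(frozen=True)
class PlotSpec:
    """Appearance of the normative percentile plot."""

    band_edges: tuple[float, ...] = (0.01, 0.05, 0.95, 0.99)
    band_colors: tuple[str, ...] = ("#d32f2f", "#fbc02d", "#7cb342", "#fbc02d", "#d32f2f")
    median_color: str = "#1b5e20"
    patient_color: str = "black"
    format: str = "svg"  # or "png"
    figsize: tuple[float, float] = (10.0, 4.5)
    dpi: int = 120

    def __post_init__(self):
        edges = np.asarray(self.band_edges)
        if np.any(edges <= 0) or np.any(edges >= 1) or np.any(np.diff(edges) <= 0):
            raise ValueError("band edges must be strictly increasing within (0, 1)")
        if len(self.band_colors) != len(self.band_edges) + 1:
            raise ValueError("need one more color than band edges")


def sector_summaries(
    delta: DifferenceProfile,
    atlas: NormativeAtlas,
    scheme: SectorScheme = SectorScheme(),
) -> pd.DataFrame:
    """Observed sector means of the difference and their normative medians.

    The observed value of a sector is the mean of the patient's difference
    over its locations; the normative median is the mean over the sector of
    the per-location modeled median (= mu) at the patient's age and radius
    difference.  ``G`` covers all 768 locations.
    """
    mus, _ = atlas.profile_musigma(delta.age, delta.rd)
    rows = []
    for name in ["G"] + scheme.names:
        idx = scheme.indices(name)
        rows.append(
            {
                "sector": name,
                "observed_um": float(delta.delta[idx].mean()),
                "normative_median_um": float(mus[idx].mean()),
            }
        )
    return pd.DataFrame(rows)


def render_normative_plot(
    delta: DifferenceProfile,
    atlas: NormativeAtlas,
    out,
    spec: PlotSpec = PlotSpec(),
    scheme: SectorScheme = SectorScheme(),
    title: str | None = None,
) -> dict:
    """Write the personalized normative percentile plot.

    Returns the plotted arrays (angles, band curves, median, patient curve)
    so callers and tests can verify the rendered content.  Output is
    deterministic: identical inputs produce byte-identical SVG.
    """
    angles = location_angles()
    mus, sigmas = atlas.profile_musigma(delta.age, delta.rd)
    z = stats.norm.ppf(np.asarray(spec.band_edges))
    bands = mus[None, :] + sigmas[None, :] * z[:, None]  # (n_edges, 768)

    span = float(np.nanmax(np.abs(np.concatenate([bands.ravel(), delta.delta]))))
    ylim = 1.15 * max(span, 1.0)

    with plt.rc_context({"svg.hashsalt": "rnflasym"}):
        fig, (ax, ax_tab) = plt.subplots(
            1,
            2,
            figsize=spec.figsize,
            dpi=spec.dpi,
            gridspec_kw={"width_ratios": [4, 1]},
        )
        lower = np.full(N_LOCATIONS, -ylim)
        for j, color in enumerate(spec.band_colors):
            upper = bands[j] if j < len(spec.band_edges) else np.full(N_LOCATIONS, ylim)
            ax.fill_between(angles, lower, upper, color=color, alpha=0.55, linewidth=0)
            lower = upper
        ax.plot(angles, mus, color=spec.median_color, lw=1.6, label="normative median")
        ax.plot(angles, delta.delta, color=spec.patient_color, lw=1.0, label="OS - OD difference")
        ax.set_xlim(0, 360)
        ax.set_ylim(-ylim, ylim)
        ax.set_xticks([0, 90, 180, 270, 360], ["T", "S", "N", "I", "T"])
        ax.set_xlabel("circumpapillary position (deg, TSNIT)")
        ax.set_ylabel("interocular RNFLT difference (um)")
        ax.legend(loc="upper right", fontsize=8, framealpha=0.9)
        if title:
            ax.set_title(title)

        table = sector_summaries(delta, atlas, scheme)
        ax_tab.axis("off")
        lines = ["sector  obs (norm)"]
        for _, row in table.iterrows():
            lines.append(
                f"{row['sector']:>4}  {row['observed_um']:6.2f} ({row['normative_median_um']:.2f})"
            )
        ax_tab.text(
            0.0, 0.95, "\n".join(lines), family="monospace", fontsize=9, va="top"
        )
        fig.tight_layout()
        fig.savefig(out, format=spec.format, metadata={"Date": None} if spec.format == "svg" else None)
        plt.close(fig)
    return {
        "angles": angles,
        "bands": bands,
        "median": mus,
        "patient": delta.delta.copy(),
        "sectors": table,
    }
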