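"""Closed-form assay calculators.

Small arithmetic readouts that accompany the imaging pipeline: autophagic
flux from LC3B immunoblot bands, colony-forming-unit (CFU) concentrations
and the supernatant/intracellular secretion ratio from serial-dilution
plating, the ratiometric dual-dextran lysosomal pH readout, PI-gated
surface-marker summarization of flow-cytometry events, and a linear-slope
helper for degradative-activity (DQ-BSA) kinetics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DomainError, NoSignalError, SampleSizeError, UncountableError
from .io import Image2D
from .puncta import PunctaSet

__all__ = [
    "DilutionPlate",
    "autophagic_flux",
    "cfu_concentration",
    "secretion_ratio",
    "ph_ratio_per_lysosome",
    "surface_marker_summary",
    "degradation_slope",
]


def autophagic_flux(
    lc3ii_baf: float, lc3i_baf: float, lc3ii_ctrl: float, lc3i_ctrl: float
) -> float:
    """Autophagic flux: (LC3B-II/LC3B-I with bafilomycin) / (same ratio untreated)."""
    for name, v in (
        ("lc3ii_baf", lc3ii_baf),
        ("lc3i_baf", lc3i_baf),
        ("lc3ii_ctrl", lc3ii_ctrl),
        ("lc3i_ctrl", lc3i_ctrl),
    ):
        if v <= 0:
            raise DomainError(f"band intensity {name} must be positive, got {v}")
    return (lc3ii_baf / lc3i_baf) / (lc3ii_ctrl / lc3i_ctrl)


@dataclass
class DilutionPlate:
    """Colony counts of one serial-dilution series.

    ``dilution_factors[i]`` is the fold dilution of plate i (>= 1);
    ``plated_volume_ml`` the volume spread per plate.
    """

    counts: list[int]
    dilution_factors: list[float]
    plated_volume_ml: float
    source: str = "supernatant"

    def __post_init__(self) -> None:
        if len(self.counts) != len(self.dilution_factors):
            raise DomainError("counts and dilution factors differ in length")
        if any(c < 0 or int(c) != c for c in self.counts):
            raise DomainError("counts must be non-negative integers")
        if any(d < 1 for d in self.dilution_factors):
            raise DomainError("dilution factors must be >= 1")
        if self.plated_volume_ml <= 0:
            raise DomainError("plated volume must be positive")


def cfu_concentration(
    plate: DilutionPlate, countable_range: tuple[int, int] = (3, 300)
) -> float:
    """CFU/mL from the countable plates of a dilution series.

    A plate is countable when its colony count falls inside
    ``countable_range`` (3-300 by standard microbiological practice); the
    concentration is the mean over countable plates of
    count * dilution_factor / plated_volume.
    """
    lo, hi = countable_range
    estimates = [
        c * d / plate.plated_volume_ml
        for c, d in zip(plate.counts, plate.dilution_factors)
        if lo <= c <= hi
    ]
    if not estimates:
        raise UncountableError(
            f"no plate in countable range {countable_range}: counts={plate.counts}"
        )
    return float(np.mean(estimates))


def secretion_ratio(
    supernatant_cfu_per_ml: float,
    supernatant_volume_ml: float,
    intracellular_cfu_per_ml: float,
    intracellular_volume_ml: float,
) -> float:
    """Ratio of total expelled to total intracellular bacteria.

    Total CFU per compartment is concentration times compartment volume;
    the readout is supernatant over intracellular.
    """
    if supernatant_volume_ml <= 0 or intracellular_volume_ml <= 0:
        raise DomainError("compartment volumes must be positive")
    intra_total = intracellular_cfu_per_ml * intracellular_volume_ml
    if intra_total <= 0:
        raise DomainError("intracellular total CFU must be positive")
    return float(supernatant_cfu_per_ml * supernatant_volume_ml / intra_total)


def ph_ratio_per_lysosome(
    fitc: Image2D,
    far_red: Image2D,
    puncta: PunctaSet,
    background: tuple[float, float] = (0.0, 0.0),
) -> pd.DataFrame:
    """Per-lysosome FITC / far-red intensity ratio (pH readout).

    Lysosome ROIs come from puncta detected in the pH-insensitive far-red
    channel; per punctum the ratio of background-subtracted summed
    intensities is computed.  Non-positive denominators yield NaN with a
    ``flagged`` marker instead of an error.
    """
    if fitc.pixels.shape != far_red.pixels.shape:
        raise DomainError("channel images differ in shape")
    if puncta.labels is None:
        raise DomainError("puncta set carries no label image")
    bg_f, bg_r = background
    rows = []
    for _, row in puncta.table.iterrows():
        sel = puncta.labels == row["label"]
        num = float((fitc.pixels[sel] - bg_f).sum())
        den = float((far_red.pixels[sel] - bg_r).sum())
        if den <= 0:
            rows.append({"label": row["label"], "ratio": np.nan, "flagged": True})
        else:
            rows.append({"label": row["label"], "ratio": num / den, "flagged": False})
    return pd.DataFrame(rows, columns=["label", "ratio", "flagged"])


def surface_marker_summary(
    events: pd.DataFrame,
    pi_threshold: float,
    min_events: int = 5000,
    pi_column: str = "pi",
    marker_column: str = "marker",
) -> dict:
    """Mean surface-marker intensity of PI-negative (live) events.

    PI-positive (membrane-compromised) events are excluded; at least
    ``min_events`` total events are required (5000 in the original
    protocol).  Returns the gated mean and the excluded fraction.
    """
    if len(events) < min_events:
        raise SampleSizeError(f"{len(events)} events < required {min_events}")
    pi = events[pi_column].to_numpy(float)
    marker = events[marker_column].to_numpy(float)
    live = pi <= pi_threshold
    if not live.any():
        raise NoSignalError("all events are PI-positive")
    return {
        "mean_marker": float(marker[live].mean()),
        "n_live": int(live.sum()),
        "fraction_excluded": float(1.0 - live.mean()),
    }


def degradation_slope(
    time_min: np.ndarray, fluorescence: np.ndarray, window: tuple[float, float] | None = None
) -> float:
    """Initial-rate slope of a degradative-activity (DQ-BSA) trace.

    Ordinary least-squares slope of fluorescence against time over the
    stated window (whole trace by default), in fluorescence units per
    minute.
    """
    t = np.asarray(time_min, float)
    y = np.asarray(fluorescence, float)
    if window is not None:
        sel = (t >= window[0]) & (t <= window[1])
        t, y = t[sel], y[sel]
    if t.size < 2:
        raise DomainError("need at least 2 points in the fit window")
    return float(np.polyfit(t, y, 1)[0])
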