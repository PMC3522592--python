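"""Correlation of sub-group profiles with the system profile and test-set
summary statistics.

The contribution of an atom selection to a rotation profile is quantified by
the inner product of the centered, normalized profile vectors,

    c = W_hat_syst . W_hat_sel,   W_hat = (W - <W>) / ||W - <W>||,

a Pearson-type coefficient in [-1, 1].  A windowed variant restricts the
poses to ±half_width about the primary and secondary minima, which isolates
how well a selection discriminates the native from the opposed orientation.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import UndefinedCorrelationError
from .scan import MinimaReport

__all__ = ["ProfileVector", "CorrelationSummary", "correlation",
           "windowed_correlation", "summarize_testset"]


@dataclass
class ProfileVector:
    """Energy-per-pose vector on an angle grid with a validity mask."""
    values: np.ndarray
    mask: np.ndarray | None = None          # True = excluded pose
    angles: np.ndarray | None = None
    label: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.mask is None:
            self.mask = np.isnan(self.values)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.angles is not None:
            self.angles = np.asarray(self.angles, dtype=float)


@dataclass(frozen=True)
class CorrelationSummary:
    coefficients: dict[str, float]   # group label -> coefficient
    window: str                      # "full" or e.g. "±30° around minima"
    n_effective: int


def _joint_values(system: ProfileVector, selection: ProfileVector,
                  extra_keep: np.ndarray | None = None):
    if system.values.shape != selection.values.shape:
        raise UndefinedCorrelationError("profile grids differ in length")
    if system.angles is not None and selection.angles is not None and \
            not np.array_equal(system.angles, selection.angles):
        raise UndefinedCorrelationError("profile grids differ")
    keep = ~(system.mask | selection.mask)
    if extra_keep is not None:
        keep &= extra_keep
    return system.values[keep], selection.values[keep]


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    if len(a) < 3:
        raise UndefinedCorrelationError(
            f"only {len(a)} usable poses (need >= 3)")
    ac = a - a.mean()
    bc = b - b.mean()
    na, nb = np.linalg.norm(ac), np.linalg.norm(bc)
    if na == 0.0 or nb == 0.0:
        raise UndefinedCorrelationError("zero-variance profile vector")
    return float((ac / na) @ (bc / nb))


def correlation(system: ProfileVector, selection: ProfileVector) -> float:
    """Full-circle correlation coefficient of two profile vectors.

    Poses masked in either vector are dropped from both.
    """
    return _pearson(*_joint_values(system, selection))


def windowed_correlation(system: ProfileVector, selection: ProfileVector,
                         minima: MinimaReport,
                         half_width: float = 30.0) -> float:
    """Correlation restricted to poses within ``half_width`` degrees of the
    primary or the secondary minimum (union of both windows)."""
    if system.angles is None:
        raise UndefinedCorrelationError("windowing needs the angle grid")
    centers = [m for m in (minima.primary_minimum, minima.secondary_minimum)
               if m is not None]
    if not centers:
        raise UndefinedCorrelationError("no minima to window around")
    ang = system.angles
    keep = np.zeros(len(ang), dtype=bool)
    for c in centers:
        delta = np.abs((ang - c + 180.0) % 360.0 - 180.0)
        keep |= delta <= half_width + 1e-9
    return _pearson(*_joint_values(system, selection, keep))


def summarize_testset(reports: list[MinimaReport],
                      correlations: list[CorrelationSummary] | None = None,
                      bin_width: float = 5.0) -> dict:
    """Aggregate minima statistics (and optionally per-group correlation
    means) over a set of complexes."""
    if not reports:
        raise ValueError("at least one minima report required")
    primaries = np.array([r.primary_minimum for r in reports
                          if r.primary_minimum is not None], dtype=float)
    amps = np.array([r.amplitude for r in reports], dtype=float)

    def _sd(x):
        return float(np.std(x, ddof=1)) if len(x) > 1 else 0.0

    out = {
        "n_reports": len(reports),
        "n_with_primary": int(len(primaries)),
        "mean_abs_primary_deg": float(np.mean(np.abs(primaries)))
        if len(primaries) else None,
        "sd_abs_primary_deg": _sd(np.abs(primaries)),
        "mean_signed_primary_deg": float(np.mean(primaries))
        if len(primaries) else None,
        "sd_signed_primary_deg": _sd(primaries),
        "mean_amplitude_kcal": float(np.mean(amps)),
        "sd_amplitude_kcal": _sd(amps),
        "n_primary_is_global": int(sum(r.primary_is_global for r in reports)),
    }
    # histogram of minima positions, Fig-3-style 5 degree bins
    edges = np.arange(-180.0, 180.0 + bin_width, bin_width)
    prim_hist, _ = np.histogram(primaries, bins=edges)
    secondaries = np.array([r.secondary_minimum for r in reports
                            if r.secondary_minimum is not None], dtype=float)
    sec_hist, _ = np.histogram(secondaries, bins=edges)
    out["histogram_bin_edges_deg"] = edges
    out["primary_histogram"] = prim_hist
    out["secondary_histogram"] = sec_hist
    if correlations:
        rows = pd.DataFrame([c.coefficients for c in correlations])
        out["correlation_mean"] = rows.mean().to_dict()
        out["correlation_sd"] = (rows.std(ddof=1).fillna(0.0).to_dict()
                                 if len(rows) > 1
                                 else {k: 0.0 for k in rows.columns})
    return out
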