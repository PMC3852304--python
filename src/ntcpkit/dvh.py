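"""Dose-volume histogram containers and dosimetric covariate extraction.

A rectal DVH is stored either in cumulative form (percent of organ volume
receiving at least each grid dose) or differential form (percent of organ
volume at each grid dose, treated as point masses).  All volumes are percent
of the whole organ; absolute-volume histograms are rejected.  The dosimetric
covariates used for NTCP modelling are Vx (percent volume receiving >= x Gy,
by default for x = 20..75 Gy in 5 Gy steps), Dmean and Dmax.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CUMULATIVE = "cumulative"
DIFFERENTIAL = "differential"

#: Default Vx thresholds in Gy (20-75 Gy in 5 Gy increments, includes V65).
DEFAULT_THRESHOLDS: tuple[int, ...] = tuple(range(20, 80, 5))

_VOL_TOL = 1e-9
# step width used to encode a point-mass drop in a cumulative grid
_STEP_EPS = 1e-9


class DVHError(ValueError):
    """Malformed DVH input (non-monotone grid, negative volume, ...)."""


@dataclass
class DVHCurve:
    """One patient's dose-volume histogram.

    Parameters
    ----------
    patient_id : str
        Identifier for the patient the curve belongs to.
    dose_edges : array-like
        Strictly increasing dose grid in Gy.
    volume : array-like
        Percent of organ volume per grid point.  In cumulative mode this is
        the volume receiving at least the grid dose (non-increasing, first
        value <= 100); in differential mode the percent volume at that dose
        (non-negative, summing to <= 100).
    mode : {"cumulative", "differential"}
    """

    patient_id: str
    dose_edges: np.ndarray
    volume: np.ndarray
    mode: str

    def __post_init__(self) -> None:
        self.dose_edges = np.asarray(self.dose_edges, dtype=float)
        self.volume = np.asarray(self.volume, dtype=float)
        pid = self.patient_id
        if self.dose_edges.ndim != 1 or self.dose_edges.shape != self.volume.shape:
            raise DVHError(f"patient {pid}: dose and volume arrays must be 1-D and equal length")
        if self.dose_edges.size < 1:
            raise DVHError(f"patient {pid}: empty DVH")
        if np.any(np.diff(self.dose_edges) <= 0):
            row = int(np.argmax(np.diff(self.dose_edges) <= 0)) + 1
            raise DVHError(f"patient {pid}: dose grid not strictly increasing at row {row}")
        if np.any(self.volume < -_VOL_TOL):
            raise DVHError(f"patient {pid}: negative volume")
        if self.mode not in (CUMULATIVE, DIFFERENTIAL):
            raise DVHError(f"patient {pid}: unknown mode {self.mode!r}")
        if self.mode == CUMULATIVE:
            if self.volume[0] > 100 * (1 + 1e-6):
                raise DVHError(f"patient {pid}: cumulative volume exceeds 100%")
            if np.any(np.diff(self.volume) > _VOL_TOL * max(1.0, self.volume[0])):
                raise DVHError(f"patient {pid}: cumulative volume must be non-increasing")
        else:
            total = float(self.volume.sum())
            if total > 100 * (1 + 1e-6):
                raise DVHError(f"patient {pid}: differential volume sums to {total:.4f}% > 100%")

    @property
    def n_points(self) -> int:
        return int(self.dose_edges.size)


@dataclass
class DoseMetrics:
    """Dosimetric covariates extracted from a single DVH.

    ``vx`` maps a dose threshold X (Gy) to the percent volume receiving at
    least X Gy; ``dmax`` is the largest grid dose with positive volume and
    ``dmean`` the volume-weighted mean dose, both in Gy.
    """

    patient_id: str
    vx: dict[float, float] = field(default_factory=dict)
    dmax: float = 0.0
    dmean: float = 0.0

    def __post_init__(self) -> None:
        thresholds = sorted(self.vx)
        vals = [self.vx[t] for t in thresholds]
        if any(v < -1e-9 or v > 100 + 1e-6 for v in vals):
            raise DVHError(f"patient {self.patient_id}: Vx outside [0, 100]")
        if any(b > a + 1e-9 for a, b in zip(vals, vals[1:])):
            raise DVHError(f"patient {self.patient_id}: Vx not non-increasing in dose")
        if self.dmean > self.dmax + 1e-6:
            raise DVHError(f"patient {self.patient_id}: Dmean exceeds Dmax")


def read_dvh(path, mode_hint: str | None = None) -> list[DVHCurve]:
    """Read one or more DVHs from a long-format CSV.

    The file must have columns ``patient_id,dose_gy,volume``; rows for one
    patient must appear with strictly increasing dose.  The curve mode is
    auto-detected (monotone non-increasing volume => cumulative) unless
    ``mode_hint`` is given.
    """
    df = pd.read_csv(path)
    required = {"patient_id", "dose_gy", "volume"}
    missing = required - set(df.columns)
    if missing:
        raise DVHError(f"{path}: missing column(s) {sorted(missing)}")
    if mode_hint is not None and mode_hint not in (CUMULATIVE, DIFFERENTIAL):
        raise DVHError(f"unknown mode hint {mode_hint!r}")
    curves: list[DVHCurve] = []
    for pid, grp in df.groupby("patient_id", sort=False):
        dose = grp["dose_gy"].to_numpy(dtype=float)
        vol = grp["volume"].to_numpy(dtype=float)
        if np.any(vol < 0):
            row = int(grp.index[np.argmax(vol < 0)]) + 2  # 1-based incl. header
            raise DVHError(f"patient {pid}: negative volume at file row {row}")
        if np.any(np.diff(dose) <= 0):
            row = int(grp.index[np.argmax(np.diff(dose) <= 0) + 1]) + 2
            raise DVHError(f"patient {pid}: dose not strictly increasing at file row {row}")
        mode = mode_hint or _detect_mode(vol)
        curves.append(DVHCurve(str(pid), dose, vol, mode))
    return curves


def write_dvh(curves: Iterable[DVHCurve], path) -> None:
    """Write DVHs to the long CSV format accepted by :func:`read_dvh`."""
    frames = [
        pd.DataFrame(
            {"patient_id": c.patient_id, "dose_gy": c.dose_edges, "volume": c.volume}
        )
        for c in curves
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def _detect_mode(volume: np.ndarray) -> str:
    if np.all(np.diff(volume) <= _VOL_TOL * max(1.0, float(volume.max(initial=1.0)))):
        return CUMULATIVE
    return DIFFERENTIAL


def to_cumulative(curve: DVHCurve) -> DVHCurve:
    """Convert a DVH to cumulative mode; idempotent on cumulative input.

    Differential input is treated as point masses: the cumulative value at
    dose X is the total percent volume at doses >= X.  The output grid
    encodes each step with a pair of points 1e-6 Gy apart so that linear
    interpolation on it reproduces the step function.
    """
    if curve.mode == CUMULATIVE:
        return DVHCurve(curve.patient_id, curve.dose_edges.copy(), curve.volume.copy(), CUMULATIVE)
    suffix = np.cumsum(curve.volume[::-1])[::-1]  # suffix[i] = sum of volume at dose >= edge i
    doses: list[float] = []
    vols: list[float] = []
    if curve.dose_edges[0] > 0:
        doses.append(0.0)
        vols.append(float(suffix[0]))
    for i, d in enumerate(curve.dose_edges):
        doses.append(float(d))
        vols.append(float(suffix[i]))
        after = float(suffix[i + 1]) if i + 1 < suffix.size else 0.0
        doses.append(float(d) + _STEP_EPS)
        vols.append(after)
    return DVHCurve(curve.patient_id, np.array(doses), np.array(vols), CUMULATIVE)


def as_differential(curve: DVHCurve) -> tuple[np.ndarray, np.ndarray]:
    """Return the DVH as point masses ``(doses, volumes)`` in percent.

    Cumulative curves are differenced: the mass lost between adjacent grid
    points is placed at the bin centre, any residual volume at the last grid
    point stays there.  Differential curves are returned as stored.
    """
    if curve.mode == DIFFERENTIAL:
        return curve.dose_edges.copy(), curve.volume.copy()
    c = curve.volume
    d = curve.dose_edges
    masses = c[:-1] - c[1:]
    centres = 0.5 * (d[:-1] + d[1:])
    doses = np.append(centres, d[-1])
    vols = np.append(masses, c[-1])
    keep = vols > _VOL_TOL
    return doses[keep], vols[keep]


def compute_metrics(
    curve: DVHCurve, thresholds: Sequence[float] = DEFAULT_THRESHOLDS
) -> DoseMetrics:
    """Extract Vx, Dmean and Dmax from a DVH.

    Vx on a cumulative curve uses linear interpolation of the grid; on a
    differential curve it is the exact sum of point masses at doses >= X.
    A threshold above the grid maximum yields Vx = 0 (logged, not an error).
    Dmean is the mass-weighted mean dose over the whole organ (volume not
    accounted for by the histogram is assumed unirradiated); Dmax is the
    largest grid dose carrying positive volume.
    """
    grid_max = float(curve.dose_edges[-1])
    vx: dict[float, float] = {}
    for x in thresholds:
        x = float(x)
        if x > grid_max:
            logger.info(
                "patient %s: threshold %g Gy above grid maximum %g Gy; V%g = 0",
                curve.patient_id, x, grid_max, x,
            )
            vx[x] = 0.0
            continue
        if curve.mode == CUMULATIVE:
            vx[x] = float(np.interp(x, curve.dose_edges, curve.volume))
        else:
            vx[x] = float(curve.volume[curve.dose_edges >= x].sum())
    doses, masses = as_differential(curve)
    dmean = float((doses * masses).sum() / 100.0)
    positive = curve.volume > _VOL_TOL
    dmax = float(curve.dose_edges[positive][-1]) if positive.any() else 0.0
    vx = {x: min(max(v, 0.0), 100.0) for x, v in vx.items()}
    return DoseMetrics(curve.patient_id, vx=vx, dmax=dmax, dmean=dmean)


def metrics_table(
    curves: Iterable[DVHCurve], thresholds: Sequence[float] = DEFAULT_THRESHOLDS
) -> pd.DataFrame:
    """Tabulate dose metrics for many curves.

    Columns: ``patient_id, dmax, dmean, v20, ..., v75`` (lower-case vX).
    """
    rows = []
    for curve in curves:
        m = compute_metrics(curve, thresholds)
        row: dict[str, object] = {"patient_id": m.patient_id, "dmax": m.dmax, "dmean": m.dmean}
        for x in thresholds:
            row[vx_column(x)] = m.vx[float(x)]
        rows.append(row)
    return pd.DataFrame(rows)


def vx_column(x: float) -> str:
    """Column name for a Vx threshold, e.g. 65 -> ``v65``."""
    xf = float(x)
    return f"v{int(xf)}" if xf == int(xf) else f"v{xf:g}"
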