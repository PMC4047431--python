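"""Experimental observables: displacement tracks and anterior chamber depth.

The in vivo experiment this package models yields, per eye, (i) the axial
(Y) displacement of a few characteristic points on the iris surface as a
function of the anterior-posterior pressure differential, digitized from
ultrasound frames, and (ii) the anterior chamber depth (ACD) at a few
pressure levels.  The ACD varies linearly with pressure over the range of
interest; its fitted slope prescribes the axial translation of the rigid
lens in the forward model.

CSV dialects (one-line headers, plain UTF-8):

* ACD file:          dp_mmHg, acd_mm
* track file:        point_id, dp_mmHg, uy_mm
* coordinates file:  point_id, dp_mmHg, x_mm, y_mm
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

__all__ = ["ACDSeries", "ACDFit", "DisplacementTrack",
           "fit_acd_vs_pressure", "lens_displacement",
           "tracks_from_coordinates",
           "read_acd_csv", "write_acd_csv",
           "read_tracks_csv", "write_tracks_csv", "read_coordinates_csv"]


@dataclass(frozen=True)
class ACDSeries:
    """Anterior chamber depth (mm) vs pressure differential (mmHg)."""

    dp: np.ndarray
    acd: np.ndarray

    def __post_init__(self):
        dp = np.asarray(self.dp, dtype=float)
        acd = np.asarray(self.acd, dtype=float)
        if dp.shape != acd.shape or dp.ndim != 1 or len(dp) < 2:
            raise ValueError("ACD series needs >= 2 (dp, depth) records")
        if np.any(dp < 0):
            raise ValueError("pressure differentials must be >= 0")
        if np.any(acd <= 0):
            raise ValueError("depths must be positive")
        object.__setattr__(self, "dp", dp)
        object.__setattr__(self, "acd", acd)


class ACDFit(NamedTuple):
    slope: float          # mm / mmHg
    intercept: float      # mm at dp = 0
    residual_se: float    # mm


@dataclass(frozen=True)
class DisplacementTrack:
    """Axial displacement (mm, positive posterior) of one characteristic
    point vs pressure differential (mmHg)."""

    point_id: str
    dp: np.ndarray
    uy: np.ndarray
    source: str = "experimental"
    reference_point: tuple[float, float] | None = None

    def __post_init__(self):
        dp = np.asarray(self.dp, dtype=float)
        uy = np.asarray(self.uy, dtype=float)
        if dp.shape != uy.shape or dp.ndim != 1:
            raise ValueError("dp and uy must be matching 1-D arrays")
        if len(dp) > 1 and np.any(np.diff(dp) <= 0):
            raise ValueError("pressure levels must be strictly increasing")
        if len(dp) and dp[0] == 0.0 and uy[0] != 0.0:
            raise ValueError("displacement at dp = 0 must be 0")
        if self.source not in ("experimental", "simulated"):
            raise ValueError("source must be experimental or simulated")
        object.__setattr__(self, "dp", dp)
        object.__setattr__(self, "uy", uy)

    def interpolated(self, dp_new: np.ndarray) -> "DisplacementTrack":
        """Piecewise-linear resampling onto a new pressure grid."""
        dp_new = np.asarray(dp_new, dtype=float)
        return DisplacementTrack(self.point_id, dp_new,
                                 np.interp(dp_new, self.dp, self.uy),
                                 source=self.source,
                                 reference_point=self.reference_point)


def fit_acd_vs_pressure(series: ACDSeries) -> ACDFit:
    """Ordinary least-squares line ACD = intercept + slope * dp.

    The residual standard error uses n - 2 degrees of freedom (0.0 when
    only two points are supplied).
    """
    dp, acd = series.dp, series.acd
    if np.ptp(dp) == 0:
        raise ValueError("degenerate fit: all pressure values equal")
    X = np.column_stack([np.ones_like(dp), dp])
    coef, *_ = np.linalg.lstsq(X, acd, rcond=None)
    resid = acd - X @ coef
    n = len(dp)
    rse = float(np.sqrt(np.sum(resid**2) / (n - 2))) if n > 2 else 0.0
    return ACDFit(slope=float(coef[1]), intercept=float(coef[0]),
                  residual_se=rse)


def lens_displacement(fit: ACDFit | Sequence[float], dp: float) -> float:
    """Axial lens translation (mm) at pressure differential dp (mmHg).

    The lens recedes by the change in anterior chamber depth relative to
    dp = 0, i.e. slope * dp.
    """
    if dp < 0:
        raise ValueError("pressure differential must be >= 0")
    slope = fit[0] if not hasattr(fit, "slope") else fit.slope
    return float(slope) * float(dp)


def tracks_from_coordinates(
        coords: pd.DataFrame | Sequence[pd.DataFrame],
        reference_dp: float = 0.0,
        return_report: bool = False):
    """Displacement tracks from marked-point coordinates.

    ``coords`` is a coordinates table (point_id, dp_mmHg, x_mm, y_mm) or a
    list of such tables from independent observers; matched (point, level)
    coordinates are averaged across observers.  u_y = y(dp) - y(reference);
    x-coordinate changes are ignored.  Points missing at some level yield a
    track truncated at the last complete level (with a warning); a point
    absent at the reference level is an error.

    With ``return_report=True`` also returns a table of inter-observer
    coordinate ranges.
    """
    if isinstance(coords, pd.DataFrame):
        frames = [coords]
    else:
        frames = list(coords)
    allc = pd.concat(frames, ignore_index=True)
    grouped = allc.groupby(["point_id", "dp_mmHg"], sort=True)
    mean = grouped[["x_mm", "y_mm"]].mean()
    rng = grouped[["x_mm", "y_mm"]].agg(lambda s: s.max() - s.min())

    tracks = []
    for pid, sub in mean.groupby(level="point_id", sort=True):
        sub = sub.droplevel("point_id")
        dps = np.asarray(sorted(sub.index))
        if reference_dp not in sub.index:
            raise ValueError(
                f"point {pid!r} has no coordinates at the reference level")
        y0 = float(sub.loc[reference_dp, "y_mm"])
        uy = sub.loc[dps, "y_mm"].to_numpy() - y0
        tracks.append(DisplacementTrack(point_id=str(pid), dp=dps, uy=uy,
                                        source="experimental"))
    # truncate tracks at the last level where every point is present
    counts = mean.groupby(level="dp_mmHg").size()
    complete = counts[counts == len(tracks)].index
    cutoff = complete.max() if len(complete) else reference_dp
    if any(t.dp[-1] > cutoff for t in tracks):
        warnings.warn("some points missing at higher levels; tracks "
                      f"truncated at dp = {cutoff} mmHg")
        tracks = [DisplacementTrack(t.point_id, t.dp[t.dp <= cutoff],
                                    t.uy[t.dp <= cutoff], t.source)
                  for t in tracks]
    if return_report:
        return tracks, rng.reset_index()
    return tracks


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

def read_acd_csv(path: str | Path) -> ACDSeries:
    df = pd.read_csv(path)
    return ACDSeries(df["dp_mmHg"].to_numpy(), df["acd_mm"].to_numpy())


def write_acd_csv(series: ACDSeries, path: str | Path) -> None:
    pd.DataFrame({"dp_mmHg": series.dp, "acd_mm": series.acd}).to_csv(
        path, index=False)


def read_tracks_csv(path: str | Path,
                    source: str = "experimental") -> list[DisplacementTrack]:
    df = pd.read_csv(path)
    out = []
    for pid, sub in df.groupby("point_id", sort=True):
        sub = sub.sort_values("dp_mmHg")
        out.append(DisplacementTrack(str(pid), sub["dp_mmHg"].to_numpy(),
                                     sub["uy_mm"].to_numpy(), source=source))
    return out


def write_tracks_csv(tracks: Sequence[DisplacementTrack],
                     path: str | Path) -> None:
    rows = []
    for t in tracks:
        for d, u in zip(t.dp, t.uy):
            rows.append((t.point_id, d, u))
    pd.DataFrame(rows, columns=["point_id", "dp_mmHg", "uy_mm"]).to_csv(
        path, index=False)


def read_coordinates_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    needed = {"point_id", "dp_mmHg", "x_mm", "y_mm"}
    if not needed.issubset(df.columns):
        raise ValueError(f"coordinates file must have columns {sorted(needed)}")
    return df
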