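"""Displacement-mismatch objective functional of the inverse problem.

For N tracked surface points and P pressure levels the functional is

    eps = (1/N) * sum_n sum_p (u_exp[n, p] - u_sim[n, p])**2    [mm^2]

i.e. the mean over points of the sum over levels of squared axial
displacement residuals.  Note the normalization is by the number of points
only, not by the number of levels; an optional normalize-by-N*P mode is
provided for cross-study comparability but is off by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .measurements import DisplacementTrack

__all__ = ["ObjectiveValue", "objective_functional", "AlignmentError"]


class AlignmentError(ValueError):
    """Experimental and simulated track sets do not line up."""


@dataclass(frozen=True)
class ObjectiveValue:
    """Objective value with its residual decomposition."""

    epsilon: float              # mm^2
    residuals: pd.DataFrame     # point_id, dp_mmHg, residual_mm
    n_points: int
    n_levels: int

    def __float__(self) -> float:
        return self.epsilon


def objective_functional(
        experimental: list[DisplacementTrack],
        simulated: list[DisplacementTrack],
        normalize_by_levels: bool = False) -> ObjectiveValue:
    """Evaluate the mismatch functional between matched track sets.

    Both sets must contain the same point ids on identical pressure grids
    (interpolate the simulation onto the experimental grid first; see
    :meth:`DisplacementTrack.interpolated`).
    """
    exp = {t.point_id: t for t in experimental}
    sim = {t.point_id: t for t in simulated}
    if set(exp) != set(sim):
        raise AlignmentError(
            f"point sets differ: {sorted(set(exp) ^ set(sim))}")
    if not exp:
        raise AlignmentError("empty track sets")

    rows = []
    total = 0.0
    n_levels = None
    for pid in sorted(exp):
        te, ts = exp[pid], sim[pid]
        if len(te.dp) != len(ts.dp) or not np.allclose(te.dp, ts.dp):
            raise AlignmentError(f"pressure grids differ for point {pid!r}")
        if n_levels is None:
            n_levels = len(te.dp)
        elif n_levels != len(te.dp):
            raise AlignmentError(f"level count differs for point {pid!r}")
        r = te.uy - ts.uy
        total += float(np.sum(r**2))
        for d, ri in zip(te.dp, r):
            rows.append((pid, d, ri))

    n = len(exp)
    eps = total / n
    if normalize_by_levels:
        eps /= n_levels
    return ObjectiveValue(
        epsilon=eps,
        residuals=pd.DataFrame(rows,
                               columns=["point_id", "dp_mmHg", "residual_mm"]),
        n_points=n, n_levels=n_levels)
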