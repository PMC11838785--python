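"""Speed-accuracy routing optimization: the q metric and the r_lex sweep.

The lexical interference strength r_lex trades errors against speed: weak
interference slows naming but avoids incongruent errors, strong
interference speeds congruent naming but lets the distractor win more
often.  The q metric scores each candidate r_lex as the sum of the
min-max-normalized incongruent error rate (e_i), mean incongruent RT (t_i),
and mean congruent RT (t_c) across the sweep; the r_lex minimizing q
balances all three.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace

import numpy as np

from .errors import DataError
from .stroop import StroopModel

__all__ = ["SweepPoint", "default_grid", "q_scores", "sweep_rlex"]


@dataclass(frozen=True)
class SweepPoint:
    """Metrics for one r_lex grid value.

    ``e_i`` is the incongruent error rate over all incongruent trials
    (convergence failures count as errors); ``t_i`` and ``t_c`` are mean
    steps over correct incongruent / congruent trials.  The normalized
    terms and ``q`` are defined only relative to a whole sweep and are NaN
    until :func:`q_scores` fills them in.
    """

    r_lex: float
    e_i: float
    t_i: float
    t_c: float
    e_i_norm: float = math.nan
    t_i_norm: float = math.nan
    t_c_norm: float = math.nan
    q: float = math.nan


def default_grid() -> np.ndarray:
    """The canonical sweep grid: 0.0 to 1.0 in 0.05 increments (21 values)."""
    return np.round(np.arange(0, 21) * 0.05, 2)


def _minmax(values: np.ndarray, name: str) -> np.ndarray:
    lo, hi = float(np.min(values)), float(np.max(values))
    if hi == lo:
        warnings.warn(
            f"metric {name} is constant across the sweep; its q term is 0",
            stacklevel=3)
        return np.zeros_like(values)
    return (values - lo) / (hi - lo)


def q_scores(points) -> list[SweepPoint]:
    """Fill in normalized metric terms and q = sum of the three terms.

    Min-max normalization is taken across the given sweep, so q is only
    meaningful for a full set of points and is invariant under affine
    rescaling of any single metric.
    """
    points = list(points)
    if len(points) < 2:
        raise DataError("q scoring needs at least two sweep points")
    e = _minmax(np.array([p.e_i for p in points]), "e_i")
    ti = _minmax(np.array([p.t_i for p in points]), "t_i")
    tc = _minmax(np.array([p.t_c for p in points]), "t_c")
    return [replace(p, e_i_norm=float(e[k]), t_i_norm=float(ti[k]),
                    t_c_norm=float(tc[k]), q=float(e[k] + ti[k] + tc[k]))
            for k, p in enumerate(points)]


def sweep_rlex(model: StroopModel, grid=None, r_sem: float = 0.05):
    """Sweep r_lex over the grid on one trained model and pick the best.

    Runs the full 272-trial factorial at each grid value with transfer gain
    ``r_sem``, computes (e_i, t_i, t_c), scores q across the sweep, and
    returns ``(points, selected_r_lex)`` where the selection is the
    q-argmin (ties break toward the smaller r_lex).  Grid values where no
    congruent trial converges are excluded with a warning.  The same
    trained model is reused for every grid value: routing parameters affect
    only the task loop, never training.
    """
    if grid is None:
        grid = default_grid()
    raw: list[SweepPoint] = []
    for r in grid:
        results = model.run_factorial(r_lex=float(r), gamma=r_sem)
        inc = [t for t in results if t.spec.condition == "incongruent"]
        con = [t for t in results if t.spec.condition == "congruent"]
        e_i = 1.0 - sum(t.correct for t in inc) / len(inc)
        inc_steps = [t.steps for t in inc if t.correct]
        con_steps = [t.steps for t in con if t.correct]
        if not con_steps:
            warnings.warn(
                f"r_lex={r}: no congruent trial converged; point excluded",
                stacklevel=2)
            continue
        t_i = float(np.mean(inc_steps)) if inc_steps else math.nan
        raw.append(SweepPoint(r_lex=float(r), e_i=e_i, t_i=t_i,
                              t_c=float(np.mean(con_steps))))
    if len(raw) < 2:
        raise DataError("fewer than two valid sweep points")
    # A grid value with no correct incongruent trial has undefined t_i;
    # treat it as the sweep maximum so it cannot win the argmin.
    t_i_vals = np.array([p.t_i for p in raw])
    if np.any(np.isnan(t_i_vals)):
        fill = float(np.nanmax(t_i_vals))
        raw = [replace(p, t_i=fill) if math.isnan(p.t_i) else p for p in raw]
    points = q_scores(raw)
    best = min(points, key=lambda p: (p.q, p.r_lex))
    return points, best.r_lex
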