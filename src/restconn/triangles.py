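"""3-cycle triangle-area functional segregation.

Each node triple (i, j, k) defines a triangle whose sides are the three
pairwise correlation coefficients; its area, by Heron's formula,
summarizes how strongly the triple is mutually coupled.  A triple is
admitted when its area reaches that of the hypothetical equilateral
triangle with side r = 0.6 — the most-representative-connectivity
criterion.  Correlation sides need not satisfy the triangle inequality,
so geometrically invalid triples are excluded and counted.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .connectivity import ConnectivityMatrix
from .exceptions import ParameterError, ScopeError

#: Numerical slack for boundary admission (areas equal to the threshold pass).
AREA_TOL = 1e-12

DEFAULT_SIDE_THRESHOLD = 0.6


@dataclass(frozen=True)
class Triangle:
    """One admitted 3-cycle: node indices i<j<k, sides, Heron area."""

    nodes: tuple[int, int, int]
    sides: tuple[float, float, float]
    area: float


@dataclass(frozen=True)
class TriangleSet:
    """Admitted triangles over one scope plus enumeration diagnostics."""

    scope: str
    admission_threshold: float
    nodes: np.ndarray          # (m, 3) int, each row sorted i<j<k
    sides: np.ndarray          # (m, 3) float
    areas: np.ndarray          # (m,) float
    n_candidates: int          # all triples examined: C(len(indices), 3)
    n_zero_side: int           # triples dropped for a zero correlation side
    n_invalid: int             # triples dropped for violating the triangle inequality

    def __len__(self) -> int:
        return int(self.areas.size)

    @property
    def triangles(self) -> list[Triangle]:
        return [
            Triangle(tuple(int(v) for v in n), tuple(float(s) for s in ss), float(a))
            for n, ss, a in zip(self.nodes, self.sides, self.areas)
        ]


def heron_area(a: float, b: float, c: float) -> float | None:
    """Heron's formula A = sqrt(s(s-a)(s-b)(s-c)), s the semiperimeter.

    Returns ``None`` when the triangle inequality fails (radicand <= 0);
    raises :class:`ParameterError` on a nonpositive side.
    """
    if a <= 0 or b <= 0 or c <= 0:
        raise ParameterError(f"triangle sides must be positive, got {(a, b, c)}")
    s = (a + b + c) / 2.0
    radicand = s * (s - a) * (s - b) * (s - c)
    if radicand <= 0:
        return None
    return math.sqrt(radicand)


def area_threshold(side: float = DEFAULT_SIDE_THRESHOLD) -> float:
    """Admission area: the equilateral triangle with the given side.

    The default side 0.6 gives 0.155885 (0.1559 at 4 dp).
    """
    if not 0.0 < side <= 1.0:
        raise ParameterError(f"side must be in (0, 1], got {side}")
    area = heron_area(side, side, side)
    assert area is not None  # equilateral is always valid
    return area


def enumerate_triangles(
    C: ConnectivityMatrix,
    indices: list[int],
    thr: float | None = None,
    scope: str = "whole_brain",
    min_side: float | None = None,
) -> TriangleSet:
    """All node triples within ``indices``, admitted by Heron area.

    Sides are raw correlation coefficients from ``C``.  Triples with any
    zero side or invalid geometry are excluded (and counted); the rest
    are admitted iff area >= thr - 1e-12.  ``thr`` defaults to
    ``area_threshold(0.6)``.  ``min_side`` optionally restricts
    enumeration to triples whose three sides all exceed that value (the
    neighbouring-nodes variant); by default all triples compete.
    """
    if C.space != "r":
        raise ParameterError("triangle sides are raw correlations; pass an r-space matrix")
    if len(indices) < 3:
        raise ScopeError(f"scope {scope!r} needs at least 3 nodes, got {len(indices)}")
    if thr is None:
        thr = area_threshold()

    idx = np.asarray(sorted(indices), dtype=int)
    triples = np.array(list(itertools.combinations(range(idx.size), 3)), dtype=int)
    sub = C.values[np.ix_(idx, idx)]
    i, j, k = triples[:, 0], triples[:, 1], triples[:, 2]
    sides = np.column_stack([sub[i, j], sub[i, k], sub[j, k]])

    nonzero = (sides > 0).all(axis=1)
    n_zero = int((~nonzero).sum())
    if min_side is not None:
        nonzero &= (sides > min_side).all(axis=1)

    s = sides.sum(axis=1) / 2.0
    radicand = s * (s - sides[:, 0]) * (s - sides[:, 1]) * (s - sides[:, 2])
    valid = nonzero & (radicand > 0)
    n_invalid = int((nonzero & (radicand <= 0)).sum())
    areas = np.where(valid, np.sqrt(np.where(valid, radicand, 1.0)), 0.0)

    admitted = valid & (areas >= thr - AREA_TOL)
    order = np.argsort(-areas[admitted], kind="stable")
    sel = np.flatnonzero(admitted)[order]
    return TriangleSet(
        scope=scope,
        admission_threshold=float(thr),
        nodes=idx[triples[sel]],
        sides=sides[sel],
        areas=areas[sel],
        n_candidates=int(triples.shape[0]),
        n_zero_side=n_zero,
        n_invalid=n_invalid,
    )


def triangle_estimators(ts: TriangleSet, adjusted_skewness: bool = False) -> dict:
    """Summary row of the admitted areas: N, mean, median, skewness, sd,
    min, max.

    For N = 0 only N is reported; skewness is 0 for N <= 2 (moment-based
    Fisher-Pearson g1 by default, the bias-adjusted estimator on request);
    sd uses the n-1 convention (0 for N = 1).
    """
    n = len(ts)
    if n == 0:
        return {"N": 0, "mean": None, "median": None, "skewness": None,
                "sd": None, "min": None, "max": None}
    areas = ts.areas
    mean = float(areas.mean())
    sd = float(areas.std(ddof=1)) if n > 1 else 0.0
    if n <= 2:
        skew = 0.0
    else:
        m2 = float(((areas - mean) ** 2).mean())
        m3 = float(((areas - mean) ** 3).mean())
        skew = 0.0 if m2 == 0 else m3 / m2 ** 1.5
        if adjusted_skewness and m2 > 0:
            skew *= math.sqrt(n * (n - 1)) / (n - 2)
    return {
        "N": n,
        "mean": mean,
        "median": float(np.median(areas)),
        "skewness": float(skew),
        "sd": sd,
        "min": float(areas.min()),
        "max": float(areas.max()),
    }


def estimator_table(rows: dict[str, TriangleSet], **kwargs) -> pd.DataFrame:
    """Estimator rows for several (group, scope) TriangleSets as a table."""
    records = []
    for name, ts in rows.items():
        rec = {"group_scope": name, **triangle_estimators(ts, **kwargs)}
        records.append(rec)
    return pd.DataFrame(records)
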