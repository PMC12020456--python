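"""Octahedral (Lebedev-type) quadrature grids on the unit sphere.

The packaged grids use the classical octahedral orbit classes

    a1  vertices            ( +-1, 0, 0 ) ...                     6 points
    a2  edge midpoints      ( +-1/sqrt2, +-1/sqrt2, 0 ) ...      12 points
    a3  face centers        ( +-1/sqrt3, +-1/sqrt3, +-1/sqrt3 )   8 points
    b   ( a, a, c )  orbits, c = sqrt(1 - 2 a^2)                 24 points
    c   ( p, q, 0 )  orbits, q = sqrt(1 - p^2)                   24 points
    d   ( a, b, c )  general orbits                              48 points

at the canonical grid sizes 6 ... 770.  The class parameters and weights are
stored as plain text (data/grid_params.json); they were produced by the
moment-fitting solver in :mod:`dracopcm.gridgen` (see
scripts/generate_grids.py) and each grid integrates all spherical harmonics
up to the algebraic degree recorded next to it.  All weights are strictly
positive (a requirement of the Gaussian width formula), which is why a few
sizes carry a slightly lower degree than the classical rules of the same
size.  Weights are normalized to sum to 1 over the unit sphere.
"""

from __future__ import annotations

import json
from functools import lru_cache
from importlib import resources
from itertools import permutations

import numpy as np

__all__ = ["lebedev_grid", "available_orders", "grid_degree"]

_SQ2 = 1.0 / np.sqrt(2.0)


def _orbit_a1() -> np.ndarray:
    return np.array(
        [[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]],
        dtype=float,
    )


def _orbit_a2() -> np.ndarray:
    pts = []
    for i in range(3):
        for j in range(i + 1, 3):
            for si in (1, -1):
                for sj in (1, -1):
                    p = [0.0, 0.0, 0.0]
                    p[i] = si * _SQ2
                    p[j] = sj * _SQ2
                    pts.append(p)
    return np.array(pts)


def _orbit_a3() -> np.ndarray:
    s = 1.0 / np.sqrt(3.0)
    return np.array(
        [[sx * s, sy * s, sz * s] for sx in (1, -1) for sy in (1, -1) for sz in (1, -1)]
    )


def _orbit_b(a: float) -> np.ndarray:
    c = np.sqrt(max(1.0 - 2.0 * a * a, 0.0))
    pts = []
    for pos in range(3):
        idx = [k for k in range(3) if k != pos]
        for s0 in (1, -1):
            for s1 in (1, -1):
                for s2 in (1, -1):
                    w = [0.0, 0.0, 0.0]
                    w[pos] = s2 * c
                    w[idx[0]] = s0 * a
                    w[idx[1]] = s1 * a
                    pts.append(w)
    return np.array(pts)


def _orbit_c(p: float) -> np.ndarray:
    q = np.sqrt(max(1.0 - p * p, 0.0))
    pts = []
    for ip in range(3):
        for iq in range(3):
            if iq == ip:
                continue
            for sp in (1, -1):
                for sq in (1, -1):
                    w = [0.0, 0.0, 0.0]
                    w[ip] = sp * p
                    w[iq] = sq * q
                    pts.append(w)
    return np.array(pts)


def _orbit_d(theta: float, phi: float) -> np.ndarray:
    a = np.sin(theta) * np.cos(phi)
    b = np.sin(theta) * np.sin(phi)
    c = np.cos(theta)
    pts = []
    for perm in permutations((0, 1, 2)):
        v = (a, b, c)
        for s0 in (1, -1):
            for s1 in (1, -1):
                for s2 in (1, -1):
                    pts.append([s0 * v[perm[0]], s1 * v[perm[1]], s2 * v[perm[2]]])
    return np.array(pts)


_ORBITS = {
    "a1": (_orbit_a1, 0, 6),
    "a2": (_orbit_a2, 0, 12),
    "a3": (_orbit_a3, 0, 8),
    "b": (_orbit_b, 1, 24),
    "c": (_orbit_c, 1, 24),
    "d": (_orbit_d, 2, 48),
}


def expand_classes(classes) -> tuple[np.ndarray, np.ndarray]:
    """Points and weights from a list of {type, params, weight} records."""
    pts, wts = [], []
    for cls in classes:
        fn, npar, size = _ORBITS[cls["type"]]
        p = fn(*cls.get("params", [])[:npar])
        pts.append(p)
        wts.append(np.full(size, cls["weight"]))
    return np.vstack(pts), np.concatenate(wts)


@lru_cache(maxsize=1)
def _load_table() -> dict:
    text = resources.files("dracopcm.data").joinpath("grid_params.json").read_text()
    return json.loads(text)


def available_orders() -> tuple:
    return tuple(sorted(int(k) for k in _load_table()))


def grid_degree(order: int) -> int:
    """Algebraic exactness degree of the packaged grid of this size."""
    return int(_load_table()[str(order)]["degree"])


@lru_cache(maxsize=None)
def _grid(order: int) -> tuple[np.ndarray, np.ndarray]:
    table = _load_table()
    key = str(order)
    if key not in table:
        raise KeyError(
            f"no packaged grid of size {order}; available: {available_orders()}"
        )
    pts, wts = expand_classes(table[key]["classes"])
    pts.setflags(write=False)
    wts.setflags(write=False)
    return pts, wts


def lebedev_grid(order: int) -> tuple[np.ndarray, np.ndarray]:
    """Unit-sphere points (order, 3) and weights (order,) summing to 1."""
    return _grid(int(order))
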