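"""CIE Lab colour engine and the hybrid response space.

The response interface presents a single colour patch whose appearance is
driven by four physical channels (tablet x/y, pen pressure, joystick
throttle).  The patch colour lives in CIE L*a*b* (D65, 2° observer); the
display can only render the subset of the Lab box that falls inside the
sRGB gamut (IEC 61966-2-1).  The *hybrid* space makes the whole input box
meaningful by giving every out-of-gamut grid cell the colour of its
nearest in-gamut cell (Euclidean distance in Lab).

Conventions pinned here:

* White point is D65 from its chromaticity (x, y) = (0.3127, 0.3290) and
  the XYZ↔linear-RGB matrices are derived exactly from the sRGB primaries
  and that white, so that L*a*b* = (100, 0, 0) maps to RGB (1, 1, 1)
  bit-exactly.
* A linear channel within [-1e-9, 1 + 1e-9] counts as inside the gamut.
* Nearest-visible ties are broken toward the cell earliest in (L, a, b)
  lexicographic grid order.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "ColourPatch",
    "InterfaceInput",
    "HybridColourGrid",
    "WHITE_D65",
    "lab_to_xyz",
    "xyz_to_lab",
    "lab_to_linear_rgb",
    "linear_rgb_to_lab",
    "lab_to_srgb",
    "srgb_to_lab",
    "is_visible",
    "build_hybrid_grid",
    "nearest_visible",
    "map_interface_input",
    "mean_patch",
]

GAMUT_TOL = 1e-9

# sRGB primaries and D65 white, IEC 61966-2-1.
_PRIMARIES_XY = np.array([[0.64, 0.33], [0.30, 0.60], [0.15, 0.06]])
_WHITE_XY = np.array([0.3127, 0.3290])


def _xy_to_xyz(x: float, y: float) -> np.ndarray:
    return np.array([x / y, 1.0, (1.0 - x - y) / y])


WHITE_D65 = _xy_to_xyz(*_WHITE_XY)


def _rgb_matrices() -> tuple[np.ndarray, np.ndarray]:
    # Solve for primary scalings so that R=G=B=1 yields the white point.
    cols = np.stack([_xy_to_xyz(x, y) for x, y in _PRIMARIES_XY], axis=1)
    scale = np.linalg.solve(cols, WHITE_D65)
    xyz_from_rgb = cols * scale
    return xyz_from_rgb, np.linalg.inv(xyz_from_rgb)


_XYZ_FROM_RGB, _RGB_FROM_XYZ = _rgb_matrices()

_DELTA = 6.0 / 29.0


def _f(t: np.ndarray) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    return np.where(t > _DELTA**3, np.cbrt(t), t / (3 * _DELTA**2) + 4.0 / 29.0)


def _f_inv(t: np.ndarray) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    return np.where(t > _DELTA, t**3, 3 * _DELTA**2 * (t - 4.0 / 29.0))


def _check_white(white_point: Sequence[float]) -> np.ndarray:
    wp = np.asarray(white_point, dtype=float)
    if wp.shape != (3,) or np.any(wp <= 0):
        raise ValueError("white point must be three strictly positive XYZ values")
    return wp


def lab_to_xyz(lab, white_point=WHITE_D65) -> np.ndarray:
    """CIE L*a*b* → XYZ (inverse CIE 1976 transform).

    Accepts a single (L, a, b) triple or an (n, 3) array.
    """
    wp = _check_white(white_point)
    lab = np.asarray(lab, dtype=float)
    fy = (lab[..., 0] + 16.0) / 116.0
    fx = fy + lab[..., 1] / 500.0
    fz = fy - lab[..., 2] / 200.0
    return np.stack(
        [wp[0] * _f_inv(fx), wp[1] * _f_inv(fy), wp[2] * _f_inv(fz)], axis=-1
    )


def xyz_to_lab(xyz, white_point=WHITE_D65) -> np.ndarray:
    """XYZ → CIE L*a*b* (CIE 1976 forward transform)."""
    wp = _check_white(white_point)
    xyz = np.asarray(xyz, dtype=float)
    fx = _f(xyz[..., 0] / wp[0])
    fy = _f(xyz[..., 1] / wp[1])
    fz = _f(xyz[..., 2] / wp[2])
    return np.stack([116.0 * fy - 16.0, 500.0 * (fx - fy), 200.0 * (fy - fz)], axis=-1)


def lab_to_linear_rgb(lab, white_point=WHITE_D65) -> np.ndarray:
    """Lab → linear (pre-gamma) sRGB channels; may fall outside [0, 1]."""
    return lab_to_xyz(lab, white_point) @ _RGB_FROM_XYZ.T


def linear_rgb_to_lab(rgb, white_point=WHITE_D65) -> np.ndarray:
    return xyz_to_lab(np.asarray(rgb, dtype=float) @ _XYZ_FROM_RGB.T, white_point)


def _srgb_encode(c: np.ndarray) -> np.ndarray:
    c = np.asarray(c, dtype=float)
    return np.where(c <= 0.0031308, 12.92 * c, 1.055 * np.abs(c) ** (1 / 2.4) - 0.055)


def _srgb_decode(c: np.ndarray) -> np.ndarray:
    c = np.asarray(c, dtype=float)
    return np.where(c <= 0.04045, c / 12.92, ((c + 0.055) / 1.055) ** 2.4)


def lab_to_srgb(lab, white_point=WHITE_D65) -> np.ndarray:
    """Lab → gamma-encoded sRGB.  Only meaningful for in-gamut colours."""
    return _srgb_encode(lab_to_linear_rgb(lab, white_point))


def srgb_to_lab(rgb, white_point=WHITE_D65) -> np.ndarray:
    return linear_rgb_to_lab(_srgb_decode(rgb), white_point)


def is_visible(lab, tol: float = GAMUT_TOL) -> np.ndarray | bool:
    """True where the Lab colour lies inside the sRGB display gamut.

    Visibility means all three *linear* RGB channels are in [0, 1] within
    ``tol``; the boundary tolerance makes the decision reproducible across
    floating-point dialects.
    """
    rgb = lab_to_linear_rgb(lab)
    ok = np.all((rgb >= -tol) & (rgb <= 1.0 + tol), axis=-1)
    return bool(ok) if ok.ndim == 0 else ok


@dataclass(frozen=True)
class ColourPatch:
    """One colour patch response: relative size plus a Lab colour.

    ``size`` is the fraction of the maximal patch radius in [0, 1];
    ``L`` in [0, 100]; ``a``/``b`` in [-100, 100].
    """

    size: float
    L: float
    a: float
    b: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.size <= 1.0:
            raise ValueError(f"size {self.size} outside [0, 1]")
        if not 0.0 <= self.L <= 100.0:
            raise ValueError(f"L {self.L} outside [0, 100]")
        for name in ("a", "b"):
            v = getattr(self, name)
            if not -100.0 <= v <= 100.0:
                raise ValueError(f"{name} {v} outside [-100, 100]")

    @property
    def lab(self) -> np.ndarray:
        return np.array([self.L, self.a, self.b])

    def colour_distance(self, other: "ColourPatch") -> float:
        """Euclidean distance between the two colours in (L, a, b)."""
        return float(np.linalg.norm(self.lab - other.lab))


@dataclass(frozen=True)
class InterfaceInput:
    """One 10 Hz sample of the physical interface.

    Tablet (x, y) steers (a*, b*); pen pressure steers patch size; the
    joystick throttle steers Lightness.  While the pen is lifted
    (``pen_down`` False) no patch is shown.
    """

    x: float
    y: float
    pressure: float
    throttle: float
    pen_down: bool = True

    def __post_init__(self) -> None:
        for name in ("x", "y", "pressure", "throttle"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} {v} outside [0, 1]")


class HybridColourGrid:
    """Discretised Lab box with visibility mask and borrowed-colour index.

    Cells are enumerated over L ∈ {0, step, …, 100} and a, b ∈
    {−100, …, 100} in lexicographic (L, a, b) order.  Invisible cells
    borrow the colour of the Euclidean-nearest visible cell (ties to the
    lexicographically earliest cell); visible cells map to themselves.
    """

    def __init__(self, step: float, labs: np.ndarray, visible: np.ndarray,
                 borrowed: np.ndarray, white_point: np.ndarray = WHITE_D65):
        self.step = float(step)
        self.labs = labs
        self.visible = visible
        self.borrowed = borrowed
        self.white_point = np.asarray(white_point, dtype=float)
        self._L_axis = np.arange(0.0, 100.0 + step / 2, step)
        self._ab_axis = np.arange(-100.0, 100.0 + step / 2, step)

    # -- basic stats -------------------------------------------------
    @property
    def n_cells(self) -> int:
        return self.labs.shape[0]

    @property
    def n_visible(self) -> int:
        return int(self.visible.sum())

    def stats(self) -> dict:
        return {
            "step": self.step,
            "cells": self.n_cells,
            "visible": self.n_visible,
            "invisible_fraction": 1.0 - self.n_visible / self.n_cells,
        }

    # -- snapping ----------------------------------------------------
    def _cell_index(self, lab: np.ndarray) -> np.ndarray:
        """Flat index of the grid cell nearest to each Lab point.

        Half-way ties round toward the lower grid value, i.e. toward the
        lexicographically earlier cell.
        """
        lab = np.atleast_2d(np.asarray(lab, dtype=float))
        nL, nab = len(self._L_axis), len(self._ab_axis)
        iL = np.clip(np.ceil((lab[:, 0] - 0.0) / self.step - 0.5), 0, nL - 1)
        ia = np.clip(np.ceil((lab[:, 1] + 100.0) / self.step - 0.5), 0, nab - 1)
        ib = np.clip(np.ceil((lab[:, 2] + 100.0) / self.step - 0.5), 0, nab - 1)
        return (iL.astype(np.int64) * nab + ia.astype(np.int64)) * nab + ib.astype(np.int64)

    def nearest_visible_lab(self, lab) -> np.ndarray:
        """Displayed (visible) colour for arbitrary Lab points; idempotent."""
        lab = np.asarray(lab, dtype=float)
        single = lab.ndim == 1
        idx = self._cell_index(lab)
        out = self.labs[self.borrowed[idx]]
        return out[0] if single else out

    # -- persistence -------------------------------------------------
    def to_csv(self, path) -> None:
        """Export as L,a,b,visible,borrowed_L,borrowed_a,borrowed_b."""
        disp = self.labs[self.borrowed]
        arr = np.column_stack([self.labs, self.visible.astype(int), disp])
        header = "L,a,b,visible,borrowed_L,borrowed_a,borrowed_b"
        np.savetxt(path, arr, delimiter=",", header=header, comments="",
                   fmt=["%.10g"] * 3 + ["%d"] + ["%.10g"] * 3)

    @classmethod
    def from_csv(cls, path, step: float) -> "HybridColourGrid":
        arr = np.loadtxt(path, delimiter=",", skiprows=1)
        labs = arr[:, :3]
        visible = arr[:, 3].astype(bool)
        tmp = cls(step, labs, visible, np.arange(len(labs)))
        borrowed = tmp._cell_index(arr[:, 4:7])
        return cls(step, labs, visible, borrowed)

    def save_npz(self, path) -> None:
        np.savez_compressed(path, step=self.step, visible=self.visible,
                            borrowed=self.borrowed, white_point=self.white_point)

    @classmethod
    def load_npz(cls, path) -> "HybridColourGrid":
        with np.load(path) as z:
            step = float(z["step"])
            labs = _enumerate_labs(step)
            return cls(step, labs, z["visible"], z["borrowed"], z["white_point"])


def _enumerate_labs(step: float) -> np.ndarray:
    L = np.arange(0.0, 100.0 + step / 2, step)
    ab = np.arange(-100.0, 100.0 + step / 2, step)
    Lg, Ag, Bg = np.meshgrid(L, ab, ab, indexing="ij")
    return np.stack([Lg.ravel(), Ag.ravel(), Bg.ravel()], axis=1)


_MEMORY_CACHE: dict[float, HybridColourGrid] = {}


def build_hybrid_grid(step: float = 2.0, cache_dir: str | Path | None = None,
                      use_memory_cache: bool = True) -> HybridColourGrid:
    """Build (or load) the hybrid grid at the given Lab resolution.

    ``step`` must divide the 100-unit L range and 200-unit a/b ranges
    evenly.  With ``cache_dir`` set, the mask and borrow index are cached
    on disk keyed by (step, gamut, white point); repeated in-process
    builds are served from a memory cache.
    """
    if step <= 0 or abs(100.0 / step - round(100.0 / step)) > 1e-12:
        raise ValueError(f"step {step} must divide the 100/200 Lab ranges evenly")
    step = float(step)
    if use_memory_cache and step in _MEMORY_CACHE:
        return _MEMORY_CACHE[step]

    cache_path = None
    if cache_dir is not None:
        key = f"grid_step{step:g}_srgb_d65.npz"
        cache_path = Path(cache_dir) / key
        if cache_path.exists():
            grid = HybridColourGrid.load_npz(cache_path)
            if use_memory_cache:
                _MEMORY_CACHE[step] = grid
            return grid

    labs = _enumerate_labs(step)
    visible = is_visible(labs)
    vis_pts = labs[visible]
    vis_flat = np.flatnonzero(visible)

    borrowed = np.arange(labs.shape[0], dtype=np.int64)
    inv_flat = np.flatnonzero(~visible)
    if inv_flat.size:
        tree = cKDTree(vis_pts)
        k = min(2, len(vis_pts))
        d, i = tree.query(labs[inv_flat], k=k)
        if k == 1:
            nearest = np.atleast_1d(i)
        else:
            nearest = i[:, 0].copy()
            # grid coordinates are integers, so tied distances compare exactly
            tied = d[:, 0] == d[:, 1]
            for row in np.flatnonzero(tied):
                ball = tree.query_ball_point(
                    labs[inv_flat[row]], d[row, 0] * (1 + 1e-12) + 1e-9
                )
                nearest[row] = min(ball)
        borrowed[inv_flat] = vis_flat[nearest]

    grid = HybridColourGrid(step, labs, visible, borrowed)
    if cache_path is not None:
        cache_path.parent.mkdir(parents=True, exist_ok=True)
        grid.save_npz(cache_path)
    if use_memory_cache:
        _MEMORY_CACHE[step] = grid
    return grid


def nearest_visible(lab, grid: HybridColourGrid) -> np.ndarray:
    """Displayed colour for a Lab point under the hybrid fill."""
    return grid.nearest_visible_lab(lab)


def map_interface_input(sample: InterfaceInput, grid: HybridColourGrid) -> ColourPatch | None:
    """Map one interface sample to the displayed colour patch.

    a* = −100 + 200·x, b* = −100 + 200·y, L = 100·throttle, size =
    pressure; the colour is snapped through the hybrid fill.  A lifted
    pen produces no patch.
    """
    if not sample.pen_down:
        return None
    lab = np.array([100.0 * sample.throttle,
                    -100.0 + 200.0 * sample.x,
                    -100.0 + 200.0 * sample.y])
    disp = grid.nearest_visible_lab(lab)
    return ColourPatch(size=sample.pressure, L=float(disp[0]),
                       a=float(disp[1]), b=float(disp[2]))


def map_interface_arrays(x, y, pressure, throttle, grid: HybridColourGrid) -> np.ndarray:
    """Vectorised interface mapping: returns an (n, 4) array of
    (size, L, a, b) rows, snapped through the hybrid fill."""
    x = np.asarray(x, dtype=float)
    for name, v in (("x", x), ("y", np.asarray(y, float)),
                    ("pressure", np.asarray(pressure, float)),
                    ("throttle", np.asarray(throttle, float))):
        if np.any((v < 0) | (v > 1)):
            raise ValueError(f"interface channel {name} outside [0, 1]")
    lab = np.column_stack([100.0 * np.asarray(throttle, float),
                           -100.0 + 200.0 * x,
                           -100.0 + 200.0 * np.asarray(y, float)])
    disp = grid.nearest_visible_lab(lab)
    return np.column_stack([np.asarray(pressure, float), disp])


def mean_patch(patches: Sequence[ColourPatch], weights=None) -> ColourPatch:
    """Weighted arithmetic mean of colour patches, per coordinate.

    Lab supports arithmetic directly (distances are Euclidean), so the
    mean patch is the coordinate-wise weighted mean of (size, L, a, b).
    Uniform weights are used when ``weights`` is omitted.
    """
    if len(patches) == 0:
        raise ValueError("mean_patch needs at least one patch")
    arr = np.array([[p.size, p.L, p.a, p.b] for p in patches])
    if weights is None:
        w = np.ones(len(patches))
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (len(patches),) or np.any(w < 0):
            raise ValueError("weights must be nonnegative, one per patch")
    if not np.any(w > 0):
        raise ValueError("all weights are zero; mean patch undefined")
    m = (arr * w[:, None]).sum(axis=0) / w.sum()
    return ColourPatch(size=float(m[0]), L=float(m[1]), a=float(m[2]), b=float(m[3]))
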