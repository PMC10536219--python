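"""Dual-polarization polarimetry: C2 covariance, speckle filtering, and indices.

A dual-pol SAR sensor measures, at every pixel, the complex scattering
amplitudes ``S_VV`` and ``S_VH``.  Spatially averaging the outer products of
the scattering vector ``k = (S_VV, S_VH)`` over a moving window yields the
2x2 Hermitian covariance matrix

    C2 = [[ <|S_VV|^2>,        <S_VV S_VH*> ],
          [ <S_VH S_VV*>,      <|S_VH|^2>   ]]

whose eigen-structure carries the polarimetric information.  With
eigenvalues ``lambda_1 >= lambda_2 >= 0``:

* degree of polarization (Barakat):  ``m = sqrt(1 - 4 det(C2) / Tr(C2)^2)``,
  0 for a fully depolarized wave, 1 for a fully polarized one;
* dominant-scattering measure:  ``beta = lambda_1 / (lambda_1 + lambda_2)``,
  in [0.5, 1];
* dual-pol radar vegetation index:  ``DpRVI = 1 - m * beta``, in [0, 1],
  near 0 over bare polarized surfaces and approaching 1 for the depolarized
  volume scattering of dense vegetation canopies.

Intensity-only companions computed from the same data are the dual-pol
radar vegetation index ``RVI = 4 sigma_VH / (sigma_VV + sigma_VH)`` and the
co/cross polarization ratio ``VV/VH``.

All grid operations are vectorized over 2-D rasters; single matrices are
handled as 0-d grids.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage

__all__ = [
    "C2Grid",
    "PolarimetricDescriptors",
    "IndexRaster",
    "RefinedLeeParams",
    "PolarimetryError",
    "DegenerateCovarianceError",
    "build_c2",
    "refined_lee_filter",
    "decompose",
    "dprvi",
    "rvi_dual_pol",
    "vv_vh_ratio",
    "index_stack",
    "index_stack_from_c2",
]

#: names of the indices this module can rasterize
INDEX_NAMES = ("dprvi", "rvi", "vvvh")

#: output nodata value used when rasters are written to disk
NODATA = -9999.0


class PolarimetryError(ValueError):
    """Invalid input to a polarimetric operation."""


class DegenerateCovarianceError(PolarimetryError):
    """A covariance matrix violates positive semidefiniteness beyond tolerance."""


@dataclass(frozen=True)
class C2Grid:
    """Grid of 2x2 Hermitian dual-pol covariance matrices.

    Only the independent elements are stored: the real diagonals ``c11``
    (co-pol power) and ``c22`` (cross-pol power) and the complex
    off-diagonal ``c12``; ``c21 = conj(c12)`` by construction.  Arrays share
    one shape; a 0-d shape represents a single matrix.
    """

    c11: np.ndarray
    c22: np.ndarray
    c12: np.ndarray

    def __post_init__(self):
        c11 = np.asarray(self.c11, dtype=float)
        c22 = np.asarray(self.c22, dtype=float)
        c12 = np.asarray(self.c12, dtype=complex)
        if not (c11.shape == c22.shape == c12.shape):
            raise PolarimetryError(
                f"C2 element shapes differ: {c11.shape}, {c22.shape}, {c12.shape}"
            )
        object.__setattr__(self, "c11", c11)
        object.__setattr__(self, "c22", c22)
        object.__setattr__(self, "c12", c12)

    @classmethod
    def single(cls, c11: float, c22: float, c12: complex = 0.0) -> "C2Grid":
        """One covariance matrix as a 0-d grid."""
        return cls(np.asarray(c11, float), np.asarray(c22, float), np.asarray(c12, complex))

    @property
    def shape(self) -> tuple:
        return self.c11.shape

    @property
    def trace(self) -> np.ndarray:
        return self.c11 + self.c22

    @property
    def det(self) -> np.ndarray:
        """Determinant c11*c22 - |c12|^2 (real for a Hermitian matrix)."""
        return self.c11 * self.c22 - np.abs(self.c12) ** 2

    def validate(self, psd_rtol: float = 1e-9) -> None:
        """Check Hermitian-PSD invariants; raise on violation.

        Negative diagonals or a determinant below ``-psd_rtol * Tr^2`` are
        rejected; tiny negative determinants from round-off pass.
        """
        if np.any(self.c11 < 0) or np.any(self.c22 < 0):
            raise DegenerateCovarianceError("negative diagonal element in C2")
        tol = psd_rtol * np.maximum(self.trace, 1.0) ** 2
        if np.any(self.det < -tol):
            raise DegenerateCovarianceError(
                "C2 determinant negative beyond tolerance (not positive semidefinite)"
            )


@dataclass(frozen=True)
class PolarimetricDescriptors:
    """Eigen-descriptors of a C2 grid: m, beta, eigenvalues, and DpRVI.

    ``dprvi`` is NaN where the matrix carries no signal (zero trace).
    """

    m: np.ndarray
    beta: np.ndarray
    lambda1: np.ndarray
    lambda2: np.ndarray
    dprvi: np.ndarray


@dataclass(frozen=True)
class RefinedLeeParams:
    """Configuration of the refined Lee adaptive speckle filter.

    ``n_looks`` is the equivalent number of looks of the input covariance
    estimates; the multiplicative-noise coefficient of variation used by the
    minimum-mean-square-error weight is ``sigma_v^2 = 1 / n_looks``.
    """

    window: int = 7
    n_looks: float = 4.4

    def __post_init__(self):
        if self.window < 5 or self.window % 2 == 0:
            raise PolarimetryError("refined Lee window must be odd and >= 5")
        if self.n_looks <= 0:
            raise PolarimetryError("n_looks must be positive")


@dataclass(frozen=True)
class IndexRaster:
    """One date of one vegetation index on a raster grid.

    ``values`` uses NaN as the in-memory nodata marker; ``transform`` is a
    4-tuple (x0, dx, y0, dy) mapping pixel (row, col) centers to
    ``x = x0 + (col + 0.5) dx``, ``y = y0 + (row + 0.5) dy``.
    """

    values: np.ndarray
    index_name: str
    doy: int
    transform: tuple = (0.0, 1.0, 0.0, 1.0)
    crs: str | None = None

    def __post_init__(self):
        if self.index_name not in INDEX_NAMES:
            raise PolarimetryError(f"unknown index {self.index_name!r}; expected {INDEX_NAMES}")
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))


def _window_mean(arr: np.ndarray, window: int) -> np.ndarray:
    """Moving-window mean using the valid intersection at edges."""
    kernel = np.ones((window, window))
    if np.iscomplexobj(arr):
        re = ndimage.correlate(arr.real, kernel, mode="constant", cval=0.0)
        im = ndimage.correlate(arr.imag, kernel, mode="constant", cval=0.0)
        total = re + 1j * im
    else:
        total = ndimage.correlate(arr, kernel, mode="constant", cval=0.0)
    count = ndimage.correlate(np.ones(arr.shape), kernel, mode="constant", cval=0.0)
    return total / count


def build_c2(stack_vv: np.ndarray, stack_vh: np.ndarray, window: int = 5) -> C2Grid:
    """Form the C2 covariance grid by spatial averaging of scattering products.

    Per pixel, over a ``window x window`` moving box (edge pixels use the
    valid intersection with the grid):

        c11 = <|S_VV|^2>,  c22 = <|S_VH|^2>,  c12 = <S_VV conj(S_VH)>.

    ``window = 1`` returns the rank-1 single-look covariances.

    Parameters
    ----------
    stack_vv, stack_vh
        Co-registered complex scattering grids of equal shape.
    window
        Odd box size >= 1.
    """
    vv = np.asarray(stack_vv, dtype=complex)
    vh = np.asarray(stack_vh, dtype=complex)
    if vv.shape != vh.shape:
        raise PolarimetryError(f"VV shape {vv.shape} != VH shape {vh.shape}")
    if window < 1 or window % 2 == 0:
        raise PolarimetryError("window must be an odd integer >= 1")
    if window == 1:
        return C2Grid(np.abs(vv) ** 2, np.abs(vh) ** 2, vv * np.conj(vh))
    return C2Grid(
        _window_mean(np.abs(vv) ** 2, window),
        _window_mean(np.abs(vh) ** 2, window),
        _window_mean(vv * np.conj(vh), window),
    )


# --- refined Lee filter -----------------------------------------------------

def _directional_masks(window: int) -> np.ndarray:
    """The 8 edge-aligned half-plane sub-windows of the refined Lee filter.

    Order: E, W, S, N, SE, NW, NE, SW halves (the retained side of a
    vertical, horizontal, or diagonal edge); every mask includes the center
    line so the center pixel always contributes.
    """
    c = window // 2
    i, j = np.mgrid[0:window, 0:window]
    return np.array(
        [
            j >= c,            # keep east half   (vertical edge)
            j <= c,            # keep west half
            i >= c,            # keep south half  (horizontal edge)
            i <= c,            # keep north half
            i + j >= 2 * c,    # keep south-east  (135-degree edge)
            i + j <= 2 * c,    # keep north-west
            i - j <= 0,        # keep north-east  (45-degree edge)
            i - j >= 0,        # keep south-west
        ],
        dtype=float,
    )


def _shifted(padded: np.ndarray, d: int, di: int, dj: int, shape: tuple) -> np.ndarray:
    h, w = shape
    return padded[d + di : d + di + h, d + dj : d + dj + w]


def refined_lee_filter(
    c2_grid: C2Grid,
    window: int = 7,
    n_looks: float = 4.4,
) -> C2Grid:
    """Refined Lee adaptive speckle filter applied to every C2 element.

    The local edge orientation is estimated from a 3x3 grid of sub-window
    means of the total span ``c11 + c22``; the brighter/closer side of the
    strongest gradient selects one of 8 edge-aligned half-windows.  Within
    that window the minimum-mean-square-error weight

        b = max(0, (var_y - sigma_v^2 * mean_y^2) / ((1 + sigma_v^2) * var_y))

    with ``sigma_v^2 = 1 / n_looks`` is computed on the span and applied
    identically to c11, c22, and c12:

        element_filtered = mean_w(element) + b * (element - mean_w(element)).

    Because the same convex weight is used for all elements, the output is
    a pointwise convex combination of Hermitian PSD matrices and is itself
    exactly Hermitian PSD; in homogeneous areas b -> 0 (full averaging of
    identical statistics), over strong point targets b -> 1 (the pixel is
    preserved).
    """
    params = RefinedLeeParams(window=window, n_looks=n_looks)
    span = c2_grid.trace
    if span.ndim != 2:
        raise PolarimetryError("refined_lee_filter expects a 2-D C2 grid")
    h, w = span.shape
    sigma_v2 = 1.0 / params.n_looks

    # 3x3 sub-window means of the span at offsets {-d, 0, d}
    d = max(window // 3, 1)
    sub = ndimage.uniform_filter(span, size=3, mode="nearest")
    padded = np.pad(sub, d, mode="edge")
    M = {
        (di, dj): _shifted(padded, d, di * d, dj * d, span.shape)
        for di in (-1, 0, 1)
        for dj in (-1, 0, 1)
    }

    # gradient magnitude of the four edge orientations
    g_vert = (M[-1, 1] + M[0, 1] + M[1, 1]) - (M[-1, -1] + M[0, -1] + M[1, -1])
    g_horz = (M[1, -1] + M[1, 0] + M[1, 1]) - (M[-1, -1] + M[-1, 0] + M[-1, 1])
    g_d135 = (M[0, 1] + M[1, 0] + M[1, 1]) - (M[-1, -1] + M[-1, 0] + M[0, -1])
    g_d45 = (M[-1, 0] + M[-1, 1] + M[0, 1]) - (M[0, -1] + M[1, -1] + M[1, 0])
    grads = np.stack([np.abs(g_vert), np.abs(g_horz), np.abs(g_d135), np.abs(g_d45)])
    orient = np.argmax(grads, axis=0)

    # retained side: the half whose sub-mean is closer to the center sub-mean
    center = M[0, 0]
    side_pairs = (
        (M[0, 1], M[0, -1]),   # vertical edge:   east vs west
        (M[1, 0], M[-1, 0]),   # horizontal edge: south vs north
        (M[1, 1], M[-1, -1]),  # 135 edge:        south-east vs north-west
        (M[-1, 1], M[1, -1]),  # 45 edge:         north-east vs south-west
    )
    direction = np.zeros(span.shape, dtype=int)
    for k, (side_a, side_b) in enumerate(side_pairs):
        sel = orient == k
        pick_b = np.abs(side_b - center) < np.abs(side_a - center)
        direction[sel] = 2 * k + pick_b[sel]

    masks = _directional_masks(window)
    elements = (c2_grid.c11, c2_grid.c22, c2_grid.c12.real, c2_grid.c12.imag)
    mean_span = np.empty((8, h, w))
    var_span = np.empty((8, h, w))
    mean_elem = np.empty((8, 4, h, w))
    for k, mask in enumerate(masks):
        npx = mask.sum()
        ms = ndimage.correlate(span, mask, mode="nearest") / npx
        ms2 = ndimage.correlate(span**2, mask, mode="nearest") / npx
        mean_span[k] = ms
        var_span[k] = np.maximum(ms2 - ms**2, 0.0)
        for e, elem in enumerate(elements):
            mean_elem[k, e] = ndimage.correlate(elem, mask, mode="nearest") / npx

    rows, cols = np.indices(span.shape)
    my = mean_span[direction, rows, cols]
    vy = var_span[direction, rows, cols]
    with np.errstate(divide="ignore", invalid="ignore"):
        b = (vy - sigma_v2 * my**2) / ((1.0 + sigma_v2) * vy)
    b = np.clip(np.nan_to_num(b, nan=0.0), 0.0, 1.0)

    out = []
    for e, elem in enumerate(elements):
        me = mean_elem[direction, e, rows, cols]
        out.append(me + b * (elem - me))
    return C2Grid(out[0], out[1], out[2] + 1j * out[3])


# --- eigen-decomposition and indices ----------------------------------------

def decompose(c2: C2Grid, psd_rtol: float = 1e-9) -> PolarimetricDescriptors:
    """Closed-form eigen-decomposition of C2 into polarimetric descriptors.

    For a 2x2 Hermitian matrix the eigenvalues are

        lambda_{1,2} = (Tr +- sqrt(Tr^2 - 4 det)) / 2

    and the discriminant ``(c11 - c22)^2 + 4 |c12|^2`` is nonnegative by
    construction.  The degree of polarization uses the Barakat form
    ``m = sqrt(1 - 4 det / Tr^2)`` and ``beta = lambda_1 / Tr``.

    Degenerate zero-trace pixels (no signal in either channel) return the
    conventional ``m = 0, beta = 0.5`` with ``dprvi = NaN`` (nodata): an
    empty measurement carries no vegetation information.

    Eigenvalues in ``(-psd_rtol * Tr, 0)`` are clipped to zero; larger
    violations raise :class:`DegenerateCovarianceError`.
    """
    c2.validate(psd_rtol=psd_rtol)
    tr = c2.trace
    det = c2.det
    disc = np.maximum((c2.c11 - c2.c22) ** 2 + 4.0 * np.abs(c2.c12) ** 2, 0.0)
    root = np.sqrt(disc)
    lam1 = (tr + root) / 2.0
    lam2 = (tr - root) / 2.0
    lam2 = np.where((lam2 < 0) & (lam2 > -psd_rtol * np.maximum(tr, 1.0)), 0.0, lam2)
    if np.any(lam2 < 0):
        raise DegenerateCovarianceError("negative eigenvalue beyond tolerance")

    # subnormal traces underflow in tr**2; treat them as no-signal pixels too
    nonzero = tr * tr > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        m = np.sqrt(np.clip(1.0 - 4.0 * det / tr**2, 0.0, 1.0))
        beta = lam1 / tr
    m = np.where(nonzero, m, 0.0)
    beta = np.where(nonzero, beta, 0.5)
    d = np.where(nonzero, 1.0 - m * beta, np.nan)
    return PolarimetricDescriptors(
        m=m, beta=beta, lambda1=lam1, lambda2=lam2, dprvi=np.clip(d, 0.0, 1.0)
    )


def dprvi(d: PolarimetricDescriptors) -> np.ndarray:
    """Dual-pol radar vegetation index ``1 - m * beta``, in [0, 1].

    NaN (nodata) where the descriptors came from a zero-trace matrix.
    """
    out = 1.0 - d.m * d.beta
    out = np.where(np.isnan(d.dprvi), np.nan, out)
    return np.clip(out, 0.0, 1.0)


def rvi_dual_pol(sigma_vv, sigma_vh) -> np.ndarray | float:
    """Dual-pol radar vegetation index from backscatter intensities.

    ``RVI = 4 sigma_VH / (sigma_VV + sigma_VH)`` with intensities in linear
    power units; ranges over [0, 4), equal to 2 when the channels balance.
    """
    svv = np.asarray(sigma_vv, dtype=float)
    svh = np.asarray(sigma_vh, dtype=float)
    if np.any(svv <= 0) or np.any(svh < 0) or np.any(svv + svh <= 0):
        raise PolarimetryError("backscatter intensities must be positive (linear units)")
    out = 4.0 * svh / (svv + svh)
    return out if out.ndim else float(out)


def vv_vh_ratio(sigma_vv, sigma_vh) -> np.ndarray | float:
    """Co/cross polarization power ratio ``sigma_VV / sigma_VH``."""
    svv = np.asarray(sigma_vv, dtype=float)
    svh = np.asarray(sigma_vh, dtype=float)
    if np.any(svv <= 0) or np.any(svh <= 0):
        raise PolarimetryError("backscatter intensities must be positive (linear units)")
    out = svv / svh
    return out if out.ndim else float(out)


def _index_from_c2(c2: C2Grid, index_name: str) -> np.ndarray:
    """Raster of one index from a C2 grid; zero-power pixels become NaN."""
    nodata = c2.trace <= 0
    if index_name == "dprvi":
        values = decompose(c2).dprvi
    elif index_name == "rvi":
        with np.errstate(divide="ignore", invalid="ignore"):
            values = 4.0 * c2.c22 / c2.trace
    elif index_name == "vvvh":
        with np.errstate(divide="ignore", invalid="ignore"):
            values = c2.c11 / c2.c22
        nodata = nodata | (c2.c22 <= 0)
    else:
        raise PolarimetryError(f"unknown index {index_name!r}; expected {INDEX_NAMES}")
    return np.where(nodata, np.nan, values)


def index_stack_from_c2(
    c2_grids: Sequence[C2Grid],
    doys: Sequence[int],
    index_name: str = "dprvi",
    filter_params: RefinedLeeParams | None = None,
    transform: tuple = (0.0, 1.0, 0.0, 1.0),
    crs: str | None = None,
) -> list[IndexRaster]:
    """Per-date index rasters from already-formed C2 covariance grids."""
    if len(c2_grids) != len(doys):
        raise PolarimetryError("one DOY per C2 grid required")
    out = []
    for c2, doy in zip(c2_grids, doys):
        if c2.shape != c2_grids[0].shape:
            raise PolarimetryError("all dates must share one grid shape")
        if filter_params is not None:
            c2 = refined_lee_filter(c2, filter_params.window, filter_params.n_looks)
        out.append(
            IndexRaster(_index_from_c2(c2, index_name), index_name, int(doy), transform, crs)
        )
    return out


def index_stack(
    scene_series: Sequence[tuple[np.ndarray, np.ndarray]],
    doys: Sequence[int],
    index_name: str = "dprvi",
    window: int = 5,
    filter_params: RefinedLeeParams | None = None,
    transform: tuple = (0.0, 1.0, 0.0, 1.0),
    crs: str | None = None,
) -> list[IndexRaster]:
    """Full per-date chain: complex (VV, VH) grids -> C2 -> (filter) -> index.

    ``scene_series`` is a sequence of per-date ``(S_VV, S_VH)`` complex grid
    pairs aligned with ``doys``; all dates must share one shape.  Returns one
    :class:`IndexRaster` per date with NaN where both channels are zero.
    """
    if len(scene_series) != len(doys):
        raise PolarimetryError("one DOY per scene required")
    if not scene_series:
        return []
    shape = np.asarray(scene_series[0][0]).shape
    c2_grids = []
    for vv, vh in scene_series:
        if np.asarray(vv).shape != shape or np.asarray(vh).shape != shape:
            raise PolarimetryError("all dates must share one grid shape")
        c2_grids.append(build_c2(vv, vh, window=window))
    return index_stack_from_c2(c2_grids, doys, index_name, filter_params, transform, crs)
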