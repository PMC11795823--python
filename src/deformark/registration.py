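"""Rigid and non-rigid (demons) registration of 2D grayscale images.

The registration stage aligns every subject image to a common reference
anatomy in two steps: a landmark-driven rigid alignment (rotation +
translation about landmark 1) followed by iterative demons non-rigid
registration, which produces a dense per-pixel displacement field on the
reference grid.

Conventions
-----------
* Images are ``(H, W)`` float arrays with intensities in ``[0, 1]`` and
  row-major (row, col) indexing; row increases downward.
* A deformation field ``d`` is an ``(H, W, 2)`` array of ``(drow, dcol)``
  displacements in pixels defined on the *reference* grid, with the pull
  (backward-warp) convention ``warped_query(x) = query(x + d(x))``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage


# --------------------------------------------------------------------------
# Domain types
# --------------------------------------------------------------------------

DEFAULT_SPACING_MM = (0.7, 0.7)


@dataclass(frozen=True)
class Image2D:
    """A single-channel 2D intensity grid with physical pixel spacing.

    Parameters
    ----------
    pixels
        ``(H, W)`` array of finite intensities in ``[0, 1]``.
    spacing
        ``(row_mm, col_mm)`` physical pixel size; purely metadata here
        (all registration operates in pixel units).
    """

    pixels: np.ndarray
    spacing: tuple[float, float] = DEFAULT_SPACING_MM

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim != 2:
            raise ValueError(f"image must be 2D, got shape {px.shape}")
        if px.shape[0] < 16 or px.shape[1] < 16:
            raise ValueError(f"image must be at least 16x16, got {px.shape}")
        if not np.all(np.isfinite(px)):
            raise ValueError("image intensities must be finite")
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass(frozen=True)
class RigidTransform:
    """Rotation + translation correction applied to a query image.

    ``rotation_deg`` is the rotation (about ``center``, in degrees,
    positive = row-toward-col) and ``translation`` the ``(drow, dcol)``
    shift that were applied to the query content to align it with the
    reference. ``degenerate`` is set when the landmarks were too
    degenerate to estimate a rotation and a translation-only fallback
    was used.
    """

    rotation_deg: float
    translation: tuple[float, float]
    center: tuple[float, float]
    degenerate: bool = False

    def __post_init__(self) -> None:
        if not (-180.0 < self.rotation_deg <= 180.0):
            raise ValueError("rotation must lie in (-180, 180] degrees")


@dataclass(frozen=True)
class DeformationField:
    """Per-pixel ``(drow, dcol)`` displacements on the reference grid.

    Backward-warp convention: ``warped_query(x) = query(x + d(x))``.
    """

    d: np.ndarray  # (H, W, 2)

    def __post_init__(self) -> None:
        d = np.asarray(self.d, dtype=float)
        if d.ndim != 3 or d.shape[2] != 2:
            raise ValueError(f"field must have shape (H, W, 2), got {d.shape}")
        if not np.all(np.isfinite(d)):
            raise ValueError("field components must be finite")
        object.__setattr__(self, "d", d)

    @property
    def shape(self) -> tuple[int, int]:
        return self.d.shape[:2]


@dataclass(frozen=True)
class DemonsParams:
    """Settings for the demons optimizer.

    smooth_sigma
        Gaussian smoothing of the accumulated field after each
        iteration, in pixels (the regularizer).
    levels
        Coarse-to-fine pyramid downsampling factors.
    max_iter
        Iteration cap per pyramid level.
    tol, window
        Stop a level early when the relative SSD improvement over
        ``window`` iterations drops below ``tol``.
    """

    smooth_sigma: float = 1.5
    levels: tuple[int, ...] = (4, 2, 1)
    max_iter: int = 100
    tol: float = 1e-4
    window: int = 5


# --------------------------------------------------------------------------
# Basic field operations
# --------------------------------------------------------------------------


def warp_image(img: Image2D | np.ndarray, field: DeformationField | np.ndarray) -> np.ndarray:
    """Backward-warp ``img`` by ``field``: ``out(x) = img(x + d(x))``.

    Bilinear interpolation with edge clamping. Returns a plain array of
    the same shape as the input image.
    """
    px = img.pixels if isinstance(img, Image2D) else np.asarray(img, dtype=float)
    d = field.d if isinstance(field, DeformationField) else np.asarray(field, dtype=float)
    if d.shape[:2] != px.shape:
        raise ValueError(f"field shape {d.shape[:2]} does not match image shape {px.shape}")
    rr, cc = np.meshgrid(
        np.arange(px.shape[0], dtype=float),
        np.arange(px.shape[1], dtype=float),
        indexing="ij",
    )
    coords = np.stack([rr + d[..., 0], cc + d[..., 1]])
    return ndimage.map_coordinates(px, coords, order=1, mode="nearest")


def field_magnitude(field: DeformationField | np.ndarray) -> np.ndarray:
    """Per-pixel Euclidean displacement magnitude in pixels."""
    d = field.d if isinstance(field, DeformationField) else np.asarray(field, dtype=float)
    return np.hypot(d[..., 0], d[..., 1])


# --------------------------------------------------------------------------
# Rigid alignment
# --------------------------------------------------------------------------


def _rotation_matrix(angle_rad: float) -> np.ndarray:
    c, s = np.cos(angle_rad), np.sin(angle_rad)
    return np.array([[c, -s], [s, c]])


def rigid_align(query: Image2D, query_landmarks, ref_landmarks) -> tuple[Image2D, RigidTransform]:
    """Rigidly align ``query`` to the reference using landmark pairs.

    The translation maps the query's landmark 1 onto the reference's
    landmark 1 (the rotation center); the rotation is the least-squares
    rotation about that center aligning the remaining landmark pairs
    (orthogonal Procrustes restricted to a proper 2D rotation). The
    image is resampled with bilinear interpolation and edge clamping.

    Degenerate landmark configurations (all remaining points coincident
    with the center, or numerically collinear through it) fall back to
    translation only, flagged in the returned transform.
    """
    q_pts = np.asarray(query_landmarks.points, dtype=float)
    r_pts = np.asarray(ref_landmarks.points, dtype=float)
    c_q, c_r = q_pts[0], r_pts[0]
    a = r_pts[1:] - c_r  # reference offsets from center
    b = q_pts[1:] - c_q  # query offsets from center

    # phi maximizes sum b . R(phi) a  (forward rotation ref->query)
    dot = float(np.sum(a[:, 0] * b[:, 0] + a[:, 1] * b[:, 1]))
    cross = float(np.sum(a[:, 0] * b[:, 1] - a[:, 1] * b[:, 0]))
    degenerate = bool(np.hypot(dot, cross) < 1e-9 * (np.linalg.norm(a) * np.linalg.norm(b) + 1e-30)
                      or np.linalg.norm(a) == 0 or np.linalg.norm(b) == 0)
    phi = 0.0 if degenerate else float(np.arctan2(cross, dot))

    # aligned(x) = query(R(phi) (x - c_r) + c_q)
    R = _rotation_matrix(phi)
    H, W = query.shape
    rr, cc = np.meshgrid(np.arange(H, dtype=float), np.arange(W, dtype=float), indexing="ij")
    x = np.stack([rr - c_r[0], cc - c_r[1]])
    src_r = R[0, 0] * x[0] + R[0, 1] * x[1] + c_q[0]
    src_c = R[1, 0] * x[0] + R[1, 1] * x[1] + c_q[1]
    aligned = ndimage.map_coordinates(query.pixels, np.stack([src_r, src_c]), order=1, mode="nearest")

    rot_deg = float(-np.degrees(phi))
    if rot_deg <= -180.0:
        rot_deg += 360.0
    transform = RigidTransform(
        rotation_deg=rot_deg,
        translation=(float(c_r[0] - c_q[0]), float(c_r[1] - c_q[1])),
        center=(float(c_r[0]), float(c_r[1])),
        degenerate=degenerate,
    )
    return Image2D(np.clip(aligned, 0.0, 1.0), query.spacing), transform


def apply_rigid_to_points(points: np.ndarray, transform: RigidTransform) -> np.ndarray:
    """Map query-image coordinates through the rigid correction.

    The inverse of the resampling lookup: a feature at query position
    ``q`` lands at ``R(-phi)(q - c_q) + c_r`` in the aligned image.
    """
    pts = np.asarray(points, dtype=float)
    c_r = np.asarray(transform.center)
    c_q = c_r - np.asarray(transform.translation)
    R = _rotation_matrix(np.radians(transform.rotation_deg))
    return (pts - c_q) @ R.T + c_r


# --------------------------------------------------------------------------
# Demons non-rigid registration
# --------------------------------------------------------------------------


def _resize(img: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Bilinear resize through coordinate mapping (anti-aliased on shrink)."""
    src = img
    fr = img.shape[0] / shape[0]
    fc = img.shape[1] / shape[1]
    if fr > 1 or fc > 1:  # smooth before decimating
        src = ndimage.gaussian_filter(img, sigma=(max(fr, 1) / 2.0, max(fc, 1) / 2.0))
    rr = (np.arange(shape[0]) + 0.5) * fr - 0.5
    cc = (np.arange(shape[1]) + 0.5) * fc - 0.5
    grid = np.meshgrid(rr, cc, indexing="ij")
    return ndimage.map_coordinates(src, np.stack(grid), order=1, mode="nearest")


def _ssd(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.sum((a - b) ** 2))


def demons_register(
    fixed: Image2D | np.ndarray,
    moving: Image2D | np.ndarray,
    params: DemonsParams | None = None,
) -> DeformationField:
    """Estimate the dense field mapping ``moving`` onto ``fixed``.

    Classic demons forces: at each iteration the update at pixel ``x``
    is ``u(x) = e(x) grad f(x) / (|grad f(x)|^2 + e(x)^2)`` with
    ``e(x) = m(x + d(x)) - f(x)``, subtracted from the accumulated field
    ``d`` which is then Gaussian-smoothed (elastic-like regularization).
    A coarse-to-fine pyramid provides capture range; each level stops
    when the relative SSD improvement stalls. The returned field is the
    best (lowest full-resolution SSD) state encountered, so the SSD
    after warping never exceeds the initial SSD.

    Both inputs are min-max normalized to ``[0, 1]`` before matching, so
    a global affine intensity difference between the images is ignored.
    """
    params = params or DemonsParams()
    f_full = fixed.pixels if isinstance(fixed, Image2D) else np.asarray(fixed, dtype=float)
    m_full = moving.pixels if isinstance(moving, Image2D) else np.asarray(moving, dtype=float)
    if f_full.shape != m_full.shape:
        raise ValueError(f"fixed shape {f_full.shape} != moving shape {m_full.shape}")

    def _norm(a: np.ndarray) -> np.ndarray:
        lo, hi = float(a.min()), float(a.max())
        return (a - lo) / (hi - lo) if hi > lo else np.zeros_like(a)

    f_full = _norm(f_full)
    m_full = _norm(m_full)
    H, W = f_full.shape

    d = None  # (h, w, 2) at current level
    for factor in params.levels:
        shape = (max(H // factor, 8), max(W // factor, 8))
        f = _resize(f_full, shape) if shape != (H, W) else f_full
        m = _resize(m_full, shape) if shape != (H, W) else m_full
        if d is None:
            d = np.zeros(shape + (2,))
        elif d.shape[:2] != shape:
            scale_r = shape[0] / d.shape[0]
            scale_c = shape[1] / d.shape[1]
            d = np.stack(
                [_resize(d[..., 0], shape) * scale_r, _resize(d[..., 1], shape) * scale_c],
                axis=-1,
            )
        d = _demons_level(f, m, d, params)

    if d.shape[:2] != (H, W):  # pragma: no cover - levels always end at 1
        d = np.stack([_resize(d[..., 0], (H, W)), _resize(d[..., 1], (H, W))], axis=-1)

    # keep the best full-resolution state (guarantees non-worsening SSD)
    if _ssd(warp_image(m_full, d), f_full) > _ssd(m_full, f_full):
        d = np.zeros_like(d)
    return DeformationField(d)


def _demons_level(f: np.ndarray, m: np.ndarray, d: np.ndarray, params: DemonsParams) -> np.ndarray:
    grad_r, grad_c = np.gradient(f)  # central differences, edge replication
    gnorm2 = grad_r**2 + grad_c**2
    rr, cc = np.meshgrid(
        np.arange(f.shape[0], dtype=float), np.arange(f.shape[1], dtype=float), indexing="ij"
    )

    best_d = d.copy()
    best_ssd = _ssd(ndimage.map_coordinates(m, np.stack([rr + d[..., 0], cc + d[..., 1]]),
                                            order=1, mode="nearest"), f)
    history = [best_ssd]
    for _ in range(params.max_iter):
        warped = ndimage.map_coordinates(
            m, np.stack([rr + d[..., 0], cc + d[..., 1]]), order=1, mode="nearest"
        )
        e = warped - f
        denom = gnorm2 + e**2
        with np.errstate(invalid="ignore", divide="ignore"):
            u_r = np.where(denom > 1e-12, e * grad_r / denom, 0.0)
            u_c = np.where(denom > 1e-12, e * grad_c / denom, 0.0)
        d = np.stack(
            [
                ndimage.gaussian_filter(d[..., 0] - u_r, params.smooth_sigma),
                ndimage.gaussian_filter(d[..., 1] - u_c, params.smooth_sigma),
            ],
            axis=-1,
        )
        ssd = _ssd(
            ndimage.map_coordinates(m, np.stack([rr + d[..., 0], cc + d[..., 1]]),
                                    order=1, mode="nearest"),
            f,
        )
        if ssd < best_ssd:
            best_ssd = ssd
            best_d = d.copy()
        history.append(ssd)
        if len(history) > params.window:
            past = history[-params.window - 1]
            if past <= 0 or (past - ssd) / past < params.tol:
                break
    return best_d
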