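"""Landmark-based thin-plate-spline (TPS) registration onto the common frame.

Each modality (transcript coordinates, protein image) lives in its own
acquisition frame; a smooth non-rigid map onto the common H&E frame is
fitted from paired landmarks.  The TPS is the canonical choice for a
"non-rigid spline" warp: it is the unique minimiser of the bending energy
among interpolants of the landmarks, decomposes into an affine part plus
radial kernel terms ``U(r) = r^2 log r``, and has a closed-form linear fit.
With regularisation ``lam > 0`` the fit trades landmark misfit against
bending energy; ``lam = 0`` interpolates the landmarks exactly.

The inverse map (needed to pull a mask from one frame into another by
nearest-neighbour resampling) is obtained by fitting a second TPS with the
landmark roles swapped, which is accurate for smooth, gentle deformations.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_io import Frame, LabelMask
from .errors import DegeneracyError, ParameterError, ValidityError

_COLLINEAR_RTOL = 1e-8


@dataclass
class LandmarkSet:
    """Paired control points: ``src`` in the moving frame, ``dst`` in the target."""

    src: np.ndarray  # (n, 2)
    dst: np.ndarray  # (n, 2)

    def __post_init__(self) -> None:
        self.src = np.atleast_2d(np.asarray(self.src, dtype=float))
        self.dst = np.atleast_2d(np.asarray(self.dst, dtype=float))
        if self.src.shape != self.dst.shape or self.src.shape[1] != 2:
            raise ParameterError(
                f"landmark arrays must both be (n, 2); got {self.src.shape} and {self.dst.shape}"
            )
        if not (np.all(np.isfinite(self.src)) and np.all(np.isfinite(self.dst))):
            raise ParameterError("landmarks must be finite")

    def __len__(self) -> int:
        return len(self.src)

    def swapped(self) -> "LandmarkSet":
        return LandmarkSet(self.dst.copy(), self.src.copy())


def read_landmarks(path) -> LandmarkSet:
    """Read a landmark CSV with columns x_src, y_src, x_dst, y_dst."""
    df = pd.read_csv(path)
    cols = ["x_src", "y_src", "x_dst", "y_dst"]
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ParameterError(f"{path}: missing landmark columns {missing}")
    return LandmarkSet(df[["x_src", "y_src"]].to_numpy(), df[["x_dst", "y_dst"]].to_numpy())


def write_landmarks(lm: LandmarkSet, path) -> None:
    pd.DataFrame(
        {
            "x_src": lm.src[:, 0],
            "y_src": lm.src[:, 1],
            "x_dst": lm.dst[:, 0],
            "y_dst": lm.dst[:, 1],
        }
    ).to_csv(path, index=False)


def _tps_kernel(r2: np.ndarray) -> np.ndarray:
    """U(r) = r^2 log r, written on squared distances; U(0) = 0."""
    out = np.zeros_like(r2)
    nz = r2 > 0
    out[nz] = 0.5 * r2[nz] * np.log(r2[nz])
    return out


def _check_degenerate(src: np.ndarray) -> None:
    uniq = np.unique(src, axis=0)
    if len(uniq) < len(src):
        raise DegeneracyError("duplicate source landmarks")
    if len(src) < 4:
        raise DegeneracyError(f"need >= 4 landmark pairs, got {len(src)}")
    centered = src - src.mean(axis=0)
    sv = np.linalg.svd(centered, compute_uv=False)
    if sv[-1] <= _COLLINEAR_RTOL * max(sv[0], 1.0):
        raise DegeneracyError("source landmarks are collinear (rank-deficient fit)")


@dataclass
class SplineTransform:
    """Fitted TPS map from a source frame to a target frame.

    ``affine`` is a (3, 2) matrix applied to ``[1, x, y]``; ``weights`` is
    (n, 2), one 2-vector per kernel centre.  The weights satisfy the TPS
    side conditions (zero sum and zero first moments), so the transform is
    affine at long range.
    """

    centers: np.ndarray           # (n, 2) source landmarks
    weights: np.ndarray           # (n, 2)
    affine: np.ndarray            # (3, 2)
    lam: float = 0.0
    landmarks: LandmarkSet | None = None
    _inverse: "SplineTransform | None" = field(default=None, repr=False)

    def __call__(self, pts) -> np.ndarray:
        return self.transform(pts)

    def transform(self, pts) -> np.ndarray:
        pts = np.asarray(pts, dtype=float)
        if pts.size == 0:
            return pts.reshape(0, 2)
        pts = np.atleast_2d(pts)
        d2 = (
            (pts[:, None, 0] - self.centers[None, :, 0]) ** 2
            + (pts[:, None, 1] - self.centers[None, :, 1]) ** 2
        )
        K = _tps_kernel(d2)
        P = np.column_stack([np.ones(len(pts)), pts])
        return P @ self.affine + K @ self.weights

    def inverse(self) -> "SplineTransform":
        """TPS fitted with landmark roles swapped (approximate inverse)."""
        if self._inverse is None:
            if self.landmarks is None:
                raise ValidityError("transform has no stored landmarks; cannot invert")
            self._inverse = fit_spline_transform(self.landmarks.swapped(), lam=self.lam)
        return self._inverse

    # -- serialization -----------------------------------------------------
    def to_json(self, path=None) -> str:
        obj = {
            "centers": self.centers.tolist(),
            "weights": self.weights.tolist(),
            "affine": self.affine.tolist(),
            "lam": self.lam,
        }
        if self.landmarks is not None:
            obj["landmarks"] = {
                "src": self.landmarks.src.tolist(),
                "dst": self.landmarks.dst.tolist(),
            }
        text = json.dumps(obj, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, path_or_text) -> "SplineTransform":
        if isinstance(path_or_text, str) and path_or_text.lstrip().startswith("{"):
            obj = json.loads(path_or_text)
        else:
            with open(path_or_text) as fh:
                obj = json.load(fh)
        lm = None
        if "landmarks" in obj:
            lm = LandmarkSet(np.array(obj["landmarks"]["src"]), np.array(obj["landmarks"]["dst"]))
        return cls(
            centers=np.array(obj["centers"], dtype=float),
            weights=np.array(obj["weights"], dtype=float),
            affine=np.array(obj["affine"], dtype=float),
            lam=float(obj["lam"]),
            landmarks=lm,
        )


def fit_spline_transform(landmarks: LandmarkSet, lam: float = 0.0) -> SplineTransform:
    """Fit a TPS minimising bending energy plus ``lam``-weighted misfit.

    With ``lam = 0`` the fitted map interpolates every landmark exactly (to
    numerical tolerance).  Collinear or duplicated source landmarks raise
    :class:`DegeneracyError`.
    """
    if lam < 0:
        raise ParameterError("lam must be >= 0")
    src, dst = landmarks.src, landmarks.dst
    _check_degenerate(src)
    n = len(src)
    d2 = (
        (src[:, None, 0] - src[None, :, 0]) ** 2
        + (src[:, None, 1] - src[None, :, 1]) ** 2
    )
    K = _tps_kernel(d2) + lam * np.eye(n)
    P = np.column_stack([np.ones(n), src])
    A = np.zeros((n + 3, n + 3))
    A[:n, :n] = K
    A[:n, n:] = P
    A[n:, :n] = P.T
    b = np.zeros((n + 3, 2))
    b[:n] = dst
    try:
        sol = np.linalg.solve(A, b)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - caught above in practice
        raise DegeneracyError(f"TPS system is singular: {exc}") from exc
    weights, affine = sol[:n], sol[n:]
    return SplineTransform(
        centers=src.copy(), weights=weights, affine=affine, lam=lam, landmarks=landmarks
    )


def transform_points(T: SplineTransform, pts) -> np.ndarray:
    """Map an (n, 2) array (or empty list) of points through the transform."""
    pts = np.asarray(pts, dtype=float)
    if pts.size == 0:
        return np.zeros((0, 2))
    return T.transform(pts)


def warp_extent(T: SplineTransform, frame: Frame, n_boundary: int = 64):
    """Polygon of the frame's rectangular extent mapped through ``T``."""
    from shapely.geometry import Polygon

    h, w = frame.shape
    t = np.linspace(0, 1, n_boundary, endpoint=False)
    top = np.column_stack([t * w, np.zeros_like(t)])
    right = np.column_stack([np.full_like(t, w), t * h])
    bottom = np.column_stack([w - t * w, np.full_like(t, h)])
    left = np.column_stack([np.zeros_like(t), h - t * h])
    boundary = np.vstack([top, right, bottom, left])
    return Polygon(T.transform(boundary))


def warp_mask(T: SplineTransform, mask: LabelMask, target: Frame,
              check_fold: bool = True) -> LabelMask:
    """Resample a label mask into ``target`` through the inverse map.

    Each target pixel centre is pulled back through the inverse TPS and the
    nearest source pixel's label copied (nearest-neighbour), so labels are
    preserved as a set except for cells warped outside the target frame.
    """
    inv = T.inverse()
    if check_fold:
        _check_invertibility(T, mask.frame)
    h, w = target.shape
    yy, xx = np.mgrid[0:h, 0:w]
    centres = np.column_stack([xx.ravel() + 0.5, yy.ravel() + 0.5])
    src_pts = inv.transform(centres)
    sx = np.floor(src_pts[:, 0]).astype(int)
    sy = np.floor(src_pts[:, 1]).astype(int)
    ok = (sx >= 0) & (sx < mask.frame.width) & (sy >= 0) & (sy < mask.frame.height)
    out = np.zeros(h * w, dtype=mask.labels.dtype)
    out[ok] = mask.labels[sy[ok], sx[ok]]
    return LabelMask(out.reshape(h, w), target)


def _check_invertibility(T: SplineTransform, frame: Frame, n_grid: int = 24) -> None:
    """Raise if the forward map folds (non-positive Jacobian) on a coarse grid."""
    h, w = frame.shape
    xs = np.linspace(0, w, n_grid)
    ys = np.linspace(0, h, n_grid)
    gx, gy = np.meshgrid(xs, ys)
    pts = np.column_stack([gx.ravel(), gy.ravel()])
    eps = max(h, w) / (4 * n_grid)
    fx = T.transform(pts + [eps, 0.0]) - T.transform(pts - [eps, 0.0])
    fy = T.transform(pts + [0.0, eps]) - T.transform(pts - [0.0, eps])
    det = (fx[:, 0] * fy[:, 1] - fx[:, 1] * fy[:, 0]) / (4 * eps * eps)
    if det.min() <= 0:
        raise ValidityError(
            f"transform folds (min Jacobian determinant {det.min():.3g} <= 0)"
        )


def registration_error(T: SplineTransform, held_out: LandmarkSet) -> dict:
    """Residual summary (mean/max px) on landmark pairs not used in fitting."""
    if len(held_out) == 0:
        raise ParameterError("held-out landmark set is empty")
    res = np.linalg.norm(T.transform(held_out.src) - held_out.dst, axis=1)
    return {
        "n": int(len(res)),
        "mean_px": float(res.mean()),
        "max_px": float(res.max()),
        "rms_px": float(np.sqrt((res**2).mean())),
    }
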