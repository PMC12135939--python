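"""Landmark-based heart-loop morphometry.

Aligns a landmark set to the embryo frame (notochord axis -> Z, cranial
positive; dorso-ventral reference -> +X; +Y = embryo's left, right-handed),
then derives the signed RV/LV axis angle, the venous-pole displacement
normalized by tube length, the tube length, and the looping direction.

Angle convention (fixed here, stated as a convention): project the
RV->LV vector onto the transverse (XY) plane and measure the signed
angle from the +Y (leftward) axis, counter-clockwise positive when
viewed from the cranial (+Z) side, range (-180, 180]. A normal
rightward loop (RV on the embryo's right) therefore reads 0 degrees.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .stats import StatResult, chi_squared_gof

__all__ = [
    "HEART_LANDMARKS",
    "LandmarkSet",
    "LoopMetrics",
    "QCError",
    "align_to_embryo_frame",
    "rvlv_axis_angle",
    "tube_length",
    "venous_pole_displacement",
    "looping_direction",
    "direction_frequency_test",
    "loop_metrics",
]

# ordered polyline used for tube length, arterial to venous pole
HEART_LANDMARKS = (
    "outflow_exit",
    "OFT",
    "RV",
    "interventricular_sulcus",
    "LV",
    "AVC_LA",
    "RA",
    "venous_pole",
)

SOMITE_QC_MIN = 18  # embryos younger than this are excluded
DIRECTION_TOL_UM = 1.0


class QCError(ValueError):
    """Raised when a sample fails a quality-control rule."""


@dataclass(frozen=True)
class LandmarkSet:
    """Named 3D heart-tube landmarks plus the embryo reference geometry.

    Coordinates in micrometres. ``notochord_points`` are ordered
    caudal -> cranial; ``dorsoventral_ref`` is a point on the ventral
    side of the notochord.
    """

    landmarks: dict
    notochord_points: np.ndarray
    dorsoventral_ref: np.ndarray
    somite_count: int | None = None
    embryo_id: str = ""
    genotype: str = ""
    aligned: bool = False

    def __post_init__(self) -> None:
        missing = [n for n in HEART_LANDMARKS if n not in self.landmarks]
        if missing:
            raise ValueError(f"missing landmark(s): {missing}")
        object.__setattr__(
            self,
            "landmarks",
            {k: np.asarray(v, dtype=float) for k, v in self.landmarks.items()},
        )
        pts = np.asarray(self.notochord_points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 3 or pts.shape[0] < 2:
            raise ValueError("notochord_points must be an (n>=2, 3) array")
        object.__setattr__(self, "notochord_points", pts)
        object.__setattr__(
            self, "dorsoventral_ref", np.asarray(self.dorsoventral_ref, dtype=float)
        )

    def point(self, name: str) -> np.ndarray:
        return self.landmarks[name]


@dataclass(frozen=True)
class LoopMetrics:
    rvlv_angle_deg: float
    venous_displacement_norm: float
    tube_length: float
    direction: str  # rightward | leftward | indeterminate


def _notochord_axis(pts: np.ndarray, outflow_exit: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Total-least-squares line through the notochord points.

    Returns (centroid, unit direction). Direction sign is fixed by the
    cranial-side convention: the hemisphere containing the outflow exit
    is cranial (+Z), so the fit is independent of point ordering. If the
    outflow exit projects onto the line's origin, the caudal->cranial
    point ordering decides.
    """
    centroid = pts.mean(axis=0)
    centered = pts - centroid
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    if s[0] <= 0:
        raise ValueError("notochord points are all coincident")
    axis = vt[0]
    proj = np.dot(axis, outflow_exit - centroid)
    if abs(proj) > 1e-9:
        if proj < 0:
            axis = -axis
    elif np.dot(axis, pts[-1] - pts[0]) < 0:
        axis = -axis
    return centroid, axis


def align_to_embryo_frame(lm: LandmarkSet, enforce_qc: bool = True) -> LandmarkSet:
    """Rigidly map the landmark set into the embryo reference frame.

    Z = notochord axis (cranial positive), X = dorso-ventral reference
    direction orthogonalized against Z (ventral positive), Y = Z x X
    (embryo's left positive). The notochord centroid maps to the origin.
    """
    if enforce_qc:
        if lm.somite_count is None:
            raise QCError("somite_count unknown; cannot apply the >=18-somite "
                          "QC rule — provide somite_count or disable QC")
        if lm.somite_count < SOMITE_QC_MIN:
            raise QCError(
                f"sample excluded: {lm.somite_count} somites < {SOMITE_QC_MIN}")

    origin, z_axis = _notochord_axis(lm.notochord_points, lm.point("outflow_exit"))
    dv = lm.dorsoventral_ref - origin
    x_axis = dv - np.dot(dv, z_axis) * z_axis
    nx = np.linalg.norm(x_axis)
    if nx < 1e-12:
        raise ValueError("dorsoventral reference lies on the notochord axis")
    x_axis = x_axis / nx
    y_axis = np.cross(z_axis, x_axis)
    rot = np.vstack([x_axis, y_axis, z_axis])  # world -> embryo frame

    def tf(p: np.ndarray) -> np.ndarray:
        return rot @ (p - origin)

    return replace(
        lm,
        landmarks={k: tf(v) for k, v in lm.landmarks.items()},
        notochord_points=np.array([tf(p) for p in lm.notochord_points]),
        dorsoventral_ref=tf(lm.dorsoventral_ref),
        aligned=True,
    )


def _require_aligned(lm: LandmarkSet) -> None:
    if not lm.aligned:
        raise ValueError("landmarks must be aligned to the embryo frame first")


def rvlv_axis_angle(aligned: LandmarkSet) -> float:
    """Signed transverse-plane angle (degrees) of the RV->LV axis.

    Measured from the +Y (leftward) axis, CCW positive viewed from
    cranial (+Z); range (-180, 180].
    """
    _require_aligned(aligned)
    v = aligned.point("LV") - aligned.point("RV")
    vx, vy = v[0], v[1]
    if np.hypot(vx, vy) < 1e-12:
        raise ValueError("RV and LV transverse projections coincide; "
                         "angle indeterminate")
    angle = np.degrees(np.arctan2(vy, vx)) - 90.0
    if angle <= -180.0:
        angle += 360.0
    return float(angle)


def tube_length(aligned: LandmarkSet) -> float:
    """Length of the ordered landmark polyline, arterial to venous pole."""
    _require_aligned(aligned)
    pts = np.array([aligned.point(n) for n in HEART_LANDMARKS])
    return float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum())


def venous_pole_displacement(aligned: LandmarkSet) -> float:
    """Signed left-right offset of the venous pole over the tube length."""
    _require_aligned(aligned)
    length = tube_length(aligned)
    if length <= 0:
        raise ValueError("tube length is zero")
    return float(aligned.point("venous_pole")[1] / length)


def looping_direction(aligned: LandmarkSet, tol_um: float = DIRECTION_TOL_UM) -> str:
    """Direction of the loop from the RV-LV left-right offset."""
    _require_aligned(aligned)
    dy = aligned.point("RV")[1] - aligned.point("LV")[1]
    if dy < -tol_um:
        return "rightward"
    if dy > tol_um:
        return "leftward"
    return "indeterminate"


def loop_metrics(lm: LandmarkSet, enforce_qc: bool = True,
                 tol_um: float = DIRECTION_TOL_UM) -> LoopMetrics:
    """Align and compute all loop metrics in one call."""
    aligned = lm if lm.aligned else align_to_embryo_frame(lm, enforce_qc=enforce_qc)
    return LoopMetrics(
        rvlv_angle_deg=rvlv_axis_angle(aligned),
        venous_displacement_norm=venous_pole_displacement(aligned),
        tube_length=tube_length(aligned),
        direction=looping_direction(aligned, tol_um=tol_um),
    )


def direction_frequency_test(n_rightward: int, n_total: int,
                             expected_prop: float = 0.5) -> StatResult:
    """Yates-corrected 1-df chi-squared test of looping-direction frequency."""
    if n_total < 1:
        raise ValueError("n_total must be >= 1")
    if n_rightward > n_total or n_rightward < 0:
        raise ValueError("n_rightward must lie in [0, n_total]")
    observed = [n_rightward, n_total - n_rightward]
    props = [expected_prop, 1.0 - expected_prop]
    return chi_squared_gof(observed, props, yates=True)
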