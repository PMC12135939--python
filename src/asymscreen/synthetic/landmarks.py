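"""Synthetic heart-tube landmark sets with known loop geometry.

Landmarks are built directly in the embryo reference frame (notochord on
Z, dorso-ventral reference on +X, +Y = left), so with zero noise and no
jitter the morphometry pipeline recovers the requested RV/LV angle and
venous-pole offset exactly. An optional random rigid motion exercises
the alignment step.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from ..morphometry import HEART_LANDMARKS, LandmarkSet
from .truth import GroundTruth

__all__ = ["LandmarkSimParams", "simulate_landmarks"]


@dataclass(frozen=True)
class LandmarkSimParams:
    rvlv_angle_deg: float = 0.0
    venous_offset_frac: float = 0.0
    tube_length: float = 700.0        # um
    noise_sd: float = 0.0
    rigid_jitter: bool = False
    somite_count: int = 25
    n_notochord_points: int = 7
    embryo_id: str = "sim"
    genotype: str = "wt"
    seed: int = 0

    def validate(self) -> None:
        if not (-180.0 < self.rvlv_angle_deg <= 180.0):
            raise ValueError("rvlv_angle_deg must lie in (-180, 180]")
        if self.tube_length <= 0:
            raise ValueError("tube_length must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if abs(self.venous_offset_frac) >= 0.9:
            raise ValueError("venous_offset_frac must lie in (-0.9, 0.9)")
        if self.somite_count < 1:
            raise ValueError("somite_count must be a positive integer")
        if self.n_notochord_points < 2:
            raise ValueError("need at least two notochord points")


def _base_chain(theta_deg: float) -> dict:
    """Unit-scale landmark chain in the embryo frame (venous pole free).

    The RV/LV pair straddles a centre point along the direction that
    makes the requested signed angle with the +Y axis; the rest of the
    chain descends along Z with small transverse offsets.
    """
    theta = np.radians(theta_deg)
    u = np.array([-np.sin(theta), np.cos(theta), 0.0])  # +Y rotated CCW by theta
    centre = np.array([0.25, 0.0, 1.5])
    return {
        "outflow_exit": np.array([0.45, 0.05, 3.0]),
        "OFT": np.array([0.65, -0.15, 2.2]),
        "RV": centre - 0.45 * u,
        "interventricular_sulcus": centre + np.array([0.1, 0.0, -0.05]),
        "LV": centre + 0.45 * u,
        "AVC_LA": np.array([0.2, 0.1, 0.8]),
        "RA": np.array([0.1, -0.05, 0.4]),
    }


def _chain_length(landmarks: dict, venous_pole: np.ndarray) -> float:
    pts = [landmarks[n] for n in HEART_LANDMARKS[:-1]] + [venous_pole]
    return float(np.linalg.norm(np.diff(np.array(pts), axis=0), axis=1).sum())


def simulate_landmarks(params: LandmarkSimParams) -> tuple[LandmarkSet, GroundTruth]:
    """Generate a landmark set realizing the requested loop geometry."""
    params.validate()
    rng = np.random.default_rng(params.seed)

    chain = _base_chain(params.rvlv_angle_deg)
    f = params.venous_offset_frac

    # place the venous pole at (0, y, 0) with y = f * polyline_length(y)
    def residual(y: float) -> float:
        return y - f * _chain_length(chain, np.array([0.0, y, 0.0]))

    if f == 0.0:
        y_sol = 0.0
    else:
        lo, hi = (-20.0, 20.0)
        y_sol = brentq(residual, lo, hi, xtol=1e-12)
    venous = np.array([0.0, y_sol, 0.0])
    length = _chain_length(chain, venous)

    scale = params.tube_length / length
    landmarks = {k: v * scale for k, v in chain.items()}
    landmarks["venous_pole"] = venous * scale

    z = np.linspace(-0.6, 3.4, params.n_notochord_points) * params.tube_length / 3.0
    notochord = np.column_stack([np.zeros_like(z), np.zeros_like(z), z])
    dv_ref = np.array([0.6 * params.tube_length, 0.0, 0.0])

    if params.noise_sd > 0:
        for k in landmarks:
            landmarks[k] = landmarks[k] + rng.normal(0, params.noise_sd, 3)
        notochord = notochord + rng.normal(0, params.noise_sd, notochord.shape)
        dv_ref = dv_ref + rng.normal(0, params.noise_sd, 3)

    if params.rigid_jitter:
        rot = _random_rotation(rng)
        shift = rng.uniform(-200, 200, size=3)
        landmarks = {k: rot @ v + shift for k, v in landmarks.items()}
        notochord = notochord @ rot.T + shift
        dv_ref = rot @ dv_ref + shift

    lm = LandmarkSet(
        landmarks=landmarks, notochord_points=notochord,
        dorsoventral_ref=dv_ref, somite_count=params.somite_count,
        embryo_id=params.embryo_id, genotype=params.genotype)
    truth = GroundTruth("landmarks", {
        "seed": params.seed,
        "rvlv_angle_deg": params.rvlv_angle_deg,
        "venous_offset_frac": params.venous_offset_frac,
        "tube_length": params.tube_length,
        "noise_sd": params.noise_sd,
        "rigid_jitter": params.rigid_jitter,
        "somite_count": params.somite_count,
    })
    return lm, truth


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix (QR of a Gaussian matrix)."""
    m = rng.normal(size=(3, 3))
    q, r = np.linalg.qr(m)
    q = q @ np.diag(np.sign(np.diag(r)))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q
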