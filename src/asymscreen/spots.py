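"""3D two-channel spot quantification of left/right expression asymmetry.

Transcript and nuclear spots are detected as local maxima of a
Laplacian-of-Gaussian response at a scale matched to the expected spot
radius. An anatomical region is bisected at the embryo midline, and the
left/right asymmetry of a transcript is summarized as

    log2_ratio = log2[ (S_L / (H_L * V_L)) / (S_R / (H_R * V_R)) ]

where S are transcript spot counts, H nuclear spot counts (the Hoechst
normalization, which cancels one-sided imaging intensity bias) and V the
region volumes in cubic micrometres.

All thresholds are computed per side from intensity percentiles of the
response, so a multiplicative intensity bias confined to one side does
not change which maxima are retained there.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .stats import bh_adjust, mann_whitney_u, wilcoxon_signed_rank_vs_zero

__all__ = [
    "SpotImage",
    "SpotSet",
    "AsymmetryMeasurement",
    "detect_spots",
    "bisect_mask_by_midline",
    "hoechst_normalization_score",
    "lr_asymmetry",
    "stage_profile",
]

NUCLEUS_CHANNEL = 0
TRANSCRIPT_CHANNEL = 1

DEFAULT_SPOT_RADIUS_UM = 1.4
DEFAULT_NUCLEUS_RADIUS_UM = 2.6
DEFAULT_PERCENTILE = 95.0
# detection floor as a fraction of the peak response; keeps percentile
# thresholds from dropping into the noise when spots are sparse
DEFAULT_REL_FLOOR = 0.15


@dataclass(frozen=True)
class SpotImage:
    """Two-channel 3D volume with a region label mask and midline plane.

    ``volume`` has shape (2, nz, ny, nx): channel 0 nuclei (Hoechst),
    channel 1 transcript. ``midline_plane`` holds coefficients
    (a, b, c, d) of a plane a*z + b*y + c*x + d = 0 in voxel-index
    coordinates; voxels with a nonnegative plane value are on the
    embryo's left.
    """

    volume: np.ndarray
    voxel_size_um: tuple
    region_mask: np.ndarray
    midline_plane: tuple
    region_labels: dict
    embryo_id: str = ""
    stage: str = ""
    genotype: str = ""

    def __post_init__(self) -> None:
        if self.volume.ndim != 4 or self.volume.shape[0] < 2:
            raise ValueError("volume must be (channels>=2, nz, ny, nx)")
        if self.volume.shape[1:] != self.region_mask.shape:
            raise ValueError("volume and region mask shapes disagree")
        if len(self.voxel_size_um) != 3 or any(v <= 0 for v in self.voxel_size_um):
            raise ValueError("voxel_size_um must be three positive reals")
        if len(self.midline_plane) != 4:
            raise ValueError("midline_plane must be (a, b, c, d)")


@dataclass(frozen=True)
class SpotSet:
    """Detected point set for one channel."""

    channel: int
    coordinates_um: np.ndarray     # (n, 3) in micrometres, (z, y, x)
    voxel_indices: np.ndarray      # (n, 3) integer voxel indices
    intensities: np.ndarray        # LoG response at each peak
    threshold: float

    def __len__(self) -> int:
        return int(self.coordinates_um.shape[0])


@dataclass
class AsymmetryMeasurement:
    embryo_id: str
    stage: str
    region: str
    S_L: int
    S_R: int
    H_L: int
    H_R: int
    V_L: float
    V_R: float
    norm_score: float
    log2_ratio: float
    genotype: str = ""
    valid: bool = True
    reason: str = ""


def _sigma_voxels(radius_um: float, voxel_size_um) -> np.ndarray:
    voxel = np.asarray(voxel_size_um, dtype=float)
    if np.any(radius_um < voxel):
        raise ValueError(
            f"spot radius {radius_um} um under-resolved by voxel size "
            f"{tuple(voxel)} um; resample the volume or increase the radius")
    return (radius_um / np.sqrt(3.0)) / voxel


def _ellipsoid_footprint(radius_vox: np.ndarray) -> np.ndarray:
    r = np.maximum(np.round(radius_vox).astype(int), 1)
    grids = np.ogrid[tuple(slice(-ri, ri + 1) for ri in r)]
    dist = sum((g / ri) ** 2 for g, ri in zip(grids, r))
    return dist <= 1.0


def detect_spots(volume: np.ndarray, voxel_size_um, spot_radius_um: float,
                 intensity_percentile: float = DEFAULT_PERCENTILE,
                 mask: np.ndarray | None = None,
                 rel_floor: float = DEFAULT_REL_FLOOR,
                 channel: int | None = None) -> SpotSet:
    """Detect bright diffraction-limited spots in a 3D volume.

    The volume is filtered with a negated Laplacian of Gaussian at scale
    sigma = spot_radius_um / sqrt(3) per axis (in voxels); local maxima
    within one spot radius are retained when their response exceeds both
    the requested percentile of the response inside ``mask`` and
    ``rel_floor`` times the peak response (the floor keeps sparse-signal
    thresholds out of the noise).
    """
    vol = np.asarray(volume, dtype=float)
    if vol.ndim == 4:
        if channel is None:
            raise ValueError("channel required for a multi-channel volume")
        vol = vol[channel]
    if vol.ndim != 3:
        raise ValueError("expected a 3D volume")
    sigma = _sigma_voxels(spot_radius_um, voxel_size_um)
    response = -ndi.gaussian_laplace(vol, sigma)

    region = mask.astype(bool) if mask is not None else np.ones(vol.shape, bool)
    if not region.any():
        raise ValueError("empty detection mask")
    in_region = response[region]
    # robust noise floor: in a signal-free region the response is pure
    # filtered noise, and no maximum should survive thresholding
    med = float(np.median(in_region))
    mad = float(np.median(np.abs(in_region - med)))
    threshold = max(
        float(np.percentile(in_region, intensity_percentile)),
        rel_floor * float(in_region.max()),
        med + 6.0 * 1.4826 * mad,
        0.0,
    )

    radius_vox = np.maximum(spot_radius_um / np.asarray(voxel_size_um, float), 1.0)
    footprint = _ellipsoid_footprint(radius_vox)
    local_max = response == ndi.maximum_filter(response, footprint=footprint,
                                               mode="nearest")
    peaks = local_max & region & (response > threshold) & (response > 0)
    idx = np.argwhere(peaks)
    coords = idx * np.asarray(voxel_size_um, dtype=float)
    chan = channel if channel is not None else 0
    return SpotSet(channel=chan, coordinates_um=coords, voxel_indices=idx,
                   intensities=response[peaks], threshold=threshold)


def bisect_mask_by_midline(region_mask: np.ndarray, label: int,
                           midline_plane) -> tuple[np.ndarray, np.ndarray]:
    """Split a labeled region into left/right halves at the midline plane.

    Voxels with nonnegative plane value (including exactly on the plane)
    go to the left half; the two halves are disjoint and their union is
    the labeled region.
    """
    a, b, c, d = (float(v) for v in midline_plane)
    if abs(a) + abs(b) + abs(c) < 1e-12:
        raise ValueError("degenerate midline plane")
    region = region_mask == label
    if not region.any():
        raise ValueError(f"region label {label} not present in mask")
    zz, yy, xx = np.indices(region_mask.shape, sparse=True)
    side = a * zz + b * yy + c * xx + d
    left = region & (side >= 0)
    right = region & (side < 0)
    return left, right


def _plane_side_of_indices(idx: np.ndarray, midline_plane) -> np.ndarray:
    a, b, c, d = (float(v) for v in midline_plane)
    return a * idx[:, 0] + b * idx[:, 1] + c * idx[:, 2] + d


def hoechst_normalization_score(
    image: SpotImage,
    left_mask: np.ndarray,
    right_mask: np.ndarray,
    nucleus_radius_um: float = DEFAULT_NUCLEUS_RADIUS_UM,
    candidate_percentile: float = 80.0,
    rel_floor: float = 0.1,
) -> tuple[float, int, int]:
    """Side normalization score from the nuclear (Hoechst) channel.

    Candidate nuclear maxima are detected independently on each side,
    then each side keeps the candidates at or above its own median
    response, i.e. the highest threshold retaining at least 50% of
    candidates on that side. Because both the candidate threshold and
    the 50%-coverage cut are per-side rank statistics, a multiplicative
    intensity bias restricted to one side leaves the counts unchanged.
    Returns (H_L / H_R, H_L, H_R).
    """
    counts = []
    for side_mask in (left_mask, right_mask):
        cands = detect_spots(image.volume, image.voxel_size_um,
                             nucleus_radius_um,
                             intensity_percentile=candidate_percentile,
                             mask=side_mask, rel_floor=rel_floor,
                             channel=NUCLEUS_CHANNEL)
        if len(cands) == 0:
            counts.append(0)
            continue
        cutoff = float(np.median(cands.intensities))
        counts.append(int(np.sum(cands.intensities >= cutoff)))
    h_l, h_r = counts
    if h_r == 0:
        raise ZeroDivisionError("no nuclei detected on the right side; "
                                "normalization score undefined")
    return h_l / h_r, h_l, h_r


def lr_asymmetry(
    image: SpotImage,
    region: str,
    spot_radius_um: float = DEFAULT_SPOT_RADIUS_UM,
    nucleus_radius_um: float = DEFAULT_NUCLEUS_RADIUS_UM,
    intensity_percentile: float = DEFAULT_PERCENTILE,
    rel_floor: float = DEFAULT_REL_FLOOR,
) -> AsymmetryMeasurement:
    """Normalized left/right asymmetry of transcript expression in a region.

    Transcript spots are detected per side (side-local thresholds),
    nuclei are counted through the 50%-coverage normalization score, and
    volumes come from voxel counts times the voxel volume.
    """
    if region not in image.region_labels:
        raise KeyError(f"unknown region {region!r}; "
                       f"known: {sorted(image.region_labels)}")
    label = image.region_labels[region]
    left_mask, right_mask = bisect_mask_by_midline(image.region_mask, label,
                                                   image.midline_plane)
    voxel_vol = float(np.prod(image.voxel_size_um))
    v_l = float(left_mask.sum()) * voxel_vol
    v_r = float(right_mask.sum()) * voxel_vol

    def _count(side_mask: np.ndarray) -> int:
        if not side_mask.any():
            return 0
        return len(detect_spots(image.volume, image.voxel_size_um,
                                spot_radius_um,
                                intensity_percentile=intensity_percentile,
                                mask=side_mask, rel_floor=rel_floor,
                                channel=TRANSCRIPT_CHANNEL))

    s_l, s_r = _count(left_mask), _count(right_mask)

    meas = AsymmetryMeasurement(
        embryo_id=image.embryo_id, stage=image.stage, region=region,
        S_L=s_l, S_R=s_r, H_L=0, H_R=0, V_L=v_l, V_R=v_r,
        norm_score=float("nan"), log2_ratio=float("nan"),
        genotype=image.genotype)

    if v_l == 0 or v_r == 0:
        meas.valid = False
        meas.reason = "midline plane does not intersect the region"
        return meas
    try:
        score, h_l, h_r = hoechst_normalization_score(
            image, left_mask, right_mask, nucleus_radius_um=nucleus_radius_um)
    except ZeroDivisionError as exc:
        meas.valid = False
        meas.reason = str(exc)
        return meas
    meas.H_L, meas.H_R, meas.norm_score = h_l, h_r, score

    if s_r == 0 or h_l == 0 or s_l == 0:
        meas.valid = False
        meas.reason = "zero spot or nucleus count makes the ratio undefined"
        return meas
    meas.log2_ratio = float(
        np.log2((s_l / (h_l * v_l)) / (s_r / (h_r * v_r))))
    return meas


def stage_profile(measurements, group_keys=("stage", "genotype")) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Summarize asymmetry measurements per group and test for asymmetry.

    Returns (summary, comparisons): the summary has mean/SD/n of the
    log2 ratio plus a signed-rank test against symmetry (log2 ratio = 0)
    per group; the comparisons table holds Mann-Whitney tests between
    genotypes within each stage. BH correction is applied across each
    reported p-value family.
    """
    rows = [m for m in measurements if m.valid]
    if not rows:
        raise ValueError("no valid measurements")
    df = pd.DataFrame([{
        "embryo_id": m.embryo_id, "stage": m.stage, "genotype": m.genotype,
        "region": m.region, "log2_ratio": m.log2_ratio} for m in rows])

    summaries = []
    for keys, grp in df.groupby(list(group_keys), sort=True):
        keys = keys if isinstance(keys, tuple) else (keys,)
        res = wilcoxon_signed_rank_vs_zero(grp["log2_ratio"].to_numpy())
        summaries.append({
            **dict(zip(group_keys, keys)),
            "n": len(grp),
            "mean_log2_ratio": float(grp["log2_ratio"].mean()),
            "sd_log2_ratio": float(grp["log2_ratio"].std(ddof=1)) if len(grp) > 1 else float("nan"),
            "symmetry_p": res.p_value,
        })
    summary = pd.DataFrame(summaries)
    summary["symmetry_p_bh"] = bh_adjust(summary["symmetry_p"].to_numpy())

    comparisons = []
    if "genotype" in df.columns and df["genotype"].nunique() > 1:
        for stage, grp in df.groupby("stage", sort=True):
            genos = sorted(grp["genotype"].unique())
            for i in range(len(genos)):
                for j in range(i + 1, len(genos)):
                    a = grp.loc[grp["genotype"] == genos[i], "log2_ratio"]
                    b = grp.loc[grp["genotype"] == genos[j], "log2_ratio"]
                    if len(a) == 0 or len(b) == 0:
                        continue
                    res = mann_whitney_u(a.to_numpy(), b.to_numpy())
                    comparisons.append({
                        "stage": stage, "group_a": genos[i], "group_b": genos[j],
                        "n_a": len(a), "n_b": len(b),
                        "U": res.statistic, "p": res.p_value,
                    })
    comp = pd.DataFrame(comparisons)
    if len(comp):
        comp["p_bh"] = bh_adjust(comp["p"].to_numpy())
    return summary, comp
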