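"""Synthetic two-channel 3D embryo volumes with known spot content.

The anatomical region is a pair of axis-aligned boxes mirrored across a
planar midline at x = nx/2 (high-x half = embryo's left). Channel 0
holds Gaussian nuclei placed uniformly per side; channel 1 holds smaller
Gaussian transcript spots at Poisson-uniform positions whose left
density is ``lr_fold`` times the right density. A multiplicative
intensity bias can be applied to one side of both channels to emulate
lightsheet attenuation, and Poisson shot noise (plus optional Gaussian
read noise) corrupts the rendered intensities.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..spots import SpotImage
from .truth import GroundTruth

__all__ = ["ImageSimParams", "simulate_embryo_image", "stage_preset",
           "STAGE_LR_FOLD"]

# true left/right transcript-density ratio per developmental stage preset;
# E8.5d is the stage of peak left-sided enrichment (4.5-fold)
STAGE_LR_FOLD = {"E8.5d": 4.5}

NUCLEUS_SIGMA_UM = 1.5
SPOT_SIGMA_UM = 0.8
NUCLEUS_AMPLITUDE = 600.0
SPOT_AMPLITUDE = 3000.0
BACKGROUND = 50.0
REGION_LABEL = 1
REGION_NAME = "heart_field"


@dataclass(frozen=True)
class ImageSimParams:
    shape_voxels: tuple = (48, 128, 128)        # (nz, ny, nx)
    voxel_size_um: tuple = (1.0, 1.0, 1.0)
    n_nuclei_per_side: tuple = (400, 400)       # (left, right)
    spot_density_right: float = 1.75e-3         # spots per um^3, right side
    lr_fold: float = 1.0
    side_intensity_bias: float = 1.0
    bias_side: str = "R"
    psf_sigma_um: tuple = (0.0, 0.0, 0.0)       # extra blur on top of blob sigma
    noise: str = "poisson"                      # "poisson", "gaussian", "none"
    gaussian_sd: float = 10.0
    margin_voxels: int = 8
    embryo_id: str = "sim"
    stage: str = "E8.5d"
    genotype: str = "wt"
    seed: int = 0

    def validate(self) -> None:
        if len(self.shape_voxels) != 3 or any(s < 4 for s in self.shape_voxels):
            raise ValueError("shape_voxels must be three integers >= 4")
        if any(v <= 0 for v in self.voxel_size_um):
            raise ValueError("voxel_size_um must be positive")
        if any(n < 1 for n in self.n_nuclei_per_side):
            raise ValueError("n_nuclei_per_side must be positive")
        if self.spot_density_right < 0:
            raise ValueError("spot_density_right must be nonnegative")
        if self.lr_fold < 0:
            raise ValueError("lr_fold must be nonnegative")
        if self.side_intensity_bias <= 0:
            raise ValueError("side_intensity_bias must be positive")
        if self.bias_side not in ("L", "R"):
            raise ValueError("bias_side must be 'L' or 'R'")
        if self.noise not in ("poisson", "gaussian", "none"):
            raise ValueError("noise must be poisson, gaussian or none")
        nz, ny, nx = self.shape_voxels
        m = self.margin_voxels
        if nx // 2 - m < 2 or ny - 2 * m < 2 or nz - 2 * m < 2:
            raise ValueError("shape too small to contain the region boxes")


def _side_boxes(params: ImageSimParams) -> tuple[tuple, tuple]:
    """Voxel-index bounds ((z0,z1),(y0,y1),(x0,x1)) for left and right boxes."""
    nz, ny, nx = params.shape_voxels
    m = params.margin_voxels
    cx = nx // 2
    z = (m, nz - m)
    y = (m, ny - m)
    left = (z, y, (cx, nx - m))
    right = (z, y, (m, cx))
    return left, right


def _render_gaussians(vol: np.ndarray, centers_vox: np.ndarray,
                      sigma_vox: np.ndarray, amplitude: float) -> None:
    """Add isotropic-in-um Gaussian blobs to a volume in place."""
    if centers_vox.size == 0:
        return
    half = np.ceil(4 * sigma_vox).astype(int)
    shape = np.array(vol.shape)
    for c in centers_vox:
        lo = np.maximum(np.floor(c - half).astype(int), 0)
        hi = np.minimum(np.ceil(c + half).astype(int) + 1, shape)
        if np.any(lo >= hi):
            continue
        grids = np.ogrid[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
        q = sum(((g - ci) / si) ** 2 for g, ci, si in zip(grids, c, sigma_vox))
        vol[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] += amplitude * np.exp(-0.5 * q)


def _uniform_in_box(rng: np.random.Generator, box, n: int) -> np.ndarray:
    """Uniform continuous positions inside a voxel box.

    Voxel indices are treated as cell centres, so a box of voxels
    [x0, x1) covers continuous [x0 - 0.5, x1 - 0.5); positions then
    round into exactly the box's voxel set, keeping the rendered content
    mirror-symmetric about the midline plane between adjacent boxes.
    """
    (z0, z1), (y0, y1), (x0, x1) = box
    lo = np.array([z0, y0, x0], dtype=float) - 0.5
    hi = np.array([z1, y1, x1], dtype=float) - 0.5
    return rng.uniform(low=lo, high=hi, size=(n, 3))


def simulate_embryo_image(params: ImageSimParams) -> tuple[SpotImage, GroundTruth]:
    """Render a two-channel volume and its ground truth."""
    params.validate()
    rng = np.random.default_rng(params.seed)
    nz, ny, nx = params.shape_voxels
    voxel = np.asarray(params.voxel_size_um, dtype=float)
    voxel_vol = float(np.prod(voxel))

    left_box, right_box = _side_boxes(params)

    def box_volume_um3(box) -> float:
        return float(np.prod([b[1] - b[0] for b in box])) * voxel_vol

    # nuclei
    n_left, n_right = params.n_nuclei_per_side
    nuclei_left = _uniform_in_box(rng, left_box, n_left)
    nuclei_right = _uniform_in_box(rng, right_box, n_right)

    # transcript spots: Poisson counts at side-specific densities
    density_left = params.lr_fold * params.spot_density_right
    lam_left = density_left * box_volume_um3(left_box)
    lam_right = params.spot_density_right * box_volume_um3(right_box)
    spots_left = _uniform_in_box(rng, left_box, rng.poisson(lam_left))
    spots_right = _uniform_in_box(rng, right_box, rng.poisson(lam_right))

    nucleus_sigma = NUCLEUS_SIGMA_UM / voxel
    spot_sigma = SPOT_SIGMA_UM / voxel

    nuclei_chan = np.full((nz, ny, nx), BACKGROUND, dtype=float)
    transcript_chan = np.full((nz, ny, nx), BACKGROUND, dtype=float)
    _render_gaussians(nuclei_chan, np.vstack([nuclei_left, nuclei_right]),
                      nucleus_sigma, NUCLEUS_AMPLITUDE)
    all_spots = np.vstack([spots_left, spots_right])
    _render_gaussians(transcript_chan, all_spots, spot_sigma, SPOT_AMPLITUDE)

    if any(s > 0 for s in params.psf_sigma_um):
        from scipy import ndimage as ndi
        psf_vox = np.asarray(params.psf_sigma_um, float) / voxel
        nuclei_chan = ndi.gaussian_filter(nuclei_chan, psf_vox)
        transcript_chan = ndi.gaussian_filter(transcript_chan, psf_vox)

    # one-sided multiplicative intensity bias, both channels
    cx = nx // 2
    if params.side_intensity_bias != 1.0:
        sl = (slice(None), slice(None),
              slice(cx, None) if params.bias_side == "L" else slice(0, cx))
        nuclei_chan[sl] *= params.side_intensity_bias
        transcript_chan[sl] *= params.side_intensity_bias

    volume = np.stack([nuclei_chan, transcript_chan])
    if params.noise == "poisson":
        volume = rng.poisson(np.maximum(volume, 0.0)).astype(float)
    elif params.noise == "gaussian":
        volume = volume + rng.normal(0.0, params.gaussian_sd, size=volume.shape)

    region_mask = np.zeros((nz, ny, nx), dtype=np.uint16)
    for box in (left_box, right_box):
        (z0, z1), (y0, y1), (x0, x1) = box
        region_mask[z0:z1, y0:y1, x0:x1] = REGION_LABEL
    # plane x = cx in voxel-index coordinates; x >= cx is the left side.
    # -0.5 places boundary voxels (index cx) strictly left of the plane's
    # right half, matching the box split above.
    midline_plane = (0.0, 0.0, 1.0, -(cx - 0.5))

    image = SpotImage(
        volume=volume, voxel_size_um=tuple(voxel),
        region_mask=region_mask, midline_plane=midline_plane,
        region_labels={REGION_NAME: REGION_LABEL},
        embryo_id=params.embryo_id, stage=params.stage,
        genotype=params.genotype)
    truth = GroundTruth("image", {
        "seed": params.seed,
        "lr_fold": params.lr_fold,
        "spot_density_right": params.spot_density_right,
        "side_intensity_bias": params.side_intensity_bias,
        "bias_side": params.bias_side,
        "n_spots_left": int(len(spots_left)),
        "n_spots_right": int(len(spots_right)),
        "spots_left_vox": spots_left,
        "spots_right_vox": spots_right,
        "nuclei_left_vox": nuclei_left,
        "nuclei_right_vox": nuclei_right,
        "volume_left_um3": box_volume_um3(left_box),
        "volume_right_um3": box_volume_um3(right_box),
    })
    return image, truth


def stage_preset(stage: str, seed: int = 0, **overrides) -> ImageSimParams:
    """Image-simulation preset whose true L/R fold matches a stage.

    Only stages with a documented enrichment are available; 'E8.5d'
    fixes the true left/right transcript-density ratio to 4.5.
    """
    if stage not in STAGE_LR_FOLD:
        raise KeyError(f"no preset for stage {stage!r}; "
                       f"available: {sorted(STAGE_LR_FOLD)}")
    return ImageSimParams(lr_fold=STAGE_LR_FOLD[stage], stage=stage,
                          seed=seed, **overrides)
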