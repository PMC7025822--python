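"""Render synthetic 3D smFISH stacks from simulated ground truth.

Geometry mirrors the acquisition used for neuroblast smFISH: anisotropic
voxels (74 nm laterally, 200 nm axially) and a diffraction-limited PSF
approximated by an anisotropic 3D Gaussian. Each mature transcript becomes a
Gaussian spot of fixed integrated intensity (``unit_photon_count``); the
transcription focus is a single brighter spot inside the nuclear mask whose
integrated intensity is ``focus_signal`` mature-transcript equivalents.
Noise is Poisson shot noise on signal + background plus Gaussian read noise.

Cell and nuclear masks are concentric ellipsoids — adequate for closed-loop
testing of the spot caller, not a model of real neuroblast morphology.
Mitotic cells are not simulated.

Axis order is (z, y, x) throughout; coordinates in the truth sidecar are in
nanometres.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ImageConfig", "RenderedCell", "render_image", "ellipsoid_mask"]


@dataclass(frozen=True)
class ImageConfig:
    """Acquisition geometry and camera model for rendered stacks.

    voxel_nm : (z, y, x) voxel size in nm (default 200, 74, 74).
    psf_sigma_nm : (lateral, axial) Gaussian PSF sigmas in nm.
    unit_photon_count : integrated photons of one mature transcript.
    background : flat background, photons per voxel.
    read_noise_sd : Gaussian read noise s.d., photons.
    stack_shape : (z, y, x) in voxels.
    cell_radius_frac / nucleus_radius_frac : ellipsoid semi-axes as a
        fraction of the half-extent of the stack.
    min_separation_nm : minimum pairwise spot separation enforced during
        placement (0 disables).
    """

    voxel_nm: tuple[float, float, float] = (200.0, 74.0, 74.0)
    psf_sigma_nm: tuple[float, float] = (110.0, 350.0)  # (lateral, axial)
    unit_photon_count: float = 5000.0
    background: float = 10.0
    read_noise_sd: float = 2.0
    stack_shape: tuple[int, int, int] = (40, 128, 128)
    cell_radius_frac: float = 0.85
    nucleus_radius_frac: float = 0.45
    min_separation_nm: float = 0.0

    def __post_init__(self) -> None:
        if any(v <= 0 for v in self.voxel_nm):
            raise ValueError("voxel sizes must be positive")
        if any(s < 4 for s in self.stack_shape):
            raise ValueError("stack too small")

    @property
    def sigma_voxels(self) -> tuple[float, float, float]:
        lat, ax = self.psf_sigma_nm
        vz, vy, vx = self.voxel_nm
        return (ax / vz, lat / vy, lat / vx)


@dataclass
class RenderedCell:
    """A rendered stack with its masks and ground-truth sidecar."""

    image: np.ndarray          # float64 photons, shape (z, y, x)
    cell_mask: np.ndarray      # bool
    nuclear_mask: np.ndarray   # bool
    truth: dict                # spot/focus coordinates (nm) and intensities
    config: ImageConfig


def ellipsoid_mask(
    shape: tuple[int, int, int],
    voxel_nm: tuple[float, float, float],
    radius_frac: float,
) -> np.ndarray:
    """Boolean ellipsoid centred in the stack.

    Semi-axes are ``radius_frac`` of the half-extent along each axis in
    physical units, so the mask is a sphere-ish blob despite anisotropy.
    """
    grids = np.meshgrid(
        *[np.arange(s, dtype=float) for s in shape], indexing="ij"
    )
    r2 = np.zeros(shape, dtype=float)
    for g, s, v in zip(grids, shape, voxel_nm):
        half = (s - 1) / 2.0
        r2 += (((g - half) * v) / (half * v * radius_frac)) ** 2
    return r2 <= 1.0


def _place_spots(
    n: int,
    region: np.ndarray,
    voxel_nm: tuple[float, float, float],
    rng: np.random.Generator,
    min_sep_nm: float,
    max_tries: int = 20_000,
) -> np.ndarray:
    """Uniformly sample n spot centres (nm) in a boolean region."""
    coords = np.argwhere(region)
    if len(coords) == 0:
        raise ValueError("placement region is empty")
    placed: list[np.ndarray] = []
    tries = 0
    v = np.asarray(voxel_nm)
    while len(placed) < n:
        tries += 1
        if tries > max_tries:
            raise ValueError("stack too small to place spots at this separation")
        vox = coords[rng.integers(len(coords))]
        pos = (vox + rng.uniform(-0.5, 0.5, size=3)) * v
        if min_sep_nm > 0 and placed:
            d = np.linalg.norm(np.array(placed) - pos, axis=1)
            if d.min() < min_sep_nm:
                continue
        placed.append(pos)
    return np.array(placed).reshape(n, 3)


def _add_gaussian(
    image: np.ndarray,
    centre_nm: np.ndarray,
    integrated: float,
    cfg: ImageConfig,
) -> None:
    """Add an anisotropic Gaussian of given integrated intensity in place."""
    sig_vox = np.asarray(cfg.sigma_voxels)
    centre_vox = centre_nm / np.asarray(cfg.voxel_nm)
    lo = np.maximum(np.floor(centre_vox - 5 * sig_vox).astype(int), 0)
    hi = np.minimum(
        np.ceil(centre_vox + 5 * sig_vox).astype(int) + 1, image.shape
    )
    axes = [np.arange(lo[d], hi[d], dtype=float) for d in range(3)]
    # separable Gaussian, normalised per-axis so the voxel sum ~= integrated
    profiles = []
    for d in range(3):
        g = np.exp(-0.5 * ((axes[d] - centre_vox[d]) / sig_vox[d]) ** 2)
        profiles.append(g / (sig_vox[d] * np.sqrt(2 * np.pi)))
    block = integrated * (
        profiles[0][:, None, None] * profiles[1][None, :, None] * profiles[2][None, None, :]
    )
    image[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] += block


def render_image(
    truth_row,
    cfg: ImageConfig | None = None,
    seed: int = 0,
    noise: bool = True,
) -> RenderedCell:
    """Render one cell's stack from a simulate_counts row (or mapping).

    Mature transcripts (``M``) are placed in the cytoplasm (inside the cell
    ellipsoid, outside the nuclear ellipsoid); the transcription focus, when
    ``focus_signal`` > 0, is a single spot of integrated intensity
    focus_signal * unit_photon_count placed inside the nucleus. With
    ``noise=False`` the stack is the noiseless photon expectation plus the
    flat background.
    """
    cfg = cfg or ImageConfig()
    rng = np.random.default_rng(seed)
    M = int(truth_row["M"])
    focus_signal = float(truth_row["focus_signal"])

    cell = ellipsoid_mask(cfg.stack_shape, cfg.voxel_nm, cfg.cell_radius_frac)
    nucleus = ellipsoid_mask(cfg.stack_shape, cfg.voxel_nm, cfg.nucleus_radius_frac)
    cyto = cell & ~nucleus

    image = np.full(cfg.stack_shape, float(cfg.background))
    spots_nm = np.zeros((0, 3))
    if M > 0:
        spots_nm = _place_spots(M, cyto, cfg.voxel_nm, rng, cfg.min_separation_nm)
        for pos in spots_nm:
            _add_gaussian(image, pos, cfg.unit_photon_count, cfg)
    focus_nm = None
    if focus_signal > 0:
        focus_nm = _place_spots(1, nucleus, cfg.voxel_nm, rng, 0.0)[0]
        _add_gaussian(image, focus_nm, focus_signal * cfg.unit_photon_count, cfg)

    if noise:
        image = rng.poisson(np.maximum(image, 0.0)).astype(float)
        image += rng.normal(0.0, cfg.read_noise_sd, size=image.shape)

    truth = {
        "cell_id": str(truth_row.get("cell_id", "cell")),
        "M": M,
        "focus_signal": focus_signal,
        "spot_coords_nm": spots_nm.tolist(),
        "focus_coord_nm": None if focus_nm is None else list(focus_nm),
        "unit_photon_count": cfg.unit_photon_count,
        "seed": int(seed),
    }
    return RenderedCell(image, cell, nucleus, truth, cfg)
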