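"""Spot detection, transcription-focus identification and nascent counting.

The detection chain is the standard single-molecule one: Laplacian-of-
Gaussian filtering at the PSF scale (per-axis sigmas, so voxel anisotropy is
respected), 3D local-maxima extraction, a threshold in robust background
s.d. units, sub-voxel centroid refinement, and background-subtracted
integrated intensity over a fixed PSF-sized box with the local background
taken as the median of the box's border shell.

Nascent counting follows the integrated-intensity convention: the
transcription focus is the brightest nuclear spot, its intensity divided by
the batch-wide single-transcript ("unit") intensity gives the nascent count
N in mature-transcript equivalents. The unit intensity is the median of all
non-focus spot intensities across the batch (mean available via config). A
focus is only *called* when it exceeds ``min_focus_multiple`` (default 2.0)
times the unit intensity.

Internally coordinates are voxel-indexed 0-based half-open; all outputs are
in nanometres.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "Spot",
    "SpotParams",
    "CellQuant",
    "detect_spots",
    "filter_spots_to_mask",
    "identify_transcription_focus",
    "unit_intensity",
    "nascent_count",
    "quantify_batch",
    "cellquants_from_counts",
]


@dataclass(frozen=True)
class SpotParams:
    """Detection and calibration parameters.

    psf_sigma_nm : (lateral, axial) PSF sigmas used to scale the LoG filter
        and the integration box.
    threshold_sd : LoG peak threshold as a multiple of the robust background
        s.d. (1.4826 * MAD) of the filtered image.
    integrate_halfwidth_sigmas : integration box half-width in PSF sigmas.
    min_focus_multiple : a nuclear spot must exceed this multiple of the
        unit intensity to be called the transcription focus.
    unit_stat : "median" (robust default) or "mean" batch averaging for the
        unit intensity.
    min_unit_spots : calibration floor — fewer non-focus spots than this in
        a batch is an error.
    channel_ratio_min : when a second (5') channel is supplied, required
        5'/3' intensity ratio for focus confirmation.
    """

    psf_sigma_nm: tuple[float, float] = (110.0, 350.0)
    threshold_sd: float = 5.0
    integrate_halfwidth_sigmas: float = 3.0
    min_focus_multiple: float = 2.0
    unit_stat: str = "median"
    min_unit_spots: int = 20
    channel_ratio_min: float = 1.2


@dataclass
class Spot:
    """One detected spot; coordinates in nm, intensity background-subtracted."""

    x: float
    y: float
    z: float
    integrated_intensity: float
    in_nucleus: bool = False
    channel: str = "main"
    voxel: tuple[int, int, int] = (0, 0, 0)  # (z, y, x) detection voxel


@dataclass
class CellQuant:
    """Per-cell quantification: mature count M and nascent count N."""

    cell_id: str
    M: int
    focus_intensity: float
    unit_intensity: float
    N: float
    focus_called: bool
    flag: str = ""


def _sigma_voxels(voxel_nm, psf_sigma_nm) -> np.ndarray:
    lat, ax = psf_sigma_nm
    vz, vy, vx = voxel_nm
    return np.array([ax / vz, lat / vy, lat / vx])


def detect_spots(
    image: np.ndarray,
    voxel_nm: tuple[float, float, float],
    params: SpotParams | None = None,
    nuclear_mask: np.ndarray | None = None,
) -> list[Spot]:
    """LoG detection of diffraction-limited spots in a 3D stack.

    Deterministic for fixed input. ``voxel_nm`` is required — without the
    anisotropy the filter cannot be scaled.

    Raises
    ------
    ValueError
        If voxel metadata is missing/invalid or shapes disagree.
    """
    params = params or SpotParams()
    if voxel_nm is None or len(voxel_nm) != 3 or any(v <= 0 for v in voxel_nm):
        raise ValueError("voxel anisotropy metadata missing; cannot scale LoG filter")
    img = np.asarray(image, dtype=float)
    if img.ndim != 3:
        raise ValueError("expected a 3D stack (z, y, x)")
    if nuclear_mask is not None and nuclear_mask.shape != img.shape:
        raise ValueError("image and mask shapes differ")

    sig = _sigma_voxels(voxel_nm, params.psf_sigma_nm)
    # -LoG: bright blobs become positive peaks
    response = -ndimage.gaussian_laplace(img, sigma=sig)
    med = np.median(response)
    mad = np.median(np.abs(response - med))
    robust_sd = 1.4826 * mad
    if robust_sd == 0:
        robust_sd = max(response.std(), np.finfo(float).tiny)
    thresh = med + params.threshold_sd * robust_sd

    size = np.maximum((2 * np.ceil(sig) + 1).astype(int), 3)
    local_max = response == ndimage.maximum_filter(response, size=size, mode="nearest")
    peaks = np.argwhere(local_max & (response > thresh))

    # integrated-intensity significance: the box sum must clear the same
    # multiple of the photon-noise s.d. of a background box, else a noise
    # maximum that slipped past the LoG threshold would become a spot
    img_med = np.median(img)
    img_sd = 1.4826 * np.median(np.abs(img - img_med))

    spots: list[Spot] = []
    half = np.maximum(
        np.round(params.integrate_halfwidth_sigmas * sig).astype(int), 1
    )
    n_box = float(np.prod(2 * half + 1))
    min_intensity = params.threshold_sd * img_sd * np.sqrt(n_box)
    for pk in peaks:
        intensity, centroid_vox = _integrate(img, pk, half)
        if intensity <= 0 or intensity < min_intensity:
            continue
        z_nm, y_nm, x_nm = centroid_vox * np.asarray(voxel_nm)
        in_nuc = (
            bool(nuclear_mask[tuple(pk)]) if nuclear_mask is not None else False
        )
        spots.append(
            Spot(
                x=float(x_nm),
                y=float(y_nm),
                z=float(z_nm),
                integrated_intensity=float(intensity),
                in_nucleus=in_nuc,
                voxel=tuple(int(v) for v in pk),
            )
        )
    # deterministic ordering: by (z, y, x) voxel
    spots.sort(key=lambda s: s.voxel)
    return spots


def _integrate(img: np.ndarray, peak: np.ndarray, half: np.ndarray):
    """Background-subtracted box integral + intensity-weighted centroid.

    The local background is the median of the box's border shell; the
    centroid refines the peak to sub-voxel precision.
    """
    lo = np.maximum(peak - half, 0)
    hi = np.minimum(peak + half + 1, img.shape)
    box = img[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
    core = box[1:-1, 1:-1, 1:-1]
    shell_mask = np.ones(box.shape, dtype=bool)
    if all(s > 2 for s in box.shape):
        shell_mask[1:-1, 1:-1, 1:-1] = False
    background = np.median(box[shell_mask])
    sub = box - background
    intensity = float(sub.sum())
    pos = np.clip(sub, 0, None)
    total = pos.sum()
    if total > 0:
        grids = np.meshgrid(
            *[np.arange(lo[d], hi[d], dtype=float) for d in range(3)], indexing="ij"
        )
        centroid = np.array([float((g * pos).sum() / total) for g in grids])
    else:
        centroid = peak.astype(float)
    return intensity, centroid


def filter_spots_to_mask(
    spots: list[Spot],
    mask: np.ndarray,
    voxel_nm: tuple[float, float, float],
) -> list[Spot]:
    """Keep spots whose centroid voxel lies inside the (boolean) mask.

    A spot exactly on a boundary voxel is kept — inside means the mask is
    true at the centroid's voxel.
    """
    out = []
    v = np.asarray(voxel_nm, dtype=float)
    for s in spots:
        vox = np.round(np.array([s.z, s.y, s.x]) / v).astype(int)
        vox = np.clip(vox, 0, np.array(mask.shape) - 1)
        if mask[tuple(vox)]:
            out.append(s)
    return out


def identify_transcription_focus(
    spots: list[Spot],
    unit: float | None = None,
    params: SpotParams | None = None,
) -> Spot | None:
    """The transcription focus: brightest nuclear spot above threshold.

    Returns the nuclear spot of maximal integrated intensity provided it
    exceeds ``min_focus_multiple * unit`` (skipped when ``unit`` is None,
    i.e. during the pre-calibration pass). Ties broken by intensity then
    lowest z, deterministically; a tie triggers a warning. None when no
    nuclear spot qualifies.
    """
    params = params or SpotParams()
    nuclear = [s for s in spots if s.in_nucleus]
    if not nuclear:
        return None
    best = sorted(nuclear, key=lambda s: (-s.integrated_intensity, s.z))[0]
    ties = [
        s
        for s in nuclear
        if s is not best and s.integrated_intensity == best.integrated_intensity
    ]
    if ties:
        warnings.warn(
            "tie between equal-intensity nuclear spots; picking lowest z",
            stacklevel=2,
        )
    if unit is not None and best.integrated_intensity < params.min_focus_multiple * unit:
        return None
    return best


def unit_intensity(
    spots_across_batch: list[Spot],
    focus_ids: set[int] | None = None,
    params: SpotParams | None = None,
) -> float:
    """Batch single-transcript intensity from non-focus spots.

    ``focus_ids`` holds ``id()`` of spots serving as focus candidates; they
    are excluded. Median by default (mean via ``unit_stat="mean"``).
    """
    params = params or SpotParams()
    focus_ids = focus_ids or set()
    vals = np.array(
        [
            s.integrated_intensity
            for s in spots_across_batch
            if id(s) not in focus_ids
        ]
    )
    if len(vals) < params.min_unit_spots:
        raise ValueError("insufficient spots for unit calibration")
    if params.unit_stat == "mean":
        return float(vals.mean())
    return float(np.median(vals))


def nascent_count(focus_intensity: float, unit: float) -> float:
    """N = focus intensity / unit intensity, real-valued (no rounding)."""
    if unit <= 0:
        raise ValueError("unit intensity must be > 0")
    return max(focus_intensity, 0.0) / unit


def quantify_batch(
    cells: list[tuple[str, np.ndarray, np.ndarray, np.ndarray]],
    voxel_nm: tuple[float, float, float],
    params: SpotParams | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Detect + quantify a batch of cells sharing one unit calibration.

    ``cells`` is a list of (cell_id, image, cell_mask, nuclear_mask). Two
    passes: spots are detected and a focus *candidate* (brightest nuclear
    spot) marked per cell; the unit intensity is then the batch median of
    all non-candidate spots; finally each candidate is called a focus only
    if it clears ``min_focus_multiple`` times the unit.

    Returns (spots table, per-cell CellQuant table). The unit intensity is
    order-independent across cells by construction.
    """
    params = params or SpotParams()
    per_cell: list[tuple[str, list[Spot], Spot | None]] = []
    for cell_id, image, cell_mask, nuclear_mask in cells:
        spots = detect_spots(image, voxel_nm, params, nuclear_mask=nuclear_mask)
        spots = filter_spots_to_mask(spots, cell_mask, voxel_nm)
        candidate = identify_transcription_focus(spots, unit=None, params=params)
        per_cell.append((cell_id, spots, candidate))

    focus_ids = {id(c) for _, _, c in per_cell if c is not None}
    all_spots = [s for _, spots, _ in per_cell for s in spots]
    unit = unit_intensity(all_spots, focus_ids, params)

    spot_rows, quant_rows = [], []
    for cell_id, spots, candidate in per_cell:
        called = (
            candidate is not None
            and candidate.integrated_intensity >= params.min_focus_multiple * unit
        )
        focus_int = candidate.integrated_intensity if called else 0.0
        M = sum(1 for s in spots if not (called and s is candidate))
        N = nascent_count(focus_int, unit)
        quant_rows.append(
            CellQuant(
                cell_id=cell_id,
                M=M,
                focus_intensity=focus_int,
                unit_intensity=unit,
                N=N,
                focus_called=called,
                flag="" if called else "no focus called",
            )
        )
        for s in spots:
            spot_rows.append(
                {
                    "cell_id": cell_id,
                    "x_nm": s.x,
                    "y_nm": s.y,
                    "z_nm": s.z,
                    "intensity": s.integrated_intensity,
                    "in_nucleus": s.in_nucleus,
                    "is_focus": called and s is candidate,
                }
            )
    spots_df = pd.DataFrame(
        spot_rows,
        columns=["cell_id", "x_nm", "y_nm", "z_nm", "intensity", "in_nucleus", "is_focus"],
    )
    quant_df = pd.DataFrame([vars(q) for q in quant_rows])
    return spots_df, quant_df


def cellquants_from_counts(
    counts: pd.DataFrame, params: SpotParams | None = None
) -> pd.DataFrame:
    """Bypass mode: build CellQuant rows straight from a counts table.

    The table (e.g. from ``simulate_counts`` or a FISHquant-style export)
    must carry ``M`` and ``focus_signal`` in mature-transcript equivalents,
    i.e. unit intensity 1. The focus-calling rule still applies: a focus
    below ``min_focus_multiple`` equivalents is not called and the cell is
    flagged.
    """
    params = params or SpotParams()
    unit = 1.0
    called = counts["focus_signal"].to_numpy() >= params.min_focus_multiple * unit
    out = pd.DataFrame(
        {
            "cell_id": counts["cell_id"],
            "M": counts["M"].astype(int),
            "focus_intensity": np.where(called, counts["focus_signal"], 0.0),
            "unit_intensity": unit,
            "N": np.where(called, counts["focus_signal"] / unit, 0.0),
            "focus_called": called,
            "flag": np.where(called, "", "no focus called"),
        }
    )
    if "group" in counts.columns:
        out.insert(0, "group", counts["group"].to_numpy())
    return out
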