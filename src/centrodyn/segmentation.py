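"""Nucleus and cell segmentation plus the reference centroids.

Nuclei (DNA channel): global Otsu threshold → morphological close then open
(disk, radius 2 px) → Euclidean distance transform → Gaussian blur →
watershed seeded at the distance maxima, which cuts merged nuclei.  Cells
(tubulin channel): multi-orientation Gabor energy → threshold → the
connected component containing the nucleus; a manually drawn polygon can
override the automatic result.  Per-frame failures are flagged, never
raised, so one bad frame does not kill a movie.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.draw import polygon2mask
from skimage.feature import peak_local_max
from skimage.filters import gabor
from skimage.measure import regionprops
from skimage.morphology import closing, disk, opening
from skimage.segmentation import watershed

from .config import SegmentationParams
from .detection import DegenerateImageError, otsu_background


@dataclass
class FrameGeometry:
    """Segmentation result for one frame of one cell."""

    frame: int
    nucleus_mask: np.ndarray | None
    cell_mask: np.ndarray | None
    nuclear_centroid_um: tuple[float, float] | None
    cellular_centroid_um: tuple[float, float] | None
    ok: bool = True
    flags: list[str] = field(default_factory=list)


def segment_nuclei(
    dna: np.ndarray, params: SegmentationParams | None = None
) -> np.ndarray:
    """Label nuclei in a DNA-channel frame; 0 labels for a blank frame."""
    p = params or SegmentationParams()
    img = np.asarray(dna, float)
    try:
        thr = otsu_background(img)
    except DegenerateImageError:
        return np.zeros(img.shape, np.int32)
    mask = img > thr
    # reject structureless frames: thresholding pure noise separates the
    # two classes by only a couple of background sigmas
    bg, fg = img[~mask], img[mask]
    if fg.size == 0 or bg.size == 0:
        return np.zeros(img.shape, np.int32)
    if (fg.mean() - bg.mean()) < p.min_contrast_snr * (bg.std() + 1e-12):
        return np.zeros(img.shape, np.int32)
    selem = disk(p.morph_radius)
    mask = opening(closing(mask, selem), selem)
    if not mask.any():
        return np.zeros(img.shape, np.int32)
    dist = ndi.distance_transform_edt(mask)
    dist = ndi.gaussian_filter(dist, p.distance_blur_sigma)
    seeds = peak_local_max(
        dist, min_distance=p.seed_min_distance, labels=ndi.label(mask)[0],
        exclude_border=False,
    )
    if len(seeds) == 0:
        labels, _ = ndi.label(mask)
    else:
        markers = np.zeros(img.shape, np.int32)
        markers[tuple(seeds.T)] = np.arange(1, len(seeds) + 1)
        labels = watershed(-dist, markers, mask=mask)
    # enforce minimum nucleus area and relabel compactly
    out = np.zeros(img.shape, np.int32)
    nxt = 1
    for prop in regionprops(labels):
        if prop.area >= p.min_nucleus_area:
            out[labels == prop.label] = nxt
            nxt += 1
    return out


def gabor_energy(
    image: np.ndarray, params: SegmentationParams | None = None
) -> np.ndarray:
    """Summed Gabor magnitude over an orientation/frequency bank."""
    p = params or SegmentationParams()
    img = np.asarray(image, float)
    img = img - img.mean()
    energy = np.zeros(img.shape)
    for freq in p.gabor_frequencies:
        for k in range(p.gabor_n_orientations):
            theta = np.pi * k / p.gabor_n_orientations
            real, imag = gabor(img, frequency=freq, theta=theta)
            energy += np.hypot(real, imag)
    return energy


def segment_cell(
    tubulin: np.ndarray,
    nucleus_mask: np.ndarray,
    params: SegmentationParams | None = None,
    manual_polygon_um: np.ndarray | None = None,
    pixel_size_um: float = 1.0,
) -> tuple[np.ndarray | None, bool]:
    """Cell outline from tubulin texture; returns (mask, ok).

    The Gabor-energy image is smoothed, thresholded (Otsu) and the
    connected component containing the nucleus is kept.  If
    `manual_polygon_um` is given ((N,2) x,y vertices in μm), its rasterized
    mask is returned exactly — the manual-estimation escape hatch.  When no
    component contains the nucleus, (None, False) is returned.
    """
    p = params or SegmentationParams()
    if manual_polygon_um is not None:
        poly = np.asarray(manual_polygon_um, float) / pixel_size_um
        mask = polygon2mask(np.asarray(tubulin).shape, poly[:, ::-1])
        return mask, True
    energy = gabor_energy(tubulin, p)
    energy = ndi.gaussian_filter(energy, p.cell_smooth_sigma)
    try:
        thr = otsu_background(energy)
    except DegenerateImageError:
        return None, False
    mask = ndi.binary_fill_holes(energy > thr)
    labels, _ = ndi.label(mask)
    nuc = np.asarray(nucleus_mask, bool)
    if not nuc.any():
        return None, False
    hit = np.bincount(labels[nuc].ravel())
    hit[0] = 0
    if hit.sum() == 0:
        return None, False
    lab = int(np.argmax(hit))
    cell = labels == lab
    # the cell must contain the nucleus; union keeps the geometry consistent
    return cell | nuc, True


def centroid(mask: np.ndarray, pixel_size_um: float = 1.0) -> tuple[float, float]:
    """Unweighted center of mass of a mask, (x, y) in μm."""
    mask = np.asarray(mask, bool)
    if not mask.any():
        raise ValueError("empty mask has no centroid")
    rr, cc = np.nonzero(mask)
    return (float(cc.mean()) * pixel_size_um, float(rr.mean()) * pixel_size_um)


def track_masks(
    labeled_frames: list[np.ndarray],
    pixel_size_um: float = 1.0,
    search_radius_um: float = 5.0,
) -> pd.DataFrame:
    """Link per-frame nucleus labels into stable cell identities.

    Centroids of the labeled masks are linked frame-to-frame exactly like
    centrosome spots (nearest-neighbour within a radius); identities of
    objects leaving the field terminate and are never reassigned.  Returns
    a table (frame, label, cell_id, x_um, y_um).
    """
    from .tracking import link

    rows = []
    spot_id = 0
    for f, labels in enumerate(labeled_frames):
        for prop in regionprops(labels):
            cy, cx = prop.centroid
            rows.append((spot_id, f, cx * pixel_size_um, cy * pixel_size_um,
                         prop.label))
            spot_id += 1
    if not rows:
        return pd.DataFrame(columns=["frame", "label", "cell_id", "x_um", "y_um"])
    spots = pd.DataFrame(rows, columns=["spot_id", "frame", "x", "y", "label"])
    tracks = link(spots, mode="nearest", search_radius=search_radius_um, max_gap=0)
    merged = tracks.merge(spots[["spot_id", "label"]], on="spot_id")
    out = merged.rename(columns={"track_id": "cell_id", "x": "x_um", "y": "y_um"})
    return out[["frame", "label", "cell_id", "x_um", "y_um"]].sort_values(
        ["frame", "cell_id"], ignore_index=True
    )


def segment_movie(
    stack,
    params: SegmentationParams | None = None,
) -> list[FrameGeometry]:
    """Segment every frame of a stack (nucleus + cell + centroids)."""
    p = params or SegmentationParams()
    px = stack.pixel_size_um
    dna = stack.channel("dna")
    tub = stack.channel("tubulin") if "tubulin" in stack.channels else None
    out = []
    cached_cell = None
    for f in range(stack.n_frames):
        labels = segment_nuclei(dna[f], p)
        flags = []
        if labels.max() == 0:
            out.append(FrameGeometry(f, None, None, None, None, False,
                                     ["no-nucleus"]))
            continue
        # largest nucleus is the analyzed one (single-cell fields)
        areas = np.bincount(labels.ravel())
        areas[0] = 0
        nuc = labels == int(np.argmax(areas))
        if tub is not None:
            if f % max(1, p.cell_stride) == 0 or cached_cell is None:
                cell, ok = segment_cell(tub[f], nuc, p, pixel_size_um=px)
                if ok:
                    cached_cell = cell
                else:
                    flags.append("no-cell")
            else:
                cell = cached_cell
        else:
            cell = None
            flags.append("no-tubulin-channel")
        out.append(
            FrameGeometry(
                frame=f,
                nucleus_mask=nuc,
                cell_mask=cell,
                nuclear_centroid_um=centroid(nuc, px),
                cellular_centroid_um=centroid(cell, px) if cell is not None else None,
                ok=True,
                flags=flags,
            )
        )
    return out
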