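"""Line-profile quantification across the nuclear envelope and a
reproducible perinuclear-ring prominence score.

Profiles are sampled by bilinear interpolation along a user-drawn segment
crossing the NE, normalized so the brightest sample of each line is 100%,
registered at the recorded NE crossing and aggregated as mean ± SD.  Ring
prominence replaces by-eye scoring of perinuclear actin: the mean intensity
in a 1-μm annulus straddling the nucleus boundary divided by the mean in a
cytoplasmic band 2–4 μm further out; the ratio is scale-invariant, ≈1
without a ring, and grows with ring amplitude.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .config import ProfileParams


@dataclass
class LineROI:
    """A straight profile line in μm, with the NE crossing recorded as a
    fractional position along it."""

    x0: float
    y0: float
    x1: float
    y1: float
    n_samples: int = 101
    crossing_frac: float = 0.5

    def __post_init__(self):
        if (self.x0, self.y0) == (self.x1, self.y1):
            raise ValueError("ROI endpoints must be distinct")
        if not (0.0 < self.crossing_frac < 1.0):
            raise ValueError("crossing fraction must be in (0, 1)")


def sample_profile(
    image: np.ndarray, roi: LineROI, pixel_size_um: float = 1.0
) -> pd.DataFrame:
    """Bilinear samples evenly spaced along the ROI.

    Returns a table with position_um (distance along the line) and
    intensity columns.
    """
    t = np.linspace(0.0, 1.0, roi.n_samples)
    xs = (roi.x0 + t * (roi.x1 - roi.x0)) / pixel_size_um
    ys = (roi.y0 + t * (roi.y1 - roi.y0)) / pixel_size_um
    vals = ndi.map_coordinates(np.asarray(image, float), [ys, xs], order=1,
                               mode="nearest")
    length = np.hypot(roi.x1 - roi.x0, roi.y1 - roi.y0)
    return pd.DataFrame({"position_um": t * length, "intensity": vals,
                         "frac": t})


def normalize_profile(profile: np.ndarray | pd.Series) -> np.ndarray:
    """Percent-of-max scaling: the brightest sample becomes exactly 100."""
    vals = np.asarray(profile, float)
    m = vals.max()
    if m <= 0:
        raise ValueError("profile has no positive sample; normalization undefined")
    return (vals / m) * 100.0


def aggregate_profiles(
    profiles: list[np.ndarray],
    crossing_fracs: list[float],
    n_samples: int = 101,
) -> pd.DataFrame:
    """Register normalized profiles at their NE crossing and aggregate.

    Each profile is resampled onto a common grid whose midpoint sits at the
    recorded crossing; columns: frac (0–1 along the registered axis), mean,
    sd.  Identical inputs give SD = 0 everywhere.
    """
    if len(profiles) != len(crossing_fracs):
        raise ValueError("one crossing fraction per profile required")
    half = (n_samples - 1) // 2
    grid = np.arange(-half, n_samples - half) / (n_samples - 1)
    resampled = []
    for prof, cf in zip(profiles, crossing_fracs):
        prof = np.asarray(prof, float)
        src = np.linspace(0.0, 1.0, len(prof)) - cf  # 0 at the crossing
        resampled.append(np.interp(grid, src, prof, left=np.nan, right=np.nan))
    arr = np.vstack(resampled)
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(arr, axis=0)
        sd = np.nanstd(arr, axis=0, ddof=0)
    return pd.DataFrame({"frac": grid + 0.5, "mean": mean, "sd": sd})


def ring_prominence(
    image: np.ndarray,
    nucleus_mask: np.ndarray,
    pixel_size_um: float,
    params: ProfileParams | None = None,
) -> tuple[float, bool]:
    """Perinuclear ring score and present/absent call.

    score = mean intensity within ±`annulus_halfwidth_um` of the nucleus
    boundary / mean intensity in the cytoplasmic band
    `cytoplasm_band_um` outside it.  Invariant to multiplying the image by
    a positive constant; present ⇔ score > cutoff.
    """
    p = params or ProfileParams()
    img = np.asarray(image, float)
    nuc = np.asarray(nucleus_mask, bool)
    inside = ndi.distance_transform_edt(nuc) * pixel_size_um
    outside = ndi.distance_transform_edt(~nuc) * pixel_size_um
    signed = np.where(nuc, inside, -outside)  # >0 inside the nucleus
    annulus = np.abs(signed) <= p.annulus_halfwidth_um
    lo, hi = p.cytoplasm_band_um
    band = (-signed >= lo) & (-signed <= hi)
    if not annulus.any() or not band.any():
        raise ValueError("annulus or cytoplasmic band empty; check geometry")
    score = float(img[annulus].mean() / img[band].mean())
    return score, score > p.ring_cutoff
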