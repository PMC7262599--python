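"""Pipeline configuration.

All stage parameters live in one dataclass tree so a single YAML file
reproduces a run.  Defaults follow the published recipe where one exists
(DoG sigmas 1.5/4.5 px for spots of size 3, minimum spot size 15 px,
circularity cutoff 0.7, EB3 search radius 3 px, 5-min frame interval);
everything else is a documented choice surfaced here.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml


@dataclass
class DetectionParams:
    """Centrosome spot detection (DoG → Otsu → maxima regions → circularity)."""

    dog_sigma_small: float = 1.5   # px, below expected feature size
    dog_sigma_large: float = 4.5   # px, above expected feature size
    min_spot_size: int = 15        # px, minimum region area above background
    min_circularity: float = 0.7   # 4πA/P²; elongated spots discarded below
    peak_min_distance: int = 3     # px, minimum separation of seed maxima
    # minimum peak height above the background threshold, in units of the
    # background sigma of the filtered image; rejects structureless frames
    min_prominence: float = 10.0
    comet_min_sigma: float = 1.0   # px, LoG scale range for comet blobs
    comet_max_sigma: float = 3.0
    comet_threshold_rel: float = 0.2


@dataclass
class SegmentationParams:
    """Nucleus (threshold/morphology/watershed) and cell (Gabor) segmentation."""

    morph_radius: int = 2          # px disk for close then open
    distance_blur_sigma: float = 2.0
    # a frame counts as containing nuclei only if the Otsu foreground mean
    # exceeds the background mean by this many background sigmas (pure
    # noise separates by ~2.7 sigma, real chromatin by tens)
    min_contrast_snr: float = 4.0
    seed_min_distance: int = 10    # px between watershed seed maxima
    min_nucleus_area: int = 100    # px
    gabor_frequencies: tuple[float, ...] = (0.1, 0.25)
    gabor_n_orientations: int = 4
    cell_smooth_sigma: float = 3.0
    # adherent cells barely move between 5-min frames; the (expensive) Gabor
    # cell outline is recomputed every Nth frame and reused in between
    cell_stride: int = 5


@dataclass
class TrackingParams:
    mode: str = "nearest"          # nearest | drift | kalman
    # centrosome regime: speeds up to ~0.5 μm/min at 5-min frames give
    # per-frame displacements up to ~2.5 μm (12.5 px at 0.2 μm/px)
    search_radius: float = 10.0    # px per frame
    comet_search_radius: float = 3.0  # px, EB3 regime
    max_gap: int = 1               # frames bridged during linking
    min_length: int = 3            # frames, track-quality filter
    max_gaps: int = 2


@dataclass
class MetricParams:
    contact_threshold_um: float = 1.5   # centrosomes "joined" below this
    contact_dwell_frames: int = 2
    onset_threshold_um: float = 2.5     # separation onset
    onset_persistence_frames: int = 2
    msd_max_lag_fraction: float = 1 / 3
    pause_window_min: float = 20.0      # NE-contact pause window
    ne_contact_tolerance_um: float = 1.0
    diametric_angle_deg: float = 150.0  # position-class rule
    detach_threshold_um: float = 5.0


@dataclass
class ProfileParams:
    n_samples: int = 101
    annulus_halfwidth_um: float = 1.0
    cytoplasm_band_um: tuple[float, float] = (2.0, 4.0)
    ring_cutoff: float = 1.5


@dataclass
class PipelineConfig:
    """Everything a full run needs; round-trips through YAML."""

    pixel_size_um: float = 0.2
    frame_interval_min: float = 5.0
    channels: dict[str, int] = field(
        default_factory=lambda: {"centrosome": 0, "dna": 1, "tubulin": 2}
    )
    detection: DetectionParams = field(default_factory=DetectionParams)
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    tracking: TrackingParams = field(default_factory=TrackingParams)
    metrics: MetricParams = field(default_factory=MetricParams)
    profiles: ProfileParams = field(default_factory=ProfileParams)
    seed: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(_listify(self.to_dict()), fh, sort_keys=False)

    @classmethod
    def load(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        kwargs = dict(raw)
        for name, sub in (
            ("detection", DetectionParams),
            ("segmentation", SegmentationParams),
            ("tracking", TrackingParams),
            ("metrics", MetricParams),
            ("profiles", ProfileParams),
        ):
            if name in kwargs and isinstance(kwargs[name], dict):
                kwargs[name] = _build(sub, kwargs[name])
        return cls(**kwargs)

    def digest(self) -> str:
        """Stable hash of the configuration for run manifests."""
        blob = json.dumps(_listify(self.to_dict()), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _build(klass, d: dict):
    fields = {f.name for f in dataclasses.fields(klass)}
    obj = klass(**{k: v for k, v in d.items() if k in fields})
    for f in dataclasses.fields(klass):
        v = getattr(obj, f.name)
        if isinstance(v, list):
            setattr(obj, f.name, tuple(v))
    return obj


def _listify(obj):
    # YAML has no tuple; emit lists
    if isinstance(obj, dict):
        return {k: _listify(v) for k, v in obj.items()}
    if isinstance(obj, tuple):
        return [_listify(v) for v in obj]
    return obj
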