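"""Derived centrosome-pair statistics.

Everything downstream of tracking: inter-centrosome distance over time,
separation onset and first-contact detection, cohort congression
percentage, speeds (path length over time), time-averaged MSD with
high/low displacement grouping, the angle subtended at the nuclear
centroid, midpoint-to-centroid alignment, distances to nuclear and
cellular centroids, nuclear-envelope contact phases (outside / pause /
after-pause), rule-based position classes, axis rotation between two time
points, and EB3 comet statistics.

All metrics are 2D (x, y in μm, time in min); a z column, when present,
is carried through but not used — these cells are flat and the geometry
reduces to two dimensions.  Gapped tracks are handled with actual time
lags; nothing is interpolated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import MetricParams


# ---------------------------------------------------------------------------
# distance and event detection

def distance_series(track_a: pd.DataFrame, track_b: pd.DataFrame) -> pd.Series:
    """Euclidean inter-centrosome distance (μm) at the common frames."""
    a = track_a.set_index("frame")[["x", "y"]]
    b = track_b.set_index("frame")[["x", "y"]]
    common = a.index.intersection(b.index).sort_values()
    d = np.hypot(
        a.loc[common, "x"] - b.loc[common, "x"],
        a.loc[common, "y"] - b.loc[common, "y"],
    )
    return pd.Series(d.to_numpy(), index=common, name="distance_um")


def extend_distance_through_merge(
    d: pd.Series,
    track_a: pd.DataFrame,
    track_b: pd.DataFrame,
    merge_tolerance_um: float = 3.0,
) -> pd.Series:
    """Continue d(t) after a detection merge ends one of the two tracks.

    Two congressed centrosomes closer than the resolution limit detect as a
    single spot, so one track dies next to the survivor and the plain
    distance series stops at or just above the contact threshold.  A merge
    is recognized when, at the first frame after the shorter track ends,
    the surviving spot lies within `merge_tolerance_um` plus the recent
    per-frame approach step of the ended track's final position.  From the
    merge frame on the pair is unresolvable and the distance is recorded as
    0 for as long as the survivor persists.  Far-apart track ends (a
    centrosome leaving the field) are left alone.
    """
    if len(d) == 0:
        return d
    a_end = int(track_a["frame"].max())
    b_end = int(track_b["frame"].max())
    if a_end == b_end:
        return d
    survivor, ended = (track_a, track_b) if a_end > b_end else (track_b, track_a)
    last = ended.sort_values("frame").iloc[-1]
    s = survivor.sort_values("frame")
    tail = s[s.frame > d.index[-1]]
    if len(tail) == 0:
        return d
    step = float(np.abs(np.diff(d.to_numpy())[-1])) if len(d) > 1 else 0.0
    gap = float(np.hypot(tail.iloc[0]["x"] - last["x"],
                         tail.iloc[0]["y"] - last["y"]))
    if gap > merge_tolerance_um + step:
        return d
    ext = pd.Series(
        0.0, index=pd.Index(tail["frame"].astype(int), name="frame"),
    )
    return pd.concat([d, ext]).rename("distance_um")


def _sustained_crossing(cond: np.ndarray, k: int) -> int | None:
    """First index where `cond` holds for k consecutive samples (k>=1)."""
    run = 0
    for i, c in enumerate(cond):
        run = run + 1 if c else 0
        if run >= k:
            return i - k + 1
    return None


def detect_separation_onset(
    d: pd.Series,
    onset_threshold: float = 2.5,
    persistence: int = 2,
) -> int | None:
    """First frame where d exceeds the onset threshold and stays above it
    for `persistence` consecutive frames; None if separation never starts."""
    idx = _sustained_crossing((d.to_numpy() > onset_threshold), persistence)
    return int(d.index[idx]) if idx is not None else None


def label_phases(
    d: pd.Series, onset: int | None, plateau_tolerance: float = 0.5
) -> pd.Series:
    """pre / active / post labels around a separation onset.

    Active runs from the onset frame until the distance first comes within
    `plateau_tolerance` μm of its eventual maximum (the plateau); tracking
    noise in the plateau therefore does not stretch the active phase."""
    labels = pd.Series("pre", index=d.index, dtype=object)
    if onset is None:
        return labels
    after = d.loc[d.index >= onset]
    plateau = after.index[after.to_numpy() >= after.max() - plateau_tolerance][0]
    labels.loc[(labels.index >= onset) & (labels.index <= plateau)] = "active"
    labels.loc[labels.index > plateau] = "post"
    return labels


def time_of_first_contact(
    d: pd.Series,
    contact_threshold: float = 1.5,
    dwell: int = 2,
) -> tuple[int | None, bool]:
    """(first frame with d below threshold sustained for `dwell` frames,
    congressed flag).  A single-frame dip shorter than the dwell is not a
    contact."""
    idx = _sustained_crossing(d.to_numpy() < contact_threshold, dwell)
    if idx is None:
        return None, False
    return int(d.index[idx]), True


def percent_congression(
    contact_times: list[float | None],
    times: np.ndarray,
) -> np.ndarray:
    """Cumulative percentage of cells whose centrosomes have joined by each
    time point; monotone nondecreasing; cells without contact never count."""
    n = len(contact_times)
    if n == 0:
        return np.zeros_like(np.asarray(times, float))
    t_arr = np.asarray(times, float)
    out = np.zeros_like(t_arr)
    for tc in contact_times:
        if tc is not None:
            out += t_arr >= tc
    return 100.0 * out / n


# ---------------------------------------------------------------------------
# speeds and MSD

def path_speed(track: pd.DataFrame, frame_interval_min: float,
               frames: tuple[int, int] | None = None) -> float:
    """Path length over elapsed time (μm/min), optionally restricted to a
    [start, stop] frame window (inclusive); gaps use actual time lags."""
    g = track.sort_values("frame")
    if frames is not None:
        g = g[(g.frame >= frames[0]) & (g.frame <= frames[1])]
    if len(g) < 2:
        return 0.0
    xy = g[["x", "y"]].to_numpy()
    f = g["frame"].to_numpy()
    path = np.hypot(*np.diff(xy, axis=0).T).sum()
    elapsed = (f[-1] - f[0]) * frame_interval_min
    return float(path / elapsed) if elapsed > 0 else 0.0


def approach_speed(d: pd.Series, frame_interval_min: float) -> float:
    """Mean |Δd|/Δt of the inter-centrosome distance (μm/min) — the rate at
    which the pair approaches or separates, as opposed to individual
    centrosome path speed."""
    if len(d) < 2:
        return 0.0
    dd = np.abs(np.diff(d.to_numpy())).sum()
    elapsed = (d.index[-1] - d.index[0]) * frame_interval_min
    return float(dd / elapsed) if elapsed > 0 else 0.0


def msd(track: pd.DataFrame, frame_interval_min: float,
        max_lag: int | None = None) -> pd.Series:
    """Time-averaged mean squared displacement (μm²) per lag.

    Averages over all overlapping pairs at each frame lag τ; by default
    lags run to one third of the track span (bias/variance compromise).
    MSD(0) = 0 by definition.  Missing frames inside a gapped track simply
    contribute no pairs at the affected lags.
    """
    g = track.sort_values("frame")
    frames = g["frame"].to_numpy()
    xy = g[["x", "y"]].to_numpy(float)
    span = int(frames[-1] - frames[0]) if len(frames) > 1 else 0
    if max_lag is None:
        max_lag = max(1, span // 3)
    pos = {int(f): xy[i] for i, f in enumerate(frames)}
    lags = np.arange(0, max_lag + 1)
    out = np.full(len(lags), np.nan)
    out[0] = 0.0
    for li, lag in enumerate(lags[1:], start=1):
        sq = [
            np.sum((pos[f + lag] - pos[f]) ** 2)
            for f in pos
            if (f + lag) in pos
        ]
        if sq:
            out[li] = float(np.mean(sq))
    return pd.Series(out, index=lags * frame_interval_min, name="msd_um2")


def displacement_grouping(
    pair_msds: list[tuple[pd.Series, pd.Series]],
    reference_lag: float | None = None,
) -> tuple[list[tuple[str, str]], pd.DataFrame]:
    """Split each cell's two centrosomes into high/low displacement groups.

    Per cell, the centrosome with the larger MSD at the reference lag (the
    largest lag common to both curves unless given) is "high"; exact ties
    break to the first centrosome (C1).  Returns the per-cell assignment
    and cohort curves: pointwise mean and SD per group.
    """
    assignment = []
    high_curves, low_curves = [], []
    for m1, m2 in pair_msds:
        common = m1.index.intersection(m2.index)
        common = common[~(m1.loc[common].isna() | m2.loc[common].isna())]
        if reference_lag is not None and reference_lag in common:
            ref = reference_lag
        else:
            ref = common.max()
        if m2.loc[ref] > m1.loc[ref]:
            assignment.append(("low", "high"))
            high_curves.append(m2)
            low_curves.append(m1)
        else:  # tie → C1 high
            assignment.append(("high", "low"))
            high_curves.append(m1)
            low_curves.append(m2)

    def summarize(curves, name):
        df = pd.concat(curves, axis=1)
        return pd.DataFrame({
            f"{name}_mean": df.mean(axis=1),
            f"{name}_sd": df.std(axis=1, ddof=0),
        })

    cohort = pd.concat(
        [summarize(high_curves, "high"), summarize(low_curves, "low")], axis=1
    )
    return assignment, cohort


# ---------------------------------------------------------------------------
# geometry relative to the nucleus and cell

def centroid_angle(c1, c2, nuclear_centroid) -> float:
    """Angle (degrees, [0, 180]) subtended at the nuclear centroid by the
    two centrosomes."""
    v1 = np.asarray(c1, float)[:2] - np.asarray(nuclear_centroid, float)[:2]
    v2 = np.asarray(c2, float)[:2] - np.asarray(nuclear_centroid, float)[:2]
    n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
    if n1 == 0 or n2 == 0:
        raise ValueError("centrosome coincides with the nuclear centroid; "
                         "angle undefined")
    cosang = np.clip(np.dot(v1, v2) / (n1 * n2), -1.0, 1.0)
    return float(math.degrees(math.acos(cosang)))


def alignment_midpoint_distance(c1, c2, nuclear_centroid) -> float:
    """Distance (μm) from the midpoint between the centrosomes to the
    nuclear centroid — 0 when the pair is symmetric about the centroid."""
    mid = (np.asarray(c1, float)[:2] + np.asarray(c2, float)[:2]) / 2.0
    return float(np.linalg.norm(mid - np.asarray(nuclear_centroid, float)[:2]))


def centroid_distance_series(
    track: pd.DataFrame,
    nuclear_centroid,
    cellular_centroid=None,
) -> pd.DataFrame:
    """Per-frame distance of a centrosome to the nuclear (and optionally
    cellular) centroid, μm.  Centroids may be constant (x, y) or per-frame
    DataFrames indexed by frame with x, y columns."""
    g = track.sort_values("frame").set_index("frame")

    def dist_to(ref):
        if isinstance(ref, pd.DataFrame):
            common = g.index.intersection(ref.index)
            return pd.Series(
                np.hypot(g.loc[common, "x"] - ref.loc[common, "x"],
                         g.loc[common, "y"] - ref.loc[common, "y"]),
                index=common,
            )
        ref = np.asarray(ref, float)
        return np.hypot(g["x"] - ref[0], g["y"] - ref[1])

    out = pd.DataFrame({"dist_nuclear_um": dist_to(nuclear_centroid)})
    if cellular_centroid is not None:
        out["dist_cellular_um"] = dist_to(cellular_centroid)
    return out


def distance_to_boundary(points: np.ndarray, boundary: np.ndarray) -> np.ndarray:
    """Unsigned distance (μm) of points to a closed boundary polygon."""
    from shapely.geometry import LinearRing, Point

    ring = LinearRing(boundary)
    pts = np.atleast_2d(np.asarray(points, float))
    return np.array([ring.distance(Point(p[0], p[1])) for p in pts])


@dataclass
class NEPhases:
    """Speeds around the first nuclear-envelope contact of one centrosome."""

    contact_frame: int | None
    outside_speed: float | None
    pause_speed: float | None
    after_speed: float | None


def ne_contact_phases(
    track: pd.DataFrame,
    nucleus_boundary: np.ndarray,
    frame_interval_min: float,
    pause_window_min: float = 20.0,
    contact_tolerance_um: float = 1.0,
) -> NEPhases:
    """Align a track by its first nuclear-envelope contact and report phase
    speeds: outside (before contact), pause (0–`pause_window_min` after
    contact) and after-pause (beyond the window).

    Contact = first frame at distance ≤ tolerance from the nucleus
    boundary.  A track that never reaches the nucleus has only an outside
    phase; a track already in contact at t=0 has no outside phase.
    """
    g = track.sort_values("frame").reset_index(drop=True)
    pts = g[["x", "y"]].to_numpy()
    d = distance_to_boundary(pts, nucleus_boundary)
    hit = np.nonzero(d <= contact_tolerance_um)[0]
    frames = g["frame"].to_numpy()
    if len(hit) == 0:
        return NEPhases(None, path_speed(g, frame_interval_min), None, None)
    fc = int(frames[hit[0]])
    pause_end = fc + pause_window_min / frame_interval_min
    out = pause = after = None
    if fc > frames[0]:
        out = path_speed(g, frame_interval_min, (int(frames[0]), fc))
    if (frames >= fc).sum() >= 2:
        pause = path_speed(g, frame_interval_min,
                           (fc, int(math.floor(pause_end))))
    if (frames > pause_end).sum() >= 2:
        after = path_speed(g, frame_interval_min,
                           (int(math.ceil(pause_end)), int(frames[-1])))
    return NEPhases(fc, out, pause, after)


POSITION_CLASSES = ("diametric-under-nucleus", "NE-border", "side-of-nucleus",
                    "detached")


def classify_position(
    c1,
    c2,
    nuclear_centroid,
    nucleus_boundary: np.ndarray,
    nucleus_mask: np.ndarray | None = None,
    pixel_size_um: float = 1.0,
    params: MetricParams | None = None,
) -> str:
    """Deterministic position class of a centrosome pair.

    Rules (tolerances inclusive): both centrosomes farther than the detach
    threshold from the NE and outside the nucleus → detached; angle at the
    nuclear centroid ≥ 150° with both under the nuclear projection →
    diametric-under-nucleus; within the NE tolerance → NE-border;
    otherwise → side-of-nucleus.
    """
    p = params or MetricParams()
    pts = np.array([np.asarray(c1, float)[:2], np.asarray(c2, float)[:2]])
    d_ne = distance_to_boundary(pts, nucleus_boundary)
    if nucleus_mask is not None:
        under = []
        for x, y in pts:
            r, c = int(round(y / pixel_size_um)), int(round(x / pixel_size_um))
            inside = (
                0 <= r < nucleus_mask.shape[0]
                and 0 <= c < nucleus_mask.shape[1]
                and bool(nucleus_mask[r, c])
            )
            under.append(inside)
    else:
        from shapely.geometry import Point, Polygon

        poly = Polygon(nucleus_boundary)
        under = [poly.contains(Point(x, y)) for x, y in pts]

    if all(~np.asarray(under)) and (d_ne > p.detach_threshold_um).all():
        return "detached"
    ang = centroid_angle(c1, c2, nuclear_centroid)
    if ang >= p.diametric_angle_deg and all(under):
        return "diametric-under-nucleus"
    if (d_ne <= p.ne_contact_tolerance_um).all():
        return "NE-border"
    return "side-of-nucleus"


def axis_rotation(pair_t1, pair_t2) -> float:
    """Acute angle (degrees, [0, 90]) between the undirected centrosome
    axes at two time points — e.g. the pair axis at NEBD versus the spindle
    axis at metaphase, estimating spindle rotation."""
    a = np.asarray(pair_t1[1], float)[:2] - np.asarray(pair_t1[0], float)[:2]
    b = np.asarray(pair_t2[1], float)[:2] - np.asarray(pair_t2[0], float)[:2]
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("degenerate axis (coincident centrosomes)")
    cosang = abs(np.dot(a, b)) / (na * nb)
    return float(math.degrees(math.acos(np.clip(cosang, -1.0, 1.0))))


# ---------------------------------------------------------------------------
# comets

def comet_stats(
    comet_tracks: pd.DataFrame,
    frame_interval_min: float,
    max_lag: int | None = None,
) -> dict:
    """Per-cell EB3 comet summary: mean of per-track path speeds (μm/min),
    pooled MSD curve, and the track-length distribution (frames)."""
    speeds, lengths, msds = [], [], []
    for _tid, g in comet_tracks.groupby("track_id"):
        lengths.append(len(g))
        if len(g) >= 2:
            speeds.append(path_speed(g, frame_interval_min))
            msds.append(msd(g, frame_interval_min,
                            max_lag=max_lag if max_lag is not None else None))
    pooled = None
    if msds:
        pooled = pd.concat(msds, axis=1).mean(axis=1)
        pooled.name = "msd_um2"
    return {
        "mean_speed_um_min": float(np.mean(speeds)) if speeds else 0.0,
        "n_tracks": len(lengths),
        "track_lengths": np.asarray(lengths),
        "pooled_msd": pooled,
    }
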