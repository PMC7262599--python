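"""Frame-to-frame linking of detections into tracks.

Three motion models are provided, matching the trackers used for the
different measurements: plain nearest-neighbour, drift prediction (next
position extrapolated from the last displacement — the EB3 regime, default
search radius 3 px), and a constant-velocity Kalman filter with innovation
gating.  Gaps up to `max_gap` frames are closed during linking with the
search radius scaled by the gap length.  Gap-closed positions are never
interpolated into a track: downstream statistics use the actual time lags.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

MODES = ("nearest", "drift", "kalman")


@dataclass
class _TrackState:
    track_id: int
    last_frame: int
    pos: np.ndarray             # last observed position
    prev_pos: np.ndarray | None = None
    kf_x: np.ndarray | None = None   # [x, y, vx, vy]
    kf_P: np.ndarray | None = None
    points: list = None

    def predict(self, mode: str, dt: int) -> np.ndarray:
        if mode == "nearest" or self.prev_pos is None and self.kf_x is None:
            return self.pos
        if mode == "drift":
            if self.prev_pos is None:
                return self.pos
            return self.pos + (self.pos - self.prev_pos) * dt
        # kalman
        x = self.kf_x
        return np.array([x[0] + x[2] * dt, x[1] + x[3] * dt])


_KF_Q = 0.05   # process noise (units²/frame²), small: near-constant velocity
_KF_R = 0.25   # measurement noise (units²)


def _kf_init(pos):
    x = np.array([pos[0], pos[1], 0.0, 0.0])
    P = np.diag([1.0, 1.0, 4.0, 4.0])
    return x, P


def _kf_update(x, P, meas, dt):
    F = np.array([[1, 0, dt, 0], [0, 1, 0, dt], [0, 0, 1, 0], [0, 0, 0, 1]], float)
    Q = _KF_Q * np.diag([dt, dt, dt, dt])
    H = np.array([[1, 0, 0, 0], [0, 1, 0, 0]], float)
    R = _KF_R * np.eye(2)
    xp = F @ x
    Pp = F @ P @ F.T + Q
    y = np.asarray(meas) - H @ xp
    S = H @ Pp @ H.T + R
    K = Pp @ H.T @ np.linalg.inv(S)
    xn = xp + K @ y
    Pn = (np.eye(4) - K @ H) @ Pp
    return xn, Pn


def link(
    spots: pd.DataFrame,
    mode: str = "nearest",
    search_radius: float = 5.0,
    max_gap: int = 0,
) -> pd.DataFrame:
    """Link a spots table into tracks.

    Parameters
    ----------
    spots : DataFrame with columns spot_id, frame, x, y (z optional).
        Coordinates and `search_radius` share one unit (px or μm).
    mode : 'nearest' (greedy minimum-distance), 'drift' (last-displacement
        extrapolation), or 'kalman' (constant-velocity prediction).
    search_radius : gating radius per frame step; a link across a gap of g
        missing frames is gated at radius × (g + 1).
    max_gap : frames a track may go undetected and still be extended.

    Returns
    -------
    DataFrame (track_id, frame, x, y[, z], spot_id), deterministic: ties in
    distance break toward the lowest spot id.
    """
    if mode not in MODES:
        raise ValueError(f"unknown linking mode {mode!r}; one of {MODES}")
    if search_radius <= 0:
        raise ValueError("search radius must be positive")
    has_z = "z" in spots.columns
    cols = ["spot_id", "frame", "x", "y"] + (["z"] if has_z else [])
    spots = spots[cols].sort_values(["frame", "spot_id"]).reset_index(drop=True)

    active: list[_TrackState] = []
    finished: list[_TrackState] = []
    next_id = 0

    for frame, group in spots.groupby("frame", sort=True):
        frame = int(frame)
        # retire tracks whose gap allowance is exhausted
        still = []
        for tr in active:
            if frame - tr.last_frame > max_gap + 1:
                finished.append(tr)
            else:
                still.append(tr)
        active = still

        pts = group[["x", "y"]].to_numpy(float)
        sids = group["spot_id"].to_numpy()
        zs = group["z"].to_numpy(float) if has_z else np.zeros(len(group))

        pairs = []
        for ti, tr in enumerate(active):
            dt = frame - tr.last_frame
            pred = tr.predict(mode, dt)
            gate = search_radius * dt
            d = np.hypot(pts[:, 0] - pred[0], pts[:, 1] - pred[1])
            for si in np.nonzero(d <= gate)[0]:
                pairs.append((d[si], tr.track_id, int(sids[si]), ti, int(si)))
        pairs.sort()

        used_tracks, used_spots = set(), set()
        for dist, _tid, _sid, ti, si in pairs:
            if ti in used_tracks or si in used_spots:
                continue
            used_tracks.add(ti)
            used_spots.add(si)
            tr = active[ti]
            meas = pts[si]
            dt = frame - tr.last_frame
            if mode == "kalman":
                tr.kf_x, tr.kf_P = _kf_update(tr.kf_x, tr.kf_P, meas, dt)
            tr.prev_pos = tr.pos
            tr.pos = meas.copy()
            tr.last_frame = frame
            tr.points.append((frame, meas[0], meas[1], zs[si], int(sids[si])))

        for si in range(len(pts)):
            if si in used_spots:
                continue
            st = _TrackState(
                track_id=next_id, last_frame=frame, pos=pts[si].copy(),
                points=[(frame, pts[si][0], pts[si][1], zs[si], int(sids[si]))],
            )
            if mode == "kalman":
                st.kf_x, st.kf_P = _kf_init(pts[si])
            active.append(st)
            next_id += 1

    finished.extend(active)
    rows = []
    for tr in sorted(finished, key=lambda t: t.track_id):
        for frame, x, y, z, sid in tr.points:
            rows.append((tr.track_id, frame, x, y, z, sid))
    out = pd.DataFrame(rows, columns=["track_id", "frame", "x", "y", "z", "spot_id"])
    if not has_z:
        out = out.drop(columns="z")
    return out


def track_stats(tracks: pd.DataFrame) -> pd.DataFrame:
    """Per-track length (points), span (frames) and gap-event count."""
    rows = []
    for tid, g in tracks.groupby("track_id"):
        frames = np.sort(g["frame"].to_numpy())
        gaps = int(np.sum(np.diff(frames) > 1))
        rows.append((tid, len(frames), int(frames[-1] - frames[0] + 1), gaps))
    return pd.DataFrame(rows, columns=["track_id", "length", "span", "n_gaps"])


def filter_tracks(
    tracks: pd.DataFrame, min_length: int = 3, max_gaps: int = 2
) -> pd.DataFrame:
    """Track-quality filter on length and gap count; idempotent."""
    stats = track_stats(tracks)
    keep = stats[(stats.length >= min_length) & (stats.n_gaps <= max_gaps)].track_id
    out = tracks[tracks.track_id.isin(set(keep))]
    return out.sort_values(["track_id", "frame"]).reset_index(drop=True)


@dataclass
class PairAssignment:
    """The two centrosome tracks of a cell, or the reason there aren't two."""

    c1: pd.DataFrame | None
    c2: pd.DataFrame | None
    ok: bool
    reason: str = ""


def assign_pair(
    tracks: pd.DataFrame,
    cell_mask: np.ndarray | None = None,
    pixel_size_um: float = 1.0,
    intensities: pd.DataFrame | None = None,
) -> PairAssignment:
    """Pick the two centrosome tracks of a cell.

    Candidates are the tracks whose points fall (majority) inside the cell
    mask; the two longest are kept.  Labels are stable: C1 is the track
    with the higher intensity at its first frame (ties and missing
    intensities break toward the lower track id).  Fewer than two
    qualifying tracks flags the cell unanalyzable.

    `tracks` coordinates are μm; `cell_mask` is indexed (row, col) px.
    `intensities`, if given, maps spot_id → intensity.
    """
    cand = []
    for tid, g in tracks.groupby("track_id"):
        if cell_mask is not None:
            cc = np.clip((g["x"] / pixel_size_um).round().astype(int), 0,
                         cell_mask.shape[1] - 1)
            rr = np.clip((g["y"] / pixel_size_um).round().astype(int), 0,
                         cell_mask.shape[0] - 1)
            frac_in = cell_mask[rr, cc].mean()
            if frac_in < 0.5:
                continue
        cand.append((len(g), tid))
    if len(cand) < 2:
        return PairAssignment(None, None, False,
                              f"only {len(cand)} qualifying track(s)")
    cand.sort(key=lambda t: (-t[0], t[1]))
    (la, ta), (lb, tb) = cand[0], cand[1]
    a = tracks[tracks.track_id == ta].sort_values("frame").reset_index(drop=True)
    b = tracks[tracks.track_id == tb].sort_values("frame").reset_index(drop=True)

    def first_intensity(g):
        if intensities is None or "spot_id" not in g.columns:
            return np.nan
        sid = g.iloc[0]["spot_id"]
        hit = intensities[intensities.spot_id == sid]
        return float(hit["intensity"].iloc[0]) if len(hit) else np.nan

    ia, ib = first_intensity(a), first_intensity(b)
    if np.isnan(ia) or np.isnan(ib) or ia == ib:
        c1, c2 = (a, b) if ta < tb else (b, a)
    else:
        c1, c2 = (a, b) if ia > ib else (b, a)
    return PairAssignment(c1, c2, True)
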