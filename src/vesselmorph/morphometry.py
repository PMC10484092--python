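"""The four vessel statistics, computed per eye inside the ROI ring.

* Bifurcation angle — the angle between the two daughter directions at each
  degree-3 node of the vessel graph (branching angle in the sense of Baker);
  the parent branch is the one pointing most directly back toward the optic
  disc.  Reported per eye as the unweighted mean over bifurcations.
* Vessel density — vessel foreground area as a percentage of a reference
  area (ROI ring by default; whole image via config).
* Fractal dimension — box-counting dimension of the centerline skeleton:
  minus the OLS slope of log N(eps) against log eps over dyadic box sizes.
* Tortuosity — Hart's arc-length-normalized total squared curvature
  (1/L) * sum(kappa^2 ds) per centerline segment, aggregated per eye as the
  length-weighted mean and reported in units of 1e-3 px^-2.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd

from .graph import VesselGraph, build_graph, prune_spurs, skeletonize
from .io_qc import FundusFrame, gate_frame
from .roi import RoiRing, build_roi, mask_to_roi, mec_of_mask

__all__ = [
    "MorphometryConfig", "MorphometryRecord",
    "bifurcation_angle", "vessel_angle_mean", "vessel_density",
    "fractal_dimension", "segment_tortuosity", "eye_tortuosity",
    "analyze_eye", "analyze_cohort",
]


@dataclass(frozen=True)
class MorphometryConfig:
    """Tunables for the per-eye analysis.  All lengths in pixels."""

    fit_len: float = 20.0            # centerline arc length used to fit branch directions
    smooth_window: int = 9           # moving-average window (applied twice) before curvature
    curv_span: int = 12              # half-chord span of the osculating-circle estimator
    min_seg_len: float = 30.0        # segments shorter than this skip tortuosity
    spur_min_len: float = 10.0       # skeleton spur pruning threshold
    density_denominator: Literal["roi_area", "image_area"] = "roi_area"
    fd_on_skeleton: bool = True      # False: box-count the full-width mask
    roi_inner_factor: float = 2.0
    roi_outer_factor: float = 4.0


@dataclass
class MorphometryRecord:
    """One eye's metrics; ``None`` marks a metric that could not be computed."""

    eye_id: str
    group_label: str
    vessel_angle_mean: float | None
    vessel_density: float | None          # percent
    fractal_dimension: float | None
    tortuosity: float | None              # units of 1e-3 px^-2
    n_bifurcations: int
    n_segments: int
    qc_passed: bool
    notes: str = ""


# ---------------------------------------------------------------------------
# bifurcation angles
# ---------------------------------------------------------------------------

def _principal_direction(points: np.ndarray) -> np.ndarray:
    """Total-least-squares line direction of a point run, oriented start->end."""
    pts = np.asarray(points, dtype=float)
    centered = pts - pts.mean(axis=0)
    cov = centered.T @ centered
    if not np.isfinite(cov).all() or np.allclose(cov, 0):
        raise ValueError("degenerate direction fit: coincident points")
    w, v = np.linalg.eigh(cov)
    d = v[:, np.argmax(w)]
    span = pts[-1] - pts[0]
    if float(d @ span) < 0:
        d = -d
    n = float(np.hypot(*d))
    if n == 0:
        raise ValueError("degenerate direction fit")
    return d / n


def _leading_points(path: np.ndarray, fit_len: float, skip: float = 4.0) -> np.ndarray:
    """Path points with arc length in [skip, skip + fit_len] from the start.

    The first few pixels leaving a node sit inside the junction zone, where
    thinning a full-width vessel union displaces the skeleton; skipping
    them removes that bias from the direction fit.
    """
    steps = np.hypot(*np.diff(path, axis=0).T)
    cum = np.concatenate([[0.0], np.cumsum(steps)])
    i0 = int(np.searchsorted(cum, skip))
    i1 = int(np.searchsorted(cum, skip + fit_len, side="right"))
    if i1 - i0 < 3:
        i0 = max(0, i1 - 3)
    return path[i0:max(i1 + 1, i0 + 3)]


def _incident_directions(graph: VesselGraph, node_id: int, fit_len: float) -> list[np.ndarray]:
    dirs = []
    for eid in graph.adjacency[node_id]:
        e = graph.edges[eid]
        if e.node_a == e.node_b:  # self-loop: one direction per end
            dirs.append(_principal_direction(_leading_points(e.points, fit_len)))
            dirs.append(_principal_direction(_leading_points(e.points[::-1], fit_len)))
        else:
            dirs.append(_principal_direction(_leading_points(e.oriented_from(node_id), fit_len)))
    return dirs


def bifurcation_angle(graph: VesselGraph, node_id: int,
                      od_center: tuple[float, float], fit_len: float = 20.0) -> float:
    """Daughter-daughter angle (degrees, 0-180) at one bifurcation.

    Each incident branch direction is the principal (total-least-squares)
    direction of the centerline run covering arc lengths 4 to 4 + fit_len
    px leaving the node, oriented away from it.  The parent is the branch
    whose direction best aligns with the unit vector from the node toward
    the optic-disc center; the returned angle separates the two remaining
    (daughter) directions.
    """
    if graph.kind(node_id) != "bifurcation":
        raise ValueError(f"node {node_id} is not a bifurcation (degree 3)")
    dirs = _incident_directions(graph, node_id, fit_len)
    pos = np.array(graph.nodes[node_id].position)
    to_od = np.array(od_center, dtype=float) - pos
    norm = np.hypot(*to_od)
    if norm == 0:
        raise ValueError("bifurcation coincides with the OD center")
    to_od /= norm
    parent = int(np.argmax([float(d @ to_od) for d in dirs]))
    d1, d2 = [d for i, d in enumerate(dirs) if i != parent]
    cosang = float(np.clip(d1 @ d2, -1.0, 1.0))
    return float(np.degrees(np.arccos(cosang)))


def vessel_angle_mean(graph: VesselGraph, od_center: tuple[float, float],
                      fit_len: float = 20.0) -> float | None:
    """Unweighted mean bifurcation angle over all degree-3 nodes; None if none."""
    angles = []
    for nid in graph.bifurcations():
        try:
            angles.append(bifurcation_angle(graph, nid, od_center, fit_len))
        except ValueError:
            continue  # degenerate fit at this node; skip, count stays in QC
    return float(np.mean(angles)) if angles else None


# ---------------------------------------------------------------------------
# density
# ---------------------------------------------------------------------------

def vessel_density(vessel_mask_in_roi: np.ndarray, roi: RoiRing,
                   denominator: Literal["roi_area", "image_area"] = "roi_area") -> float:
    """Vessel area as a percentage of the reference area.

    ``roi_area`` divides by the ring's pixel count (comparable across disc
    sizes); ``image_area`` divides by the full raster area.
    """
    m = np.asarray(vessel_mask_in_roi, dtype=bool)
    if denominator == "roi_area":
        denom = roi.pixel_count
    elif denominator == "image_area":
        denom = m.shape[0] * m.shape[1]
    else:
        raise ValueError(f"unknown denominator {denominator!r}")
    if denom == 0:
        raise ValueError("zero-area density denominator")
    return 100.0 * float(np.count_nonzero(m)) / float(denom)


# ---------------------------------------------------------------------------
# fractal dimension
# ---------------------------------------------------------------------------

def default_box_sizes(short_side: int) -> list[int]:
    """Powers of two from 2 up to a quarter of the bounding-box short side."""
    sizes = []
    s = 2
    while s <= max(short_side // 4, 2):
        sizes.append(s)
        s *= 2
    return sizes


def fractal_dimension(mask: np.ndarray, box_sizes: list[int] | None = None,
                      anchor: tuple[int, int] | None = None) -> float:
    """Box-counting dimension of a binary pattern.

    For each box size eps, N(eps) counts occupied eps x eps grid cells, with
    the grid anchored at ``anchor`` (default: the foreground bounding-box
    origin).  Returns minus the OLS slope of log N(eps) vs log eps.

    Raises ``ValueError`` on an empty mask or fewer than two distinct sizes.
    """
    ys, xs = np.nonzero(np.asarray(mask, dtype=bool))
    if xs.size == 0:
        raise ValueError("empty mask: fractal dimension undefined")
    if anchor is None:
        anchor = (int(xs.min()), int(ys.min()))
    if box_sizes is None:
        h = int(ys.max()) - anchor[1] + 1
        w = int(xs.max()) - anchor[0] + 1
        box_sizes = default_box_sizes(min(w, h))
    sizes = sorted(set(int(s) for s in box_sizes))
    if len(sizes) < 2:
        raise ValueError("need at least 2 distinct box sizes")
    x0, y0 = anchor
    counts = []
    for eps in sizes:
        bx = (xs - x0) // eps
        by = (ys - y0) // eps
        counts.append(len(np.unique(bx * np.int64(2 ** 32) + by)))
    log_eps = np.log(np.asarray(sizes, dtype=float))
    log_n = np.log(np.asarray(counts, dtype=float))
    slope = np.polyfit(log_eps, log_n, 1)[0]
    return float(-slope)


# ---------------------------------------------------------------------------
# tortuosity
# ---------------------------------------------------------------------------

def _resample_1px(points: np.ndarray) -> np.ndarray:
    pts = np.asarray(points, dtype=float)
    steps = np.hypot(*np.diff(pts, axis=0).T)
    cum = np.concatenate([[0.0], np.cumsum(steps)])
    total = cum[-1]
    if total <= 0:
        return pts[:1]
    s = np.arange(0.0, np.floor(total) + 0.5, 1.0)
    return np.column_stack([np.interp(s, cum, pts[:, 0]), np.interp(s, cum, pts[:, 1])])


def segment_tortuosity(path, smooth_window: int = 9, curv_span: int = 12) -> float:
    """Hart tortuosity of one centerline: (1/L) * integral kappa^2 ds, px^-2.

    The polyline is resampled at 1-px arc-length steps and smoothed with a
    moving average of ``smooth_window`` samples applied twice (a triangular
    kernel, suppressing pixel-lattice stair-step noise).  Curvature at each
    remaining sample is the inverse circumradius of the osculating circle
    through the points ``k`` samples to either side, with k shrinking from
    ``curv_span`` to 4 near the path ends; this three-point estimator is
    exact on circular arcs at any span, so heavy smoothing and a wide span
    cost little bias on smooth vessels while averaging out rasterization.
    The returned value is the mean squared curvature over unit arc steps.

    Raises ``ValueError`` for paths too short to support the estimator.
    """
    pts = np.asarray(getattr(path, "points", path), dtype=float)
    res = _resample_1px(pts)
    w = max(1, int(smooth_window))
    kernel = np.ones(w) / w
    sm = res
    for _ in range(2):
        if len(sm) < w + 2:
            raise ValueError("path too short for tortuosity estimation")
        sm = np.column_stack([np.convolve(sm[:, 0], kernel, mode="valid"),
                              np.convolve(sm[:, 1], kernel, mode="valid")])
    n = len(sm)
    k_min = 4
    if n < 2 * k_min + 3:
        raise ValueError("path too short for tortuosity estimation")
    idx = np.arange(n)
    spans = np.minimum(curv_span, np.minimum(idx, n - 1 - idx))
    valid = spans >= k_min
    iv, kv = idx[valid], spans[valid]
    a, b, c = sm[iv - kv], sm[iv], sm[iv + kv]
    ab, bc, ac = b - a, c - b, c - a
    cross = np.abs(ab[:, 0] * bc[:, 1] - ab[:, 1] * bc[:, 0])
    sides = np.hypot(*ab.T) * np.hypot(*bc.T) * np.hypot(*ac.T)
    kappa = 2.0 * cross / np.maximum(sides, 1e-12)
    return float(np.mean(kappa ** 2))


def eye_tortuosity(graph: VesselGraph, min_seg_len: float = 30.0,
                   smooth_window: int = 9, curv_span: int = 12) -> float | None:
    """Length-weighted mean segment tortuosity, in units of 1e-3 px^-2.

    Segments shorter than ``min_seg_len`` px are excluded.  Returns None
    when no segment is eligible (recorded as a missing metric, not zero).
    """
    taus, weights = [], []
    for e in graph.edges.values():
        length = e.arc_length
        if length < min_seg_len:
            continue
        try:
            taus.append(segment_tortuosity(e.points, smooth_window, curv_span))
            weights.append(length)
        except ValueError:
            continue
    if not taus:
        return None
    return 1e3 * float(np.average(taus, weights=weights))


# ---------------------------------------------------------------------------
# per-eye and per-cohort drivers
# ---------------------------------------------------------------------------

def _roi_bbox(roi: RoiRing, width: int, height: int) -> tuple[int, int, int, int]:
    x0 = max(0, int(np.floor(roi.center[0] - roi.r_outer)))
    y0 = max(0, int(np.floor(roi.center[1] - roi.r_outer)))
    x1 = min(width - 1, int(np.ceil(roi.center[0] + roi.r_outer)))
    y1 = min(height - 1, int(np.ceil(roi.center[1] + roi.r_outer)))
    return x0, y0, x1, y1


def analyze_eye(frame: FundusFrame, roi: RoiRing,
                config: MorphometryConfig = MorphometryConfig()) -> MorphometryRecord:
    """Run the full per-eye measurement inside the ROI ring.

    Pipeline: clip vessel mask to the ring, skeletonize, build and prune the
    centerline graph, then measure all four statistics.  Metric-level
    degeneracies (no bifurcations, no eligible segments, empty skeleton)
    yield missing values and a QC note; they never raise.
    """
    notes = []
    vessel_roi = mask_to_roi(frame.vessel_mask, roi)
    density = vessel_density(vessel_roi, roi, config.density_denominator)

    skel = skeletonize(vessel_roi)
    graph = prune_spurs(build_graph(skel), config.spur_min_len)

    angle = None
    tort = None
    fd = None
    n_bif = len(graph.bifurcations())
    n_seg = len(graph.edges)

    if not skel.any():
        notes.append("empty vessel mask in ROI")
    else:
        x0, y0, x1, y1 = _roi_bbox(roi, frame.width, frame.height)
        sizes = default_box_sizes(min(x1 - x0 + 1, y1 - y0 + 1))
        fd_target = skel if config.fd_on_skeleton else vessel_roi
        try:
            fd = fractal_dimension(fd_target, sizes, anchor=(x0, y0))
        except ValueError as exc:
            notes.append(f"fractal dimension missing: {exc}")
        angle = vessel_angle_mean(graph, roi.center, config.fit_len)
        if angle is None:
            notes.append("no measurable bifurcations in ROI")
        tort = eye_tortuosity(graph, config.min_seg_len, config.smooth_window,
                              config.curv_span)
        if tort is None:
            notes.append("no tortuosity-eligible segments in ROI")

    return MorphometryRecord(frame.eye_id, frame.group_label, angle, density, fd,
                             tort, n_bif, n_seg, qc_passed=True,
                             notes="; ".join(notes))


def analyze_cohort(manifest: pd.DataFrame,
                   config: MorphometryConfig = MorphometryConfig(),
                   loader=None) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Gate and analyze every eye in a manifest.

    Returns ``(metrics, qc)`` DataFrames: one MorphometryRecord row per eye
    (metrics missing for frames that failed gating) and one QC row per eye.
    ``loader`` may override frame loading for testing.
    """
    from .io_qc import load_frame, qc_table

    load = loader or (lambda row: load_frame(row["vessel_path"], row["od_path"],
                                             row["eye_id"], row["group"]))
    qc_rows, records = [], []
    for _, row in manifest.iterrows():
        frame = load(row)
        qc = gate_frame(frame)
        qc_rows.append(qc)
        if not qc.passed:
            records.append(MorphometryRecord(frame.eye_id, frame.group_label,
                                             None, None, None, None, 0, 0,
                                             qc_passed=False, notes=qc.reason))
            continue
        od_circle = mec_of_mask(frame.od_mask)
        try:
            roi = build_roi(od_circle, frame.width, frame.height,
                            config.roi_inner_factor, config.roi_outer_factor)
        except ValueError as exc:
            records.append(MorphometryRecord(frame.eye_id, frame.group_label,
                                             None, None, None, None, 0, 0,
                                             qc_passed=False, notes=str(exc)))
            continue
        records.append(analyze_eye(frame, roi, config))
    metrics = pd.DataFrame([vars(r) for r in records])
    return metrics, qc_table(qc_rows)
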