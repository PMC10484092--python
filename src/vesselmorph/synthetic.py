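"""Synthetic posterior-pole vascular trees with per-tree ground truth.

Emulates the geometry the morphometry pipeline assumes: an optic disc (OD)
near the image center and binary vessel trees radiating outward from the
disc rim, built by stochastic recursive bifurcation.  Each non-terminal
segment ends in exactly one bifurcation whose daughter starting tangents
are the parent direction rotated by +/- (theta/2), with theta drawn from a
normal distribution truncated to (10, 170) degrees.  Centerlines are the
straight chord plus a sinusoidal normal displacement (an integer number of
half-waves, so segments join continuously), giving analytically known
tortuosity.  Masks are centerlines dilated to a width that tapers
geometrically with branch level (factor 0.8 per level, floor 1 px).

The generator returns, alongside the rasterized masks, the exact truth used
by the recovery tests: every bifurcation angle, every centerline polyline,
the analytic tortuosity of every segment, and the vessel pixel count.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io_qc import write_mask
from .roi import Circle

__all__ = [
    "SynthParams",
    "SegmentTruth",
    "BifurcationTruth",
    "SynthGroundTruth",
    "GenerationError",
    "generate_tree",
    "generate_cohort",
    "analytic_tortuosity_of_sinusoid",
]


class GenerationError(ValueError):
    """Raised when a parameter set cannot produce a tree inside the image."""


@dataclass(frozen=True)
class SynthParams:
    """Controls for one synthetic eye.

    Lengths and widths are in pixels; angles in degrees.  The defaults
    describe a 1,600 x 1,200 px posterior-pole frame with the disc at the
    image center, branching angles in the range reported for infant retinal
    vasculature, and a mild sinusoidal waviness.
    """

    image_width: int = 1600
    image_height: int = 1200
    od_center: tuple[float, float] = (800.0, 600.0)
    od_radius: float = 50.0
    n_roots: int = 6
    branch_depth: int = 3
    bifurcation_angle_mean: float = 60.0
    bifurcation_angle_sd: float = 5.0
    segment_length_mean: float = 120.0
    tortuosity_amplitude: float = 2.5
    tortuosity_wavelength: float = 80.0
    root_width: float = 3.0
    seed: int = 0

    def __post_init__(self):
        if min(self.image_width, self.image_height) <= 0:
            raise ValueError("image dimensions must be positive")
        for name in ("od_radius", "segment_length_mean", "tortuosity_wavelength", "root_width"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.tortuosity_amplitude < 0:
            raise ValueError("tortuosity_amplitude must be >= 0")
        if not 0 < self.bifurcation_angle_mean < 180:
            raise ValueError("bifurcation_angle_mean must lie in (0, 180) degrees")
        if self.bifurcation_angle_sd < 0:
            raise ValueError("bifurcation_angle_sd must be >= 0")
        if self.branch_depth < 0 or self.n_roots < 1:
            raise ValueError("branch_depth must be >= 0 and n_roots >= 1")
        if self.od_radius >= min(self.image_width, self.image_height) / 4:
            raise ValueError("od_radius must be < min(image dimensions) / 4")


@dataclass(frozen=True)
class SegmentTruth:
    segment_id: int
    level: int
    polyline: np.ndarray          # (n, 2) float (x, y), sampled at <= 0.5 px steps
    chord_length: float
    amplitude: float
    wavelength_eff: float         # effective wavelength after rounding to half-waves
    analytic_tortuosity: float    # (1/L) integral kappa^2 ds, px^-2
    width: float


@dataclass(frozen=True)
class BifurcationTruth:
    position: tuple[float, float]
    angle_deg: float              # true daughter-daughter angle
    level: int                    # level of the parent segment


@dataclass
class SynthGroundTruth:
    segments: list[SegmentTruth]
    bifurcations: list[BifurcationTruth]
    true_vessel_pixel_count: int
    od_circle: Circle

    @property
    def angles(self) -> np.ndarray:
        return np.array([b.angle_deg for b in self.bifurcations])

    @property
    def tortuosities(self) -> np.ndarray:
        return np.array([s.analytic_tortuosity for s in self.segments])


def analytic_tortuosity_of_sinusoid(amplitude: float, wavelength: float,
                                    chord_length: float, n_samples: int = 20_000) -> float:
    """Arc-length-normalized total squared curvature of a sinusoidal arc.

    The curve is (t, a*sin(2*pi*t / lambda)) for t in [0, L] with a =
    amplitude, lambda = wavelength, L = chord_length.  Returns
    (1/S) * integral of kappa^2 ds where S is the arc length, evaluated by
    dense trapezoidal quadrature with analytic derivatives.  This is the
    generator's independent truth oracle, not the pipeline's estimator.
    """
    if wavelength <= 0 or chord_length <= 0:
        raise ValueError("wavelength and chord_length must be > 0")
    if amplitude < 0:
        raise ValueError("amplitude must be >= 0")
    if amplitude == 0:
        return 0.0
    t = np.linspace(0.0, chord_length, n_samples)
    w = 2.0 * np.pi / wavelength
    yp = amplitude * w * np.cos(w * t)
    ypp = -amplitude * w * w * np.sin(w * t)
    ds = np.sqrt(1.0 + yp * yp)
    kappa = np.abs(ypp) / ds ** 3
    total = np.trapezoid(kappa * kappa * ds, t)
    arclen = np.trapezoid(ds, t)
    return float(total / arclen)


def _rot(v: np.ndarray, deg: float) -> np.ndarray:
    a = np.deg2rad(deg)
    c, s = np.cos(a), np.sin(a)
    return np.array([c * v[0] - s * v[1], s * v[0] + c * v[1]])


def _sample_angle(rng: np.random.Generator, mean: float, sd: float) -> float:
    """Normal(mean, sd) truncated to (10, 170) degrees by rejection."""
    if sd == 0:
        return float(np.clip(mean, 10.0, 170.0))
    for _ in range(1000):
        a = rng.normal(mean, sd)
        if 10.0 < a < 170.0:
            return float(a)
    return float(np.clip(mean, 10.0, 170.0))


def _segment_polyline(start: np.ndarray, direction: np.ndarray, length: float,
                      amplitude: float, wavelength: float,
                      sign: float) -> tuple[np.ndarray, float]:
    """Chord plus sinusoidal normal displacement, zero at both endpoints.

    The displacement uses an integer number of half-waves so consecutive
    segments join without jumps; returns (polyline, effective wavelength).
    """
    n_half = max(1, int(round(2.0 * length / wavelength)))
    lam_eff = 2.0 * length / n_half
    n = max(3, int(np.ceil(length / 0.5)) + 1)
    t = np.linspace(0.0, length, n)
    normal = np.array([-direction[1], direction[0]])
    disp = sign * amplitude * np.sin(np.pi * n_half * t / length)
    pts = start[None, :] + t[:, None] * direction[None, :] + disp[:, None] * normal[None, :]
    return pts, lam_eff


def _max_extent(p: SynthParams) -> float:
    return (p.od_radius + (p.branch_depth + 1) * p.segment_length_mean * 1.1
            + p.tortuosity_amplitude + p.root_width / 2.0 + 1.0)


def generate_tree(params: SynthParams) -> tuple[np.ndarray, np.ndarray, SynthGroundTruth]:
    """Generate one synthetic eye: vessel mask, OD mask, and ground truth.

    Deterministic for a fixed ``params.seed``.  Raises ``GenerationError``
    if the worst-case radial extent of the tree cannot fit between the OD
    center and the nearest image border.
    """
    cx, cy = params.od_center
    margin = min(cx, cy, params.image_width - 1 - cx, params.image_height - 1 - cy)
    extent = _max_extent(params)
    if extent > margin:
        raise GenerationError(
            f"tree extent {extent:.0f} px exceeds distance {margin:.0f} px from "
            f"od_center to the nearest image border; reduce branch_depth or "
            f"segment_length_mean, or move od_center inward")

    rng = np.random.default_rng(params.seed)
    segments: list[SegmentTruth] = []
    bifurcations: list[BifurcationTruth] = []

    # (start, unit chord direction, level) work queue, depth-first
    phase = rng.uniform(0.0, 2.0 * np.pi)
    stack = []
    for k in range(params.n_roots - 1, -1, -1):
        ang = phase + 2.0 * np.pi * k / params.n_roots
        d = np.array([np.cos(ang), np.sin(ang)])
        stack.append((np.array([cx, cy]) + params.od_radius * d, d, 0))

    seg_id = 0
    while stack:
        start, direction, level = stack.pop()
        length = params.segment_length_mean * rng.uniform(0.9, 1.1)
        sign = 1.0 if rng.random() < 0.5 else -1.0
        # `direction` is the segment's initial tangent.  The sinusoidal
        # displacement d(t) = sign * a * sin(pi * n_half * t / L) has slope
        # sign * a * pi * n_half / L at t = 0, so the chord is rotated the
        # other way to make the actual starting tangent equal `direction`
        # (bifurcation angles are then local tangent angles, the quantity
        # the angle estimator measures).
        n_half = max(1, int(round(2.0 * length / params.tortuosity_wavelength)))
        slope0 = sign * params.tortuosity_amplitude * np.pi * n_half / length
        chord_dir = _rot(direction, -np.degrees(np.arctan(slope0)))
        poly, lam_eff = _segment_polyline(start, chord_dir, length,
                                          params.tortuosity_amplitude,
                                          params.tortuosity_wavelength, sign)
        width = max(1.0, params.root_width * 0.8 ** level)
        tau = (analytic_tortuosity_of_sinusoid(params.tortuosity_amplitude, lam_eff, length)
               if params.tortuosity_amplitude > 0 else 0.0)
        segments.append(SegmentTruth(seg_id, level, poly, length,
                                     params.tortuosity_amplitude, lam_eff, tau, width))
        seg_id += 1
        if level < params.branch_depth:
            theta = _sample_angle(rng, params.bifurcation_angle_mean,
                                  params.bifurcation_angle_sd)
            end = poly[-1]
            bifurcations.append(BifurcationTruth((float(end[0]), float(end[1])),
                                                 theta, level))
            for half in (+theta / 2.0, -theta / 2.0):
                stack.append((end.copy(), _rot(direction, half), level + 1))

    vessel = _rasterize(segments, params.image_width, params.image_height)
    od_mask = _disc_mask(params.od_center, params.od_radius,
                         params.image_width, params.image_height)
    truth = SynthGroundTruth(segments, bifurcations, int(vessel.sum()),
                             Circle((float(cx), float(cy)), float(params.od_radius)))
    return vessel, od_mask, truth


def _disc_mask(center: tuple[float, float], radius: float,
               width: int, height: int) -> np.ndarray:
    ys, xs = np.ogrid[0:height, 0:width]
    return (xs - center[0]) ** 2 + (ys - center[1]) ** 2 <= radius ** 2


def _rasterize(segments: list[SegmentTruth], width: int, height: int) -> np.ndarray:
    from scipy import ndimage

    mask = np.zeros((height, width), dtype=bool)
    # group centerlines by dilation radius so each radius dilates once
    by_radius: dict[int, np.ndarray] = {}
    for seg in segments:
        r = int(round((seg.width - 1) / 2.0))
        canvas = by_radius.setdefault(r, np.zeros((height, width), dtype=bool))
        ix = np.round(seg.polyline[:, 0]).astype(int)
        iy = np.round(seg.polyline[:, 1]).astype(int)
        ok = (ix >= 0) & (ix < width) & (iy >= 0) & (iy < height)
        canvas[iy[ok], ix[ok]] = True
    for r, canvas in by_radius.items():
        if r > 0:
            yy, xx = np.mgrid[-r:r + 1, -r:r + 1]
            selem = xx ** 2 + yy ** 2 <= r ** 2
            canvas = ndimage.binary_dilation(canvas, structure=selem)
        mask |= canvas
    return mask


def _eye_seed(cohort_seed: int, group_index: int, eye_index: int) -> int:
    ss = np.random.SeedSequence([cohort_seed, group_index, eye_index])
    return int(ss.generate_state(1)[0] % (2 ** 31))


def generate_cohort(group_specs: list[tuple[str, SynthParams, int]], seed: int,
                    out_dir: str | Path) -> pd.DataFrame:
    """Generate a multi-group cohort on disk and return its manifest.

    Writes, under ``out_dir``: one vessel-mask and one OD-mask PNG per eye,
    ``manifest.csv`` (eye_id, group, vessel_path, od_path), ground-truth
    tables ``truth_segments.csv`` and ``truth_bifurcations.csv``, and one
    JSON truth sidecar per eye.  Per-eye seeds derive deterministically
    from the cohort seed.
    """
    labels = [lab for lab, _, _ in group_specs]
    if len(set(labels)) != len(labels):
        raise ValueError("group labels must be unique")
    for lab, _, n in group_specs:
        if n < 1:
            raise ValueError(f"group {lab!r} must have n_eyes >= 1")

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest_rows, seg_rows, bif_rows = [], [], []
    for gi, (label, base_params, n_eyes) in enumerate(group_specs):
        for ei in range(n_eyes):
            eye_id = f"{label}_{ei:03d}"
            p = dataclasses.replace(base_params, seed=_eye_seed(seed, gi, ei))
            vessel, od, truth = generate_tree(p)
            vpath = out / f"{eye_id}_vessel.png"
            opath = out / f"{eye_id}_od.png"
            write_mask(vpath, vessel)
            write_mask(opath, od)
            manifest_rows.append({"eye_id": eye_id, "group": label,
                                  "vessel_path": vpath.name, "od_path": opath.name})
            for s in truth.segments:
                seg_rows.append({"eye_id": eye_id, "segment_id": s.segment_id,
                                 "level": s.level, "chord_length": s.chord_length,
                                 "amplitude": s.amplitude,
                                 "wavelength_eff": s.wavelength_eff,
                                 "analytic_tortuosity": s.analytic_tortuosity,
                                 "width": s.width})
            for b in truth.bifurcations:
                bif_rows.append({"eye_id": eye_id, "x": b.position[0],
                                 "y": b.position[1], "angle_deg": b.angle_deg,
                                 "level": b.level})
            sidecar = {"eye_id": eye_id, "group": label, "seed": p.seed,
                       "od_cx": truth.od_circle.center[0],
                       "od_cy": truth.od_circle.center[1],
                       "od_r": truth.od_circle.radius,
                       "true_vessel_pixel_count": truth.true_vessel_pixel_count,
                       "n_segments": len(truth.segments),
                       "n_bifurcations": len(truth.bifurcations)}
            (out / f"{eye_id}_truth.json").write_text(json.dumps(sidecar, indent=1))
    manifest = pd.DataFrame(manifest_rows)
    manifest.to_csv(out / "manifest.csv", index=False)
    pd.DataFrame(seg_rows).to_csv(out / "truth_segments.csv", index=False)
    pd.DataFrame(bif_rows).to_csv(out / "truth_bifurcations.csv", index=False)
    return manifest
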