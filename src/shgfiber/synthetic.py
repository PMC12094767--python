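"""Synthetic two-channel SHG collagen scenes with ground truth.

Collagen fibers are modelled as correlated random walks rendered with a
Gaussian cross-section into a continuous forward-detector field; the backward
field shares the geometry with per-fiber amplitude scaled down by the
forward/backward (FB) ratio.  Detection is emulated as per-frame Poisson shot
noise quantised to 8 bit, matching photon-counting acquisition of ``n_frames``
repeat frames per site that are later averaged.

Every generated scene carries a :class:`GroundTruth` record (total centerline
length, endpoint/branchpoint counts, mean width, orientation order parameter,
mean FB ratio) so downstream measurements can be validated by parameter
recovery rather than against any external data set.

Coordinates are 0-based ``(row, col)`` with pixel centers at integers; fiber
centerlines are sub-pixel polylines in ``(x, y) = (col, row)`` order.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile
from scipy.spatial import cKDTree

__all__ = [
    "FiberSpec",
    "SceneParams",
    "GroundTruth",
    "ChannelStack",
    "StudyDesign",
    "GroupDesign",
    "sample_fiber_network",
    "rasterize_scene",
    "simulate_stack",
    "generate_scene",
    "generate_cohort",
    "write_cohort",
]

# 512 px scan of an approximately 45.96 um square field of view
DEFAULT_PIXEL_SIZE_UM = 45.96 / 512.0

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass
class FiberSpec:
    """One rendered fiber bundle.

    ``fb_ratio`` is the dimensionless forward/backward intensity ratio; it
    reports on how tightly the collagen fibrils are packed within the bundle.
    """

    centerline: np.ndarray  # (n, 2) float, (x, y) in pixel units
    width: float  # full width at half maximum, px
    peak_intensity: float  # forward-channel peak, detector units in [0, 255]
    fb_ratio: float

    def __post_init__(self) -> None:
        self.centerline = np.asarray(self.centerline, dtype=float)
        if self.centerline.ndim != 2 or self.centerline.shape[1] != 2:
            raise ValueError("centerline must be an (n, 2) array")
        if len(self.centerline) < 2:
            raise ValueError("centerline needs at least 2 points")
        steps = np.linalg.norm(np.diff(self.centerline, axis=0), axis=1)
        if np.any(steps > 1.0 + 1e-9):
            raise ValueError("consecutive centerline points must be <= 1 px apart")
        if self.width <= 0:
            raise ValueError("width must be positive")
        if self.fb_ratio <= 0:
            raise ValueError("fb_ratio must be positive")

    @property
    def length(self) -> float:
        """Polyline arc length in pixels."""
        return float(np.linalg.norm(np.diff(self.centerline, axis=0), axis=1).sum())


@dataclass
class SceneParams:
    """Parameters of one synthetic imaging site.

    Defaults emulate the acquisition this pipeline targets: 512x512 8-bit
    frames, 20 frames per site, and a per-fiber FB-ratio mixture with modes
    near 50 and 225 on the 0-255 ratio axis.
    """

    image_shape: tuple[int, int] = (512, 512)
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
    n_fibers: int = 30
    length_mean: float = 150.0
    length_sd: float = 40.0
    length_min: float = 20.0  # shorter bundles are not resolvable as lines
    width_mean: float = 10.0
    width_sd: float = 2.0
    orientation_kappa: float = 1.0  # von Mises concentration, 0 = isotropic
    step_angle_sd: float = 3.0  # degrees per 1-px step
    branch_prob: float = 0.3
    fb_ratio_modes: tuple[tuple[float, float], ...] = ((50.0, 0.8), (225.0, 0.2))
    fb_mode_sd: float = 8.0
    peak_intensity_mean: float = 160.0
    peak_intensity_sd: float = 30.0
    background_level: float = 2.0
    detector_gain: float = 0.2  # DN per detected photon
    n_frames: int = 20
    min_separation_px: float = 0.0  # >0 rejects overlapping fibers
    seed: int | None = None

    def __post_init__(self) -> None:
        rows, cols = self.image_shape
        if rows <= 0 or cols <= 0:
            raise ValueError("image dimensions must be positive")
        if self.length_min < 2:
            raise ValueError("length_min must be >= 2 px")
        for name in ("length_sd", "width_sd", "step_angle_sd", "fb_mode_sd", "peak_intensity_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.n_fibers < 0 or self.n_frames < 1:
            raise ValueError("n_fibers must be >= 0 and n_frames >= 1")
        if self.orientation_kappa < 0:
            raise ValueError("orientation_kappa must be non-negative")
        if not 0.0 <= self.branch_prob <= 1.0:
            raise ValueError("branch_prob must lie in [0, 1]")
        if self.background_level < 0:
            raise ValueError("background_level must be non-negative")
        if self.detector_gain <= 0:
            raise ValueError("detector_gain must be positive")
        weights = [w for _, w in self.fb_ratio_modes]
        if not weights or abs(sum(weights) - 1.0) > 1e-9:
            raise ValueError("fb_ratio_modes weights must sum to 1")
        if any(c <= 0 for c, _ in self.fb_ratio_modes):
            raise ValueError("fb_ratio_modes centers must be positive")


@dataclass
class GroundTruth:
    """Scene-level truth computed from the generated polylines."""

    fibers: list[FiberSpec]
    true_total_length: float
    true_endpoints: int
    true_branchpoints: int
    true_mean_width: float
    true_alignment: float
    true_mean_fb: float

    def as_row(self) -> dict[str, float]:
        return {
            "true_total_length": self.true_total_length,
            "true_endpoints": self.true_endpoints,
            "true_branchpoints": self.true_branchpoints,
            "true_mean_width": self.true_mean_width,
            "true_alignment": self.true_alignment,
            "true_mean_fb": self.true_mean_fb,
        }


@dataclass
class ChannelStack:
    """Paired forward/backward frame stacks for one imaged site."""

    forward: np.ndarray  # (n_frames, rows, cols) uint8
    backward: np.ndarray
    pixel_size_um: float
    site_id: str = ""
    sample_id: str = ""
    group_label: str = ""

    def __post_init__(self) -> None:
        if self.forward.shape != self.backward.shape:
            raise ValueError("forward and backward stacks must have identical shape")
        if self.forward.ndim != 3:
            raise ValueError("stacks must be (n_frames, rows, cols)")


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float, low: float) -> float:
    if sd == 0:
        return max(mean, low)
    for _ in range(200):
        x = rng.normal(mean, sd)
        if x >= low:
            return float(x)
    return low


def _walk(
    rng: np.random.Generator,
    start: np.ndarray,
    theta: float,
    n_steps: int,
    step_sd_rad: float,
    shape: tuple[int, int],
) -> np.ndarray:
    """Correlated random walk with unit steps, stopped at the image border."""
    rows, cols = shape
    pts = [start.copy()]
    p = start.copy()
    for _ in range(n_steps):
        theta = theta + rng.normal(0.0, step_sd_rad) if step_sd_rad > 0 else theta
        p = p + np.array([np.cos(theta), np.sin(theta)])
        if not (0.0 <= p[0] <= cols - 1 and 0.0 <= p[1] <= rows - 1):
            break
        pts.append(p.copy())
    return np.asarray(pts)


def sample_fiber_network(params: SceneParams, rng: np.random.Generator | None = None) -> tuple[list[FiberSpec], GroundTruth]:
    """Sample a fiber network as correlated random walks.

    Initial orientations are von Mises distributed (axial, mean 0); each unit
    step turns by a Normal(0, ``step_angle_sd``) angle.  With probability
    ``branch_prob`` a fiber spawns one branch at a random interior vertex,
    departing at a Normal(45 deg, 10 deg) relative angle and inheriting the
    parent's width, intensity and FB ratio.  Deterministic for a fixed seed.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    rows, cols = params.image_shape
    step_sd_rad = np.deg2rad(params.step_angle_sd)

    fibers: list[FiberSpec] = []
    root_orientations: list[float] = []
    n_branches = 0
    occupied_pts: list[np.ndarray] = []  # for optional overlap rejection
    tree: cKDTree | None = None

    for _ in range(params.n_fibers):
        for _attempt in range(50):
            theta0 = float(rng.vonmises(0.0, params.orientation_kappa))
            length = _truncated_normal(rng, params.length_mean, params.length_sd, params.length_min)
            width = _truncated_normal(rng, params.width_mean, params.width_sd, 1.0)
            peak = float(np.clip(rng.normal(params.peak_intensity_mean, params.peak_intensity_sd), 10.0, 255.0))
            fb = _sample_fb_ratio(rng, params)
            start = np.array(
                [rng.uniform(1.0, cols - 2.0), rng.uniform(1.0, rows - 2.0)]
            )
            pts = _walk(rng, start, theta0, int(round(length)), step_sd_rad, params.image_shape)
            if len(pts) - 1 < params.length_min:
                continue  # border-truncated below the configured minimum
            if params.min_separation_px > 0 and tree is not None:
                d, _ = tree.query(pts, k=1)
                if np.min(d) < params.min_separation_px + width:
                    continue
            break
        else:
            continue  # could not place this fiber; scene stays valid

        fibers.append(FiberSpec(pts, width, peak, fb))
        root_orientations.append(theta0)

        if params.branch_prob > 0 and len(pts) >= 4 and rng.uniform() < params.branch_prob:
            i = int(rng.integers(1, len(pts) - 2))
            local = pts[i + 1] - pts[i - 1]
            local_theta = float(np.arctan2(local[1], local[0]))
            rel = np.deg2rad(rng.normal(45.0, 10.0)) * rng.choice([-1.0, 1.0])
            blen = _truncated_normal(rng, params.length_mean, params.length_sd, params.length_min)
            bpts = _walk(rng, pts[i].copy(), local_theta + rel, int(round(blen)), step_sd_rad, params.image_shape)
            if len(bpts) - 1 >= params.length_min:
                fibers.append(FiberSpec(bpts, width, peak, fb))
                n_branches += 1

        if params.min_separation_px > 0:
            occupied_pts.append(fibers[-1].centerline)
            tree = cKDTree(np.vstack(occupied_pts))

    truth = _ground_truth(fibers, root_orientations, n_branches)
    return fibers, truth


def _sample_fb_ratio(rng: np.random.Generator, params: SceneParams) -> float:
    centers = np.array([c for c, _ in params.fb_ratio_modes])
    weights = np.array([w for _, w in params.fb_ratio_modes])
    k = int(rng.choice(len(centers), p=weights))
    return _truncated_normal(rng, float(centers[k]), params.fb_mode_sd, 0.05)


def _ground_truth(fibers: list[FiberSpec], root_orientations: list[float], n_branches: int) -> GroundTruth:
    total_length = float(sum(f.length for f in fibers))
    n_roots = len(root_orientations)
    # each root polyline contributes two termini; each branch adds one terminus
    # and one junction on its parent
    endpoints = 2 * n_roots + n_branches
    if root_orientations:
        # axial order parameter: doubled-angle circular resultant length
        z = np.exp(2j * np.asarray(root_orientations))
        alignment = float(np.abs(z.mean()))
    else:
        alignment = 0.0
    mean_width = float(np.mean([f.width for f in fibers])) if fibers else 0.0
    mean_fb = float(np.mean([f.fb_ratio for f in fibers])) if fibers else 0.0
    return GroundTruth(
        fibers=fibers,
        true_total_length=total_length,
        true_endpoints=endpoints if fibers else 0,
        true_branchpoints=n_branches,
        true_mean_width=mean_width,
        true_alignment=alignment,
        true_mean_fb=mean_fb,
    )


def rasterize_scene(
    fibers: Sequence[FiberSpec], params: SceneParams
) -> tuple[np.ndarray, np.ndarray]:
    """Render fibers into noiseless continuous forward/backward fields.

    Each fiber has a Gaussian cross-section profile of FWHM = ``width``; the
    forward field accumulates ``peak_intensity``-scaled profiles on top of
    ``background_level`` and the backward field the same geometry with
    amplitude ``peak_intensity / fb_ratio`` (so the background-subtracted
    pixel-wise ratio equals ``fb_ratio`` wherever one fiber dominates).
    """
    rows, cols = params.image_shape
    forward = np.full((rows, cols), float(params.background_level))
    backward = np.full((rows, cols), float(params.background_level))
    yy, xx = np.mgrid[0:rows, 0:cols]
    for fib in fibers:
        sigma = fib.width * _FWHM_TO_SIGMA
        dense = _resample_polyline(fib.centerline, 0.25)
        pad = 3.0 * sigma + 1.0
        x0 = max(int(np.floor(dense[:, 0].min() - pad)), 0)
        x1 = min(int(np.ceil(dense[:, 0].max() + pad)) + 1, cols)
        y0 = max(int(np.floor(dense[:, 1].min() - pad)), 0)
        y1 = min(int(np.ceil(dense[:, 1].max() + pad)) + 1, rows)
        if x0 >= x1 or y0 >= y1:
            continue
        sub = np.column_stack(
            [xx[y0:y1, x0:x1].ravel(), yy[y0:y1, x0:x1].ravel()]
        ).astype(float)
        d, _ = cKDTree(dense).query(sub, k=1)
        profile = np.exp(-(d**2) / (2.0 * sigma**2)).reshape(y1 - y0, x1 - x0)
        forward[y0:y1, x0:x1] += fib.peak_intensity * profile
        backward[y0:y1, x0:x1] += (fib.peak_intensity / fib.fb_ratio) * profile
    return forward, backward


def _resample_polyline(pts: np.ndarray, spacing: float) -> np.ndarray:
    steps = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(steps)])
    total = s[-1]
    if total == 0:
        return pts[:1]
    n = max(int(np.ceil(total / spacing)) + 1, 2)
    si = np.linspace(0.0, total, n)
    return np.column_stack([np.interp(si, s, pts[:, 0]), np.interp(si, s, pts[:, 1])])


def simulate_stack(
    forward_field: np.ndarray,
    backward_field: np.ndarray,
    params: SceneParams,
    rng: np.random.Generator | None = None,
    site_id: str = "",
    sample_id: str = "",
    group_label: str = "",
) -> ChannelStack:
    """Acquire ``n_frames`` shot-noise 8-bit frames of each field.

    Shot noise is Poisson on detected photons; ``detector_gain`` converts
    photons to detector units (DN), so a frame value is
    ``round(gain * Poisson(field / gain))`` clipped to [0, 255].  Gain 1
    reduces to Poisson noise directly on DN.
    """
    forward_field = np.asarray(forward_field, dtype=float)
    backward_field = np.asarray(backward_field, dtype=float)
    if np.any(forward_field < 0) or np.any(backward_field < 0):
        raise ValueError("fields must be non-negative")
    if rng is None:
        rng = np.random.default_rng(params.seed)
    g = params.detector_gain
    shape = (params.n_frames,) + forward_field.shape
    fwd = np.clip(np.round(g * rng.poisson(forward_field / g, size=shape)), 0, 255).astype(np.uint8)
    bwd = np.clip(np.round(g * rng.poisson(backward_field / g, size=shape)), 0, 255).astype(np.uint8)
    return ChannelStack(
        forward=fwd,
        backward=bwd,
        pixel_size_um=params.pixel_size_um,
        site_id=site_id,
        sample_id=sample_id,
        group_label=group_label,
    )


def generate_scene(
    params: SceneParams,
    rng: np.random.Generator | None = None,
    site_id: str = "",
    sample_id: str = "",
    group_label: str = "",
) -> tuple[ChannelStack, GroundTruth]:
    """Sample, rasterize and acquire one site in a single call."""
    if rng is None:
        rng = np.random.default_rng(params.seed)
    fibers, truth = sample_fiber_network(params, rng)
    ff, bf = rasterize_scene(fibers, params)
    stack = simulate_stack(ff, bf, params, rng, site_id, sample_id, group_label)
    return stack, truth


@dataclass
class GroupDesign:
    """One cohort arm: its label, size, and site-level scene parameters."""

    name: str
    n_samples: int
    params: SceneParams = field(default_factory=SceneParams)


@dataclass
class StudyDesign:
    """Two-arm (or k-arm) imaging study layout.

    ``sample_jitter_frac`` scales per-sample multiplicative heterogeneity in
    fiber count and mean length (biological between-sample variation); sites
    within a sample then vary only through sampling noise.
    """

    groups: list[GroupDesign]
    sites_per_sample: int = 20
    sample_jitter_frac: float = 0.10

    def __post_init__(self) -> None:
        names = [g.name for g in self.groups]
        if len(set(names)) != len(names):
            raise ValueError("duplicate group names")
        if self.sites_per_sample < 1:
            raise ValueError("sites_per_sample must be >= 1")
        if self.sample_jitter_frac < 0:
            raise ValueError("sample_jitter_frac must be non-negative")

    @classmethod
    def default_two_group(
        cls,
        n_samples: tuple[int, int] = (10, 17),
        sites_per_sample: int = 20,
        image_shape: tuple[int, int] = (512, 512),
        n_frames: int = 20,
    ) -> "StudyDesign":
        """Two-arm design mirroring the study this pipeline emulates.

        Group A (10 samples) is denser: more and longer fibers, hence higher
        area/length/endpoint/branchpoint counts and lower lacunarity than
        group B (17 samples); group B puts more FB-ratio weight on the
        high (225) mode.
        """
        params_a = SceneParams(
            image_shape=image_shape,
            n_fibers=35,
            length_mean=170.0,
            n_frames=n_frames,
            fb_ratio_modes=((50.0, 0.85), (225.0, 0.15)),
        )
        params_b = SceneParams(
            image_shape=image_shape,
            n_fibers=22,
            length_mean=130.0,
            n_frames=n_frames,
            fb_ratio_modes=((50.0, 0.7), (225.0, 0.3)),
        )
        return cls(
            groups=[
                GroupDesign("A", n_samples[0], params_a),
                GroupDesign("B", n_samples[1], params_b),
            ],
            sites_per_sample=sites_per_sample,
        )


def generate_cohort(
    design: StudyDesign, seed: int
) -> list[tuple[ChannelStack, GroundTruth]]:
    """Generate every site of a study design; deterministic for fixed seed."""
    out: list[tuple[ChannelStack, GroundTruth]] = []
    seen: set[str] = set()
    root = np.random.SeedSequence(seed)
    for gi, group in enumerate(design.groups):
        for si in range(group.n_samples):
            sample_id = f"{group.name}{si + 1:02d}"
            if sample_id in seen:
                raise ValueError(f"duplicate sample id {sample_id}")
            seen.add(sample_id)
            sample_seq = np.random.SeedSequence(
                entropy=root.entropy, spawn_key=(gi, si)
            )
            sample_rng = np.random.default_rng(sample_seq)
            params = _jitter_params(group.params, design.sample_jitter_frac, sample_rng)
            for ti in range(design.sites_per_sample):
                site_rng = np.random.default_rng(
                    np.random.SeedSequence(entropy=root.entropy, spawn_key=(gi, si, ti))
                )
                stack, truth = generate_scene(
                    params,
                    site_rng,
                    site_id=f"s{ti + 1:02d}",
                    sample_id=sample_id,
                    group_label=group.name,
                )
                out.append((stack, truth))
    return out


def _jitter_params(params: SceneParams, frac: float, rng: np.random.Generator) -> SceneParams:
    if frac == 0:
        # still draw to keep the per-sample stream layout stable
        rng.normal(size=2)
        return params
    z = rng.normal(size=2)
    return dataclasses.replace(
        params,
        n_fibers=max(0, int(round(params.n_fibers * (1.0 + frac * z[0])))),
        length_mean=max(5.0, params.length_mean * (1.0 + frac * z[1])),
    )


def write_cohort(
    cohort: Sequence[tuple[ChannelStack, GroundTruth]], out_dir: str | Path
) -> Path:
    """Write per-site multi-page TIFFs plus a ground-truth CSV sidecar.

    Files are named ``{sample}_{site}_{F|B}.tif``; ``ground_truth.csv`` holds
    one row per site with the ``true_*`` columns.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for stack, truth in cohort:
        base = f"{stack.sample_id}_{stack.site_id}"
        tifffile.imwrite(out_dir / f"{base}_F.tif", stack.forward)
        tifffile.imwrite(out_dir / f"{base}_B.tif", stack.backward)
        rows.append(
            {"sample_id": stack.sample_id, "site_id": stack.site_id, **truth.as_row()}
        )
    pd.DataFrame(rows).to_csv(out_dir / "ground_truth.csv", index=False)
    return out_dir
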