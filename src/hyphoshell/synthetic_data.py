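"""Synthetic phantoms of hyphal cells with known ground truth.

The phantom is a capsule-shaped cell (cylindrical tube with hemispherical
caps, radius ~1-1.5 um) whose wall is represented by two infinitely thin
curves: the inner wall face (where the plasma-membrane label sits) and the
outer face (where the lectin label sits), separated along the local outward
normal by the true thickness profile h(s'), with s' the arclength distance
from the tip apex.  Rendering emulates a two-channel mid-slice confocal
image: line sources convolved with per-channel Gaussian PSFs, asymmetric
inside/outside backgrounds, a chromatic shift applied to channel 2, Poisson
shot noise and Gaussian read noise.  The truth geometry travels with every
image, so every downstream estimator can be scored exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from . import tipmodel
from .wallmech import ElasticStrains

__all__ = [
    "PhantomGeometry",
    "ImagingSpec",
    "SyntheticImage",
    "make_phantom",
    "constant_profile",
    "tip_bump_profile",
    "tip_scaled_profile",
    "sinusoidal_profile",
    "render_image",
    "make_deflation_pair",
    "simulate_timelapse",
    "make_trace_pair",
    "save_timelapse",
]

_SS = 4  # supersampling factor for rasterization


# ---------------------------------------------------------------- geometry

def constant_profile(h_nm: float) -> Callable[[np.ndarray], np.ndarray]:
    """h(s') = const."""
    if h_nm <= 0:
        raise ValueError("thickness must be positive")
    return lambda s: np.full_like(np.asarray(s, dtype=float), h_nm)


def tip_bump_profile(base_nm: float, bump_nm: float, width_um: float = 1.0):
    """Constant base with a Gaussian bump (signed) centered at the tip."""
    if base_nm <= 0 or base_nm + bump_nm <= 0:
        raise ValueError("thickness must stay positive")
    return lambda s: base_nm + bump_nm * np.exp(-np.asarray(s, float) ** 2
                                                / (2 * width_um ** 2))


def tip_scaled_profile(side_nm: float, tip_factor: float, width_um: float = 1.5):
    """Side thickness with the tip scaled by ``tip_factor`` (e.g. 0.87 for a
    tip 13% thinner than the sides)."""
    return tip_bump_profile(side_nm, side_nm * (tip_factor - 1.0), width_um)


def sinusoidal_profile(lo_nm: float, hi_nm: float, period_um: float = 3.0):
    """Thickness oscillating between lo and hi along the arclength."""
    if lo_nm <= 0:
        raise ValueError("thickness must be positive")
    mid, amp = (lo_nm + hi_nm) / 2.0, (hi_nm - lo_nm) / 2.0
    return lambda s: mid + amp * np.sin(2 * np.pi * np.asarray(s, float) / period_um)


@dataclass(frozen=True)
class PhantomGeometry:
    """Capsule phantom: midline polyline + radius + thickness profile.

    midline : (M, 2) um, ordered rear -> tip.
    radius : um (tube and cap radius).
    cap : hemispherical caps at both ends (always True for the capsule).
    thickness_profile : s' (um, arclength from tip apex) -> h (nm).
    """

    midline: np.ndarray
    radius: float
    thickness_profile: Callable[[np.ndarray], np.ndarray]
    cap: bool = True
    _step_um: float = 0.02

    def __post_init__(self):
        object.__setattr__(self, "midline",
                           np.atleast_2d(np.asarray(self.midline, dtype=float)))
        if self.radius <= 0:
            raise ValueError("radius must be positive")
        if self.midline.shape[0] < 2:
            raise ValueError("midline needs at least two points")
        probe = self.thickness_profile(np.linspace(0, 20, 50))
        if np.any(np.asarray(probe) <= 0):
            raise ValueError("thickness_profile must be positive everywhere")

    @property
    def tip_position(self) -> np.ndarray:
        """Tip apex (um): midline end extended by the cap radius."""
        t = self._end_tangent()
        return self.midline[-1] + self.radius * t

    def _end_tangent(self) -> np.ndarray:
        d = self.midline[-1] - self.midline[-2]
        return d / np.linalg.norm(d)

    def _start_tangent(self) -> np.ndarray:
        d = self.midline[1] - self.midline[0]
        return d / np.linalg.norm(d)

    def inner_contour(self):
        """Dense closed inner-face polyline.

        Returns (points (N,2) um, s_prime (N,) um, outward normals (N,2)).
        Ordering starts at the tip apex and runs around the cell; s_prime is
        the shorter arclength distance to the tip apex.
        """
        R = self.radius
        mid = self._resampled_midline()
        tang = self._tangents(mid)
        nrm = np.column_stack([-tang[:, 1], tang[:, 0]])  # left normal

        n_arc = max(8, int(np.ceil(np.pi * R / self._step_um)))
        t_tip = tang[-1]
        t_rear = tang[0]

        def arc(center, v_from, v_to, n):
            """Circular arc of radius R from direction v_from to v_to (short way)."""
            a0 = np.arctan2(v_from[1], v_from[0])
            a1 = np.arctan2(v_to[1], v_to[0])
            da = (a1 - a0 + np.pi) % (2 * np.pi) - np.pi
            if da == 0:
                da = np.pi
            ang = a0 + da * np.linspace(0, 1, n, endpoint=False)
            return center + R * np.column_stack([np.cos(ang), np.sin(ang)])

        # walk: tip apex -> left cap half -> left side (tip->rear) ->
        # rear cap -> right side (rear->tip) -> right cap half -> back to apex
        left = mid + R * nrm
        right = mid - R * nrm
        tip_c, rear_c = mid[-1], mid[0]
        pts = np.vstack([
            arc(tip_c, t_tip, nrm[-1], n_arc // 2),
            left[::-1],
            arc(rear_c, nrm[0], -t_rear, n_arc // 2),
            arc(rear_c, -t_rear, -nrm[0], n_arc // 2),
            right,
            arc(tip_c, -nrm[-1], t_tip, n_arc // 2),
        ])
        # drop near-duplicate consecutive points
        keep = np.ones(len(pts), dtype=bool)
        keep[1:] = np.linalg.norm(np.diff(pts, axis=0), axis=1) > 1e-9
        pts = pts[keep]
        seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        s = np.concatenate([[0.0], np.cumsum(seg)])
        total = s[-1] + np.linalg.norm(pts[0] - pts[-1])
        s_prime = np.minimum(s, total - s)
        normals = _polyline_outward_normals(pts)
        return pts, s_prime, normals

    def outer_contour(self):
        """Outer-face polyline: inner offset by h(s') along the outward normal."""
        pts, s_prime, normals = self.inner_contour()
        h_um = np.asarray(self.thickness_profile(s_prime), dtype=float) / 1000.0
        return pts + normals * h_um[:, None], s_prime

    def thickness_at(self, s_prime) -> np.ndarray:
        """Ground-truth thickness (nm) at arclength distance s' (um)."""
        return np.asarray(self.thickness_profile(np.asarray(s_prime, float)))

    def _resampled_midline(self) -> np.ndarray:
        seg = np.linalg.norm(np.diff(self.midline, axis=0), axis=1)
        s = np.concatenate([[0.0], np.cumsum(seg)])
        n = max(2, int(np.ceil(s[-1] / self._step_um)))
        su = np.linspace(0, s[-1], n)
        mid = np.column_stack([np.interp(su, s, self.midline[:, i])
                               for i in range(2)])
        if len(mid) > 20:
            # round off polyline corners so the normal offset at radius R
            # stays well defined (no cusps in the offset curves)
            from scipy.ndimage import gaussian_filter1d
            sigma = max(1.0, 0.15 / self._step_um)
            sm = np.column_stack([
                gaussian_filter1d(mid[:, i], sigma, mode="nearest")
                for i in range(2)])
            sm[0], sm[-1] = mid[0], mid[-1]
            mid = sm
        return mid

    @staticmethod
    def _tangents(pts: np.ndarray) -> np.ndarray:
        t = np.gradient(pts, axis=0)
        return t / np.linalg.norm(t, axis=1, keepdims=True)


def _polyline_outward_normals(pts: np.ndarray) -> np.ndarray:
    """Outward unit normals of a closed polyline (any orientation)."""
    nxt = np.roll(pts, -1, axis=0)
    prv = np.roll(pts, 1, axis=0)
    t = nxt - prv
    t /= np.linalg.norm(t, axis=1, keepdims=True)
    n = np.column_stack([t[:, 1], -t[:, 0]])
    # signed area decides which rotation points outward: for a
    # counter-clockwise polygon (positive area) the interior lies left of
    # the tangent, so (ty, -tx) already points outward
    x, y = pts[:, 0], pts[:, 1]
    area = 0.5 * np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y)
    if area < 0:
        n = -n
    return n


def make_phantom(radius_um: float = 1.2, length_um: float = 5.0,
                 thickness_profile=None, h_nm: float = 80.0,
                 midline: np.ndarray | None = None) -> PhantomGeometry:
    """Convenience constructor for a capsule phantom.

    With no profile supplied, the wall is uniform at ``h_nm``.  A custom
    midline (um, rear -> tip) makes a bent hypha.
    """
    if radius_um <= 0 or length_um <= 0:
        raise ValueError("radius and length must be positive")
    if thickness_profile is None:
        thickness_profile = constant_profile(h_nm)
    if midline is None:
        midline = np.array([[0.0, 0.0], [length_um, 0.0]])
    return PhantomGeometry(midline=midline, radius=radius_um,
                           thickness_profile=thickness_profile)


# ---------------------------------------------------------------- imaging

@dataclass(frozen=True)
class ImagingSpec:
    """Imaging model parameters (all lengths in nm, intensities in counts).

    Defaults approximate a 100x spinning-disk acquisition: 65 nm pixels, a
    200 nm PSF sigma in both channels, ~200 counts of peak signal, a small
    chromatic shift between channels, cytoplasmic background inside the cell
    in the membrane channel and medium background outside in the lectin
    channel.
    """

    pixel_size: float = 65.0
    psf_sigma: tuple[float, float] = (200.0, 200.0)
    chromatic_shift: tuple[float, float] = (30.0, -20.0)
    background_in: tuple[float, float] = (50.0, 2.0)
    background_out: tuple[float, float] = (2.0, 15.0)
    photon_scale: float = 200.0
    read_noise_sd: float = 3.0
    seed: int = 0
    margin_um: float = 1.0

    def __post_init__(self):
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if min(self.psf_sigma) < 0:
            raise ValueError("psf_sigma must be non-negative")
        if self.photon_scale <= 0:
            raise ValueError("photon_scale must be positive")

    def to_dict(self) -> dict:
        return {
            "pixel_size_nm": self.pixel_size,
            "psf_sigma_nm": list(self.psf_sigma),
            "chromatic_shift_nm": list(self.chromatic_shift),
            "background_in": list(self.background_in),
            "background_out": list(self.background_out),
            "photon_scale": self.photon_scale,
            "read_noise_sd": self.read_noise_sd,
            "seed": self.seed,
        }


@dataclass(frozen=True)
class SyntheticImage:
    """Two-channel rendered raster plus its ground truth.

    channels : (2, H, W) float counts; channel 0 = membrane (inner face),
    channel 1 = lectin (outer face).  Pixel centers sit at integer indices;
    world x (um) = origin_um[0] + col * pixel, y = origin_um[1] + row * pixel
    with y increasing downward in the displayed raster.
    """

    channels: np.ndarray
    truth: PhantomGeometry
    spec: ImagingSpec
    origin_um: tuple[float, float]
    expectation: np.ndarray | None = None
    extra_channels: np.ndarray | None = None

    def __post_init__(self):
        ch = np.asarray(self.channels)
        if ch.ndim != 3 or ch.shape[0] != 2:
            raise ValueError("channels must have shape (2, H, W)")

    @property
    def pixel_nm(self) -> float:
        return self.spec.pixel_size

    def world_to_px(self, pts_um: np.ndarray) -> np.ndarray:
        """um world coordinates -> fractional (x, y) pixel coordinates."""
        p = np.atleast_2d(np.asarray(pts_um, float))
        return (p - np.asarray(self.origin_um)) / (self.pixel_size_um())

    def pixel_size_um(self) -> float:
        return self.spec.pixel_size / 1000.0


def _splat(points_px: np.ndarray, weights: np.ndarray, shape) -> np.ndarray:
    """Bilinear deposition of weighted samples onto a raster."""
    img = np.zeros(shape)
    x, y = points_px[:, 0], points_px[:, 1]
    x0 = np.floor(x).astype(int)
    y0 = np.floor(y).astype(int)
    fx, fy = x - x0, y - y0
    for dy in (0, 1):
        for dx in (0, 1):
            w = weights * (fx if dx else 1 - fx) * (fy if dy else 1 - fy)
            xs, ys = x0 + dx, y0 + dy
            ok = (xs >= 0) & (xs < shape[1]) & (ys >= 0) & (ys < shape[0])
            np.add.at(img, (ys[ok], xs[ok]), w[ok])
    return img


def _densify(pts: np.ndarray, step: float) -> np.ndarray:
    """Resample a closed polyline at roughly uniform spacing ``step``."""
    closed = np.vstack([pts, pts[:1]])
    seg = np.linalg.norm(np.diff(closed, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    n = max(8, int(np.ceil(s[-1] / step)))
    su = np.linspace(0, s[-1], n, endpoint=False)
    return np.column_stack([np.interp(su, s, closed[:, i]) for i in range(2)])


def _polygon_coverage(pts_px_ss: np.ndarray, ss_shape, native_shape) -> np.ndarray:
    """Anti-aliased interior coverage in [0, 1] on the native grid."""
    from skimage.draw import polygon2mask
    # polygon2mask wants (row, col)
    mask = polygon2mask(ss_shape, pts_px_ss[:, ::-1]).astype(float)
    H, W = native_shape
    return mask.reshape(H, _SS, W, _SS).mean(axis=(1, 3))


def render_image(geometry: PhantomGeometry, spec: ImagingSpec,
                 noise: bool = True, rng: np.random.Generator | None = None,
                 bounds_um: tuple | None = None,
                 extra_spots: Sequence[tuple] = ()) -> SyntheticImage:
    """Render the two-channel mid-slice image of a phantom.

    Channel 0: line source on the inner face + cytoplasmic background inside
    the cell.  Channel 1: line source on the outer face + medium background
    outside, the whole channel translated by the chromatic shift.  Both are
    convolved with their Gaussian PSFs; Poisson shot noise and Gaussian read
    noise are added unless ``noise=False`` (the noise-free expectation image
    is retained either way).

    ``extra_spots`` is a sequence of (center_um, sigma_nm, amplitude_counts)
    Gaussian blobs added to a third channel (apical vesicle spot).
    """
    px_um = spec.pixel_size / 1000.0
    inner, s_in, _ = geometry.inner_contour()
    outer, _ = geometry.outer_contour()
    shift_um = np.asarray(spec.chromatic_shift) / 1000.0

    if bounds_um is None:
        lo = outer.min(axis=0) - spec.margin_um
        hi = outer.max(axis=0) + spec.margin_um
    else:
        lo, hi = np.asarray(bounds_um[0], float), np.asarray(bounds_um[1], float)
        if np.any(outer.min(axis=0) < lo) or np.any(outer.max(axis=0) > hi):
            raise ValueError(
                f"geometry (extent {outer.min(axis=0)}..{outer.max(axis=0)} um) "
                f"overflows the requested raster bounds {lo}..{hi} um"
            )
    W = int(np.ceil((hi[0] - lo[0]) / px_um)) + 1
    H = int(np.ceil((hi[1] - lo[1]) / px_um)) + 1
    origin = (float(lo[0]), float(lo[1]))

    ss_px_um = px_um / _SS
    ss_shape = (H * _SS, W * _SS)

    def to_ss_px(pts_um):
        return (pts_um - np.asarray(origin)) / ss_px_um + (_SS - 1) / 2.0

    step_um = ss_px_um / 2.0
    channels = []
    expect = []
    line_curves = [inner, outer + shift_um]
    fill_curves = [inner, outer + shift_um]
    fill_inside = [True, False]  # ch1: bg inside; ch2: bg outside

    for ci in range(2):
        dense = _densify(line_curves[ci], step_um)
        # weight = sample length in native px so a straight-line cross
        # section sums to 1 per native pixel of length; the splat goes on
        # the native grid directly -- bilinear deposition preserves the
        # centroid exactly, which supersample-and-pool would quantize
        w = np.full(len(dense), step_um / px_um)
        line = _splat(dense / px_um - np.asarray(origin) / px_um, w, (H, W))

        sigma_px = spec.psf_sigma[ci] / spec.pixel_size
        if sigma_px > 0:
            amp = spec.photon_scale * np.sqrt(2 * np.pi) * sigma_px
        else:
            amp = spec.photon_scale

        cov = _polygon_coverage(to_ss_px(_densify(fill_curves[ci], step_um * 4)),
                                ss_shape, (H, W))
        if fill_inside[ci]:
            bg = spec.background_in[ci] * cov + spec.background_out[ci] * (1 - cov)
        else:
            bg = spec.background_in[ci] * cov + spec.background_out[ci] * (1 - cov)
        raw = amp * line + bg
        E = gaussian_filter(raw, sigma_px, mode="nearest") if sigma_px > 0 else raw
        expect.append(E)

    extra = None
    if extra_spots:
        xx = (np.arange(W) * px_um + origin[0])
        yy = (np.arange(H) * px_um + origin[1])
        X, Y = np.meshgrid(xx, yy)
        spot = np.zeros((H, W))
        for center_um, sigma_nm, amplitude in extra_spots:
            s_um = sigma_nm / 1000.0
            spot += amplitude * np.exp(-((X - center_um[0]) ** 2 +
                                         (Y - center_um[1]) ** 2) / (2 * s_um ** 2))
        extra = spot[None]

    if noise:
        if rng is None:
            rng = np.random.default_rng(spec.seed)
        for E in expect:
            img = rng.poisson(np.clip(E, 0, None)).astype(float)
            img += rng.normal(0.0, spec.read_noise_sd, size=E.shape)
            channels.append(img)
        if extra is not None:
            extra = (rng.poisson(np.clip(extra, 0, None)).astype(float)
                     + rng.normal(0.0, spec.read_noise_sd, size=extra.shape))
    else:
        channels = [E.copy() for E in expect]

    return SyntheticImage(channels=np.stack(channels), truth=geometry,
                          spec=spec, origin_um=origin,
                          expectation=np.stack(expect),
                          extra_channels=extra)


# ----------------------------------------------------------- deflation pair

def make_deflation_pair(geometry: PhantomGeometry, strains: ElasticStrains,
                        spec: ImagingSpec):
    """Render a turgid/deflated image pair with known elastic strains.

    The deflated geometry has radius R0 = R1/(1 + radial strain) and midline
    length L0 = L1/(1 + longitudinal strain), so that (R1-R0)/R0 recovers the
    requested strains exactly.  Both images share one raster so they are
    registered.  Returns (before, after, strains).
    """
    for name, e in (("radial", strains.radial),
                    ("longitudinal", strains.longitudinal)):
        if e is not None and e <= -1:
            raise ValueError(f"{name} strain must be > -1")
        if e is not None and e < 0:
            raise ValueError(f"{name} strain must be >= 0 for a deflating cell")
    e_r = strains.radial or 0.0
    e_l = strains.longitudinal or 0.0
    mid = geometry.midline
    R1 = geometry.radius
    R0 = R1 / (1.0 + e_r)
    # the measured cell length includes both caps (which scale with the
    # radius), so the midline is rescaled such that the TOTAL pole-to-pole
    # length shrinks by exactly the longitudinal strain
    seg = np.linalg.norm(np.diff(mid, axis=0), axis=1).sum()
    L1_tot = seg + 2.0 * R1
    L0_mid = L1_tot / (1.0 + e_l) - 2.0 * R0
    if L0_mid <= 0:
        raise ValueError("deflated midline length non-positive; strains too "
                         "large for this geometry")
    center = mid.mean(axis=0)
    mid0 = center + (mid - center) * (L0_mid / seg)
    deflated = PhantomGeometry(midline=mid0, radius=R0,
                               thickness_profile=geometry.thickness_profile)
    outer, _ = geometry.outer_contour()
    lo = outer.min(axis=0) - spec.margin_um
    hi = outer.max(axis=0) + spec.margin_um
    rng = np.random.default_rng(spec.seed)
    before = render_image(geometry, spec, rng=rng, bounds_um=(lo, hi))
    after = render_image(deflated, spec, rng=rng, bounds_um=(lo, hi))
    return before, after, strains


# ------------------------------------------------------------- time lapses

def simulate_timelapse(params: tipmodel.ModelParams,
                       scenario: tipmodel.Scenario,
                       spec: ImagingSpec,
                       frame_interval: float = 1.0,
                       radius_um: float = 1.2,
                       initial_length_um: float = 4.0,
                       spot_sigma_nm: float = 350.0,
                       spot_counts_per_ev: float = 60.0,
                       render: bool = True):
    """Model-driven time lapse: growing phantom + apical vesicle spot.

    The tip advances at v(t) = G(t)*R/(2*pi) (hemispherical-cap kinematics);
    the wall thickness field follows h(t) from the model; a third channel
    carries an apical Gaussian spot of intensity proportional to EV(t).

    Returns (frames, truth) where truth is a DataFrame with columns
    (t_min, h_nm, EV_au, G_per_min, tip_x_um) and frames is a list of
    SyntheticImage (or None if ``render=False``).
    """
    if frame_interval <= 0:
        raise ValueError("frame_interval must be positive")
    t_grid = np.arange(0.0, scenario.duration + 1e-9, frame_interval)
    traj = tipmodel.integrate(params, scenario, t_grid)
    if np.any(traj["h_nm"] <= 0):
        raise RuntimeError("scenario drove h to zero; aborting time lapse")
    v = traj["G_per_min"].to_numpy() * params.R / (2 * np.pi)  # um/min
    tip_x = initial_length_um + np.concatenate(
        [[0.0], np.cumsum(0.5 * (v[1:] + v[:-1]) * np.diff(t_grid))])
    truth = pd.DataFrame({
        "t_min": t_grid,
        "h_nm": traj["h_nm"],
        "EV_au": traj["EV_au"],
        "G_per_min": traj["G_per_min"],
        "tip_x_um": tip_x,
    })
    frames = None
    if render:
        ss = tipmodel.steady_state(params)
        final_len = tip_x[-1]
        lo = np.array([-spec.margin_um - radius_um, -radius_um - spec.margin_um])
        hi = np.array([final_len + radius_um + spec.margin_um,
                       radius_um + spec.margin_um])
        rng = np.random.default_rng(spec.seed)
        frames = []
        for k, t in enumerate(t_grid):
            geom = make_phantom(radius_um=radius_um, length_um=tip_x[k],
                                h_nm=float(traj["h_nm"].iloc[k]))
            spot_amp = spot_counts_per_ev * traj["EV_au"].iloc[k] / ss.EV_star
            frames.append(render_image(
                geom, spec, rng=rng, bounds_um=(lo, hi),
                extra_spots=[(geom.tip_position, spot_sigma_nm, spot_amp)]))
    return frames, truth


def save_timelapse(frames, truth: pd.DataFrame, out_dir) -> dict:
    """Write a rendered time lapse to disk.

    Multi-page TIFF (pages ordered frame-major, channels membrane, lectin,
    then the spot channel if present), the truth table as CSV, and the
    imaging spec echoed as JSON.  Returns the paths written.
    """
    import tifffile

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pages = []
    for fr in frames:
        pages.extend(np.asarray(fr.channels, dtype=np.float32))
        if fr.extra_channels is not None:
            pages.extend(np.asarray(fr.extra_channels, dtype=np.float32))
    tif = out / "timelapse.tif"
    tifffile.imwrite(tif, np.stack(pages))
    csv = out / "truth.csv"
    truth.to_csv(csv, index=False)
    js = out / "imaging_spec.json"
    meta = frames[0].spec.to_dict()
    meta["n_frames"] = len(frames)
    meta["channels_per_frame"] = len(pages) // len(frames)
    meta["channel_order"] = ["membrane", "lectin", "vesicle_spot"][
        : meta["channels_per_frame"]]
    js.write_text(json.dumps(meta, indent=2))
    return {"tiff": tif, "truth_csv": csv, "spec_json": js}


# ------------------------------------------------------------- trace pairs

def make_trace_pair(n: int, lag: int, noise_sd: float, seed: int,
                    smooth: float = 3.0):
    """Two series where B is A delayed by ``lag`` samples plus noise.

    A is smoothed standardized Gaussian noise (correlation length ``smooth``
    samples), so the pair has a known cross-correlation structure with its
    maximum at dt = lag.  Positive lag: B follows A.
    """
    if n <= 3 * abs(lag):
        raise ValueError("need n > 3*|lag|")
    rng = np.random.default_rng(seed)
    raw = rng.normal(size=n + 2 * abs(lag) + 20)
    sig = gaussian_filter(raw, smooth, mode="wrap")
    sig = (sig - sig.mean()) / sig.std()
    off = abs(lag) + 10
    a = sig[off: off + n]
    b = sig[off - lag: off - lag + n].copy()
    if noise_sd > 0:
        b += rng.normal(0.0, noise_sd, size=n)
    return a, b
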