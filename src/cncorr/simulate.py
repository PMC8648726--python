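"""Synthetic single-cell data generators with recoverable ground truth.

This module emulates every input the analysis pipeline consumes:

* time-lapse cell + nucleus movies whose per-minute steps are draws from a
  phase-specific :class:`~cncorr.mixtures.ActivityMixture`
  (:func:`generate_cell_movie`);
* raw CN polar-angle samples (:func:`sample_cn_angles`);
* fixed-cell fluorescence images containing line-like stress fibers and
  blob-like focal adhesions (:func:`generate_cytoskeleton_image`);
* per-cell DNA-content populations with G1/S/G2M structure
  (:func:`generate_dna_population`);
* piecewise phenotype time courses with division events
  (:func:`generate_phenotype_series`, :func:`generate_division_cohort`).

Every generator is seeded and bit-reproducible; a master seed expands into
independent per-stream child seeds through :func:`child_seeds` so adding a
generator never perturbs the draws of another.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .mixtures import ActivityMixture

__all__ = [
    "MovieGenConfig",
    "CellMovie",
    "GroundTruthImage",
    "GapSpec",
    "DNAPopulation",
    "child_seeds",
    "reflect_angle",
    "sample_cn_angles",
    "generate_cell_movie",
    "generate_cytoskeleton_image",
    "generate_dna_population",
    "generate_phenotype_series",
    "generate_division_cohort",
]


def child_seeds(master_seed: int, n: int) -> list[int]:
    """Expand one master seed into ``n`` independent 31-bit child seeds."""
    ss = np.random.SeedSequence(master_seed)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]


def reflect_angle(angles_deg):
    """Fold angles onto [0, 180] by reflection at the boundaries.

    Reflection (rather than clipping) avoids probability atoms at 0/180.
    """
    a = np.asarray(angles_deg, dtype=float)
    return np.abs(((a + 180.0) % 360.0) - 180.0)


# ---------------------------------------------------------------------------
# movies
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MovieGenConfig:
    """Geometry and sampling settings for a synthetic cell movie."""

    duration: float = 60.0      # minutes
    interval: float = 1.0       # minutes between frames
    pixel_size: float = 0.3     # µm per pixel (raster rendering only)
    cell_radius: float = 15.0   # µm
    nucleus_radius: float = 6.0  # µm
    noise_sd: float = 0.0       # µm, isotropic centroid jitter
    heading_sd: float = 10.0    # deg, per-step direction jitter
    seed: int = 0

    def __post_init__(self) -> None:
        if self.interval <= 0:
            raise ValueError("interval must be positive")
        if self.duration < 0:
            raise ValueError("duration must be non-negative")
        if self.nucleus_radius >= self.cell_radius:
            raise ValueError("nucleus_radius must be smaller than cell_radius")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")


@dataclass
class CellMovie:
    """Paired cell/nucleus centroid tracks (µm) with optional raster masks.

    The float centroid tracks are the primary representation consumed by
    the CN analysis; masks are rendered on demand for the raster/TIFF code
    path and for shape descriptors.
    """

    times: np.ndarray                 # minutes, shape (n_frames,)
    cell_centroids: np.ndarray        # µm, shape (n_frames, 2)
    nucleus_centroids: np.ndarray     # µm, shape (n_frames, 2)
    pixel_size: float = 0.3           # µm / px
    cell_radius: float = 15.0         # µm (disk rendering)
    nucleus_radius: float = 6.0       # µm
    step_labels: list[str] | None = None    # ground-truth activity per step
    step_angles: np.ndarray | None = None   # ground-truth CN angle per step
    step_ccd: np.ndarray | None = None      # ground-truth CCD per step (µm)
    division_times: list[float] = field(default_factory=list)  # minutes

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.cell_centroids = np.asarray(self.cell_centroids, dtype=float)
        self.nucleus_centroids = np.asarray(self.nucleus_centroids, dtype=float)
        n = len(self.times)
        if self.cell_centroids.shape != (n, 2):
            raise ValueError("cell_centroids must have shape (n_frames, 2)")
        if self.nucleus_centroids.shape != (n, 2):
            raise ValueError("nucleus_centroids must have shape (n_frames, 2)")

    @property
    def n_frames(self) -> int:
        return len(self.times)

    @property
    def interval(self) -> float:
        if self.n_frames < 2:
            return float("nan")
        return float(self.times[1] - self.times[0])

    @classmethod
    def from_masks(cls, cell_masks, nucleus_masks, pixel_size: float,
                   interval: float = 1.0) -> "CellMovie":
        """Build a movie from per-frame binary masks (centroids in µm)."""
        if nucleus_masks is None:
            raise ValueError("nucleus channel is required for CN analysis")
        if len(cell_masks) != len(nucleus_masks):
            raise ValueError("cell and nucleus stacks differ in length")

        def _centroid(mask):
            mask = np.asarray(mask, dtype=bool)
            if not mask.any():
                raise ValueError("empty mask frame")
            rr, cc = np.nonzero(mask)
            return np.array([cc.mean(), rr.mean()]) * pixel_size  # (x, y)

        cells = np.array([_centroid(m) for m in cell_masks])
        nucs = np.array([_centroid(m) for m in nucleus_masks])
        times = np.arange(len(cell_masks), dtype=float) * interval
        return cls(times, cells, nucs, pixel_size=pixel_size)

    # -- raster output -----------------------------------------------------

    def render_masks(self) -> tuple[np.ndarray, np.ndarray]:
        """Render disk masks for all frames; returns (cell, nucleus) stacks."""
        pad = self.cell_radius + 2 * self.pixel_size
        allc = np.vstack([self.cell_centroids, self.nucleus_centroids])
        lo = allc.min(axis=0) - pad
        hi = allc.max(axis=0) + pad
        w = int(np.ceil((hi[0] - lo[0]) / self.pixel_size))
        h = int(np.ceil((hi[1] - lo[1]) / self.pixel_size))
        yy, xx = np.mgrid[0:h, 0:w]
        xs = lo[0] + (xx + 0.5) * self.pixel_size
        ys = lo[1] + (yy + 0.5) * self.pixel_size
        cell = np.zeros((self.n_frames, h, w), dtype=np.uint8)
        nuc = np.zeros_like(cell)
        for i in range(self.n_frames):
            cx, cy = self.cell_centroids[i]
            nx, ny = self.nucleus_centroids[i]
            cell[i] = ((xs - cx) ** 2 + (ys - cy) ** 2
                       <= self.cell_radius**2).astype(np.uint8)
            nuc[i] = ((xs - nx) ** 2 + (ys - ny) ** 2
                      <= self.nucleus_radius**2).astype(np.uint8)
        return cell, nuc

    def to_tiff(self, path) -> None:
        """Write a two-channel (cell, nucleus) multi-page TIFF."""
        import tifffile

        cell, nuc = self.render_masks()
        stack = np.stack([cell, nuc], axis=1) * np.uint8(255)  # (T, C, H, W)
        tifffile.imwrite(str(path), stack, metadata={"axes": "TCYX"})

    def to_csv(self, path) -> None:
        """Write the per-frame centroid track CSV."""
        df = pd.DataFrame({
            "frame": np.arange(self.n_frames),
            "time_min": self.times,
            "cell_cx_um": self.cell_centroids[:, 0],
            "cell_cy_um": self.cell_centroids[:, 1],
            "nuc_cx_um": self.nucleus_centroids[:, 0],
            "nuc_cy_um": self.nucleus_centroids[:, 1],
        })
        df.to_csv(path, index=False)

    def truth_to_json(self, path) -> None:
        """Write the per-step ground-truth sidecar."""
        payload = {
            "step_labels": self.step_labels,
            "step_angles": None if self.step_angles is None
            else list(map(float, self.step_angles)),
            "step_ccd": None if self.step_ccd is None
            else list(map(float, self.step_ccd)),
            "division_times": list(map(float, self.division_times)),
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_csv(cls, path, **kwargs) -> "CellMovie":
        df = pd.read_csv(path)
        return cls(
            times=df["time_min"].to_numpy(),
            cell_centroids=df[["cell_cx_um", "cell_cy_um"]].to_numpy(),
            nucleus_centroids=df[["nuc_cx_um", "nuc_cy_um"]].to_numpy(),
            **kwargs,
        )


def sample_cn_angles(mixture: ActivityMixture, n: int, seed: int,
                     return_labels: bool = False):
    """Draw ``n`` CN polar angles (degrees in [0, 180]) from a mixture.

    Each draw picks an activity by its weight, then a normal deviate around
    that activity's peak angle, reflected into [0, 180].
    """
    if n < 0:
        raise ValueError("n must be non-negative")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(mixture.components), size=n, p=mixture.weights)
    raw = rng.normal(mixture.mean_angles[idx], mixture.sd_angles[idx])
    angles = reflect_angle(raw)
    if return_labels:
        return angles, [mixture.labels[i] for i in idx]
    return angles


# per-activity offset of the step direction relative to the cell's
# polarity heading: side protrusions go orthogonal, retractions backwards
_DIRECTION_OFFSET = {
    "nucleus_forward": 0.0,
    "trailing_edge_detachment": 0.0,
    "simultaneous_de_pro": 0.0,
    "leading_edge_protrusion": 0.0,
    "side_protrusion": 90.0,
    "leading_edge_retraction": 180.0,
}

_MIN_TAN_ANGLE = 1.0  # deg; guards ncd = ccd / tan(angle) near 0/180


def generate_cell_movie(mixture: ActivityMixture,
                        config: MovieGenConfig) -> CellMovie:
    """Simulate a cell + nucleus centroid movie from an activity mixture.

    At each frame interval one activity is drawn from the mixture weights;
    its CN polar angle is drawn around the activity's peak, the CCD
    magnitude from the mixture's log-normal magnitude model, and the
    parallel nuclear displacement follows from the angle
    (``ncd_par = ccd / tan(angle)``), so that, e.g., a trailing-edge
    detachment at exactly 45 deg translates cell and nucleus equally and a
    pure protrusion at 90 deg leaves the nucleus fixed.  The step direction
    follows a slowly drifting polarity heading, with side protrusions
    orthogonal to it and retractions against it.  True per-step labels,
    angles and CCD magnitudes are recorded.
    """
    rng = np.random.default_rng(config.seed)
    n_steps = int(round(config.duration / config.interval))
    times = np.arange(n_steps + 1, dtype=float) * config.interval

    cell = np.zeros((n_steps + 1, 2))
    nuc = np.zeros((n_steps + 1, 2))
    labels: list[str] = []
    true_angles = np.empty(n_steps)
    true_ccd = np.empty(n_steps)

    heading = rng.uniform(0.0, 360.0)
    side_sign = 1.0
    for t in range(n_steps):
        k = rng.choice(len(mixture.components), p=mixture.weights)
        comp = mixture.components[k]
        angle = reflect_angle(rng.normal(comp.mean_angle, comp.sd_angle))
        angle = float(np.clip(angle, _MIN_TAN_ANGLE, 180.0 - _MIN_TAN_ANGLE))
        ccd = mixture.ccd_median * float(
            np.exp(rng.normal(0.0, mixture.ccd_sigma_log)))
        ncd_par = ccd / np.tan(np.deg2rad(angle))

        offset = _DIRECTION_OFFSET[comp.label]
        if comp.label == "side_protrusion":
            side_sign = rng.choice([-1.0, 1.0])
            offset *= side_sign
        step_dir = heading + offset + rng.normal(0.0, config.heading_sd)
        u = np.array([np.cos(np.deg2rad(step_dir)),
                      np.sin(np.deg2rad(step_dir))])

        cell[t + 1] = cell[t] + ccd * u
        nuc[t + 1] = nuc[t] + ncd_par * u
        if config.noise_sd > 0:
            cell[t + 1] += rng.normal(0.0, config.noise_sd, 2)
            nuc[t + 1] += rng.normal(0.0, config.noise_sd, 2)

        heading += rng.normal(0.0, 3.0)  # slow polarity drift
        labels.append(comp.label)
        true_angles[t] = angle
        true_ccd[t] = ccd

    return CellMovie(
        times=times,
        cell_centroids=cell,
        nucleus_centroids=nuc,
        pixel_size=config.pixel_size,
        cell_radius=config.cell_radius,
        nucleus_radius=config.nucleus_radius,
        step_labels=labels,
        step_angles=true_angles,
        step_ccd=true_ccd,
    )


# ---------------------------------------------------------------------------
# cytoskeleton images
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GapSpec:
    """Optional break inserted into one rendered fiber.

    Splits the fiber into two segments separated by ``gap_px`` along the
    fiber axis; the second segment may be rotated and re-scaled in
    intensity/width to probe the reconnection criteria one at a time.
    """

    fiber_index: int = 0
    gap_px: float = 5.0
    angle_offset_deg: float = 0.0
    intensity_ratio: float = 1.0
    width_ratio: float = 1.0


@dataclass
class GroundTruthImage:
    """A synthetic fluorescence field with stored segmentation truth."""

    intensity: np.ndarray                     # 2-D, a.u. >= 0
    cell_mask: np.ndarray                     # 2-D bool
    truth_fibers: list[dict]                  # endpoints (px), width, intensity
    truth_adhesions: list[dict]               # centroid (px), area (px^2)
    pixel_size: float = 0.3                   # µm / px


def _render_segment(img, p0, p1, width, amplitude):
    """Additively render an anti-aliased line segment with a flat-top
    super-Gaussian cross-section of the given full width (px)."""
    h, w = img.shape
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    p0 = np.asarray(p0, float)
    p1 = np.asarray(p1, float)
    d = p1 - p0
    L2 = float(d @ d)
    if L2 == 0:
        return
    t = ((xx - p0[0]) * d[0] + (yy - p0[1]) * d[1]) / L2
    t = np.clip(t, 0.0, 1.0)
    px = p0[0] + t * d[0]
    py = p0[1] + t * d[1]
    dist = np.hypot(xx - px, yy - py)
    img += amplitude * np.exp(-((dist / (width / 2.0 + 1e-9)) ** 4))


def _seg_min_dist(a0, a1, b0, b1):
    """Minimum distance between two segments (coarse sampling)."""
    ta = np.linspace(0, 1, 25)[:, None]
    pa = np.asarray(a0) + ta * (np.asarray(a1) - np.asarray(a0))
    pb = np.asarray(b0) + ta * (np.asarray(b1) - np.asarray(b0))
    return np.min(np.hypot(*(pa[:, None, :] - pb[None, :, :]).T))


def generate_cytoskeleton_image(n_fibers: int, n_adhesions: int,
                                polarity_bias: float = 0.0,
                                gap_spec: GapSpec | None = None,
                                noise_sd: float = 0.0,
                                seed: int = 0,
                                shape: tuple[int, int] = (256, 256),
                                fiber_width: float = 3.0,
                                fiber_intensity: float = 600.0,
                                fiber_length: tuple[float, float] = (50.0, 90.0),
                                adhesion_sigma: float = 2.0,
                                adhesion_intensity: float = 800.0,
                                background: float = 20.0,
                                cytoplasm: float = 60.0,
                                pixel_size: float = 0.3) -> GroundTruthImage:
    """Render a synthetic actin/vinculin-like field with known features.

    Fibers are bright anti-aliased line segments of stated width, adhesions
    are 2-D Gaussian blobs; ``polarity_bias`` in [0, 1] concentrates the
    angular positions of the features about the cell's major axis;
    ``gap_spec`` optionally breaks one fiber into two segments.  Additive
    Gaussian noise of ``noise_sd`` is applied on top of a flat background.
    """
    if n_fibers < 0 or n_adhesions < 0:
        raise ValueError("feature counts must be non-negative")
    if not 0.0 <= polarity_bias <= 1.0:
        raise ValueError("polarity_bias must be in [0, 1]")

    rng = np.random.default_rng(seed)
    h, w = shape
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    a_ax, b_ax = 0.45 * w, 0.32 * h  # ellipse semi-axes, major along x
    yy, xx = np.mgrid[0:h, 0:w]
    cell_mask = ((xx - cx) / a_ax) ** 2 + ((yy - cy) / b_ax) ** 2 <= 1.0

    img = np.zeros(shape, dtype=float)

    def _position_angle():
        # with probability `polarity_bias` cluster about 0/180 deg
        if rng.random() < polarity_bias:
            base = rng.choice([0.0, 180.0])
            return np.deg2rad(base + rng.normal(0.0, 15.0))
        return rng.uniform(0.0, 2 * np.pi)

    # -- fibers ------------------------------------------------------------
    truth_fibers: list[dict] = []
    segments: list[tuple] = []
    attempts = 0
    while len(truth_fibers) < n_fibers and attempts < 2000:
        attempts += 1
        theta = _position_angle()
        r = rng.uniform(0.0, 0.55)
        mid = np.array([cx + r * a_ax * np.cos(theta),
                        cy + r * b_ax * np.sin(theta)])
        length = rng.uniform(*fiber_length)
        ori = theta if rng.random() < polarity_bias else rng.uniform(0, np.pi)
        dvec = 0.5 * length * np.array([np.cos(ori), np.sin(ori)])
        p0, p1 = mid - dvec, mid + dvec
        inside = (((p - [cx, cy]) / [a_ax, b_ax]) @ ((p - [cx, cy]) / [a_ax, b_ax])
                  <= 0.9 for p in (p0, p1))
        if not all(inside):
            continue
        if any(_seg_min_dist(p0, p1, q0, q1) < 8.0 for q0, q1, *_ in segments):
            continue
        segments.append((p0, p1, fiber_width, fiber_intensity))
        truth_fibers.append({
            "endpoints": [p0.tolist(), p1.tolist()],
            "width_px": fiber_width,
            "intensity": fiber_intensity,
            "length_px": float(np.hypot(*(p1 - p0))),
            "orientation_deg": float(np.rad2deg(ori) % 180.0),
        })

    for i, (p0, p1, width, amp) in enumerate(segments):
        if gap_spec is not None and i == gap_spec.fiber_index:
            mid = 0.5 * (p0 + p1)
            u = (p1 - p0) / np.hypot(*(p1 - p0))
            half_gap = gap_spec.gap_px / 2.0
            a1 = mid - half_gap * u
            b0 = mid + half_gap * u
            _render_segment(img, p0, a1, width, amp)
            # second segment, optionally rotated about its start
            phi = np.deg2rad(gap_spec.angle_offset_deg)
            rot = np.array([[np.cos(phi), -np.sin(phi)],
                            [np.sin(phi), np.cos(phi)]])
            b1 = b0 + rot @ (p1 - b0)
            _render_segment(img, b0, b1, width * gap_spec.width_ratio,
                            amp * gap_spec.intensity_ratio)
        else:
            _render_segment(img, p0, p1, width, amp)

    # -- adhesions ---------------------------------------------------------
    truth_adhesions: list[dict] = []
    placed: list[np.ndarray] = []
    attempts = 0
    while len(truth_adhesions) < n_adhesions and attempts < 5000:
        attempts += 1
        theta = _position_angle()
        r = np.sqrt(rng.uniform(0.05, 0.8))
        pos = np.array([cx + r * a_ax * np.cos(theta),
                        cy + r * b_ax * np.sin(theta)])
        if any(np.hypot(*(pos - q)) < 8 * adhesion_sigma for q in placed):
            continue
        placed.append(pos)
        g = np.exp(-(((xx - pos[0]) ** 2 + (yy - pos[1]) ** 2)
                     / (2 * adhesion_sigma**2)))
        img += adhesion_intensity * g
        truth_adhesions.append({
            "centroid": pos.tolist(),
            "angle_rad": float(theta % (2 * np.pi)),
            # area of the half-maximum support
            "area_px2": float(2 * np.pi * np.log(2) * adhesion_sigma**2),
        })

    if n_fibers or n_adhesions or noise_sd or background or cytoplasm:
        img += background
        img[cell_mask] += cytoplasm  # diffuse cytoplasmic signal
    if noise_sd > 0:
        img += rng.normal(0.0, noise_sd, shape)
    img = np.clip(img, 0.0, None)
    img[~cell_mask] = np.clip(img[~cell_mask], 0.0, background + 3 * noise_sd)

    return GroundTruthImage(intensity=img, cell_mask=cell_mask,
                            truth_fibers=truth_fibers,
                            truth_adhesions=truth_adhesions,
                            pixel_size=pixel_size)


# ---------------------------------------------------------------------------
# DNA-content populations
# ---------------------------------------------------------------------------

@dataclass
class DNAPopulation:
    """Per-cell DNA-content intensities with known phase composition."""

    intensities: np.ndarray
    truth_fractions: tuple[float, float, float]   # (G1, S, G2M) in %
    cv: float
    truth_labels: np.ndarray | None = None


def generate_dna_population(truth_fractions, n_cells: int, cv: float,
                            seed: int = 0, mu: float = 100.0) -> DNAPopulation:
    """Simulate a DNA-content population with G1/S/G2M structure.

    G1 cells have content Normal(mu, cv*mu), G2/M cells Normal(2mu, cv*2mu)
    (the same coefficient of variation), and S cells a uniform underlying
    content between mu and 2mu carrying the same relative noise.
    """
    fr = np.asarray(truth_fractions, dtype=float)
    if fr.shape != (3,):
        raise ValueError("truth_fractions must be (G1, S, G2M)")
    if abs(fr.sum() - 100.0) > 1e-6:
        raise ValueError("truth_fractions must sum to 100")
    if cv <= 0:
        raise ValueError("cv must be positive")
    rng = np.random.default_rng(seed)
    counts = rng.multinomial(n_cells, fr / 100.0)
    g1 = rng.normal(mu, cv * mu, counts[0])
    base = rng.uniform(mu, 2 * mu, counts[1])
    s = base * (1.0 + cv * rng.normal(0.0, 1.0, counts[1]))
    g2m = rng.normal(2 * mu, cv * 2 * mu, counts[2])
    vals = np.concatenate([g1, s, g2m])
    labels = np.concatenate([np.zeros(counts[0], int),
                             np.ones(counts[1], int),
                             np.full(counts[2], 2, int)])
    order = rng.permutation(n_cells)
    vals = np.clip(vals[order], 1e-6, None)
    return DNAPopulation(intensities=vals,
                         truth_fractions=tuple(fr),
                         cv=cv,
                         truth_labels=labels[order])


# ---------------------------------------------------------------------------
# phenotype time courses
# ---------------------------------------------------------------------------

def generate_phenotype_series(n_frames: int, boundaries: tuple[int, int],
                              levels, noise_sd: float = 0.0, seed: int = 0,
                              n_params: int = 4) -> np.ndarray:
    """Piecewise-constant multi-parameter series with three true periods.

    ``levels`` is either a (3,) sequence shared by all parameters or a
    (n_params, 3) array of per-period means.  Returns an array of shape
    (n_frames, n_params).
    """
    b1, b2 = boundaries
    if not 0 < b1 < b2 < n_frames:
        raise ValueError("boundaries must satisfy 0 < b1 < b2 < n_frames")
    levels = np.atleast_2d(np.asarray(levels, dtype=float))
    if levels.shape[0] == 1:
        levels = np.repeat(levels, n_params, axis=0)
    rng = np.random.default_rng(seed)
    out = np.empty((n_frames, levels.shape[0]))
    seg = np.zeros(n_frames, dtype=int)
    seg[b1:b2] = 1
    seg[b2:] = 2
    for j in range(levels.shape[0]):
        out[:, j] = levels[j, seg]
        if noise_sd > 0:
            out[:, j] += rng.normal(0.0, noise_sd, n_frames)
    return out


def generate_division_cohort(n_movies: int, cycle_h: float = 18.0,
                             span_h: float = 20.0, seed: int = 0):
    """Division-event times (hours) for a cohort plus a two-division reference.

    Each movie spans ``span_h`` hours and records one division at a random
    offset; the reference movie contains two consecutive divisions one cell
    cycle apart.
    """
    rng = np.random.default_rng(seed)
    reference = [rng.uniform(0.5, span_h - cycle_h - 0.5)]
    reference.append(reference[0] + cycle_h)
    cohort = [[float(rng.uniform(0.2, span_h - 0.2))] for _ in range(n_movies)]
    return cohort, [float(t) for t in reference]
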