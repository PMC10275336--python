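"""Synthetic nerve-phantom generator.

Produces reproducible microCT-like image stacks with paired ground-truth
fascicle and epineurium masks. The phantoms mimic the statistical structure
of osmium-stained peripheral-nerve microCT: bright, roughly convex fascicle
blobs inside a dimmer epineurium ellipse on a dark background, per-slice
brightness drift, rare very-bright staining-artifact specks (16-bit values
above 18,000), a fascicle pixel fraction near 5% of the frame, fascicle
cross-sections spanning the tiny/small/medium/large size classes, and
occasional fascicle merge/split events along the stack axis.

The generator is an anatomy-free stand-in for real data: it reproduces the
topology and intensity ordering that the downstream pipeline depends on, not
vagus-nerve morphometry.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter1d
from skimage.draw import ellipse as draw_ellipse
from skimage.draw import polygon as draw_polygon

__all__ = ["SynthParams", "NerveStack", "generate_stack", "generate_edge_case_slice"]

# Size-class boundaries in um^2 (see fasciseg.metrics.SizeClass); used here only
# to stratify sampled fascicle areas so a default stack exercises every class.
_BIN_EDGES_UM2 = (0.0, 20_000.0, 90_000.0, 300_000.0, np.inf)


@dataclass(frozen=True)
class SynthParams:
    """Parameters of a synthetic nerve stack.

    Defaults describe a frame of 512 x 512 pixels at 10 um in-plane spacing
    and 100 um between slices, with ~5% of pixels belonging to fascicles.

    Attributes
    ----------
    image_size : int
        Pixels per side of the (square) frame.
    n_slices : int
        Number of slices along the nerve axis.
    n_fascicles : int
        Number of fascicle instances threaded through the stack.
    fascicle_area_range : (float, float)
        Minimum/maximum fascicle cross-section area in um^2. The default
        spans all four size classes (tiny < 20,000 to large > 300,000 um^2).
    target_fascicle_fraction : float
        Desired mean fraction of fascicle pixels per slice, in (0, 0.5).
    artifact_density : float
        Expected number of bright staining-artifact specks per slice.
    artifact_value_range : (int, int)
        16-bit intensity range of artifact specks; the range must contain
        values above 18,000 so the saturation rule is exercised.
    brightness_drift : (float, float)
        Per-slice multiplicative brightness range (relative to 1).
    merge_split_rate : float
        Expected fascicle merge/split events per mm of nerve length.
    pixel_spacing : float
        In-plane pixel size, um.
    slice_spacing : float
        Distance between slices, um.
    seed : int
        Seed of the single RNG stream driving the whole stack.
    """

    image_size: int = 512
    n_slices: int = 100
    n_fascicles: int = 12
    fascicle_area_range: tuple[float, float] = (5_000.0, 600_000.0)
    target_fascicle_fraction: float = 0.05
    artifact_density: float = 1.5
    artifact_value_range: tuple[int, int] = (19_000, 30_000)
    brightness_drift: tuple[float, float] = (0.9, 1.1)
    merge_split_rate: float = 0.5
    pixel_spacing: float = 10.0
    slice_spacing: float = 100.0
    seed: int = 0
    # Intensity model (free parameters of the phantom, 16-bit scale).
    intensity_background: float = 3_000.0
    intensity_epineurium: float = 7_000.0
    intensity_fascicle: float = 12_000.0
    noise_std: float = 250.0

    def validate(self) -> None:
        """Raise ``ValueError`` naming the offending field if invalid."""
        if self.image_size < 32:
            raise ValueError(f"image_size must be >= 32, got {self.image_size}")
        if self.n_slices < 1:
            raise ValueError(f"n_slices must be positive, got {self.n_slices}")
        if self.n_fascicles < 1:
            raise ValueError(f"n_fascicles must be positive, got {self.n_fascicles}")
        lo, hi = self.fascicle_area_range
        if not (0 < lo <= hi):
            raise ValueError(f"fascicle_area_range must be ordered positive, got {self.fascicle_area_range}")
        if not (0.0 < self.target_fascicle_fraction < 0.5):
            raise ValueError(
                f"target_fascicle_fraction must lie in (0, 0.5), got {self.target_fascicle_fraction}"
            )
        if self.artifact_density < 0:
            raise ValueError(f"artifact_density must be nonnegative, got {self.artifact_density}")
        alo, ahi = self.artifact_value_range
        if not (0 < alo <= ahi <= 65535):
            raise ValueError(f"artifact_value_range must be ordered within (0, 65535], got {self.artifact_value_range}")
        if ahi <= 18_000:
            raise ValueError(
                f"artifact_value_range must include values above 18,000, got {self.artifact_value_range}"
            )
        blo, bhi = self.brightness_drift
        if not (0 < blo <= bhi):
            raise ValueError(f"brightness_drift must be ordered positive, got {self.brightness_drift}")
        if self.merge_split_rate < 0:
            raise ValueError(f"merge_split_rate must be nonnegative, got {self.merge_split_rate}")
        if self.pixel_spacing <= 0:
            raise ValueError(f"pixel_spacing must be positive, got {self.pixel_spacing}")
        if self.slice_spacing <= 0:
            raise ValueError(f"slice_spacing must be positive, got {self.slice_spacing}")

    def to_dict(self) -> dict:
        return {
            "image_size": self.image_size,
            "n_slices": self.n_slices,
            "n_fascicles": self.n_fascicles,
            "fascicle_area_range": list(self.fascicle_area_range),
            "target_fascicle_fraction": self.target_fascicle_fraction,
            "artifact_density": self.artifact_density,
            "artifact_value_range": list(self.artifact_value_range),
            "brightness_drift": list(self.brightness_drift),
            "merge_split_rate": self.merge_split_rate,
            "pixel_spacing": self.pixel_spacing,
            "slice_spacing": self.slice_spacing,
            "seed": self.seed,
            "intensity_background": self.intensity_background,
            "intensity_epineurium": self.intensity_epineurium,
            "intensity_fascicle": self.intensity_fascicle,
            "noise_std": self.noise_std,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SynthParams":
        d = dict(d)
        for key in ("fascicle_area_range", "artifact_value_range", "brightness_drift"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def desk_scale(cls, seed: int = 0, **overrides) -> "SynthParams":
        """A small, easy phantom preset (128 px frames) for CPU-scale training."""
        base = dict(
            image_size=128,
            n_slices=20,
            n_fascicles=4,
            fascicle_area_range=(5_000.0, 60_000.0),
            target_fascicle_fraction=0.05,
            artifact_density=0.3,
            brightness_drift=(0.95, 1.05),
            merge_split_rate=0.0,
            noise_std=150.0,
            seed=seed,
        )
        base.update(overrides)
        return cls(**base)


@dataclass
class NerveStack:
    """A nerve's image stack with paired ground-truth masks.

    ``images`` is an ``(n_slices, H, W)`` uint16 array; ``fascicle_masks``
    and ``epineurium_masks`` are boolean arrays of the same shape. Ground
    truth satisfies fascicle ⊆ epineurium on every slice.
    """

    nerve_id: str
    images: np.ndarray
    fascicle_masks: np.ndarray
    epineurium_masks: np.ndarray
    pixel_spacing: float = 10.0
    slice_spacing: float = 100.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.images = np.asarray(self.images)
        self.fascicle_masks = np.asarray(self.fascicle_masks, dtype=bool)
        self.epineurium_masks = np.asarray(self.epineurium_masks, dtype=bool)
        if self.images.ndim != 3:
            raise ValueError(f"images must be (n_slices, H, W), got shape {self.images.shape}")
        if self.fascicle_masks.shape != self.images.shape:
            raise ValueError(
                f"fascicle_masks shape {self.fascicle_masks.shape} does not match images {self.images.shape}"
            )
        if self.epineurium_masks.shape != self.images.shape:
            raise ValueError(
                f"epineurium_masks shape {self.epineurium_masks.shape} does not match images {self.images.shape}"
            )

    @property
    def n_slices(self) -> int:
        return self.images.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.images.shape[1], self.images.shape[2]

    def fascicle_fraction(self) -> float:
        """Mean fraction of fascicle pixels per slice."""
        return float(self.fascicle_masks.mean())


def _sample_fascicle_areas(params: SynthParams, rng: np.random.Generator) -> np.ndarray:
    """Sample per-fascicle target areas (um^2), stratified across size classes.

    Fascicles are assigned to size classes cycling large -> medium -> small ->
    tiny -> small -> tiny ... so that a default stack covers every class while
    keeping most instances small (as in real nerves). Sampled areas are then
    rescaled so the total pixel area matches ``target_fascicle_fraction``,
    with each area clamped to stay inside its assigned class.
    """
    lo, hi = params.fascicle_area_range
    target_total = params.target_fascicle_fraction * params.image_size**2 * params.pixel_spacing**2
    cycle = [3, 2, 1, 0, 1, 0]  # indices into _BIN_EDGES_UM2 intervals, 0 = tiny
    bins = []
    for k in range(params.n_fascicles):
        b = cycle[k % len(cycle)]
        blo = max(_BIN_EDGES_UM2[b], lo)
        bhi = min(_BIN_EDGES_UM2[b + 1], hi)
        # a class is feasible only if it fits the range and a single instance
        # would not eat more than half the total area budget (small frames)
        if blo >= bhi or blo > 0.5 * target_total:
            blo, bhi = lo, min(hi, max(0.5 * target_total, lo * 1.5))
            b = None
        bins.append((b, blo, bhi))
    # Log-uniform draw, shrunk 5% inside the class edges to survive rescaling.
    areas = np.empty(params.n_fascicles)
    for k, (b, blo, bhi) in enumerate(bins):
        llo, lhi = np.log(blo), np.log(min(bhi, hi))
        margin = 0.05 * (lhi - llo)
        areas[k] = np.exp(rng.uniform(llo + margin, lhi - margin))
    areas *= target_total / areas.sum()
    # Clamp back into the assigned class so stratification survives; fallback
    # slots (b is None) clamp to their relaxed range only.
    for k, (b, blo, bhi) in enumerate(bins):
        if b is None:
            areas[k] = np.clip(areas[k], blo, bhi)
        else:
            areas[k] = np.clip(areas[k], blo * 1.02 if blo > 0 else lo, bhi * 0.98 if np.isfinite(bhi) else hi)
    # Push any residual onto the largest fascicle (its class is open above).
    residual = target_total - areas.sum()
    j = int(np.argmax(areas))
    areas[j] = np.clip(areas[j] + residual, lo, hi)
    return areas


def _place_centers(
    radii: np.ndarray,
    ellipse_center: np.ndarray,
    ellipse_axes: np.ndarray,
    gap: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Rejection-sample fascicle centers inside the epineurium ellipse.

    Centers keep pairwise distance >= r_i + r_j + gap and stay at least
    r_i + 2 px inside the ellipse, so blobs neither touch each other nor the
    epineurium boundary unless a merge event moves them deliberately.
    """
    n = len(radii)
    order = np.argsort(radii)[::-1]  # place big ones first
    centers = np.full((n, 2), np.nan)
    for attempt in range(200):
        g = gap * (0.5 ** (attempt // 40))  # relax the gap if placement is tight
        ok = True
        for idx in order:
            placed = False
            for _ in range(400):
                u = rng.uniform(0, 2 * np.pi)
                rad = np.sqrt(rng.uniform(0, 1))
                shrink = np.maximum(ellipse_axes - (radii[idx] + 2.0 + g / 2), 1.0)
                cand = ellipse_center + rad * shrink * np.array([np.sin(u), np.cos(u)])
                good = True
                for jdx in order:
                    if jdx == idx or np.isnan(centers[jdx, 0]):
                        continue
                    if np.linalg.norm(cand - centers[jdx]) < radii[idx] + radii[jdx] + g:
                        good = False
                        break
                if good:
                    centers[idx] = cand
                    placed = True
                    break
            if not placed:
                ok = False
                centers[:] = np.nan
                break
        if ok:
            return centers
    raise ValueError(
        "could not place fascicles: n_fascicles/target_fascicle_fraction too large for image_size"
    )


def _blob_shape(rng: np.random.Generator, n_theta: int = 64) -> np.ndarray:
    """Radial modulation r(theta)/r of a smooth, star-shaped fascicle blob."""
    theta = np.linspace(0.0, 2 * np.pi, n_theta, endpoint=False)
    mod = np.ones(n_theta)
    for h in (2, 3, 4, 5):
        amp = rng.normal(0.0, 0.035)
        phase = rng.uniform(0, 2 * np.pi)
        mod += amp * np.cos(h * theta + phase)
    return np.clip(mod, 0.85, 1.15)


def _smooth_walk(n: int, step_std: float, cap: float, rng: np.random.Generator) -> np.ndarray:
    """A smooth zero-start random walk along z, capped in amplitude."""
    if n == 1:
        return np.zeros((1, 2))
    steps = rng.normal(0.0, step_std, size=(n, 2))
    walk = np.cumsum(steps, axis=0)
    walk -= walk[0]
    walk = gaussian_filter1d(walk, sigma=3.0, axis=0)
    amp = np.abs(walk).max()
    if amp > cap > 0:
        walk *= cap / amp
    return walk


def generate_stack(params: SynthParams, nerve_id: str = "synth") -> NerveStack:
    """Generate a deterministic synthetic nerve stack.

    Given identical ``params`` (including ``seed``) the output is
    bit-identical. Fascicle blobs are brighter than the epineurium, which is
    brighter than the background; staining-artifact specks exceed 18,000;
    when ``merge_split_rate > 0`` at least one fascicle pair merges and
    splits again along the stack axis.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    n, size = params.n_slices, params.image_size

    # --- epineurium geometry -------------------------------------------------
    ell_center = np.array([size / 2, size / 2]) + rng.uniform(-0.01 * size, 0.01 * size, size=2)
    ell_axes = np.array([rng.uniform(0.33, 0.36), rng.uniform(0.38, 0.41)]) * size
    if rng.random() < 0.5:
        ell_axes = ell_axes[::-1]
    ell_drift = _smooth_walk(n, 0.4, 0.02 * size, rng)

    # --- fascicle geometry ---------------------------------------------------
    areas_um2 = _sample_fascicle_areas(params, rng)
    radii_px = np.sqrt(areas_um2 / np.pi) / params.pixel_spacing
    # Effective radii include the boundary-modulation headroom (<= 1.15x).
    r_eff = radii_px * 1.15
    gap = max(4.0, 0.015 * size)
    centers = _place_centers(r_eff, ell_center, ell_axes, gap, rng)
    shapes = [_blob_shape(rng) for _ in range(params.n_fascicles)]
    drift_cap = gap / 2 - 1.0
    drifts = np.stack([_smooth_walk(n, 0.5, max(drift_cap, 0.0), rng) for _ in range(params.n_fascicles)])
    # mild smooth radius variation along z (+-5%)
    rvar = np.stack(
        [1.0 + _smooth_walk(n, 0.02, 0.05, rng)[:, 0] for _ in range(params.n_fascicles)]
    )

    # --- merge/split schedule ------------------------------------------------
    length_mm = n * params.slice_spacing / 1000.0
    events: list[tuple[int, int, int, int]] = []  # (i, j, z0, half_width)
    if params.merge_split_rate > 0 and params.n_fascicles >= 2 and n >= 5:
        n_events = max(1, int(rng.poisson(params.merge_split_rate * length_mm)))
        # candidate pairs sorted by proximity; events reuse pairs if needed
        d = np.linalg.norm(centers[:, None, :] - centers[None, :, :], axis=-1)
        iu, ju = np.triu_indices(params.n_fascicles, k=1)
        pair_order = np.argsort(d[iu, ju])
        half_w = max(2, int(round(0.25 / (params.slice_spacing / 1000.0))))  # ~0.25 mm half-width
        for e in range(n_events):
            pi = pair_order[e % len(pair_order)]
            z0 = int(rng.integers(half_w, max(n - half_w, half_w + 1)))
            events.append((int(iu[pi]), int(ju[pi]), z0, half_w))

    # per-slice, per-fascicle pull toward the event partner (0..1)
    pull = np.zeros((n, params.n_fascicles, 2))
    for i, j, z0, hw in events:
        zz = np.arange(n)
        w = np.clip(1.0 - np.abs(zz - z0) / hw, 0.0, 1.0)  # triangular window
        mid = (centers[i] + centers[j]) / 2
        # at w=1 the two centers sit 0.5*(r_i+r_j) apart -> guaranteed overlap
        target_half = 0.25 * (radii_px[i] + radii_px[j])
        axis = centers[j] - centers[i]
        axis_n = axis / max(np.linalg.norm(axis), 1e-9)
        goal_i = mid - axis_n * target_half
        goal_j = mid + axis_n * target_half
        pull[:, i, :] += w[:, None] * (goal_i - centers[i])[None, :]
        pull[:, j, :] += w[:, None] * (goal_j - centers[j])[None, :]

    # --- rasterize -----------------------------------------------------------
    images = np.empty((n, size, size), dtype=np.uint16)
    fasc_masks = np.zeros((n, size, size), dtype=bool)
    epi_masks = np.zeros((n, size, size), dtype=bool)
    theta = np.linspace(0.0, 2 * np.pi, 64, endpoint=False)
    sin_t, cos_t = np.sin(theta), np.cos(theta)

    brightness = rng.uniform(params.brightness_drift[0], params.brightness_drift[1], size=n)
    n_artifacts = rng.poisson(params.artifact_density, size=n) if params.artifact_density > 0 else np.zeros(n, int)
    if params.artifact_density > 0 and n_artifacts.sum() == 0:
        n_artifacts[rng.integers(0, n)] = 1

    for z in range(n):
        ec = ell_center + ell_drift[z]
        rr, cc = draw_ellipse(ec[0], ec[1], ell_axes[0], ell_axes[1], shape=(size, size))
        epi = np.zeros((size, size), dtype=bool)
        epi[rr, cc] = True
        fasc = np.zeros((size, size), dtype=bool)
        for k in range(params.n_fascicles):
            c = centers[k] + drifts[k, z] + pull[z, k]
            rad = radii_px[k] * rvar[k, z] * shapes[k]
            rows = c[0] + rad * sin_t
            cols = c[1] + rad * cos_t
            pr, pc = draw_polygon(rows, cols, shape=(size, size))
            fasc[pr, pc] = True
        fasc &= epi  # ground-truth containment
        img = np.full((size, size), params.intensity_background, dtype=np.float64)
        img[epi] = params.intensity_epineurium
        img[fasc] = params.intensity_fascicle
        img *= brightness[z]
        img += rng.normal(0.0, params.noise_std, size=(size, size))
        for _ in range(int(n_artifacts[z])):
            ar = int(rng.integers(1, size - 1))
            ac = int(rng.integers(1, size - 1))
            aval = float(rng.uniform(params.artifact_value_range[0], params.artifact_value_range[1]))
            arr, acc = draw_ellipse(ar, ac, rng.integers(1, 3), rng.integers(1, 3), shape=(size, size))
            img[arr, acc] = aval
        images[z] = np.clip(img, 0, 65535).astype(np.uint16)
        fasc_masks[z] = fasc
        epi_masks[z] = epi

    return NerveStack(
        nerve_id=nerve_id,
        images=images,
        fascicle_masks=fasc_masks,
        epineurium_masks=epi_masks,
        pixel_spacing=params.pixel_spacing,
        slice_spacing=params.slice_spacing,
        meta={"params": params.to_dict(), "n_merge_split_events": len(events)},
    )


_EDGE_KINDS = (
    "empty",
    "single_pixel_fascicle",
    "fascicle_touching_border",
    "epineurium_touching_border",
    "all_saturated",
)


def generate_edge_case_slice(kind: str, size: int = 64) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Return an ``(image, fascicle_mask, epineurium_mask)`` triple exhibiting
    exactly the named degeneracy.

    Kinds: ``empty`` (no fascicle pixels), ``single_pixel_fascicle``,
    ``fascicle_touching_border``, ``epineurium_touching_border``,
    ``all_saturated`` (every image value above the 18,000 saturation rule).
    """
    if kind not in _EDGE_KINDS:
        raise ValueError(f"unknown edge-case kind {kind!r}; expected one of {_EDGE_KINDS}")
    c = size // 2
    image = np.full((size, size), 3000, dtype=np.uint16)
    fasc = np.zeros((size, size), dtype=bool)
    epi = np.zeros((size, size), dtype=bool)

    def disk(center, radius):
        rr, cc = draw_ellipse(center[0], center[1], radius, radius, shape=(size, size))
        m = np.zeros((size, size), dtype=bool)
        m[rr, cc] = True
        return m

    if kind == "empty":
        epi = disk((c, c), size // 3)
    elif kind == "single_pixel_fascicle":
        epi = disk((c, c), size // 3)
        fasc[c, c] = True
    elif kind == "fascicle_touching_border":
        epi = disk((c, 2), size // 3)  # spills over the left edge
        fasc = disk((c, 1), 4) & epi
        if not fasc[:, 0].any():
            fasc[c, 0] = True
            epi[c, 0] = True
    elif kind == "epineurium_touching_border":
        epi = disk((c, 2), size // 3)
        fasc = disk((c, size // 4), 4) & epi
    elif kind == "all_saturated":
        image[:] = 65535
        epi = disk((c, c), size // 3)
        fasc = disk((c, c), size // 8)

    image[epi] = np.uint16(7000)
    image[fasc] = np.uint16(12000)
    if kind == "all_saturated":
        image[:] = 65535
    return image, fasc, epi
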