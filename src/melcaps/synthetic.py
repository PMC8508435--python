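"""Seeded generator of two-class lesion-like RGB images.

The generator embodies the clinical ABCD cues that separate melanoma from
benign nevi — Asymmetry, Border irregularity, Color variegation — as
explicit generative parameters of a radial-harmonic blob composited over a
skin-tone background:

* the boundary is ``r(theta) = R * (1 + sum_k a_k sin(k theta + phi_k))``,
  so the harmonic amplitudes control border irregularity;
* one half of the lesion is radially inflated by ``asymmetry_shift``;
* pigment patches (angular sectors in typical lesion browns/blacks/reds)
  control colour variegation.

Nevi draw all three from low ranges, melanomas from high ranges; a
``difficulty`` knob linearly interpolates the melanoma ranges onto the
nevus ranges (0 = disjoint ranges, 1 = indistinguishable classes).  Every
image is a pure function of the dataset spec (including its seed).

These are deliberately synthetic stand-ins for dermoscopy data: no hair,
rulers, specular highlights or acquisition artefacts are simulated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import LabeledImageSet

__all__ = [
    "LesionParams",
    "SyntheticDatasetSpec",
    "sample_lesion_params",
    "render_lesion",
    "generate_dataset",
    "measure_boundary_radii",
    "asymmetry_statistic",
]

# (low-range for nevus, high-range for melanoma); difficulty interpolates
# the melanoma range onto the nevus range.
_RANGES = {
    "amp_total": ((0.0, 0.04), (0.12, 0.22)),  # sum of border-harmonic amplitudes
    "n_harmonics": ((0, 2), (3, 5)),
    "asymmetry": ((0.0, 0.05), (0.15, 0.30)),
    "n_patches": ((0, 1), (3, 6)),
}

_SKIN_TONES = np.array(
    [[0.95, 0.80, 0.72], [0.87, 0.68, 0.55], [0.80, 0.60, 0.48], [0.72, 0.54, 0.44]]
)
_NEVUS_BASE = np.array([0.58, 0.42, 0.30])
_MELANOMA_BASE = np.array([0.45, 0.30, 0.22])
# patch palettes: light/medium browns for nevi; dark browns, black-ish,
# red and blue-grey zones for melanoma
_NEVUS_PALETTE = np.array([[0.62, 0.45, 0.32], [0.50, 0.36, 0.26]])
_MELANOMA_PALETTE = np.array(
    [[0.25, 0.15, 0.12], [0.10, 0.08, 0.08], [0.55, 0.15, 0.12], [0.35, 0.35, 0.45], [0.30, 0.18, 0.10]]
)


@dataclass
class LesionParams:
    """Generative parameters of one lesion."""

    label: int  # 0 = nevus, 1 = melanoma
    center: tuple[float, float]  # (x, y) pixels
    base_radius: float  # pixels
    border_harmonics: list[tuple[int, float, float]] = field(default_factory=list)  # (k, a_k, phi_k)
    asymmetry_shift: float = 0.0
    color_patches: list[tuple[tuple[float, float, float], tuple[float, float]]] = field(
        default_factory=list
    )  # (rgb, (theta0, theta1))
    base_color: tuple[float, float, float] = tuple(_NEVUS_BASE)
    background_tone: tuple[float, float, float] = tuple(_SKIN_TONES[0])

    def max_radius(self) -> float:
        amp = sum(a for _, a, _ in self.border_harmonics)
        return self.base_radius * (1.0 + amp) * (1.0 + self.asymmetry_shift)


@dataclass(frozen=True)
class SyntheticDatasetSpec:
    """Conditions of one synthetic study: size, difficulty, noise, seed."""

    n_per_class: int = 100
    image_size: tuple[int, int] = (96, 96)
    difficulty: float = 0.0
    noise_sd: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_class < 1:
            raise ValueError("n_per_class must be >= 1")
        if min(self.image_size) < 32:
            raise ValueError("image_size must be at least 32 px")
        if not 0.0 <= self.difficulty <= 1.0:
            raise ValueError("difficulty must lie in [0, 1]")


def _interp_range(key: str, label: int, difficulty: float) -> tuple[float, float]:
    lo_rng, hi_rng = _RANGES[key]
    if label == 0:
        return float(lo_rng[0]), float(lo_rng[1])
    lo = hi_rng[0] + difficulty * (lo_rng[0] - hi_rng[0])
    hi = hi_rng[1] + difficulty * (lo_rng[1] - hi_rng[1])
    return float(lo), float(hi)


def sample_lesion_params(
    label: int, spec: SyntheticDatasetSpec, draw_seed: int
) -> LesionParams:
    """Draw one lesion's parameters from its class ranges (deterministic)."""
    rng = np.random.default_rng([spec.seed & 0x7FFFFFFF, int(label), draw_seed & 0x7FFFFFFF])
    h, w = spec.image_size
    side = min(h, w)

    base_radius = rng.uniform(0.18, 0.24) * side
    cx = w / 2 + rng.uniform(-0.03, 0.03) * w
    cy = h / 2 + rng.uniform(-0.03, 0.03) * h

    amp_lo, amp_hi = _interp_range("amp_total", label, spec.difficulty)
    amp_total = rng.uniform(amp_lo, amp_hi)
    nh_lo, nh_hi = _interp_range("n_harmonics", label, spec.difficulty)
    n_harm = int(round(rng.uniform(nh_lo, nh_hi)))
    harmonics: list[tuple[int, float, float]] = []
    if n_harm > 0 and amp_total > 0:
        weights = rng.dirichlet(np.ones(n_harm))
        ks = rng.choice(np.arange(2, 9), size=n_harm, replace=False)
        harmonics = [
            (int(k), float(amp_total * wgt), float(rng.uniform(0, 2 * np.pi)))
            for k, wgt in zip(ks, weights)
        ]

    asy_lo, asy_hi = _interp_range("asymmetry", label, spec.difficulty)
    asymmetry = rng.uniform(asy_lo, asy_hi)

    np_lo, np_hi = _interp_range("n_patches", label, spec.difficulty)
    n_patches = int(round(rng.uniform(np_lo, np_hi)))
    palette = _MELANOMA_PALETTE if label == 1 else _NEVUS_PALETTE
    patches = []
    for _ in range(n_patches):
        color = palette[rng.integers(len(palette))] + rng.uniform(-0.03, 0.03, 3)
        t0 = rng.uniform(0, 2 * np.pi)
        t1 = t0 + rng.uniform(0.4, 1.5)
        patches.append((tuple(np.clip(color, 0, 1)), (float(t0), float(t1))))

    base = _MELANOMA_BASE if label == 1 else _NEVUS_BASE
    base = np.clip(base + rng.uniform(-0.05, 0.05, 3), 0, 1)
    tone = _SKIN_TONES[rng.integers(len(_SKIN_TONES))] + rng.uniform(-0.03, 0.03, 3)

    return LesionParams(
        label=int(label),
        center=(float(cx), float(cy)),
        base_radius=float(base_radius),
        border_harmonics=harmonics,
        asymmetry_shift=float(asymmetry),
        color_patches=patches,
        base_color=tuple(base),
        background_tone=tuple(np.clip(tone, 0, 1)),
    )


def _radius_at(params: LesionParams, theta: np.ndarray) -> np.ndarray:
    r = np.full_like(theta, params.base_radius, dtype=float)
    for k, a, phi in params.border_harmonics:
        r += params.base_radius * a * np.sin(k * theta + phi)
    # displace the upper half (theta in (0, pi)) outward
    r *= np.where((theta > 0) & (theta < np.pi), 1.0 + params.asymmetry_shift, 1.0)
    return r


def render_lesion(
    params: LesionParams,
    image_size: tuple[int, int],
    noise_sd: float = 0.0,
    noise_seed: int = 0,
) -> np.ndarray:
    """Rasterise one lesion over its background tone.

    The radial-harmonic boundary is drawn with a one-pixel soft edge,
    pigment patches fill their angular sectors, and clipped Gaussian pixel
    noise is added last.  Raises if the lesion does not fit in the frame.
    """
    h, w = image_size
    cx, cy = params.center
    margin = params.max_radius()
    if cx - margin < 0 or cx + margin > w or cy - margin < 0 or cy + margin > h:
        raise ValueError("lesion exceeds the image frame")

    yy, xx = np.mgrid[0:h, 0:w]
    dx, dy = xx - cx, yy - cy
    rr = np.hypot(dx, dy)
    theta = np.mod(np.arctan2(dy, dx), 2 * np.pi)
    boundary = _radius_at(params, theta)

    # soft 1-px edge: 1 inside, 0 outside
    alpha = np.clip(boundary - rr + 0.5, 0.0, 1.0)

    img = np.empty((h, w, 3))
    img[:] = params.background_tone
    lesion = np.empty((h, w, 3))
    lesion[:] = params.base_color
    for color, (t0, t1) in params.color_patches:
        span = (t1 - t0) % (2 * np.pi)
        in_sector = ((theta - t0) % (2 * np.pi)) <= span
        lesion[in_sector] = color
    img = img * (1 - alpha[..., None]) + lesion * alpha[..., None]

    if noise_sd > 0:
        rng = np.random.default_rng(noise_seed & 0x7FFFFFFF)
        img = img + rng.normal(0.0, noise_sd, img.shape)
    return np.clip(img, 0.0, 1.0)


def generate_dataset(spec: SyntheticDatasetSpec) -> LabeledImageSet:
    """Generate ``2 * n_per_class`` images (labels balanced by construction)."""
    images, labels, ids = [], [], []
    for label, prefix in ((0, "nevus"), (1, "melanoma")):
        for i in range(spec.n_per_class):
            params = sample_lesion_params(label, spec, i)
            noise_seed = spec.seed * 100003 + label * 50001 + i
            images.append(
                render_lesion(params, spec.image_size, spec.noise_sd, noise_seed)
            )
            labels.append(label)
            ids.append(f"{prefix}_{i:04d}")
    return LabeledImageSet(images=images, labels=np.asarray(labels), ids=ids)


# -- diagnostics used by the validation suite ------------------------------


def measure_boundary_radii(
    image_or_mask: np.ndarray,
    center: tuple[float, float],
    n_angles: int = 360,
    background_tone: tuple[float, float, float] | None = None,
) -> np.ndarray:
    """Measured lesion radius along rays from the center.

    Accepts either a boolean lesion mask or an RGB image plus its
    background tone (pixels further than 0.08 RGB distance from the tone
    count as lesion).
    """
    if image_or_mask.ndim == 3:
        if background_tone is None:
            raise ValueError("background_tone required for RGB input")
        mask = np.linalg.norm(image_or_mask - np.asarray(background_tone), axis=-1) > 0.08
    else:
        mask = image_or_mask.astype(bool)
    h, w = mask.shape
    cx, cy = center
    max_r = int(min(h, w) / 2)
    radii = np.zeros(n_angles)
    ts = np.linspace(0, 2 * np.pi, n_angles, endpoint=False)
    rs = np.arange(1, max_r)
    for i, t in enumerate(ts):
        xs = np.clip(np.round(cx + rs * np.cos(t)).astype(int), 0, w - 1)
        ys = np.clip(np.round(cy + rs * np.sin(t)).astype(int), 0, h - 1)
        on = mask[ys, xs]
        radii[i] = rs[on.nonzero()[0].max()] if on.any() else 0.0
    return radii


def asymmetry_statistic(image: np.ndarray) -> float:
    """Hand-crafted asymmetry cue: lesion mass that fails to overlap the
    lesion's reflection about its centroid row, as a fraction of the total.

    Pixels deviating from the corner-estimated background tone count as
    lesion (isolated noise pixels are removed by a binary opening).  A
    vertically symmetric disc scores ~0; a lesion whose lower half is
    radially inflated by (1 + s) scores on the order of s.
    """
    from scipy.ndimage import binary_opening

    img = np.asarray(image, dtype=float)
    corners = np.concatenate(
        [img[:4, :4].reshape(-1, 3), img[:4, -4:].reshape(-1, 3),
         img[-4:, :4].reshape(-1, 3), img[-4:, -4:].reshape(-1, 3)]
    )
    tone = corners.mean(axis=0)
    mask = np.linalg.norm(img - tone, axis=-1) > 0.08
    mask = binary_opening(mask, structure=np.ones((2, 2)))
    if not mask.any():
        return 0.0
    h = mask.shape[0]
    yc = np.nonzero(mask)[0].mean()
    src = np.round(2 * yc - np.arange(h)).astype(int)
    reflected = np.zeros_like(mask)
    valid = (src >= 0) & (src < h)
    reflected[valid] = mask[src[valid]]
    return float((mask ^ reflected).sum()) / (2.0 * mask.sum())
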