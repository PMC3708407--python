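"""Seeded generator of labeled nodule / non-nodule image patches.

The generator emulates the structure of a small clinical patch dataset:
95 nodule and 75 non-nodule patterns, nodules being roughly compact blobs
with equivalent diameters drawn from a truncated normal (mean 6.42 mm,
SD 3.00 mm, support [2, 20] mm), non-nodules being elongated, slightly
curved vessel-like structures.  Shapes are generated in physical mm and
rasterized at the configured pixel spacing (default 0.7 mm), so the
diameter distribution is independent of the patch size.

``class_separation`` in [0, 1] controls how distinguishable the two class
shape distributions are: at 1, non-nodules are strongly elongated and bent;
at 0, both classes are drawn from the same compact-blob distribution, so
labels carry no information and downstream accuracy sits at chance level.

The intensity model is deliberately simple — a smooth falloff from the
shape core plus additive Gaussian noise — because the discriminative signal
of the classification approach is shape-dominated.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np

from .patterns import Pattern, PatternSet


@dataclasses.dataclass
class GeneratorConfig:
    """Study-condition defaults for the synthetic patch generator."""

    n_nodule: int = 95
    n_nonnodule: int = 75
    pixel_spacing_mm: float = 0.7
    diameter_mean_mm: float = 6.42
    diameter_sd_mm: float = 3.00
    diameter_min_mm: float = 2.0
    diameter_max_mm: float = 20.0
    noise_sd: float = 0.05
    seed: int = 0
    class_separation: float = 1.0
    patch_side: int = 64

    def __post_init__(self) -> None:
        if self.n_nodule < 1 or self.n_nonnodule < 1:
            raise ValueError("class counts must be >= 1")
        if not 0.0 <= self.class_separation <= 1.0:
            raise ValueError("class_separation must be in [0, 1]")


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      lo: float, hi: float) -> float:
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return float(x)
    return float(np.clip(mean, lo, hi))


def generate_pattern(
    label: str,
    cfg: GeneratorConfig,
    rng: np.random.Generator,
    pattern_id: str = "p0",
) -> Pattern:
    """Draw one labeled patch.

    Nodules are mildly perturbed ellipses with aspect ratio >= 0.6 and a
    smooth intensity falloff; non-nodules are elongated (aspect ratio
    shrinking with ``class_separation``), parabolically bent ridges.  The
    mask is the generating shape; the equivalent diameter is the truncated
    normal draw.
    """
    s = cfg.class_separation
    d_eq = _truncated_normal(
        rng, cfg.diameter_mean_mm, cfg.diameter_sd_mm,
        cfg.diameter_min_mm, cfg.diameter_max_mm,
    )
    r = d_eq / 2.0
    if label == "nodule":
        q = rng.uniform(0.6, 1.0)
        bend = 0.0
        pert_sd = 0.03
    else:
        # interpolate from the nodule distribution (s=0) to strongly
        # elongated vessel-like shapes (s=1)
        q = rng.uniform(0.6 - 0.45 * s, 1.0 - 0.6 * s)
        bend = 0.8 * s * rng.uniform(0.5, 1.0)
        pert_sd = 0.03 + 0.02 * s
    a = r / math.sqrt(q)  # semi-major (mm); area pi*a*b = pi*r^2
    b = r * math.sqrt(q)
    theta = rng.uniform(0, math.pi)
    eps = rng.normal(0.0, pert_sd, size=3)
    psi = rng.uniform(0, 2 * math.pi, size=3)

    spacing = cfg.pixel_spacing_mm
    side = max(cfg.patch_side, int(math.ceil(2.6 * a / spacing)))
    side += side % 2
    half = side * spacing / 2.0
    coords = (np.arange(side) + 0.5) * spacing - half
    yy, xx = np.meshgrid(coords, coords, indexing="ij")
    xr = math.cos(theta) * xx + math.sin(theta) * yy
    yr = -math.sin(theta) * xx + math.cos(theta) * yy
    yb = yr - bend * b * ((xr / a) ** 2 - 0.5)  # parabolic centerline bend
    u, v = xr / a, yb / b
    phi = np.arctan2(v, u)
    boundary = 1.0
    for k, (e, p) in enumerate(zip(eps, psi), start=2):
        boundary = boundary + e * np.cos(k * phi + p)
    boundary = np.clip(boundary, 0.5, 1.5)
    f = u ** 2 + v ** 2
    mask = f <= boundary ** 2
    if not mask.any():
        mask[side // 2, side // 2] = True

    intensity = np.exp(-f / (boundary ** 2 + 1e-9))
    noise = rng.normal(0.0, cfg.noise_sd, size=intensity.shape)
    image = np.clip(0.15 + 0.8 * intensity + noise, 0.0, 1.0)
    return Pattern(
        id=pattern_id, image=image, mask=mask, label=label,
        pixel_spacing_mm=spacing,
    )


def generate_dataset(cfg: GeneratorConfig | None = None) -> PatternSet:
    """Generate the full labeled dataset with stratified ~50/50 split tags.

    With the default 95/75 class counts, the split tags reproduce a
    47-nodule + 37-non-nodule training set and a 48 + 38 test set.
    Deterministic under ``cfg.seed``.
    """
    cfg = cfg or GeneratorConfig()
    rng = np.random.default_rng(cfg.seed)
    patterns: list[Pattern] = []
    tags: list[str] = []
    for label, count, prefix in (
        ("nodule", cfg.n_nodule, "nod"),
        ("nonnodule", cfg.n_nonnodule, "non"),
    ):
        n_train = count // 2
        for i in range(count):
            patterns.append(
                generate_pattern(label, cfg, rng, pattern_id=f"{prefix}{i:03d}")
            )
            tags.append("train" if i < n_train else "test")
    return PatternSet(patterns, tags)
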