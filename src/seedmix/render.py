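"""Synthetic seed-mixture image renderer.

Emulates the field acquisition protocol used for seed-mix photo datasets: a
round (camembert-style) box filled with a scooped sample of a seed mix,
photographed from above at the center of the frame against a uniform
background.  Each mix is scooped into several physical samples and each sample
is photographed several times, shaking the box between photos so the seeds
rearrange (default protocol: 5 samples x 5 photos per mix).

The renderer's ground truth is *exact by construction*: a requested weight
composition is converted to integer seed counts via largest-remainder
rounding, and the stored ground truth is the composition recomputed from those
integer counts and the per-seed masses — mirroring physical weighing, and
keeping targets exactly consistent with the rendered pixels.

Seeds are drawn as textured, rotated ellipses with random z-order occlusion
(no physics); "other" debris, when given a profile, is drawn as irregular
polygons.  Coordinates are pixel coordinates, origin top-left, x rightward,
y downward; ellipse angles are degrees counter-clockwise.

All randomness flows through one dataset seed; each image uses a recorded
sub-seed derived by hashing (dataset seed, mix id, sample index, shake index),
so any single image can be re-rendered bit-identically.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass

import numpy as np
from PIL import Image, ImageDraw

from .catalog import (
    OTHER_LABEL,
    CompositionVector,
    VarietyCatalog,
    validate_composition,
)

__all__ = [
    "REFERENCE_PX",
    "VarietyProfile",
    "RenderConfig",
    "SampleRealization",
    "OverfullBoxError",
    "weights_to_counts",
    "render_sample",
    "render_dataset",
    "high_contrast_profiles",
    "preset_profiles",
    "random_mix_specs",
]

#: image side length at which profile axes are expressed; axes scale linearly
#: with the configured output resolution.
REFERENCE_PX = 512


class OverfullBoxError(ValueError):
    """Requested seed area exceeds the box area by more than 5x."""


@dataclass(frozen=True)
class VarietyProfile:
    """Rendering and mass parameters for one variety.

    The visual parameters (color, size, shape) are synthetic stand-ins chosen
    for plausibility or for contrast, not measurements; ``per_seed_mass_g`` is
    likewise a configuration default on the order of real thousand-kernel
    weights.
    """

    label: str
    mean_axis_px: float  # semi-major axis at REFERENCE_PX resolution
    axis_cv: float  # coefficient of variation of the semi-major axis
    base_color: tuple[int, int, int]
    color_jitter: float  # per-channel std, 0-255 scale
    per_seed_mass_g: float
    elongation: float = 1.6  # semi-major / semi-minor ratio
    shape: str = "ellipse"  # "ellipse" or "debris"

    def __post_init__(self) -> None:
        if self.per_seed_mass_g <= 0:
            raise ValueError(f"{self.label}: per_seed_mass_g must be > 0")
        if self.mean_axis_px <= 0 or self.elongation <= 0:
            raise ValueError(f"{self.label}: axes must be > 0")
        if any(not (0 <= c <= 255) for c in self.base_color):
            raise ValueError(f"{self.label}: RGB components must be in [0, 255]")


@dataclass(frozen=True)
class RenderConfig:
    """Global rendering parameters for one dataset."""

    image_px: int = 256
    box_radius_frac: float = 0.42
    background_color: tuple[int, int, int] = (168, 160, 150)
    box_color: tuple[int, int, int] = (226, 219, 205)
    lighting_gain_range: tuple[float, float] = (0.85, 1.15)
    noise_std: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.box_radius_frac <= 0.5):
            raise ValueError("box_radius_frac must be in (0, 0.5]")
        if self.image_px < 64:
            raise ValueError("image_px must be >= 64")


@dataclass
class SampleRealization:
    """One physical scoop of a mix, discretized into integer seed counts."""

    counts: dict[str, int]
    realized_composition: CompositionVector
    total_mass_g: float
    other_mass_g: float = 0.0  # residual mass kept continuous (no profile)
    placement: list | None = None  # filled by render_sample metadata


def _subseed(*parts) -> int:
    digest = hashlib.sha256("|".join(map(str, parts)).encode()).digest()
    return int.from_bytes(digest[:4], "little")


def weights_to_counts(
    target: CompositionVector,
    total_mass_g: float,
    profiles: dict[str, VarietyProfile],
) -> SampleRealization:
    """Convert a target weight composition into integer seed counts.

    Ideal counts ``total_mass_g * w_v / per_seed_mass_v`` are rounded by the
    largest-remainder method (total count fixed to the rounded ideal total).
    The realized composition is then recomputed from ``counts * mass`` — this,
    not the request, is the ground truth stored with rendered images.

    Residual "other" mass with no profile stays continuous: it is carried as
    weighed mass in the realized composition but yields no particles.
    """
    if total_mass_g <= 0:
        raise ValueError("total_mass_g must be > 0")
    cat = target.catalog
    labels, ideal = [], []
    other_mass = 0.0
    for name, w in zip(cat.names, target.weights):
        if w <= 0:
            continue
        if name not in profiles:
            if name == OTHER_LABEL:
                other_mass = total_mass_g * float(w)
                continue
            raise ValueError(f"nonzero weight for {name!r} but no profile provided")
        labels.append(name)
        ideal.append(total_mass_g * float(w) / profiles[name].per_seed_mass_g)

    ideal_arr = np.asarray(ideal, dtype=float)
    counts: dict[str, int] = {}
    if ideal_arr.size:
        total = int(round(ideal_arr.sum()))
        floors = np.floor(ideal_arr).astype(int)
        remainder = total - int(floors.sum())
        order = np.argsort(-(ideal_arr - floors), kind="stable")
        alloc = floors.copy()
        for i in order[:max(remainder, 0)]:
            alloc[i] += 1
        counts = {lab: int(c) for lab, c in zip(labels, alloc)}
        for lab, c in counts.items():
            if c == 0:
                warnings.warn(
                    f"total mass {total_mass_g} g too small to place one seed of "
                    f"{lab!r}; realized composition reflects the zero count",
                    stacklevel=2,
                )

    masses = np.zeros(len(cat))
    for lab, c in counts.items():
        masses[cat.index(lab)] = c * profiles[lab].per_seed_mass_g
    if other_mass > 0:
        masses[cat.index(OTHER_LABEL)] = other_mass
    realized_total = float(masses.sum())
    if realized_total <= 0:
        raise ValueError("no seed could be placed: total mass too small")
    realized = validate_composition(masses / realized_total, cat, tol=1e-9)
    return SampleRealization(
        counts=counts,
        realized_composition=realized,
        total_mass_g=realized_total,
        other_mass_g=other_mass,
    )


def _ellipse_polygon(cx, cy, a, b, angle_deg, n=24, wobble=None):
    """Vertices of a (possibly wobbled) rotated ellipse; y axis points down."""
    theta = np.linspace(0.0, 2 * np.pi, n, endpoint=False)
    ra, rb = np.full(n, a), np.full(n, b)
    if wobble is not None:
        ra = ra * wobble
        rb = rb * wobble
    phi = np.deg2rad(angle_deg)
    x = ra * np.cos(theta)
    y = rb * np.sin(theta)
    # CCW angle in a y-down frame: rotate by -phi in screen coordinates
    xr = cx + x * np.cos(phi) + y * np.sin(phi)
    yr = cy - x * np.sin(phi) + y * np.cos(phi)
    return list(zip(xr.tolist(), yr.tolist()))


def render_sample(
    realization: SampleRealization,
    profiles: dict[str, VarietyProfile],
    config: RenderConfig,
    shake_index: int = 0,
    mix_id: str = "",
    sample_idx: int = 0,
):
    """Render one photo of a sample; returns ``(PIL.Image, metadata dict)``.

    Deterministic for fixed ``(config.seed, mix_id, sample_idx, shake_index)``
    and realization: the same call renders a bit-identical raster.  A new
    ``shake_index`` reseeds the placement (the seeds rearrange) but never the
    counts — as when the physical box is shaken between photos.
    """
    sub = _subseed(config.seed, mix_id, sample_idx, shake_index)
    rng = np.random.default_rng(sub)
    px = config.image_px
    scale = px / REFERENCE_PX
    cx = cy = px / 2.0
    r_box = config.box_radius_frac * px

    # overfull guard: total seed footprint vs box area
    area = 0.0
    for lab, c in realization.counts.items():
        p = profiles[lab]
        a = p.mean_axis_px * scale
        area += c * np.pi * a * (a / p.elongation)
    box_area = np.pi * r_box**2
    if area > 5.0 * box_area:
        raise OverfullBoxError(
            f"overfull box: requested seed area {area:.0f} px^2 exceeds 5x the box "
            f"area {box_area:.0f} px^2; lower total_mass_g or raise image_px"
        )

    gain = float(rng.uniform(*config.lighting_gain_range))
    img = Image.new("RGB", (px, px), tuple(int(c) for c in config.background_color))
    draw = ImageDraw.Draw(img)
    draw.ellipse(
        [cx - r_box, cy - r_box, cx + r_box, cy + r_box],
        fill=tuple(int(c) for c in config.box_color),
        outline=tuple(max(0, int(c * 0.55)) for c in config.box_color),
        width=max(1, int(round(3 * scale))),
    )

    # generate every seed, then paint in a shuffled z-order (occlusion)
    seeds = []
    for lab in sorted(realization.counts):
        p = profiles[lab]
        base_a = p.mean_axis_px * scale
        for _ in range(realization.counts[lab]):
            a = base_a * max(0.25, 1.0 + p.axis_cv * rng.standard_normal())
            b = max(a / p.elongation, 0.8)
            a = max(a, 0.8)
            r_allow = max(r_box - a, 1.0)
            rr = r_allow * np.sqrt(rng.uniform())
            th = rng.uniform(0, 2 * np.pi)
            x, y = cx + rr * np.cos(th), cy + rr * np.sin(th)
            angle = float(rng.uniform(0, 360))
            color = tuple(
                int(np.clip(c + p.color_jitter * rng.standard_normal(), 0, 255))
                for c in p.base_color
            )
            wobble = (
                1.0 + rng.uniform(-0.35, 0.35, size=24) if p.shape == "debris" else None
            )
            seeds.append((lab, x, y, a, b, angle, color, wobble))
    order = rng.permutation(len(seeds))

    placement = []
    for z, i in enumerate(order):
        lab, x, y, a, b, angle, color, wobble = seeds[i]
        poly = _ellipse_polygon(x, y, a, b, angle, wobble=wobble)
        outline = tuple(max(0, int(c * 0.65)) for c in color)
        draw.polygon(poly, fill=color, outline=outline)
        placement.append(
            {"label": lab, "center": (x, y), "axes": (a, b), "angle_deg": angle, "z": z}
        )

    arr = np.asarray(img, dtype=float) * gain
    if config.noise_std > 0:
        arr = arr + rng.normal(0.0, config.noise_std, size=arr.shape)
    img = Image.fromarray(np.clip(arr, 0, 255).astype(np.uint8))

    metadata = {
        "mix_id": mix_id,
        "sample_idx": sample_idx,
        "shake_index": shake_index,
        "subseed": sub,
        "lighting_gain": gain,
        "coordinates": "pixels, origin top-left, x right, y down; angle deg CCW",
        "placement": placement,
    }
    return img, metadata


def render_dataset(
    mix_specs,
    profiles: dict[str, VarietyProfile],
    config: RenderConfig,
    out_dir,
    samples_per_mix: int = 5,
    photos_per_sample: int = 5,
    total_mass_g: float = 12.0,
    overwrite: bool = False,
    mix_type: str = "composition",
):
    """Render a full dataset and return its :class:`~seedmix.manifest.MixManifest`.

    ``mix_specs`` is a list of ``(mix_id, CompositionVector)`` or
    ``(mix_id, CompositionVector, total_mass_g)`` tuples.  Emits
    ``samples_per_mix * photos_per_sample`` PNGs per mix under ``out_dir`` and
    one manifest row per image carrying the per-sample realized composition.
    """
    from pathlib import Path

    from .manifest import MixManifest

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ids = [s[0] for s in mix_specs]
    if len(set(ids)) != len(ids):
        raise ValueError("mix_ids must be unique")

    rows = []
    for spec in mix_specs:
        mix_id, comp = spec[0], spec[1]
        mass = spec[2] if len(spec) > 2 else total_mass_g
        for s in range(samples_per_mix):
            realization = weights_to_counts(comp, mass, profiles)
            for ph in range(photos_per_sample):
                name = f"{mix_id}_s{s}_p{ph}.png"
                path = out / name
                if path.exists() and not overwrite:
                    raise FileExistsError(
                        f"{path} exists; pass overwrite=True to replace it"
                    )
                img, _ = render_sample(
                    realization, profiles, config,
                    shake_index=ph, mix_id=str(mix_id), sample_idx=s,
                )
                img.save(path)
                rows.append(
                    {
                        "mix_id": str(mix_id),
                        "sample_idx": s,
                        "photo_idx": ph,
                        "image_path": name,
                        "year": None,
                        "mix_type": mix_type,
                        "composition": realization.realized_composition,
                    }
                )
    return MixManifest.from_rows(rows, catalog=mix_specs[0][1].catalog)


# ---------------------------------------------------------------------------
# profile presets

def high_contrast_profiles() -> dict[str, VarietyProfile]:
    """Six visually well-separated varieties for desk-scale experiments.

    Saturated, maximally distinct colors so that composition recovery does not
    hinge on fragile visual similarity; masses are round numbers.  Intended
    for tests and demos, not for realism.
    """
    spec = [
        ("barley", (205, 40, 40), 22.0, 0.06),
        ("wheat", (40, 170, 40), 20.0, 0.05),
        ("oats", (45, 70, 205), 26.0, 0.04),
        ("spelt", (225, 205, 40), 24.0, 0.055),
        ("forage_peas", (200, 45, 200), 28.0, 0.20),
        ("lupine", (40, 200, 200), 30.0, 0.30),
    ]
    return {
        lab: VarietyProfile(
            label=lab,
            mean_axis_px=axis,
            axis_cv=0.12,
            base_color=color,
            color_jitter=10.0,
            per_seed_mass_g=mass,
            elongation=1.2 if mass > 0.1 else 1.8,
        )
        for lab, color, axis, mass in spec
    }


def preset_profiles() -> dict[str, VarietyProfile]:
    """Plausible (synthetic, invented) profiles for the 11 canonical varieties
    plus "other" debris.

    Colors approximate the visual appearance of each grain; per-seed masses
    are on the order of real thousand-kernel weights.  None of these values is
    a measurement.
    """
    spec = {
        # label: (color, semi-major px @512, elongation, mass g)
        "triticale": ((193, 154, 107), 15.0, 2.2, 0.043),
        "oats": ((214, 196, 158), 19.0, 2.8, 0.035),
        "barley": ((206, 177, 128), 16.0, 2.4, 0.046),
        "spelt": ((181, 148, 100), 17.0, 2.5, 0.050),
        "wheat": ((189, 145, 96), 13.0, 1.9, 0.045),
        "rye": ((148, 124, 94), 14.0, 2.5, 0.033),
        "forage_peas": ((151, 142, 102), 18.0, 1.05, 0.20),
        "faba_bean": ((123, 92, 62), 26.0, 1.35, 0.55),
        "vetch": ((72, 60, 52), 11.0, 1.05, 0.055),
        "protein_peas": ((173, 160, 114), 19.0, 1.05, 0.25),
        "lupine": ((235, 228, 208), 22.0, 1.15, 0.35),
    }
    profiles = {
        lab: VarietyProfile(
            label=lab,
            mean_axis_px=axis,
            axis_cv=0.10,
            base_color=color,
            color_jitter=8.0,
            per_seed_mass_g=mass,
            elongation=elong,
        )
        for lab, (color, axis, elong, mass) in spec.items()
    }
    profiles[OTHER_LABEL] = VarietyProfile(
        label=OTHER_LABEL,
        mean_axis_px=10.0,
        axis_cv=0.45,
        base_color=(110, 100, 80),
        color_jitter=25.0,
        per_seed_mass_g=0.02,
        elongation=2.0,
        shape="debris",
    )
    return profiles


def random_mix_specs(
    n_mixes: int,
    labels: tuple[str, ...],
    rng: np.random.Generator,
    catalog: VarietyCatalog | None = None,
    n_varieties_range: tuple[int, int] = (1, 7),
    min_fraction: float = 0.05,
):
    """Draw random mix compositions over ``labels`` (1–7 varieties per mix).

    Emulates the variety-count range of real acquisition campaigns: each mix
    uses a uniform number of varieties within ``n_varieties_range`` (capped by
    the available labels) and Dirichlet(1) weight fractions, re-drawn until
    every present variety holds at least ``min_fraction`` of the mass so no
    requested variety vanishes in the discretization.
    """
    cat = catalog or VarietyCatalog.default(includes_other=False)
    lo, hi = n_varieties_range
    hi = min(hi, len(labels))
    specs = []
    for i in range(n_mixes):
        k = int(rng.integers(lo, hi + 1))
        chosen = rng.choice(len(labels), size=k, replace=False)
        for _ in range(200):
            frac = rng.dirichlet(np.ones(k))
            if frac.min() >= min(min_fraction, 1.0 / k):
                break
        w = np.zeros(len(cat))
        for j, f in zip(chosen, frac):
            w[cat.index(labels[j])] = f
        specs.append((f"mix{i:03d}", validate_composition(w, cat, tol=1e-9)))
    return specs
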