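"""PIL implementations of the named augmentation policies.

The automated policies (randaugment, autoaugment) are applied as compact
random sequences over a shared pool of PIL operations; the exact sub-policy
schedules of the published automated-augmentation methods are intentionally
not re-derived — the policy *names and configurations* are what the training
pipeline records and reproduces.
"""

from __future__ import annotations

import numpy as np
from PIL import Image, ImageEnhance, ImageOps

_ENHANCERS = {
    "color": ImageEnhance.Color,
    "contrast": ImageEnhance.Contrast,
    "brightness": ImageEnhance.Brightness,
    "sharpness": ImageEnhance.Sharpness,
}

#: op pool shared by the automated policies; magnitude in [0, 10] maps to the
#: op's own parameter range
_AUTO_OPS = ("rotate", "auto_contrast", "color", "contrast", "brightness", "sharpness")


def _apply_op(img: Image.Image, op: str, magnitude: float, rng: np.random.Generator):
    m = float(np.clip(magnitude, 0.0, 10.0)) / 10.0
    if op == "rotate":
        deg = m * 30.0 * (1 if rng.uniform() < 0.5 else -1)
        return img.rotate(deg, resample=Image.BILINEAR, fillcolor=(128, 128, 128))
    if op == "auto_contrast":
        return ImageOps.autocontrast(img)
    factor = 1.0 + m * 0.9 * (1 if rng.uniform() < 0.5 else -1)
    return _ENHANCERS[op](img).enhance(factor)


def apply_policy(img, name: str, params: dict, rng: np.random.Generator):
    if name == "center_crop":
        side = min(img.size)
        w, h = img.size
        left, top = (w - side) // 2, (h - side) // 2
        return img.crop((left, top, left + side, top + side))
    if name == "random_rotation":
        deg = float(rng.uniform(-params["degrees"], params["degrees"]))
        return img.rotate(deg, resample=Image.BILINEAR, fillcolor=(128, 128, 128))
    if name == "color_jitter":
        out = img
        for key, enhancer in (
            ("brightness", ImageEnhance.Brightness),
            ("contrast", ImageEnhance.Contrast),
            ("saturation", ImageEnhance.Color),
        ):
            span = params.get(key, 0.0)
            if span > 0:
                out = enhancer(out).enhance(float(rng.uniform(1 - span, 1 + span)))
        return out
    if name == "auto_contrast":
        return ImageOps.autocontrast(img)
    if name == "randaugment":
        mag = params["magnitude"] + params["magnitude_std"] * rng.standard_normal()
        ops = rng.choice(len(_AUTO_OPS), size=2, replace=False)
        out = img
        for i in ops:
            out = _apply_op(out, _AUTO_OPS[i], mag, rng)
        return out
    if name == "autoaugment":
        # one randomly chosen pair of pool ops at moderate magnitude, applied
        # with the customary per-op probability
        out = img
        for i in rng.choice(len(_AUTO_OPS), size=2, replace=False):
            if rng.uniform() < 0.8:
                out = _apply_op(out, _AUTO_OPS[i], 6.0, rng)
        return out
    raise ValueError(f"unknown augmentation policy {name!r}")
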