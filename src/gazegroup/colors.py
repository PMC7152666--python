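"""CIELAB base palette and lightness-encoded similarity colors.

Every metric gets a saturated base color from the CIELAB hue circle
(constant chroma and reference lightness, hues 20° apart for the default
16-metric set). A cell's similarity value only moves the lightness L*
between a dark floor (identical participants) and a light ceiling, so hue
identifies the metric while lightness encodes the value.

The CIELAB↔sRGB conversions are implemented here directly because gamut
mapping needs the *unclipped* linear RGB values: out-of-gamut colors are
pulled toward the neutral axis by reducing chroma, which preserves the hue
that carries the metric identity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

# D65 reference white
_WHITE = np.array([0.95047, 1.0, 1.08883])
_M_XYZ_TO_RGB = np.array(
    [
        [3.2404542, -1.5371385, -0.4985314],
        [-0.9692660, 1.8760108, 0.0415560],
        [0.0556434, -0.2040259, 1.0572252],
    ]
)
_M_RGB_TO_XYZ = np.linalg.inv(_M_XYZ_TO_RGB)
_DELTA = 6.0 / 29.0


def lab_to_rgb(lab: np.ndarray, clip: bool = True) -> np.ndarray:
    """CIELAB → sRGB (D65). With ``clip=False`` out-of-gamut values survive."""
    lab = np.asarray(lab, dtype=float)
    L, a, b = lab[..., 0], lab[..., 1], lab[..., 2]
    fy = (L + 16.0) / 116.0
    fx = fy + a / 500.0
    fz = fy - b / 200.0

    def finv(t):
        return np.where(t > _DELTA, t**3, 3.0 * _DELTA**2 * (t - 4.0 / 29.0))

    xyz = np.stack([finv(fx), finv(fy), finv(fz)], axis=-1) * _WHITE
    lin = xyz @ _M_XYZ_TO_RGB.T
    srgb = np.where(
        lin <= 0.0031308, 12.92 * lin, 1.055 * np.sign(lin) * np.abs(lin) ** (1 / 2.4) - 0.055
    )
    if clip:
        srgb = np.clip(srgb, 0.0, 1.0)
    return srgb


def rgb_to_lab(rgb: np.ndarray) -> np.ndarray:
    """sRGB → CIELAB (D65)."""
    rgb = np.asarray(rgb, dtype=float)
    lin = np.where(rgb <= 0.04045, rgb / 12.92, ((rgb + 0.055) / 1.055) ** 2.4)
    xyz = lin @ _M_RGB_TO_XYZ.T
    t = xyz / _WHITE

    def f(v):
        return np.where(v > _DELTA**3, np.cbrt(v), v / (3.0 * _DELTA**2) + 4.0 / 29.0)

    fx, fy, fz = f(t[..., 0]), f(t[..., 1]), f(t[..., 2])
    return np.stack([116.0 * fy - 16.0, 500.0 * (fx - fy), 200.0 * (fy - fz)], axis=-1)


def _in_gamut(lab: np.ndarray, tol: float = 1e-6) -> bool:
    rgb = lab_to_rgb(lab, clip=False)
    return bool(np.all(rgb >= -tol) and np.all(rgb <= 1 + tol))


def lch_to_rgb(L: float, C: float, h_deg: float) -> np.ndarray:
    """LCh → sRGB with gamut mapping by chroma reduction (hue preserved)."""
    hr = np.deg2rad(h_deg)
    cos_h, sin_h = np.cos(hr), np.sin(hr)

    def lab_at(c):
        return np.array([L, c * cos_h, c * sin_h])

    if not _in_gamut(lab_at(C)):
        lo, hi = 0.0, C
        for _ in range(40):  # bisect chroma toward the neutral axis
            mid = (lo + hi) / 2.0
            if _in_gamut(lab_at(mid)):
                lo = mid
            else:
                hi = mid
        C = lo
    return np.clip(lab_to_rgb(lab_at(C)), 0.0, 1.0)


@dataclass(frozen=True)
class BaseColor:
    """Hue/chroma identity of one metric at reference lightness."""

    metric: str
    hue: float  # degrees in [0, 360)
    chroma: float
    lightness: float

    def lab(self, L: float | None = None) -> np.ndarray:
        L = self.lightness if L is None else L
        hr = np.deg2rad(self.hue)
        return np.array([L, self.chroma * np.cos(hr), self.chroma * np.sin(hr)])


@dataclass
class ColorScheme:
    """Ordered palette plus the value→lightness mapping."""

    colors: list[BaseColor]
    lightness_range: tuple[float, float] = (30.0, 90.0)
    dark_is_similar: bool = True  # value 0 (identical) renders darkest
    _by_metric: dict[str, BaseColor] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        lo, hi = self.lightness_range
        if not lo < hi:
            raise ValueError("lightness range must satisfy L_lo < L_hi")
        self._by_metric = {c.metric: c for c in self.colors}

    def base(self, metric: str) -> BaseColor:
        try:
            return self._by_metric[metric]
        except KeyError:
            raise KeyError(f"unknown metric {metric!r}") from None

    def to_dict(self) -> dict:
        return {
            "lightness_range": list(self.lightness_range),
            "dark_is_similar": self.dark_is_similar,
            "colors": [
                {
                    "metric": c.metric,
                    "hue": c.hue,
                    "chroma": c.chroma,
                    "lightness": c.lightness,
                    "hex": rgb_to_hex(lch_to_rgb(c.lightness, c.chroma, c.hue)),
                }
                for c in self.colors
            ],
        }


def base_palette(
    metrics: list[str] | int = 16,
    hue_step: float = 20.0,
    chroma: float = 50.0,
    lightness: float = 60.0,
    h0: float = 0.0,
) -> ColorScheme:
    """Build the categorical base palette: one hue per metric, 20° apart.

    Accepts a metric-name list or a bare count. Raises when the requested
    hues would wrap past 360° and collide.
    """
    if isinstance(metrics, int):
        metrics = [f"M{k + 1}" for k in range(metrics)]
    n = len(metrics)
    if n < 1:
        raise ValueError("palette needs at least one metric")
    if n * hue_step > 360.0:
        raise ValueError(f"{n} hues with step {hue_step} exceed the 360-degree circle")
    colors = [
        BaseColor(metric=m, hue=(h0 + k * hue_step) % 360.0, chroma=chroma, lightness=lightness)
        for k, m in enumerate(metrics)
    ]
    return ColorScheme(colors=colors)


def encode_value(scheme: ColorScheme, metric: str, value: float) -> np.ndarray:
    """Map a normalized dissimilarity in [0, 1] to a display sRGB triple."""
    if not 0.0 <= value <= 1.0 + 1e-12:
        raise ValueError(f"value must be in [0, 1], got {value}")
    base = scheme.base(metric)
    lo, hi = scheme.lightness_range
    v = value if scheme.dark_is_similar else 1.0 - value
    L = lo + v * (hi - lo)
    return lch_to_rgb(L, base.chroma, base.hue)


def encode_array(scheme: ColorScheme, metric: str, values: np.ndarray) -> np.ndarray:
    """Vectorized :func:`encode_value` for one metric (returns (..., 3))."""
    values = np.asarray(values, dtype=float)
    out = np.empty(values.shape + (3,))
    for idx in np.ndindex(values.shape):
        out[idx] = encode_value(scheme, metric, float(values[idx]))
    return out


def palette_discriminability(scheme: ColorScheme) -> float:
    """Minimum pairwise CIELAB ΔE between base colors at reference lightness."""
    labs = np.array([c.lab() for c in scheme.colors])
    if len(labs) < 2:
        return float("inf")
    diffs = labs[:, None, :] - labs[None, :, :]
    de = np.sqrt((diffs**2).sum(-1))
    iu = np.triu_indices(len(labs), k=1)
    return float(de[iu].min())


def rgb_to_hex(rgb: np.ndarray) -> str:
    r, g, b = (int(round(255 * float(v))) for v in np.clip(rgb, 0, 1))
    return f"#{r:02x}{g:02x}{b:02x}"
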