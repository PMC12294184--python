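"""Synthetic tooth-bud phantom radiographs with known ground truth.

Panoramic radiographs of patients cannot be redistributed, so the
measurement operators are validated against rendered phantoms instead: a
stylized lower-molar crown on a uniform background, with exactly known
geometry and grey levels.

The crown is an isosceles trapezoid, widest at the occlusal (top) edge and
symmetric about a vertical longitudinal axis.  On each side a straight
outer enamel surface is inclined at ``ea_true_deg`` to the vertical, and a
straight dentine–enamel junction (DEJ) at ``da_true_deg``; the band between
them is enamel, the core is dentine.  ``enamel_thickness_px`` is the
horizontal enamel thickness at half crown height — the level at which the
densitometry profile is drawn — so a profile of length twice the thickness
centred on the DEJ runs from mid-dentine exactly to the enamel surface.

Rendering is a hard per-pixel assignment (a pixel takes the grey level of
the region containing its center), optionally followed by Gaussian blur and
additive Gaussian noise, then clipping and quantization to the declared bit
depth.  Higher grey value means more radiopaque, so control-like phantoms
have ``enamel_grey > dentine_grey`` and a true mineralization ratio above 1.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .landmarks import LandmarkSet

__all__ = [
    "PhantomSpec",
    "PhantomImage",
    "PhantomGeometryError",
    "CohortParams",
    "generate_phantom",
    "generate_cohort",
    "sample_truth_table",
]


class PhantomGeometryError(ValueError):
    """Raised when a spec describes a self-intersecting or empty crown."""


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one phantom crown.

    Angles are in degrees from the vertical, in [0, 45); grey levels are in
    the range of the declared bit depth.  Identical spec + seed renders a
    bit-identical image.
    """

    crown_width_px: int = 160
    crown_height_px: int = 120
    enamel_thickness_px: float = 18.0
    ea_true_deg: float = 14.63
    da_true_deg: float = 7.22
    enamel_grey: float = 140.0
    dentine_grey: float = 120.0
    background_grey: float = 40.0
    blur_sigma_px: float = 0.0
    noise_sd: float = 0.0
    bit_depth: int = 8
    margin_px: int = 24
    seed: int = 0

    def __post_init__(self) -> None:
        if self.bit_depth not in (8, 16):
            raise ValueError("bit_depth must be 8 or 16")
        lo, hi = 0.0, float(2**self.bit_depth - 1)
        for name in ("enamel_grey", "dentine_grey", "background_grey"):
            g = getattr(self, name)
            if not lo <= g <= hi:
                raise ValueError(f"{name}={g} outside {self.bit_depth}-bit range")
        greys = (self.enamel_grey, self.dentine_grey, self.background_grey)
        if min(abs(a - b) for i, a in enumerate(greys) for b in greys[i + 1:]) < 1.0:
            raise ValueError("grey levels must be pairwise distinguishable (≥ 1 apart)")
        if self.blur_sigma_px < 0 or self.noise_sd < 0:
            raise ValueError("blur_sigma_px and noise_sd must be non-negative")
        if not (0.0 <= self.ea_true_deg < 45.0 and 0.0 <= self.da_true_deg < 45.0):
            raise ValueError("angles must be in [0, 45) degrees")
        if self.enamel_thickness_px <= 0:
            raise ValueError("enamel_thickness_px must be positive")
        if self.enamel_thickness_px >= self.crown_width_px / 4:
            raise ValueError("enamel_thickness_px must be < crown_width_px / 4")
        self._check_geometry()

    def _check_geometry(self) -> None:
        w, h, t = self.crown_width_px, self.crown_height_px, self.enamel_thickness_px
        tan_ea = np.tan(np.deg2rad(self.ea_true_deg))
        tan_da = np.tan(np.deg2rad(self.da_true_deg))
        # CEJ must stay on its own side of the axis
        if h * tan_ea > w / 2 - 2:
            raise PhantomGeometryError("enamel surfaces cross before reaching the CEJ")
        # enamel band must not self-intersect anywhere inside the crown
        if t - (h / 2) * abs(tan_ea - tan_da) < 0.5:
            raise PhantomGeometryError("enamel band self-intersects within the crown")
        # dentine core must be non-empty at every height
        if w / 2 - (h / 2) * tan_ea - t - (h / 2) * tan_da < 1.0:
            raise PhantomGeometryError("dentine core vanishes within the crown")

    @property
    def edmr_true(self) -> float:
        return self.enamel_grey / self.dentine_grey

    @property
    def truth_values(self) -> dict:
        return {
            "w_px": float(self.crown_width_px),
            "h_px": float(self.crown_height_px),
            "ea_deg": float(self.ea_true_deg),
            "da_deg": float(self.da_true_deg),
            "edmr": float(self.edmr_true),
        }


@dataclass
class PhantomImage:
    """A rendered phantom plus its ground-truth annotations."""

    pixels: np.ndarray
    spec: PhantomSpec
    truth_landmarks: LandmarkSet
    truth_values: dict

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def save(self, path) -> None:
        import imageio.v3 as iio

        iio.imwrite(path, self.pixels)


def _truth_landmarks(spec: PhantomSpec, subject_id: str = "phantom") -> LandmarkSet:
    w, h, t = spec.crown_width_px, spec.crown_height_px, spec.enamel_thickness_px
    m = spec.margin_px
    tan_ea = np.tan(np.deg2rad(spec.ea_true_deg))
    tan_da = np.tan(np.deg2rad(spec.da_true_deg))
    cx = m + w / 2
    y_top, y_bot = float(m), float(m + h)
    y_mid = y_top + h / 2

    def surf_r(y):  # outer enamel surface, distal (right) side
        return cx + w / 2 - (y - y_top) * tan_ea

    def dej_r(y):
        return cx + w / 2 - (h / 2) * tan_ea - t - (y - y_mid) * tan_da

    def mirror(x):
        return 2 * cx - x

    ya, yb = y_top + 0.25 * h, y_top + 0.75 * h  # DEJ segment endpoints
    points = {
        "axis_a": (cx, y_top),
        "axis_b": (cx, y_bot),
        "cej_mesial": (mirror(surf_r(y_bot)), y_bot),
        "cej_distal": (surf_r(y_bot), y_bot),
        "enamel_surface_mesial_a": (mirror(surf_r(y_top)), y_top),
        "enamel_surface_mesial_b": (mirror(surf_r(y_bot)), y_bot),
        "enamel_surface_distal_a": (surf_r(y_top), y_top),
        "enamel_surface_distal_b": (surf_r(y_bot), y_bot),
        "dej_mesial_a": (mirror(dej_r(ya)), ya),
        "dej_mesial_b": (mirror(dej_r(yb)), yb),
        "dej_distal_a": (dej_r(ya), ya),
        "dej_distal_b": (dej_r(yb), yb),
        "crown_top": (cx, y_top),
        "crown_bottom": (cx, y_bot),
        "crown_left": (cx - w / 2, y_top),
        "crown_right": (cx + w / 2, y_top),
        "profile_anchor_mesial": (mirror(dej_r(y_mid)), y_mid),
        "profile_anchor_distal": (dej_r(y_mid), y_mid),
    }
    return LandmarkSet(
        subject_id=subject_id,
        tooth_id="phantom",
        points=points,
        enamel_thickness_px={"mesial": t, "distal": t},
    )


def generate_phantom(spec: PhantomSpec, subject_id: str = "phantom") -> PhantomImage:
    """Render one phantom crown.

    Deterministic: the same spec (including ``seed``) always yields a
    bit-identical pixel array.
    """
    w, h, t = spec.crown_width_px, spec.crown_height_px, spec.enamel_thickness_px
    m = spec.margin_px
    img_w, img_h = w + 2 * m + 1, h + 2 * m + 1
    tan_ea = np.tan(np.deg2rad(spec.ea_true_deg))
    tan_da = np.tan(np.deg2rad(spec.da_true_deg))
    cx = m + w / 2
    y_top, y_bot = float(m), float(m + h)
    y_mid = y_top + h / 2

    ys, xs = np.mgrid[0:img_h, 0:img_w].astype(float)
    surf_r = cx + w / 2 - (ys - y_top) * tan_ea
    surf_l = 2 * cx - surf_r
    dej_r = cx + w / 2 - (h / 2) * tan_ea - t - (ys - y_mid) * tan_da
    dej_l = 2 * cx - dej_r

    crown = (ys >= y_top) & (ys <= y_bot) & (xs >= surf_l) & (xs <= surf_r)
    dentine = crown & (xs > dej_l) & (xs < dej_r)

    img = np.full((img_h, img_w), spec.background_grey, dtype=float)
    img[crown] = spec.enamel_grey
    img[dentine] = spec.dentine_grey

    if spec.blur_sigma_px > 0:
        img = ndimage.gaussian_filter(img, spec.blur_sigma_px)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        img = img + rng.normal(0.0, spec.noise_sd, img.shape)

    maxval = 2**spec.bit_depth - 1
    dtype = np.uint8 if spec.bit_depth == 8 else np.uint16
    pixels = np.rint(np.clip(img, 0, maxval)).astype(dtype)

    return PhantomImage(
        pixels=pixels,
        spec=spec,
        truth_landmarks=_truth_landmarks(spec, subject_id),
        truth_values=spec.truth_values,
    )


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

# Control distributions: medians at the control-group cut-offs of the
# radiographic method (EA 14.63 deg, DA 7.22 deg, EDMR 1.06) with normal SDs
# recovered from the printed interquartile ranges (SD = IQR / 1.349).
_CONTROL = {
    "ea_deg": (14.63, (17.0 - 12.5) / 1.349),
    "da_deg": (7.22, (8.75 - 5.5) / 1.349),
    "edmr": (1.06, (1.125 - 1.025) / 1.349),
}
# Affected group: strong DA decrease, moderate EDMR decrease, negligible EA
# shift, 1.5x dispersion — the pattern reported for DCV-positive patients.
_AFFECTED = {
    "ea_deg": (13.5, 1.5 * _CONTROL["ea_deg"][1]),
    "da_deg": (4.5, 1.5 * _CONTROL["da_deg"][1]),
    "edmr": (0.95, 1.5 * _CONTROL["edmr"][1]),
}


@dataclass(frozen=True)
class CohortParams:
    """Per-field normal (mean, SD) sampling distributions for a cohort.

    Geometry fields are sampled too so phantom crowns vary in size; grey
    levels are set so the true mineralization ratio equals the sampled
    ``edmr`` with a fixed dentine grey level.
    """

    ea_deg: tuple = _CONTROL["ea_deg"]
    da_deg: tuple = _CONTROL["da_deg"]
    edmr: tuple = _CONTROL["edmr"]
    crown_width_px: tuple = (160.0, 10.0)
    crown_height_px: tuple = (120.0, 8.0)
    enamel_thickness_px: tuple = (18.0, 1.5)
    dentine_grey: float = 120.0
    background_grey: float = 40.0
    blur_sigma_px: float = 0.0
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        for name in ("ea_deg", "da_deg", "edmr", "crown_width_px",
                     "crown_height_px", "enamel_thickness_px"):
            mean, sd = getattr(self, name)
            if sd < 0:
                raise ValueError(f"negative SD for {name}")

    @classmethod
    def control(cls, **overrides) -> "CohortParams":
        return cls(**overrides)

    @classmethod
    def affected(cls, **overrides) -> "CohortParams":
        kw = dict(_AFFECTED)
        kw.update(overrides)
        return cls(**kw)


_BOUNDS = {
    "ea_deg": (0.5, 40.0),
    "da_deg": (0.5, 40.0),
    "edmr": (0.55, 1.9),
    "crown_width_px": (100.0, 220.0),
    "crown_height_px": (70.0, 170.0),
    "enamel_thickness_px": (8.0, 30.0),
}


def _sample_field(rng: np.random.Generator, name: str, dist: tuple) -> float:
    mean, sd = dist
    lo, hi = _BOUNDS[name]
    for _ in range(1000):
        v = rng.normal(mean, sd)
        if lo <= v <= hi:
            return float(v)
    return float(np.clip(mean, lo, hi))


def _sample_spec(rng: np.random.Generator, params: CohortParams) -> PhantomSpec:
    """Draw one valid PhantomSpec (resampling specs whose crown geometry
    would be degenerate)."""
    for _ in range(200):
        edmr = _sample_field(rng, "edmr", params.edmr)
        kw = dict(
            crown_width_px=int(round(_sample_field(rng, "crown_width_px", params.crown_width_px))),
            crown_height_px=int(round(_sample_field(rng, "crown_height_px", params.crown_height_px))),
            enamel_thickness_px=_sample_field(rng, "enamel_thickness_px", params.enamel_thickness_px),
            ea_true_deg=_sample_field(rng, "ea_deg", params.ea_deg),
            da_true_deg=_sample_field(rng, "da_deg", params.da_deg),
            enamel_grey=params.dentine_grey * edmr,
            dentine_grey=params.dentine_grey,
            background_grey=params.background_grey,
            blur_sigma_px=params.blur_sigma_px,
            noise_sd=params.noise_sd,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        try:
            return PhantomSpec(**kw)
        except (PhantomGeometryError, ValueError):
            continue
    raise PhantomGeometryError("could not sample a valid phantom spec in 200 tries")


def sample_truth_table(n: int, params: CohortParams, seed: int,
                       group: str = "control", id_prefix: str = "C") -> pd.DataFrame:
    """Sample the ground-truth parameter table of a cohort without rendering."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n):
        spec = _sample_spec(rng, params)
        rows.append({
            "subject_id": f"{id_prefix}{i + 1:03d}",
            "group": group,
            **{k: v for k, v in dataclasses.asdict(spec).items()
               if k in ("crown_width_px", "crown_height_px", "enamel_thickness_px",
                        "ea_true_deg", "da_true_deg", "blur_sigma_px", "noise_sd", "seed")},
            "edmr_true": spec.edmr_true,
        })
    return pd.DataFrame(rows)


def generate_cohort(n: int, params: CohortParams | None = None, seed: int = 0,
                    group: str = "control", id_prefix: str = "C",
                    ) -> tuple[list[PhantomImage], pd.DataFrame]:
    """Render *n* phantoms drawn from *params* and return them with the
    ground-truth table (one row per subject).

    Reproducible: the output is a pure function of ``(params, seed)``.
    """
    params = params or CohortParams.control()
    table = sample_truth_table(n, params, seed, group=group, id_prefix=id_prefix)
    phantoms = []
    for row in table.itertuples(index=False):
        spec = PhantomSpec(
            crown_width_px=int(row.crown_width_px),
            crown_height_px=int(row.crown_height_px),
            enamel_thickness_px=float(row.enamel_thickness_px),
            ea_true_deg=float(row.ea_true_deg),
            da_true_deg=float(row.da_true_deg),
            enamel_grey=params.dentine_grey * float(row.edmr_true),
            dentine_grey=params.dentine_grey,
            background_grey=params.background_grey,
            blur_sigma_px=float(row.blur_sigma_px),
            noise_sd=float(row.noise_sd),
            seed=int(row.seed),
        )
        phantoms.append(generate_phantom(spec, subject_id=row.subject_id))
    return phantoms, table


def two_group_cohort(n_control: int = 24, n_affected: int = 24, seed: int = 0,
                     control: CohortParams | None = None,
                     affected: CohortParams | None = None) -> pd.DataFrame:
    """Ground-truth table for a control + DCV-positive study, emulating the
    24 vs 24 design of the radiographic cohort."""
    rng = np.random.default_rng(seed)
    s1, s2 = (int(s) for s in rng.integers(0, 2**31 - 1, size=2))
    tc = sample_truth_table(n_control, control or CohortParams.control(), s1,
                            group="control", id_prefix="C")
    ta = sample_truth_table(n_affected, affected or CohortParams.affected(), s2,
                            group="affected", id_prefix="A")
    return pd.concat([tc, ta], ignore_index=True)
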