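"""Measurement operators for tooth-bud radiographs.

Implements the five radiographic parameters measured on lower second
permanent molar buds:

* crown width ``W`` and height ``H`` (straight-line distances between the
  annotated crown extremity points, optionally scaled to millimetres);
* enamel angle ``EA`` — the acute angle between the straight outer-enamel
  surface segment and the vertical side of a reference rectangle aligned
  with the bud's longitudinal axis, whose sides pass through the mesial and
  distal cementum–enamel junction (CEJ) points;
* dentine angle ``DA`` — the same construction applied to the
  dentine–enamel junction (DEJ) segment;
* enamel–dentine mineralization ratio ``EDMR`` — on a line of length twice
  the enamel thickness drawn at half crown height from the dentine across
  the DEJ to the enamel surface, the mean grey value of the middle third of
  the enamel half divided by the mean grey value of the middle third of the
  dentine half.

All operators take explicit landmark annotations; no automatic landmark
detection is attempted.  Grey values are sampled by bilinear interpolation
at sub-pixel positions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .landmarks import LandmarkError, LandmarkSet

__all__ = [
    "ReferenceRectangle",
    "MeasurementRecord",
    "measure_width_height",
    "build_reference_rectangle",
    "measure_enamel_angle",
    "measure_dentine_angle",
    "sample_profile",
    "compute_edmr",
    "measure_tooth",
    "aggregate_patient",
    "read_image",
    "records_to_frame",
]

SIDES = ("mesial", "distal")

#: default sampling step along densitometry profiles, in pixels
PROFILE_STEP_PX = 0.5


def read_image(path) -> np.ndarray:
    """Read an 8- or 16-bit greyscale PNG/TIFF as a 2-D array."""
    import imageio.v3 as iio

    img = np.asarray(iio.imread(path))
    if img.ndim == 3:  # greyscale stored with redundant channels
        img = img[..., 0]
    if img.ndim != 2:
        raise ValueError(f"expected a 2-D greyscale image, got shape {img.shape}")
    return img


# ---------------------------------------------------------------------------
# reference rectangle and angles
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ReferenceRectangle:
    """The imaginary rectangle placed on the molar bud: its vertical
    direction is the bud's longitudinal axis, and its two vertical sides
    pass through the mesial and distal CEJ points."""

    vertical_direction: np.ndarray  # unit vector
    mesial_point: np.ndarray        # CEJ point the mesial side passes through
    distal_point: np.ndarray

    def side_distance(self, point, side: str) -> float:
        """Perpendicular distance from *point* to the given vertical side."""
        anchor = self.mesial_point if side == "mesial" else self.distal_point
        v = np.asarray(point, dtype=float) - anchor
        lateral = v - (v @ self.vertical_direction) * self.vertical_direction
        return float(np.linalg.norm(lateral))


def build_reference_rectangle(landmarks: LandmarkSet) -> ReferenceRectangle:
    axis = landmarks.axis
    d = axis[1] - axis[0]
    n = np.linalg.norm(d)
    if n == 0:
        raise LandmarkError("axis points coincide")
    return ReferenceRectangle(
        vertical_direction=d / n,
        mesial_point=landmarks.point("cej_mesial"),
        distal_point=landmarks.point("cej_distal"),
    )


def _acute_angle_deg(u: np.ndarray, v: np.ndarray) -> float:
    """Acute angle between two directions, in degrees, range [0, 90]."""
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise LandmarkError("zero-length segment")
    c = abs(float(u @ v)) / (nu * nv)
    return math.degrees(math.acos(min(c, 1.0)))


def measure_enamel_angle(landmarks: LandmarkSet, rect: ReferenceRectangle,
                         side: str) -> float:
    """Acute angle (degrees) between the outer enamel surface segment on
    *side* and the rectangle's vertical side."""
    seg = landmarks.segment(f"enamel_surface_{side}")
    return _acute_angle_deg(seg[1] - seg[0], rect.vertical_direction)


def measure_dentine_angle(landmarks: LandmarkSet, rect: ReferenceRectangle,
                          side: str) -> float:
    """Acute angle (degrees) between the DEJ segment on *side* and the
    rectangle's vertical side."""
    seg = landmarks.segment(f"dej_{side}")
    return _acute_angle_deg(seg[1] - seg[0], rect.vertical_direction)


# ---------------------------------------------------------------------------
# width / height
# ---------------------------------------------------------------------------

def measure_width_height(landmarks: LandmarkSet,
                         pixel_size: float | None = None) -> tuple[float, float]:
    """Crown width and height as straight-line distances between the
    annotated extremity points, in pixels (or scaled units if *pixel_size*
    is given)."""
    w = float(np.linalg.norm(landmarks.point("crown_right") - landmarks.point("crown_left")))
    h = float(np.linalg.norm(landmarks.point("crown_top") - landmarks.point("crown_bottom")))
    if w == 0 or h == 0:
        raise LandmarkError("coincident crown extremity points")
    if pixel_size is not None:
        w, h = w * pixel_size, h * pixel_size
    return w, h


# ---------------------------------------------------------------------------
# densitometry profile and EDMR
# ---------------------------------------------------------------------------

def sample_profile(image: np.ndarray, anchor, direction, enamel_thickness: float,
                   step: float = PROFILE_STEP_PX) -> np.ndarray:
    """Grey values along the mineralization profile.

    The line is centred on *anchor* (a point on the DEJ), runs along the
    unit vector *direction* (pointing from dentine towards the enamel
    surface) and has total length twice *enamel_thickness*: the first half
    lies in dentine, the second half in enamel.  Values are sampled by
    bilinear interpolation at spacing *step*, ordered dentine → enamel.
    """
    if enamel_thickness <= 0:
        raise ValueError("enamel_thickness must be positive")
    if step <= 0:
        raise ValueError("step must be positive")
    a = np.asarray(anchor, dtype=float)
    d = np.asarray(direction, dtype=float)
    n = np.linalg.norm(d)
    if n == 0:
        raise ValueError("zero direction vector")
    d = d / n
    t = float(enamel_thickness)
    n_samples = int(round(2 * t / step)) + 1
    s = -t + step * np.arange(n_samples)
    pts = a[None, :] + s[:, None] * d[None, :]
    h, w = image.shape
    if (pts[:, 0].min() < 0 or pts[:, 0].max() > w - 1
            or pts[:, 1].min() < 0 or pts[:, 1].max() > h - 1):
        raise ValueError("profile line exits image bounds")
    # map_coordinates wants (row, col) = (y, x)
    return ndimage.map_coordinates(image.astype(float),
                                   [pts[:, 1], pts[:, 0]], order=1)


def _middle_third(values: np.ndarray) -> np.ndarray:
    m = max(len(values) // 3, 1)
    start = (len(values) - m) // 2
    return values[start:start + m]


def compute_edmr(profile: np.ndarray) -> float:
    """Enamel–dentine mineralization ratio of a dentine→enamel profile.

    The profile is split into its dentine half and enamel half (an odd-
    length profile drops the central DEJ sample) and the ratio of the mean
    grey value over the central third of each half is returned.
    """
    p = np.asarray(profile, dtype=float)
    if len(p) < 6:
        raise ValueError("profile must have at least 6 samples")
    half = len(p) // 2
    dentine = p[:half]
    enamel = p[-half:]
    md = float(np.mean(_middle_third(dentine)))
    me = float(np.mean(_middle_third(enamel)))
    if md == 0:
        raise ZeroDivisionError("dentine middle-third mean is zero; EDMR undefined")
    return me / md


# ---------------------------------------------------------------------------
# per-tooth convenience and per-patient aggregation
# ---------------------------------------------------------------------------

def _profile_direction(landmarks: LandmarkSet, rect: ReferenceRectangle,
                       side: str) -> np.ndarray:
    """Unit vector perpendicular to the bud axis, pointing from the axis
    outward through the profile anchor (dentine → enamel)."""
    anchor = landmarks.point(f"profile_anchor_{side}")
    axis = landmarks.axis
    v = anchor - axis[0]
    lateral = v - (v @ rect.vertical_direction) * rect.vertical_direction
    n = np.linalg.norm(lateral)
    if n == 0:
        raise LandmarkError(f"profile anchor {side} lies on the axis")
    return lateral / n


def measure_tooth(image: np.ndarray, landmarks: LandmarkSet,
                  step: float = PROFILE_STEP_PX) -> dict:
    """Run all measurement operators for one annotated tooth.

    Returns a flat dict with ``w_px``, ``h_px`` and per-side ``ea_deg``,
    ``da_deg``, ``edmr`` entries keyed ``<param>_<side>``.
    """
    rect = build_reference_rectangle(landmarks)
    w, h = measure_width_height(landmarks)
    out = {"subject_id": landmarks.subject_id, "tooth_id": landmarks.tooth_id,
           "w_px": w, "h_px": h}
    for side in SIDES:
        out[f"ea_deg_{side}"] = measure_enamel_angle(landmarks, rect, side)
        out[f"da_deg_{side}"] = measure_dentine_angle(landmarks, rect, side)
        profile = sample_profile(
            image,
            landmarks.point(f"profile_anchor_{side}"),
            _profile_direction(landmarks, rect, side),
            landmarks.thickness(side),
            step=step,
        )
        out[f"edmr_{side}"] = compute_edmr(profile)
    return out


@dataclass
class MeasurementRecord:
    """Per-patient aggregate of the five radiographic parameters.

    Means and sample SDs pool every available (side × tooth) value; a
    parameter with no contributing measurement is ``None``, never zero.
    """

    subject_id: str
    mean_ea: float | None = None
    sd_ea: float = 0.0
    n_ea: int = 0
    mean_da: float | None = None
    sd_da: float = 0.0
    n_da: int = 0
    mean_edmr: float | None = None
    sd_edmr: float = 0.0
    n_edmr: int = 0
    mean_w: float | None = None
    sd_w: float = 0.0
    n_w: int = 0
    mean_h: float | None = None
    sd_h: float = 0.0
    n_h: int = 0
    pixel_size_mm: float | None = None
    group: str | None = None


_PARAM_KEYS = {"ea": "ea_deg", "da": "da_deg", "edmr": "edmr", "w": "w", "h": "h"}


def _mean_sd(values: list[float]) -> tuple[float, float, int]:
    a = np.asarray(values, dtype=float)
    mean = float(a.mean())
    sd = float(a.std(ddof=1)) if len(a) > 1 else 0.0
    return mean, sd, len(a)


def aggregate_patient(subject_id: str, measurements: list[dict],
                      pixel_size_mm: float | None = None,
                      group: str | None = None) -> MeasurementRecord:
    """Pool per-side, per-tooth measurements into one patient record.

    *measurements* is a list of dicts; angle/EDMR entries come one per
    (tooth, side) under keys ``ea_deg``/``da_deg``/``edmr``, width/height
    one per tooth under ``w``/``h``.  Missing entries are simply excluded
    and the contributing count per parameter is recorded.
    """
    if not measurements:
        raise ValueError("no measurements supplied")
    rec = MeasurementRecord(subject_id=subject_id, pixel_size_mm=pixel_size_mm,
                            group=group)
    for short, key in _PARAM_KEYS.items():
        values = [m[key] for m in measurements if m.get(key) is not None]
        if values:
            mean, sd, n = _mean_sd(values)
            setattr(rec, f"mean_{short}", mean)
            setattr(rec, f"sd_{short}", sd)
            setattr(rec, f"n_{short}", n)
    return rec


def tooth_results_to_side_rows(result: dict) -> list[dict]:
    """Explode a :func:`measure_tooth` result into per-side rows suitable
    for :func:`aggregate_patient` (W/H attached to the first row only)."""
    rows = []
    for i, side in enumerate(SIDES):
        row = {
            "tooth_id": result["tooth_id"],
            "side": side,
            "ea_deg": result[f"ea_deg_{side}"],
            "da_deg": result[f"da_deg_{side}"],
            "edmr": result[f"edmr_{side}"],
        }
        if i == 0:
            row["w"] = result["w_px"]
            row["h"] = result["h_px"]
        rows.append(row)
    return rows


def records_to_frame(records: list[MeasurementRecord]) -> pd.DataFrame:
    """Measurement table with one row per subject (the CSV surface)."""
    cols = ["subject_id", "group", "mean_w", "sd_w", "mean_h", "sd_h",
            "mean_ea", "sd_ea", "mean_da", "sd_da", "mean_edmr", "sd_edmr",
            "n_ea", "n_da", "n_edmr", "pixel_size_mm"]
    rows = [{c: getattr(r, c) for c in cols} for r in records]
    return pd.DataFrame(rows, columns=cols)
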