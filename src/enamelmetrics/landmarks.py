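"""Per-tooth landmark annotations.

A :class:`LandmarkSet` carries every point the measurement operators need:
the bud's longitudinal axis, the mesial/distal cementum–enamel junction
(CEJ) points through which the reference rectangle's sides pass, straight
two-point segments on the outer enamel surface and on the dentine–enamel
junction (DEJ) of each side, the four crown extremity points used for
width/height, and one densitometry-profile anchor per side (a point on the
DEJ at half crown height, together with the enamel thickness at that
level).

Coordinates are 0-based pixel indices, ``x`` rightward, ``y`` downward,
with landmarks located at pixel centers.  Landmark files are plain JSON:

.. code-block:: json

    {
      "subject_id": "P01",
      "tooth_id": "37",
      "points": {"axis_a": [x, y], "axis_b": [x, y], "...": [x, y]},
      "enamel_thickness_px": {"mesial": 18.0, "distal": 18.0},
      "pixel_size_mm": 0.1
    }
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["LandmarkSet", "LandmarkError"]

TOOTH_IDS = ("37", "47", "phantom")

#: point names stored in the JSON ``points`` mapping; segment endpoints are
#: suffixed ``_a`` / ``_b``.
POINT_NAMES = (
    "axis_a",
    "axis_b",
    "cej_mesial",
    "cej_distal",
    "enamel_surface_mesial_a",
    "enamel_surface_mesial_b",
    "enamel_surface_distal_a",
    "enamel_surface_distal_b",
    "dej_mesial_a",
    "dej_mesial_b",
    "dej_distal_a",
    "dej_distal_b",
    "crown_top",
    "crown_bottom",
    "crown_left",
    "crown_right",
    "profile_anchor_mesial",
    "profile_anchor_distal",
)


class LandmarkError(ValueError):
    """Raised for degenerate or out-of-bounds landmark annotations."""


def _pt(p) -> np.ndarray:
    a = np.asarray(p, dtype=float)
    if a.shape != (2,):
        raise LandmarkError(f"point must be (x, y), got shape {a.shape}")
    return a


@dataclass
class LandmarkSet:
    """Annotated points for one tooth bud (or one phantom crown)."""

    subject_id: str
    tooth_id: str
    points: dict = field(default_factory=dict)
    enamel_thickness_px: dict = field(default_factory=dict)  # side -> px
    pixel_size_mm: float | None = None

    def __post_init__(self) -> None:
        if self.tooth_id not in TOOTH_IDS:
            raise LandmarkError(
                f"tooth_id must be one of {TOOTH_IDS}, got {self.tooth_id!r}"
            )
        self.points = {k: _pt(v) for k, v in self.points.items()}

    # -- accessors -------------------------------------------------------

    def point(self, name: str) -> np.ndarray:
        try:
            return self.points[name]
        except KeyError:
            raise LandmarkError(f"missing landmark point {name!r}") from None

    def segment(self, name: str) -> np.ndarray:
        """Return a (2, 2) array of the two endpoints of segment *name*."""
        seg = np.stack([self.point(name + "_a"), self.point(name + "_b")])
        if np.allclose(seg[0], seg[1]):
            raise LandmarkError(f"segment {name!r} has zero length")
        return seg

    @property
    def axis(self) -> np.ndarray:
        return self.segment("axis")

    def thickness(self, side: str) -> float:
        try:
            return float(self.enamel_thickness_px[side])
        except KeyError:
            raise LandmarkError(f"missing enamel thickness for side {side!r}") from None

    # -- validation ------------------------------------------------------

    def validate(self, image_shape: tuple[int, int] | None = None) -> None:
        """Check segment lengths and (optionally) image bounds."""
        for name in ("axis", "enamel_surface_mesial", "enamel_surface_distal",
                     "dej_mesial", "dej_distal"):
            self.segment(name)
        for name in POINT_NAMES:
            self.point(name)
        if image_shape is not None:
            h, w = image_shape
            for name, p in self.points.items():
                if not (-0.5 <= p[0] <= w - 0.5 and -0.5 <= p[1] <= h - 0.5):
                    raise LandmarkError(
                        f"point {name!r} at {tuple(p)} outside image {image_shape}"
                    )

    # -- transforms (used by invariance tests and rotated acquisitions) --

    def transformed(self, rotation_deg: float, center=(0.0, 0.0)) -> "LandmarkSet":
        """Return a copy with all points rotated about *center*."""
        th = np.deg2rad(rotation_deg)
        rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        c = np.asarray(center, dtype=float)
        pts = {k: rot @ (v - c) + c for k, v in self.points.items()}
        return LandmarkSet(
            subject_id=self.subject_id,
            tooth_id=self.tooth_id,
            points=pts,
            enamel_thickness_px=dict(self.enamel_thickness_px),
            pixel_size_mm=self.pixel_size_mm,
        )

    # -- JSON I/O --------------------------------------------------------

    def to_dict(self) -> dict:
        d = {
            "subject_id": self.subject_id,
            "tooth_id": self.tooth_id,
            "points": {k: [float(v[0]), float(v[1])] for k, v in self.points.items()},
            "enamel_thickness_px": {k: float(v) for k, v in self.enamel_thickness_px.items()},
        }
        if self.pixel_size_mm is not None:
            d["pixel_size_mm"] = float(self.pixel_size_mm)
        return d

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def from_dict(cls, d: dict) -> "LandmarkSet":
        return cls(
            subject_id=str(d["subject_id"]),
            tooth_id=str(d["tooth_id"]),
            points=d["points"],
            enamel_thickness_px=dict(d.get("enamel_thickness_px", {})),
            pixel_size_mm=d.get("pixel_size_mm"),
        )

    @classmethod
    def load(cls, path) -> "LandmarkSet":
        return cls.from_dict(json.loads(Path(path).read_text()))
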