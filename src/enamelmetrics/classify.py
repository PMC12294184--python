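"""Control-derived thresholds and enamel defect classification.

Thresholds for the three discriminative parameters (mean EA, mean DA,
EDMR) are the medians of a healthy control group, reported together with
the interquartile range.  A patient is flagged

* *hypomineralized* when mean EDMR falls strictly below the EDMR cut;
* *hypoplastic by EA* when mean EA falls strictly below the EA cut;
* *hypoplastic by DA* when mean DA falls strictly below the DA cut.

The published control cut-offs are EA 14.63° (q1 12.5°, q3 17°), DA 7.22°
(q1 5.5°, q3 8.75°) and EDMR 1.06 (q1 1.025, q3 1.125); values exactly at
a cut are not flagged.  The two hypoplasia flags are kept separate: cohorts
exist in which the DEJ inclination is distinctly reduced while the enamel
surface inclination is normal (and vice versa), so no combined verdict is
invented.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .geometry import MeasurementRecord

__all__ = ["ThresholdSet", "EnamelClass", "derive_thresholds", "classify",
           "scatter_report", "PAPER_DEFAULT"]

PARAMS = ("ea", "da", "edmr")


@dataclass(frozen=True)
class ThresholdSet:
    """Per-parameter cut-offs (control medians) with their quartiles."""

    ea_cut: float
    da_cut: float
    edmr_cut: float
    quartiles: dict  # param -> (q1, q3)
    source: str = "derived"  # "paper_default" | "derived"

    def cut(self, param: str) -> float:
        return getattr(self, f"{param}_cut")

    def to_toml(self) -> str:
        lines = [f'source = "{self.source}"']
        for p in PARAMS:
            q1, q3 = self.quartiles[p]
            lines += [f"", f"[{p}]", f"cut = {self.cut(p)!r}",
                      f"q1 = {q1!r}", f"q3 = {q3!r}"]
        return "\n".join(lines) + "\n"

    def save(self, path) -> None:
        Path(path).write_text(self.to_toml())

    @classmethod
    def load(cls, path) -> "ThresholdSet":
        import tomllib

        d = tomllib.loads(Path(path).read_text())
        return cls(
            ea_cut=d["ea"]["cut"], da_cut=d["da"]["cut"], edmr_cut=d["edmr"]["cut"],
            quartiles={p: (d[p]["q1"], d[p]["q3"]) for p in PARAMS},
            source=d.get("source", "derived"),
        )


#: published control-group cut-offs
PAPER_DEFAULT = ThresholdSet(
    ea_cut=14.63,
    da_cut=7.22,
    edmr_cut=1.06,
    quartiles={"ea": (12.5, 17.0), "da": (5.5, 8.75), "edmr": (1.025, 1.125)},
    source="paper_default",
)


@dataclass(frozen=True)
class EnamelClass:
    """Flags for one patient; ``None`` means undetermined (the parameter
    was missing from the record)."""

    hypomineralized: bool | None
    hypoplastic_by_ea: bool | None
    hypoplastic_by_da: bool | None


def derive_thresholds(control_records: list[MeasurementRecord]) -> ThresholdSet:
    """Derive cut-offs from a control cohort: per-parameter cut = median of
    the per-patient means, quartiles = 25th/75th percentiles (linear
    interpolation).  Requires at least three complete control records."""
    values = {p: [] for p in PARAMS}
    for rec in control_records:
        for p in PARAMS:
            v = getattr(rec, f"mean_{p}")
            if v is None:
                raise ValueError(f"control record {rec.subject_id} missing mean_{p}")
            values[p].append(v)
    if len(control_records) < 3:
        raise ValueError("need at least 3 control records to derive thresholds")
    cuts = {p: float(np.median(values[p])) for p in PARAMS}
    quart = {p: (float(np.percentile(values[p], 25)),
                 float(np.percentile(values[p], 75))) for p in PARAMS}
    return ThresholdSet(ea_cut=cuts["ea"], da_cut=cuts["da"], edmr_cut=cuts["edmr"],
                        quartiles=quart, source="derived")


def _flag(value: float | None, cut: float) -> bool | None:
    return None if value is None else bool(value < cut)


def classify(record: MeasurementRecord, thresholds: ThresholdSet = PAPER_DEFAULT,
             ) -> EnamelClass:
    """Assign hypomineralization / hypoplasia flags (strict inequalities;
    a value exactly at its cut is unflagged)."""
    return EnamelClass(
        hypomineralized=_flag(record.mean_edmr, thresholds.edmr_cut),
        hypoplastic_by_ea=_flag(record.mean_ea, thresholds.ea_cut),
        hypoplastic_by_da=_flag(record.mean_da, thresholds.da_cut),
    )


def scatter_report(records: list[MeasurementRecord],
                   thresholds: ThresholdSet = PAPER_DEFAULT,
                   path=None) -> dict:
    """Two-panel scatter description (mean EA vs EDMR; mean DA vs EDMR)
    with the hypomineralization band (EDMR below its cut) and hypoplastic
    band (angle below its cut) as shaded strict-inequality half-planes.

    Returns the declarative plot description; renders it with matplotlib
    when *path* is given.
    """
    if not records:
        raise ValueError("no records to plot")
    panels = []
    for angle in ("ea", "da"):
        pts = []
        for r in records:
            x = getattr(r, f"mean_{angle}")
            y = r.mean_edmr
            if x is None or y is None:
                continue
            pts.append({
                "subject_id": r.subject_id,
                "group": r.group or "unlabelled",
                "x": x,
                "y": y,
                "in_hypomineralized_region": y < thresholds.edmr_cut,
                "in_hypoplastic_region": x < thresholds.cut(angle),
            })
        panels.append({
            "x_param": f"mean_{angle}",
            "y_param": "mean_edmr",
            "angle_cut": thresholds.cut(angle),
            "edmr_cut": thresholds.edmr_cut,
            "regions": {
                "hypomineralization": f"mean_edmr < {thresholds.edmr_cut}",
                "hypoplastic": f"mean_{angle} < {thresholds.cut(angle)}",
            },
            "points": pts,
        })
    report = {"thresholds_source": thresholds.source, "panels": panels}
    if path is not None:
        _render_scatter(report, path)
    return report


_GROUP_COLORS = {"control": "tab:green", "affected": "tab:red",
                 "unlabelled": "tab:gray"}


def _render_scatter(report: dict, path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 2, figsize=(10, 4.5), sharey=True)
    for ax, panel in zip(axes, report["panels"]):
        xs = [p["x"] for p in panel["points"]]
        ys = [p["y"] for p in panel["points"]]
        xmax = max(xs + [panel["angle_cut"]]) * 1.15 + 1
        ymin = min(ys + [panel["edmr_cut"]]) - 0.1
        ymax = max(ys + [panel["edmr_cut"]]) + 0.1
        ax.axhspan(ymin, panel["edmr_cut"], color="gold", alpha=0.3,
                   label="hypomineralization")
        ax.axvspan(0, panel["angle_cut"], color="red", alpha=0.2,
                   label="hypoplastic")
        for grp in sorted({p["group"] for p in panel["points"]}):
            gx = [p["x"] for p in panel["points"] if p["group"] == grp]
            gy = [p["y"] for p in panel["points"] if p["group"] == grp]
            ax.scatter(gx, gy, s=22, label=grp,
                       color=_GROUP_COLORS.get(grp, None))
        ax.set_xlim(0, xmax)
        ax.set_ylim(ymin, ymax)
        ax.set_xlabel(panel["x_param"] + " (deg)")
        ax.set_ylabel("mean EDMR")
    axes[0].legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
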