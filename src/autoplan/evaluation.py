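"""DVH computation, dose metrics and constraint reporting.

The constraint table follows the GEC-ESTRO EMBRACE II hard limits (maximum
organ dose below 105 % of the prescription for bladder, rectum, femurs,
spinal cord and bowel) together with the common soft dose-volume limits
(bladder V40Gy<75 %, V30Gy<85 %; rectum V40Gy<85 %, V30Gy<95 %; bowel-space
V40Gy<30 %; femurs V40Gy<15 %) and internal-protocol V45Gy limits (<50 %
bladder, <80 % rectum).  VxGy uses the conventional '>= x Gy' boundary; the
bowel limits are evaluated on the whole bowel space, not on bowel loops.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from .dose import DoseGrid
from .morphology import volume_cc
from .structures import StructureSet

__all__ = [
    "DVHCurve",
    "ConstraintResult",
    "compute_dvh",
    "metric_v",
    "metric_dmax",
    "metric_dcc",
    "embrace_report",
    "report_to_json",
    "report_to_table",
    "dvh_to_csv",
]


@dataclass
class DVHCurve:
    """Cumulative dose-volume histogram of one structure."""

    structure: str
    bin_edges: np.ndarray       # Gy
    cumulative_volume: np.ndarray  # fraction of structure volume with dose >= edge
    absolute_volume_cc: float

    def at(self, dose_gy: float) -> float:
        """Fraction of the structure receiving at least ``dose_gy`` (nearest bin)."""
        idx = int(np.clip(np.searchsorted(self.bin_edges, dose_gy), 0, len(self.bin_edges) - 1))
        return float(self.cumulative_volume[idx])


@dataclass
class ConstraintResult:
    structure: str
    metric: str          # e.g. "Dmax", "V40Gy"
    value: float | None  # None when not evaluable
    limit: float
    comparator: str      # "<"
    severity: str        # "hard" | "soft"
    unit: str            # "Gy" | "%"

    @property
    def evaluable(self) -> bool:
        return self.value is not None

    @property
    def passed(self) -> bool | None:
        if self.value is None:
            return None
        return bool(self.value < self.limit)


def compute_dvh(dose: DoseGrid, mask: np.ndarray, bin_width_gy: float = 0.1,
                structure: str = "") -> DVHCurve:
    """Cumulative DVH by voxel counting."""
    mask = dose.geometry.check_mask(mask)
    if not mask.any():
        raise ValueError(f"cannot compute a DVH for empty structure '{structure}'")
    if bin_width_gy <= 0:
        raise ValueError("bin width must be positive")
    vals = dose.values[mask]
    top = float(vals.max())
    edges = np.arange(0.0, top + 2 * bin_width_gy, bin_width_gy)
    hist, _ = np.histogram(vals, bins=np.append(edges, np.inf))
    counts = hist[::-1].cumsum()[::-1] / vals.size
    return DVHCurve(
        structure=structure,
        bin_edges=edges,
        cumulative_volume=np.asarray(counts, dtype=float),
        absolute_volume_cc=volume_cc(mask, dose.geometry),
    )


def metric_v(dose: DoseGrid, mask: np.ndarray, x_gy: float) -> tuple[float, float]:
    """VxGy: (percent of structure, absolute cc) receiving at least ``x_gy``."""
    mask = dose.geometry.check_mask(mask)
    if not mask.any():
        raise ValueError("VxGy of an empty structure is undefined")
    sel = dose.values[mask] >= x_gy
    frac = float(sel.mean())
    return 100.0 * frac, frac * volume_cc(mask, dose.geometry)


def metric_dmax(dose: DoseGrid, mask: np.ndarray) -> float:
    """Maximum voxel dose inside the structure, Gy."""
    mask = dose.geometry.check_mask(mask)
    if not mask.any():
        raise ValueError("Dmax of an empty structure is undefined")
    return float(dose.values[mask].max())


def metric_dcc(dose: DoseGrid, mask: np.ndarray, v_cc: float) -> float:
    """Minimum dose among the hottest ``v_cc`` of the structure, Gy."""
    mask = dose.geometry.check_mask(mask)
    total = volume_cc(mask, dose.geometry)
    if v_cc <= 0 or v_cc > total:
        raise ValueError(f"requested volume {v_cc} cc outside (0, {total:.2f}] cc")
    vals = np.sort(dose.values[mask])[::-1]
    n = int(np.ceil(v_cc / dose.geometry.voxel_volume_cc))
    return float(vals[min(n, vals.size) - 1])


# (structure key, metric, threshold Gy or None for Dmax, limit, severity)
# Hard limits: Dmax < 1.05 × rx.  Soft/internal: VxGy < limit %.
_RULES: tuple[tuple[str, str, float | None, float | None, str], ...] = (
    ("bladder", "Dmax", None, None, "hard"),
    ("rectum", "Dmax", None, None, "hard"),
    ("femurs", "Dmax", None, None, "hard"),
    ("spinal_cord", "Dmax", None, None, "hard"),
    ("bowel_space", "Dmax", None, None, "hard"),
    ("bladder", "V40Gy", 40.0, 75.0, "soft"),
    ("bladder", "V30Gy", 30.0, 85.0, "soft"),
    ("bladder", "V45Gy", 45.0, 50.0, "soft"),
    ("rectum", "V40Gy", 40.0, 85.0, "soft"),
    ("rectum", "V30Gy", 30.0, 95.0, "soft"),
    ("rectum", "V45Gy", 45.0, 80.0, "soft"),
    ("bowel_space", "V40Gy", 40.0, 30.0, "soft"),
    ("femurs", "V40Gy", 40.0, 15.0, "soft"),
)

HARD_DMAX_FRACTION = 1.05


def embrace_report(dose: DoseGrid, structures: StructureSet, rx: float) -> list[ConstraintResult]:
    """Evaluate the full constraint table; missing structures are reported as
    not-evaluable rather than silently passed."""
    results: list[ConstraintResult] = []
    for struct, metric, x_gy, limit_pct, severity in _RULES:
        if struct == "femurs":
            present = "femur_l" in structures and "femur_r" in structures
            mask = structures.femurs if present else None
        else:
            present = struct in structures
            mask = structures[struct] if present else None
        evaluable = present and mask is not None and bool(mask.any())
        if metric == "Dmax":
            limit = HARD_DMAX_FRACTION * rx
            value = metric_dmax(dose, mask) if evaluable else None
            results.append(ConstraintResult(struct, "Dmax", value, limit, "<", severity, "Gy"))
        else:
            value = metric_v(dose, mask, x_gy)[0] if evaluable else None
            results.append(ConstraintResult(struct, metric, value, limit_pct, "<", severity, "%"))
    return results


def report_to_json(results: list[ConstraintResult]) -> str:
    rows = []
    for r in results:
        d = asdict(r)
        d["pass"] = r.passed
        rows.append(d)
    return json.dumps({"format": "autoplan-report-v1", "constraints": rows}, indent=2)


def report_to_table(results: list[ConstraintResult]) -> str:
    lines = [f"{'structure':<12} {'metric':<7} {'value':>9} {'limit':>9} {'sev':<5} {'pass':<4}"]
    for r in results:
        val = f"{r.value:.2f}{r.unit}" if r.value is not None else "n/a"
        status = {True: "yes", False: "NO", None: "n/e"}[r.passed]
        lines.append(
            f"{r.structure:<12} {r.metric:<7} {val:>9} "
            f"{f'{r.limit:.2f}{r.unit}':>9} {r.severity:<5} {status:<4}"
        )
    return "\n".join(lines)


def plot_dvh(curves: list[DVHCurve], rx: float | None = None, ax=None):
    """Cumulative DVH plot (requires matplotlib, an optional dependency)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    for curve in curves:
        ax.plot(curve.bin_edges, 100 * curve.cumulative_volume, label=curve.structure)
    if rx is not None:
        ax.axvline(rx, color="k", lw=0.8, ls="--", label="rx")
    ax.set_xlabel("dose (Gy)")
    ax.set_ylabel("volume (%)")
    ax.set_ylim(0, 105)
    ax.legend(fontsize=8)
    return ax


def dvh_to_csv(curves: list[DVHCurve], path: str | Path) -> Path:
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["structure", "dose_gy", "fraction", "cc"])
        for curve in curves:
            for edge, frac in zip(curve.bin_edges, curve.cumulative_volume):
                writer.writerow(
                    [curve.structure, f"{edge:.3f}", f"{frac:.6f}",
                     f"{frac * curve.absolute_volume_cc:.4f}"]
                )
    return path
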