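"""Dosimetric impact of residual tracking errors.

The residual error series of a patient (predicted minus reference target
position per image) is turned into a dose perturbation by rigidly
shifting the planned dose grid:

* *stochastic accumulation*: for each of ``n_fractions`` fractions and
  each beam of the plan, one residual shift is drawn uniformly from the
  series and applied to that beam's per-fraction dose; the sum over all
  beams and fractions is one accumulated course.  Repeating the draw
  (default 10 repeats) yields a band of dose-volume histograms.
* *expectation dose*: the mean of the total plan shifted by every
  residual in the series - the infinite-repeat limit.

DVH curves and the dose metrics D95% (dose covering 95% of a structure)
and D0.5cc (dose received by the hottest 0.5 cm^3) quantify the impact.
Doses are in Gy, distances in mm; the default grid resolution is
2 x 2 x 2 mm^3.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "DoseGrid",
    "DVHCurve",
    "shift_dose",
    "stochastic_accumulate",
    "expectation_dose",
    "dvh",
    "dose_metrics",
    "impact_report",
]


@dataclass(frozen=True)
class DoseGrid:
    """A 3D dose distribution (Gy) on a regular grid."""

    dose: np.ndarray
    spacing: tuple[float, float, float] = (2.0, 2.0, 2.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        dose = np.asarray(self.dose, dtype=float)
        if dose.ndim != 3:
            raise ValueError("dose must be 3D")
        if not np.all(np.isfinite(dose)) or dose.min() < 0:
            raise ValueError("dose must be finite and non-negative")
        object.__setattr__(self, "dose", dose)

    @property
    def voxel_volume_cc(self) -> float:
        sx, sy, sz = self.spacing
        return sx * sy * sz / 1000.0

    def like(self, dose: np.ndarray) -> "DoseGrid":
        return DoseGrid(dose, self.spacing, self.origin)


@dataclass(frozen=True)
class DVHCurve:
    """Cumulative dose-volume histogram: fraction of volume receiving >= D."""

    dose_gy: np.ndarray
    volume_fraction: np.ndarray


def shift_dose(grid: DoseGrid, offset_mm) -> DoseGrid:
    """Rigidly translate the dose cloud by ``offset_mm`` (patient frame).

    Trilinear resampling; samples falling outside the original grid are
    zero (synthetic grids carry a zero-dose pad so structures never see
    the fill value for realistic shifts).
    """
    offset = np.asarray(offset_mm, dtype=float)
    if offset.shape != (3,) or not np.all(np.isfinite(offset)):
        raise ValueError("offset must be a finite 3-vector (mm)")
    if not offset.any():
        return grid.like(grid.dose.copy())  # exact identity, no resampling
    voxels = offset / np.asarray(grid.spacing)
    shifted = ndimage.shift(grid.dose, voxels, order=1, mode="constant", cval=0.0)
    return grid.like(np.clip(shifted, 0.0, None))


def stochastic_accumulate(
    beam_doses: list[DoseGrid],
    shifts: np.ndarray,
    n_fractions: int = 5,
    n_repeats: int = 10,
    seed: int | np.random.Generator = 0,
) -> list[DoseGrid]:
    """Accumulate the plan under per-beam random residual shifts.

    For each repeat, fraction and beam, one index into the residual-shift
    series is drawn uniformly and the beam's per-fraction dose (total
    beam dose / n_fractions) is translated by that shift; everything is
    summed into one accumulated course per repeat.  Shift indices are
    drawn independently for every (repeat, fraction, beam).
    Deterministic for a fixed seed.
    """
    shifts = np.atleast_2d(np.asarray(shifts, dtype=float))
    if len(beam_doses) == 0:
        raise ValueError("need at least one beam")
    if shifts.shape[0] == 0 or shifts.shape[1] != 3:
        raise ValueError("shifts must be a non-empty (n, 3) array (mm)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_shifts = shifts.shape[0]
    repeats = []
    for _ in range(n_repeats):
        draw = rng.integers(0, n_shifts, size=(n_fractions, len(beam_doses)))
        acc = np.zeros_like(beam_doses[0].dose)
        for m in range(n_fractions):
            # group beams sharing a drawn shift: one resampling per index
            for idx in np.unique(draw[m]):
                member = np.flatnonzero(draw[m] == idx)
                partial = sum(beam_doses[k].dose for k in member) / n_fractions
                acc += shift_dose(beam_doses[0].like(partial), shifts[idx]).dose
        repeats.append(beam_doses[0].like(acc))
    return repeats


def expectation_dose(total_dose: DoseGrid, shifts: np.ndarray) -> DoseGrid:
    """Mean of the total plan translated by every residual shift.

    The infinite-repeat limit of the stochastic accumulation, in which
    every part of the plan receives every observed shift.
    """
    shifts = np.atleast_2d(np.asarray(shifts, dtype=float))
    if shifts.shape[0] == 0 or shifts.shape[1] != 3:
        raise ValueError("shifts must be a non-empty (n, 3) array (mm)")
    acc = np.zeros_like(total_dose.dose)
    for s in shifts:
        acc += shift_dose(total_dose, s).dose
    return total_dose.like(acc / shifts.shape[0])


def dvh(grid: DoseGrid, mask: np.ndarray, bin_width: float = 0.1) -> DVHCurve:
    """Cumulative DVH of the masked voxels on a fixed 0.1 Gy dose axis."""
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != grid.dose.shape:
        raise ValueError("mask and dose grid shapes differ")
    doses = grid.dose[mask]
    if doses.size == 0:
        raise ValueError("structure mask is empty")
    top = float(doses.max())
    axis = np.arange(0.0, top + 2 * bin_width, bin_width)
    volume = (doses[None, :] >= axis[:, None]).mean(axis=1)
    volume[0] = 1.0  # every voxel receives >= 0 Gy
    return DVHCurve(dose_gy=axis, volume_fraction=volume)


def dose_metrics(grid: DoseGrid, mask: np.ndarray, structure: str = "structure") -> dict:
    """D95%, D0.5cc, Dmin, Dmax and Dmean of a structure (Gy).

    D95% is the dose received by at least 95% of the structure volume
    (5th percentile of the voxel doses, linear interpolation).  D0.5cc is
    the dose D such that exactly 0.5 cm^3 receives >= D, interpolated on
    the sorted cumulative-volume curve of the exact voxel list.
    """
    mask = np.asarray(mask, dtype=bool)
    doses = grid.dose[mask]
    if doses.size == 0:
        raise ValueError(f"structure mask for {structure!r} is empty")
    vv = grid.voxel_volume_cc
    total_cc = doses.size * vv
    out = {
        "d95_gy": float(np.percentile(doses, 5)),
        "dmin_gy": float(doses.min()),
        "dmax_gy": float(doses.max()),
        "dmean_gy": float(doses.mean()),
        "volume_cc": total_cc,
    }
    if total_cc > 0.5:
        desc = np.sort(doses)[::-1]
        cum_cc = (np.arange(desc.size) + 1) * vv
        out["d05cc_gy"] = float(np.interp(0.5, cum_cc, desc))
    else:
        raise ValueError(
            f"structure {structure!r} volume {total_cc:.3f} cc is too small "
            "for D0.5cc"
        )
    return out


def impact_report(
    planned: DoseGrid,
    repeats: list[DoseGrid],
    expectation: DoseGrid,
    masks: dict[str, np.ndarray],
) -> tuple[pd.DataFrame, dict[str, dict]]:
    """Per-structure planned-vs-accumulated metrics and DVH bands.

    Returns a table with planned and expectation D95%/D0.5cc and their
    differences per structure, and per structure the planned and
    expectation DVH curves plus the voxelwise min/max band over the
    stochastic repeats (evaluated on a shared dose axis).
    """
    for g in [*repeats, expectation]:
        if g.dose.shape != planned.dose.shape or g.spacing != planned.spacing:
            raise ValueError("all dose grids must be aligned with the plan")
    rows = []
    curves: dict[str, dict] = {}
    for name, mask in masks.items():
        p = dose_metrics(planned, mask, name)
        e = dose_metrics(expectation, mask, name)
        rows.append(
            {
                "structure": name,
                "planned_d95_gy": p["d95_gy"],
                "expected_d95_gy": e["d95_gy"],
                "delta_d95_gy": p["d95_gy"] - e["d95_gy"],
                "planned_d05cc_gy": p["d05cc_gy"],
                "expected_d05cc_gy": e["d05cc_gy"],
                "delta_d05cc_gy": p["d05cc_gy"] - e["d05cc_gy"],
            }
        )
        planned_curve = dvh(planned, mask)
        axis = planned_curve.dose_gy
        top = max([axis[-1]] + [float(g.dose[mask].max()) for g in repeats]
                  + [float(expectation.dose[mask].max())])
        axis = np.arange(0.0, top + 0.2, 0.1)

        def _on_axis(g):
            d = g.dose[np.asarray(mask, bool)]
            return (d[None, :] >= axis[:, None]).mean(axis=1)

        repeat_curves = np.array([_on_axis(g) for g in repeats])
        curves[name] = {
            "dose_gy": axis,
            "planned": _on_axis(planned),
            "expectation": _on_axis(expectation),
            "band_min": repeat_curves.min(axis=0),
            "band_max": repeat_curves.max(axis=0),
        }
    return pd.DataFrame(rows), curves
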