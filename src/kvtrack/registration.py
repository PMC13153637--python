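"""Two-stage rigid registration of treatment images to DRRs.

Stage 1 registers the whole images of the two oblique views in a coupled
manner: a shared superior-inferior shift ``J_AB`` is applied to both views
while the left-right shifts ``I_A`` and ``I_B`` are optimised
independently inside the ``J`` loop (two passes: +-20 px step 4, then
+-2 px step 1).

Stage 2 refines the result in a 5x5 grid of 50%-overlapping subregions
per image (each a free 2D search, passes +-10/2 then +-1/1) and in one
additional coupled search restricted to the beam's-eye-view bounding box
of the PTV plus a 20 mm margin.

Every candidate shift is scored by gamma = NMS * NMI: a normalised
mean-square similarity (spatial agreement) times a normalised mutual
information (robust to residual intensity mismatch), both evaluated on
the shifted overlap of the region.

The outcome per image pair is a 104-component registration vector:
2 views x 26 regions (25 grid + 1 PTV) x 2 shift components, in mm.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from kvtrack.geometry import CoupledShift, ImagingGeometry, project

__all__ = [
    "RegistrationRegion",
    "ObjectiveValue",
    "RegionMatcher",
    "nms",
    "nmi",
    "objective",
    "coupled_search",
    "subregion_search",
    "ptv_region_search",
    "assemble_vector",
    "grid_regions",
    "ptv_bounding_box",
    "register_pair",
    "GLOBAL_PASSES",
    "SUBREGION_PASSES",
    "DegenerateRegionError",
]

#: (half-range, step) schedules: whole-image coupled stage and subregion stage.
GLOBAL_PASSES: tuple[tuple[int, int], ...] = ((20, 4), (2, 1))
SUBREGION_PASSES: tuple[tuple[int, int], ...] = ((10, 2), (1, 1))

N_BINS = 128


class DegenerateRegionError(ValueError):
    """Raised when a registration region carries no usable information."""


@dataclass(frozen=True)
class RegistrationRegion:
    """Half-open, 0-based pixel bounds of a registration region."""

    row_start: int
    row_stop: int
    col_start: int
    col_stop: int
    role: str = "grid"

    def __post_init__(self) -> None:
        if self.row_stop <= self.row_start or self.col_stop <= self.col_start:
            raise ValueError(f"empty region {self}")

    def clamped(self, shape) -> "RegistrationRegion":
        r0 = max(self.row_start, 0)
        c0 = max(self.col_start, 0)
        r1 = min(self.row_stop, shape[0])
        c1 = min(self.col_stop, shape[1])
        if r1 <= r0 or c1 <= c0:
            raise DegenerateRegionError(f"region {self} empty after clamping to {shape}")
        return RegistrationRegion(r0, r1, c0, c1, self.role)


@dataclass(frozen=True)
class ObjectiveValue:
    """Similarity scores of one candidate shift; higher is better."""

    nms: float
    nmi: float

    @property
    def gamma(self) -> float:
        return self.nms * self.nmi


def grid_regions(size: int) -> list[RegistrationRegion]:
    """The 5x5 matrix of subregions with 50% overlap.

    Region width is floor(2 * size / 6) and the stride half of that, so
    five regions span the image per axis; the last region is clamped to
    the image edge.
    """
    w = (2 * size) // 6
    stride = w // 2
    starts = []
    for i in range(5):
        s = i * stride
        if s + w > size:
            s = size - w
        starts.append(s)
    regions = []
    for i, rs in enumerate(starts):
        for j, cs in enumerate(starts):
            regions.append(
                RegistrationRegion(rs, rs + w, cs, cs + w, role=f"grid({i},{j})")
            )
    return regions


def ptv_bounding_box(
    ptv_center_mm: Sequence[float],
    ptv_radius_mm: float,
    geometry: ImagingGeometry,
    view: str,
    margin_mm: float = 20.0,
) -> RegistrationRegion:
    """Beam's-eye-view bounding box of a spherical PTV plus a margin.

    The patient origin projects to the image centre; the PTV centre's
    in-plane coordinates follow the oblique projection relations (view A
    lateral coordinate R(x - y), view B R(x + y), rows running inferior).
    """
    x, y, z = (float(v) for v in ptv_center_mm)
    sp = geometry.pixel_spacing
    c0 = (geometry.image_size - 1) / 2.0
    shift = project((x, y, z))
    lateral = shift.I_A if view == "A" else shift.I_B
    col = c0 + lateral / sp
    row = c0 + shift.J_AB / sp
    half = (ptv_radius_mm + margin_mm) / sp
    region = RegistrationRegion(
        int(np.floor(row - half)),
        int(np.ceil(row + half)) + 1,
        int(np.floor(col - half)),
        int(np.ceil(col + half)) + 1,
        role="ptv",
    )
    return region.clamped((geometry.image_size, geometry.image_size))


class RegionMatcher:
    """Scores integer shifts of one treatment-image region against a DRR region.

    The NMI histogram range (128 equal-width bins) is fixed from the union
    of both images over the region at zero shift and held constant while
    the search explores candidate shifts, so the bin edges do not move
    under the optimiser.  Treatment pixels falling outside the image at a
    candidate shift are excluded and the pixel count reduced accordingly.
    """

    def __init__(self, drr: np.ndarray, treatment: np.ndarray, region: RegistrationRegion):
        self.region = region = region.clamped(drr.shape)
        self.treatment = np.asarray(treatment, dtype=float)
        self.drr_region = np.asarray(
            drr[region.row_start : region.row_stop, region.col_start : region.col_stop],
            dtype=float,
        )
        t0 = self.treatment[
            region.row_start : region.row_stop, region.col_start : region.col_stop
        ]
        lo = min(self.drr_region.min(), t0.min())
        hi = max(self.drr_region.max(), t0.max())
        self._lo = lo
        self._width = (hi - lo) / N_BINS if hi > lo else 0.0
        self._d_idx = self._digitize(self.drr_region)
        self._t_idx_full = self._digitize(self.treatment)

    def _digitize(self, values: np.ndarray) -> np.ndarray:
        if self._width == 0.0:
            return np.zeros(values.shape, dtype=np.int64)
        idx = np.floor((values - self._lo) / self._width).astype(np.int64)
        return np.clip(idx, 0, N_BINS - 1)

    def _overlap(self, I: int, J: int):
        """Cropped DRR block, treatment block and index blocks at shift (I, J)."""
        reg = self.region
        n_rows, n_cols = self.treatment.shape
        r0, r1 = reg.row_start + J, reg.row_stop + J
        c0, c1 = reg.col_start + I, reg.col_stop + I
        tr0, tr1 = max(r0, 0), min(r1, n_rows)
        tc0, tc1 = max(c0, 0), min(c1, n_cols)
        if tr1 <= tr0 or tc1 <= tc0:
            raise DegenerateRegionError(
                f"shift ({I}, {J}) leaves no overlap for region {reg}"
            )
        dr0, dr1 = tr0 - r0, tr1 - r0
        dc0, dc1 = tc0 - c0, tc1 - c0
        d_block = self.drr_region[dr0:dr1, dc0:dc1]
        t_block = self.treatment[tr0:tr1, tc0:tc1]
        d_idx = self._d_idx[dr0:dr1, dc0:dc1]
        t_idx = self._t_idx_full[tr0:tr1, tc0:tc1]
        return d_block, t_block, d_idx, t_idx

    def nms(self, I: int = 0, J: int = 0) -> float:
        d, t, _, _ = self._overlap(I, J)
        norm = max(d.max() - t.min(), t.max() - d.min()) ** 2
        if norm == 0.0:
            return 1.0  # both blocks constant and equal
        diff = t - d
        return 1.0 - float(np.mean(diff * diff)) / norm

    def nmi(self, I: int = 0, J: int = 0) -> float:
        _, _, d_idx, t_idx = self._overlap(I, J)
        counts = np.bincount(
            (d_idx * N_BINS + t_idx).ravel(), minlength=N_BINS * N_BINS
        ).reshape(N_BINS, N_BINS)
        p = counts / counts.sum()
        nz = p[p > 0]
        h_joint = -float(np.sum(nz * np.log(nz)))
        if h_joint == 0.0:
            raise DegenerateRegionError(
                "joint histogram collapsed to a single cell (constant regions)"
            )
        pd = p.sum(axis=1)
        pt = p.sum(axis=0)
        pd = pd[pd > 0]
        pt = pt[pt > 0]
        h_d = -float(np.sum(pd * np.log(pd)))
        h_t = -float(np.sum(pt * np.log(pt)))
        return (h_d + h_t) / h_joint

    def objective(self, I: int = 0, J: int = 0) -> ObjectiveValue:
        s = self.nms(I, J)
        try:
            m = self.nmi(I, J)
        except DegenerateRegionError:
            # both regions constant: information content identical,
            # treated as a perfect-match NMI of 2
            m = 2.0
        return ObjectiveValue(nms=s, nmi=m)

    def gamma(self, I: int = 0, J: int = 0) -> float:
        return self.objective(I, J).gamma

    def gamma_or_worst(self, I: int = 0, J: int = 0) -> float:
        """gamma, with candidates that leave no overlap scored -inf."""
        try:
            return self.objective(I, J).gamma
        except DegenerateRegionError:
            return -np.inf


def nms(drr_region: np.ndarray, treatment_region: np.ndarray, shift=(0, 0)) -> float:
    """Normalised mean-square similarity of two equally-shaped regions.

    ``1 - (1/(N n)) sum (T(i+I, j+J) - D(i, j))^2`` with N the squared
    largest possible intensity excursion between the two blocks.
    """
    m = RegionMatcher(
        np.asarray(drr_region, float),
        np.asarray(treatment_region, float),
        RegistrationRegion(0, np.asarray(drr_region).shape[0], 0, np.asarray(drr_region).shape[1]),
    )
    return m.nms(int(shift[0]), int(shift[1]))


def nmi(drr_region: np.ndarray, treatment_region: np.ndarray, shift=(0, 0)) -> float:
    """Normalised mutual information (H(D) + H(T)) / H(D, T), 128 bins."""
    m = RegionMatcher(
        np.asarray(drr_region, float),
        np.asarray(treatment_region, float),
        RegistrationRegion(0, np.asarray(drr_region).shape[0], 0, np.asarray(drr_region).shape[1]),
    )
    return m.nmi(int(shift[0]), int(shift[1]))


def objective(drr: np.ndarray, treatment: np.ndarray, region: RegistrationRegion, shift=(0, 0)) -> ObjectiveValue:
    """gamma = NMS * NMI for one region at one candidate shift."""
    return RegionMatcher(drr, treatment, region).objective(int(shift[0]), int(shift[1]))


def _candidates(center: int, half_range: int, step: int) -> np.ndarray:
    return np.arange(center - half_range, center + half_range + 1, step, dtype=int)


def _better(score, norm, key, best) -> bool:
    """Deterministic argmax ordering: score desc, |shift| asc, raster asc."""
    if best is None:
        return True
    b_score, b_norm, b_key = best
    if score != b_score:
        return score > b_score
    if norm != b_norm:
        return norm < b_norm
    return key < b_key


def coupled_search(
    drr_A: np.ndarray,
    drr_B: np.ndarray,
    treatment_A: np.ndarray,
    treatment_B: np.ndarray,
    region_A: RegistrationRegion | None = None,
    region_B: RegistrationRegion | None = None,
    passes: Iterable[tuple[int, int]] = GLOBAL_PASSES,
    start: tuple[int, int, int] = (0, 0, 0),
) -> CoupledShift:
    """Maximise the summed objective over (I_A, I_B, J_AB), J shared.

    Nested exhaustive grid search: the outer loop walks the shared
    superior-inferior shift ``J_AB``; for each ``J`` the lateral shifts of
    the two views are maximised independently and the per-view optima
    summed.  Later passes re-centre on the previous optimum.  Returns the
    shift in pixels.
    """
    if region_A is None:
        region_A = RegistrationRegion(0, drr_A.shape[0], 0, drr_A.shape[1], role="global")
    if region_B is None:
        region_B = RegistrationRegion(0, drr_B.shape[0], 0, drr_B.shape[1], role="global")
    m_A = RegionMatcher(drr_A, treatment_A, region_A)
    m_B = RegionMatcher(drr_B, treatment_B, region_B)

    best_IA, best_IB, best_J = (int(v) for v in start)
    for half_range, step in passes:
        best = None
        sol = None
        for J in _candidates(best_J, half_range, step).tolist():
            inner = []
            for matcher, center in ((m_A, best_IA), (m_B, best_IB)):
                best_i = None
                pick = None
                for I in _candidates(center, half_range, step).tolist():
                    g = matcher.gamma_or_worst(I, J)
                    if _better(g, abs(I), I, best_i):
                        best_i = (g, abs(I), I)
                        pick = (g, I)
                inner.append(pick)
            total = inner[0][0] + inner[1][0]
            norm = inner[0][1] ** 2 + inner[1][1] ** 2 + J * J
            if _better(total, norm, J, best):
                best = (total, norm, J)
                sol = (inner[0][1], inner[1][1], J)
        best_IA, best_IB, best_J = sol
    return CoupledShift(I_A=best_IA, I_B=best_IB, J_AB=best_J, unit="pixels")


def _search_2d(
    matcher: RegionMatcher,
    passes: Iterable[tuple[int, int]],
    start: tuple[int, int],
) -> tuple[int, int]:
    """Free 2D exhaustive search over (I, J) for a single region."""
    best_I, best_J = (int(v) for v in start)
    for half_range, step in passes:
        best = None
        sol = None
        for J in _candidates(best_J, half_range, step).tolist():
            for I in _candidates(best_I, half_range, step).tolist():
                g = matcher.gamma_or_worst(I, J)
                if _better(g, I * I + J * J, (J, I), best):
                    best = (g, I * I + J * J, (J, I))
                    sol = (I, J)
        best_I, best_J = sol
    return best_I, best_J


def subregion_search(
    drr: np.ndarray,
    treatment: np.ndarray,
    start: tuple[int, int],
    passes: Iterable[tuple[int, int]] = SUBREGION_PASSES,
) -> np.ndarray:
    """Refine one image's registration in the 5x5 overlapping subregions.

    Each region is searched independently in both components, seeded at
    the whole-image result.  Returns an array of shape (5, 5, 2) holding
    (I, J) per region, in pixels.
    """
    size = drr.shape[0]
    out = np.zeros((5, 5, 2), dtype=int)
    for k, region in enumerate(grid_regions(size)):
        matcher = RegionMatcher(drr, treatment, region)
        i, j = _search_2d(matcher, passes, start)
        out[k // 5, k % 5] = (i, j)
    return out


def ptv_region_search(
    drr_A: np.ndarray,
    drr_B: np.ndarray,
    treatment_A: np.ndarray,
    treatment_B: np.ndarray,
    ptv_box_A: RegistrationRegion,
    ptv_box_B: RegistrationRegion,
    start: tuple[int, int, int],
    passes: Iterable[tuple[int, int]] = SUBREGION_PASSES,
) -> CoupledShift:
    """Coupled registration restricted to the PTV bounding boxes.

    Shares the superior-inferior shift between the views (same structure
    as the whole-image stage) but runs on the PTV region with the
    subregion pass schedule, seeded at the whole-image optimum.
    """
    return coupled_search(
        drr_A,
        drr_B,
        treatment_A,
        treatment_B,
        region_A=ptv_box_A,
        region_B=ptv_box_B,
        passes=passes,
        start=start,
    )


def assemble_vector(
    grid_A: np.ndarray,
    grid_B: np.ndarray,
    ptv_shift: CoupledShift,
    pixel_spacing: float,
) -> np.ndarray:
    """Pack the registration results into the 104-component vector (mm).

    Ordering: view A's 25 grid regions in raster order, each contributing
    (I, J), then view A's PTV slot (I_A, J_AB); then view B likewise.
    The motion model depends on this ordering.
    """
    grid_A = np.asarray(grid_A, dtype=float)
    grid_B = np.asarray(grid_B, dtype=float)
    if grid_A.shape != (5, 5, 2) or grid_B.shape != (5, 5, 2):
        raise ValueError("grid shift arrays must have shape (5, 5, 2)")
    if ptv_shift.unit != "pixels":
        raise ValueError("ptv_shift must be in pixels")
    parts = [
        grid_A.reshape(-1),
        np.array([ptv_shift.I_A, ptv_shift.J_AB], dtype=float),
        grid_B.reshape(-1),
        np.array([ptv_shift.I_B, ptv_shift.J_AB], dtype=float),
    ]
    return np.concatenate(parts) * pixel_spacing


def register_pair(
    drr_A: np.ndarray,
    drr_B: np.ndarray,
    treatment_A: np.ndarray,
    treatment_B: np.ndarray,
    geometry: ImagingGeometry,
    ptv_box_A: RegistrationRegion,
    ptv_box_B: RegistrationRegion,
) -> tuple[np.ndarray, CoupledShift]:
    """Run the full two-stage registration on one (preprocessed) image pair.

    Returns the 104-component registration vector (mm) and the coupled
    PTV-region shift (pixels).
    """
    global_shift = coupled_search(drr_A, drr_B, treatment_A, treatment_B)
    grid_A = subregion_search(drr_A, treatment_A, (global_shift.I_A, global_shift.J_AB))
    grid_B = subregion_search(drr_B, treatment_B, (global_shift.I_B, global_shift.J_AB))
    ptv = ptv_region_search(
        drr_A,
        drr_B,
        treatment_A,
        treatment_B,
        ptv_box_A,
        ptv_box_B,
        start=(int(global_shift.I_A), int(global_shift.I_B), int(global_shift.J_AB)),
    )
    vector = assemble_vector(grid_A, grid_B, ptv, geometry.pixel_spacing)
    return vector, ptv
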