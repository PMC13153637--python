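"""Inter/intra-fraction linear motion models with a truncated-SVD solver.

Each image pair yields a 104-component registration vector v and a
reference 3D target position r.  Both are split into a per-fraction mean
(inter-fraction part) and a residual about that mean (intra-fraction
part):

    v_mn = v_m + v'_mn   =>   r_mn = r_m + r'_mn

Two affine models are fitted by least squares on the design matrix
A = [V, 1] using a singular value decomposition A = U W V^T, with
reciprocal singular values zeroed for singular values below W_max / R
before forming x = V W^-1 U^T b.  The cutoff ratio R regularises the
solution: R = 1.2 for the inter-fraction model (aggressive, because the
daily baseline is hard to predict from the images), R = 7.0 for the
intra-fraction model.

Tracking scenarios:

* without daily volumetric imaging (DVI):
  r_mn = f_inter(v_m) + f_intra(v_mn - v_m)
* with DVI (the fraction's mean position r_m is known from pre-fraction
  volumetric imaging): r_mn = r_m + f_intra(v_mn - v_m)

Leave-one-out cross validation over patients produces per-patient and
pooled error tables (min / lower quartile / median / upper quartile /
max of the 3D and per-axis errors).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "R_INTER",
    "R_INTRA",
    "ObservationSet",
    "MotionModel",
    "decompose",
    "fit_svd",
    "build_design",
    "track_without_dvi",
    "track_with_dvi",
    "loocv",
    "fitting_set_table",
    "error_stats",
]

#: Default singular-value cutoff ratios.
R_INTER: float = 1.2
R_INTRA: float = 7.0

N_COMPONENTS = 104


@dataclass
class ObservationSet:
    """Paired registration vectors and reference positions with indices."""

    v: np.ndarray  # (n, 104) mm
    r: np.ndarray  # (n, 3) mm
    patient: np.ndarray  # (n,)
    fraction: np.ndarray  # (n,)
    image: np.ndarray  # (n,)

    def __post_init__(self) -> None:
        self.v = np.asarray(self.v, dtype=float)
        self.r = np.asarray(self.r, dtype=float)
        n = self.v.shape[0]
        if self.v.ndim != 2:
            raise ValueError("v must be 2D (n_obs, n_components)")
        if self.r.shape != (n, 3):
            raise ValueError(f"r must have shape ({n}, 3)")
        if not (np.all(np.isfinite(self.v)) and np.all(np.isfinite(self.r))):
            raise ValueError("observations must be finite")
        for name in ("patient", "fraction", "image"):
            arr = np.asarray(getattr(self, name))
            if arr.shape != (n,):
                raise ValueError(f"{name} index must have length {n}")
            setattr(self, name, arr)

    def __len__(self) -> int:
        return self.v.shape[0]

    def subset(self, mask: np.ndarray) -> "ObservationSet":
        return ObservationSet(
            self.v[mask], self.r[mask],
            self.patient[mask], self.fraction[mask], self.image[mask],
        )

    def patients(self) -> np.ndarray:
        return np.unique(self.patient)


@dataclass
class Decomposition:
    """Per-fraction means and residuals of an observation set."""

    #: one row per (patient, fraction): mean v_m and r_m
    v_mean: np.ndarray
    r_mean: np.ndarray
    keys: list[tuple]
    #: per-image residuals, aligned with the source observation set
    v_resid: np.ndarray
    r_resid: np.ndarray
    #: index into keys for every image row
    group_index: np.ndarray


def decompose(obs: ObservationSet) -> Decomposition:
    """Split observations into per-fraction means and zero-mean residuals.

    v_m (and r_m) are the arithmetic means over the images of fraction m;
    residuals are value minus fraction mean, so they sum to zero exactly
    within every fraction.
    """
    if len(obs) == 0:
        raise ValueError("empty observation set")
    keys = []
    key_of = {}
    group_index = np.empty(len(obs), dtype=int)
    for i, (p, m) in enumerate(zip(obs.patient.tolist(), obs.fraction.tolist())):
        k = (p, m)
        if k not in key_of:
            key_of[k] = len(keys)
            keys.append(k)
        group_index[i] = key_of[k]
    n_groups = len(keys)
    v_mean = np.zeros((n_groups, obs.v.shape[1]))
    r_mean = np.zeros((n_groups, 3))
    counts = np.bincount(group_index, minlength=n_groups).astype(float)
    np.add.at(v_mean, group_index, obs.v)
    np.add.at(r_mean, group_index, obs.r)
    v_mean /= counts[:, None]
    r_mean /= counts[:, None]
    return Decomposition(
        v_mean=v_mean,
        r_mean=r_mean,
        keys=keys,
        v_resid=obs.v - v_mean[group_index],
        r_resid=obs.r - r_mean[group_index],
        group_index=group_index,
    )


def build_design(v: np.ndarray) -> np.ndarray:
    """Design matrix [V, 1]: components plus an intercept column of ones."""
    v = np.atleast_2d(np.asarray(v, dtype=float))
    return np.hstack([v, np.ones((v.shape[0], 1))])


@dataclass(frozen=True)
class MotionModel:
    """Affine map from registration space (104 + intercept) to patient space."""

    coef: np.ndarray  # (105, 3)
    cutoff_ratio: float
    kind: str = "inter"
    n_retained: int = 0
    n_train: int = 0

    def predict(self, v: np.ndarray) -> np.ndarray:
        """[v; 1] @ coef for one vector or a stack of vectors."""
        v = np.asarray(v, dtype=float)
        single = v.ndim == 1
        A = build_design(v)
        if A.shape[1] != self.coef.shape[0]:
            raise ValueError(
                f"expected vectors of length {self.coef.shape[0] - 1}, "
                f"got {A.shape[1] - 1}"
            )
        out = A @ self.coef
        return out[0] if single else out


def fit_svd(
    v: np.ndarray,
    r: np.ndarray,
    cutoff_ratio: float,
    kind: str = "inter",
    literal_cutoff: bool = False,
) -> MotionModel:
    """Least-squares fit of r = [v; 1] x via regularised SVD.

    The default convention zeroes the reciprocals of singular values
    smaller than W_max / R (standard truncated SVD: weak directions make
    a negligible contribution to the fit and mostly carry noise).
    ``literal_cutoff`` instead zeroes reciprocals *themselves* smaller
    than W_max / R, i.e. discards the largest singular values - kept only
    as a diagnostic variant.
    """
    if cutoff_ratio <= 1.0:
        raise ValueError("cutoff_ratio must be > 1")
    A = build_design(v)
    b = np.atleast_2d(np.asarray(r, dtype=float))
    if not np.any(A[:, :-1]):
        raise ValueError("design matrix is all-zero apart from the intercept")
    U, w, Vt = np.linalg.svd(A, full_matrices=False)
    w_max = w.max()
    if literal_cutoff:
        keep = (1.0 / np.where(w > 0, w, np.inf)) >= w_max / cutoff_ratio
    else:
        keep = w >= w_max / cutoff_ratio
    w_inv = np.where(keep, 1.0 / np.where(w > 0, w, 1.0), 0.0)
    coef = (Vt.T * w_inv) @ (U.T @ b)
    return MotionModel(
        coef=coef,
        cutoff_ratio=cutoff_ratio,
        kind=kind,
        n_retained=int(keep.sum()),
        n_train=A.shape[0],
    )


def fit_models(
    obs: ObservationSet,
    r_inter: float = R_INTER,
    r_intra: float = R_INTRA,
) -> tuple[MotionModel, MotionModel]:
    """Fit the inter- and intra-fraction models on a training set."""
    dec = decompose(obs)
    inter = fit_svd(dec.v_mean, dec.r_mean, r_inter, kind="inter")
    intra = fit_svd(dec.v_resid, dec.r_resid, r_intra, kind="intra")
    return inter, intra


def track_without_dvi(
    inter: MotionModel, intra: MotionModel, obs: ObservationSet
) -> np.ndarray:
    """Predicted positions r_mn = f_inter(v_m) + f_intra(v_mn - v_m).

    v_m is the test patient's own per-fraction mean of the registration
    vectors (available without any volumetric imaging).
    """
    dec = decompose(obs)
    r_hat_mean = inter.predict(dec.v_mean)
    return r_hat_mean[dec.group_index] + intra.predict(dec.v_resid)


def track_with_dvi(
    intra: MotionModel,
    obs: ObservationSet,
    fraction_means: Mapping[tuple, np.ndarray],
) -> np.ndarray:
    """Predicted positions r_mn = r_m + f_intra(v_mn - v_m).

    ``fraction_means`` supplies the known per-fraction mean position r_m
    (keyed by (patient, fraction)), as determined from daily volumetric
    imaging; the motion model only predicts excursions about it.
    """
    dec = decompose(obs)
    try:
        r_m = np.array([np.asarray(fraction_means[k], float) for k in dec.keys])
    except KeyError as exc:
        raise KeyError(f"missing fraction mean for {exc.args[0]}") from exc
    return r_m[dec.group_index] + intra.predict(dec.v_resid)


def true_fraction_means(obs: ObservationSet) -> dict[tuple, np.ndarray]:
    """Ground-truth per-fraction mean positions (the ideal DVI input)."""
    dec = decompose(obs)
    return {k: dec.r_mean[i] for i, k in enumerate(dec.keys)}


def error_stats(predicted: np.ndarray, truth: np.ndarray) -> pd.DataFrame:
    """Five-number summaries of the per-axis and 3D tracking errors (mm).

    Per-axis errors are absolute component differences; the 3D error is
    the Euclidean norm of the difference.  Quartiles use linear
    interpolation between order statistics.
    """
    predicted = np.atleast_2d(np.asarray(predicted, float))
    truth = np.atleast_2d(np.asarray(truth, float))
    if predicted.shape != truth.shape or predicted.shape[0] == 0:
        raise ValueError("predicted and truth must be equal-length, non-empty")
    diff = predicted - truth
    errors = {
        "left-right": np.abs(diff[:, 0]),
        "antero-posterior": np.abs(diff[:, 1]),
        "supero-inferior": np.abs(diff[:, 2]),
        "3d": np.linalg.norm(diff, axis=1),
    }
    rows = []
    for name, e in errors.items():
        q = np.percentile(e, [0, 25, 50, 75, 100])
        rows.append(
            {"direction": name, "min_mm": q[0], "lq_mm": q[1],
             "median_mm": q[2], "uq_mm": q[3], "max_mm": q[4]}
        )
    return pd.DataFrame(rows)


def _scenario_errors(
    inter: MotionModel, intra: MotionModel, obs: ObservationSet, dvi: bool
) -> np.ndarray:
    if dvi:
        pred = track_with_dvi(intra, obs, true_fraction_means(obs))
    else:
        pred = track_without_dvi(inter, intra, obs)
    return pred - obs.r


@dataclass
class LoocvResult:
    """Cross-validation error tables for both imaging scenarios."""

    #: scenario -> table with one row per held-out patient plus 'all'
    tables: dict[str, pd.DataFrame]
    #: scenario -> {patient -> residual array (n_images, 3)}
    residuals: dict[str, dict]
    #: scenario -> {patient -> predicted positions}
    predictions: dict[str, dict]


def _summary_row(diff: np.ndarray, label) -> dict:
    e3 = np.linalg.norm(diff, axis=1)
    q = np.percentile(e3, [0, 25, 50, 75, 100])
    return {"patient": label, "n_images": diff.shape[0], "min_mm": q[0],
            "lq_mm": q[1], "median_mm": q[2], "uq_mm": q[3], "max_mm": q[4]}


def loocv(
    obs: ObservationSet,
    r_inter: float = R_INTER,
    r_intra: float = R_INTRA,
    scenarios: Iterable[str] = ("no_dvi", "dvi"),
) -> LoocvResult:
    """Leave-one-patient-out cross validation of the motion models.

    For each held-out patient the two models are fitted on the remaining
    patients and evaluated in the requested scenarios.  Pooled
    ('all') rows aggregate the per-image errors across held-out patients,
    not the medians of medians.
    """
    patients = obs.patients()
    if patients.size < 2:
        raise ValueError("leave-one-out cross validation needs >= 2 patients")
    tables: dict[str, list] = {s: [] for s in scenarios}
    residuals: dict[str, dict] = {s: {} for s in scenarios}
    predictions: dict[str, dict] = {s: {} for s in scenarios}
    pooled: dict[str, list] = {s: [] for s in scenarios}
    for held_out in patients:
        train = obs.subset(obs.patient != held_out)
        test = obs.subset(obs.patient == held_out)
        inter, intra = fit_models(train, r_inter, r_intra)
        for s in scenarios:
            diff = _scenario_errors(inter, intra, test, dvi=(s == "dvi"))
            tables[s].append(_summary_row(diff, held_out))
            residuals[s][held_out] = diff
            predictions[s][held_out] = diff + test.r
            pooled[s].append(diff)
    out_tables = {}
    for s in scenarios:
        rows = tables[s] + [_summary_row(np.vstack(pooled[s]), "all")]
        out_tables[s] = pd.DataFrame(rows)
    return LoocvResult(tables=out_tables, residuals=residuals, predictions=predictions)


def fitting_set_table(
    obs: ObservationSet,
    r_inter: float = R_INTER,
    r_intra: float = R_INTRA,
) -> pd.DataFrame:
    """Training-set error table: each row holds out one patient and
    evaluates the fitted models on the *fitting* patients themselves
    (no-DVI scenario), mirroring the structure of the cross-validation
    table."""
    patients = obs.patients()
    if patients.size < 2:
        raise ValueError("needs >= 2 patients")
    rows = []
    for held_out in patients:
        train = obs.subset(obs.patient != held_out)
        inter, intra = fit_models(train, r_inter, r_intra)
        diff = _scenario_errors(inter, intra, train, dvi=False)
        rows.append(_summary_row(diff, f"excluding {held_out}"))
    return pd.DataFrame(rows)
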