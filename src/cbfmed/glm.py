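"""Four-regressor GLM of the unsubtracted ASL time series.

The design has the columns

* ``bold_hrf`` — canonical double-gamma HRF convolved with the task blocks,
* ``baseline_perfusion`` — the alternating tag/control waveform, coded
  +0.5 on control frames and -0.5 on tag frames so its coefficient is
  directly the tag-control difference ΔM,
* ``activation_perfusion`` — the perfusion waveform gated to task-on frames,
* ``baseline_signal`` — all ones (static tissue signal).

Voxelwise coefficients are estimated by ordinary least squares or by robust
weighted least squares (rWLS): per-frame variances are estimated as the
mean squared residual over all in-mask voxels at that frame, and each frame
is re-weighted with the inverse of its variance, "soft"-excluding
motion-corrupted volumes rather than deleting them.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .synthetic import ASLSeries, TAG, CONTROL, breath_hold_onsets

__all__ = [
    "DESIGN_COLUMNS",
    "DesignMatrix",
    "build_design_matrix",
    "hrf_regressor",
    "PerfusionFit",
    "PerfusionGLM",
    "fit_ols",
    "fit_rwls",
]

logger = logging.getLogger(__name__)

DESIGN_COLUMNS = ("bold_hrf", "baseline_perfusion", "activation_perfusion",
                  "baseline_signal")

#: Frame weights are capped at this multiple of the median positive weight
#: when a frame's residual variance is (numerically) zero.
MAX_WEIGHT_RATIO = 1e12


def hrf_regressor(frame_times, onsets, duration: float) -> np.ndarray:
    """Canonical double-gamma HRF convolved with task blocks, sampled at
    ``frame_times`` (seconds).  Empty onsets yield an all-zero regressor."""
    frame_times = np.asarray(frame_times, dtype=float)
    onsets = np.asarray(onsets, dtype=float)
    if onsets.size == 0:
        return np.zeros(frame_times.size)
    from nilearn.glm.first_level import compute_regressor
    condition = np.vstack([onsets, np.full(onsets.size, float(duration)),
                           np.ones(onsets.size)])
    signal, _ = compute_regressor(condition, "glover", frame_times)
    return signal.ravel()


@dataclass
class DesignMatrix:
    """Named 4-column GLM design."""

    matrix: np.ndarray  # (n_frames, 4) in DESIGN_COLUMNS order
    frame_labels: list[str]

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != len(DESIGN_COLUMNS):
            raise ValueError(f"design must have exactly {len(DESIGN_COLUMNS)} columns")
        if self.matrix.shape[0] != len(self.frame_labels):
            raise ValueError("design rows must match frame_labels length")

    @property
    def n_frames(self) -> int:
        return self.matrix.shape[0]

    @property
    def columns(self) -> tuple[str, ...]:
        return DESIGN_COLUMNS

    def column(self, name: str) -> np.ndarray:
        return self.matrix[:, DESIGN_COLUMNS.index(name)]

    def as_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, columns=list(DESIGN_COLUMNS))


def build_design_matrix(frame_labels, task_onsets=None, tr: float = 4.5,
                        task_duration: float = 18.0) -> DesignMatrix:
    """Construct the four-regressor ASL design.

    ``task_onsets`` (seconds) define the task blocks for the BOLD and
    activation regressors; ``None`` or an empty sequence yields all-zero
    BOLD/activation columns (shape is preserved for a baseline-only
    analysis).
    """
    frame_labels = list(frame_labels)
    if not frame_labels:
        raise ValueError("frame_labels must be nonempty")
    bad = set(frame_labels) - {TAG, CONTROL}
    if bad:
        raise ValueError(f"unknown frame labels: {sorted(bad)}")
    n = len(frame_labels)
    times = np.arange(n) * tr

    perfusion = np.where([lab == CONTROL for lab in frame_labels], 0.5, -0.5)
    onsets = np.asarray([] if task_onsets is None else task_onsets, dtype=float)
    bold = hrf_regressor(times, onsets, task_duration)
    task_on = np.zeros(n, dtype=bool)
    for onset in onsets:
        task_on |= (times >= onset) & (times < onset + task_duration)
    activation = perfusion * task_on

    matrix = np.column_stack([bold, perfusion, activation, np.ones(n)])
    return DesignMatrix(matrix=matrix, frame_labels=frame_labels)


@dataclass
class PerfusionFit:
    """Voxelwise GLM coefficient maps plus per-frame rWLS weights."""

    delta_m_map: np.ndarray      # coefficient of baseline_perfusion (tag-control difference)
    m0_map: np.ndarray           # fitted control-frame level (static tissue signal)
    bold_map: np.ndarray
    activation_map: np.ndarray
    frame_weights: np.ndarray    # nonnegative, mean 1; all ones for OLS
    residual_variance_per_frame: np.ndarray
    design: DesignMatrix


def _lstsq_nonzero(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Least squares with all-zero columns allowed (their coefficient is 0).

    Raises on genuine rank deficiency among the nonzero columns.
    """
    nonzero = np.ptp(X, axis=0) + np.abs(X).max(axis=0) > 0
    Xn = X[:, nonzero]
    if np.linalg.matrix_rank(Xn) < Xn.shape[1]:
        raise np.linalg.LinAlgError("design matrix is rank deficient")
    beta = np.zeros((X.shape[1], Y.shape[1]))
    beta[nonzero], *_ = np.linalg.lstsq(Xn, Y, rcond=None)
    return beta


class PerfusionGLM(BaseEstimator):
    """Voxelwise ASL GLM estimator (scikit-learn style).

    Parameters
    ----------
    method : "ols" or "rwls".
    n_iter : number of reweighting passes for rWLS (fit, estimate per-frame
        variance, refit); ignored for OLS.
    task_onsets, task_duration : task timing for the BOLD/activation
        regressors; ``task_onsets=None`` means baseline-only (all-zero BOLD
        and activation columns).  ``task_onsets="breath_hold"`` uses the
        standard six-block breath-hold paradigm.

    Fitted attributes (trailing underscore): ``delta_m_map_``, ``m0_map_``,
    ``bold_map_``, ``activation_map_``, ``frame_weights_``,
    ``residual_variance_per_frame_``, ``design_``.
    """

    def __init__(self, method: str = "rwls", n_iter: int = 2,
                 task_onsets=None, task_duration: float = 18.0):
        self.method = method
        self.n_iter = n_iter
        self.task_onsets = task_onsets
        self.task_duration = task_duration

    # -- internals --------------------------------------------------------
    def _resolve_design(self, series: ASLSeries, design: DesignMatrix | None):
        if design is not None:
            if design.n_frames != series.n_frames:
                raise ValueError("design n_frames != series frame count")
            return design
        onsets = self.task_onsets
        if isinstance(onsets, str):
            if onsets != "breath_hold":
                raise ValueError(f"unknown task_onsets preset {onsets!r}")
            onsets, duration = breath_hold_onsets()
            return build_design_matrix(series.frame_labels, onsets,
                                       tr=series.acquisition.tr, task_duration=duration)
        return build_design_matrix(series.frame_labels, onsets,
                                   tr=series.acquisition.tr,
                                   task_duration=self.task_duration)

    def fit(self, X: ASLSeries, y=None, design: DesignMatrix | None = None):
        if self.method not in ("ols", "rwls"):
            raise ValueError("method must be 'ols' or 'rwls'")
        if self.method == "rwls" and self.n_iter < 1:
            raise ValueError("n_iter must be >= 1")
        series = X
        design = self._resolve_design(series, design)
        spatial = series.data.shape[:3]
        n_frames = series.n_frames
        Y = series.data.reshape(-1, n_frames).T  # (n_frames, n_voxels)
        Xd = design.matrix
        in_mask = series.brain_mask().ravel()

        weights = np.ones(n_frames)
        beta = _lstsq_nonzero(Xd, Y)
        resid = Y - Xd @ beta
        var = self._frame_variance(resid, in_mask)

        if self.method == "rwls":
            for _ in range(self.n_iter):
                weights = self._weights_from_variance(var)
                sw = np.sqrt(weights)[:, None]
                beta = _lstsq_nonzero(Xd * sw, Y * sw)
                resid = Y - Xd @ beta
                var = self._frame_variance(resid, in_mask)

        idx = {name: i for i, name in enumerate(DESIGN_COLUMNS)}
        maps = beta.reshape(len(DESIGN_COLUMNS), *spatial)
        delta_m = maps[idx["baseline_perfusion"]]
        # the baseline coefficient is the tag/control mid-level under +-0.5
        # coding; the static tissue (control) level is baseline + dM/2
        m0 = maps[idx["baseline_signal"]] + 0.5 * delta_m

        self.design_ = design
        self.delta_m_map_ = delta_m
        self.m0_map_ = m0
        self.bold_map_ = maps[idx["bold_hrf"]]
        self.activation_map_ = maps[idx["activation_perfusion"]]
        self.frame_weights_ = weights / weights.mean()
        self.residual_variance_per_frame_ = var
        self.n_features_in_ = n_frames
        return self

    @staticmethod
    def _frame_variance(resid: np.ndarray, in_mask: np.ndarray) -> np.ndarray:
        """Mean squared residual over in-mask voxels, per frame."""
        sel = resid[:, in_mask] if in_mask.any() else resid
        return np.mean(sel**2, axis=1)

    @staticmethod
    def _weights_from_variance(var: np.ndarray) -> np.ndarray:
        if np.all(var == 0):
            warnings.warn("all frame variances are zero (noise-free input); "
                          "using equal weights", RuntimeWarning, stacklevel=2)
            return np.ones_like(var)
        positive = var[var > 0]
        floor = positive.min() / MAX_WEIGHT_RATIO
        if np.any(var <= floor):
            warnings.warn("zero/near-zero residual variance at some frames; "
                          f"weights capped at {MAX_WEIGHT_RATIO:g} x the "
                          "smallest-variance frame", RuntimeWarning, stacklevel=2)
        return 1.0 / np.maximum(var, floor)

    def result_(self) -> PerfusionFit:
        return PerfusionFit(
            delta_m_map=self.delta_m_map_, m0_map=self.m0_map_,
            bold_map=self.bold_map_, activation_map=self.activation_map_,
            frame_weights=self.frame_weights_,
            residual_variance_per_frame=self.residual_variance_per_frame_,
            design=self.design_,
        )


def fit_ols(series: ASLSeries, design: DesignMatrix | None = None,
            **kwargs) -> PerfusionFit:
    """Ordinary least-squares voxelwise fit (all frame weights = 1)."""
    return PerfusionGLM(method="ols", **kwargs).fit(series, design=design).result_()


def fit_rwls(series: ASLSeries, design: DesignMatrix | None = None,
             n_iter: int = 2, **kwargs) -> PerfusionFit:
    """Robust weighted least-squares fit with inverse-variance frame weights."""
    est = PerfusionGLM(method="rwls", n_iter=n_iter, **kwargs)
    return est.fit(series, design=design).result_()
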