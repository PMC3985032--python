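"""Single-compartment CBF quantification and regional aggregation.

The fitted tag-control difference ΔM and static tissue signal M0 are
converted to perfusion in mL/100 g/min via

    CBF = (ΔM / M0) * 6000 / (λ_blood * T1_blood)
          * exp((w + T_slc * (n - 1)) / T1_blood) * exp(TE / T2_blood)

with T1_blood in seconds, w the post-labeling delay, T_slc the per-slice
readout duration, n the 1-based acquisition index of the slice, and TE the
echo time.  The factor 6000 converts mL/g/s to mL/100 g/min.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin

from .config import QuantParams

__all__ = [
    "quantification_factor",
    "quantify_cbf",
    "regional_mean_cbf",
    "tissue_contrast",
    "RegionalCBF",
    "CBFQuantifier",
]

logger = logging.getLogger(__name__)


def quantification_factor(params: QuantParams, slice_index: int | np.ndarray):
    """CBF per unit ΔM/M0 for a slice with 1-based acquisition index ``n``.

    This is the closed-form multiplier of the quantification equation; the
    forward simulator divides by it to inject a ground-truth perfusion
    signal, guaranteeing an exact round trip in the noise-free limit.
    """
    n = np.asarray(slice_index, dtype=float)
    if np.any(n < 1):
        raise ValueError("slice acquisition index is 1-based")
    return (
        6000.0 / (params.lambda_blood * params.t1_blood)
        * np.exp((params.w + params.t_slc * (n - 1.0)) / params.t1_blood)
        * np.exp(params.te / params.t2_blood)
    )


def _slice_indices(params: QuantParams, n_slices: int) -> np.ndarray:
    if params.slice_order is not None:
        order = np.asarray(params.slice_order, dtype=int)
        if sorted(order.tolist()) != list(range(1, n_slices + 1)):
            raise ValueError("slice_order must be a permutation of 1..n_slices")
        return order
    return np.arange(1, n_slices + 1)


def quantify_cbf(delta_m_map, m0_map, params: QuantParams | None = None) -> np.ndarray:
    """Convert ΔM and M0 coefficient maps to a CBF map (mL/100 g/min).

    Voxels whose |M0| falls below ``m0_floor_frac`` times the median |M0|
    (over voxels with positive M0) are set to NaN and excluded from any
    downstream regional mean.
    """
    params = params or QuantParams()
    delta_m = np.asarray(delta_m_map, dtype=float)
    m0 = np.asarray(m0_map, dtype=float)
    if delta_m.shape != m0.shape:
        raise ValueError(f"shape mismatch: delta_m {delta_m.shape} vs m0 {m0.shape}")
    if delta_m.ndim != 3:
        raise ValueError("expected 3-D coefficient maps (x, y, slice)")
    n_slices = delta_m.shape[2]
    params.validate(n_slices)

    factors = quantification_factor(params, _slice_indices(params, n_slices))
    with np.errstate(divide="ignore", invalid="ignore"):
        cbf = delta_m / m0 * factors[np.newaxis, np.newaxis, :]

    abs_m0 = np.abs(m0)
    positive = abs_m0[abs_m0 > 0]
    floor = params.m0_floor_frac * np.median(positive) if positive.size else 0.0
    low = abs_m0 < floor
    if np.any(low):
        logger.info("quantify_cbf: %d voxels below M0 floor set to NaN", int(low.sum()))
    cbf[low] = np.nan
    return cbf


@dataclass
class RegionalCBF:
    """Mean perfusion over one mask."""

    region: str
    tissue: str  # "gray" or "white"
    mean_cbf: float
    voxel_count: int


def regional_mean_cbf(cbf_map, mask, region: str = "", tissue: str = "") -> RegionalCBF:
    """Mean CBF over in-mask, non-missing voxels."""
    cbf_map = np.asarray(cbf_map, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != cbf_map.shape:
        raise ValueError(f"mask shape {mask.shape} != map shape {cbf_map.shape}")
    values = cbf_map[mask]
    values = values[np.isfinite(values)]
    if values.size == 0:
        raise ValueError(f"region {region or '<unnamed>'}: empty mask or all voxels missing")
    return RegionalCBF(region=region, tissue=tissue or _infer_tissue(region),
                       mean_cbf=float(values.mean()), voxel_count=int(values.size))


def _infer_tissue(region: str) -> str:
    if "white" in region:
        return "white"
    if "gray" in region:
        return "gray"
    return ""


def tissue_contrast(gray_values, white_values):
    """Paired t test of gray- vs white-matter CBF across subjects.

    Returns ``(t, df, p_two_tailed)``; a positive t means gray > white.
    """
    gray = np.asarray(gray_values, dtype=float)
    white = np.asarray(white_values, dtype=float)
    if gray.shape != white.shape:
        raise ValueError("gray and white samples must be paired (equal length)")
    if gray.size < 3:
        raise ValueError("need at least 3 pairs")
    res = stats.ttest_rel(gray, white)
    return float(res.statistic), int(gray.size - 1), float(res.pvalue)


class CBFQuantifier(BaseEstimator, TransformerMixin):
    """Transformer wrapping the quantification equation.

    Stateless (``fit`` is a no-op); ``transform`` accepts a
    :class:`~cbfmed.glm.PerfusionFit` or an ``(delta_m, m0)`` pair and
    returns a CBF map.
    """

    def __init__(self, lambda_blood=0.9, w=0.5, t1_blood=1.68, t2_blood=0.275,
                 te=0.044, t_slc=0.06, slice_order=None, m0_floor_frac=0.05):
        self.lambda_blood = lambda_blood
        self.w = w
        self.t1_blood = t1_blood
        self.t2_blood = t2_blood
        self.te = te
        self.t_slc = t_slc
        self.slice_order = slice_order
        self.m0_floor_frac = m0_floor_frac

    def _params(self) -> QuantParams:
        return QuantParams(
            lambda_blood=self.lambda_blood, w=self.w, t1_blood=self.t1_blood,
            t2_blood=self.t2_blood, te=self.te, t_slc=self.t_slc,
            slice_order=self.slice_order, m0_floor_frac=self.m0_floor_frac,
        )

    def fit(self, X=None, y=None):
        self._params().validate()
        self.n_features_in_ = 0
        return self

    def transform(self, X):
        if hasattr(X, "delta_m_map"):
            delta_m, m0 = X.delta_m_map, X.m0_map
        else:
            delta_m, m0 = X
        return quantify_cbf(delta_m, m0, self._params())
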