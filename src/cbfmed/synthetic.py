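"""Synthetic cohorts and ASL acquisitions with known ground truth.

Two generators:

* :func:`generate_cohort` draws a cohort whose covariates follow a known
  age -> eCRF -> CBF path structure.  Fitness covariates are constructed so
  that the eCRF estimating equation reproduces the generative eCRF exactly
  (the activity score is back-solved, and is therefore continuous rather
  than ordinal).
* :func:`simulate_asl_series` builds a 4-D tag/control time series by
  inverting the single-compartment quantification equation at each voxel's
  ground-truth perfusion, so the GLM + quantification chain recovers the
  generating CBF exactly in the noise-free limit.

No pulse-sequence physics or rigid-body motion is simulated; motion enters
only as extra-variance "spike" frames, which is the aspect the robust
weighted least-squares stage addresses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import (AcquisitionConfig, CohortConfig, QuantParams,
                     DEFAULT_REGIONS, GRAY_REGIONS, WHITE_REGIONS)
from .fitness import solve_activity_score
from .quant import quantification_factor

__all__ = [
    "ASLSeries",
    "build_masks",
    "generate_cohort",
    "simulate_asl_series",
    "breath_hold_onsets",
]

TAG, CONTROL = "tag", "control"


@dataclass
class ASLSeries:
    """A 4-D tag/control image series plus frame labels and masks.

    ``data`` is (x, y, slice, frame) in arbitrary signal units;
    ``frame_labels`` has one ``"tag"``/``"control"`` entry per frame;
    ``masks`` maps region names to 3-D boolean arrays on the series grid.
    """

    data: np.ndarray
    frame_labels: list[str]
    acquisition: AcquisitionConfig
    masks: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise ValueError("ASL data must be 4-D (x, y, slice, frame)")
        if len(self.frame_labels) != self.data.shape[3]:
            raise ValueError("frame_labels length must equal the frame dimension")
        bad = set(self.frame_labels) - {TAG, CONTROL}
        if bad:
            raise ValueError(f"unknown frame labels: {sorted(bad)}")
        spatial = self.data.shape[:3]
        for name, m in self.masks.items():
            m = np.asarray(m, dtype=bool)
            if m.shape != spatial:
                raise ValueError(f"mask {name!r} shape {m.shape} != series grid {spatial}")
            self.masks[name] = m
        if "gray" in self.masks and "white" in self.masks:
            if np.any(self.masks["gray"] & self.masks["white"]):
                raise ValueError("gray and white masks must be disjoint")

    @property
    def n_frames(self) -> int:
        return self.data.shape[3]

    def brain_mask(self) -> np.ndarray:
        """Union of all masks; whole grid if no masks were provided."""
        if not self.masks:
            return np.ones(self.data.shape[:3], dtype=bool)
        out = np.zeros(self.data.shape[:3], dtype=bool)
        for m in self.masks.values():
            out |= m
        return out


def default_frame_labels(n_tag: int, n_control: int) -> list[str]:
    """Strictly alternating control/tag labels (control first)."""
    if n_tag != n_control:
        raise ValueError("the default alternating design requires n_tag == n_control")
    labels = []
    for _ in range(n_tag):
        labels += [CONTROL, TAG]
    return labels


def breath_hold_onsets(n_blocks: int = 6, hold_s: float = 18.0,
                       rest_s: float = 36.0) -> tuple[np.ndarray, float]:
    """Onset times and duration of the breath-hold task blocks.

    Default: six repetitions of 18 s breath-hold after 36 s of self-paced
    breathing (5 min 24 s total at TR = 4.5 s, 72 frames).
    """
    onsets = rest_s + np.arange(n_blocks) * (hold_s + rest_s)
    return onsets, hold_s


# ---------------------------------------------------------------------------
# masks
# ---------------------------------------------------------------------------

def build_masks(shape: tuple[int, int, int]) -> dict[str, np.ndarray]:
    """Geometric tissue/region masks on an (nx, ny, nz) grid.

    White matter is a central in-plane disk, gray matter the surrounding
    annulus; the anterior half of the grid (low y) is "frontal" and the
    posterior half "parietal".  By construction
    ``gray = frontal_gray | parietal_gray`` (disjoint), likewise for white.
    """
    nx, ny, nz = shape
    if min(nx, ny) < 8 or nz < 1:
        raise ValueError("grid too small for mask construction (need >= 8x8 in-plane)")
    x = np.arange(nx)[:, None] - (nx - 1) / 2.0
    y = np.arange(ny)[None, :] - (ny - 1) / 2.0
    r = np.sqrt(x**2 + y**2)
    r_white = min(nx, ny) * 0.18
    r_gray = min(nx, ny) * 0.42
    white2d = r < r_white
    gray2d = (r >= r_white) & (r < r_gray)
    frontal2d = np.broadcast_to(np.arange(ny)[None, :] < ny // 2, (nx, ny))

    def stack(m2d):
        return np.repeat(m2d[:, :, None], nz, axis=2)

    gray, white, frontal = stack(gray2d), stack(white2d), stack(frontal2d)
    masks = {
        "gray": gray,
        "white": white,
        "frontal_gray": gray & frontal,
        "frontal_white": white & frontal,
        "parietal_gray": gray & ~frontal,
        "parietal_white": white & ~frontal,
    }
    for name, m in masks.items():
        if not m.any():
            raise ValueError(f"constructed mask {name!r} is empty; enlarge the grid")
    return masks


# ---------------------------------------------------------------------------
# cohort
# ---------------------------------------------------------------------------

def _truncated_normal(rng, mean, sd, lo, hi, size):
    """Reject-and-redraw sampling of a normal restricted to [lo, hi]."""
    if sd == 0:
        if not lo <= mean <= hi:
            raise ValueError("degenerate age distribution outside range")
        return np.full(size, float(mean))
    out = np.empty(size)
    remaining = np.arange(size)
    while remaining.size:
        draw = rng.normal(mean, sd, size=remaining.size)
        ok = (draw >= lo) & (draw <= hi)
        out[remaining[ok]] = draw[ok]
        remaining = remaining[~ok]
    return out


def generate_cohort(config: CohortConfig | None = None,
                    seed: int | None = None) -> pd.DataFrame:
    """Draw a cohort table with known mediation structure.

    Per subject: age ~ truncated normal; eCRF_true = intercept +
    path_a*(age - age_mean) + noise; each leaf region's CBF =
    intercept_region + b*(eCRF_true - mean) + c'*(age - mean) + noise with
    the gray paths (``path_b``, ``path_c_prime``) for gray regions and the
    white paths for white regions.  Global ``cbf_gray`` / ``cbf_white`` are
    the means of the corresponding leaf regions.

    Returns a DataFrame with one row per subject; deterministic for a fixed
    seed (``seed`` overrides ``config.seed``).
    """
    config = config or CohortConfig()
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n = config.n_subjects

    age = _truncated_normal(rng, config.age_mean, config.age_sd,
                            config.age_range[0], config.age_range[1], n)
    gender = (rng.random(n) < config.gender_balance).astype(int)
    ecrf = (config.ecrf_intercept
            + config.path_a * (age - config.age_mean)
            + rng.normal(0.0, config.noise_sd_ecrf, n))

    age_c = age - config.age_mean
    ecrf_c = ecrf - ecrf.mean()
    cols = {
        "id": [f"sub-{i + 1:03d}" for i in range(n)],
        "age": age,
        "gender_code": gender,
        "ecrf_true": ecrf,
    }
    for region in DEFAULT_REGIONS:
        if region in GRAY_REGIONS:
            b, cp = config.path_b, config.path_c_prime
        else:
            b, cp = config.path_b_white, config.path_c_prime_white
        cols[f"cbf_{region}"] = (config.cbf_intercepts[region]
                                 + b * ecrf_c + cp * age_c
                                 + rng.normal(0.0, config.noise_sd_cbf, n))
    cols["cbf_gray"] = np.mean([cols[f"cbf_{r}"] for r in GRAY_REGIONS], axis=0)
    cols["cbf_white"] = np.mean([cols[f"cbf_{r}"] for r in WHITE_REGIONS], axis=0)

    # fitness covariates; activity score back-solved so compute_ecrf == ecrf_true
    bmi = rng.normal(config.bmi_mean, config.bmi_sd, n).clip(15.0, 45.0)
    rhr = rng.normal(config.rhr_mean, config.rhr_sd, n).clip(40.0, 110.0)
    activity = solve_activity_score(ecrf, gender, age, bmi, rhr)
    sbp = rng.normal(config.sbp_mean, config.sbp_sd, n)
    dbp = np.minimum(rng.normal(config.dbp_mean, config.dbp_sd, n), sbp - 1.0)
    cols.update(bmi=bmi, resting_heart_rate=rhr, activity_score=activity,
                systolic_bp=sbp, diastolic_bp=dbp)

    # anatomy: ICV and two regional volumes weakly coupled to regional CBF
    icv = rng.normal(config.icv_mean, config.icv_sd, n)
    vol_sf = (45_000.0 * icv / config.icv_mean
              + 100.0 * (cols["cbf_frontal_gray"] - config.cbf_intercepts["frontal_gray"])
              + rng.normal(0.0, 2_000.0, n))
    vol_ip = (25_000.0 * icv / config.icv_mean
              + 100.0 * (cols["cbf_parietal_gray"] - config.cbf_intercepts["parietal_gray"])
              + rng.normal(0.0, 2_000.0, n))
    cols.update(icv=icv, vol_superior_frontal=vol_sf, vol_inferior_parietal=vol_ip)

    return pd.DataFrame(cols)


# ---------------------------------------------------------------------------
# imaging
# ---------------------------------------------------------------------------

def subject_regional_cbf(subject) -> dict[str, float]:
    """Extract the region -> CBF map from a cohort row (``cbf_*`` columns)."""
    out = {}
    for key in subject.index if hasattr(subject, "index") else subject:
        if str(key).startswith("cbf_"):
            out[str(key)[4:]] = float(subject[key])
    return out


def _ground_truth_cbf_map(regional_cbf: dict[str, float],
                          masks: dict[str, np.ndarray]) -> np.ndarray:
    """Voxelwise CBF from leaf-region masks (most specific mask wins)."""
    leaf = [r for r in masks if r in DEFAULT_REGIONS]
    if not leaf:  # masks without the standard leaves: every mask is a leaf
        leaf = [r for r in masks]
    shape = next(iter(masks.values())).shape
    cbf = np.zeros(shape)
    for region in leaf:
        if region not in regional_cbf:
            raise ValueError(f"mask region {region!r} has no ground-truth CBF value")
        cbf[masks[region]] = regional_cbf[region]
    return cbf


def simulate_asl_series(subject, acq: AcquisitionConfig | None = None,
                        masks: dict[str, np.ndarray] | None = None,
                        seed: int | None = None) -> ASLSeries:
    """Forward-simulate a tag/control series for one subject.

    Control-frame signal at an in-brain voxel is
    ``M0 * (1 + drift_slope*k + bold_amplitude*hrf(t_k)) + noise`` (frame
    index k); tag frames are additionally reduced by ΔM, where ΔM inverts
    the quantification equation at the voxel's ground-truth CBF and slice
    acquisition index.  Frames listed in ``spike_frames`` receive extra
    zero-mean noise of SD ``spike_sd`` (a motion-variance surrogate).

    ``subject`` is a cohort-table row (or mapping) carrying ``cbf_<region>``
    entries for every leaf region present in ``masks``.
    """
    acq = acq or AcquisitionConfig()
    acq.validate()
    masks = masks if masks is not None else build_masks(acq.shape)
    rng = np.random.default_rng(acq.seed if seed is None else seed)

    regional = subject_regional_cbf(subject) if not isinstance(subject, dict) else dict(subject)
    shape = next(iter(masks.values())).shape
    cbf_map = _ground_truth_cbf_map(regional, masks)

    brain = np.zeros(shape, dtype=bool)
    for m in masks.values():
        brain |= m

    params = QuantParams.from_acquisition(acq)
    factors = quantification_factor(params, np.arange(1, shape[2] + 1))
    m0_map = acq.m0 * brain.astype(float)
    delta_m_map = cbf_map * m0_map / factors[None, None, :]

    labels = default_frame_labels(acq.n_tag, acq.n_control)
    n_frames = len(labels)
    frame_idx = np.arange(n_frames)
    hrf = np.zeros(n_frames)
    if acq.bold_amplitude != 0.0:
        from .glm import hrf_regressor
        onsets, dur = breath_hold_onsets()
        hrf = hrf_regressor(frame_idx * acq.tr, onsets, dur)
        peak = np.max(np.abs(hrf))
        if peak > 0:
            hrf = hrf / peak

    modulation = 1.0 + acq.drift_slope * frame_idx + acq.bold_amplitude * hrf
    tag_frame = np.array([lab == TAG for lab in labels])

    data = m0_map[..., None] * modulation[None, None, None, :]
    data[..., tag_frame] -= delta_m_map[..., None]
    if acq.noise_sd > 0:
        data += rng.normal(0.0, acq.noise_sd, data.shape)
    for f in acq.spike_frames:
        data[..., f] += rng.normal(0.0, acq.spike_sd, shape)

    return ASLSeries(data=data, frame_labels=labels, acquisition=acq, masks=dict(masks))
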