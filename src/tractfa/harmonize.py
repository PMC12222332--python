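"""Control-based harmonization of FA maps: age and center correction.

Age is removed first: a per-voxel ordinary-least-squares regression of FA
on age, fitted on controls of one center, yields slope maps used to shift
every subject to a common reference age. The inter-center difference is
then removed by a per-voxel linear first-order map (gain and offset) that
matches the center-B control distribution to center-A moments; a pure
offset variant is available. A verification step runs a voxel-wise Welch
test with FDR between the corrected control sets — after correction, no
residual site effect should survive.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .grids import ScalarMap
from .wbss import fdr_correct, welch_from_stacks

EPS_SD = 1e-6  # FA units; guards zero-variance voxels


@dataclass
class AgeModel:
    intercept: np.ndarray      # per-voxel FA at age 0
    slope: np.ndarray          # per-voxel FA per year
    reference_age: float
    center: str = ""

    def save(self, prefix, affine) -> None:
        prefix = str(prefix)
        ScalarMap(self.intercept, affine, "component").save(prefix + "_intercept.nii.gz")
        ScalarMap(self.slope, affine, "component").save(prefix + "_slope.nii.gz")
        with open(prefix + "_meta.json", "w") as fh:
            json.dump({"reference_age": self.reference_age, "center": self.center}, fh)

    @classmethod
    def load(cls, prefix) -> "AgeModel":
        prefix = str(prefix)
        icpt = ScalarMap.load(prefix + "_intercept.nii.gz").data
        slope = ScalarMap.load(prefix + "_slope.nii.gz").data
        meta = json.loads(Path(prefix + "_meta.json").read_text())
        return cls(icpt, slope, meta["reference_age"], meta["center"])


@dataclass
class CenterCorrection:
    gain: np.ndarray           # per-voxel multiplicative term for center-B FA
    offset: np.ndarray         # per-voxel additive term

    def apply(self, fa: ScalarMap) -> ScalarMap:
        return fa.like(np.clip(fa.data * self.gain + self.offset, 0.0, 1.0))

    def save(self, prefix, affine) -> None:
        prefix = str(prefix)
        ScalarMap(self.gain, affine, "component").save(prefix + "_gain.nii.gz")
        ScalarMap(self.offset, affine, "component").save(prefix + "_offset.nii.gz")

    @classmethod
    def load(cls, prefix) -> "CenterCorrection":
        prefix = str(prefix)
        return cls(ScalarMap.load(prefix + "_gain.nii.gz").data,
                   ScalarMap.load(prefix + "_offset.nii.gz").data)


def fit_age_model(control_fa_maps: list[ScalarMap], ages, reference_age: float,
                  center: str = "") -> AgeModel:
    """Per-voxel OLS of FA on age across controls.

    The slope is zeroed wherever the regressor is degenerate (all ages
    equal) or fewer than 3 controls contribute.
    """
    ages = np.asarray(ages, dtype=float)
    stack = np.stack([m.data for m in control_fa_maps])
    n = stack.shape[0]
    if n != len(ages):
        raise ValueError("one age per control map required")
    mean_fa = stack.mean(axis=0)
    if n < 3 or np.ptp(ages) == 0:
        slope = np.zeros_like(mean_fa)
        intercept = mean_fa.copy()
        return AgeModel(intercept, slope, float(reference_age), center)
    ac = ages - ages.mean()
    denom = np.sum(ac ** 2)
    slope = np.tensordot(ac, stack - mean_fa, axes=([0], [0])) / denom
    intercept = mean_fa - slope * ages.mean()
    return AgeModel(intercept, slope, float(reference_age), center)


def apply_age_correction(fa: ScalarMap, age: float, model: AgeModel) -> ScalarMap:
    """FA_corr = FA - slope * (age - reference_age), clipped to [0, 1]."""
    corrected = fa.data - model.slope * (float(age) - model.reference_age)
    return fa.like(np.clip(corrected, 0.0, 1.0))


def fit_center_correction(controls_a: list[ScalarMap], controls_b: list[ScalarMap],
                          mode: str = "gain_offset") -> CenterCorrection:
    """Per-voxel linear map taking center-B control FA to center-A moments.

    ``gain_offset`` matches mean and SD (gain = sd_A/sd_B,
    offset = mean_A - gain * mean_B); ``offset`` matches means only.
    The gain falls back to 1 wherever sd_B < EPS_SD or either side has
    fewer than 2 maps.
    """
    if mode not in ("gain_offset", "offset"):
        raise ValueError("mode must be 'gain_offset' or 'offset'")
    a = np.stack([m.data for m in controls_a])
    b = np.stack([m.data for m in controls_b])
    mean_a, mean_b = a.mean(axis=0), b.mean(axis=0)
    if mode == "offset" or a.shape[0] < 2 or b.shape[0] < 2:
        gain = np.ones_like(mean_a)
    else:
        sd_a = a.std(axis=0, ddof=1)
        sd_b = b.std(axis=0, ddof=1)
        gain = np.where(sd_b > EPS_SD, sd_a / np.maximum(sd_b, EPS_SD), 1.0)
    offset = mean_a - gain * mean_b
    return CenterCorrection(gain, offset)


def verify_no_site_effect(corrected_a: list[ScalarMap], corrected_b: list[ScalarMap],
                          mask: np.ndarray | None = None,
                          alpha: float = 0.05) -> dict:
    """Voxel-wise Welch test with BH FDR between corrected control sets.

    Returns the surviving fraction/count; after a successful correction the
    expected surviving fraction is ~0.
    """
    a = np.stack([m.data for m in corrected_a])
    b = np.stack([m.data for m in corrected_b])
    if mask is None:
        mask = np.ones(a.shape[1:], dtype=bool)
    _, _, p = welch_from_stacks(a, b)
    p_map = corrected_a[0].like(np.where(mask, p, 1.0), "p")
    q_map, rej = fdr_correct(p_map, mask, alpha)
    n_mask = int(mask.sum())
    n_rej = int(rej.sum())
    return {"n_voxels": n_mask, "n_surviving": n_rej,
            "surviving_fraction": n_rej / n_mask if n_mask else 0.0,
            "alpha": alpha,
            "max_abs_mean_residual": float(np.max(np.abs((a.mean(0) - b.mean(0))[mask]))
                                           if n_mask else 0.0)}
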