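"""Derived echocardiographic and necropsy indices, and genotype comparison.

All indices are computed per animal and only then summarized per genotype:
stroke volume is linear in the LV volumes so the order would not matter, but
ejection fraction, fractional shortening and cardiac output are ratios and
per-animal computation is the convention that matches reported cohort tables.

Formulas (units):
    SV  = LVVol;d - LVVol;s                              [ul]
    EF  = 100 * (LVVol;d - LVVol;s) / LVVol;d            [%]
    FS  = 100 * (LVID;d - LVID;s) / LVID;d               [%]
    CO  = SV * HR / 1000                                 [ml/min]
    LVm = 1.053 * ((LVID;d + LVPW;d + LVAW;d)^3 - LVID;d^3)   [mg]
    LVm(corrected) = 0.8 * LVm                           [mg]
    HW/BW = heart weight [mg] / body weight [g]          [mg/g]
"""

from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DomainError

__all__ = [
    "stroke_volume",
    "ejection_fraction",
    "fractional_shortening",
    "cardiac_output",
    "lv_mass",
    "hypertrophy_index",
    "derive_cardiac",
    "group_compare",
    "summarize_cardiac",
]

MYOCARDIAL_DENSITY = 1.053  # g/ml, specific gravity of myocardium
LV_MASS_CORRECTION = 0.8    # standard corrected-cube factor

DERIVED_FIELDS = ("stroke_volume", "ejection_fraction", "fractional_shortening",
                  "cardiac_output", "lv_mass", "lv_mass_corrected",
                  "hw_bw_ratio", "mv_ea_ratio")


def _as_arrays(*values):
    arrays = [np.asarray(v, dtype=float) for v in values]
    return arrays if len(arrays) > 1 else arrays[0]


def stroke_volume(lv_vol_d, lv_vol_s):
    """Stroke volume (ul): diastolic minus systolic LV volume."""
    d, s = _as_arrays(lv_vol_d, lv_vol_s)
    if np.any(s < 0) or np.any(d <= 0):
        raise DomainError("LV volumes must be positive")
    if np.any(s > d):
        raise DomainError("systolic LV volume exceeds diastolic LV volume")
    out = d - s
    return float(out) if out.ndim == 0 else out


def ejection_fraction(lv_vol_d, lv_vol_s):
    """Ejection fraction (%): ejected fraction of the diastolic LV volume."""
    d, s = _as_arrays(lv_vol_d, lv_vol_s)
    if np.any(d <= 0):
        raise DomainError("diastolic LV volume must be positive")
    if np.any(s < 0) or np.any(s > d):
        raise DomainError("systolic LV volume must lie in [0, diastolic volume]")
    out = 100.0 * (d - s) / d
    return float(out) if out.ndim == 0 else out


def fractional_shortening(lvid_d, lvid_s):
    """Fractional shortening (%): systolic reduction of the LV internal diameter."""
    d, s = _as_arrays(lvid_d, lvid_s)
    if np.any(d <= 0) or np.any(s <= 0):
        raise DomainError("LV internal diameters must be positive")
    if np.any(s > d):
        raise DomainError("systolic LV diameter exceeds diastolic LV diameter")
    out = 100.0 * (d - s) / d
    return float(out) if out.ndim == 0 else out


def cardiac_output(sv, heart_rate):
    """Cardiac output (ml/min) from stroke volume (ul) and heart rate (bpm)."""
    v, hr = _as_arrays(sv, heart_rate)
    if np.any(v < 0) or np.any(hr <= 0):
        raise DomainError("stroke volume must be >= 0 and heart rate > 0")
    out = v * hr / 1000.0
    return float(out) if out.ndim == 0 else out


def lv_mass(lvid_d, lvpw_d, lvaw_d):
    """LV mass (mg) by the corrected-cube convention.

    Returns ``(mass, corrected)`` where ``corrected = 0.8 * mass``; inputs are
    diastolic internal diameter and posterior/anterior wall thicknesses in mm.
    """
    lvid, pw, aw = _as_arrays(lvid_d, lvpw_d, lvaw_d)
    if np.any(lvid <= 0) or np.any(pw <= 0) or np.any(aw <= 0):
        raise DomainError("LV dimensions must be positive")
    mass = MYOCARDIAL_DENSITY * ((lvid + pw + aw) ** 3 - lvid**3)
    corrected = LV_MASS_CORRECTION * mass
    if mass.ndim == 0:
        return float(mass), float(corrected)
    return mass, corrected


def hypertrophy_index(heart_weight, body_weight):
    """Heart-weight/body-weight ratio (mg/g), an index of hypertrophy."""
    hw, bw = _as_arrays(heart_weight, body_weight)
    if np.any(hw <= 0) or np.any(bw <= 0):
        raise DomainError("heart and body weight must be positive")
    out = hw / bw
    return float(out) if out.ndim == 0 else out


def derive_cardiac(echo: pd.DataFrame) -> pd.DataFrame:
    """Append every derived index to a per-animal echo/necropsy table."""
    out = echo.copy()
    out["stroke_volume"] = stroke_volume(echo["lv_vol_d"], echo["lv_vol_s"])
    out["ejection_fraction"] = ejection_fraction(echo["lv_vol_d"], echo["lv_vol_s"])
    out["fractional_shortening"] = fractional_shortening(echo["lvid_d"], echo["lvid_s"])
    out["cardiac_output"] = cardiac_output(out["stroke_volume"], echo["heart_rate"])
    mass, corrected = lv_mass(echo["lvid_d"], echo["lvpw_d"], echo["lvaw_d"])
    out["lv_mass"] = mass
    out["lv_mass_corrected"] = corrected
    out["hw_bw_ratio"] = hypertrophy_index(echo["heart_weight"], echo["body_weight"])
    out["mv_ea_ratio"] = np.asarray(echo["mv_e"], float) / np.asarray(echo["mv_a"], float)
    return out


def group_compare(groups: Mapping[str, Sequence[float]]) -> pd.DataFrame:
    """One-way ANOVA with Tukey HSD pairwise comparison across genotype groups.

    Groups with fewer than two values are excluded with a warning.  Returns a
    table with one row per pair: ``group_a, group_b, mean_diff, p_adj``, plus
    the overall ANOVA statistic attached as ``.attrs['anova_F']`` and
    ``.attrs['anova_p']``.
    """
    usable = {k: np.asarray(v, dtype=float) for k, v in groups.items()
              if len(v) >= 2}
    dropped = sorted(set(groups) - set(usable))
    if dropped:
        warnings.warn(f"groups {dropped} have < 2 values and were excluded",
                      stacklevel=2)
    if len(usable) < 2:
        raise ValueError("need at least two groups with >= 2 values each")
    labels = list(usable)
    samples = [usable[k] for k in labels]
    f_stat, f_p = sps.f_oneway(*samples)
    tukey = sps.tukey_hsd(*samples)
    rows = []
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            rows.append({"group_a": labels[i], "group_b": labels[j],
                         "mean_diff": float(np.mean(samples[i]) - np.mean(samples[j])),
                         "p_adj": float(tukey.pvalue[i, j])})
    out = pd.DataFrame(rows)
    out.attrs["anova_F"] = float(f_stat)
    out.attrs["anova_p"] = float(f_p)
    return out


def summarize_cardiac(
    derived: pd.DataFrame,
    parameters: Sequence[str] | None = None,
    genotypes: Sequence[str] | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Cohort summary: mean +/- SD per genotype per parameter with pairwise
    Tukey-adjusted significance against every other genotype."""
    if genotypes is None:
        genotypes = list(dict.fromkeys(derived["genotype"]))
    if parameters is None:
        parameters = [c for c in derived.columns
                      if c not in ("animal_id", "genotype")
                      and pd.api.types.is_numeric_dtype(derived[c])]
    rows = []
    for param in parameters:
        groups = {g: derived.loc[derived["genotype"] == g, param].to_numpy()
                  for g in genotypes}
        row: dict[str, object] = {"parameter": param}
        for g in genotypes:
            vals = groups[g]
            row[f"{g}_mean"] = float(np.mean(vals)) if len(vals) else np.nan
            row[f"{g}_sd"] = float(np.std(vals, ddof=1)) if len(vals) > 1 else np.nan
        try:
            pairs = group_compare(groups)
        except ValueError:
            pairs = None
        if pairs is not None:
            sig = pairs.loc[pairs["p_adj"] < alpha]
            row["significant_pairs"] = ";".join(
                f"{a}|{b}" for a, b in zip(sig["group_a"], sig["group_b"])) or "NS"
            row["anova_p"] = pairs.attrs["anova_p"]
        else:
            row["significant_pairs"] = "NA"
            row["anova_p"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)
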