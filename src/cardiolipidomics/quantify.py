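"""Stereological point-count estimators and qPCR relative expression.

Volume density uses the pooled (ratio-of-sums) estimator: with varying
per-field point totals it weights fields by the points actually counted, the
standard stereological choice.  Relative expression follows the conventional
two-step Ct normalization: within-sample normalization to a reference gene
(delta-Ct), then centering on the control group's mean delta-Ct, so the
control group's relative quantities have geometric mean 1.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .errors import DomainError

__all__ = ["volume_density", "per_field_densities", "mito_per_field",
           "ddct_relative_expression"]


def volume_density(counts: pd.DataFrame) -> float:
    """Pooled volume density: total points on the compartment over total
    points counted, across all fields.  Lies in [0, 1] by construction."""
    if counts.empty:
        raise ValueError("need at least one counted field")
    mito = np.asarray(counts["points_mito"], dtype=float)
    total = np.asarray(counts["points_total"], dtype=float)
    if np.any(total <= 0):
        raise DomainError("every field must contain at least one counted point")
    if np.any(mito < 0) or np.any(mito > total):
        raise DomainError("compartment points must lie in [0, points_total]")
    return float(mito.sum() / total.sum())


def per_field_densities(counts: pd.DataFrame) -> pd.Series:
    """Per-field densities (points_mito / points_total), for dispersion checks."""
    if counts.empty:
        raise ValueError("need at least one counted field")
    return counts["points_mito"] / counts["points_total"]


def mito_per_field(counts: Sequence[float] | np.ndarray) -> float:
    """Mean organelle count per image field."""
    arr = np.asarray(counts, dtype=float)
    if arr.size == 0:
        raise ValueError("need at least one field count")
    return float(arr.mean())


def ddct_relative_expression(
    records: pd.DataFrame, control_genotype: str = "WT"
) -> pd.DataFrame:
    """Per-sample relative expression by the delta-delta-Ct method.

    delta-Ct = ct_target - ct_reference; delta-delta-Ct subtracts the control
    group's mean delta-Ct; RQ = 2^(-delta-delta-Ct).  Returns the input plus
    ``dct, ddct, rq`` columns.
    """
    required = ("sample_id", "genotype", "ct_target", "ct_reference")
    missing = [c for c in required if c not in records.columns]
    if missing:
        raise ValueError(f"Ct table missing columns: {missing}")
    ct_t = np.asarray(records["ct_target"], dtype=float)
    ct_r = np.asarray(records["ct_reference"], dtype=float)
    if not (np.isfinite(ct_t).all() and np.isfinite(ct_r).all()):
        raise DomainError("threshold cycles must be finite")
    if np.any(ct_t <= 0) or np.any(ct_r <= 0):
        raise DomainError("threshold cycles must be positive")
    out = records.copy()
    out["dct"] = ct_t - ct_r
    control = out.loc[out["genotype"] == control_genotype, "dct"]
    if control.empty:
        raise ValueError(f"no samples for control genotype {control_genotype!r}")
    out["ddct"] = out["dct"] - control.mean()
    out["rq"] = np.power(2.0, -out["ddct"])
    return out
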