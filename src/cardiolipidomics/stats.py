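"""Class-level paired fold-change statistics for lipidomics profiles.

The question asked of each lipid class is: across its member species, do
mutant/wildtype fold-changes differ from 1 in aggregate?  Each species
contributes one paired observation — the log fold-change of its genotype mean
concentrations — and the class is tested with a Wilcoxon signed-rank test of
those log fold-changes against zero.  For the small species counts typical of
a lipid class the test is computed *exactly*: the null distribution of the
positive rank sum is built over all 2^n equiprobable sign assignments of the
realized (possibly tied) rank vector, so exactness holds under ties.  The
family of class x comparison tests is controlled with Bonferroni, and both
pre-correction ("*") and post-correction ("***") significance are reported.

Implementation note: the 2^n enumeration is carried out by convolving the
polynomials (1 + x^r) over the realized ranks r (doubled to integers so that
average ranks of ties stay exact).  This is algebraically identical to
enumerating every sign vector, at polynomial cost.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field
from scipy import stats as sps

from .presets import COMPARISONS, LIPID_CLASSES

__all__ = [
    "ComparisonSpec",
    "FamilyConfig",
    "SignedRankResult",
    "DEFAULT_COMPARISONS",
    "exact_signed_rank",
    "compute_fold_changes",
    "summarize_class",
    "class_tests",
    "apply_family_control",
    "build_report",
]

MARKER_PRE = "*"
MARKER_POST = "***"


@dataclass(frozen=True)
class ComparisonSpec:
    """A pairwise genotype contrast: numerator over denominator (reference)."""

    label: str
    numerator: str
    denominator: str = "WT"

    def __post_init__(self) -> None:
        if self.numerator == self.denominator:
            raise ValueError("comparison numerator and denominator must differ")

    @classmethod
    def from_label(cls, label: str) -> "ComparisonSpec":
        num, _, den = label.partition("_vs_")
        if not num or not den:
            raise ValueError(f"comparison label {label!r} is not of the form A_vs_B")
        return cls(label, num, den)


DEFAULT_COMPARISONS = tuple(ComparisonSpec.from_label(c) for c in COMPARISONS)


class FamilyConfig(BaseModel):
    """Family-wise error control across the class x comparison test family."""

    model_config = ConfigDict(frozen=True)

    alpha: float = Field(default=0.05, gt=0.0, lt=1.0)
    m: int = Field(default=len(LIPID_CLASSES) * len(COMPARISONS), ge=1)
    exact_n_max: int = Field(default=25, ge=1)
    p_convention: str = "doubling"


@dataclass(frozen=True)
class SignedRankResult:
    """Outcome of one signed-rank test.

    ``p_two_sided`` is NaN when the test is untestable (no nonzero
    differences); ``method`` is then ``"untestable"`` rather than a silent 1.
    """

    n_used: int
    w_plus: float
    w_minus: float
    p_two_sided: float
    method: str  # "exact" | "approximate" | "untestable"

    @property
    def testable(self) -> bool:
        return self.method != "untestable"


def _exact_null_counts(doubled_ranks: np.ndarray) -> np.ndarray:
    """Counts of sign assignments achieving each doubled positive rank sum.

    Convolves (1 + x^r) over the realized doubled ranks; entry s holds the
    number of the 2^n sign vectors whose positive doubled rank sum equals s.
    """
    total = int(doubled_ranks.sum())
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in doubled_ranks:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: counts.size - r]
        counts += shifted
    return counts


def exact_signed_rank(
    diffs: Sequence[float] | np.ndarray,
    exact_n_max: int = 25,
    p_convention: str = "doubling",
) -> SignedRankResult:
    """Wilcoxon signed-rank test of paired differences against zero.

    Zeros are removed before ranking; absolute differences receive average
    ranks on ties.  For ``n <= exact_n_max`` the two-sided p is exact over all
    2^n sign assignments of the realized rank vector; larger samples use a
    normal approximation with tie-corrected variance and a continuity
    correction, flagged ``method="approximate"``.

    Two p conventions are available: ``"doubling"`` (default;
    ``min(1, 2 * min(P(W+ <= w), P(W+ >= w)))``) and ``"min_likelihood"``
    (sums null probabilities of all rank sums no more probable than the
    observed one).
    """
    if p_convention not in ("doubling", "min_likelihood"):
        raise ValueError(f"unknown p convention {p_convention!r}")
    d = np.asarray(diffs, dtype=float)
    if d.size and not np.isfinite(d).all():
        raise ValueError("differences must be finite")
    d = d[d != 0.0]
    n = int(d.size)
    if n == 0:
        return SignedRankResult(0, math.nan, math.nan, math.nan, "untestable")

    ranks = sps.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    w_minus = float(ranks[d < 0].sum())

    if n <= exact_n_max:
        doubled = np.rint(2.0 * ranks).astype(int)
        counts = _exact_null_counts(doubled)
        total = float(2.0**n)
        w2 = int(round(2.0 * w_plus))
        if p_convention == "doubling":
            lower = counts[: w2 + 1].sum() / total
            upper = counts[w2:].sum() / total
            p = min(1.0, 2.0 * min(lower, upper))
        else:
            probs = counts / total
            p_obs = probs[w2]
            p = float(probs[probs <= p_obs * (1 + 1e-12)].sum())
        return SignedRankResult(n, w_plus, w_minus, float(p), "exact")

    # Normal approximation; Var(W+) = sum(r_i^2)/4 absorbs ties exactly.
    mean = n * (n + 1) / 4.0
    sd = math.sqrt(float(np.square(ranks).sum()) / 4.0)
    if sd == 0.0:  # all differences tied at zero rank mass; cannot happen for n>0
        return SignedRankResult(n, w_plus, w_minus, math.nan, "untestable")
    delta = w_plus - mean
    z = (delta - 0.5 * np.sign(delta)) / sd
    p = min(1.0, 2.0 * float(sps.norm.sf(abs(z))))
    return SignedRankResult(n, w_plus, w_minus, p, "approximate")


def compute_fold_changes(
    profiles: pd.DataFrame,
    comparison: ComparisonSpec,
    log_base: float = 2.0,
) -> pd.DataFrame:
    """Per-species fold-changes of genotype mean concentrations.

    A species contributes only if its mean is present in *both* genotypes and
    the denominator mean is positive; excluded species are reported with a
    warning, never an exception.  Returns columns ``class, species_id,
    fold_change, log_fold_change`` (log in ``log_base``).
    """
    wide = profiles.pivot_table(index=["species_id", "class"], columns="genotype",
                                values="mean_concentration", aggfunc="first")
    for g in (comparison.numerator, comparison.denominator):
        if g not in wide.columns:
            wide[g] = np.nan
    num = wide[comparison.numerator]
    den = wide[comparison.denominator]
    usable = num.notna() & den.notna() & (den > 0)
    n_excluded = int((~usable).sum())
    if n_excluded:
        warnings.warn(
            f"{comparison.label}: {n_excluded} species excluded "
            "(missing in one genotype or zero denominator)", stacklevel=2)
    fc = (num[usable] / den[usable]).rename("fold_change")
    out = fc.reset_index()
    out["log_fold_change"] = np.log(out["fold_change"]) / np.log(log_base)
    return out


def summarize_class(
    fold_changes: pd.DataFrame,
    profiles: pd.DataFrame,
    comparison: ComparisonSpec,
) -> tuple[float, float]:
    """(median per-species fold-change, total-mass fold-change) for one class.

    The total-mass ratio sums genotype mean concentrations over the same
    species that contributed fold-changes, so both summaries describe one
    species set.  The median uses the conventional midpoint for even counts.
    """
    if fold_changes.empty:
        raise ValueError("cannot summarize an empty fold-change set")
    median_fc = float(np.median(fold_changes["fold_change"]))
    species = fold_changes["species_id"]
    sub = profiles[profiles["species_id"].isin(species)]
    mass = sub.pivot_table(index="species_id", columns="genotype",
                           values="mean_concentration", aggfunc="first")
    total_fc = float(mass[comparison.numerator].sum() / mass[comparison.denominator].sum())
    return median_fc, total_fc


def class_tests(
    profiles: pd.DataFrame,
    comparisons: Iterable[ComparisonSpec] = DEFAULT_COMPARISONS,
    family: FamilyConfig | None = None,
    classes: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Run the full class-level analysis: fold-changes, exact signed-rank
    tests, and Bonferroni dual reporting.

    Returns one row per class x comparison (long format) with columns
    ``class, comparison, n_species, median_fold_change, total_mass_fold_change,
    n_used, w_plus, w_minus, p_value, method, significant_pre,
    significant_post, marker``.
    """
    family = family or FamilyConfig()
    if classes is None:
        classes = list(dict.fromkeys(profiles["class"]))
    rows = []
    for comparison in comparisons:
        fcs = compute_fold_changes(profiles, comparison)
        for klass in classes:
            sub = fcs[fcs["class"] == klass]
            if sub.empty:
                rows.append({"class": klass, "comparison": comparison.label,
                             "n_species": 0, "median_fold_change": math.nan,
                             "total_mass_fold_change": math.nan, "n_used": 0,
                             "w_plus": math.nan, "w_minus": math.nan,
                             "p_value": math.nan, "method": "untestable"})
                continue
            median_fc, total_fc = summarize_class(sub, profiles, comparison)
            res = exact_signed_rank(sub["log_fold_change"].to_numpy(),
                                    exact_n_max=family.exact_n_max,
                                    p_convention=family.p_convention)
            rows.append({"class": klass, "comparison": comparison.label,
                         "n_species": int(len(sub)),
                         "median_fold_change": median_fc,
                         "total_mass_fold_change": total_fc,
                         "n_used": res.n_used, "w_plus": res.w_plus,
                         "w_minus": res.w_minus, "p_value": res.p_two_sided,
                         "method": res.method})
    return apply_family_control(pd.DataFrame(rows), family)


def apply_family_control(results: pd.DataFrame, family: FamilyConfig | None = None) -> pd.DataFrame:
    """Annotate a results table with Bonferroni dual significance.

    ``significant_pre`` marks p < alpha, ``significant_post`` marks
    p < alpha/m; the marker column is "" / "*" / "***" accordingly.  Untestable
    rows (NaN p) are never significant.
    """
    family = family or FamilyConfig()
    n_tests = int(results["p_value"].notna().sum())
    if family.m < n_tests:
        warnings.warn(
            f"family size m={family.m} smaller than the {n_tests} tests supplied; "
            "correction is anticonservative", stacklevel=2)
    out = results.copy()
    p = out["p_value"]
    out["significant_pre"] = (p < family.alpha).fillna(False)
    out["significant_post"] = (p < family.alpha / family.m).fillna(False)
    out["marker"] = np.select(
        [out["significant_post"], out["significant_pre"]],
        [MARKER_POST, MARKER_PRE], default="")
    return out


def build_report(
    results: pd.DataFrame,
    classes: Sequence[str] | None = None,
    comparisons: Sequence[str] = COMPARISONS,
) -> pd.DataFrame:
    """Wide, display-ready class report: one row per class, and per comparison
    a fold-change (2 decimals), p-value (4 decimals) and marker column.
    Untestable entries print as ``NA``."""
    if classes is None:
        classes = list(dict.fromkeys(results["class"]))
    by_key = results.set_index(["class", "comparison"])
    rows = []
    for klass in classes:
        row: dict[str, str] = {"class": klass}
        for comp in comparisons:
            try:
                r = by_key.loc[(klass, comp)]
            except KeyError:
                r = None
            if r is None or not np.isfinite(r["p_value"]):
                row[f"fc_{comp}"] = "NA"
                row[f"p_{comp}"] = "NA"
                row[f"marker_{comp}"] = ""
            else:
                row[f"fc_{comp}"] = f"{r['median_fold_change']:.2f}"
                row[f"p_{comp}"] = f"{r['p_value']:.4f}"
                row[f"marker_{comp}"] = r["marker"]
        rows.append(row)
    return pd.DataFrame(rows)
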