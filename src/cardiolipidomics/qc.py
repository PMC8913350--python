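"""Peak-level cleanup of lipidomics peak tables.

The cleanup chain mirrors standard practice for vendor peak tables:

1. drop peaks whose signal-to-noise ratio or peak-quality score falls below
   threshold (strictly below: boundary values are retained);
2. drop whole replicate groups left with fewer than two surviving
   observations — a lone surviving replicate cannot be averaged reliably;
3. sum adducts of the same molecular species within each sample;
4. average biological replicates within each genotype, with QC-dropped
   replicates reducing the denominator;
5. group species profiles by lipid class.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd
from pydantic import BaseModel, ConfigDict, Field

from .errors import ConsistencyError, DuplicatePeakError, SchemaError

__all__ = [
    "QCConfig",
    "QCReport",
    "filter_peaks",
    "apply_triplicate_rule",
    "aggregate_adducts",
    "average_replicates",
    "group_by_class",
    "clean_peaks",
]

PEAK_COLUMNS = ("species_id", "class", "adduct", "sample_id", "genotype",
                "replicate", "concentration", "snr", "pq")

#: replicate groups share one measured peak across same-genotype animals
_GROUP_KEY = ["species_id", "adduct", "genotype"]


class QCConfig(BaseModel):
    """Cleanup thresholds; scores strictly below a threshold fail."""

    model_config = ConfigDict(frozen=True)

    snr_min: float = 2.0
    pq_min: float = 0.8
    group_size: int = Field(default=3, ge=1)


@dataclass
class QCReport:
    """Row accounting for one cleanup run."""

    n_in: int
    n_fail_scores: int
    n_dropped_with_group: int
    n_retained: int

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return (f"peaks in: {self.n_in}; failed QC scores: {self.n_fail_scores}; "
                f"dropped with depleted group: {self.n_dropped_with_group}; "
                f"retained: {self.n_retained}")


def _require_columns(peaks: pd.DataFrame, columns: tuple[str, ...]) -> None:
    missing = [c for c in columns if c not in peaks.columns]
    if missing:
        raise SchemaError(f"peak table missing columns: {missing}")


def _require_numeric(peaks: pd.DataFrame, columns: tuple[str, ...]) -> None:
    for col in columns:
        if not pd.api.types.is_numeric_dtype(peaks[col]):
            try:
                pd.to_numeric(peaks[col], errors="raise")
            except (ValueError, TypeError) as exc:
                raise SchemaError(f"column {col!r} is not numeric: {exc}") from exc


def filter_peaks(peaks: pd.DataFrame, qc: QCConfig | None = None) -> pd.DataFrame:
    """Retain peaks with snr >= snr_min and pq >= pq_min, preserving order.

    Thresholds are exclusive on the failing side ("less than" fails), so a
    peak exactly at a threshold is kept.
    """
    qc = qc or QCConfig()
    _require_columns(peaks, ("snr", "pq"))
    _require_numeric(peaks, ("snr", "pq"))
    snr = pd.to_numeric(peaks["snr"])
    pq = pd.to_numeric(peaks["pq"])
    return peaks.loc[(snr >= qc.snr_min) & (pq >= qc.pq_min)]


def apply_triplicate_rule(
    peaks_before: pd.DataFrame,
    peaks_after: pd.DataFrame,
    qc: QCConfig | None = None,
) -> pd.DataFrame:
    """Drop replicate groups depleted by QC filtering.

    ``peaks_after`` must be a row-subset of ``peaks_before`` (as returned by
    :func:`filter_peaks`, which preserves the index).  Within each
    (species, adduct, genotype) replicate group, if fewer than two
    observations survive the score filter the whole group is removed: for the
    default triplicates this is exactly "two of three removed implies the
    third is removed as well".
    """
    qc = qc or QCConfig()
    _require_columns(peaks_before, tuple(_GROUP_KEY))
    if not peaks_after.index.isin(peaks_before.index).all():
        raise ConsistencyError("filtered peaks contain rows absent from the input table")
    if peaks_after.empty:
        return peaks_after
    survivors = peaks_after.groupby(_GROUP_KEY, sort=False).size()
    needed = min(2, qc.group_size)  # a lone survivor of a replicated group is unreliable
    keep_groups = survivors[survivors >= needed].index
    key = pd.MultiIndex.from_frame(peaks_after[_GROUP_KEY])
    return peaks_after.loc[key.isin(keep_groups)]


def aggregate_adducts(peaks: pd.DataFrame) -> pd.DataFrame:
    """Sum adducts of the same species within each sample.

    Returns one row per (species, sample) with columns ``species_id, class,
    sample_id, genotype, replicate, concentration``.  Samples are never mixed.
    """
    _require_columns(peaks, ("species_id", "class", "adduct", "sample_id",
                             "genotype", "replicate", "concentration"))
    dup = peaks.duplicated(subset=["species_id", "adduct", "sample_id"])
    if dup.any():
        first = peaks.loc[dup, ["species_id", "adduct", "sample_id"]].iloc[0]
        raise DuplicatePeakError(
            f"duplicate peak for species {first['species_id']!r} adduct "
            f"{first['adduct']!r} sample {first['sample_id']!r}")
    out = (peaks.groupby(["species_id", "class", "sample_id", "genotype", "replicate"],
                         sort=False, as_index=False)["concentration"].sum())
    return out


def average_replicates(species_sample: pd.DataFrame) -> pd.DataFrame:
    """Average biological replicates per species per genotype.

    Replicates removed upstream simply shrink the denominator; a species with
    no surviving replicate in a genotype has no row for that genotype.
    Returns columns ``species_id, class, genotype, mean_concentration,
    n_replicates``.
    """
    _require_columns(species_sample, ("species_id", "class", "genotype", "concentration"))
    out = (species_sample
           .groupby(["species_id", "class", "genotype"], sort=False)["concentration"]
           .agg(mean_concentration="mean", n_replicates="size")
           .reset_index())
    return out


def group_by_class(
    profiles: pd.DataFrame, known_classes: tuple[str, ...] | None = None
) -> dict[str, pd.DataFrame]:
    """Partition species profiles by lipid class.

    With ``known_classes`` given, labels outside the list are routed to an
    ``"unassigned"`` bucket with a warning.  Species are conserved: every
    input row lands in exactly one group.
    """
    _require_columns(profiles, ("class",))
    if profiles.empty:
        return {}
    labels = profiles["class"]
    if known_classes is not None:
        unknown = ~labels.isin(known_classes)
        if unknown.any():
            warnings.warn(
                f"{sorted(labels[unknown].unique())} not in configured class list; "
                "routed to 'unassigned'", stacklevel=2)
            labels = labels.where(~unknown, "unassigned")
    return {klass: sub.drop(columns="_label")
            for klass, sub in profiles.assign(_label=labels).groupby("_label", sort=False)}


def clean_peaks(
    peaks: pd.DataFrame, qc: QCConfig | None = None
) -> tuple[pd.DataFrame, QCReport]:
    """Full cleanup: score filter, depleted-group rule, adduct sum, replicate
    average.  Returns the species-profile table plus a :class:`QCReport`."""
    qc = qc or QCConfig()
    filtered = filter_peaks(peaks, qc)
    kept = apply_triplicate_rule(peaks, filtered, qc)
    profiles = average_replicates(aggregate_adducts(kept)) if not kept.empty else \
        pd.DataFrame(columns=["species_id", "class", "genotype",
                              "mean_concentration", "n_replicates"])
    report = QCReport(
        n_in=len(peaks),
        n_fail_scores=len(peaks) - len(filtered),
        n_dropped_with_group=len(filtered) - len(kept),
        n_retained=len(kept),
    )
    return profiles, report
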