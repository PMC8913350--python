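"""Synthetic generators for every pipeline input.

No raw data accompany the study this package emulates, so each input family —
LipidSearch-style lipid peak tables, per-animal echocardiography/necropsy
tables, stereology grid counts and qPCR threshold cycles — is generated with
the statistical structure the downstream analysis assumes:

* lipid concentrations are positive and right-skewed, so baselines and
  replicate noise are log-normal (multiplicative);
* per-species fold-changes scatter log-normally around their class value, so
  the class *median* fold-change equals the configured preset;
* each species is detected as several mass-spectrometric adducts whose
  concentrations split a species total by fixed positive weights;
* a configurable fraction of peaks is emitted with a failing signal-to-noise
  ratio or peak-quality score, exercising the QC stage.

All generators are deterministic given their seed.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, field_validator, model_validator
from scipy import stats

from .presets import (
    DEFAULT_CLASS_FC,
    ECHO_FIELDS,
    ECHO_GROUP_N,
    ECHO_GROUP_PRESETS,
    GENOTYPES,
    LIPID_CLASSES,
)

__all__ = [
    "LipidSimConfig",
    "EchoGroupConfig",
    "EchoSimConfig",
    "generate_peak_table",
    "generate_echo_table",
    "generate_grid_counts",
    "generate_ct_table",
]

_ADDUCT_LABELS = ("+H", "+Na", "+NH4", "+K", "+HCOO", "-H")


class LipidSimConfig(BaseModel):
    """Design of a simulated lipidomics experiment.

    ``class_fc`` maps lipid class -> comparison label -> true median
    fold-change of that class in the mutant genotype relative to wildtype.
    Classes or comparisons absent from the mapping default to no effect
    (fold-change 1).
    """

    model_config = ConfigDict(frozen=True)

    classes: tuple[str, ...] = LIPID_CLASSES
    species_per_class: int | dict[str, int] = 14
    replicates_per_genotype: int = Field(default=3, ge=1)
    genotypes: tuple[str, ...] = GENOTYPES
    class_fc: dict[str, dict[str, float]] = Field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_CLASS_FC.items()}
    )
    species_fc_sd: float = Field(default=0.1, ge=0.0)
    baseline_log_mean: float = 3.0
    baseline_log_sd: float = Field(default=1.0, ge=0.0)
    noise_log_sd: float = Field(default=0.2, ge=0.0)
    adduct_weights: tuple[float, ...] = (0.7, 0.3)
    qc_fail_rate: float = Field(default=0.05, ge=0.0, le=1.0)
    seed: int = 0

    @field_validator("classes")
    @classmethod
    def _classes_nonempty(cls, v: tuple[str, ...]) -> tuple[str, ...]:
        if not v:
            raise ValueError("classes: at least one lipid class required")
        if len(set(v)) != len(v):
            raise ValueError("classes: duplicate class labels")
        return v

    @field_validator("genotypes")
    @classmethod
    def _genotypes_valid(cls, v: tuple[str, ...]) -> tuple[str, ...]:
        if len(v) < 2:
            raise ValueError("genotypes: need a reference and at least one mutant")
        if len(set(v)) != len(v):
            raise ValueError("genotypes: duplicate labels")
        return v

    @field_validator("class_fc")
    @classmethod
    def _fc_positive(cls, v: dict[str, dict[str, float]]) -> dict[str, dict[str, float]]:
        for klass, comps in v.items():
            for comp, fc in comps.items():
                if not fc > 0:
                    raise ValueError(f"class_fc[{klass}][{comp}]: fold-change must be > 0")
        return v

    @field_validator("adduct_weights")
    @classmethod
    def _weights_valid(cls, v: tuple[float, ...]) -> tuple[float, ...]:
        if not v or any(w <= 0 for w in v):
            raise ValueError("adduct_weights: weights must be positive")
        if abs(sum(v) - 1.0) > 1e-9:
            raise ValueError("adduct_weights: weights must sum to 1 within 1e-9")
        return v

    @model_validator(mode="after")
    def _species_counts_valid(self) -> "LipidSimConfig":
        if isinstance(self.species_per_class, int):
            if self.species_per_class < 1:
                raise ValueError("species_per_class: must be >= 1")
        else:
            for klass, n in self.species_per_class.items():
                if n < 1:
                    raise ValueError(f"species_per_class[{klass}]: must be >= 1")
        return self

    def n_species(self, klass: str) -> int:
        if isinstance(self.species_per_class, int):
            return self.species_per_class
        return self.species_per_class.get(klass, 14)


def generate_peak_table(config: LipidSimConfig) -> pd.DataFrame:
    """Simulate a long-format peak table, one row per species x adduct x sample.

    Columns: ``species_id, class, adduct, sample_id, genotype, replicate,
    concentration, snr, pq``.  The wildtype (first genotype) carries no effect;
    mutant genotypes multiply each species baseline by a per-species
    fold-change drawn log-normally around the configured class value.
    """
    rng = np.random.default_rng(config.seed)
    reference = config.genotypes[0]
    weights = np.asarray(config.adduct_weights)
    adducts = [_ADDUCT_LABELS[i % len(_ADDUCT_LABELS)] for i in range(len(weights))]

    records: list[tuple] = []
    for klass in config.classes:
        comps = config.class_fc.get(klass, {})
        for i in range(config.n_species(klass)):
            species_id = f"{klass}({i:02d})"
            baseline = float(
                np.exp(rng.normal(config.baseline_log_mean, config.baseline_log_sd))
            )
            effect = {reference: 1.0}
            for genotype in config.genotypes[1:]:
                class_fc = comps.get(f"{genotype}_vs_{reference}", 1.0)
                effect[genotype] = class_fc * float(
                    np.exp(rng.normal(0.0, config.species_fc_sd))
                )
            for genotype in config.genotypes:
                for rep in range(1, config.replicates_per_genotype + 1):
                    sample_id = f"{genotype}{rep}"
                    noise = float(np.exp(rng.normal(0.0, config.noise_log_sd)))
                    total = baseline * effect[genotype] * noise
                    for adduct, w in zip(adducts, weights):
                        snr, pq = _draw_qc_scores(rng, config.qc_fail_rate)
                        records.append(
                            (species_id, klass, adduct, sample_id, genotype,
                             rep, total * float(w), snr, pq)
                        )
    return pd.DataFrame.from_records(
        records,
        columns=["species_id", "class", "adduct", "sample_id", "genotype",
                 "replicate", "concentration", "snr", "pq"],
    )


def _draw_qc_scores(rng: np.random.Generator, fail_rate: float) -> tuple[float, float]:
    """One (snr, pq) pair; with probability ``fail_rate`` one score fails
    (which of the two is chosen with equal probability)."""
    if rng.random() < fail_rate:
        if rng.random() < 0.5:
            return float(rng.uniform(0.2, 1.999)), float(rng.uniform(0.8, 1.0))
        return float(rng.uniform(2.0, 30.0)), float(rng.uniform(0.3, 0.799))
    return float(rng.uniform(2.0, 30.0)), float(rng.uniform(0.8, 1.0))


class EchoGroupConfig(BaseModel):
    """Per-genotype cohort size plus mean/SD of every raw echo field."""

    model_config = ConfigDict(frozen=True)

    n_animals: int = Field(ge=1)
    means: dict[str, float]
    sds: dict[str, float]

    @model_validator(mode="after")
    def _fields_complete(self) -> "EchoGroupConfig":
        for f in ECHO_FIELDS:
            if f not in self.means:
                raise ValueError(f"means: missing field {f!r}")
            if f not in self.sds:
                raise ValueError(f"sds: missing field {f!r}")
            if self.sds[f] < 0:
                raise ValueError(f"sds[{f}]: standard deviation must be >= 0")
        if not self.means["lv_vol_d"] > self.means["lv_vol_s"]:
            raise ValueError("means: lv_vol_d must exceed lv_vol_s")
        return self


class EchoSimConfig(BaseModel):
    """Echo/necropsy cohort design: one :class:`EchoGroupConfig` per genotype."""

    model_config = ConfigDict(frozen=True)

    groups: dict[str, EchoGroupConfig]
    seed: int = 0

    @classmethod
    def from_presets(
        cls,
        seed: int = 0,
        n_animals: Mapping[str, int] | None = None,
        zero_sd: bool = False,
    ) -> "EchoSimConfig":
        """Build the default knockout-study cohort from the shipped presets."""
        n = dict(ECHO_GROUP_N)
        if n_animals:
            n.update(n_animals)
        groups = {
            g: EchoGroupConfig(
                n_animals=n[g],
                means={f: ECHO_GROUP_PRESETS[g][f][0] for f in ECHO_FIELDS},
                sds={f: 0.0 if zero_sd else ECHO_GROUP_PRESETS[g][f][1]
                     for f in ECHO_FIELDS},
            )
            for g in ECHO_GROUP_PRESETS
        }
        return cls(groups=groups, seed=seed)


def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, size: int
) -> np.ndarray:
    """Normal draws truncated at zero (measurements are positive)."""
    if sd == 0.0:
        return np.full(size, mean)
    a = (0.0 - mean) / sd
    return stats.truncnorm.rvs(a, np.inf, loc=mean, scale=sd, size=size, random_state=rng)


def generate_echo_table(config: EchoSimConfig) -> pd.DataFrame:
    """Simulate one echo/necropsy row per animal.

    Fields are independent truncated normals per genotype; the volume pair is
    redrawn until diastolic exceeds systolic, preserving the per-animal
    invariant the derived indices rely on.
    """
    rng = np.random.default_rng(config.seed)
    frames = []
    for genotype, grp in config.groups.items():
        n = grp.n_animals
        data = {"animal_id": [f"{genotype}-{i + 1:02d}" for i in range(n)],
                "genotype": genotype}
        for f in ECHO_FIELDS:
            data[f] = _truncated_normal(rng, grp.means[f], grp.sds[f], n)
        frame = pd.DataFrame(data)
        bad = frame["lv_vol_d"] <= frame["lv_vol_s"]
        tries = 0
        while bad.any() and tries < 1000:
            k = int(bad.sum())
            frame.loc[bad, "lv_vol_s"] = _truncated_normal(
                rng, grp.means["lv_vol_s"], grp.sds["lv_vol_s"], k)
            frame.loc[bad, "lv_vol_d"] = _truncated_normal(
                rng, grp.means["lv_vol_d"], grp.sds["lv_vol_d"], k)
            bad = frame["lv_vol_d"] <= frame["lv_vol_s"]
            tries += 1
        frames.append(frame)
    return pd.concat(frames, ignore_index=True)


def generate_grid_counts(
    n_fields: int, density: float, grid_points: int = 400, seed: int = 0,
    grid_spacing: float = 165.0,
) -> pd.DataFrame:
    """Simulate stereology point counts: per image field, the number of grid
    points landing on mitochondria is Binomial(``grid_points``, ``density``).

    ``grid_spacing`` (nm) is carried as metadata only.
    """
    if not 0.0 <= density <= 1.0:
        raise ValueError("density: must lie in [0, 1]")
    if grid_points < 1:
        raise ValueError("grid_points: must be >= 1")
    if n_fields < 1:
        raise ValueError("n_fields: must be >= 1")
    rng = np.random.default_rng(seed)
    mito = rng.binomial(grid_points, density, size=n_fields)
    return pd.DataFrame({
        "field_id": [f"field{i + 1:03d}" for i in range(n_fields)],
        "points_mito": mito,
        "points_total": grid_points,
        "grid_spacing": grid_spacing,
    })


def generate_ct_table(
    n_per_genotype: Mapping[str, int] | None = None,
    true_fc: Mapping[str, float] | None = None,
    control_genotype: str = "WT",
    ct_reference_mean: float = 18.0,
    ct_reference_sd: float = 0.3,
    dct_control_mean: float = 5.0,
    ct_sd: float = 0.15,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a qPCR threshold-cycle table for one target gene.

    ``true_fc`` maps genotype -> true expression fold-change relative to the
    control genotype; a fold-change f shifts the target Ct by -log2(f)
    (one cycle per doubling).  Defaults emulate the ~1.9-fold mitochondrial
    Nd1 elevation of the heterozygote.
    """
    n_per_genotype = dict(n_per_genotype or {"WT": 3, "HET": 3, "KO": 3})
    true_fc = dict(true_fc or {"WT": 1.0, "HET": 1.9, "KO": 1.0})
    if control_genotype not in n_per_genotype:
        raise ValueError(f"control genotype {control_genotype!r} has no samples")
    rng = np.random.default_rng(seed)
    rows = []
    for genotype, n in n_per_genotype.items():
        fc = true_fc.get(genotype, 1.0)
        if not fc > 0:
            raise ValueError(f"true_fc[{genotype}]: fold-change must be > 0")
        for i in range(n):
            ct_ref = rng.normal(ct_reference_mean, ct_reference_sd)
            dct = dct_control_mean - np.log2(fc) + rng.normal(0.0, ct_sd)
            rows.append((f"{genotype}{i + 1}", genotype,
                         float(ct_ref + dct), float(ct_ref)))
    return pd.DataFrame(rows, columns=["sample_id", "genotype", "ct_target", "ct_reference"])
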