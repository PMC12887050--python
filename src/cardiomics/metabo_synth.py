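"""Seeded GC-MS-like feature tables with planted group effects.

Emulates the structure of an endometabolome profiling experiment:
a handful of biological groups with three replicates each, pooled
quality-control (QC) injections, log-normal baseline intensities,
multiplicative group effects specified in log2 units, intensity-dependent
missingness, and a controlled QC relative standard deviation.  A toy
pathway library generator stands in for curated pathway databases so that
over-representation analysis can be exercised end to end.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .flim_synth import ValidationError

__all__ = ["FeatureTable", "EffectSpec", "synth_table", "toy_pathways"]


@dataclass
class FeatureTable:
    """Samples x features intensity matrix with sample and feature metadata.

    ``intensities`` is a DataFrame (rows = samples, columns = features,
    NaN = missing); ``sample_meta`` carries ``group`` and ``is_qc`` per
    sample; ``feature_meta`` carries at least ``name`` and optionally a
    ``pathways`` list per feature.
    """

    intensities: pd.DataFrame
    sample_meta: pd.DataFrame
    feature_meta: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.intensities.index.equals(self.sample_meta.index):
            raise ValidationError("sample metadata does not align with the intensity matrix")
        if not self.intensities.columns.equals(pd.Index(self.feature_meta.index)):
            raise ValidationError("feature metadata does not align with the intensity matrix")

    def validate_nonnegative(self) -> None:
        """Raw intensity tables must be non-negative where present;
        transformed stages (e.g. autoscaled) are exempt."""
        if (self.intensities.to_numpy() < 0).any():
            raise ValidationError("intensities must be non-negative where present")

    @property
    def biological(self) -> pd.DataFrame:
        return self.intensities.loc[~self.sample_meta["is_qc"]]

    @property
    def qc(self) -> pd.DataFrame:
        return self.intensities.loc[self.sample_meta["is_qc"]]

    @property
    def groups(self) -> pd.Series:
        return self.sample_meta.loc[~self.sample_meta["is_qc"], "group"]

    def copy_with(self, intensities: pd.DataFrame) -> "FeatureTable":
        return FeatureTable(
            intensities,
            self.sample_meta.loc[intensities.index].copy(),
            self.feature_meta.loc[intensities.columns].copy(),
        )

    def to_csv(self, path: str | Path) -> None:
        path = Path(path)
        wide = self.intensities.copy()
        wide.insert(0, "group", self.sample_meta["group"])
        wide.insert(1, "is_qc", self.sample_meta["is_qc"])
        wide.to_csv(path, index_label="sample")

    @classmethod
    def from_csv(cls, path: str | Path) -> "FeatureTable":
        wide = pd.read_csv(path, index_col="sample")
        wide.index.name = None
        meta = wide[["group", "is_qc"]].copy()
        meta["is_qc"] = meta["is_qc"].astype(bool)
        intens = wide.drop(columns=["group", "is_qc"])
        fmeta = pd.DataFrame(index=intens.columns)
        fmeta["name"] = fmeta.index
        out = cls(intens, meta, fmeta)
        out.validate_nonnegative()
        return out


@dataclass
class EffectSpec:
    """Planted structure of a synthetic feature table.

    ``log2_effects`` maps feature index -> log2 fold change applied to the
    second group (and, for multi-group designs, scaled linearly along the
    group sequence, emulating a progressive shift).  ``replicate_cv`` is
    the biological coefficient of variation; ``qc_rsd`` the target QC
    relative standard deviation; ``missing_rate`` the mean missingness
    over biological samples, enriched in low-intensity features.
    """

    log2_effects: dict[int, float] = field(default_factory=dict)
    missing_rate: float = 0.15
    qc_rsd: float = 0.12
    replicate_cv: float = 0.25
    baseline_log10_mean: float = 5.0
    baseline_log10_sd: float = 0.8

    def __post_init__(self) -> None:
        if not 0 <= self.missing_rate < 1:
            raise ValidationError("missing_rate must lie in [0, 1)")
        if self.qc_rsd <= 0 or self.replicate_cv <= 0:
            raise ValidationError("qc_rsd and replicate_cv must be positive")


def synth_table(
    n_features: int,
    groups: tuple[str, ...] = ("day0", "day10"),
    n_replicates: int = 3,
    n_qc: int = 3,
    effect: EffectSpec | None = None,
    seed: int = 0,
) -> tuple[FeatureTable, dict]:
    """Generate a feature table with planted effects and pooled QCs.

    QC intensities are the per-feature mean of the biological samples
    perturbed by log-normal noise calibrated to the target QC RSD.
    Returns the table and a truth record (baselines, effects, missing
    mask).
    """
    if n_replicates < 2:
        raise ValidationError("need >= 2 replicates per group")
    if len(groups) < 2:
        raise ValidationError("need >= 2 groups")
    effect = effect or EffectSpec()
    rng = np.random.default_rng(seed)

    feat_names = [f"F{i:04d}" for i in range(n_features)]
    base = 10 ** rng.normal(effect.baseline_log10_mean, effect.baseline_log10_sd, n_features)

    sample_names, group_labels = [], []
    for g in groups:
        for r in range(n_replicates):
            sample_names.append(f"{g}_r{r + 1}")
            group_labels.append(g)
    qc_names = [f"QC_{i + 1}" for i in range(n_qc)]

    sigma_rep = np.sqrt(np.log1p(effect.replicate_cv**2))
    n_bio = len(sample_names)
    X = np.empty((n_bio, n_features))
    # planted log2 effects scale linearly along the group sequence so the
    # last group carries the full effect
    group_pos = {g: (i / (len(groups) - 1)) for i, g in enumerate(groups)}
    log2_fx = np.zeros(n_features)
    for j, fx in effect.log2_effects.items():
        log2_fx[j] = fx
    for i, g in enumerate(group_labels):
        mu = base * 2.0 ** (log2_fx * group_pos[g])
        X[i] = mu * np.exp(rng.normal(-sigma_rep**2 / 2, sigma_rep, n_features))

    # intensity-dependent missingness: low-abundance features lose values first
    if effect.missing_rate > 0:
        rank = np.argsort(np.argsort(base)) / max(n_features - 1, 1)
        p_missing = np.clip(2 * effect.missing_rate * (1 - rank), 0, 0.95)
        miss = rng.random(X.shape) < p_missing[None, :]
    else:
        miss = np.zeros(X.shape, dtype=bool)

    sigma_qc = np.sqrt(np.log1p(effect.qc_rsd**2))
    observed = np.where(miss, np.nan, X)
    n_obs = (~miss).sum(axis=0)
    with np.errstate(invalid="ignore"):
        qc_base = np.where(n_obs > 0, np.nansum(observed, axis=0) / np.maximum(n_obs, 1), base)
    Q = qc_base[None, :] * np.exp(rng.normal(-sigma_qc**2 / 2, sigma_qc, (n_qc, n_features)))

    intens = pd.DataFrame(
        np.vstack([np.where(miss, np.nan, X), Q]),
        index=sample_names + qc_names,
        columns=feat_names,
    )
    sample_meta = pd.DataFrame(
        {
            "group": group_labels + ["QC"] * n_qc,
            "is_qc": [False] * n_bio + [True] * n_qc,
        },
        index=sample_names + qc_names,
    )
    feature_meta = pd.DataFrame({"name": feat_names}, index=feat_names)
    truth = {
        "baseline": base,
        "log2_effects": log2_fx,
        "missing_mask": miss,
        "seed": seed,
    }
    return FeatureTable(intens, sample_meta, feature_meta), truth


def toy_pathways(
    n_pathways: int,
    sizes,
    feature_names,
    seed: int = 0,
) -> dict[str, list[str]]:
    """Random pathway-membership library over the given feature names.

    ``sizes`` is either one int applied to all pathways or a sequence of
    per-pathway sizes; members are drawn without replacement within a
    pathway, pathways may overlap.  Serialisable directly as JSON.
    """
    feature_names = list(feature_names)
    if np.isscalar(sizes):
        sizes = [int(sizes)] * n_pathways
    sizes = [int(s) for s in sizes]
    if len(sizes) != n_pathways:
        raise ValidationError("one size per pathway required")
    if any(s <= 0 for s in sizes):
        raise ValidationError("pathway sizes must be positive")
    if any(s > len(feature_names) for s in sizes):
        raise ValidationError("pathway size exceeds the feature universe")
    rng = np.random.default_rng(seed)
    return {
        f"pathway_{i + 1:02d}": sorted(rng.choice(feature_names, size=s, replace=False).tolist())
        for i, s in enumerate(sizes)
    }


def write_pathways(library: dict[str, list[str]], path: str | Path) -> None:
    Path(path).write_text(json.dumps(library, indent=1))


def read_pathways(path: str | Path) -> dict[str, list[str]]:
    return json.loads(Path(path).read_text())
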