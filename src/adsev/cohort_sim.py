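"""Synthetic ADNI-like cohorts for the MCI-to-AD conversion pipeline.

Four diagnostic groups (NC, sMCI, pMCI, AD) are treated as ordered
disease stages 0..3.  Informative MRI features carry a monotone disease
effect (atrophy: more negative with stage) *and* an aging slope of the
same sign, so normal aging and disease are deliberately confounded —
the situation the pipeline's aging-effect removal exists for.  Cognitive
scores decline with stage.  MCI subjects carry a conversion label
(pMCI = 1, sMCI = 0); it is undefined for NC and AD.

Feature model for informative feature j of subject i:

    x_ij = beta_age * age_i - d[stage_i] + N(0, noise_sd^2)

Non-informative features are pure noise.  Everything is drawn from one
seeded generator, so cohorts are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["CohortSpec", "Cohort", "generate_cohort"]

GROUPS = ("NC", "sMCI", "pMCI", "AD")


@dataclass(frozen=True)
class CohortSpec:
    """Generative parameters of a synthetic cohort.

    ``disease_effects`` are SD-unit shifts per stage (NC, sMCI, pMCI, AD),
    monotone non-decreasing; they are *subtracted* from informative
    features (volumetric atrophy).  ``beta_age`` (SD/yr, negative) applies
    to informative features only, co-directional with the disease effect.
    ``cog_effects`` give, per cognitive score, the baseline deficit of
    pMCI relative to sMCI in SD units — the contrast that defines the
    conversion-prediction task.  ``cog_stage_profile`` anchors the full
    monotone decline across stages in units of that contrast (default
    (0, 0.5, 1.5, 2.5): a mild deficit at stable MCI, an accelerated
    drop of exactly one contrast at conversion, further decline at AD).
    """

    n_per_group: tuple[int, int, int, int] = (100, 100, 100, 100)
    n_features: int = 50
    n_informative: int = 10
    disease_effects: tuple[float, float, float, float] = (0.0, 0.3, 0.7, 1.2)
    beta_age: float = -0.02
    age_range: tuple[float, float] = (60.0, 85.0)
    cog_effects: tuple[float, ...] = (0.5, 1.0)
    cog_stage_profile: tuple[float, float, float, float] = (0.0, 0.5, 1.5, 2.5)
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n < 0 for n in self.n_per_group) or len(self.n_per_group) != 4:
            raise ValueError("n_per_group must be four non-negative counts")
        if not 0 <= self.n_informative <= self.n_features:
            raise ValueError("need 0 <= n_informative <= n_features")
        if any(b > a + 1e-12 for a, b in zip(self.disease_effects[1:],
                                             self.disease_effects[:-1])):
            raise ValueError("disease_effects must be monotone non-decreasing "
                             "across NC -> sMCI -> pMCI -> AD")
        if any(b > a + 1e-12 for a, b in zip(self.cog_stage_profile[1:],
                                             self.cog_stage_profile[:-1])):
            raise ValueError("cog_stage_profile must be monotone non-decreasing")
        if self.age_range[0] >= self.age_range[1]:
            raise ValueError("age_range must be increasing")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    @property
    def informative_indices(self) -> np.ndarray:
        """Ground-truth indices of the disease-carrying features."""
        return np.arange(self.n_informative)


@dataclass
class Cohort:
    """Per-subject table with the generating spec attached.

    Column contract: id, group, age, cog1..cogM, f1..fN, converter
    (1 = pMCI, 0 = sMCI, missing otherwise).
    """

    df: pd.DataFrame
    spec: CohortSpec
    feature_columns: list[str] = field(default_factory=list)
    cog_columns: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.feature_columns:
            self.feature_columns = [c for c in self.df.columns
                                    if c.startswith("f")]
        if not self.cog_columns:
            self.cog_columns = [c for c in self.df.columns
                                if c.startswith("cog")]

    def features(self, mask=None) -> np.ndarray:
        sub = self.df if mask is None else self.df[mask]
        return sub[self.feature_columns].to_numpy(float)

    def ages(self, mask=None) -> np.ndarray:
        sub = self.df if mask is None else self.df[mask]
        return sub["age"].to_numpy(float)

    def group_mask(self, *groups: str) -> pd.Series:
        return self.df["group"].isin(groups)

    @property
    def mci_mask(self) -> pd.Series:
        return self.group_mask("sMCI", "pMCI")

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, spec: CohortSpec | None = None) -> "Cohort":
        df = pd.read_csv(path)
        required = {"id", "group", "age", "converter"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"cohort CSV missing columns: {sorted(missing)}")
        df["converter"] = df["converter"].astype("Int64")
        return cls(df=df, spec=spec or CohortSpec())


def generate_cohort(spec: CohortSpec) -> Cohort:
    """Draw a seeded cohort from the spec; identical seed, identical table."""
    rng = np.random.default_rng(spec.seed)
    rows = []
    n_total = sum(spec.n_per_group)
    ages = rng.uniform(*spec.age_range, size=n_total)
    noise = rng.normal(0.0, spec.noise_sd, size=(n_total, spec.n_features))
    cog_noise = rng.normal(0.0, 1.0, size=(n_total, len(spec.cog_effects)))

    subject = 0
    for stage, (group, n) in enumerate(zip(GROUPS, spec.n_per_group)):
        d = spec.disease_effects[stage]
        for _ in range(n):
            age = ages[subject]
            feats = noise[subject].copy()
            feats[: spec.n_informative] += spec.beta_age * age - d
            cogs = (cog_noise[subject]
                    - np.asarray(spec.cog_effects)
                    * spec.cog_stage_profile[stage])
            converter = {1: 0, 2: 1}.get(stage, pd.NA)
            rows.append({
                "id": f"S{subject:05d}", "group": group,
                "age": float(age),
                **{f"cog{j + 1}": float(cogs[j])
                   for j in range(len(spec.cog_effects))},
                **{f"f{j + 1}": float(feats[j])
                   for j in range(spec.n_features)},
                "converter": converter,
            })
            subject += 1
    df = pd.DataFrame(rows)
    df["converter"] = df["converter"].astype("Int64")
    return Cohort(df=df, spec=spec)
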