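"""Trait exceptionality scores against reference populations.

A trait exceptionality score is the negative logarithm of the probability,
under a matched reference population, of an outcome at least as favourable
as the one observed: for survival, the cohort-life-table probability of
living past the observed age conditional on reaching 40; for quantitative
traits, the one-sided tail probability in the beneficial direction; for
diseases, the reference probability of onset at the observed age or later.
Larger scores mean more exceptional (healthier) outcomes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "LifeTable",
    "ReferenceDistribution",
    "ExceptionalityScore",
    "survival_exceptionality",
    "trait_exceptionality",
    "onset_exceptionality",
    "residualize_scores",
]


@dataclass
class LifeTable:
    """Survival curve S(age) for one sex and birth-year cohort.

    ``ages`` must start at 0 with S(0) = 1; S is non-increasing and is
    evaluated between grid points by linear interpolation.
    """

    sex: str
    birth_year_cohort: int
    ages: np.ndarray = field(repr=False)
    survival: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.ages = np.asarray(self.ages, dtype=float)
        self.survival = np.asarray(self.survival, dtype=float)
        if self.ages.shape != self.survival.shape or self.ages.ndim != 1:
            raise ValueError("ages and survival must be 1-D and the same length")
        if np.any(np.diff(self.ages) <= 0):
            raise ValueError("ages must be strictly increasing")
        if self.ages[0] != 0 or not np.isclose(self.survival[0], 1.0):
            raise ValueError("life table must start at age 0 with S(0) = 1")
        if np.any(np.diff(self.survival) > 1e-12):
            raise ValueError("survival must be monotone non-increasing")
        if np.any((self.survival < 0) | (self.survival > 1)):
            raise ValueError("survival values must lie in [0, 1]")

    def S(self, age) -> np.ndarray | float:
        out = np.interp(age, self.ages, self.survival)
        return float(out) if np.isscalar(age) else out


@dataclass
class ReferenceDistribution:
    """Reference values for a trait within one age/sex/birth-cohort stratum.

    Either empirical (``values``) or parametric normal (``mean``, ``sd``).
    ``beneficial`` is "lower" or "higher" — the direction of better health.
    """

    trait: str
    beneficial: str = "lower"
    values: np.ndarray | None = None
    mean: float | None = None
    sd: float | None = None

    def __post_init__(self) -> None:
        if self.beneficial not in ("lower", "higher"):
            raise ValueError("beneficial must be 'lower' or 'higher'")
        if self.values is not None:
            self.values = np.asarray(self.values, dtype=float)
            if self.values.size == 0:
                raise ValueError("empirical reference needs at least one value")
        elif self.mean is None or self.sd is None:
            raise ValueError("reference needs either values or (mean, sd)")

    def tail_probability(self, value: float, two_sided: bool = False) -> float:
        """P(reference at least as extreme as ``value`` in the beneficial direction),
        floored at 1/(n+1) in empirical mode."""
        if self.values is not None:
            n = self.values.size
            if self.beneficial == "lower":
                k = int(np.sum(self.values <= value))
            else:
                k = int(np.sum(self.values >= value))
            p = max(k / n, 1.0 / (n + 1.0))
        else:
            z = (value - self.mean) / self.sd
            p = stats.norm.cdf(z) if self.beneficial == "lower" else stats.norm.sf(z)
        if two_sided:
            p = min(1.0, 2.0 * min(p, 1.0 - p))
        return float(min(p, 1.0))


@dataclass
class ExceptionalityScore:
    individual: object
    trait: str
    score: float
    probability: float
    stratum: object = None


def _neg_log(p: float, base: float) -> float:
    return float(-np.log(p) / np.log(base)) if base != np.e else float(-np.log(p))


def survival_exceptionality(
    age_last: float,
    sex: str,
    birth_year: int,
    table: LifeTable,
    log_base: float = np.e,
    individual=None,
) -> ExceptionalityScore:
    """Survival exceptionality: -log S(age_last) / S(40) from the matched
    cohort life table. Conditioning on surviving to 40 restricts the score
    to adult mortality; ages below 40 are outside its support."""
    if age_last < 40:
        raise ValueError(f"age at last contact {age_last} < 40; score is conditional on reaching 40")
    if table.sex != sex or table.birth_year_cohort != birth_year:
        raise ValueError(
            f"life table is for ({table.sex}, {table.birth_year_cohort}); "
            f"requested ({sex}, {birth_year})"
        )
    s40 = table.S(40.0)
    if s40 <= 0:
        raise ValueError("life table has S(40) = 0; cannot condition on survival to 40")
    p = min(table.S(age_last) / s40, 1.0)
    if p <= 0:
        p = np.finfo(float).tiny
    return ExceptionalityScore(
        individual=individual,
        trait="survival",
        score=max(_neg_log(p, log_base), 0.0),
        probability=p,
        stratum=(sex, birth_year),
    )


def trait_exceptionality(
    value: float,
    ref: ReferenceDistribution,
    log_base: float = np.e,
    two_sided: bool = False,
    individual=None,
    stratum=None,
) -> ExceptionalityScore:
    """Quantitative-trait exceptionality: -log of the one-sided tail
    probability of a reference value at least as favourable as observed."""
    p = ref.tail_probability(float(value), two_sided=two_sided)
    return ExceptionalityScore(
        individual=individual,
        trait=ref.trait,
        score=max(_neg_log(p, log_base), 0.0),
        probability=p,
        stratum=stratum,
    )


def onset_exceptionality(
    onset_age: float | None,
    ref_onset_ages,
    trait: str = "disease",
    log_base: float = np.e,
    individual=None,
    stratum=None,
) -> ExceptionalityScore | None:
    """Disease-onset exceptionality for affected individuals: -log of the
    reference probability of onset at the observed age or later (later onset
    is more exceptional). Unaffected individuals (onset_age None) get a
    missing score, not zero."""
    if onset_age is None or (isinstance(onset_age, float) and np.isnan(onset_age)):
        return None
    ref = ReferenceDistribution(trait=trait, beneficial="higher",
                                values=np.asarray(ref_onset_ages, dtype=float))
    p = ref.tail_probability(float(onset_age))
    return ExceptionalityScore(
        individual=individual,
        trait=trait,
        score=max(_neg_log(p, log_base), 0.0),
        probability=p,
        stratum=stratum,
    )


def residualize_scores(scores, covariates: pd.DataFrame | None, standardize: bool = True):
    """Adjust exceptionality scores for covariates (field center, PCs, ...);
    the residuals are the final analysis phenotype."""
    from .phenotypes import adjust_covariates

    return adjust_covariates(scores, covariates, mode="full", standardize=standardize)
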