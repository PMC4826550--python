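"""In-memory genotype container shared across the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["GenotypeMatrix"]

#: columns every variant table carries; QC/annotation columns are optional extras
VARIANT_COLUMNS = ["variant", "chrom", "pos", "ref", "alt"]


@dataclass
class GenotypeMatrix:
    """Individuals x variants additive dosage matrix.

    ``dosages`` is float with entries in {0, 1, 2} and NaN for missing.
    ``variants`` is a DataFrame with one row per column of ``dosages``;
    it always has ``variant`` (chrom:pos:ref:alt key), ``chrom``, ``pos``
    (1-based), ``ref``, ``alt`` and may carry ``rsid``, ``quality``,
    ``mean_coverage``, ``gene``, ``function_class``, and QC summaries.
    """

    individuals: list
    variants: pd.DataFrame = field(repr=False)
    dosages: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.individuals), len(self.variants)):
            raise ValueError(
                f"dosage shape {self.dosages.shape} does not match "
                f"{len(self.individuals)} individuals x {len(self.variants)} variants"
            )
        valid = np.isnan(self.dosages) | np.isin(self.dosages, (0.0, 1.0, 2.0))
        if not valid.all():
            raise ValueError("dosages must be 0, 1, 2 or missing (NaN)")
        missing = [c for c in VARIANT_COLUMNS if c not in self.variants.columns]
        if missing:
            raise ValueError(f"variant table missing columns: {missing}")
        self.variants = self.variants.reset_index(drop=True)

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def subset_variants(self, mask) -> "GenotypeMatrix":
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.nonzero(mask)[0]
        else:
            idx = mask
        return GenotypeMatrix(
            individuals=list(self.individuals),
            variants=self.variants.iloc[idx].reset_index(drop=True),
            dosages=self.dosages[:, idx],
        )

    def subset_individuals(self, individuals) -> "GenotypeMatrix":
        idx = [self.individuals.index(i) for i in individuals]
        return GenotypeMatrix(
            individuals=list(individuals),
            variants=self.variants.copy(),
            dosages=self.dosages[idx, :],
        )

    def column(self, variant_id) -> np.ndarray:
        j = list(self.variants["variant"]).index(variant_id)
        return self.dosages[:, j]

    def call_rates(self) -> np.ndarray:
        return 1.0 - np.isnan(self.dosages).mean(axis=0)
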