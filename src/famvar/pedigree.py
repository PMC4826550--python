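"""Pedigree structure, kinship coefficients, and Mendelian-inconsistency detection.

Families are directed acyclic graphs of parent -> child links. The kinship
coefficient phi(i, j) is the probability that one allele sampled at random
from i and one from j are identical by descent; 2*phi scales the polygenic
covariance used by the mixed models downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Pedigree",
    "KinshipMatrix",
    "MendelErrorReport",
    "PedigreeError",
    "compute_kinship",
    "find_mendel_errors",
    "mendel_family_counts",
    "gene_drop_kinship",
]

SEX_CODES = {0: "unknown", 1: "male", 2: "female"}


class PedigreeError(ValueError):
    """Structural problem in a pedigree (cycle, unknown parent, duplicate id)."""


@dataclass
class Pedigree:
    """Family structure table.

    ``table`` has one row per individual with columns ``family``,
    ``individual``, ``father``, ``mother`` (None for missing) and ``sex``
    in {"male", "female", "unknown"}. ``founder`` and ``generation``
    (0 = founder) are derived at construction.
    """

    table: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        t = self.table.copy()
        required = {"family", "individual", "father", "mother", "sex"}
        missing = required - set(t.columns)
        if missing:
            raise PedigreeError(f"pedigree table missing columns: {sorted(missing)}")
        if t["individual"].duplicated().any():
            dup = t.loc[t["individual"].duplicated(), "individual"].iloc[0]
            raise PedigreeError(f"duplicate individual id: {dup!r}")
        ids = set(t["individual"])
        fam = dict(zip(t["individual"], t["family"]))
        for col in ("father", "mother"):
            for child, parent in zip(t["individual"], t[col]):
                if parent is None or (isinstance(parent, float) and np.isnan(parent)):
                    continue
                if parent not in ids:
                    raise PedigreeError(
                        f"individual {child!r} names unknown {col} {parent!r}"
                    )
                if fam[parent] != fam[child]:
                    raise PedigreeError(
                        f"parent link crosses families: {child!r} ({fam[child]!r}) "
                        f"-> {parent!r} ({fam[parent]!r})"
                    )
        gen = _generations(t)
        t["generation"] = [gen[i] for i in t["individual"]]
        t["founder"] = t["father"].isna() & t["mother"].isna()
        self.table = t.reset_index(drop=True)

    @property
    def individuals(self) -> list:
        return list(self.table["individual"])

    @property
    def families(self) -> list:
        return sorted(set(self.table["family"]))

    def trios(self) -> pd.DataFrame:
        """Child-father-mother triples where both parents are recorded."""
        t = self.table
        both = t["father"].notna() & t["mother"].notna()
        out = t.loc[both, ["family", "individual", "father", "mother"]]
        return out.rename(columns={"individual": "child"}).reset_index(drop=True)

    def parents_of(self, individual) -> tuple:
        row = self.table.set_index("individual").loc[individual]
        f = row["father"]
        m = row["mother"]
        return (None if pd.isna(f) else f, None if pd.isna(m) else m)


def _generations(t: pd.DataFrame) -> dict:
    """Longest-path depth from founders; raises on cycles."""
    parents = {}
    for _, row in t.iterrows():
        f = row["father"] if pd.notna(row["father"]) else None
        m = row["mother"] if pd.notna(row["mother"]) else None
        parents[row["individual"]] = [p for p in (f, m) if p is not None]
    gen: dict = {}
    state: dict = {}  # 1 = in progress, 2 = done

    order = list(parents)
    for start in order:
        if state.get(start) == 2:
            continue
        stack = [start]
        while stack:
            node = stack[-1]
            if state.get(node) == 2:
                stack.pop()
                continue
            state[node] = 1
            pending = []
            for p in parents[node]:
                if state.get(p) == 1:
                    raise PedigreeError(f"pedigree cycle involving individual {node!r}")
                if state.get(p) != 2:
                    pending.append(p)
            if pending:
                stack.extend(pending)
            else:
                gen[node] = 1 + max((gen[p] for p in parents[node]), default=-1)
                state[node] = 2
                stack.pop()
    return gen


@dataclass
class KinshipMatrix:
    individuals: list
    phi: np.ndarray

    def __post_init__(self) -> None:
        self.phi = np.asarray(self.phi, dtype=float)
        n = len(self.individuals)
        if self.phi.shape != (n, n):
            raise ValueError("phi shape does not match individual list")

    def index_of(self, individual) -> int:
        return self.individuals.index(individual)

    def get(self, i, j) -> float:
        return float(self.phi[self.index_of(i), self.index_of(j)])

    def submatrix(self, individuals) -> "KinshipMatrix":
        idx = [self.individuals.index(i) for i in individuals]
        return KinshipMatrix(list(individuals), self.phi[np.ix_(idx, idx)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.phi, index=self.individuals, columns=self.individuals)


def compute_kinship(pedigree: Pedigree) -> KinshipMatrix:
    """Kinship matrix by the recursive tabular method in generation order.

    phi(i, i) = 0.5 * (1 + phi(f_i, m_i)); for j processed before i,
    phi(i, j) = 0.5 * (phi(f_i, j) + phi(m_i, j)). A missing parent
    contributes 0 (treated as an unrelated founder). Individuals in
    different families have phi = 0 by construction.
    """
    t = pedigree.table.sort_values("generation", kind="stable")
    ids = list(t["individual"])
    pos = {ind: k for k, ind in enumerate(ids)}
    n = len(ids)
    phi = np.zeros((n, n))
    fathers = [pos.get(f) if pd.notna(f) else None for f in t["father"]]
    mothers = [pos.get(m) if pd.notna(m) else None for m in t["mother"]]
    for i in range(n):
        fi, mi = fathers[i], mothers[i]
        if fi is None and mi is None:
            phi[i, i] = 0.5
        else:
            inb = phi[fi, mi] if (fi is not None and mi is not None) else 0.0
            phi[i, i] = 0.5 * (1.0 + inb)
            row = np.zeros(i)
            if fi is not None:
                row += phi[fi, :i]
            if mi is not None:
                row += phi[mi, :i]
            phi[i, :i] = 0.5 * row
            phi[:i, i] = phi[i, :i]
    # restore the caller's ordering
    order = [pos[ind] for ind in pedigree.individuals]
    phi = phi[np.ix_(order, order)]
    return KinshipMatrix(list(pedigree.individuals), phi)


def gene_drop_kinship(
    pedigree: Pedigree, n_drops: int = 100_000, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Monte Carlo kinship by gene dropping: estimate and standard error.

    Founders receive unique allele labels; each descendant draws one allele
    from each parent uniformly. The per-drop kinship of a pair is the
    fraction of the four cross-pair allele comparisons that are identical
    by descent. Returns (phi_hat, se) aligned with ``pedigree.individuals``.
    """
    rng = np.random.default_rng(seed)
    t = pedigree.table.sort_values("generation", kind="stable")
    ids = list(t["individual"])
    pos = {ind: k for k, ind in enumerate(ids)}
    n = len(ids)
    alleles = np.zeros((n_drops, n, 2), dtype=np.int32)
    label = 0
    for i, (f, m) in enumerate(zip(t["father"], t["mother"])):
        fi = pos.get(f) if pd.notna(f) else None
        mi = pos.get(m) if pd.notna(m) else None
        if fi is None:
            alleles[:, i, 0] = label
            label += 1
        else:
            pick = rng.integers(0, 2, size=n_drops)
            alleles[:, i, 0] = alleles[np.arange(n_drops), fi, pick]
        if mi is None:
            alleles[:, i, 1] = label
            label += 1
        else:
            pick = rng.integers(0, 2, size=n_drops)
            alleles[:, i, 1] = alleles[np.arange(n_drops), mi, pick]
    phi_hat = np.zeros((n, n))
    se = np.zeros((n, n))
    for i in range(n):
        ai = alleles[:, i, :]
        for j in range(i, n):
            aj = alleles[:, j, :]
            share = (
                (ai[:, 0] == aj[:, 0]).astype(float)
                + (ai[:, 0] == aj[:, 1])
                + (ai[:, 1] == aj[:, 0])
                + (ai[:, 1] == aj[:, 1])
            ) / 4.0
            phi_hat[i, j] = phi_hat[j, i] = share.mean()
            se[i, j] = se[j, i] = share.std(ddof=1) / np.sqrt(n_drops)
    order = [pos[ind] for ind in pedigree.individuals]
    return phi_hat[np.ix_(order, order)], se[np.ix_(order, order)]


@dataclass
class MendelErrorReport:
    """Flagged genotype-inconsistent trios.

    ``errors`` has columns variant, family, child, father, mother — one row
    per inconsistent trio per variant.
    """

    errors: pd.DataFrame
    variants: list

    def family_counts(self) -> pd.Series:
        counts = (
            self.errors.groupby("variant")["family"].nunique()
            if len(self.errors)
            else pd.Series(dtype=int)
        )
        return counts.reindex(self.variants, fill_value=0).astype(int)


def find_mendel_errors(genotypes, pedigree: Pedigree) -> MendelErrorReport:
    """Flag trios whose child dosage is impossible under biallelic autosomal
    transmission. Trios with any missing member genotype are skipped.

    ``genotypes`` is a GenotypeMatrix (dosages with NaN for missing).
    """
    known = set(pedigree.individuals)
    unknown = [i for i in genotypes.individuals if i not in known]
    if unknown:
        raise PedigreeError(
            f"genotyped individuals absent from pedigree: {unknown[:5]}"
        )
    trios = pedigree.trios()
    idx = {ind: k for k, ind in enumerate(genotypes.individuals)}
    rows = []
    D = genotypes.dosages
    variant_ids = list(genotypes.variants["variant"])
    usable = trios[
        trios["child"].isin(idx) & trios["father"].isin(idx) & trios["mother"].isin(idx)
    ]
    if len(usable):
        c = D[[idx[i] for i in usable["child"]], :]
        f = D[[idx[i] for i in usable["father"]], :]
        m = D[[idx[i] for i in usable["mother"]], :]
        complete = ~(np.isnan(c) | np.isnan(f) | np.isnan(m))
        # child dosage must lie in [#obligate-alt, #possible-alt] transmissions
        lo = (f == 2).astype(float) + (m == 2)
        hi = (f >= 1).astype(float) + (m >= 1)
        bad = complete & ((c < lo) | (c > hi))
        trio_i, var_j = np.nonzero(bad)
        for ti, vj in zip(trio_i, var_j):
            trow = usable.iloc[ti]
            rows.append(
                {
                    "variant": variant_ids[vj],
                    "family": trow["family"],
                    "child": trow["child"],
                    "father": trow["father"],
                    "mother": trow["mother"],
                }
            )
    errors = pd.DataFrame(rows, columns=["variant", "family", "child", "father", "mother"])
    return MendelErrorReport(errors=errors, variants=variant_ids)


def mendel_family_counts(report: MendelErrorReport) -> pd.Series:
    """Per-variant count of distinct families containing >= 1 inconsistency."""
    return report.family_counts()
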