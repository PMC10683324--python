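"""Core in-memory containers shared across the pipeline.

Genotypes are stored as an ``n_individuals x n_variants`` float matrix of
alternate-allele dosages in [0, 2] (NaN marks missing), with a pandas
DataFrame of per-variant metadata (1-based VCF coordinates). Phenotypes are
an ``n_individuals x T`` table of trait deviations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

VARIANT_COLUMNS = ["variant_id", "chrom", "pos", "ref", "alt", "alt_freq", "accuracy"]


@dataclass
class GenotypeMatrix:
    """Dosage matrix plus variant metadata and individual ids.

    Attributes
    ----------
    dosages:
        ``(n, m)`` float array, alternate-allele dosage in [0, 2]; NaN = missing.
    variants:
        DataFrame with columns ``variant_id, chrom, pos, ref, alt, alt_freq,
        accuracy`` (``accuracy`` may be NaN when no imputation score exists).
        Positions are 1-based, strictly increasing within each chromosome.
    individual_ids:
        Length-``n`` list of unique sample identifiers.
    """

    dosages: np.ndarray
    variants: pd.DataFrame
    individual_ids: list[str]

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be 2-D (individuals x variants)")
        n, m = self.dosages.shape
        if len(self.individual_ids) != n:
            raise ValueError("individual_ids length does not match dosage rows")
        if len(self.variants) != m:
            raise ValueError("variant metadata rows do not match dosage columns")
        if len(set(self.individual_ids)) != n:
            raise ValueError("individual ids must be unique")
        finite = self.dosages[np.isfinite(self.dosages)]
        if finite.size and (finite.min() < -1e-9 or finite.max() > 2 + 1e-9):
            raise ValueError("dosages outside [0, 2]")
        self.variants = self.variants.reset_index(drop=True)
        for chrom, sub in self.variants.groupby("chrom", sort=False):
            pos = sub["pos"].to_numpy()
            if np.any(np.diff(pos) <= 0):
                raise ValueError(f"positions not strictly increasing on {chrom}")

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    @property
    def variant_ids(self) -> np.ndarray:
        return self.variants["variant_id"].to_numpy()

    def alt_freq(self) -> np.ndarray:
        """Alternate-allele frequency recomputed from non-missing dosages."""
        return np.nanmean(self.dosages, axis=0) / 2.0

    def maf(self) -> np.ndarray:
        p = self.alt_freq()
        return np.minimum(p, 1.0 - p)

    def call_rate(self) -> np.ndarray:
        return np.mean(np.isfinite(self.dosages), axis=0)

    def variant_index(self, variant_id: str) -> int:
        idx = np.flatnonzero(self.variant_ids == variant_id)
        if idx.size == 0:
            raise KeyError(f"unknown variant id: {variant_id}")
        return int(idx[0])

    def subset_variants(self, mask_or_index) -> "GenotypeMatrix":
        idx = np.asarray(mask_or_index)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return GenotypeMatrix(
            dosages=self.dosages[:, idx],
            variants=self.variants.iloc[idx].reset_index(drop=True),
            individual_ids=list(self.individual_ids),
        )

    def subset_individuals(self, mask_or_index) -> "GenotypeMatrix":
        idx = np.asarray(mask_or_index)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return GenotypeMatrix(
            dosages=self.dosages[idx, :],
            variants=self.variants.copy(),
            individual_ids=[self.individual_ids[i] for i in idx],
        )


@dataclass
class PhenotypeTable:
    """Trait deviations per individual, plus optional raw columns.

    ``values`` is ``(n, T)``; ``raw`` may hold unadjusted phenotypes together
    with ``age`` and contemporary ``group`` columns used by pre-correction.
    """

    individual_ids: list[str]
    trait_names: list[str]
    values: np.ndarray
    raw: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n, t = self.values.shape
        if len(self.individual_ids) != n:
            raise ValueError("individual_ids length mismatch")
        if len(set(self.individual_ids)) != n:
            raise ValueError("individual ids must be unique")
        if len(self.trait_names) != t:
            raise ValueError("trait_names length mismatch")

    @property
    def n_traits(self) -> int:
        return len(self.trait_names)

    def trait(self, name: str) -> np.ndarray:
        return self.values[:, self.trait_names.index(name)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.individual_ids, columns=self.trait_names
        )


@dataclass
class GwasResult:
    """Per-variant single-trait association statistics."""

    trait: str
    table: pd.DataFrame  # variant_id, chrom, pos, alt_freq, beta, se, t, p, n
    covariates: list[str] = field(default_factory=list)

    def significant(self, threshold: float) -> pd.DataFrame:
        ok = self.table["p"].notna() & (self.table["p"] <= threshold)
        return self.table[ok]


@dataclass
class MtGwasResult:
    """Per-variant multi-trait association statistics (Wald, df = T)."""

    traits: list[str]
    table: pd.DataFrame  # variant_id, chrom, pos, wald, df, p + beta_<trait>
    covariates: list[str] = field(default_factory=list)


@dataclass
class AnnotationTable:
    """VEP-style per-variant annotation; coding == MODERATE or HIGH impact."""

    table: pd.DataFrame  # variant_id, consequence, impact, gene, sift

    IMPACTS = ("MODIFIER", "LOW", "MODERATE", "HIGH")

    def __post_init__(self) -> None:
        bad = set(self.table["impact"]) - set(self.IMPACTS)
        if bad:
            raise ValueError(f"unknown impact classes: {sorted(bad)}")

    def coding_mask(self) -> np.ndarray:
        return self.table["impact"].isin(["MODERATE", "HIGH"]).to_numpy()

    def coding_ids(self) -> set[str]:
        return set(self.table.loc[self.coding_mask(), "variant_id"])


@dataclass
class CredibleSet:
    """A set of candidate causal variants for one association signal.

    ``method`` is one of ``IBSS``, ``LD90``, ``LD80``, ``MT-merged``. For
    IBSS sets, ``pip`` holds per-member posterior inclusion probabilities and
    the member PIPs sum to at least ``coverage``.
    """

    method: str
    lead: str
    members: list[str]
    source: str | None = None
    pip: dict[str, float] | None = None
    coverage: float | None = None
    r2_to_lead: dict[str, float] | None = None
    span: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if self.lead not in self.members:
            raise ValueError("lead variant must be a member of its credible set")

    @property
    def size(self) -> int:
        return len(self.members)

    def member_set(self) -> set[str]:
        return set(self.members)
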