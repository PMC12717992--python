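"""Core in-memory containers for genotype and haplotype data.

The central object is :class:`GenotypePanel`, a samples x sites matrix of
allele dosages (0, 1, 2, or MISSING) with per-site metadata carried in a
pandas DataFrame. Dosages count copies of the ALT allele as read from a VCF
(``coding == "alt"``) or copies of the derived allele after polarization
(``coding == "derived"``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Sentinel for a missing genotype call. Kept negative so that any arithmetic
#: that forgets to mask it produces obviously wrong (negative) dosage sums.
MISSING: int = -1

SITE_COLUMNS = ["chrom", "pos", "ref", "alt", "ancestral", "quality_class"]


@dataclass
class GenotypePanel:
    """Samples x sites dosage matrix plus sample and site metadata.

    Parameters
    ----------
    sample_ids
        Ordered sample identifiers (rows of ``dosage``).
    pop_of_sample
        Mapping from sample id to population label; every sample must
        appear.
    sites
        DataFrame with at least ``chrom, pos, ref, alt, ancestral,
        quality_class`` columns; one row per site, ordered as the columns
        of ``dosage``. ``pos`` is 1-based and strictly increasing within a
        chromosome.
    dosage
        int8/int16 array of shape (n_samples, n_sites) with entries in
        {0, 1, 2, MISSING}.
    coding
        "alt" for raw VCF dosages, "derived" after polarization.
    """

    sample_ids: list[str]
    pop_of_sample: dict[str, str]
    sites: pd.DataFrame
    dosage: np.ndarray
    coding: str = "alt"
    history: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.sites = self.sites.reset_index(drop=True)
        if self.dosage.shape != (len(self.sample_ids), len(self.sites)):
            raise ValueError(
                f"dosage shape {self.dosage.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.sites)} sites"
            )
        missing_pop = [s for s in self.sample_ids if s not in self.pop_of_sample]
        if missing_pop:
            raise ValueError(f"samples without a population label: {missing_pop}")
        bad = ~np.isin(self.dosage, [0, 1, 2, MISSING])
        if bad.any():
            raise ValueError("dosage entries must be in {0, 1, 2, MISSING}")
        self._check_sorted()

    def _check_sorted(self) -> None:
        for _, grp in self.sites.groupby("chrom", sort=False):
            pos = grp["pos"].to_numpy()
            if np.any(np.diff(pos) <= 0):
                raise ValueError("pos must be strictly increasing within chrom")

    # -- basic geometry -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def populations(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.sample_ids:
            seen.setdefault(self.pop_of_sample[s], None)
        return list(seen)

    def sample_index(self, sample: str) -> int:
        try:
            return self.sample_ids.index(sample)
        except ValueError:
            raise KeyError(f"sample {sample!r} not in panel") from None

    def samples_of_pop(self, population: str) -> list[int]:
        idx = [
            i
            for i, s in enumerate(self.sample_ids)
            if self.pop_of_sample[s] == population
        ]
        if not idx:
            raise KeyError(f"population {population!r} not in panel")
        return idx

    # -- subsetting ------------------------------------------------------
    def take_sites(self, mask_or_index) -> "GenotypePanel":
        """New panel restricted to the given site boolean mask or index."""
        idx = np.asarray(mask_or_index)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return GenotypePanel(
            sample_ids=list(self.sample_ids),
            pop_of_sample=dict(self.pop_of_sample),
            sites=self.sites.iloc[idx].reset_index(drop=True),
            dosage=self.dosage[:, idx].copy(),
            coding=self.coding,
            history=list(self.history),
        )

    def take_samples(self, keep: list[str]) -> "GenotypePanel":
        idx = [self.sample_index(s) for s in keep]
        return GenotypePanel(
            sample_ids=list(keep),
            pop_of_sample={s: self.pop_of_sample[s] for s in keep},
            sites=self.sites.copy(),
            dosage=self.dosage[idx, :].copy(),
            coding=self.coding,
            history=list(self.history),
        )

    # -- summaries -------------------------------------------------------
    def missing_mask(self) -> np.ndarray:
        return self.dosage == MISSING

    def site_missing_fraction(self) -> np.ndarray:
        return self.missing_mask().mean(axis=0)

    def sample_missing_fraction(self) -> np.ndarray:
        return self.missing_mask().mean(axis=1)

    def allele_counts(self, sample_idx=None) -> tuple[np.ndarray, np.ndarray]:
        """Per-site (alt-or-derived allele count, called allele count).

        Restricted to ``sample_idx`` rows when given. Counts are haploid:
        each called genotype contributes 2 alleles.
        """
        d = self.dosage if sample_idx is None else self.dosage[sample_idx, :]
        called = d != MISSING
        ac = np.where(called, d, 0).sum(axis=0)
        an = 2 * called.sum(axis=0)
        return ac.astype(np.int64), an.astype(np.int64)

    def allele_freq(self, sample_idx=None) -> np.ndarray:
        """Per-site frequency of the counted allele; NaN where no calls."""
        ac, an = self.allele_counts(sample_idx)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(an > 0, ac / np.maximum(an, 1), np.nan)


@dataclass
class HaplotypePanel:
    """Binary haplotype matrix for doubled-haploid (DH) lines.

    Each DH line is fully homozygous, so its genome is a single naturally
    phased haplotype: ``H[i, j] = 1`` if line i carries the derived allele
    at site j.
    """

    line_ids: list[str]
    sites: pd.DataFrame
    H: np.ndarray

    def __post_init__(self) -> None:
        self.sites = self.sites.reset_index(drop=True)
        if self.H.shape != (len(self.line_ids), len(self.sites)):
            raise ValueError("H shape does not match line_ids x sites")
        if not np.isin(self.H, [0, 1]).all():
            raise ValueError("haplotype matrix must be binary (DH lines)")
        for _, grp in self.sites.groupby("chrom", sort=False):
            if np.any(np.diff(grp["pos"].to_numpy()) <= 0):
                raise ValueError("pos must be strictly increasing within chrom")

    @property
    def n_lines(self) -> int:
        return len(self.line_ids)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def derived_freq(self) -> np.ndarray:
        return self.H.mean(axis=0)
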