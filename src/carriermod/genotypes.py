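"""Genotype matrix container shared by simulation, QC, I/O and association."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING = -1  # internal sentinel for a missing hard call


@dataclass
class GenotypeMatrix:
    """Hard-call genotypes (0/1/2 minor-allele dosage, -1 missing).

    ``calls`` has shape (n_samples, n_snps), dtype int8.  ``snps`` is a
    DataFrame with at least columns snp_id, chrom, pos, a1, a2 (positions are
    1-based, .bim/.map convention).
    """

    sample_ids: list[str]
    snps: pd.DataFrame
    calls: np.ndarray
    family_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.sample_ids), len(self.snps)):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.snps)} SNPs"
            )
        if not self.family_ids:
            self.family_ids = list(self.sample_ids)
        bad = (self.calls < -1) | (self.calls > 2)
        if bad.any():
            raise ValueError("genotype calls must be in {-1, 0, 1, 2}")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    def observed(self) -> np.ndarray:
        return self.calls != MISSING

    def sample_call_rate(self) -> np.ndarray:
        return self.observed().mean(axis=1)

    def snp_call_rate(self) -> np.ndarray:
        return self.observed().mean(axis=0)

    def allele_freq(self) -> np.ndarray:
        """Frequency of the counted (a1) allele per SNP, over observed calls."""
        obs = self.observed()
        n = obs.sum(axis=0)
        tot = np.where(obs, self.calls, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n > 0, tot / (2.0 * n), np.nan)

    def maf(self) -> np.ndarray:
        p = self.allele_freq()
        return np.minimum(p, 1.0 - p)

    def heterozygosity(self) -> np.ndarray:
        """Per-sample fraction of heterozygous calls among observed calls."""
        obs = self.observed()
        n = obs.sum(axis=1)
        het = ((self.calls == 1) & obs).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n > 0, het / n, np.nan)

    def subset(
        self,
        sample_idx: np.ndarray | list[int] | None = None,
        snp_idx: np.ndarray | list[int] | None = None,
    ) -> "GenotypeMatrix":
        si = np.arange(self.n_samples) if sample_idx is None else np.asarray(sample_idx)
        vi = np.arange(self.n_snps) if snp_idx is None else np.asarray(snp_idx)
        return GenotypeMatrix(
            sample_ids=[self.sample_ids[i] for i in si],
            snps=self.snps.iloc[vi].reset_index(drop=True),
            calls=self.calls[np.ix_(si, vi)].copy(),
            family_ids=[self.family_ids[i] for i in si],
        )

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(
            list(self.sample_ids), self.snps.copy(), self.calls.copy(), list(self.family_ids)
        )


def snp_table(
    n: int, prefix: str = "snp", chrom: int | np.ndarray = 1, pos: np.ndarray | None = None
) -> pd.DataFrame:
    """Convenience SNP metadata table for simulated markers."""
    if pos is None:
        pos = np.arange(1, n + 1) * 1000
    chrom_arr = np.full(n, chrom) if np.isscalar(chrom) else np.asarray(chrom)
    return pd.DataFrame(
        {
            "snp_id": [f"{prefix}{i}" for i in range(n)],
            "chrom": chrom_arr,
            "pos": np.asarray(pos),
            "a1": "A",
            "a2": "B",
        }
    )
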