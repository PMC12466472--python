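"""Core data containers: abundance tables and genotype matrices."""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd


@dataclasses.dataclass
class AbundanceTable:
    """Samples x genera abundance matrix (counts or relative abundances).

    Rows are samples, columns genera. ``counts`` holds the raw values;
    ``rel_abundance`` is the row-normalized view (rows with zero total stay
    all-zero).
    """

    sample_ids: list[str]
    genus_ids: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (len(self.sample_ids), len(self.genus_ids)):
            raise ValueError(
                f"counts shape {self.counts.shape} inconsistent with "
                f"{len(self.sample_ids)} samples x {len(self.genus_ids)} genera"
            )
        if np.any(self.counts < 0):
            raise ValueError("abundances must be nonnegative")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_genera(self) -> int:
        return len(self.genus_ids)

    @property
    def rel_abundance(self) -> np.ndarray:
        totals = self.counts.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            rel = np.where(totals > 0, self.counts / totals, 0.0)
        return rel

    def prevalence(self) -> pd.Series:
        """Fraction of samples in which each genus is present (nonzero)."""
        return pd.Series((self.counts > 0).mean(axis=0), index=self.genus_ids)

    def subset_samples(self, keep: np.ndarray | list) -> "AbundanceTable":
        idx = np.asarray(keep)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return AbundanceTable(
            [self.sample_ids[i] for i in idx], list(self.genus_ids), self.counts[idx]
        )

    def subset_genera(self, genera: list[str]) -> "AbundanceTable":
        pos = [self.genus_ids.index(g) for g in genera]
        return AbundanceTable(list(self.sample_ids), list(genera), self.counts[:, pos])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.sample_ids, columns=self.genus_ids)

    def to_tsv(self, path: str | Path) -> None:
        df = self.to_frame()
        df.index.name = "sample_id"
        df.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "AbundanceTable":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(list(df.index.astype(str)), list(df.columns.astype(str)), df.to_numpy(float))


@dataclasses.dataclass
class GenotypeMatrix:
    """Diploid dosage matrix (samples x SNPs), dosages in {0,1,2} or NaN."""

    sample_ids: list[str]
    snp_ids: list[str]
    chrom: np.ndarray
    pos: np.ndarray
    dosages: np.ndarray
    n_alleles: np.ndarray | None = None  # total alleles per site when parsed from VCF

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        self.chrom = np.asarray(self.chrom)
        self.pos = np.asarray(self.pos, dtype=int)
        n, m = len(self.sample_ids), len(self.snp_ids)
        if self.dosages.shape != (n, m):
            raise ValueError(f"dosages shape {self.dosages.shape} != ({n}, {m})")
        valid = np.isnan(self.dosages) | np.isin(self.dosages, (0.0, 1.0, 2.0))
        if not valid.all():
            raise ValueError("dosages must be 0/1/2 or missing (NaN)")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    def allele_freqs(self) -> np.ndarray:
        """Alternate-allele frequency per SNP, ignoring missing calls."""
        return np.nanmean(self.dosages, axis=0) / 2.0

    def missingness(self) -> np.ndarray:
        return np.isnan(self.dosages).mean(axis=0)

    def maf(self) -> np.ndarray:
        p = self.allele_freqs()
        return np.minimum(p, 1.0 - p)

    def mean_imputed(self) -> np.ndarray:
        """Dosages with per-SNP mean substituted for missing calls."""
        x = self.dosages.copy()
        if np.isnan(x).any():
            means = np.nanmean(x, axis=0)
            rows, cols = np.where(np.isnan(x))
            x[rows, cols] = means[cols]
        return x

    def subset_snps(self, keep: np.ndarray | list) -> "GenotypeMatrix":
        idx = np.asarray(keep)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return GenotypeMatrix(
            list(self.sample_ids),
            [self.snp_ids[i] for i in idx],
            self.chrom[idx],
            self.pos[idx],
            self.dosages[:, idx],
            None if self.n_alleles is None else self.n_alleles[idx],
        )

    def snp_index(self, snp_id: str) -> int:
        return self.snp_ids.index(snp_id)

    def to_vcf(self, path: str | Path) -> None:
        """Write a minimal plain-text VCF v4.2 with GT fields."""
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
            header = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO", "FORMAT"]
            fh.write("\t".join(header + list(self.sample_ids)) + "\n")
            code = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
            for j in range(self.n_snps):
                gts = [
                    "./." if np.isnan(d) else code[d] for d in self.dosages[:, j]
                ]
                row = [
                    str(self.chrom[j]), str(self.pos[j]), self.snp_ids[j],
                    "A", "G", ".", "PASS", ".", "GT",
                ]
                fh.write("\t".join(row + gts) + "\n")

    @classmethod
    def from_vcf(cls, path: str | Path) -> "GenotypeMatrix":
        from cyvcf2 import VCF

        vcf = VCF(str(path), gts012=True)
        samples = list(vcf.samples)
        snp_ids, chrom, pos, rows, nall = [], [], [], [], []
        for var in vcf:
            snp_ids.append(var.ID or f"{var.CHROM}:{var.POS}")
            chrom.append(var.CHROM)
            pos.append(var.POS)
            nall.append(1 + len(var.ALT))
            gt = var.gt_types.astype(float)  # 0,1,2 and 3 = unknown
            gt[gt == 3] = np.nan
            rows.append(gt)
        vcf.close()
        return cls(samples, snp_ids, np.array(chrom), np.array(pos, dtype=int),
                   np.array(rows).T if rows else np.empty((len(samples), 0)),
                   np.array(nall, dtype=int))
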