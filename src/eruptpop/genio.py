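"""Genotype-matrix data model and VCF / metadata I/O.

The in-memory container for every statistic in this package is a dense
individuals x sites dosage matrix: each entry counts copies of the
alternate allele (0, 1 or 2), with ``-1`` marking a missing genotype.
Sites are biallelic SNPs identified by a target-region label and a
1-based position within that region; all windowing downstream uses
half-open intervals ``[start, end)`` on these 1-based positions.

Genotypes are treated as unphased; phase separators in input VCFs are
accepted and ignored.  Missing-data policy (per-site complete case) is
owned by the statistics modules, not by I/O.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

#: dosage code for a missing genotype
MISSING = -1

METADATA_COLUMNS = ["sample", "population", "period", "sex", "age", "burrow"]

_PERIODS = {"pre", "post"}
_SEXES = {"M", "F"}
_AGES = {"juvenile", "adult"}


@dataclass
class GenotypeMatrix:
    """Diploid dosage matrix over biallelic SNP sites.

    Parameters
    ----------
    dosages
        ``(n_samples, n_sites)`` integer array with entries in
        ``{0, 1, 2, MISSING}``.
    sample_ids
        Ordered sample labels, one per row.
    site_regions, site_positions
        Target-region label and 1-based position per site (column).
    ref, alt
        Optional per-site alleles; synthesized as A/C when absent.
    """

    dosages: np.ndarray
    sample_ids: list[str]
    site_regions: np.ndarray
    site_positions: np.ndarray
    ref: np.ndarray | None = None
    alt: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be 2-D (samples x sites)")
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.site_regions = np.asarray(self.site_regions, dtype=object)
        self.site_positions = np.asarray(self.site_positions, dtype=np.int64)
        n, m = self.dosages.shape
        if len(self.sample_ids) != n:
            raise ValueError("sample_ids length does not match dosage rows")
        if len(self.site_regions) != m or len(self.site_positions) != m:
            raise ValueError("site coordinate arrays do not match dosage columns")
        bad = ~np.isin(self.dosages, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError(f"invalid dosage codes at {int(bad.sum())} entries")
        if len(set(self.sample_ids)) != n:
            raise ValueError("duplicate sample ids")
        coords = list(zip(self.site_regions, self.site_positions))
        if len(set(coords)) != m:
            raise ValueError("site coordinates are not unique")
        if self.ref is None:
            self.ref = np.full(m, "A", dtype=object)
        if self.alt is None:
            self.alt = np.full(m, "C", dtype=object)

    # -- basic introspection -------------------------------------------------

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_sites(self) -> int:
        return self.dosages.shape[1]

    @property
    def site_ids(self) -> list[str]:
        return [f"{r}:{p}" for r, p in zip(self.site_regions, self.site_positions)]

    def missing_mask(self) -> np.ndarray:
        return self.dosages == MISSING

    def allele_counts(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-site (alt allele count, total non-missing allele count)."""
        called = self.dosages != MISSING
        alt = np.where(called, self.dosages, 0).sum(axis=0)
        return alt.astype(np.int64), 2 * called.sum(axis=0).astype(np.int64)

    def segregating_mask(self) -> np.ndarray:
        """True for sites polymorphic among the non-missing genotypes."""
        alt, tot = self.allele_counts()
        return (alt > 0) & (alt < tot)

    # -- subsetting ----------------------------------------------------------

    def _sample_indices(self, selector) -> np.ndarray:
        if selector is None:
            return np.arange(self.n_samples)
        sel = list(selector)
        if len(sel) == 0:
            raise ValueError("empty sample selector")
        if all(isinstance(s, (int, np.integer)) for s in sel):
            idx = np.asarray(sel, dtype=int)
            if idx.min() < 0 or idx.max() >= self.n_samples:
                raise KeyError("sample index out of range")
            return idx
        lookup = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in sel if s not in lookup]
        if missing:
            raise KeyError(f"unknown sample ids: {missing}")
        return np.asarray([lookup[s] for s in sel], dtype=int)

    def _site_indices(self, selector) -> np.ndarray:
        if selector is None:
            return np.arange(self.n_sites)
        sel = list(selector)
        if len(sel) == 0:
            raise ValueError("empty site selector")
        if all(isinstance(s, (int, np.integer)) for s in sel):
            idx = np.asarray(sel, dtype=int)
            if idx.min() < 0 or idx.max() >= self.n_sites:
                raise KeyError("site index out of range")
            return idx
        lookup = {sid: i for i, sid in enumerate(self.site_ids)}
        missing = [s for s in sel if s not in lookup]
        if missing:
            raise KeyError(f"unknown site ids: {missing}")
        return np.asarray([lookup[s] for s in sel], dtype=int)

    def subset(self, samples=None, sites=None) -> "GenotypeMatrix":
        """Order-preserving subset by sample and/or site labels or indices."""
        ri = self._sample_indices(samples)
        ci = self._site_indices(sites)
        return GenotypeMatrix(
            dosages=self.dosages[np.ix_(ri, ci)].copy(),
            sample_ids=[self.sample_ids[i] for i in ri],
            site_regions=self.site_regions[ci].copy(),
            site_positions=self.site_positions[ci].copy(),
            ref=self.ref[ci].copy(),
            alt=self.alt[ci].copy(),
        )


def subset_matrix(matrix: GenotypeMatrix, sample_selector=None, site_selector=None) -> GenotypeMatrix:
    """Functional alias for :meth:`GenotypeMatrix.subset`."""
    return matrix.subset(samples=sample_selector, sites=site_selector)


@dataclass
class SampleMetadata:
    """Per-individual annotations: population, period, sex, age, burrow.

    Backed by a DataFrame indexed by sample id.  Unknown tokens in the
    categorical columns are normalised to ``"unknown"``.
    """

    table: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        t = self.table.copy()
        if t.index.name != "sample":
            if "sample" in t.columns:
                t = t.set_index("sample")
            else:
                t.index.name = "sample"
        t.index = t.index.astype(str)
        if t.index.has_duplicates:
            dups = sorted(t.index[t.index.duplicated()].unique())
            raise ValueError(f"duplicated sample rows in metadata: {dups}")
        for col in ("population", "period", "sex", "age", "burrow"):
            if col not in t.columns:
                t[col] = "unknown"
            t[col] = t[col].astype(object).where(t[col].notna(), "unknown").astype(str)
        t["period"] = [p if p in _PERIODS else "unknown" for p in t["period"].str.lower()]
        t["sex"] = [s if s in _SEXES else "unknown" for s in t["sex"].str.upper()]
        t["age"] = [a if a in _AGES else "unknown" for a in t["age"].str.lower()]
        t["burrow"] = [b if b.lower() not in ("", "na", "nan", "unknown", ".") else "unknown" for b in t["burrow"]]
        self.table = t[["population", "period", "sex", "age", "burrow"]]

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    def __len__(self) -> int:
        return len(self.table)

    def for_samples(self, sample_ids: Sequence[str]) -> "SampleMetadata":
        """Rows for the given samples, in the given order; hard error if absent."""
        missing = [s for s in sample_ids if s not in self.table.index]
        if missing:
            raise KeyError(f"samples absent from metadata: {missing}")
        return SampleMetadata(self.table.loc[list(sample_ids)].copy())

    def column(self, name: str) -> np.ndarray:
        return self.table[name].to_numpy()

    def groups(self, by: Sequence[str] = ("population", "period")) -> dict[tuple, list[str]]:
        """Sample ids grouped by the given metadata columns (sorted keys)."""
        out: dict[tuple, list[str]] = {}
        for sid, row in self.table.iterrows():
            key = tuple(row[c] for c in by)
            out.setdefault(key, []).append(sid)
        return dict(sorted(out.items()))

    def write(self, path) -> None:
        t = self.table.reset_index()
        t.to_csv(path, sep="\t", index=False)


# -- VCF I/O -----------------------------------------------------------------

_GT_TYPE_TO_DOSAGE = np.array([0, 1, MISSING, 2], dtype=np.int8)  # cyvcf2 gt_types


def read_vcf(path) -> GenotypeMatrix:
    """Load biallelic SNP records from a VCF (optionally gzipped).

    Multi-allelic or non-SNP records are skipped (count logged); missing
    genotypes become the missing code.  A VCF with no GT field / no samples,
    or with zero usable records, is a hard error.
    """
    from cyvcf2 import VCF

    path = str(path)
    vcf = VCF(path, gts012=False)
    samples = list(vcf.samples)
    if not samples:
        raise ValueError(f"{path}: VCF has no samples / no GT field")
    rows, regions, positions, refs, alts = [], [], [], [], []
    skipped = 0
    for v in vcf:
        if (not v.is_snp) or len(v.ALT) != 1 or len(v.REF) != 1:
            skipped += 1
            continue
        rows.append(_GT_TYPE_TO_DOSAGE[v.gt_types])
        regions.append(v.CHROM)
        positions.append(v.POS)
        refs.append(v.REF)
        alts.append(v.ALT[0])
    vcf.close()
    if skipped:
        log.info("read_vcf: skipped %d non-biallelic-SNP records in %s", skipped, path)
    if not rows:
        raise ValueError(f"{path}: no usable biallelic SNP records")
    return GenotypeMatrix(
        dosages=np.asarray(rows, dtype=np.int8).T,
        sample_ids=samples,
        site_regions=np.asarray(regions, dtype=object),
        site_positions=np.asarray(positions, dtype=np.int64),
        ref=np.asarray(refs, dtype=object),
        alt=np.asarray(alts, dtype=object),
    )


_DOSAGE_TO_GT = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(matrix: GenotypeMatrix, path) -> None:
    """Write a VCF v4.2; records ordered deterministically by (region, position)."""
    path = str(path)
    order = np.lexsort((matrix.site_positions, matrix.site_regions.astype(str)))
    opener = gzip.open if path.endswith(".gz") else open
    contigs = sorted(set(matrix.site_regions.astype(str)))
    with opener(path, "wt") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=eruptpop\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for c in contigs:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(matrix.sample_ids) + "\n")
        for j in order:
            gts = "\t".join(_DOSAGE_TO_GT[int(d)] for d in matrix.dosages[:, j])
            fh.write(
                f"{matrix.site_regions[j]}\t{matrix.site_positions[j]}\t.\t"
                f"{matrix.ref[j]}\t{matrix.alt[j]}\t.\tPASS\t.\tGT\t{gts}\n"
            )


def read_metadata(path) -> SampleMetadata:
    """Read the sample-metadata TSV (columns: sample, population, period, sex, age, burrow)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in ("sample", "population", "period") if c not in df.columns]
    if missing:
        raise ValueError(f"metadata is missing required columns: {missing}")
    return SampleMetadata(df)


def write_metadata(meta: SampleMetadata, path) -> None:
    meta.write(path)
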