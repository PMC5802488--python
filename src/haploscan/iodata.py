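"""Readers and writers for the formats the pipeline touches.

Phased VCF (GT with ``|``), HapMap phase II genetic-map text, a
phenotype/covariate TSV and the summary-statistics TSV.  All readers
validate strictly: the pipeline analyses fully phased biallelic panels,
so unphased, missing or multi-allelic records are hard errors rather
than things to impute around.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from cyvcf2 import VCF


class FormatError(ValueError):
    """Raised when an input file violates the pipeline's contracts."""


@dataclasses.dataclass(frozen=True)
class SnpRecord:
    """One biallelic SNP with physical and genetic-map coordinates.

    ``bp`` is 1-based (GRCh37-style convention); ``cm`` is the interpolated
    map position in centimorgans and may be NaN until a genetic map has
    been applied.  ``alleles`` is the (ref, alt) pair.
    """

    id: str
    chrom: str
    bp: int
    cm: float
    alleles: tuple[str, str]


@dataclasses.dataclass
class PhasedPanel:
    """A fully phased diploid panel.

    ``haps`` has shape ``(2 * n_individuals, n_snps)`` with rows ``2i`` and
    ``2i + 1`` holding the two haploid allele vectors (0 = ref, 1 = alt) of
    individual ``i``, in SNP order.
    """

    snps: list[SnpRecord]
    individuals: list[str]
    haps: np.ndarray

    def __post_init__(self) -> None:
        self.haps = np.asarray(self.haps, dtype=np.uint8)
        if self.haps.shape != (2 * len(self.individuals), len(self.snps)):
            raise ValueError(
                f"haplotype matrix shape {self.haps.shape} does not match "
                f"{len(self.individuals)} individuals x {len(self.snps)} SNPs"
            )

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    def bp(self) -> np.ndarray:
        return np.asarray([s.bp for s in self.snps], dtype=np.int64)

    def cm(self) -> np.ndarray:
        return np.asarray([s.cm for s in self.snps], dtype=float)

    def chroms(self) -> np.ndarray:
        return np.asarray([s.chrom for s in self.snps], dtype=object)

    def with_cm(self, cm: Sequence[float]) -> "PhasedPanel":
        """Return a panel with genetic-map positions attached to the SNPs."""
        if len(cm) != self.n_snps:
            raise ValueError("cm vector length mismatch")
        snps = [dataclasses.replace(s, cm=float(c)) for s, c in zip(self.snps, cm)]
        return PhasedPanel(snps, self.individuals, self.haps)

    def genotype_dosages(self) -> np.ndarray:
        """Per-SNP alt-allele dosage matrix, shape (n_individuals, n_snps)."""
        return (self.haps[0::2].astype(np.int16) + self.haps[1::2]).astype(np.int16)


def _check_sorted(snps: list[SnpRecord]) -> None:
    prev: dict[str, int] = {}
    seen_order: list[str] = []
    for s in snps:
        if s.chrom not in prev:
            if s.chrom in seen_order:
                raise FormatError(f"chromosome {s.chrom} appears in two blocks")
            seen_order.append(s.chrom)
        elif s.bp <= prev[s.chrom]:
            raise FormatError(
                f"SNPs not strictly increasing in bp on chromosome {s.chrom} "
                f"(… {prev[s.chrom]} then {s.bp})"
            )
        prev[s.chrom] = s.bp


def read_phased_vcf(path: str | Path) -> PhasedPanel:
    """Read a phased diploid VCF into a :class:`PhasedPanel`.

    Every genotype must be a phased biallelic pair (``0|1`` style); an
    unphased separator, a missing call or a multi-allelic record raises
    :class:`FormatError`.
    """
    vcf = VCF(str(path))
    individuals = list(vcf.samples)
    if not individuals:
        raise FormatError("VCF has no samples")
    snps: list[SnpRecord] = []
    cols: list[np.ndarray] = []
    for v in vcf:
        if len(v.ALT) != 1:
            raise FormatError(
                f"non-biallelic record at {v.CHROM}:{v.POS} (ALT={v.ALT})"
            )
        g = np.asarray(v.genotypes, dtype=np.int64)  # (n, 3): a0, a1, phased
        if g.shape != (len(individuals), 3):
            raise FormatError(f"non-diploid genotype at {v.CHROM}:{v.POS}")
        if np.any(g[:, :2] < 0):
            raise FormatError(f"missing genotype at {v.CHROM}:{v.POS}")
        het = g[:, 0] != g[:, 1]
        if np.any(~g[:, 2].astype(bool) & het):
            raise FormatError(f"unphased genotype at {v.CHROM}:{v.POS}")
        if np.any(g[:, :2] > 1):
            raise FormatError(f"allele index >1 at {v.CHROM}:{v.POS}")
        snps.append(
            SnpRecord(
                id=v.ID or f"{v.CHROM}:{v.POS}",
                chrom=str(v.CHROM),
                bp=int(v.POS),
                cm=float("nan"),
                alleles=(str(v.REF), str(v.ALT[0])),
            )
        )
        cols.append(g[:, :2].reshape(-1).astype(np.uint8))
    if not snps:
        raise FormatError("VCF contains no variant records")
    _check_sorted(snps)
    haps = np.column_stack(cols)
    return PhasedPanel(snps, individuals, haps)


def write_phased_vcf(panel: PhasedPanel, path: str | Path) -> None:
    """Write a panel as a minimal phased VCF 4.2 text file."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in dict.fromkeys(s.chrom for s in panel.snps):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(panel.individuals)
            + "\n"
        )
        for j, s in enumerate(panel.snps):
            a = panel.haps[0::2, j]
            b = panel.haps[1::2, j]
            gts = "\t".join(f"{x}|{y}" for x, y in zip(a, b))
            fh.write(
                f"{s.chrom}\t{s.bp}\t{s.id}\t{s.alleles[0]}\t{s.alleles[1]}"
                f"\t.\t.\t.\tGT\t{gts}\n"
            )


def read_genetic_map(path: str | Path) -> pd.DataFrame:
    """Read a HapMap phase II style genetic map.

    Whitespace-delimited columns: Chromosome, Position(bp), Rate(cM/Mb),
    Map(cM); a header line is allowed.  Within each chromosome bp must be
    strictly increasing and cM non-decreasing.
    """
    df = pd.read_csv(path, sep=r"\s+", header=None, comment="#", dtype=str)
    if df.shape[1] != 4:
        raise FormatError(f"genetic map must have 4 columns, got {df.shape[1]}")
    # drop a header row if the bp column is not numeric there
    try:
        float(df.iloc[0, 1])
    except (ValueError, TypeError):
        df = df.iloc[1:]
    if df.empty:
        raise FormatError("empty genetic map")
    out = pd.DataFrame(
        {
            "chrom": df.iloc[:, 0].astype(str).values,
            "bp": df.iloc[:, 1].astype(np.int64).values,
            "rate_cm_mb": df.iloc[:, 2].astype(float).values,
            "cm": df.iloc[:, 3].astype(float).values,
        }
    )
    for chrom, grp in out.groupby("chrom", sort=False):
        if not np.all(np.diff(grp["bp"].values) > 0):
            raise FormatError(f"non-monotone map: bp not increasing on {chrom}")
        if not np.all(np.diff(grp["cm"].values) >= 0):
            raise FormatError(f"non-monotone map: cm decreasing on {chrom}")
    return out


def write_genetic_map(gmap: pd.DataFrame, path: str | Path) -> None:
    out = gmap[["chrom", "bp", "rate_cm_mb", "cm"]].copy()
    out.columns = ["Chromosome", "Position(bp)", "Rate(cM/Mb)", "Map(cM)"]
    out.to_csv(path, sep=" ", index=False, float_format="%.12g")


PHENO_REQUIRED = ("iid", "y", "sex", "age")
PHENO_OPTIONAL = ("batch", "centre")


def read_phenotypes(path: str | Path, panel: PhasedPanel | None = None) -> pd.DataFrame:
    """Read the phenotype/covariate TSV (iid, y, sex, age[, batch, centre]).

    ``y`` must be binary 0/1 and individual IDs unique; if a panel is given,
    every ID must be present in it.
    """
    df = pd.read_csv(path, sep="\t", dtype={"iid": str})
    missing = [c for c in PHENO_REQUIRED if c not in df.columns]
    if missing:
        raise FormatError(f"phenotype table missing columns: {missing}")
    if df["iid"].duplicated().any():
        dup = df.loc[df["iid"].duplicated(), "iid"].iloc[0]
        raise FormatError(f"duplicate iid {dup!r} in phenotype table")
    y = df["y"].values
    if not np.isin(y, [0, 1]).all():
        bad = y[~np.isin(y, [0, 1])][0]
        raise FormatError(f"y must be binary 0/1, found {bad!r}")
    df["y"] = df["y"].astype(np.int8)
    if panel is not None:
        unknown = set(df["iid"]) - set(panel.individuals)
        if unknown:
            raise FormatError(f"phenotype IDs not in panel: {sorted(unknown)[:5]}")
    return df


def write_phenotypes(phen: pd.DataFrame, path: str | Path) -> None:
    cols = [c for c in (*PHENO_REQUIRED, *PHENO_OPTIONAL) if c in phen.columns]
    phen[cols].to_csv(path, sep="\t", index=False, float_format="%.12g")


SUMMARY_COLUMNS = [
    "chrom",
    "start_bp",
    "end_bp",
    "window_cm",
    "allele_string",
    "freq",
    "hwe_x2",
    "beta",
    "se",
    "p",
    "or_",
    "or_lo",
    "or_hi",
]


def write_summary_stats(results: pd.DataFrame, path: str | Path) -> None:
    """Write association results, one row per tested haplotype.

    Numeric columns are emitted at 12 significant digits so a read-back is
    lossless at that precision.
    """
    missing = [c for c in SUMMARY_COLUMNS if c not in results.columns]
    if missing:
        raise FormatError(f"summary statistics missing columns: {missing}")
    results[SUMMARY_COLUMNS].to_csv(
        path, sep="\t", index=False, float_format="%.12g"
    )


def read_summary_stats(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "allele_string": str})
    missing = [c for c in SUMMARY_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"summary statistics missing columns: {missing}")
    return df
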