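"""Haplotype allele enumeration, frequency and HWE statistics, QC, dosages.

Within each window every distinct haploid allele string is a "haplotype
allele" A, tested against the pooled alternative a (all other strings in
that window).  Collapsing to A-vs-a gives a three-class diploid table
(AA, Aa, aa) from which the allele frequency

    p = (2 obs(AA) + obs(Aa)) / (2 (obs(AA) + obs(Aa) + obs(aa)))

and a 1-df Pearson Hardy–Weinberg chi-squared statistic are computed.
Alleles failing QC (p outside [p_min, p_max] or X² above the threshold,
24 ≈ the 1-df critical value for P < 1e-6) are not tested themselves but
remain inside the pooled alternative of every kept allele.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .genmap import Window
from .iodata import PhasedPanel


@dataclasses.dataclass
class HaplotypeAllele:
    """One distinct allele string within a window, with its A-vs-a table."""

    window: Window
    allele_string: str
    obs_AA: int
    obs_Aa: int
    obs_aa: int
    n: int
    p: float
    x2: float
    merged: bool = False

    @property
    def q(self) -> float:
        return 1.0 - self.p


def haplotype_frequency(obs_AA: int, obs_Aa: int, obs_aa: int) -> float:
    """Allele frequency from the collapsed A-vs-a diploid genotype counts."""
    n = obs_AA + obs_Aa + obs_aa
    if n == 0:
        raise ValueError("all-zero genotype counts")
    if min(obs_AA, obs_Aa, obs_aa) < 0:
        raise ValueError("negative genotype count")
    return (2 * obs_AA + obs_Aa) / (2 * n)


def hwe_chisq(obs_AA: int, obs_Aa: int, obs_aa: int) -> float:
    """Pearson chi-squared for Hardy–Weinberg equilibrium (1 df).

    Expected counts are (p²n, 2pqn, q²n).  For a monomorphic allele
    (p = 0 or 1) the statistic is defined as 0.
    """
    n = obs_AA + obs_Aa + obs_aa
    p = haplotype_frequency(obs_AA, obs_Aa, obs_aa)
    q = 1.0 - p
    if p <= 0.0 or p >= 1.0:
        return 0.0
    exp = np.array([p * p * n, 2 * p * q * n, q * q * n])
    obs = np.array([obs_AA, obs_Aa, obs_aa], dtype=float)
    return float(np.sum((obs - exp) ** 2 / exp))


def _window_hap_codes(panel: PhasedPanel, window: Window) -> tuple[np.ndarray, list[str]]:
    """Map each haploid's allele string in the window to an integer code.

    Returns (codes of shape (2n,), list of allele strings by code).
    """
    block = np.ascontiguousarray(panel.haps[:, window.first_idx : window.last_idx + 1])
    uniq, codes = np.unique(block, axis=0, return_inverse=True)
    strings = ["".join(map(str, row)) for row in uniq]
    return codes.ravel(), strings


def call_haplotypes(panel: PhasedPanel, window: Window) -> list[HaplotypeAllele]:
    """Enumerate the distinct haplotype alleles of one window with counts.

    Genotype classes per allele A: AA = both haploids carry A, Aa = exactly
    one, aa = neither (a pools every other allele string in the window).
    """
    codes, strings = _window_hap_codes(panel, window)
    n = panel.n_individuals
    a = codes[0::2]
    b = codes[1::2]
    alleles: list[HaplotypeAllele] = []
    for code, s in enumerate(strings):
        hits = (a == code).astype(np.int8) + (b == code).astype(np.int8)
        obs_AA = int(np.sum(hits == 2))
        obs_Aa = int(np.sum(hits == 1))
        obs_aa = n - obs_AA - obs_Aa
        p = haplotype_frequency(obs_AA, obs_Aa, obs_aa)
        alleles.append(
            HaplotypeAllele(
                window=window,
                allele_string=s,
                obs_AA=obs_AA,
                obs_Aa=obs_Aa,
                obs_aa=obs_aa,
                n=n,
                p=p,
                x2=hwe_chisq(obs_AA, obs_Aa, obs_aa),
            )
        )
    alleles.sort(key=lambda al: (-al.p, al.allele_string))
    return alleles


def qc_filter(
    alleles: list[HaplotypeAllele],
    p_min: float = 0.005,
    p_max: float = 0.995,
    x2_max: float = 24.0,
) -> tuple[list[HaplotypeAllele], list[HaplotypeAllele]]:
    """Split a window's alleles into (kept, merged).

    Merged alleles (too rare, too common, or out of HWE with X² strictly
    above ``x2_max``) are excluded from testing but stay pooled inside the
    alternative of every kept allele's A-vs-a contrast.
    """
    kept: list[HaplotypeAllele] = []
    merged: list[HaplotypeAllele] = []
    for al in alleles:
        if al.p < p_min or al.p > p_max or al.x2 > x2_max:
            al.merged = True
            merged.append(al)
        else:
            al.merged = False
            kept.append(al)
    return kept, merged


def dosage(panel: PhasedPanel, window: Window, allele_string: str) -> np.ndarray:
    """Per-individual count (0/1/2) of haploids exactly matching the allele."""
    if len(allele_string) != window.n_snps:
        raise ValueError(
            f"allele string length {len(allele_string)} != window SNP count "
            f"{window.n_snps}"
        )
    target = np.frombuffer(allele_string.encode(), dtype=np.uint8) - ord("0")
    block = panel.haps[:, window.first_idx : window.last_idx + 1]
    match = np.all(block == target, axis=1).astype(np.int8)
    return (match[0::2] + match[1::2]).astype(np.int8)


def window_dosages(panel: PhasedPanel, window: Window) -> tuple[list[str], np.ndarray]:
    """Dosages of every distinct allele in a window at once.

    Returns (allele strings, matrix of shape (n_alleles, n_individuals)).
    Per individual the dosages sum to 2 across alleles.
    """
    codes, strings = _window_hap_codes(panel, window)
    a = codes[0::2]
    b = codes[1::2]
    k = len(strings)
    dos = np.zeros((k, panel.n_individuals), dtype=np.int8)
    for code in range(k):
        dos[code] = (a == code).astype(np.int8) + (b == code).astype(np.int8)
    return strings, dos


def founders_only_frequency(
    panel: PhasedPanel, window: Window, allele_string: str, founder_ids: set[str]
) -> float:
    """Allele frequency computed on a founder/unrelated subset only.

    Reported alongside the all-individuals frequency for comparison with
    frequencies calculated using unrelated individuals.
    """
    mask = np.asarray([iid in founder_ids for iid in panel.individuals])
    if not mask.any():
        raise ValueError("no founders in panel")
    dos = dosage(panel, window, allele_string)
    return float(dos[mask].sum() / (2 * mask.sum()))


def catalogue_frame(alleles: list[HaplotypeAllele]) -> pd.DataFrame:
    """Haplotype catalogue as a flat table (TSV-exportable)."""
    return pd.DataFrame(
        {
            "chrom": [al.window.chrom for al in alleles],
            "start_bp": [al.window.start_bp for al in alleles],
            "end_bp": [al.window.end_bp for al in alleles],
            "window_cm": [al.window.size_cm for al in alleles],
            "allele_string": [al.allele_string for al in alleles],
            "obs_AA": [al.obs_AA for al in alleles],
            "obs_Aa": [al.obs_Aa for al in alleles],
            "obs_aa": [al.obs_aa for al in alleles],
            "freq": [al.p for al in alleles],
            "hwe_x2": [al.x2 for al in alleles],
            "merged": [al.merged for al in alleles],
        }
    )
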