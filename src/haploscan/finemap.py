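"""Fine mapping of haplotype boundaries.

Testing a haplotype against all other alleles in its window can dilute
the signal when overlapping windows carry similar haplotypes tagging the
same causal variant.  Fine mapping takes pairs of directly overlapping
same-size-class haplotypes that are both suggestively associated
(P below a candidate threshold, effects in the same direction), extracts
every shared consecutive SNP run of at least five SNPs where the two
allele strings agree, and re-tests each such run as a new haplotype in
the same mixed model using all individuals.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .haplotypes import dosage
from .genmap import Window
from .iodata import PhasedPanel
from .mlm import AssociationResult, MlmScan


@dataclasses.dataclass(frozen=True)
class OverlapPair:
    """Two same-size-class associated alleles whose windows overlap."""

    result_a: AssociationResult
    result_b: AssociationResult

    @property
    def windows(self) -> tuple[Window, Window]:
        return (self.result_a.window, self.result_b.window)


@dataclasses.dataclass(frozen=True)
class RefinedAllele:
    """A shared consecutive sub-haplotype of an overlapping pair."""

    chrom: str
    first_idx: int
    last_idx: int
    allele_string: str
    parent: OverlapPair

    @property
    def n_snps(self) -> int:
        return self.last_idx - self.first_idx + 1


def _overlap_span(wa: Window, wb: Window) -> tuple[int, int] | None:
    if wa.chrom != wb.chrom:
        return None
    lo = max(wa.first_idx, wb.first_idx)
    hi = min(wa.last_idx, wb.last_idx)
    return (lo, hi) if hi >= lo else None


def find_candidate_pairs(
    results: list[AssociationResult],
    p_thresh: float = 1e-3,
    min_overlap_snps: int = 5,
) -> list[OverlapPair]:
    """All same-size-class pairs with ≥ ``min_overlap_snps`` shared
    consecutive SNPs, both P < ``p_thresh`` and effects in the same
    direction."""
    cands = [
        r
        for r in results
        if not r.skipped and r.window is not None and r.p < p_thresh
    ]
    pairs: list[OverlapPair] = []
    for i in range(len(cands)):
        for j in range(i + 1, len(cands)):
            a, b = cands[i], cands[j]
            if a.window.size_cm != b.window.size_cm:
                continue
            if np.sign(a.beta) != np.sign(b.beta):
                continue
            span = _overlap_span(a.window, b.window)
            if span is None or span[1] - span[0] + 1 < min_overlap_snps:
                continue
            if (a.window.key(), a.allele_string) == (b.window.key(), b.allele_string):
                continue
            pairs.append(OverlapPair(a, b))
    return pairs


def shared_runs(pair: OverlapPair, min_snps: int = 5) -> list[RefinedAllele]:
    """Every run of ≥ ``min_snps`` consecutive overlap SNPs where the two
    parent allele strings agree, as candidate refined haplotypes."""
    a, b = pair.result_a, pair.result_b
    span = _overlap_span(a.window, b.window)
    if span is None:
        return []
    lo, hi = span
    sa = a.allele_string[lo - a.window.first_idx : hi - a.window.first_idx + 1]
    sb = b.allele_string[lo - b.window.first_idx : hi - b.window.first_idx + 1]
    agree = np.frombuffer(sa.encode(), dtype=np.uint8) == np.frombuffer(
        sb.encode(), dtype=np.uint8
    )
    runs: list[RefinedAllele] = []
    start = None
    for k, ok in enumerate([*agree, False]):
        if ok and start is None:
            start = k
        elif not ok and start is not None:
            if k - start >= min_snps:
                runs.append(
                    RefinedAllele(
                        chrom=a.window.chrom,
                        first_idx=lo + start,
                        last_idx=lo + k - 1,
                        allele_string=sa[start:k],
                        parent=pair,
                    )
                )
            start = None
    return runs


def shared_consecutive_region(
    pair: OverlapPair, min_snps: int = 5
) -> RefinedAllele | None:
    """The longest agreeing consecutive run of the pair, or None if < min."""
    runs = shared_runs(pair, min_snps=min_snps)
    if not runs:
        return None
    return max(runs, key=lambda r: (r.n_snps, -r.first_idx))


def retest_refined(
    panel: PhasedPanel,
    refined: list[RefinedAllele],
    scan: MlmScan,
) -> list[AssociationResult]:
    """Re-test refined alleles (exact haploid match over the refined span)
    with the same null-model projection as the main scan.

    Duplicate refined alleles (same span and string from different pairs)
    are tested once.
    """
    seen: set[tuple[int, int, str]] = set()
    out: list[AssociationResult] = []
    for r in refined:
        key = (r.first_idx, r.last_idx, r.allele_string)
        if key in seen:
            continue
        seen.add(key)
        win = Window(
            chrom=r.chrom,
            size_cm=r.parent.result_a.window.size_cm,
            first_idx=r.first_idx,
            last_idx=r.last_idx,
            start_bp=panel.snps[r.first_idx].bp,
            end_bp=panel.snps[r.last_idx].bp,
            start_cm=panel.snps[r.first_idx].cm,
        )
        d = dosage(panel, win, r.allele_string)
        out.append(scan.test(d, window=win, allele_string=r.allele_string))
    return out
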