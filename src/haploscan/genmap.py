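"""Genetic-map interpolation and tiling of overlapping centimorgan windows.

Windows of a fixed genetic length (1, 0.5 or 0.25 cM) are anchored at the
map position of each chromosome's first SNP and advanced by a quarter of
the window size, so consecutive same-size windows overlap by three
quarters of their span.  A window keeps the SNPs whose map position falls
in the half-open interval [anchor, anchor + size); windows holding fewer
than ``min_snps`` SNPs are dropped.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .iodata import PhasedPanel, SnpRecord

WINDOW_SIZES_CM = (1.0, 0.5, 0.25)


@dataclasses.dataclass(frozen=True)
class Window:
    """A cM-delimited SNP span; indices are into the panel's SNP order."""

    chrom: str
    size_cm: float
    first_idx: int
    last_idx: int
    start_bp: int
    end_bp: int
    start_cm: float

    @property
    def n_snps(self) -> int:
        return self.last_idx - self.first_idx + 1

    def key(self) -> tuple:
        return (self.chrom, self.size_cm, self.start_cm, self.first_idx)


def interpolate_cm(gmap: pd.DataFrame, chrom: str, bp) -> np.ndarray | float:
    """Piecewise-linear interpolation of Map(cM) at physical position(s).

    Positions outside the map's span are clamped to the boundary cM value.
    Accepts a scalar or an array of bp; returns the matching shape.
    """
    sub = gmap[gmap["chrom"] == str(chrom)]
    if sub.empty:
        raise KeyError(f"chromosome {chrom!r} not in genetic map")
    out = np.interp(np.asarray(bp, dtype=float), sub["bp"].values, sub["cm"].values)
    return float(out) if np.ndim(bp) == 0 else out


def assign_cm(panel: PhasedPanel, gmap: pd.DataFrame) -> PhasedPanel:
    """Attach interpolated cM positions to every SNP of a panel."""
    cm = np.empty(panel.n_snps)
    chroms = panel.chroms()
    bp = panel.bp()
    for chrom in dict.fromkeys(chroms):
        mask = chroms == chrom
        cm[mask] = interpolate_cm(gmap, chrom, bp[mask])
    return panel.with_cm(cm)


def tile_windows(
    snps: list[SnpRecord],
    size_cm: float,
    step_fraction: float = 0.25,
    min_snps: int = 5,
) -> list[Window]:
    """Tile overlapping windows of ``size_cm`` over each chromosome.

    Anchors start at the cM of the chromosome's first SNP and advance by
    ``size_cm * step_fraction`` while the anchor is strictly below the cM
    of the last SNP.  Windows with fewer than ``min_snps`` SNPs (including
    truncated tail windows) are dropped.
    """
    if not snps:
        raise ValueError("empty SNP list")
    cm = np.asarray([s.cm for s in snps], dtype=float)
    if np.isnan(cm).any():
        raise ValueError("SNPs lack cM positions; run assign_cm first")
    chroms = np.asarray([s.chrom for s in snps], dtype=object)
    step = size_cm * step_fraction
    windows: list[Window] = []
    for chrom in dict.fromkeys(chroms):
        idx = np.flatnonzero(chroms == chrom)
        c = cm[idx]
        anchor = c[0]
        last_cm = c[-1]
        while anchor < last_cm or np.isclose(anchor, c[0]):
            lo = int(np.searchsorted(c, anchor, side="left"))
            hi = int(np.searchsorted(c, anchor + size_cm, side="left"))
            if hi - lo >= min_snps:
                first, last = int(idx[lo]), int(idx[hi - 1])
                windows.append(
                    Window(
                        chrom=str(chrom),
                        size_cm=size_cm,
                        first_idx=first,
                        last_idx=last,
                        start_bp=snps[first].bp,
                        end_bp=snps[last].bp,
                        start_cm=float(anchor),
                    )
                )
            anchor += step
            if anchor >= last_cm:
                break
    return windows


def tile_all_sizes(
    snps: list[SnpRecord],
    sizes=WINDOW_SIZES_CM,
    step_fraction: float = 0.25,
    min_snps: int = 5,
) -> list[Window]:
    out: list[Window] = []
    for size in sizes:
        out.extend(tile_windows(snps, size, step_fraction, min_snps))
    return out


def windows_to_bed(windows: list[Window]) -> pd.DataFrame:
    """Window table in BED-like form (0-based half-open bp, for export only)."""
    return pd.DataFrame(
        {
            "chrom": [w.chrom for w in windows],
            "start": [w.start_bp - 1 for w in windows],
            "end": [w.end_bp for w in windows],
            "size_cm": [w.size_cm for w in windows],
        }
    )
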