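"""SNP-based genomic relationship matrices.

G follows the standard VanRaden-style estimator

    G_jk = (1/M) Σ_i (x_ij − 2 p_i)(x_ik − 2 p_i) / (2 p_i (1 − p_i))

over M polymorphic SNPs with alt-dosages x ∈ {0, 1, 2} and frequencies
p_i.  The thresholded companion G_t zeroes off-diagonal entries strictly
below a cutoff (default 0.05), keeping only the closer relationships; the
pair (G, G_t) lets a mixed model separate distant-ancestry structure from
family covariance.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np


@dataclasses.dataclass
class GrmPair:
    G: np.ndarray
    Gt: np.ndarray
    ids: list[str]


def compute_grm(genotype_dosages: np.ndarray, allele_freqs: np.ndarray) -> np.ndarray:
    """Genomic relationship matrix from an (n, M) alt-dosage matrix.

    Monomorphic SNPs (p ∈ {0, 1}) are excluded with a warning; allele
    frequencies are supplied by the caller (analyzed-sample estimates by
    default, founders-only if desired).
    """
    X = np.asarray(genotype_dosages, dtype=float)
    p = np.asarray(allele_freqs, dtype=float)
    if X.ndim != 2 or p.shape != (X.shape[1],):
        raise ValueError("dosage matrix (n, M) and M frequencies required")
    poly = (p > 0.0) & (p < 1.0)
    if not poly.all():
        warnings.warn(
            f"excluding {int((~poly).sum())} monomorphic SNPs from GRM",
            stacklevel=2,
        )
        X = X[:, poly]
        p = p[poly]
    m = X.shape[1]
    if m == 0:
        raise ValueError("no polymorphic SNPs left for GRM")
    W = (X - 2.0 * p) / np.sqrt(2.0 * p * (1.0 - p))
    G = W @ W.T / m
    return (G + G.T) / 2.0


def threshold_grm(G: np.ndarray, cutoff: float = 0.05) -> np.ndarray:
    """Zero the off-diagonal entries of G that are strictly below ``cutoff``."""
    G = np.asarray(G, dtype=float)
    if G.shape[0] != G.shape[1] or not np.allclose(G, G.T, atol=1e-10):
        raise ValueError("G must be symmetric")
    Gt = np.where(G < cutoff, 0.0, G)
    np.fill_diagonal(Gt, np.diag(G))
    return Gt


def grm_pair(
    genotype_dosages: np.ndarray,
    allele_freqs: np.ndarray,
    ids: list[str],
    cutoff: float = 0.05,
) -> GrmPair:
    G = compute_grm(genotype_dosages, allele_freqs)
    return GrmPair(G=G, Gt=threshold_grm(G, cutoff), ids=list(ids))


def export_grm_triplets(G: np.ndarray, ids: list[str], path) -> None:
    """GCTA-style text triplets (id_i, id_j, value) for the lower triangle."""
    with open(path, "w") as fh:
        for j in range(len(ids)):
            for k in range(j + 1):
                fh.write(f"{ids[j]}\t{ids[k]}\t{G[j, k]:.10g}\n")
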