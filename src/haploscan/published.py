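"""Printed summary statistics of the MDD haplotype GWAS candidate set.

The twelve candidate haplotypes (discovery P < 1e-6) from the published
genome-wide haplotype association study of major depressive disorder in
Generation Scotland: Scottish Family Health Study (family-based discovery
cohort) with UK Biobank as population-based replication.  Per haplotype:
window coordinates (GRCh37, outermost SNPs), discovery and replication
odds ratios with 95% CIs and P-values, and the haplotype frequencies
observed in each cohort (calculated on unrelated individuals).

These rows are *inputs* — e.g. to the inverse-variance meta-analysis and
the replication power calculation — not outputs of this package.
"""

from __future__ import annotations

import dataclasses


@dataclasses.dataclass(frozen=True)
class CandidateHaplotype:
    chrom: str
    start_bp: int
    end_bp: int
    window_cm: float
    or_disc: float
    ci_disc: tuple[float, float]
    p_disc: float
    or_repl: float
    ci_repl: tuple[float, float]
    p_repl: float
    freq_disc: float
    freq_repl: float
    fine_mapped: bool = False


CANDIDATE_HAPLOTYPES: tuple[CandidateHaplotype, ...] = (
    CandidateHaplotype("6", 108338267, 108454437, 0.34, 1.83, (1.53, 2.16),
                       7.06e-9, 1.11, (1.01, 1.22), 3.62e-2, 0.0152, 0.0197,
                       fine_mapped=True),
    CandidateHaplotype("6", 108407662, 108454437, 0.25, 1.68, (1.42, 1.96),
                       8.17e-8, 1.14, (1.04, 1.24), 4.47e-3, 0.0193, 0.0241),
    CandidateHaplotype("7", 139682412, 139708901, 0.25, 2.17, (1.67, 2.73),
                       4.37e-7, 0.87, (0.68, 1.08), 2.20e-1, 0.0066, 0.0069),
    CandidateHaplotype("8", 79700362, 80387861, 0.5, 1.98, (1.56, 2.46),
                       9.02e-7, 1.06, (0.86, 1.28), 5.93e-1, 0.0076, 0.0081),
    CandidateHaplotype("8", 79759499, 80156474, 0.25, 1.77, (1.47, 2.10),
                       7.90e-8, 1.05, (0.91, 1.21), 5.06e-1, 0.0147, 0.0157),
    CandidateHaplotype("10", 4588261, 4822210, 0.5, 2.33, (1.83, 2.91),
                       8.50e-9, 1.15, (0.80, 1.59), 4.39e-1, 0.0064, 0.0027),
    CandidateHaplotype("11", 2260854, 2437425, 0.41, 1.64, (1.38, 1.91),
                       2.86e-7, 1.00, (0.87, 1.34), 9.91e-1, 0.0196, 0.0187,
                       fine_mapped=True),
    CandidateHaplotype("12", 48159721, 48263828, 0.25, 2.00, (1.58, 2.47),
                       4.78e-7, 0.97, (0.79, 1.17), 7.36e-1, 0.0078, 0.0090),
    CandidateHaplotype("12", 116904503, 117062860, 0.25, 2.13, (1.64, 2.69),
                       9.90e-7, 1.04, (0.79, 1.34), 7.79e-1, 0.0057, 0.0045),
    CandidateHaplotype("15", 49206902, 49260601, 0.25, 2.03, (1.62, 2.48),
                       9.21e-8, 1.09, (0.88, 1.32), 4.04e-1, 0.0082, 0.0080),
    CandidateHaplotype("15", 93806447, 93851224, 0.5, 1.58, (1.34, 1.83),
                       4.47e-7, 0.93, (0.81, 1.05), 2.38e-1, 0.0224, 0.0206),
    CandidateHaplotype("15", 93821340, 93845622, 0.25, 1.52, (1.31, 1.75),
                       8.67e-7, 0.91, (0.81, 1.03), 1.37e-1, 0.0265, 0.0243),
)

#: discovery cohort case/control counts after phenotype QC
DISCOVERY_CASES = 2605
DISCOVERY_CONTROLS = 16168
#: replication cohort case/control counts
REPLICATION_CASES = 8508
REPLICATION_CONTROLS = 16527
#: MDD prevalence from structured clinical diagnoses in comparable populations
REFERENCE_PREVALENCE = 0.146
#: approximately independent haplotypes at LD r² < 0.4 in the discovery cohort
N_INDEPENDENT_HAPLOTYPES = 1_070_216
#: genome-wide significance level used
GENOME_WIDE_ALPHA = 5e-8
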