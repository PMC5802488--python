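"""Post-scan machinery: LD clumping, genomic control, meta-analysis, power.

The number of approximately independent haplotype tests is estimated by
greedy LD clumping of the scan results (PLINK's clump logic: best
remaining P becomes an index; correlated neighbours join it), and the
Bonferroni level is 0.05 divided by the clump count.  Cohorts are
combined by fixed-effect inverse-variance-weighted meta-analysis on the
log-OR scale.  Replication power uses a 1-df allelic two-proportion test
under a multiplicative risk model with screened controls.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
from scipy import stats

from .mlm import Z_95, AssociationResult

#: median of the 1-df chi-squared distribution, used by genomic control
CHI2_1_MEDIAN = 0.454936423119573


@dataclasses.dataclass
class Clump:
    index: int  # position of the index haplotype in the input list
    members: list[int]  # positions of all clump members (index included)


@dataclasses.dataclass
class ClumpReport:
    n_input: int
    n_independent: int
    r2_threshold: float
    clumps: list[Clump]

    @property
    def bonferroni_alpha(self) -> float:
        return 0.05 / self.n_independent


@dataclasses.dataclass
class MetaResult:
    cohort_stats: list[tuple[float, float]]
    beta: float
    se: float
    z: float
    p: float

    @property
    def or_(self) -> float:
        return math.exp(self.beta)

    @property
    def or_ci(self) -> tuple[float, float]:
        return (
            math.exp(self.beta - Z_95 * self.se),
            math.exp(self.beta + Z_95 * self.se),
        )


@dataclasses.dataclass(frozen=True)
class PowerSpec:
    """Inputs of the allelic replication-power calculation."""

    grr: float  # genotype relative risk per copy of the risk haplotype
    freq: float  # risk haplotype frequency in the population
    prevalence: float  # population prevalence K of the trait
    n_case: int
    n_control: int
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.grr <= 0:
            raise ValueError("genotype relative risk must be positive")
        if not 0.0 < self.freq < 1.0:
            raise ValueError("freq must be in (0, 1)")
        if not 0.0 < self.prevalence < 1.0:
            raise ValueError("prevalence must be in (0, 1)")


def ld_r2(dosage_a: np.ndarray, dosage_b: np.ndarray) -> float:
    """Squared Pearson correlation between two haplotype dosage vectors."""
    a = np.asarray(dosage_a, dtype=float)
    b = np.asarray(dosage_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("dosage vectors differ in length")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("constant dosage vector has undefined r²")
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


def clump(
    results: list[AssociationResult],
    dosages: np.ndarray,
    r2_threshold: float = 0.4,
    distance_kb: float = 1000.0,
) -> ClumpReport:
    """Greedy LD clumping of scan results.

    Results are visited in ascending P (ties by chrom then start_bp); each
    unassigned haplotype becomes a clump index, and every unassigned
    haplotype on the same chromosome within ``distance_kb`` of the index
    window whose dosage r² with the index is ≥ ``r2_threshold`` joins it.
    """
    if not results:
        raise ValueError("no results to clump")
    D = np.asarray(dosages, dtype=float)
    if D.shape[0] != len(results):
        raise ValueError("dosage matrix does not match results")
    order = sorted(
        range(len(results)),
        key=lambda i: (
            results[i].p,
            results[i].window.chrom if results[i].window else "",
            results[i].window.start_bp if results[i].window else 0,
        ),
    )
    assigned = np.zeros(len(results), dtype=bool)
    clumps: list[Clump] = []
    dist_bp = distance_kb * 1000.0
    for i in order:
        if assigned[i]:
            continue
        assigned[i] = True
        members = [i]
        wi = results[i].window
        for j in order:
            if assigned[j]:
                continue
            wj = results[j].window
            if wi is not None and wj is not None:
                if wi.chrom != wj.chrom:
                    continue
                gap = max(wj.start_bp - wi.end_bp, wi.start_bp - wj.end_bp, 0)
                if gap > dist_bp:
                    continue
            if np.ptp(D[j]) == 0 or np.ptp(D[i]) == 0:
                continue
            if ld_r2(D[i], D[j]) >= r2_threshold:
                assigned[j] = True
                members.append(j)
        clumps.append(Clump(index=i, members=members))
    return ClumpReport(
        n_input=len(results),
        n_independent=len(clumps),
        r2_threshold=r2_threshold,
        clumps=clumps,
    )


def genomic_inflation(p_values: np.ndarray) -> float:
    """Genomic inflation factor λGC: median implied χ²₁ over its null median."""
    p = np.asarray(p_values, dtype=float)
    if p.size < 100:
        raise ValueError("need at least 100 P-values for a stable λGC")
    chi2 = stats.chi2.isf(p, df=1)
    return float(np.median(chi2) / CHI2_1_MEDIAN)


def ivw_meta(cohort_stats: list[tuple[float, float]]) -> MetaResult:
    """Fixed-effect inverse-variance-weighted combination of (beta, se)."""
    if len(cohort_stats) < 2:
        raise ValueError("meta-analysis needs at least two cohorts")
    betas = np.asarray([b for b, _ in cohort_stats], dtype=float)
    ses = np.asarray([s for _, s in cohort_stats], dtype=float)
    if np.any(ses <= 0):
        raise ValueError("standard errors must be positive")
    w = 1.0 / ses**2
    beta = float(np.sum(w * betas) / np.sum(w))
    se = float(np.sum(w) ** -0.5)
    z = beta / se
    return MetaResult(
        cohort_stats=list(cohort_stats),
        beta=beta,
        se=se,
        z=float(z),
        p=float(2.0 * stats.norm.sf(abs(z))),
    )


def or_ci_to_beta_se(or_: float, lo: float, hi: float) -> tuple[float, float]:
    """Recover (log-OR, SE) from a printed odds ratio and 95% CI."""
    if not 0.0 < lo <= or_ <= hi:
        raise ValueError("require 0 < lo ≤ OR ≤ hi")
    return float(math.log(or_)), float((math.log(hi) - math.log(lo)) / (2.0 * Z_95))


def allelic_power(spec: PowerSpec) -> float:
    """Power of the two-proportion allelic test under a multiplicative model.

    Case risk-allele frequency: p_case = f·GRR / (1 + f·(GRR − 1)).  With
    screened controls, the population frequency decomposes as
    f = K·p_case + (1 − K)·p_ctrl, giving the control frequency.  Power is
    the probability that the two-proportion z statistic (allele counts,
    2·n_case vs 2·n_control chromosomes, pooled-variance null) exceeds the
    two-sided critical value.
    """
    f, grr, K = spec.freq, spec.grr, spec.prevalence
    p_case = f * grr / (1.0 + f * (grr - 1.0))
    p_ctrl = (f - K * p_case) / (1.0 - K)
    if not 0.0 < p_ctrl < 1.0:
        raise ValueError("control frequency outside (0, 1); inputs inconsistent")
    n1 = 2.0 * spec.n_case
    n2 = 2.0 * spec.n_control
    pbar = (n1 * p_case + n2 * p_ctrl) / (n1 + n2)
    se_null = math.sqrt(pbar * (1.0 - pbar) * (1.0 / n1 + 1.0 / n2))
    se_alt = math.sqrt(p_case * (1.0 - p_case) / n1 + p_ctrl * (1.0 - p_ctrl) / n2)
    z_crit = stats.norm.isf(spec.alpha / 2.0)
    d = p_case - p_ctrl
    upper = stats.norm.sf((z_crit * se_null - d) / se_alt)
    lower = stats.norm.cdf((-z_crit * se_null - d) / se_alt)
    return float(upper + lower)


def monte_carlo_power(spec: PowerSpec, n_reps: int, seed: int) -> float:
    """Simulation estimate of the allelic-test power (oracle cross-check).

    Draws case/control allele counts binomially at the model's case and
    screened-control frequencies and applies the same pooled z-test.
    """
    f, grr, K = spec.freq, spec.grr, spec.prevalence
    p_case = f * grr / (1.0 + f * (grr - 1.0))
    p_ctrl = (f - K * p_case) / (1.0 - K)
    rng = np.random.default_rng(seed)
    n1 = 2 * spec.n_case
    n2 = 2 * spec.n_control
    x1 = rng.binomial(n1, p_case, size=n_reps)
    x2 = rng.binomial(n2, p_ctrl, size=n_reps)
    f1 = x1 / n1
    f2 = x2 / n2
    pbar = (x1 + x2) / (n1 + n2)
    se0 = np.sqrt(pbar * (1 - pbar) * (1 / n1 + 1 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (f1 - f2) / se0
    z_crit = stats.norm.isf(spec.alpha / 2.0)
    return float(np.mean(np.abs(z) > z_crit))
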