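"""Synthetic family cohorts with planted causal haplotypes.

The generator emulates the structure the association pipeline assumes:

* a genetic map (one chromosome, constant recombination rate, jittered
  physical spacing);
* founder haplotypes from a first-order Markov copying model: each
  founder haploid is a mosaic of a small pool of ancestral haplotypes,
  switching between pool members at a rate set by the LD decay length
  (``ld_decay_cm``, the expected copying-segment length in cM) with a
  small per-SNP mutation rate — long shared haplotypes with realistic
  local LD and direct control over per-window haplotype diversity;
* a family-structured cohort — many singletons plus families of 2–31
  members, mimicking a family-based population study — where offspring
  haploids are crossover mosaics of the parental haploids with crossovers
  placed as a Poisson process on the cM map;
* a binary phenotype from a liability-threshold model: sex/age/age²
  covariate effects, planted causal-haplotype effects, a pedigree-
  correlated polygenic term of variance h², and unit-scale residual
  noise, with cases defined above the empirical (1 − K) liability
  quantile so the realized prevalence matches the target K;
* a truth ledger (:class:`SimTruth`) recording the planted alleles,
  realized frequencies, prevalence and pedigree.

All randomness descends from a single seed through a named
``SeedSequence`` hierarchy (map, founders, planting, meiosis, phenotype).
"""

from __future__ import annotations

import dataclasses
import json
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .iodata import PhasedPanel, SnpRecord

#: family-size frequencies patterned on a family-based population cohort
#: (many singletons, mostly 2–4-member families, a thin tail up to 31)
DEFAULT_FAMILY_SIZE_WEIGHTS: dict[int, float] = {
    1: 1789, 2: 1799, 3: 1216, 4: 829, 5: 400, 6: 180,
    7: 80, 8: 40, 10: 15, 15: 5, 31: 1,
}


@dataclasses.dataclass(frozen=True)
class PlantedEffect:
    """A causal haplotype to plant: where, how common, how strong."""

    locus_cm: float
    target_freq: float
    beta_liability: float
    span_snps: int = 8


@dataclasses.dataclass
class SimConfig:
    n_individuals: int = 1000
    n_snps: int = 2000
    chrom: str = "1"
    map_length_cm: float = 5.0
    rate_cm_per_mb: float = 1.0
    ld_decay_cm: float = 0.5
    n_founder_haplotypes: int = 30
    mutation_rate: float = 0.002
    maf_range: tuple[float, float] = (0.01, 0.5)
    family_size_weights: dict[int, float] = dataclasses.field(
        default_factory=lambda: dict(DEFAULT_FAMILY_SIZE_WEIGHTS)
    )
    prevalence: float = 0.139
    h2: float = 0.3
    beta_sex: float = 0.10
    beta_age: float = 0.10
    beta_age2: float = 0.05
    planted: tuple[PlantedEffect, ...] = ()
    n_batches: int = 0
    n_centres: int = 0
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if not 0.0 < self.prevalence < 1.0:
            raise ValueError("prevalence must be in (0, 1)")
        if not 0.0 <= self.h2 < 1.0:
            raise ValueError("h² must be in [0, 1)")


@dataclasses.dataclass
class CausalAllele:
    """Definition of one planted causal haplotype for the truth ledger."""

    first_idx: int
    last_idx: int
    allele_string: str
    target_freq: float
    realized_freq: float
    beta_liability: float = 0.0
    edited: bool = False


@dataclasses.dataclass
class SimTruth:
    causal: list[CausalAllele]
    prevalence_target: float
    prevalence_realized: float
    h2: float
    liability_threshold: float
    covariate_betas: dict[str, float]
    pedigree: list[tuple[str, str, str]]  # (iid, father, mother); "0" = founder
    seed: int

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "causal": [dataclasses.asdict(c) for c in self.causal],
                    "prevalence_target": self.prevalence_target,
                    "prevalence_realized": self.prevalence_realized,
                    "h2": self.h2,
                    "liability_threshold": self.liability_threshold,
                    "covariate_betas": self.covariate_betas,
                    "pedigree": self.pedigree,
                    "seed": self.seed,
                },
                fh,
                indent=1,
            )


def _make_map(cfg: SimConfig, rng: np.random.Generator):
    mean_gap_bp = cfg.map_length_cm / cfg.rate_cm_per_mb * 1e6 / cfg.n_snps
    gaps = rng.uniform(0.5, 1.5, cfg.n_snps) * mean_gap_bp
    bp = 10_000 + np.cumsum(gaps).astype(np.int64)
    bp = np.maximum.accumulate(bp + np.arange(cfg.n_snps))  # strictly increasing
    cm = (bp - bp[0]) * cfg.rate_cm_per_mb / 1e6
    gmap = pd.DataFrame(
        {
            "chrom": cfg.chrom,
            "bp": bp,
            "rate_cm_mb": cfg.rate_cm_per_mb,
            "cm": cm,
        }
    )
    return bp, cm, gmap


def _ancestral_pool(
    n_pool: int, maf: np.ndarray, cm: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Pool of ancestral haplotypes via a latent Gaussian AR(1) chain.

    Marginal allele frequency tracks ``maf``; the latent correlation keeps
    nearby SNPs in LD within each pool haplotype.  Every SNP is forced
    polymorphic within the pool.
    """
    m = len(maf)
    thresh = stats.norm.ppf(maf)
    z = np.empty((n_pool, m))
    z[:, 0] = rng.standard_normal(n_pool)
    rho = np.exp(-np.diff(cm) / 0.05)  # short-range latent LD inside the pool
    eps = rng.standard_normal((n_pool, m - 1))
    for i in range(1, m):
        r = rho[i - 1]
        z[:, i] = r * z[:, i - 1] + np.sqrt(1.0 - r * r) * eps[:, i - 1]
    pool = (z < thresh).astype(np.uint8)
    const = np.ptp(pool, axis=0) == 0
    for j in np.flatnonzero(const):
        pool[rng.integers(n_pool), j] ^= 1
    return pool


def _founder_haploids(
    n_hap: int,
    maf: np.ndarray,
    cm: np.ndarray,
    ld_decay_cm: float,
    n_pool: int,
    mutation_rate: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Founder haploids as first-order-Markov mosaics of the ancestral pool.

    The copying state switches between pool haplotypes with probability
    1 − exp(−d_cM / ld_decay_cm) per SNP interval, so ``ld_decay_cm`` is the
    expected copying-segment length; a small per-SNP mutation rate adds
    rare private variation.
    """
    m = len(maf)
    pool = _ancestral_pool(n_pool, maf, cm, rng)
    p_switch = 1.0 - np.exp(-np.diff(cm) / max(ld_decay_cm, 1e-9))
    out = np.empty((n_hap, m), dtype=np.uint8)
    state = rng.integers(0, n_pool, size=n_hap)
    out[:, 0] = pool[state, 0]
    for i in range(1, m):
        sw = rng.random(n_hap) < p_switch[i - 1]
        if sw.any():
            state[sw] = rng.integers(0, n_pool, size=int(sw.sum()))
        out[:, i] = pool[state, i]
    if mutation_rate > 0:
        flips = rng.random(out.shape) < mutation_rate
        out ^= flips.astype(np.uint8)
    return out


def _plant_on_haploids(
    haps: np.ndarray,
    first_idx: int,
    last_idx: int,
    target_freq: float,
    rng: np.random.Generator,
) -> CausalAllele:
    """Select, or minimally edit haploids to create, an allele near target_freq."""
    n_hap = haps.shape[0]
    want = int(round(target_freq * n_hap))
    if want < 1:
        raise ValueError(
            f"target frequency {target_freq} unreachable with {n_hap} haploids"
        )
    block = np.ascontiguousarray(haps[:, first_idx : last_idx + 1])
    uniq, inv, counts = np.unique(
        block, axis=0, return_inverse=True, return_counts=True
    )
    inv = inv.ravel()
    freqs = counts / n_hap
    best = int(np.argmin(np.abs(freqs - target_freq)))
    edited = False
    if abs(freqs[best] - target_freq) > 0.25 * target_freq:
        edited = True
        carriers = np.flatnonzero(inv == best)
        others = np.flatnonzero(inv != best)
        if counts[best] < want:
            take = rng.choice(others, size=want - counts[best], replace=False)
            haps[np.ix_(take, range(first_idx, last_idx + 1))] = uniq[best]
        else:
            drop = rng.choice(carriers, size=counts[best] - want, replace=False)
            if others.size == 0:
                repl = uniq[best].copy()
                repl[0] ^= 1  # monomorphic window: make an alternative string
                haps[np.ix_(drop, range(first_idx, last_idx + 1))] = repl
            else:
                src = rng.choice(others, size=drop.size, replace=True)
                haps[drop, first_idx : last_idx + 1] = haps[
                    src, first_idx : last_idx + 1
                ]
    block = haps[:, first_idx : last_idx + 1]
    realized = float(np.mean(np.all(block == uniq[best], axis=1)))
    return CausalAllele(
        first_idx=first_idx,
        last_idx=last_idx,
        allele_string="".join(map(str, uniq[best])),
        target_freq=target_freq,
        realized_freq=realized,
        edited=edited,
    )


def plant_causal_haplotype(
    panel: PhasedPanel,
    locus_cm: float,
    target_freq: float,
    seed: int,
    span_snps: int = 8,
) -> CausalAllele:
    """Plant a causal allele in a panel (in place) and return its definition.

    The span is ``span_snps`` consecutive SNPs starting at the first SNP at
    or beyond ``locus_cm``.  An existing allele within ±25% relative of the
    target frequency is selected unmodified; otherwise haploids are
    minimally edited toward the target.
    """
    if not 0.005 < target_freq < 0.5:
        raise ValueError("target_freq must be in (0.005, 0.5)")
    if span_snps < 5:
        raise ValueError("causal haplotypes must span at least 5 SNPs")
    cm = panel.cm()
    first = int(np.searchsorted(cm, locus_cm))
    if first + span_snps > panel.n_snps:
        raise ValueError("locus too close to the end of the panel")
    rng = np.random.default_rng(seed)
    return _plant_on_haploids(panel.haps, first, first + span_snps - 1,
                              target_freq, rng)


def _gamete(
    hap_a: np.ndarray, hap_b: np.ndarray, cm: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """One meiotic product: crossovers as a Poisson process on the cM map."""
    length_cm = cm[-1] - cm[0]
    k = rng.poisson(length_cm / 100.0)
    if k > 0:
        xs = np.sort(rng.uniform(cm[0], cm[-1], size=k))
        seg = np.searchsorted(xs, cm, side="right")
    else:
        seg = np.zeros(len(cm), dtype=np.int64)
    phase = (seg + rng.integers(2)) % 2
    return np.where(phase == 0, hap_a, hap_b).astype(np.uint8)


def _sample_families(cfg: SimConfig, rng: np.random.Generator) -> list[int]:
    sizes = np.array(sorted(cfg.family_size_weights), dtype=int)
    w = np.array([cfg.family_size_weights[int(s)] for s in sizes], dtype=float)
    w /= w.sum()
    out: list[int] = []
    total = 0
    while total < cfg.n_individuals:
        s = int(rng.choice(sizes, p=w))
        s = min(s, cfg.n_individuals - total)
        out.append(s)
        total += s
    return out


def simulate_cohort(
    cfg: SimConfig,
) -> tuple[PhasedPanel, pd.DataFrame, pd.DataFrame, SimTruth]:
    """Simulate (panel, phenotype table, genetic map, truth ledger)."""
    ss = np.random.SeedSequence(cfg.seed)
    rng_map, rng_found, rng_plant, rng_meio, rng_phen = (
        np.random.default_rng(s) for s in ss.spawn(5)
    )

    bp, cm, gmap = _make_map(cfg, rng_map)
    maf = rng_found.uniform(*cfg.maf_range, size=cfg.n_snps)

    # pedigree: persons are (father, mother) indices or (-1, -1) founders;
    # genotyped[] marks cohort members (hidden parents support sib families)
    fathers: list[int] = []
    mothers: list[int] = []
    genotyped: list[bool] = []

    def add_person(f: int, m: int, geno: bool) -> int:
        fathers.append(f)
        mothers.append(m)
        genotyped.append(geno)
        return len(fathers) - 1

    for size in _sample_families(cfg, rng_meio):
        if size == 1:
            add_person(-1, -1, True)
        elif size == 2:
            f = add_person(-1, -1, False)
            m = add_person(-1, -1, False)
            add_person(f, m, True)
            add_person(f, m, True)
        else:
            f = add_person(-1, -1, True)
            m = add_person(-1, -1, True)
            for _ in range(size - 2):
                add_person(f, m, True)

    n_persons = len(fathers)
    founder_idx = [i for i in range(n_persons) if fathers[i] < 0]
    haps = np.zeros((2 * n_persons, cfg.n_snps), dtype=np.uint8)
    fh = _founder_haploids(
        2 * len(founder_idx),
        maf,
        cm,
        cfg.ld_decay_cm,
        cfg.n_founder_haplotypes,
        cfg.mutation_rate,
        rng_found,
    )
    for k, i in enumerate(founder_idx):
        haps[2 * i] = fh[2 * k]
        haps[2 * i + 1] = fh[2 * k + 1]

    # plant causal alleles on the founder haploids, pre-meiosis
    founder_rows = np.asarray(
        [r for i in founder_idx for r in (2 * i, 2 * i + 1)], dtype=int
    )
    causal: list[CausalAllele] = []
    for eff in cfg.planted:
        first = int(np.searchsorted(cm, eff.locus_cm))
        if first + eff.span_snps > cfg.n_snps:
            raise ValueError("planted locus too close to the end of the map")
        fview = haps[founder_rows]
        ca = _plant_on_haploids(
            fview, first, first + eff.span_snps - 1, eff.target_freq, rng_plant
        )
        haps[founder_rows] = fview
        ca.beta_liability = eff.beta_liability
        causal.append(ca)

    # meiosis, in creation order (parents always precede children)
    for i in range(n_persons):
        if fathers[i] < 0:
            continue
        f, m = fathers[i], mothers[i]
        haps[2 * i] = _gamete(haps[2 * f], haps[2 * f + 1], cm, rng_meio)
        haps[2 * i + 1] = _gamete(haps[2 * m], haps[2 * m + 1], cm, rng_meio)

    # polygenic values down the pedigree
    a = np.zeros(n_persons)
    if cfg.h2 > 0:
        for i in range(n_persons):
            if fathers[i] < 0:
                a[i] = rng_phen.normal(0.0, np.sqrt(cfg.h2))
            else:
                a[i] = 0.5 * (a[fathers[i]] + a[mothers[i]]) + rng_phen.normal(
                    0.0, np.sqrt(cfg.h2 / 2.0)
                )

    geno = np.flatnonzero(genotyped)
    n = len(geno)
    rows = np.asarray([r for i in geno for r in (2 * i, 2 * i + 1)], dtype=int)
    ids = [f"ind{k + 1:05d}" for k in range(n)]
    snps = [
        SnpRecord(
            id=f"snp{j + 1:06d}",
            chrom=cfg.chrom,
            bp=int(bp[j]),
            cm=float(cm[j]),
            alleles=("A", "G"),
        )
        for j in range(cfg.n_snps)
    ]
    panel = PhasedPanel(snps, ids, haps[rows])

    # covariates and liability
    sex = rng_phen.integers(0, 2, size=n)
    age = rng_phen.uniform(18.0, 99.0, size=n)
    z_age = (age - 58.5) / np.sqrt((99.0 - 18.0) ** 2 / 12.0)
    liab = (
        cfg.beta_sex * (sex - 0.5)
        + cfg.beta_age * z_age
        + cfg.beta_age2 * (z_age**2 - 1.0)
        + a[geno]
        + rng_phen.normal(0.0, np.sqrt(1.0 - cfg.h2), size=n)
    )
    for ca in causal:
        target = np.frombuffer(ca.allele_string.encode(), np.uint8) - ord("0")
        match = np.all(
            panel.haps[:, ca.first_idx : ca.last_idx + 1] == target, axis=1
        )
        dos = (match[0::2] + match[1::2]).astype(float)
        ca.realized_freq = float(dos.mean() / 2.0)
        liab += ca.beta_liability * (dos - dos.mean())
    thresh = float(np.quantile(liab, 1.0 - cfg.prevalence))
    y = (liab > thresh).astype(np.int8)

    phen = pd.DataFrame({"iid": ids, "y": y, "sex": sex, "age": age})
    if cfg.n_batches > 0:
        phen["batch"] = [
            f"b{k}" for k in rng_phen.integers(0, cfg.n_batches, size=n)
        ]
    if cfg.n_centres > 0:
        phen["centre"] = [
            f"c{k}" for k in rng_phen.integers(0, cfg.n_centres, size=n)
        ]

    def name(i: int) -> str:
        if i < 0:
            return "0"
        if genotyped[i]:
            return ids[int(np.searchsorted(geno, i))]
        return f"founder{i}"

    pedigree = [
        (name(i), name(fathers[i]), name(mothers[i])) for i in range(n_persons)
    ]
    truth = SimTruth(
        causal=causal,
        prevalence_target=cfg.prevalence,
        prevalence_realized=float(y.mean()),
        h2=cfg.h2,
        liability_threshold=thresh,
        covariate_betas={
            "sex": cfg.beta_sex,
            "age": cfg.beta_age,
            "age2": cfg.beta_age2,
        },
        pedigree=pedigree,
        seed=cfg.seed,
    )
    return panel, phen, gmap, truth


def sibling_pairs(truth: SimTruth) -> list[tuple[str, str]]:
    """Genotyped full-sib pairs from the truth pedigree (for GRM checks)."""
    by_parents: dict[tuple[str, str], list[str]] = {}
    for iid, f, m in truth.pedigree:
        if f != "0" and not iid.startswith("founder"):
            by_parents.setdefault((f, m), []).append(iid)
    pairs = []
    for sibs in by_parents.values():
        for i in range(len(sibs)):
            for j in range(i + 1, len(sibs)):
                pairs.append((sibs[i], sibs[j]))
    return pairs
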