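"""End-to-end orchestration: windows → haplotypes/QC → GRMs → REML → scan
→ fine mapping → clumping → optional replication scan → meta-analysis.

Every stage writes its artifact (TSV/JSON) into the run directory and
records filter bookkeeping in a MANIFEST, so a run is auditable: windows
tiled vs kept, alleles called vs merged, clumps, the Bonferroni level and
λGC of the scan.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .finemap import find_candidate_pairs, retest_refined, shared_runs
from .genmap import Window, assign_cm, tile_windows
from .haplotypes import call_haplotypes, dosage, qc_filter
from .iodata import (
    PhasedPanel,
    read_genetic_map,
    read_phased_vcf,
    read_phenotypes,
    write_summary_stats,
)
from .mlm import AssociationResult, MlmScan, VarComp, build_design, reml_fit
from .postprocess import clump, genomic_inflation, ivw_meta, or_ci_to_beta_se
from .relatedness import compute_grm, threshold_grm

log = logging.getLogger("haploscan")

ALLOWED_WINDOW_SIZES = (1.0, 0.5, 0.25)


@dataclasses.dataclass
class CohortPaths:
    vcf: str
    genetic_map: str
    phenotypes: str


@dataclasses.dataclass
class RunConfig:
    discovery: CohortPaths
    out_dir: str
    replication: CohortPaths | None = None
    window_sizes: tuple[float, ...] = (1.0, 0.5, 0.25)
    step_fraction: float = 0.25
    min_snps: int = 5
    p_min: float = 0.005
    p_max: float = 0.995
    x2_max: float = 24.0
    two_grm: bool = True
    grm_cutoff: float = 0.05
    covariates: tuple[str, ...] = ("sex", "age")
    replication_covariates: tuple[str, ...] = ("sex", "age", "batch", "centre")
    candidate_p: float = 1e-6
    finemap_p: float = 1e-3
    genome_wide_p: float = 5e-8
    clump_r2: float = 0.4
    clump_distance_kb: float = 1000.0
    maf_min: float = 0.01
    seed: int = 1

    def validate(self) -> None:
        bad = [w for w in self.window_sizes if w not in ALLOWED_WINDOW_SIZES]
        if bad or not self.window_sizes:
            raise ValueError(
                f"window sizes must be a non-empty subset of "
                f"{ALLOWED_WINDOW_SIZES}, got {self.window_sizes}"
            )
        for name in ("p_min", "p_max", "finemap_p", "candidate_p", "genome_wide_p"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must be in (0, 1), got {v}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh)
        raw["discovery"] = CohortPaths(**raw["discovery"])
        if raw.get("replication"):
            raw["replication"] = CohortPaths(**raw["replication"])
        for key in ("window_sizes", "covariates", "replication_covariates"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def results_frame(results: list[AssociationResult]) -> pd.DataFrame:
    rows = [r for r in results if not r.skipped]
    return pd.DataFrame(
        {
            "chrom": [r.window.chrom for r in rows],
            "start_bp": [r.window.start_bp for r in rows],
            "end_bp": [r.window.end_bp for r in rows],
            "window_cm": [r.window.size_cm for r in rows],
            "allele_string": [r.allele_string for r in rows],
            "freq": [r.freq for r in rows],
            "hwe_x2": [getattr(r, "hwe_x2", float("nan")) for r in rows],
            "beta": [r.beta for r in rows],
            "se": [r.se for r in rows],
            "p": [r.p for r in rows],
            "or_": [r.or_ for r in rows],
            "or_lo": [r.or_lo for r in rows],
            "or_hi": [r.or_hi for r in rows],
        }
    )


def _load_cohort(paths: CohortPaths):
    panel = read_phased_vcf(paths.vcf)
    gmap = read_genetic_map(paths.genetic_map)
    panel = assign_cm(panel, gmap)
    phen = read_phenotypes(paths.phenotypes, panel)
    # align phenotype rows to panel order
    phen = phen.set_index("iid").loc[panel.individuals].reset_index()
    return panel, phen


def fit_null_model(
    panel: PhasedPanel,
    phen: pd.DataFrame,
    covariates: tuple[str, ...],
    two_grm: bool,
    grm_cutoff: float,
    maf_min: float,
) -> tuple[MlmScan, VarComp, np.ndarray]:
    """GRM(s) from QC-passed SNPs, null REML fit, and the scan projector."""
    dos = panel.genotype_dosages().astype(float)
    freqs = dos.mean(axis=0) / 2.0
    maf = np.minimum(freqs, 1 - freqs)
    keep = maf >= maf_min
    G = compute_grm(dos[:, keep], freqs[keep])
    kernels = [G]
    names: tuple[str, ...] = ("g",)
    if two_grm:
        kernels.append(threshold_grm(G, grm_cutoff))
        names = ("g", "gt")
    covs = tuple(c for c in covariates if c in phen.columns)
    X = build_design(phen, covs)
    y = phen["y"].to_numpy(dtype=float)
    vc = reml_fit(y, X, kernels, names=names)
    scan = MlmScan(y, X, vc, kernels)
    return scan, vc, X


def scan_windows(
    panel: PhasedPanel,
    windows: list[Window],
    scan: MlmScan,
    p_min: float,
    p_max: float,
    x2_max: float,
) -> tuple[list[AssociationResult], list[np.ndarray], dict[str, int]]:
    """Call, QC and test every window's alleles; returns results + dosages."""
    results: list[AssociationResult] = []
    dosages: list[np.ndarray] = []
    n_called = n_merged = 0
    for w in windows:
        alleles = call_haplotypes(panel, w)
        kept, merged = qc_filter(alleles, p_min, p_max, x2_max)
        n_called += len(alleles)
        n_merged += len(merged)
        for al in kept:
            d = dosage(panel, w, al.allele_string)
            res = scan.test(
                d, window=w, allele_string=al.allele_string, freq=al.p
            )
            res.hwe_x2 = al.x2  # annotate for the summary table
            if not res.skipped:
                results.append(res)
                dosages.append(d)
    counts = {
        "alleles_called": n_called,
        "alleles_merged": n_merged,
        "alleles_tested": len(results),
    }
    return results, dosages, counts


def run_pipeline(cfg: RunConfig) -> Path:
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": cfg.seed,
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "complete": False,
        "counts": {},
    }
    stage = "load-discovery"
    try:
        panel, phen = _load_cohort(cfg.discovery)

        stage = "windows"
        windows: list[Window] = []
        per_size = {}
        for size in cfg.window_sizes:
            ws = tile_windows(panel.snps, size, cfg.step_fraction, cfg.min_snps)
            per_size[str(size)] = len(ws)
            windows.extend(ws)
        manifest["counts"]["windows_kept"] = len(windows)
        manifest["counts"]["windows_per_size"] = per_size
        log.info("tiled %d windows (%s)", len(windows), per_size)

        stage = "null-model"
        scan, vc, _ = fit_null_model(
            panel, phen, cfg.covariates, cfg.two_grm, cfg.grm_cutoff, cfg.maf_min
        )
        with open(out / "varcomp.json", "w") as fh:
            json.dump(
                {
                    "sigma2": vc.as_dict(),
                    "loglik_restricted": vc.loglik_restricted,
                    "n_iter": vc.n_iter,
                    "converged": vc.converged,
                    "case_fraction": scan.case_fraction,
                },
                fh,
                indent=1,
            )

        stage = "scan"
        results, dosages, counts = scan_windows(
            panel, windows, scan, cfg.p_min, cfg.p_max, cfg.x2_max
        )
        manifest["counts"].update(counts)
        disc = results_frame(results)
        write_summary_stats(disc, out / "discovery_assoc.tsv")
        if len(disc) >= 100:
            manifest["lambda_gc"] = genomic_inflation(disc["p"].values)

        stage = "finemap"
        pairs = find_candidate_pairs(results, cfg.finemap_p)
        refined = [r for pr in pairs for r in shared_runs(pr)]
        fm_results = retest_refined(panel, refined, scan)
        write_summary_stats(results_frame(fm_results), out / "finemap_assoc.tsv")
        manifest["counts"]["finemap_pairs"] = len(pairs)
        manifest["counts"]["finemap_haplotypes"] = len(
            [r for r in fm_results if not r.skipped]
        )

        stage = "clump"
        if results:
            report = clump(
                results, np.asarray(dosages), cfg.clump_r2, cfg.clump_distance_kb
            )
            manifest["counts"]["clumps_independent"] = report.n_independent
            manifest["bonferroni_alpha"] = report.bonferroni_alpha
            clump_rows = pd.DataFrame(
                {
                    "clump": np.arange(len(report.clumps)),
                    "index_p": [results[c.index].p for c in report.clumps],
                    "n_members": [len(c.members) for c in report.clumps],
                }
            )
            clump_rows.to_csv(out / "clumps.tsv", sep="\t", index=False)

        all_results = results + [r for r in fm_results if not r.skipped]
        candidates = [r for r in all_results if r.p < cfg.candidate_p]
        manifest["counts"]["candidates"] = len(candidates)

        if cfg.replication is not None and candidates:
            stage = "replication"
            rpanel, rphen = _load_cohort(cfg.replication)
            rscan, rvc, _ = fit_null_model(
                rpanel,
                rphen,
                cfg.replication_covariates,
                two_grm=False,
                grm_cutoff=cfg.grm_cutoff,
                maf_min=cfg.maf_min,
            )
            rep_results = []
            metas = []
            for r in candidates:
                w = r.window
                # the replication panel must share SNP order/orientation
                d = dosage(rpanel, w, r.allele_string)
                rr = rscan.test(
                    d, window=w, allele_string=r.allele_string
                )
                rep_results.append(rr)
                if not rr.skipped:
                    m = ivw_meta(
                        [
                            or_ci_to_beta_se(r.or_, r.or_lo, r.or_hi),
                            or_ci_to_beta_se(rr.or_, rr.or_lo, rr.or_hi),
                        ]
                    )
                    metas.append(
                        {
                            "chrom": w.chrom,
                            "start_bp": w.start_bp,
                            "end_bp": w.end_bp,
                            "allele_string": r.allele_string,
                            "p_discovery": r.p,
                            "p_replication": rr.p,
                            "or_meta": m.or_,
                            "or_meta_lo": m.or_ci[0],
                            "or_meta_hi": m.or_ci[1],
                            "p_meta": m.p,
                        }
                    )
            write_summary_stats(
                results_frame(rep_results), out / "replication_assoc.tsv"
            )
            pd.DataFrame(metas).to_csv(out / "meta.tsv", sep="\t", index=False)

        manifest["complete"] = True
    except Exception as exc:
        manifest["failed_stage"] = stage
        manifest["error"] = str(exc)
        with open(out / "MANIFEST.json", "w") as fh:
            json.dump(manifest, fh, indent=1)
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
    with open(out / "MANIFEST.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    log.info("run complete: %s", out)
    return out
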