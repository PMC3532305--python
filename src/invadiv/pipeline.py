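"""Study-shaped analysis pipeline driven by a single config file.

``run_analysis`` executes, in order: per-population diversity summaries
(all loci and an optional matched-locus subset), rarefaction, diversity vs
time-since-colonisation, group comparisons, bottleneck tests,
differentiation estimates (theta, D_est, R_ST) with permutation
significance, Bonferroni thresholds and bootstrap CIs, the
isolation-by-distance Mantel suite, phenotype/spectra processing with
outlier screening and MANOVA, and the P_ST sensitivity analysis per trait
and sex.  Outputs are CSV tables plus a machine-readable run log
(config echo, versions, per-stage seeds) sufficient to re-execute an
identical run.

Each stochastic stage gets its own child seed derived deterministically
from the config seed, so runs are byte-for-byte reproducible.  Any stage
failure aborts the run, removes partial outputs, and reports the stage
name.
"""

from __future__ import annotations

import json
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .bottleneck import TpmConfig, bottleneck_test
from .differentiation import (
    PairwiseMatrix,
    bonferroni_threshold,
    great_circle_matrix,
    jost_d,
    mantel,
    rst,
    wc_theta,
)
from .diversity import (
    diversity_summary,
    group_diversity_test,
    rarefied_richness,
    time_correlation,
)
from .io import (
    GenotypeDataset,
    allele_frequencies,
    parse_genepop,
    read_long_csv,
    read_site_metadata,
)
from .phenotype import color_table, manova_pillai, outlier_filter, process_spectra
from .pst import pst_sensitivity

__all__ = ["AnalysisConfig", "StageError", "run_analysis"]


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class AnalysisConfig:
    """Pipeline settings; mirrors the YAML config file one-to-one."""

    output_dir: str
    genotypes: str | None = None
    site_metadata: str | None = None
    phenotypes: str | None = None
    spectra: str | None = None
    analysis_groups: dict[str, list[str]] = field(default_factory=dict)
    matched_loci: list[str] = field(default_factory=list)
    rarefaction_g: dict[str, int] = field(default_factory=dict)
    n_perm: int = 1000
    n_boot: int = 1000
    alpha: float = 0.05
    reference_year: int = 2012
    hwe_max_tables: int = 20000
    hwe_mc_reps: int = 10000
    run_bottleneck: bool = True
    bottleneck: dict[str, Any] = field(default_factory=dict)
    traits: list[str] = field(default_factory=list)
    covariate: str = "body_length"
    outlier_quantile: float = 0.975
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def _load_genotypes(path: str) -> GenotypeDataset:
    p = Path(path)
    if p.suffix.lower() in (".gen", ".genepop", ".txt"):
        return parse_genepop(p.read_text())
    return read_long_csv(p)


def _write_combined_matrix(low: PairwiseMatrix, up: PairwiseMatrix, path: Path) -> None:
    """Lower triangle from one statistic, upper from another (table style)."""
    k = len(low.labels)
    m = np.full((k, k), np.nan)
    iu = np.triu_indices(k, 1)
    il = np.tril_indices(k, -1)
    m[iu] = up.values[iu]
    m[il] = low.values[il]
    pd.DataFrame(m, index=low.labels, columns=low.labels).to_csv(path)


def run_analysis(cfg: AnalysisConfig) -> dict[str, Any]:
    """Run the configured pipeline; returns the run log dict."""
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    log: dict[str, Any] = {
        "invadiv_version": __version__,
        "python": sys.version.split()[0],
        "config": {k: getattr(cfg, k) for k in cfg.__dataclass_fields__},
        "stages": {},
    }
    seeds = np.random.SeedSequence(cfg.seed).spawn(8)
    stage_seed = {
        name: int(s.generate_state(1)[0] % (2**31))
        for name, s in zip(
            ["theta", "jost", "rst", "mantel", "bottleneck", "pst", "hwe", "spare"],
            seeds,
        )
    }
    log["stage_seeds"] = stage_seed

    def emit(df: pd.DataFrame, name: str, **kw) -> None:
        path = out / name
        df.to_csv(path, **kw)
        written.append(path)

    current_stage = "setup"
    try:
        if cfg.genotypes is None:
            raise ValueError("a genotype input is required")
        ds = _load_genotypes(cfg.genotypes)
        missing = set(cfg.matched_loci) - set(ds.locus_names)
        if missing:
            raise ValueError(f"matched_loci not in dataset: {sorted(missing)}")
        groups = cfg.analysis_groups or {"all": list(ds.populations)}
        for gname, pops in groups.items():
            missing_p = set(pops) - set(ds.populations)
            if missing_p:
                raise ValueError(
                    f"analysis group {gname!r} references unknown populations "
                    f"{sorted(missing_p)}"
                )
        sites = (
            read_site_metadata(cfg.site_metadata, analysis_year=cfg.reference_year)
            if cfg.site_metadata
            else None
        )

        # ---- diversity --------------------------------------------------
        current_stage = "diversity"
        locus_sets = {"all_loci": ds}
        if cfg.matched_loci:
            locus_sets["matched_loci"] = ds.with_loci(cfg.matched_loci)
        div_frames = []
        for set_name, sub in locus_sets.items():
            summ = diversity_summary(sub)
            freqs = allele_frequencies(sub)
            for gname, pops in groups.items():
                g_conf = cfg.rarefaction_g.get(gname)
                g_obs = min(
                    freqs.n_genes(p, loc) for p in pops for loc in sub.locus_names
                )
                g = min(g_conf, g_obs) if g_conf else g_obs
                rar = rarefied_richness(freqs, g, populations=pops)
                rar_mean = rar.groupby("population")[["Ar", "Par"]].mean()
                block = summ.per_population.set_index("population").loc[pops]
                block = block.join(rar_mean)
                block["group"] = gname
                block["locus_set"] = set_name
                block["rarefaction_g"] = g
                div_frames.append(block.reset_index())
        diversity = pd.concat(div_frames, ignore_index=True)
        emit(diversity, "diversity.csv", index=False)
        log["stages"]["diversity"] = {
            "n_populations": len(ds.populations),
            "n_loci": len(ds.loci),
        }

        # time since colonisation and group comparisons
        if sites is not None:
            years = {s.site: s.arrival_year for s in sites}
            rows = []
            base = diversity[
                (diversity["locus_set"] == "all_loci")
            ].drop_duplicates("population")
            arr = [years.get(p) for p in base["population"]]
            if sum(a is not None for a in arr) >= 3:
                for index in ["Na", "Ar", "Par", "Ho", "UHe"]:
                    ok = [i for i, a in enumerate(arr) if a is not None]
                    r, dfree, p = time_correlation(
                        base[index].to_numpy()[ok],
                        [arr[i] for i in ok],
                        cfg.reference_year,
                    )
                    rows.append(dict(index=index, r=r, df=dfree, p=p))
                emit(pd.DataFrame(rows), "time_correlation.csv", index=False)
        if len(groups) == 2:
            (ga, pa), (gb, pb) = groups.items()
            base = diversity[diversity["locus_set"] == "all_loci"]
            rows = []
            for index in ["Na", "Ar", "Par", "Ho", "UHe", "Fis"]:
                va = base[base["group"] == ga][index].dropna()
                vb = base[base["group"] == gb][index].dropna()
                w, p = group_diversity_test(va, vb)
                rows.append(dict(index=index, group_a=ga, group_b=gb, W=w, p=p))
            emit(pd.DataFrame(rows), "group_comparison.csv", index=False)

        # ---- bottleneck -------------------------------------------------
        if cfg.run_bottleneck:
            current_stage = "bottleneck"
            tpm = TpmConfig(
                seed=stage_seed["bottleneck"],
                **{k: v for k, v in cfg.bottleneck.items() if k != "seed"},
            )
            rows = []
            for pop in ds.populations:
                res = bottleneck_test(ds, pop, tpm)
                per = res.per_locus.copy()
                per.insert(0, "population", pop)
                rows.append(per)
                log["stages"].setdefault("bottleneck", {})[pop] = {
                    "p_excess": res.p_excess,
                    "p_deficit": res.p_deficit,
                }
            emit(pd.concat(rows, ignore_index=True), "bottleneck.csv", index=False)

        # ---- differentiation --------------------------------------------
        current_stage = "differentiation"
        fst_interval = None
        mantel_rows = []
        for gname, pops in groups.items():
            theta = wc_theta(
                ds, pops, n_perm=cfg.n_perm, n_boot=cfg.n_boot, pairwise=True,
                pairwise_perm=cfg.n_perm, seed=stage_seed["theta"],
            )
            dest = jost_d(
                ds, pops, n_boot=cfg.n_boot, pairwise=True, seed=stage_seed["jost"],
            )
            rst_est = rst(ds, pops, pairwise=True, seed=stage_seed["rst"])
            n_pairs = len(pops) * (len(pops) - 1) // 2
            thr = bonferroni_threshold(cfg.alpha, n_pairs)
            _write_combined_matrix(
                theta.pairwise, dest.pairwise, out / f"fst_dest_{gname}.csv"
            )
            written.append(out / f"fst_dest_{gname}.csv")
            emit(rst_est.pairwise.to_dataframe(), f"rst_{gname}.csv")
            emit(theta.pairwise_p.to_dataframe(), f"fst_pvalues_{gname}.csv")
            log["stages"].setdefault("differentiation", {})[gname] = {
                "global_theta": theta.global_value,
                "theta_ci": theta.ci,
                "theta_p": theta.global_p,
                "global_dest": dest.global_value,
                "dest_ci": dest.ci,
                "global_rst": rst_est.global_value,
                "bonferroni_threshold": thr,
                "n_pairwise_tests": n_pairs,
            }
            if fst_interval is None and theta.ci is not None:
                fst_interval = theta.ci

            # ---- isolation by distance ---------------------------------
            if sites is not None:
                current_stage = "ibd"
                site_map = {s.site: s for s in sites}
                if all(p in site_map for p in pops):
                    geo = great_circle_matrix([site_map[p] for p in pops])
                    emit(geo.to_dataframe(), f"distances_km_{gname}.csv")
                    for stat_name, est in [
                        ("theta", theta), ("d_est", dest), ("r_st", rst_est)
                    ]:
                        mres = mantel(
                            est.pairwise, geo, n_perm=cfg.n_perm, transform_b="ln",
                            seed=stage_seed["mantel"],
                        )
                        mantel_rows.append(
                            dict(group=gname, a=stat_name, b="ln_km",
                                 r=mres.r, p=mres.p)
                        )
                    cross = mantel(
                        theta.pairwise, dest.pairwise, n_perm=cfg.n_perm,
                        seed=stage_seed["mantel"],
                    )
                    mantel_rows.append(
                        dict(group=gname, a="theta", b="d_est", r=cross.r, p=cross.p)
                    )
                current_stage = "differentiation"
        if mantel_rows:
            emit(pd.DataFrame(mantel_rows), "mantel.csv", index=False)

        # ---- phenotypes --------------------------------------------------
        if cfg.phenotypes:
            current_stage = "phenotypes"
            pheno = pd.read_csv(cfg.phenotypes)
            if cfg.spectra:
                spectra = pd.read_csv(cfg.spectra)
                processed = process_spectra(spectra)
                colors = color_table(processed)
                wide = colors.pivot(index="id", columns="patch")
                wide.columns = [f"{m}_{patch}" for m, patch in wide.columns]
                pheno = pheno.merge(
                    wide.reset_index().rename(columns={"id": "individual"}),
                    on="individual", how="left",
                )
            traits = cfg.traits or [
                c for c in pheno.columns
                if c not in ("individual", "site", "sex") and pheno[c].dtype.kind == "f"
            ]
            kept = []
            excluded_counts = {}
            for sex, sub in pheno.groupby("sex"):
                x = sub[traits].dropna()
                flags = outlier_filter(x.to_numpy(), quantile=cfg.outlier_quantile)
                excluded_counts[sex] = int(flags.sum())
                kept.append(sub.loc[x.index[~flags]])
            pheno_clean = pd.concat(kept, ignore_index=True)
            emit(pheno_clean, "phenotypes_clean.csv", index=False)
            log["stages"]["phenotypes"] = {
                "n_traits": len(traits),
                "excluded_outliers": excluded_counts,
            }
            man_rows = []
            for sex, sub in pheno_clean.groupby("sex"):
                res = manova_pillai(sub[traits].to_numpy(), sub["site"].to_numpy())
                man_rows.append(
                    dict(sex=sex, pillai=res.pillai, F=res.f_value,
                         df1=res.df1, df2=res.df2, p=res.p)
                )
            emit(pd.DataFrame(man_rows), "manova.csv", index=False)

            # ---- P_ST sensitivity ---------------------------------------
            current_stage = "pst"
            if fst_interval is None:
                raise ValueError(
                    "P_ST needs a bootstrap F_ST interval; set n_boot > 0"
                )
            summary_rows = []
            for sex, sub in pheno_clean.groupby("sex"):
                for trait in traits:
                    cov = cfg.covariate if trait != cfg.covariate else None
                    if cov is not None and cov not in pheno_clean.columns:
                        cov = None
                    curve = pst_sensitivity(
                        sub, trait, sex=None, fst_interval=fst_interval,
                        covariate=cov, n_boot=cfg.n_boot, seed=stage_seed["pst"],
                    )
                    emit(
                        curve.to_dataframe(), f"pst_{trait}_{sex}.csv", index=False
                    )
                    summary_rows.append(
                        dict(trait=trait, sex=sex,
                             sigma2_b=curve.components.sigma2_b,
                             sigma2_w=curve.components.sigma2_w,
                             pst_at_1=curve.pst[curve.ratios == 1.0][0],
                             critical_ratio=curve.critical_ratio,
                             fst_low=fst_interval[0], fst_high=fst_interval[1])
                    )
            emit(pd.DataFrame(summary_rows), "pst_summary.csv", index=False)

        current_stage = "runlog"
        log_path = out / "run_log.json"
        log_path.write_text(json.dumps(log, indent=2, default=str))
        written.append(log_path)
        return log
    except Exception as exc:
        for path in written:
            path.unlink(missing_ok=True)
        raise StageError(current_stage, exc) from exc
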