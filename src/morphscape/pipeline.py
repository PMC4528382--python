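"""End-to-end orchestration: morph statistics -> genetic structure ->
distance construction -> matrix-regression model selection -> per-morph
environmental regressions, with seeding, provenance and a JSON report.

A single master seed is fanned out deterministically to per-stage child
seeds (SeedSequence on (seed, stage index)), so any stage can be re-run in
isolation and the full report is byte-identical under a fixed config.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from ._version import __version__
from .distances import (
    covariate_distance_matrix,
    fst_distance_matrix,
    geographic_distance_matrix,
    morph_distance_matrix,
)
from .envreg import collinearity_screen, fit_morph_regressions, regressions_frame
from .io import (
    MORPH_ORDER,
    GenotypePanel,
    LikelihoodSeries,
    MorphCountTable,
    SiteTable,
    read_genepop,
    read_likelihoods,
    read_morph_counts,
    read_sites,
    write_genepop,
    write_likelihoods,
    write_morph_counts,
    write_sites,
)
from .mmrr import mantel_test, model_selection
from .morphstats import frequencies, grubbs_test, heterogeneity_test, posthoc_pairwise
from .popgen import evanno_delta_k, locus_summaries, pairwise_fst
from .simulate import (
    SimulationConfig,
    ground_truth_to_json,
    simulate_dataset,
    simulate_likelihood_series,
)


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass(frozen=True)
class PipelineConfig:
    counts: str
    genepop: str
    sites: str
    likelihoods: str | None = None
    n_permutations: int = 10_000
    n_hwe_shuffles: int = 10_000
    delta_window: float = 5.0
    exclusion_pairs: tuple[tuple[str, str], ...] | None = None  # None = auto screen
    collinearity_threshold: float = 0.6
    env_predictors: tuple[str, ...] = ("aridity", "vegetation")
    predictor_pool: tuple[str, ...] = (
        "fst",
        "distance",
        "aridity",
        "topography",
        "vegetation",
        "rock",
    )
    geographic_method: str = "greatcircle"
    exclude_population: str | None = None
    seed: int = 0
    out_dir: str | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if not isinstance(raw, dict):
            raise ValueError(f"{path}: config must be a mapping")
        if "exclusion_pairs" in raw and raw["exclusion_pairs"] is not None:
            raw["exclusion_pairs"] = tuple(tuple(p) for p in raw["exclusion_pairs"])
        for key in ("env_predictors", "predictor_pool"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def validate_paths(self) -> None:
        for name in ("counts", "genepop", "sites"):
            p = getattr(self, name)
            if not Path(p).exists():
                raise FileNotFoundError(f"config: {name} file not found: {p}")
        if self.likelihoods is not None and not Path(self.likelihoods).exists():
            raise FileNotFoundError(f"config: likelihoods file not found: {self.likelihoods}")


def _stage_seed(master: int, stage: int) -> int:
    return int(np.random.SeedSequence([master, stage]).generate_state(1)[0] % (2**31))


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return None if not np.isfinite(v) else v
    if isinstance(obj, (np.integer, int)):
        return int(obj)
    if isinstance(obj, np.ndarray):
        return _jsonable(obj.tolist())
    if isinstance(obj, pd.Series):
        return _jsonable(obj.to_dict())
    if isinstance(obj, pd.DataFrame):
        return _jsonable(obj.to_dict(orient="records"))
    return obj


def run_analysis(
    counts: MorphCountTable,
    panel: GenotypePanel,
    sites: SiteTable,
    likelihoods: LikelihoodSeries | None = None,
    config: PipelineConfig | None = None,
) -> dict:
    """Run the full inference chain on in-memory inputs; returns the report."""
    cfg = config or PipelineConfig(counts="-", genepop="-", sites="-")
    seed = cfg.seed
    report: dict = {
        "provenance": {
            "package": "morphscape",
            "version": __version__,
            "seed": seed,
            "n_permutations": cfg.n_permutations,
            "delta_window": cfg.delta_window,
        }
    }

    # --- stage 1: morph-frequency statistics -------------------------------
    try:
        freqs = frequencies(counts)
        het = heterogeneity_test(counts)
        post = posthoc_pairwise(counts)
        grubbs = {}
        for m in MORPH_ORDER:
            try:
                g = grubbs_test(freqs.proportions()[m].to_numpy(), alternative="one-sided")
                pops = freqs.populations
                grubbs[m] = {
                    "G": g.statistic,
                    "p_value": g.p_value,
                    "population": pops[g.index],
                }
            except ValueError:
                grubbs[m] = None
        report["morph_stats"] = {
            "frequencies": freqs.data.reset_index(names="population"),
            "heterogeneity": {
                "statistic": het.statistic,
                "df": het.df,
                "p_value": het.p_value,
                "low_expected_warning": het.low_expected_warning,
            },
            "posthoc_pairwise": post,
            "grubbs": grubbs,
        }
    except Exception as e:  # noqa: BLE001
        raise PipelineError("morph_stats", str(e)) from e

    # --- stage 2: genetic structure ----------------------------------------
    try:
        summaries = locus_summaries(panel, n_shuffles=cfg.n_hwe_shuffles, seed=_stage_seed(seed, 2))
        fst = pairwise_fst(panel, n_permutations=cfg.n_permutations, seed=_stage_seed(seed, 3))
        report["popgen"] = {
            "locus_summaries": [
                {
                    "locus": s.locus,
                    "population": s.population,
                    "h_obs": s.h_obs,
                    "h_exp": s.h_exp,
                    "hwe_p": s.hwe_p,
                    "n": s.n_genotyped,
                    "monomorphic": s.monomorphic,
                }
                for s in summaries
            ],
            "pairwise_fst": [
                {
                    "pop_a": r.pop_a,
                    "pop_b": r.pop_b,
                    "theta": r.theta,
                    "p_value": r.p_value,
                    "significant_bonferroni": r.significant_bonferroni,
                }
                for r in fst
            ],
        }
        if likelihoods is not None:
            dk = evanno_delta_k(likelihoods)
            report["popgen"]["delta_k"] = {"table": dk.table, "best_k": dk.best_k}
    except Exception as e:  # noqa: BLE001
        raise PipelineError("popgen", str(e)) from e

    # --- stage 3: distance matrices and inference --------------------------
    try:
        order = freqs.populations
        sites_ordered = SiteTable(
            sites.data.set_index("site").loc[order].reset_index()
        )
        morph_d = morph_distance_matrix(freqs)
        geo_d = geographic_distance_matrix(sites_ordered, method=cfg.geographic_method)
        fst_d = fst_distance_matrix(fst, labels=order)
        pool = {}
        for name in cfg.predictor_pool:
            if name == "fst":
                pool[name] = fst_d
            elif name == "distance":
                pool[name] = geo_d
            else:
                pool[name] = covariate_distance_matrix(sites_ordered, name)
        ibd = mantel_test(
            fst_d, geo_d, n_permutations=cfg.n_permutations, seed=_stage_seed(seed, 4)
        )
        if cfg.exclusion_pairs is None:
            screen_pool = {k: v for k, v in pool.items() if k != "fst"}
            flagged, corr = collinearity_screen(screen_pool, cfg.collinearity_threshold)
        else:
            flagged = [tuple(p) for p in cfg.exclusion_pairs]
            corr = None
        selection = model_selection(
            morph_d,
            pool,
            exclusion_pairs=flagged,
            delta_window=cfg.delta_window,
            n_permutations=cfg.n_permutations,
            seed=_stage_seed(seed, 5),
        )
        best = selection.best_fit
        report["inference"] = {
            "isolation_by_distance": {
                "r": ibd.r,
                "p_value": ibd.p_value,
                "n_permutations": ibd.n_permutations,
            },
            "exclusion_pairs": [list(p) for p in flagged],
            "collinearity": corr.reset_index(names="variable") if corr is not None else None,
            "model_selection": selection.table.assign(
                predictors=selection.table["predictors"].map(lambda t: "+".join(t))
            ),
            "riv": selection.riv,
            "best_model": {
                "predictors": list(selection.best),
                "r_squared": best.rsquared,
                "std_slopes": best.params,
                "r_partial": best.r_partial,
                "p_values": best.pvalues,
            },
        }
    except PipelineError:
        raise
    except Exception as e:  # noqa: BLE001
        raise PipelineError("distance_inference", str(e)) from e

    # --- stage 4: per-morph environmental regressions ----------------------
    try:
        reg = fit_morph_regressions(
            freqs, sites_ordered, predictors=cfg.env_predictors
        )
        report["env_regression"] = {"fits": regressions_frame(reg)}
        if cfg.exclude_population is not None:
            reg_x = fit_morph_regressions(
                freqs,
                sites_ordered,
                predictors=cfg.env_predictors,
                exclude_population=cfg.exclude_population,
            )
            report["env_regression"]["outlier_excluded"] = regressions_frame(reg_x)
    except Exception as e:  # noqa: BLE001
        raise PipelineError("env_regression", str(e)) from e

    report = _jsonable(report)
    digest = hashlib.sha256(
        json.dumps(report, sort_keys=True).encode()
    ).hexdigest()[:16]
    report["provenance"]["report_digest"] = digest
    return report


def run_pipeline(config: PipelineConfig) -> dict:
    """Read the configured inputs, run the analysis and write the report."""
    config.validate_paths()
    counts = read_morph_counts(config.counts)
    panel = read_genepop(config.genepop)
    sites = read_sites(config.sites)
    lks = read_likelihoods(config.likelihoods) if config.likelihoods else None
    report = run_analysis(counts, panel, sites, lks, config)
    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
        pd.DataFrame(report["inference"]["model_selection"]).to_csv(
            out / "model_selection.csv", index=False
        )
        pd.DataFrame(report["popgen"]["pairwise_fst"]).to_csv(
            out / "pairwise_fst.csv", index=False
        )
    return report


def make_demo(seed: int = 7, out_dir: str | Path = "demo") -> Path:
    """Write a full synthetic dataset emulating the study's shape.

    Produces sites.csv, counts.csv, panel.gen, likelihoods.csv,
    truth.json and a ready-to-run config.yaml in ``out_dir``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config = SimulationConfig(seed=seed)
    sites, counts, panel, truth = simulate_dataset(config)
    write_sites(sites, out / "sites.csv")
    write_morph_counts(counts, out / "counts.csv")
    write_genepop(panel, out / "panel.gen")
    write_likelihoods(
        simulate_likelihood_series(true_k=2, seed=seed), out / "likelihoods.csv"
    )
    ground_truth_to_json(truth, out / "truth.json")
    cfg = {
        "counts": str(out / "counts.csv"),
        "genepop": str(out / "panel.gen"),
        "sites": str(out / "sites.csv"),
        "likelihoods": str(out / "likelihoods.csv"),
        "n_permutations": 999,
        "n_hwe_shuffles": 999,
        "seed": seed,
        "out_dir": str(out / "results"),
    }
    (out / "config.yaml").write_text(yaml.safe_dump(cfg))
    return out
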