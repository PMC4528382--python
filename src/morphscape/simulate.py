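"""Synthetic populations with known ground truth.

Emulates the study design the package analyses: a handful of rocky-range
sites with environmental covariates, four male throat-colour morphs whose
per-population frequencies respond to two covariates through a
multinomial-logit link, and neutral multi-locus microsatellite genotypes
with a controllable level of differentiation (Balding-Nichols model, so
target F_ST maps directly onto the Dirichlet concentration).

The defaults reproduce the study's shape: 8 populations, 30 genotyped
individuals each, phenotyped-male sample sizes 22/48/29/22/26/20/21/20,
8 loci, F_ST around 0.04 (the observed range being roughly 0.01-0.07),
aridity correlated with a geographic axis at about 0.64, and logit-scale
noise that leaves the environment-frequency relationship with an R-squared
in the 0.45-0.85 band typical of the field regressions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import (
    MISSING,
    MORPH_ORDER,
    GenotypePanel,
    LikelihoodSeries,
    MorphCountTable,
    SiteTable,
)

#: Phenotyped adult males per site in the emulated design.
DEFAULT_PHENOTYPED = (22, 48, 29, 22, 26, 20, 21, 20)

# Flinders/Olary ranges footprint used for demo coordinates (deg)
_LAT_RANGE = (-33.1, -31.2)
_LON_RANGE = (137.9, 140.3)

_DEFAULT_INTERCEPTS = (0.02, 0.14, 0.20, -0.36)
# rows: morphs (canonical order); cols: (aridity index, vegetation cover).
# A negative aridity-index slope means "more of this morph where drier".
_DEFAULT_ENV_EFFECTS = ((-0.89, 0.0), (0.0, 0.83), (0.86, 0.0), (0.0, -0.74))


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic study; defaults emulate the field design."""

    n_populations: int = 8
    n_individuals_per_pop: int = 30
    n_males_phenotyped_per_pop: tuple[int, ...] | int | None = None
    n_loci: int = 8
    target_fst: float = 0.04
    morph_intercepts: tuple[float, ...] = _DEFAULT_INTERCEPTS
    env_effects: tuple[tuple[float, float], ...] = _DEFAULT_ENV_EFFECTS
    env_spatial_correlation: float = 0.64
    noise_sd: float = 0.25
    missing_rate: float = 0.0
    alleles_min: int = 4
    alleles_max: int = 12
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_populations <= 0:
            raise ValueError("n_populations must be positive")
        if self.n_individuals_per_pop <= 0 or self.n_loci <= 0:
            raise ValueError("counts must be positive")
        if not 0 <= self.target_fst < 1:
            raise ValueError("target_fst must lie in [0, 1)")
        if len(self.morph_intercepts) != 4:
            raise ValueError("exactly four morph intercepts required")
        if len(self.env_effects) != 4 or any(len(r) != 2 for r in self.env_effects):
            raise ValueError("env_effects must be a 4x2 matrix")
        if not -1 <= self.env_spatial_correlation <= 1:
            raise ValueError("env_spatial_correlation must lie in [-1, 1]")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must lie in [0, 1)")

    def phenotyped(self) -> np.ndarray:
        v = self.n_males_phenotyped_per_pop
        if v is None:
            if self.n_populations == len(DEFAULT_PHENOTYPED):
                return np.array(DEFAULT_PHENOTYPED)
            return np.full(self.n_populations, 30)
        if np.isscalar(v):
            return np.full(self.n_populations, int(v))
        arr = np.asarray(v, dtype=int)
        if arr.size != self.n_populations:
            raise ValueError("phenotyped sample sizes do not match n_populations")
        if (arr <= 0).any():
            raise ValueError("phenotyped sample sizes must be positive")
        return arr

    def _rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence([self.seed, stream]))


@dataclass
class GroundTruth:
    """True parameters realized by a simulation run."""

    morph_probs: pd.DataFrame | None = None  # populations x morphs
    env_effects: np.ndarray | None = None
    ancestral_freqs: list[np.ndarray] = field(default_factory=list)
    pop_freqs: list[np.ndarray] = field(default_factory=list)  # per locus: pops x alleles
    allele_codes: list[np.ndarray] = field(default_factory=list)

    def validate(self) -> None:
        if self.morph_probs is not None:
            s = self.morph_probs.sum(axis=1).to_numpy()
            assert np.allclose(s, 1.0, atol=1e-12)
        for f in self.ancestral_freqs:
            assert abs(f.sum() - 1.0) < 1e-9
        for pf in self.pop_freqs:
            assert np.allclose(pf.sum(axis=1), 1.0, atol=1e-9)


def _site_labels(n: int) -> list[str]:
    return [f"site{i + 1:02d}" for i in range(n)]


def simulate_sites(config: SimulationConfig) -> SiteTable:
    """Sites with coordinates and environmental covariates.

    The aridity index (precipitation over potential evaporation; lower =
    drier) is constructed to correlate with longitude at approximately
    ``env_spatial_correlation``; vegetation and rock cover are independent
    proportions, topographic relief an independent positive covariate.
    """
    rng = config._rng(1)
    n = config.n_populations
    lat = rng.uniform(*_LAT_RANGE, size=n)
    lon = rng.uniform(*_LON_RANGE, size=n)
    z_lon = (lon - lon.mean()) / lon.std() if n > 1 else np.zeros(n)
    rho = config.env_spatial_correlation
    eps = rng.standard_normal(n)
    z_arid = rho * z_lon + np.sqrt(max(0.0, 1 - rho**2)) * eps
    aridity = np.maximum(0.02, 0.20 + 0.05 * z_arid)
    vegetation = 1.0 / (1.0 + np.exp(-rng.normal(-0.8, 0.5, size=n)))
    rock = 1.0 / (1.0 + np.exp(-rng.normal(-1.0, 0.5, size=n)))
    topography = np.exp(rng.normal(np.log(60.0), 0.4, size=n))
    return SiteTable(
        pd.DataFrame(
            {
                "site": _site_labels(n),
                "lat": lat,
                "lon": lon,
                "aridity": aridity,
                "topography": topography,
                "vegetation": vegetation,
                "rock": rock,
            }
        )
    )


def simulate_morph_counts(
    config: SimulationConfig, sites: SiteTable
) -> tuple[MorphCountTable, GroundTruth]:
    """Multinomial morph counts with a logit-linear environmental response.

    Per population, eta = intercepts + env_effects @ z-scored (aridity,
    vegetation) + Normal(0, noise_sd) and p = softmax(eta); counts are
    multinomial over the phenotyped males. All four morphs always have
    nonzero probability.
    """
    if len(sites.sites) != config.n_populations:
        raise ValueError("site table does not match n_populations")
    rng = config._rng(2)
    z = np.column_stack(
        [
            _zscore(sites.values("aridity").to_numpy()),
            _zscore(sites.values("vegetation").to_numpy()),
        ]
    )
    b = np.asarray(config.env_effects, dtype=float)  # 4 x 2
    eta = (
        np.asarray(config.morph_intercepts)[None, :]
        + z @ b.T
        + rng.normal(0.0, config.noise_sd, size=(config.n_populations, 4))
    )
    p = np.exp(eta - eta.max(axis=1, keepdims=True))
    p /= p.sum(axis=1, keepdims=True)
    sizes = config.phenotyped()
    counts = np.vstack([rng.multinomial(sizes[i], p[i]) for i in range(len(sizes))])
    table = MorphCountTable(
        pd.DataFrame(counts, columns=list(MORPH_ORDER)).assign(population=sites.sites)[
            ["population", *MORPH_ORDER]
        ]
    )
    truth = GroundTruth(
        morph_probs=pd.DataFrame(p, index=sites.sites, columns=list(MORPH_ORDER)),
        env_effects=b,
    )
    truth.validate()
    return table, truth


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    return (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)


def simulate_genotypes(
    config: SimulationConfig, sites: SiteTable | None = None
) -> tuple[GenotypePanel, GroundTruth]:
    """Neutral microsatellite genotypes under the Balding-Nichols model.

    Per locus, ancestral allele frequencies are Dirichlet over 4-12
    alleles; population frequencies are Dirichlet with concentration
    p * (1 - F)/F so that the expected Weir-Cockerham F_ST equals the
    target (the F -> 0 limit copies the ancestral frequencies exactly).
    Genotypes are drawn in Hardy-Weinberg proportions within populations.
    """
    rng = config._rng(3)
    n_pops = config.n_populations
    labels = sites.sites if sites is not None else _site_labels(n_pops)
    if len(labels) != n_pops:
        raise ValueError("site table does not match n_populations")
    f = config.target_fst
    n_ind = config.n_individuals_per_pop
    truth = GroundTruth()
    loci = [f"loc{j + 1:02d}" for j in range(config.n_loci)]
    genos = np.zeros((n_pops * n_ind, config.n_loci, 2), dtype=np.int64)
    for j in range(config.n_loci):
        k = int(rng.integers(config.alleles_min, config.alleles_max + 1))
        ancestral = rng.dirichlet(np.ones(k))
        codes = 100 + 2 * np.arange(k)  # microsat-like 3-digit fragment sizes
        if f == 0:
            pop_freqs = np.tile(ancestral, (n_pops, 1))
        else:
            conc = ancestral * (1 - f) / f
            pop_freqs = rng.dirichlet(conc, size=n_pops)
        truth.ancestral_freqs.append(ancestral)
        truth.pop_freqs.append(pop_freqs)
        truth.allele_codes.append(codes)
        for i in range(n_pops):
            draws = rng.choice(codes, size=(n_ind, 2), p=pop_freqs[i])
            genos[i * n_ind : (i + 1) * n_ind, j, :] = draws
    if config.missing_rate > 0:
        drop = rng.random((n_pops * n_ind, config.n_loci)) < config.missing_rate
        genos[drop] = MISSING
    ids = tuple(
        f"{labels[i]}_{k + 1:03d}" for i in range(n_pops) for k in range(n_ind)
    )
    pops = tuple(labels[i] for i in range(n_pops) for _ in range(n_ind))
    panel = GenotypePanel(ids, pops, tuple(loci), genos)
    truth.validate()
    return panel, truth


def simulate_likelihood_series(
    true_k: int = 2,
    k_max: int = 10,
    n_replicates: int = 20,
    replicate_sd: float = 15.0,
    seed: int = 0,
) -> LikelihoodSeries:
    """Synthetic clustering log-likelihood summaries for delta-K exercises.

    A stand-in for the per-K replicate log-likelihoods an external
    admixture-clustering run would produce: mean ln P(X|K) rises steeply
    up to the true K, then plateaus with mild overfitting decline, with
    Gaussian replicate scatter. Purely synthetic - it emulates the shape,
    not the MCMC.
    """
    rng = np.random.default_rng(seed)
    base = -10_000.0
    means = {}
    for k in range(1, k_max + 1):
        gain = 400.0 * min(k, true_k) - 5.0 * max(0, k - true_k) ** 1.5
        means[k] = base + gain
    reps = {
        k: means[k] + rng.normal(0.0, replicate_sd, size=n_replicates)
        for k in range(1, k_max + 1)
    }
    return LikelihoodSeries(reps)


def simulate_dataset(
    config: SimulationConfig,
) -> tuple[SiteTable, MorphCountTable, GenotypePanel, GroundTruth]:
    """Sites, morph counts and genotypes from one config (shared ground truth)."""
    sites = simulate_sites(config)
    counts, truth_m = simulate_morph_counts(config, sites)
    panel, truth_g = simulate_genotypes(config, sites)
    truth = GroundTruth(
        morph_probs=truth_m.morph_probs,
        env_effects=truth_m.env_effects,
        ancestral_freqs=truth_g.ancestral_freqs,
        pop_freqs=truth_g.pop_freqs,
        allele_codes=truth_g.allele_codes,
    )
    return sites, counts, panel, truth


def ground_truth_to_json(truth: GroundTruth, path: str | Path) -> None:
    payload = {
        "morph_probs": (
            truth.morph_probs.to_dict(orient="index") if truth.morph_probs is not None else None
        ),
        "env_effects": truth.env_effects.tolist() if truth.env_effects is not None else None,
        "ancestral_freqs": [f.tolist() for f in truth.ancestral_freqs],
        "pop_freqs": [f.tolist() for f in truth.pop_freqs],
        "allele_codes": [c.tolist() for c in truth.allele_codes],
    }
    Path(path).write_text(json.dumps(payload, indent=2))
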