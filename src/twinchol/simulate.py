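"""Synthetic twin cohorts with the covariance structure the model assumes.

The generator is the generative mirror of the Cholesky model: each pair draws
unit-variance latent factors A (additive genetic, shared fully by MZ twins
and correlated 0.5 in DZ twins via A_twin = sqrt(0.5)·A_pair +
sqrt(0.5)·A_individual), C (shared within pair) and E (independent per twin),
one per visit-factor, and phenotypes are the path-weighted sums plus a
per-visit mean (plus an optional mean-arterial-pressure covariate effect).
Phenotypes are generated on the log scale and exponentiated for the canonical
wide CSV, so a pipeline run exercises the log-transform step end to end.

``published_fit_config`` packages the published two-visit, bi-ethnic pulse wave
velocity cohort: the best-fitting AE model (visit-1 heritability 0.62,
visit-2 heritability 0.35 of which 0.19 is visit-2-specific, no
environmental tracking), the published MZ/DZ pair and singleton counts for
European-American and African-American twins with their female fractions, and
log-scale means matched to the published raw-scale group means.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import yaml

from .data import TwinDataset, TwinPair
from .model import CholeskyParams, GENETIC_SHARING, expected_pair_covariance

__all__ = [
    "GroupCounts",
    "MapModel",
    "GeneratorConfig",
    "published_fit_config",
    "simulate_cohort",
    "simple_cohort_config",
]


@dataclass(frozen=True)
class GroupCounts:
    """Pair and singleton counts for one ethnicity × sex cell."""

    n_mz: int = 0
    n_dz: int = 0
    n_singletons: int = 0

    def __post_init__(self) -> None:
        if min(self.n_mz, self.n_dz, self.n_singletons) < 0:
            raise ValueError("counts must be non-negative")


@dataclass(frozen=True)
class MapModel:
    """Gaussian mean-arterial-pressure covariate, optional effect on phenotype.

    ``beta`` is the per-visit effect of MAP (mmHg) on the log phenotype;
    the packaged published-fit config sets it to zero because adjustment left the
    published results unchanged.
    """

    mean: tuple[float, float] = (77.0, 79.0)
    sd: tuple[float, float] = (8.0, 8.0)
    beta: tuple[float, float] = (0.0, 0.0)


@dataclass(frozen=True)
class GeneratorConfig:
    """Full description of a synthetic cohort.

    ``groups`` maps (ethnicity, sex) -> GroupCounts; ``params`` is the
    generating truth (shared across groups unless ``group_params`` overrides
    a cell); ``log_means`` maps (ethnicity, sex) -> per-visit means on the
    log scale; ``missingness`` is a per-visit MCAR probability applied
    independently to every phenotype entry.
    """

    groups: Mapping[tuple[str, str], GroupCounts]
    params: CholeskyParams
    log_means: Mapping[tuple[str, str], tuple[float, float]]
    group_params: Mapping[tuple[str, str], CholeskyParams] = field(default_factory=dict)
    map_model: MapModel = MapModel()
    missingness: tuple[float, float] = (0.0, 0.0)
    mean_age: tuple[float, float] = (17.3, 20.9)
    sd_age: tuple[float, float] = (3.4, 4.2)
    seed: int | None = None

    def __post_init__(self) -> None:
        for m in self.missingness:
            if not 0.0 <= m < 1.0:
                raise ValueError("missingness probabilities must be in [0, 1)")
        for key, params in {**{k: self.params for k in self.groups},
                            **dict(self.group_params)}.items():
            sigma = expected_pair_covariance(params, "MZ")
            if np.linalg.eigvalsh(sigma)[0] <= 0:
                raise ValueError(f"generating params for {key} not positive definite")

    def params_for(self, key: tuple[str, str]) -> CholeskyParams:
        return self.group_params.get(key, self.params)

    def to_dict(self) -> dict:
        return {
            "groups": {
                f"{e}_{s}": [c.n_mz, c.n_dz, c.n_singletons]
                for (e, s), c in sorted(self.groups.items())
            },
            "params": self.params.as_dict(),
            "log_means": {
                f"{e}_{s}": list(m) for (e, s), m in sorted(self.log_means.items())
            },
            "map_model": {
                "mean": list(self.map_model.mean),
                "sd": list(self.map_model.sd),
                "beta": list(self.map_model.beta),
            },
            "missingness": list(self.missingness),
            "mean_age": list(self.mean_age),
            "sd_age": list(self.sd_age),
            "seed": self.seed,
        }

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=True)

    @staticmethod
    def from_dict(d: Mapping) -> "GeneratorConfig":
        def key(s: str) -> tuple[str, str]:
            eth, sex = s.rsplit("_", 1)
            return eth, sex

        mm = d.get("map_model", {})
        return GeneratorConfig(
            groups={key(k): GroupCounts(*v) for k, v in d["groups"].items()},
            params=CholeskyParams(**d["params"]),
            log_means={key(k): tuple(v) for k, v in d["log_means"].items()},
            map_model=MapModel(
                mean=tuple(mm.get("mean", (77.0, 79.0))),
                sd=tuple(mm.get("sd", (8.0, 8.0))),
                beta=tuple(mm.get("beta", (0.0, 0.0))),
            ),
            missingness=tuple(d.get("missingness", (0.0, 0.0))),
            mean_age=tuple(d.get("mean_age", (17.3, 20.9))),
            sd_age=tuple(d.get("sd_age", (3.4, 4.2))),
            seed=d.get("seed"),
        )

    @staticmethod
    def from_yaml(text: str) -> "GeneratorConfig":
        return GeneratorConfig.from_dict(yaml.safe_load(text))


#: published raw-scale phenotype means (m/s) per (ethnicity, sex), visits 1, 2
_RAW_MEANS = {
    ("EA", "M"): (7.08, 7.60),
    ("EA", "F"): (6.99, 7.24),
    ("AA", "M"): (6.98, 7.73),
    ("AA", "F"): (7.21, 7.82),
}


def published_fit_config() -> GeneratorConfig:
    """The packaged cohort emulating the published study conditions.

    Unit phenotypic variance on the log scale at both visits with the
    best-fitting AE structure: a11² = 0.62, a21² = 0.16, a22² = 0.19,
    e11² = 0.38, e21 = 0, e22² = 0.65, no shared environment. Group sizes
    are the published MZ/DZ/singleton counts split by the published female
    fractions so the per-cell individual counts match the published table
    (EA 138 M / 151 F, AA 86 M / 122 F). Log-scale means are set so the
    back-transformed (log-normal) means equal the published raw-scale group
    means: μ = ln(m) − σ²/2 with σ² = 1.
    """
    params = CholeskyParams.from_standardized(
        h2_v1=0.62, h2_v2=0.35, specific_h2=0.19, e21=0.0
    )
    groups = {
        ("EA", "M"): GroupCounts(22, 36, 22),
        ("EA", "F"): GroupCounts(24, 39, 25),
        ("AA", "M"): GroupCounts(10, 24, 18),
        ("AA", "F"): GroupCounts(15, 35, 22),
    }
    log_means = {
        key: (math.log(m1) - 0.5, math.log(m2) - 0.5)
        for key, (m1, m2) in _RAW_MEANS.items()
    }
    return GeneratorConfig(
        groups=groups,
        params=params,
        log_means=log_means,
        map_model=MapModel(beta=(0.0, 0.0)),
        missingness=(0.0, 0.0),
    )


def simple_cohort_config(
    n_mz: int,
    n_dz: int,
    params: CholeskyParams,
    n_singletons: int = 0,
    log_means: tuple[float, float] = (0.0, 0.0),
    missingness: tuple[float, float] = (0.0, 0.0),
) -> GeneratorConfig:
    """One-group cohort (EA females by convention) for simulations."""
    return GeneratorConfig(
        groups={("EA", "F"): GroupCounts(n_mz, n_dz, n_singletons)},
        params=params,
        log_means={("EA", "F"): log_means},
        missingness=missingness,
    )


def _simulate_block(
    rng: np.random.Generator,
    n: int,
    params: CholeskyParams,
    zygosity: str,
) -> np.ndarray:
    """(n, 2 twins, 2 visits) centered log phenotypes for one zygosity."""
    if n == 0:
        return np.zeros((0, 2, 2))
    k = GENETIC_SHARING[zygosity]
    # latent factor draws: shape (n, 2 factors); A split into pair/individual
    a_pair = rng.standard_normal((n, 2))
    a_ind = rng.standard_normal((n, 2, 2))
    c_pair = rng.standard_normal((n, 2))
    e_ind = rng.standard_normal((n, 2, 2))
    # per-twin A with cross-twin correlation k
    A = math.sqrt(k) * a_pair[:, None, :] + math.sqrt(1.0 - k) * a_ind
    C = np.broadcast_to(c_pair[:, None, :], (n, 2, 2))
    E = e_ind
    out = np.zeros((n, 2, 2))
    for comp, latent in (("A", A), ("C", C), ("E", E)):
        L = params.factor(comp)  # visits x factors, lower triangular
        out += np.einsum("vf,ntf->ntv", L, latent)
    return out


def simulate_cohort(config: GeneratorConfig, seed: int | None = None) -> TwinDataset:
    """Draw one cohort; identical (config, seed) gives an identical dataset.

    Phenotypes are exponentiated to the raw scale. Singletons are generated
    as pairs with the co-twin removed and are labelled DZ (the label never
    enters a marginal likelihood). Missingness is MCAR, independent per
    phenotype entry with the configured per-visit probability.
    """
    if seed is None:
        seed = config.seed
    if seed is None:
        raise ValueError("a seed is required (argument or config.seed)")
    master = np.random.SeedSequence(seed)
    pairs: list[TwinPair] = []
    counter = 0
    group_keys = sorted(config.groups)
    streams = master.spawn(len(group_keys))
    for (key, stream) in zip(group_keys, streams):
        eth, sex = key
        counts = config.groups[key]
        rng = np.random.default_rng(stream)
        params = config.params_for(key)
        mu = np.array(config.log_means[key])
        for zyg, n_pairs, as_singleton in (
            ("MZ", counts.n_mz, False),
            ("DZ", counts.n_dz, False),
            ("DZ", counts.n_singletons, True),
        ):
            centered = _simulate_block(rng, n_pairs, params, zyg)
            map_vals = config.map_model.mean + rng.standard_normal(
                (n_pairs, 2, 2)
            ) * config.map_model.sd
            ages = config.mean_age + rng.standard_normal(
                (n_pairs, 2, 2)
            ) * config.sd_age
            ages.sort(axis=2)  # visit 2 after visit 1 within person
            beta = np.array(config.map_model.beta)
            log_pheno = centered + mu + beta * map_vals
            miss = rng.random((n_pairs, 2, 2)) < np.array(config.missingness)
            log_pheno = np.where(miss, np.nan, log_pheno)
            for i in range(n_pairs):
                counter += 1
                pheno = np.exp(log_pheno[i])
                mapbp = map_vals[i].copy()
                age = ages[i].copy()
                singleton = as_singleton
                if singleton:
                    pheno[1] = np.nan
                    mapbp[1] = np.nan
                    age[1] = np.nan
                if np.isnan(pheno).all():
                    continue  # MCAR wiped the whole pair; drop it
                pairs.append(
                    TwinPair(
                        family_id=f"{eth}{sex}{counter:05d}",
                        zygosity=zyg,
                        ethnicity=eth,
                        sex1=sex,
                        sex2=None if singleton else sex,
                        phenotype=pheno,
                        map_bp=mapbp,
                        age=age,
                        singleton=singleton,
                    )
                )
    return TwinDataset(
        pairs,
        phenotype_name="pwv",
        transform="none",
        provenance=f"simulated (seed={seed})",
    )
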