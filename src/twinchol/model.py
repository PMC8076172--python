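"""Bivariate Cholesky variance-component model and its FIML likelihood.

The phenotype at two visits is decomposed into additive-genetic (A),
shared-environment (C) and unique-environment (E) latent factors, each loaded
through a lower-triangular 2×2 path factor::

    L_X = [[x11, 0],
           [x21, x22]]          X in {A, C, E}

so each component's covariance across visits is L_X L_Xᵀ, positive
semidefinite by construction. Twin resemblance comes from cross-twin sharing
of the latent factors: MZ twins share A fully (coefficient 1), DZ twins share
half (0.5); C is shared fully in both; E is never shared.

The likelihood is full-information maximum likelihood (FIML): each pair
contributes the multivariate-normal log density of whatever subset of its
four phenotype slots (twin1·v1, twin1·v2, twin2·v1, twin2·v2) is observed,
so incomplete pairs and singletons are handled without imputation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.linalg import cho_factor, solve_triangular

from .data import SLOT_ORDER, SLOT_TWIN, SLOT_VISIT, TwinDataset, TwinPair

__all__ = [
    "CholeskyParams",
    "MeansModel",
    "ModelSpec",
    "PATH_NAMES",
    "GENETIC_SHARING",
    "component_covariance",
    "expected_pair_covariance",
    "pair_loglik",
    "dataset_m2ll",
    "PackedData",
]

LOG2PI = math.log(2.0 * math.pi)

PATH_NAMES = ("a11", "a21", "a22", "c11", "c21", "c22", "e11", "e21", "e22")

#: cross-twin sharing coefficient of the additive-genetic factors
GENETIC_SHARING = {"MZ": 1.0, "DZ": 0.5}
#: shared environment is, by definition, fully shared within a pair
COMMON_ENV_SHARING = 1.0

#: deviance returned for parameter points outside the feasible region
PENALTY_DEVIANCE = 1.0e10
#: smallest admissible eigenvalue of an expected pair covariance
MIN_EIGENVALUE = 1.0e-10


@dataclass(frozen=True)
class CholeskyParams:
    """The nine path coefficients of the bivariate ACE Cholesky model."""

    a11: float = 0.0
    a21: float = 0.0
    a22: float = 0.0
    c11: float = 0.0
    c21: float = 0.0
    c22: float = 0.0
    e11: float = 1.0
    e21: float = 0.0
    e22: float = 1.0

    def factor(self, component: str) -> np.ndarray:
        """Lower-triangular 2×2 path factor for component ``A``/``C``/``E``."""
        x = component.lower()
        x11 = getattr(self, f"{x}11")
        x21 = getattr(self, f"{x}21")
        x22 = getattr(self, f"{x}22")
        return np.array([[x11, 0.0], [x21, x22]])

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in PATH_NAMES}

    def reflect_signs(self) -> "CholeskyParams":
        """Resolve Cholesky sign indeterminacy: non-negative diagonals.

        Flipping the sign of a whole factor column leaves L·Lᵀ (and every
        derived statistic) unchanged; the reported convention is a11, a22,
        c11, c22, e11, e22 ≥ 0.
        """
        vals = self.as_dict()
        for x in ("a", "c", "e"):
            if vals[f"{x}11"] < 0:  # column 1 flip
                vals[f"{x}11"] = -vals[f"{x}11"]
                vals[f"{x}21"] = -vals[f"{x}21"]
            if vals[f"{x}22"] < 0:  # column 2 flip
                vals[f"{x}22"] = -vals[f"{x}22"]
        return CholeskyParams(**vals)

    @staticmethod
    def from_standardized(
        h2_v1: float,
        h2_v2: float,
        specific_h2: float,
        c2_v1: float = 0.0,
        c2_v2: float = 0.0,
        specific_c2: float = 0.0,
        e21: float = 0.0,
        total_v1: float = 1.0,
        total_v2: float = 1.0,
    ) -> "CholeskyParams":
        """Build paths from standardized variance fractions.

        ``h2_v2`` is the total genetic fraction at visit 2 and
        ``specific_h2`` the part from the visit-2-specific factor
        (a22² / total), so a21² carries the difference. The unique-environment
        paths absorb whatever variance remains at each visit; ``e21`` is a raw
        path (0 means no environmental tracking).
        """
        a11 = math.sqrt(h2_v1 * total_v1)
        c11 = math.sqrt(c2_v1 * total_v1)
        a21 = math.sqrt((h2_v2 - specific_h2) * total_v2)
        a22 = math.sqrt(specific_h2 * total_v2)
        c21 = math.sqrt((c2_v2 - specific_c2) * total_v2)
        c22 = math.sqrt(specific_c2 * total_v2)
        e11_sq = total_v1 - a11**2 - c11**2
        e22_sq = total_v2 - a21**2 - a22**2 - c21**2 - c22**2 - e21**2
        if e11_sq <= 0 or e22_sq <= 0:
            raise ValueError("variance fractions leave no unique-environment variance")
        return CholeskyParams(
            a11=a11, a21=a21, a22=a22,
            c11=c11, c21=c21, c22=c22,
            e11=math.sqrt(e11_sq), e21=e21, e22=math.sqrt(e22_sq),
        )


@dataclass(frozen=True)
class MeansModel:
    """Means structure: per-visit intercepts plus optional covariate slopes.

    ``beta`` maps covariate name -> (slope at visit 1, slope at visit 2);
    slopes are shared across twins (and, in multigroup fits, across groups).
    """

    mu: tuple[float, float] = (0.0, 0.0)
    beta: Mapping[str, tuple[float, float]] = field(default_factory=dict)

    def expected(self, visit: int, covariates: Mapping[str, float] | None = None) -> float:
        m = self.mu[visit]
        for name, (b1, b2) in self.beta.items():
            if covariates is None or name not in covariates:
                raise ValueError(f"covariate {name!r} required by means model is absent")
            m += (b1, b2)[visit] * covariates[name]
        return m


@dataclass(frozen=True)
class ModelSpec:
    """Which components and paths are free, and how groups are handled.

    ``components`` is a subset of {"A", "C", "E"} (E mandatory);
    ``drop_paths`` fixes individual paths to zero (e.g. {"e21"});
    ``grouping`` is None, "ethnicity" or "ethnicity_sex";
    ``equate_paths`` constrains path coefficients equal across groups
    (means stay group-specific either way);
    ``covariates`` lists means-model covariates (e.g. ("map",)).
    """

    components: tuple[str, ...] = ("A", "E")
    drop_paths: frozenset[str] = frozenset()
    grouping: str | None = None
    equate_paths: bool = True
    covariates: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        comps = tuple(dict.fromkeys(c.upper() for c in self.components))
        object.__setattr__(self, "components", comps)
        object.__setattr__(self, "drop_paths", frozenset(self.drop_paths))
        if "E" not in comps:
            raise ValueError("unique environment (E) is mandatory")
        for c in comps:
            if c not in ("A", "C", "E"):
                raise ValueError(f"unknown component {c!r}")
        for p in self.drop_paths:
            if p not in PATH_NAMES:
                raise ValueError(f"unknown path {p!r}")
        if self.grouping not in (None, "ethnicity", "ethnicity_sex"):
            raise ValueError(f"unknown grouping {self.grouping!r}")
        if "e11" in self.drop_paths:
            raise ValueError("e11 cannot be fixed to zero (visit-1 E variance)")

    @property
    def free_paths(self) -> tuple[str, ...]:
        """Free path names in canonical order."""
        return tuple(
            p
            for p in PATH_NAMES
            if p[0].upper() in self.components and p not in self.drop_paths
        )

    def is_nested_in(self, other: "ModelSpec") -> bool:
        """True if this spec's free paths are a subset of ``other``'s."""
        return (
            set(self.free_paths) <= set(other.free_paths)
            and self.grouping == other.grouping
            and self.covariates == other.covariates
        )

    def to_dict(self) -> dict:
        return {
            "components": list(self.components),
            "drop_paths": sorted(self.drop_paths),
            "grouping": self.grouping,
            "equate_paths": self.equate_paths,
            "covariates": list(self.covariates),
        }

    @staticmethod
    def from_dict(d: Mapping) -> "ModelSpec":
        return ModelSpec(
            components=tuple(d.get("components", ("A", "E"))),
            drop_paths=frozenset(d.get("drop_paths", ())),
            grouping=d.get("grouping"),
            equate_paths=bool(d.get("equate_paths", True)),
            covariates=tuple(d.get("covariates", ())),
        )


def component_covariance(params: CholeskyParams, component: str) -> np.ndarray:
    """2×2 across-visit covariance of one component: L·Lᵀ of its factor."""
    L = params.factor(component)
    return L @ L.T


def expected_pair_covariance(params: CholeskyParams, zygosity: str) -> np.ndarray:
    """Expected 4×4 pair covariance, slot order (t1·v1, t1·v2, t2·v1, t2·v2).

    Within-twin blocks are A + C + E; cross-twin blocks are k·A + C with the
    genetic sharing coefficient k = 1 (MZ) or 0.5 (DZ).
    """
    if zygosity not in GENETIC_SHARING:
        raise ValueError(f"unknown zygosity {zygosity!r}")
    A = component_covariance(params, "A")
    C = component_covariance(params, "C")
    E = component_covariance(params, "E")
    within = A + C + E
    cross = GENETIC_SHARING[zygosity] * A + COMMON_ENV_SHARING * C
    out = np.empty((4, 4))
    out[:2, :2] = within
    out[2:, 2:] = within
    out[:2, 2:] = cross
    out[2:, :2] = cross.T
    return out


def _pair_covariate_values(pair: TwinPair, covariates: Sequence[str]) -> list[dict[str, float]]:
    """Per-slot covariate dicts in slot order."""
    source = {"map": pair.map_bp, "age": pair.age}
    out = []
    for t, v in SLOT_ORDER:
        out.append({name: float(source[name][t, v]) for name in covariates})
    return out


def pair_loglik(
    params: CholeskyParams,
    means: MeansModel,
    pair: TwinPair,
) -> float:
    """FIML log likelihood of one pair.

    The observed sub-vector of the four phenotype slots is scored against the
    matching sub-matrix of the expected pair covariance and sub-vector of
    expected means; a pair with nothing observed contributes exactly 0, and a
    singleton reduces to the within-twin marginal.
    """
    y, mask = pair.observed_vector()
    k = int(mask.sum())
    if k == 0:
        return 0.0
    sigma = expected_pair_covariance(params, pair.zygosity)
    sub = sigma[np.ix_(mask, mask)]
    covs = _pair_covariate_values(pair, tuple(means.beta.keys()))
    mu = np.array(
        [
            means.expected(int(SLOT_VISIT[i]), covs[i])
            for i in range(4)
            if mask[i]
        ]
    )
    r = y[mask] - mu
    try:
        c, low = cho_factor(sub, lower=True)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - defensive
        raise FloatingPointError(
            f"pair {pair.family_id!r}: singular expected covariance"
        ) from exc
    if not np.all(np.isfinite(np.diag(c))) or np.any(np.diag(c) <= 0):
        raise FloatingPointError(
            f"pair {pair.family_id!r}: singular expected covariance"
        )
    z = solve_triangular(c, r, lower=True)
    logdet = 2.0 * float(np.sum(np.log(np.diag(c))))
    return -0.5 * (k * LOG2PI + logdet + float(z @ z))


# ---------------------------------------------------------------------------
# Packed evaluation: pairs grouped by (group, zygosity, observation pattern)
# so the deviance is a handful of vectorized Gaussian evaluations. This is
# what the optimizer calls; pair_loglik above is the per-pair contract.
# ---------------------------------------------------------------------------


@dataclass
class _Block:
    group: str
    zygosity: str
    mask: np.ndarray            # (4,) bool
    y: np.ndarray               # (n, k) observed phenotypes
    cov: dict[str, np.ndarray]  # name -> (n, k) covariate values
    visits: np.ndarray          # (k,) visit index per observed slot


class PackedData:
    """A :class:`TwinDataset` reorganized for fast repeated FIML evaluation."""

    def __init__(
        self,
        dataset: TwinDataset,
        grouping: str | None = None,
        covariates: Sequence[str] = (),
    ) -> None:
        self.grouping = grouping
        self.covariates = tuple(covariates)
        buckets: dict[tuple[str, str, bytes], list[TwinPair]] = {}
        self.n_pairs = 0
        self.excluded: list[str] = []
        for pair in dataset:
            g = self.group_of(pair)
            if g is None:
                self.excluded.append(pair.family_id)
                continue
            _, mask = pair.observed_vector()
            if not mask.any():
                continue
            self._check_covariates(pair, mask)
            buckets.setdefault((g, pair.zygosity, mask.tobytes()), []).append(pair)
            self.n_pairs += 1
        self.blocks: list[_Block] = []
        for (g, zyg, _), pairs in sorted(
            buckets.items(), key=lambda kv: (kv[0][0], kv[0][1], kv[0][2])
        ):
            _, mask = pairs[0].observed_vector()
            idx = np.flatnonzero(mask)
            y = np.array([p.observed_vector()[0][mask] for p in pairs])
            cov = {}
            for name in self.covariates:
                source = {"map": "map_bp", "age": "age"}[name]
                cov[name] = np.array(
                    [
                        [getattr(p, source)[SLOT_TWIN[i], SLOT_VISIT[i]] for i in idx]
                        for p in pairs
                    ]
                )
            self.blocks.append(
                _Block(
                    group=g,
                    zygosity=zyg,
                    mask=mask,
                    y=y,
                    cov=cov,
                    visits=SLOT_VISIT[idx],
                )
            )
        self.groups = sorted({b.group for b in self.blocks})

    def group_of(self, pair: TwinPair) -> str | None:
        """Group key per the grouping rule; None means excluded.

        Opposite-sex DZ pairs have no single pair-level sex and are excluded
        from ethnicity × sex analyses.
        """
        if self.grouping is None:
            return "all"
        if self.grouping == "ethnicity":
            return pair.ethnicity
        sex = pair.pair_sex
        if sex is None:
            return None
        return f"{pair.ethnicity}_{sex}"

    def _check_covariates(self, pair: TwinPair, mask: np.ndarray) -> None:
        source = {"map": pair.map_bp, "age": pair.age}
        for name in self.covariates:
            vals = np.array(
                [source[name][t, v] for t, v in SLOT_ORDER]
            )[mask]
            if np.isnan(vals).any():
                raise ValueError(
                    f"pair {pair.family_id!r}: covariate {name!r} missing at an "
                    "observed phenotype entry"
                )

    def m2ll(
        self,
        params_by_group: Mapping[str, CholeskyParams],
        means_by_group: Mapping[str, MeansModel],
    ) -> float:
        """−2 × total FIML log likelihood; penalized outside the feasible set."""
        sigma_cache: dict[tuple[str, str], np.ndarray] = {}
        min_eig = math.inf
        for g, params in params_by_group.items():
            for zyg in ("MZ", "DZ"):
                sigma = expected_pair_covariance(params, zyg)
                min_eig = min(min_eig, float(np.linalg.eigvalsh(sigma)[0]))
                sigma_cache[(g, zyg)] = sigma
        if min_eig < MIN_EIGENVALUE:
            # graded penalty: slopes away from the infeasible region so
            # quasi-Newton steps are pushed back inside
            return PENALTY_DEVIANCE * (1.0 + (MIN_EIGENVALUE - min_eig))
        total = 0.0
        for block in self.blocks:
            sigma = sigma_cache[(block.group, block.zygosity)]
            sub = sigma[np.ix_(block.mask, block.mask)]
            means = means_by_group[block.group]
            mu = np.array([means.mu[v] for v in block.visits])
            M = np.broadcast_to(mu, block.y.shape).copy()
            for name, (b1, b2) in means.beta.items():
                slopes = np.where(block.visits == 0, b1, b2)
                M += slopes * block.cov[name]
            r = block.y - M
            try:
                L = np.linalg.cholesky(sub)
            except np.linalg.LinAlgError:
                return PENALTY_DEVIANCE
            z = solve_triangular(L, r.T, lower=True)
            logdet = 2.0 * float(np.sum(np.log(np.diag(L))))
            n, k = block.y.shape
            total += -0.5 * (n * (k * LOG2PI + logdet) + float(np.sum(z * z)))
        return -2.0 * total


def dataset_m2ll(
    params: CholeskyParams,
    means: MeansModel,
    dataset: TwinDataset,
) -> float:
    """−2 × sum of pair log likelihoods over the dataset (single group)."""
    if len(dataset) == 0:
        raise ValueError("dataset is empty")
    packed = PackedData(dataset, grouping=None, covariates=tuple(means.beta.keys()))
    return packed.m2ll({"all": params}, {"all": means})
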