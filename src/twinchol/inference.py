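"""Maximum-likelihood fitting and likelihood-ratio inference.

Fitting minimizes the FIML deviance (−2 log L) over raw path coefficients
with a quasi-Newton optimizer and a small multistart battery (moment-based
start plus seeded perturbations). Model comparison is by likelihood-ratio
tests of nested specifications: the component ladder (ACE vs AE, ACE vs CE,
AE vs E, each df 3 in the bivariate model) followed by single-path tests
(e21 = 0, a21 = 0, a22 = 0, df 1) inside the selected model, and a
multigroup homogeneity test that equates path coefficients across ethnicity ×
sex groups while leaving means group-specific. Boundary-adjusted null
distributions are deliberately not used: variance-component tests are
referred to the standard χ², which is conservative for components on the
boundary.

Confidence intervals are profile-likelihood based: the bound is where the
profile deviance rises by the χ²(1) quantile of the level (3.84 at 95%),
searched within the quantity's natural domain.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy import optimize, stats

from . import derived as _derived
from .data import TwinDataset
from .model import (
    CholeskyParams,
    MeansModel,
    ModelSpec,
    PackedData,
    PATH_NAMES,
    PENALTY_DEVIANCE,
)

__all__ = [
    "FitOptions",
    "FitResult",
    "LRTResult",
    "ConfidenceInterval",
    "LadderReport",
    "fit",
    "lrt",
    "model_ladder",
    "fit_multigroup",
    "profile_ci",
    "QUANTITIES",
]


@dataclass(frozen=True)
class FitOptions:
    """Optimizer settings.

    ``restarts`` counts total start points (the moment-based start plus
    seeded perturbations), capped at 5; ``seed`` drives the perturbations.
    """

    restarts: int = 3
    seed: int = 0
    ftol: float = 1e-11
    gtol: float = 1e-7
    maxiter: int = 1000

    def __post_init__(self) -> None:
        if not 1 <= self.restarts <= 5:
            raise ValueError("restarts must be between 1 and 5")


@dataclass
class FitResult:
    """A fitted model: estimates, deviance and convergence diagnostics."""

    spec: ModelSpec
    params_by_group: dict[str, CholeskyParams]
    means_by_group: dict[str, MeansModel]
    deviance: float
    n_free: int
    converged: bool
    grad_norm: float
    restarts_used: int
    n_pairs: int
    excluded_pairs: tuple[str, ...] = ()
    _layout: "_ParamLayout | None" = field(default=None, repr=False)
    _packed: PackedData | None = field(default=None, repr=False)

    @property
    def params(self) -> CholeskyParams:
        """Single-group (or equated) path estimates."""
        vals = list(self.params_by_group.values())
        return vals[0]

    @property
    def means(self) -> MeansModel:
        return list(self.means_by_group.values())[0]


@dataclass(frozen=True)
class LRTResult:
    """Likelihood-ratio comparison of nested fits."""

    chi2: float
    df: int
    p: float
    comparison: str = ""


@dataclass(frozen=True)
class ConfidenceInterval:
    """Profile-likelihood interval for a derived quantity."""

    quantity: str
    level: float
    point: float
    lower: float
    upper: float
    lower_at_boundary: bool = False
    upper_at_boundary: bool = False


# ---------------------------------------------------------------------------
# Parameter layout: mapping between the flat optimizer vector and
# (CholeskyParams, MeansModel) per group.
# ---------------------------------------------------------------------------


class _ParamLayout:
    def __init__(self, spec: ModelSpec, groups: Sequence[str]) -> None:
        self.spec = spec
        self.groups = list(groups)
        self.slots: list[tuple[str, str, str | None]] = []  # (kind, name, group)
        shared_paths = spec.equate_paths or len(self.groups) == 1
        if shared_paths:
            for p in spec.free_paths:
                self.slots.append(("path", p, None))
        else:
            for g in self.groups:
                for p in spec.free_paths:
                    self.slots.append(("path", p, g))
        for g in self.groups:
            self.slots.append(("mu", "v1", g))
            self.slots.append(("mu", "v2", g))
        for cov in spec.covariates:
            self.slots.append(("beta", f"{cov}_v1", None))
            self.slots.append(("beta", f"{cov}_v2", None))
        self.n_free = len(self.slots)

    def unpack(
        self, theta: np.ndarray
    ) -> tuple[dict[str, CholeskyParams], dict[str, MeansModel]]:
        paths: dict[str | None, dict[str, float]] = {}
        mus: dict[str, dict[str, float]] = {g: {} for g in self.groups}
        betas: dict[str, float] = {}
        for value, (kind, name, group) in zip(theta, self.slots):
            if kind == "path":
                paths.setdefault(group, {})[name] = float(value)
            elif kind == "mu":
                mus[group][name] = float(value)
            else:
                betas[name] = float(value)
        params_by_group = {}
        means_by_group = {}
        for g in self.groups:
            pd = paths.get(None, paths.get(g, {}))
            params_by_group[g] = CholeskyParams(
                **{p: pd.get(p, 0.0) for p in PATH_NAMES}
            )
            beta_map = {
                cov: (betas[f"{cov}_v1"], betas[f"{cov}_v2"])
                for cov in self.spec.covariates
            }
            means_by_group[g] = MeansModel(
                mu=(mus[g]["v1"], mus[g]["v2"]), beta=beta_map
            )
        return params_by_group, means_by_group

    def pack(
        self,
        params_by_group: Mapping[str, CholeskyParams],
        means_by_group: Mapping[str, MeansModel],
    ) -> np.ndarray:
        theta = np.empty(self.n_free)
        for i, (kind, name, group) in enumerate(self.slots):
            if kind == "path":
                g = group if group is not None else self.groups[0]
                theta[i] = getattr(params_by_group[g], name)
            elif kind == "mu":
                theta[i] = means_by_group[group].mu[0 if name == "v1" else 1]
            else:
                cov, visit = name.rsplit("_", 1)
                theta[i] = means_by_group[group or self.groups[0]].beta[cov][
                    0 if visit == "v1" else 1
                ]
        return theta


def _sample_moments(packed: PackedData) -> dict[str, dict[str, tuple[float, float]]]:
    """Per group: observed mean and variance of the phenotype at each visit."""
    values: dict[str, dict[int, list[float]]] = {
        g: {0: [], 1: []} for g in packed.groups
    }
    for block in packed.blocks:
        for j, v in enumerate(block.visits):
            values[block.group][int(v)].extend(block.y[:, j].tolist())
    out: dict[str, dict[str, tuple[float, float]]] = {}
    for g, per_visit in values.items():
        means = []
        variances = []
        for v in (0, 1):
            arr = np.asarray(per_visit[v])
            means.append(float(arr.mean()) if arr.size else 0.0)
            variances.append(float(arr.var(ddof=1)) if arr.size > 1 else 1.0)
        out[g] = {"mean": tuple(means), "var": tuple(variances)}
    return out


def _start_vector(layout: _ParamLayout, packed: PackedData) -> np.ndarray:
    """Moment-based start: visit-wise variances split across free components.

    A and E split the variance evenly when C is absent; with C free the split
    is A:C:E = 0.4:0.2:0.4 (an exact zero start for C is a stationary point
    of the deviance in the path parameterization and would stall the
    optimizer). Cross-visit paths start at 0.1 × the within-visit scale.
    """
    moments = _sample_moments(packed)
    has_c = "C" in layout.spec.components
    frac = {"a": 0.4 if has_c else 0.5, "c": 0.2, "e": 0.4 if has_c else 0.5}
    if "A" not in layout.spec.components:
        frac = {"a": 0.0, "c": 0.5 if has_c else 0.0, "e": 1.0 - (0.5 if has_c else 0.0)}
    theta = np.empty(layout.n_free)
    for i, (kind, name, group) in enumerate(layout.slots):
        g = group if group is not None else layout.groups[0]
        if kind == "path":
            comp = name[0]
            visit_var = moments[g]["var"]
            if name.endswith("11"):
                theta[i] = math.sqrt(frac[comp] * visit_var[0])
            elif name.endswith("22"):
                theta[i] = math.sqrt(frac[comp] * visit_var[1])
            else:  # cross path x21
                theta[i] = 0.1 * math.sqrt(max(frac[comp], 0.1) * visit_var[1])
        elif kind == "mu":
            theta[i] = moments[group]["mean"][0 if name == "v1" else 1]
        else:
            theta[i] = 0.0
    return theta


def fit(
    dataset: TwinDataset,
    spec: ModelSpec,
    options: FitOptions | None = None,
) -> FitResult:
    """Fit a Cholesky model by FIML.

    Minimizes the dataset deviance over the free paths, per-group visit
    intercepts and any covariate slopes, from a moment-based start plus
    seeded perturbed restarts; the best solution is sign-reflected so factor
    diagonals are non-negative.
    """
    if len(dataset) == 0:
        raise ValueError("dataset is empty")
    options = options or FitOptions()
    packed = PackedData(dataset, grouping=spec.grouping, covariates=spec.covariates)
    if not packed.blocks:
        raise ValueError("no pairs with observed phenotypes")
    layout = _ParamLayout(spec, packed.groups)

    def objective(theta: np.ndarray) -> float:
        params_by_group, means_by_group = layout.unpack(theta)
        return packed.m2ll(params_by_group, means_by_group)

    theta0 = _start_vector(layout, packed)
    rng = np.random.default_rng(options.seed)
    scale = np.maximum(np.abs(theta0), 0.1)
    best = None
    used = 0
    for attempt in range(options.restarts):
        start = theta0 if attempt == 0 else theta0 + 0.3 * scale * rng.standard_normal(
            layout.n_free
        )
        res = optimize.minimize(
            objective,
            start,
            method="L-BFGS-B",
            options={
                "ftol": options.ftol,
                "gtol": options.gtol,
                "maxiter": options.maxiter,
            },
        )
        used = attempt + 1
        if best is None or res.fun < best.fun:
            best = res
    assert best is not None
    converged = bool(np.isfinite(best.fun)) and best.fun < PENALTY_DEVIANCE / 2
    params_by_group, means_by_group = layout.unpack(best.x)
    params_by_group = {g: p.reflect_signs() for g, p in params_by_group.items()}
    theta_hat = layout.pack(params_by_group, means_by_group)
    deviance = objective(theta_hat)
    grad = optimize.approx_fprime(theta_hat, objective, 1e-6)
    return FitResult(
        spec=spec,
        params_by_group=params_by_group,
        means_by_group=means_by_group,
        deviance=float(deviance),
        n_free=layout.n_free,
        converged=converged,
        grad_norm=float(np.linalg.norm(grad)),
        restarts_used=used,
        n_pairs=packed.n_pairs,
        excluded_pairs=tuple(packed.excluded),
        _layout=layout,
        _packed=packed,
    )


def lrt(full: FitResult, reduced: FitResult, comparison: str = "") -> LRTResult:
    """Likelihood-ratio test of a reduced model nested in a full model.

    χ² is the deviance difference, df the difference in free parameters, p
    the upper χ²(df) tail. A negative χ² beyond numerical tolerance means
    the "full" fit is worse than the nested one and triggers a refit warning.
    """
    if not (set(reduced.spec.free_paths) <= set(full.spec.free_paths)):
        raise ValueError("reduced model paths are not a subset of the full model")
    if reduced.spec.grouping != full.spec.grouping:
        raise ValueError("models use different groupings")
    if not (full.converged and reduced.converged):
        raise ValueError("both fits must have converged")
    df = full.n_free - reduced.n_free
    chi2_stat = reduced.deviance - full.deviance
    if chi2_stat < -1e-6:
        import warnings

        warnings.warn(
            f"negative LRT statistic ({chi2_stat:.3g}): the full model fit worse "
            "than the nested one; refit with more restarts",
            RuntimeWarning,
            stacklevel=2,
        )
    chi2_stat = max(chi2_stat, 0.0)
    if df == 0:
        p = 1.0
    else:
        p = float(stats.chi2.sf(chi2_stat, df))
    return LRTResult(chi2=float(chi2_stat), df=df, p=p, comparison=comparison)


@dataclass
class LadderReport:
    """The full nested-model comparison ladder on one dataset."""

    rows: list[LRTResult]
    fits: dict[str, FitResult]
    selected: str
    final_spec: ModelSpec
    final_fit: FitResult

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            [
                {"comparison": r.comparison, "chi2": r.chi2, "df": r.df, "p": r.p}
                for r in self.rows
            ]
        )

    def to_text(self) -> str:
        lines = ["Model comparison ladder", "-" * 47]
        for r in self.rows:
            lines.append(
                f"{r.comparison:<28s} chi2={r.chi2:8.3f}  df={r.df}  p={r.p:.4f}"
            )
        lines.append(f"selected model: {self.selected}")
        lines.append(
            "final spec: components="
            + "".join(self.final_spec.components)
            + (
                ", dropped " + ",".join(sorted(self.final_spec.drop_paths))
                if self.final_spec.drop_paths
                else ""
            )
        )
        lines.append(f"final deviance: {self.final_fit.deviance:.4f}")
        return "\n".join(lines) + "\n"


def model_ladder(
    dataset: TwinDataset,
    options: FitOptions | None = None,
    alpha: float = 0.05,
    covariates: tuple[str, ...] = (),
) -> LadderReport:
    """Run the nested-model ladder and select a final specification.

    Component rungs (each df 3 in the bivariate model): ACE vs AE, ACE vs CE,
    AE vs E. A submodel is acceptable when not significantly worse than ACE;
    AE is preferred over CE when both are acceptable (MZ correlations
    exceeding DZ correlations indicate genetic rather than shared-environment
    resemblance). Within the selected model each of e21, a21, a22 that is
    free is tested against zero (df 1); paths whose test is non-significant
    are dropped from the final specification, which is then refitted.
    """
    options = options or FitOptions()
    specs = {
        "ACE": ModelSpec(components=("A", "C", "E"), covariates=covariates),
        "AE": ModelSpec(components=("A", "E"), covariates=covariates),
        "CE": ModelSpec(components=("C", "E"), covariates=covariates),
        "E": ModelSpec(components=("E",), covariates=covariates),
    }
    fits = {name: fit(dataset, s, options) for name, s in specs.items()}
    rows = [
        lrt(fits["ACE"], fits["AE"], "ACE vs AE"),
        lrt(fits["ACE"], fits["CE"], "ACE vs CE"),
        lrt(fits["AE"], fits["E"], "AE vs E"),
    ]
    ae_ok = rows[0].p > alpha
    ce_ok = rows[1].p > alpha
    if ae_ok:
        selected = "AE"
    elif ce_ok:
        selected = "CE"
    else:
        selected = "ACE"
    if selected == "AE" and rows[2].p > alpha:
        selected = "E"
    sel_spec = specs[selected]
    sel_fit = fits[selected]
    drop: set[str] = set()
    for path in ("e21", "a21", "a22"):
        if path not in sel_spec.free_paths:
            continue
        reduced_spec = replace(
            sel_spec, drop_paths=frozenset(sel_spec.drop_paths | {path})
        )
        reduced_fit = fit(dataset, reduced_spec, options)
        row = lrt(sel_fit, reduced_fit, f"{selected}: {path} = 0")
        rows.append(row)
        if row.p > alpha:
            drop.add(path)
    final_spec = replace(sel_spec, drop_paths=frozenset(sel_spec.drop_paths | drop))
    final_fit = fit(dataset, final_spec, options) if drop else sel_fit
    return LadderReport(
        rows=rows,
        fits=fits,
        selected=selected,
        final_spec=final_spec,
        final_fit=final_fit,
    )


def fit_multigroup(
    dataset: TwinDataset,
    grouping: str = "ethnicity_sex",
    base_spec: ModelSpec | None = None,
    options: FitOptions | None = None,
) -> tuple[FitResult, FitResult, LRTResult]:
    """Homogeneity test across groups.

    The full model frees every path coefficient per group; the reduced model
    equates paths across groups. Means stay group-specific in both, so the
    test targets variance components, not mean differences. df =
    (groups − 1) × number of path parameters.
    """
    base = base_spec or ModelSpec(components=("A", "E"))
    full_spec = replace(base, grouping=grouping, equate_paths=False)
    reduced_spec = replace(base, grouping=grouping, equate_paths=True)
    probe = PackedData(dataset, grouping=grouping)
    expected = {"ethnicity": 2, "ethnicity_sex": 4}.get(grouping)
    if expected is not None and len(probe.groups) < 2:
        raise ValueError(f"multigroup analysis needs >= 2 groups, got {probe.groups}")
    empty = [g for g in probe.groups if not any(b.group == g for b in probe.blocks)]
    if empty:
        raise ValueError(f"empty group(s): {empty}")
    full = fit(dataset, full_spec, options)
    reduced = fit(dataset, reduced_spec, options)
    test = lrt(full, reduced, f"homogeneity across {grouping}")
    return full, reduced, test


# ---------------------------------------------------------------------------
# Profile-likelihood confidence intervals
# ---------------------------------------------------------------------------

#: derived quantities available for profiling: name -> (function, domain)
QUANTITIES: dict[str, tuple[Callable[[CholeskyParams], float], tuple[float, float]]] = {
    "h2_v1": (lambda p: _derived.standardized_components(p)["h2_v1"], (0.0, 1.0)),
    "h2_v2": (lambda p: _derived.standardized_components(p)["h2_v2"], (0.0, 1.0)),
    "specific_h2": (lambda p: _derived.specific_heritability(p), (0.0, 1.0)),
    "h2_delta": (
        lambda p: _derived.difference_score_decomposition(p)["h2_delta"],
        (0.0, 1.0),
    ),
    "r_g": (lambda p: _derived.cross_visit_correlations(p)["r_g"], (-1.0, 1.0)),
    "r_ph": (lambda p: _derived.cross_visit_correlations(p)["r_ph"], (-1.0, 1.0)),
}


def profile_ci(
    dataset: TwinDataset,
    fit_result: FitResult,
    quantity: str,
    level: float = 0.95,
    options: FitOptions | None = None,
) -> ConfidenceInterval:
    """Profile-likelihood CI for a derived quantity of a single-group fit.

    For candidate values q of the quantity, the deviance is minimized subject
    to the equality constraint quantity(θ) = q; the bound is where this
    profile deviance exceeds the minimum by the χ²(1) quantile of ``level``.
    A bound that runs into the quantity's domain boundary before crossing is
    reported at the boundary and flagged one-sided.
    """
    if quantity not in QUANTITIES:
        raise ValueError(f"unknown quantity {quantity!r}; use one of {sorted(QUANTITIES)}")
    if not fit_result.converged:
        raise ValueError("fit did not converge")
    layout = fit_result._layout
    packed = fit_result._packed
    if layout is None or packed is None:
        raise ValueError("fit result lacks internal state; refit with twinchol.fit")
    if len(layout.groups) != 1:
        raise ValueError("profile CIs are defined for single-group fits")
    gfun, domain = QUANTITIES[quantity]
    group = layout.groups[0]

    def objective(theta: np.ndarray) -> float:
        pbg, mbg = layout.unpack(theta)
        return packed.m2ll(pbg, mbg)

    def qty(theta: np.ndarray) -> float:
        pbg, _ = layout.unpack(theta)
        val = gfun(pbg[group])
        if val is None:
            raise ValueError(f"quantity {quantity!r} undefined at profile point")
        return float(val)

    theta_hat = layout.pack(fit_result.params_by_group, fit_result.means_by_group)
    dev_min = fit_result.deviance
    point = qty(theta_hat)
    target = dev_min + float(stats.chi2.ppf(level, 1))

    def profile(q: float, warm: np.ndarray) -> tuple[float, np.ndarray]:
        res = optimize.minimize(
            objective,
            warm,
            method="SLSQP",
            constraints=[{"type": "eq", "fun": lambda th: qty(th) - q}],
            options={"maxiter": 200, "ftol": 1e-9},
        )
        return float(res.fun), res.x

    lo, hi = domain
    eps = 1e-6

    def search(direction: int) -> tuple[float, bool]:
        boundary = hi if direction > 0 else lo
        warm = theta_hat.copy()
        prev_q = point
        step = 0.02
        while True:
            q = point + direction * step
            if direction * (q - boundary) >= 0:
                q = boundary - direction * eps
            dev, warm = profile(q, warm)
            if dev > target:
                # bracket between prev_q (below target) and q (above)
                f = lambda qq: profile(qq, warm)[0] - target
                a, b = (prev_q, q) if direction > 0 else (q, prev_q)
                try:
                    bound = optimize.brentq(f, a, b, xtol=1e-4, maxiter=60)
                except ValueError:
                    bound = q
                return float(bound), False
            prev_q = q
            if abs(q - boundary) <= 2 * eps:
                return boundary, True
            step *= 2.0

    lower, lower_bd = search(-1)
    upper, upper_bd = search(+1)
    lower = min(lower, point)
    upper = max(upper, point)
    return ConfidenceInterval(
        quantity=quantity,
        level=level,
        point=point,
        lower=lower,
        upper=upper,
        lower_at_boundary=lower_bd,
        upper_at_boundary=upper_bd,
    )
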