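"""Derived quantities of a fitted bivariate Cholesky model.

Everything here is closed-form arithmetic on the nine path coefficients:
per-visit standardized variance fractions (heritability h², shared- and
unique-environment fractions c², e²), the visit-2-specific ("novel")
heritability a22²/V_tot2, cross-visit component correlations (r_g, r_c, r_e)
and the model-implied phenotypic tracking correlation r_ph, and the
difference-score (visit 2 − visit 1) variance decomposition obtained by
applying δ-weights (−1, +1) to the path factors.

Correlations whose component has zero variance at either visit are undefined
and reported as ``None`` — never coerced to 0 or 1.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from .model import CholeskyParams, component_covariance

__all__ = [
    "DerivedStats",
    "standardized_components",
    "specific_heritability",
    "cross_visit_correlations",
    "difference_score_decomposition",
    "compute_derived",
]


@dataclass(frozen=True)
class DerivedStats:
    """Flat record of every derived statistic for one fitted model."""

    h2_v1: float
    c2_v1: float
    e2_v1: float
    h2_v2: float
    c2_v2: float
    e2_v2: float
    specific_h2: float
    r_g: float | None
    r_c: float | None
    r_e: float | None
    r_ph: float
    h2_delta: float | None
    c2_delta: float | None
    e2_delta: float | None
    V_A: tuple[float, float]
    V_C: tuple[float, float]
    V_E: tuple[float, float]
    COV_A: float
    COV_C: float
    COV_E: float

    def to_record(self) -> dict[str, object]:
        """Serialize to a flat dict; undefined values become "undefined"."""
        rec: dict[str, object] = {}
        for key, val in asdict(self).items():
            if isinstance(val, tuple):
                rec[f"{key}_v1"], rec[f"{key}_v2"] = val
            else:
                rec[key] = "undefined" if val is None else val
        return rec

    def to_json(self) -> str:
        return json.dumps(self.to_record(), indent=2, sort_keys=True)


def _component_moments(params: CholeskyParams) -> dict[str, tuple[float, float, float]]:
    """Per component: (variance v1, variance v2, cross-visit covariance)."""
    out = {}
    for comp in ("A", "C", "E"):
        m = component_covariance(params, comp)
        out[comp] = (float(m[0, 0]), float(m[1, 1]), float(m[1, 0]))
    return out


def _totals(params: CholeskyParams) -> tuple[float, float]:
    mom = _component_moments(params)
    v1 = sum(mom[c][0] for c in mom)
    v2 = sum(mom[c][1] for c in mom)
    return v1, v2


def standardized_components(params: CholeskyParams) -> dict[str, float]:
    """Standardized variance fractions h², c², e² at each visit.

    h²_v1 = a11² / (a11² + c11² + e11²) and
    h²_v2 = (a21² + a22²) / (total visit-2 variance); c², e² analogous.
    """
    mom = _component_moments(params)
    v1, v2 = _totals(params)
    if v1 <= 0 or v2 <= 0:
        raise ValueError("total phenotypic variance must be positive at each visit")
    return {
        "h2_v1": mom["A"][0] / v1,
        "c2_v1": mom["C"][0] / v1,
        "e2_v1": mom["E"][0] / v1,
        "h2_v2": mom["A"][1] / v2,
        "c2_v2": mom["C"][1] / v2,
        "e2_v2": mom["E"][1] / v2,
    }


def specific_heritability(params: CholeskyParams) -> float:
    """Novel-genetic fraction at visit 2: a22² over total visit-2 variance."""
    _, v2 = _totals(params)
    if v2 <= 0:
        raise ValueError("total visit-2 variance must be positive")
    return params.a22**2 / v2


def cross_visit_correlations(params: CholeskyParams) -> dict[str, float | None]:
    """Component correlations r_g, r_c, r_e and phenotypic correlation r_ph.

    r_g = COV_A(v1, v2) / sqrt(V_A(v1) · V_A(v2)); r_c, r_e analogous. A
    correlation is undefined (``None``) when its component has zero variance
    at either visit. r_ph divides the total cross-visit covariance by the
    geometric mean of the total variances.
    """
    mom = _component_moments(params)
    out: dict[str, float | None] = {}
    for comp, key in (("A", "r_g"), ("C", "r_c"), ("E", "r_e")):
        v1, v2, cov = mom[comp]
        if v1 <= 0 or v2 <= 0:
            out[key] = None
        else:
            out[key] = cov / math.sqrt(v1 * v2)
    tot1, tot2 = _totals(params)
    if tot1 <= 0 or tot2 <= 0:
        raise ValueError("total phenotypic variance must be positive at each visit")
    total_cov = sum(mom[c][2] for c in mom)
    out["r_ph"] = total_cov / math.sqrt(tot1 * tot2)
    return out


def difference_score_decomposition(
    params: CholeskyParams,
) -> dict[str, float | None]:
    """Variance decomposition of the difference score Δ = visit 2 − visit 1.

    Applying δ-weights (−1, +1) to each path factor gives
    V_X(Δ) = (x21 − x11)² + x22² per component X, and
    h²_Δ = V_A(Δ) / Var(Δ). When Var(Δ) = 0 (visit-2 paths identical to
    visit-1 with no specific paths) the fractions are undefined.
    """
    parts = {}
    for x in ("a", "c", "e"):
        x11 = getattr(params, f"{x}11")
        x21 = getattr(params, f"{x}21")
        x22 = getattr(params, f"{x}22")
        parts[x.upper()] = (x21 - x11) ** 2 + x22**2
    var_delta = sum(parts.values())
    out: dict[str, float | None] = {
        "V_A_delta": parts["A"],
        "V_C_delta": parts["C"],
        "V_E_delta": parts["E"],
        "var_delta": var_delta,
    }
    if var_delta <= 0:
        out.update(h2_delta=None, c2_delta=None, e2_delta=None)
    else:
        out.update(
            h2_delta=parts["A"] / var_delta,
            c2_delta=parts["C"] / var_delta,
            e2_delta=parts["E"] / var_delta,
        )
    return out


def compute_derived(params: CholeskyParams) -> DerivedStats:
    """All derived statistics for one parameter set."""
    std = standardized_components(params)
    corr = cross_visit_correlations(params)
    delta = difference_score_decomposition(params)
    mom = _component_moments(params)
    return DerivedStats(
        h2_v1=std["h2_v1"], c2_v1=std["c2_v1"], e2_v1=std["e2_v1"],
        h2_v2=std["h2_v2"], c2_v2=std["c2_v2"], e2_v2=std["e2_v2"],
        specific_h2=specific_heritability(params),
        r_g=corr["r_g"], r_c=corr["r_c"], r_e=corr["r_e"],
        r_ph=corr["r_ph"],  # type: ignore[arg-type]
        h2_delta=delta["h2_delta"],
        c2_delta=delta["c2_delta"],
        e2_delta=delta["e2_delta"],
        V_A=(mom["A"][0], mom["A"][1]),
        V_C=(mom["C"][0], mom["C"][1]),
        V_E=(mom["E"][0], mom["E"][1]),
        COV_A=mom["A"][2], COV_C=mom["C"][2], COV_E=mom["E"][2],
    )
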