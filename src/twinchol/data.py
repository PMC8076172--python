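"""Twin phenotype tables: data model, I/O, transformation, descriptives.

The unit of analysis is the twin *pair* (or a singleton whose co-twin is
unmeasured). A pair carries a phenotype measured at two visits for each twin,
a pair-level ethnicity label, per-twin sex, and optional covariates (mean
arterial pressure and age, per twin per visit). The canonical on-disk format
is a wide CSV with one row per pair; empty cells are missing values.

Phenotype slots are ordered (twin1·visit1, twin1·visit2, twin2·visit1,
twin2·visit2) throughout the package — the same ordering the expected pair
covariance matrix uses.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TwinPair",
    "TwinDataset",
    "TwinTableError",
    "ParseError",
    "ValidationError",
    "CANONICAL_COLUMNS",
    "read_twin_table",
    "write_twin_table",
    "log_transform",
    "twin_correlations",
    "double_entry_correlation",
    "descriptives",
]

ZYGOSITIES = ("MZ", "DZ")
ETHNICITIES = ("EA", "AA")
SEXES = ("M", "F")

#: canonical wide-CSV column names: pwv{twin}_v{visit} etc.
CANONICAL_COLUMNS = [
    "family_id", "zygosity", "ethnicity", "sex1", "sex2",
    "pwv1_v1", "pwv1_v2", "pwv2_v1", "pwv2_v2",
    "map1_v1", "map1_v2", "map2_v1", "map2_v2",
    "age1_v1", "age1_v2", "age2_v1", "age2_v2",
]

REQUIRED_COLUMNS = CANONICAL_COLUMNS[:9]

#: slot order used for likelihood vectors: (twin, visit) 0-based
SLOT_ORDER = ((0, 0), (0, 1), (1, 0), (1, 1))
SLOT_VISIT = np.array([0, 1, 0, 1])
SLOT_TWIN = np.array([0, 0, 1, 1])
SLOT_NAMES = ("twin1_v1", "twin1_v2", "twin2_v1", "twin2_v2")


class TwinTableError(ValueError):
    """Base error for twin-table problems."""


class ParseError(TwinTableError):
    """A cell could not be interpreted (bad zygosity code, non-numeric value)."""


class ValidationError(TwinTableError):
    """A structural invariant of the table is violated."""


@dataclass(frozen=True)
class TwinPair:
    """One twin pair (or singleton) with per-twin, per-visit measurements.

    ``phenotype``, ``map_bp`` and ``age`` are 2×2 arrays indexed
    [twin, visit] with ``nan`` marking missing entries. ``sex2`` is ``None``
    for singletons.
    """

    family_id: str
    zygosity: str
    ethnicity: str
    sex1: str
    sex2: str | None
    phenotype: np.ndarray
    map_bp: np.ndarray
    age: np.ndarray
    singleton: bool = False

    def __post_init__(self) -> None:
        if self.zygosity not in ZYGOSITIES:
            raise ParseError(
                f"pair {self.family_id!r}: unknown zygosity code {self.zygosity!r}"
            )
        if self.sex1 not in SEXES:
            raise ParseError(f"pair {self.family_id!r}: bad sex code {self.sex1!r}")
        if self.sex2 is not None and self.sex2 not in SEXES:
            raise ParseError(f"pair {self.family_id!r}: bad sex code {self.sex2!r}")
        if (
            self.zygosity == "MZ"
            and self.sex2 is not None
            and self.sex1 != self.sex2
        ):
            raise ValidationError(
                f"pair {self.family_id!r}: MZ pair with discordant sexes"
            )
        for name in ("phenotype", "map_bp", "age"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (2, 2):
                raise ValidationError(
                    f"pair {self.family_id!r}: {name} must be 2x2 [twin, visit]"
                )
            object.__setattr__(self, name, arr)

    @property
    def pair_sex(self) -> str | None:
        """Pair-level sex: the shared sex for same-sex pairs, else None."""
        if self.sex2 is None or self.sex1 == self.sex2:
            return self.sex1
        return None

    def observed_vector(self) -> tuple[np.ndarray, np.ndarray]:
        """Phenotype values in slot order plus a boolean observed mask."""
        y = np.array([self.phenotype[t, v] for t, v in SLOT_ORDER])
        return y, ~np.isnan(y)

    def swap_twins(self) -> "TwinPair":
        """Relabel twin 1 <-> twin 2 (with covariates)."""
        return TwinPair(
            family_id=self.family_id,
            zygosity=self.zygosity,
            ethnicity=self.ethnicity,
            sex1=self.sex2 if self.sex2 is not None else self.sex1,
            sex2=self.sex1 if self.sex2 is not None else None,
            phenotype=self.phenotype[::-1].copy(),
            map_bp=self.map_bp[::-1].copy(),
            age=self.age[::-1].copy(),
            singleton=self.singleton,
        )


@dataclass
class TwinDataset:
    """An ordered collection of :class:`TwinPair` with provenance metadata."""

    pairs: list[TwinPair]
    phenotype_name: str = "pwv"
    transform: str = "none"  # "none" | "log"
    provenance: str = ""

    def __post_init__(self) -> None:
        ids = [p.family_id for p in self.pairs]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate family_id values: {dup}")

    def __len__(self) -> int:
        return len(self.pairs)

    def __iter__(self) -> Iterator[TwinPair]:
        return iter(self.pairs)

    def to_frame(self) -> pd.DataFrame:
        """Render as the canonical wide table (one row per pair)."""
        rows = []
        for p in self.pairs:
            row: dict[str, object] = {
                "family_id": p.family_id,
                "zygosity": p.zygosity,
                "ethnicity": p.ethnicity,
                "sex1": p.sex1,
                "sex2": p.sex2 if p.sex2 is not None else "",
            }
            for label, arr in (("pwv", p.phenotype), ("map", p.map_bp), ("age", p.age)):
                for t in range(2):
                    for v in range(2):
                        row[f"{label}{t + 1}_v{v + 1}"] = arr[t, v]
            rows.append(row)
        return pd.DataFrame(rows, columns=CANONICAL_COLUMNS)


def _parse_float(cell: object, row_label: str, col: str) -> float:
    if cell is None:
        return math.nan
    s = str(cell).strip()
    if s == "" or s.lower() in ("nan", "na"):
        return math.nan
    try:
        return float(s)
    except ValueError:
        raise ParseError(f"row {row_label}: non-numeric value {s!r} in column {col!r}")


def read_twin_table(
    path,
    schema: Mapping[str, str] | None = None,
    phenotype_name: str = "pwv",
) -> TwinDataset:
    """Read a wide twin CSV (one row per pair) into a :class:`TwinDataset`.

    Parameters
    ----------
    path
        CSV file path. Empty cells are missing; a row whose twin-2 cells are
        all empty is a singleton.
    schema
        Optional mapping from canonical column names (``family_id``,
        ``zygosity``, ``pwv1_v1``, ...) to the file's actual header names.

    Rows with no observed phenotype at all are dropped (they carry no
    likelihood information); the count is recorded in ``provenance``.
    """
    schema = dict(schema or {})
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)

    def col(name: str) -> str:
        return schema.get(name, name)

    missing_cols = [c for c in REQUIRED_COLUMNS if col(c) not in raw.columns]
    if missing_cols:
        raise ValidationError(f"missing required columns: {missing_cols}")

    pairs: list[TwinPair] = []
    n_dropped = 0
    for idx, rec in raw.iterrows():
        row_label = str(idx + 2)  # 1-based with header line
        fam = str(rec[col("family_id")]).strip()
        zyg = str(rec[col("zygosity")]).strip()
        if zyg not in ZYGOSITIES:
            raise ParseError(f"row {row_label}: unknown zygosity code {zyg!r}")
        eth = str(rec[col("ethnicity")]).strip()
        sex1 = str(rec[col("sex1")]).strip()
        sex2_raw = str(rec[col("sex2")]).strip()

        def grid(label: str) -> np.ndarray:
            out = np.full((2, 2), math.nan)
            for t in range(2):
                for v in range(2):
                    name = f"{label}{t + 1}_v{v + 1}"
                    c = col(name)
                    if c in raw.columns:
                        out[t, v] = _parse_float(rec[c], row_label, c)
            return out

        pheno = grid("pwv")
        mapbp = grid("map")
        age = grid("age")

        twin2_absent = (
            sex2_raw == ""
            and np.isnan(pheno[1]).all()
            and np.isnan(mapbp[1]).all()
            and np.isnan(age[1]).all()
        )
        if np.isnan(pheno).all():
            n_dropped += 1
            continue
        pairs.append(
            TwinPair(
                family_id=fam,
                zygosity=zyg,
                ethnicity=eth,
                sex1=sex1,
                sex2=None if twin2_absent else sex2_raw,
                phenotype=pheno,
                map_bp=mapbp,
                age=age,
                singleton=twin2_absent,
            )
        )
    note = f"read from {path}"
    if n_dropped:
        note += f"; dropped {n_dropped} all-missing row(s)"
    return TwinDataset(pairs, phenotype_name=phenotype_name, provenance=note)


def write_twin_table(dataset: TwinDataset, path) -> None:
    """Write the canonical wide CSV; missing values become empty cells."""
    frame = dataset.to_frame()
    frame.to_csv(path, index=False, na_rep="")


def log_transform(dataset: TwinDataset) -> TwinDataset:
    """Natural-log transform every non-missing phenotype value.

    Raises if the transform was already applied or any value is non-positive
    (log-normal phenotypes must be positive on the raw scale).
    """
    if dataset.transform != "none":
        raise ValidationError("log transform already applied")
    new_pairs = []
    for p in dataset.pairs:
        pheno = p.phenotype
        bad = np.argwhere(~np.isnan(pheno) & (pheno <= 0))
        if bad.size:
            t, v = bad[0]
            raise ValidationError(
                f"pair {p.family_id!r}: non-positive phenotype at twin{t + 1}"
                f"_v{v + 1} ({pheno[t, v]!r}) cannot be log transformed"
            )
        with np.errstate(invalid="ignore"):
            new_pairs.append(replace(p, phenotype=np.log(pheno)))
    return TwinDataset(
        new_pairs,
        phenotype_name=dataset.phenotype_name,
        transform="log",
        provenance=dataset.provenance + "; log transformed",
    )


def double_entry_correlation(x1: Sequence[float], x2: Sequence[float]) -> float:
    """Double-entry Pearson correlation between co-twins.

    Each pair enters twice, once in each ordering, which makes the estimate
    exactly invariant to twin labelling (it equals the intraclass-style
    correlation about the pooled mean with a pooled variance).
    """
    a = np.asarray(x1, dtype=float)
    b = np.asarray(x2, dtype=float)
    left = np.concatenate([a, b])
    right = np.concatenate([b, a])
    lc = left - left.mean()
    rc = right - right.mean()
    denom = math.sqrt((lc**2).sum() * (rc**2).sum())
    if denom == 0:
        return math.nan
    return float((lc * rc).sum() / denom)


def twin_correlations(
    dataset: TwinDataset,
    visit: int,
    min_pairs: int = 3,
) -> pd.DataFrame:
    """Twin correlations by ethnicity × zygosity for one visit.

    Pairs with either twin missing at the visit are dropped; singletons
    contribute nothing. Strata with fewer than ``min_pairs`` complete pairs
    are reported with ``r = NaN`` (unavailable), never a fabricated value.
    """
    if visit not in (1, 2):
        raise ValueError("visit must be 1 or 2")
    v = visit - 1
    buckets: dict[tuple[str, str], list[tuple[float, float]]] = {}
    for p in dataset.pairs:
        y1, y2 = p.phenotype[0, v], p.phenotype[1, v]
        if math.isnan(y1) or math.isnan(y2):
            continue
        buckets.setdefault((p.ethnicity, p.zygosity), []).append((y1, y2))
    eths = sorted({p.ethnicity for p in dataset.pairs})
    rows = []
    for eth in eths:
        for zyg in ZYGOSITIES:
            vals = buckets.get((eth, zyg), [])
            n = len(vals)
            if n >= min_pairs:
                r = double_entry_correlation([a for a, _ in vals], [b for _, b in vals])
            else:
                r = math.nan
            rows.append(
                {"ethnicity": eth, "zygosity": zyg, "visit": visit, "n_pairs": n, "r": r}
            )
    return pd.DataFrame(rows, columns=["ethnicity", "zygosity", "visit", "n_pairs", "r"])


def _individual_frame(dataset: TwinDataset) -> pd.DataFrame:
    rows = []
    for p in dataset.pairs:
        twins = [(0, p.sex1)]
        if not p.singleton:
            twins.append((1, p.sex2 if p.sex2 is not None else p.sex1))
        for t, sex in twins:
            for v in range(2):
                rows.append(
                    {
                        "ethnicity": p.ethnicity,
                        "sex": sex,
                        "visit": v + 1,
                        "pwv": p.phenotype[t, v],
                        "map": p.map_bp[t, v],
                        "age": p.age[t, v],
                    }
                )
    return pd.DataFrame(rows)


def descriptives(dataset: TwinDataset) -> pd.DataFrame:
    """Mean (SD) descriptive table by ethnicity × sex × visit.

    Individuals (including singletons) are the unit; missing entries are
    excluded variable-wise; SD uses the n−1 divisor. Empty strata appear with
    ``n = 0`` and NaN summaries.
    """
    ind = _individual_frame(dataset)
    rows = []
    eths = sorted(ind["ethnicity"].unique()) if len(ind) else []
    for eth in eths:
        for sex in SEXES:
            for visit in (1, 2):
                sub = ind[
                    (ind["ethnicity"] == eth)
                    & (ind["sex"] == sex)
                    & (ind["visit"] == visit)
                ]
                row: dict[str, object] = {
                    "ethnicity": eth,
                    "sex": sex,
                    "visit": visit,
                    "n": len(sub),
                }
                for var in ("pwv", "map", "age"):
                    vals = sub[var].dropna()
                    row[f"{var}_mean"] = vals.mean() if len(vals) else math.nan
                    row[f"{var}_sd"] = vals.std(ddof=1) if len(vals) > 1 else math.nan
                rows.append(row)
    cols = ["ethnicity", "sex", "visit", "n"] + [
        f"{v}_{s}" for v in ("pwv", "map", "age") for s in ("mean", "sd")
    ]
    return pd.DataFrame(rows, columns=cols)
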