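"""End-to-end pipeline: descriptives, twin correlations, model ladder,
derived statistics with confidence intervals, and the covariate-adjusted
rerun, written as CSV tables plus a plain-text summary.

Every output file starts with comment lines carrying the seed and a hash of
the run configuration, so identical inputs provably produce identical
bundles.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .data import descriptives, log_transform, read_twin_table, twin_correlations
from .derived import compute_derived
from .inference import FitOptions, model_ladder, profile_ci
from .simulate import GeneratorConfig, simulate_cohort

__all__ = ["RunConfig", "run_pipeline"]

log = logging.getLogger("twinchol")


@dataclass
class RunConfig:
    """One pipeline run: exactly one of ``input_path`` / ``generator``.

    ``schema`` maps canonical column names to the input file's headers;
    ``ci_level`` sets the profile-interval level; ``adjust_map`` adds the
    mean-arterial-pressure rerun; ``ci_quantities`` are profiled on the
    final model.
    """

    input_path: str | None = None
    generator: GeneratorConfig | None = None
    schema: dict[str, str] = field(default_factory=dict)
    out_dir: str = "twinchol_out"
    seed: int = 0
    ci_level: float = 0.95
    adjust_map: bool = True
    ci_quantities: tuple[str, ...] = ("h2_v1", "h2_v2", "specific_h2", "h2_delta")
    restarts: int = 3
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if (self.input_path is None) == (self.generator is None):
            raise ValueError("set exactly one of input_path / generator")

    def digest(self) -> str:
        payload = {
            "input_path": self.input_path,
            "generator": self.generator.to_dict() if self.generator else None,
            "schema": self.schema,
            "seed": self.seed,
            "ci_level": self.ci_level,
            "adjust_map": self.adjust_map,
            "ci_quantities": list(self.ci_quantities),
            "restarts": self.restarts,
            "alpha": self.alpha,
        }
        blob = json.dumps(payload, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _setup_logging(out_dir: Path, verbose: bool = False) -> None:
    log.setLevel(logging.DEBUG if verbose else logging.INFO)
    log.handlers.clear()
    fmt = logging.Formatter("%(asctime)s %(levelname)s %(message)s")
    for handler in (
        logging.StreamHandler(sys.stderr),
        logging.FileHandler(out_dir / "run.log", mode="w"),
    ):
        handler.setFormatter(fmt)
        log.addHandler(handler)


def _write_table(frame: pd.DataFrame, path: Path, header: str) -> None:
    with open(path, "w") as fh:
        fh.write(header)
        frame.to_csv(fh, index=False, float_format="%.6g")


def run_pipeline(config: RunConfig, verbose: bool = False) -> dict[str, object]:
    """Run the full analysis battery and write the report bundle.

    Returns a dict of in-memory results keyed by stage name. A failing stage
    is logged and skipped along with its dependents; independent stages still
    run.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    _setup_logging(out_dir, verbose)
    stamp = f"# twinchol {__version__}  seed={config.seed}  config={config.digest()}\n"
    log.info("run config digest %s, seed %d", config.digest(), config.seed)

    if config.generator is not None:
        dataset = simulate_cohort(config.generator, seed=config.seed)
        log.info("simulated cohort: %d pairs", len(dataset))
    else:
        dataset = read_twin_table(config.input_path, schema=config.schema)
        log.info("read %d pairs from %s", len(dataset), config.input_path)

    results: dict[str, object] = {"dataset": dataset}

    # stage 1-2: raw-scale descriptives, then log transform + correlations
    try:
        desc = descriptives(dataset)
        _write_table(desc, out_dir / "descriptives.csv", stamp)
        results["descriptives"] = desc
    except Exception:
        log.exception("descriptives stage failed")

    try:
        logged = log_transform(dataset)
        results["log_dataset"] = logged
    except Exception:
        log.exception("log transform failed; downstream stages skipped")
        return results

    try:
        corr = pd.concat(
            [twin_correlations(logged, visit=v) for v in (1, 2)], ignore_index=True
        )
        _write_table(corr, out_dir / "twin_correlations.csv", stamp)
        results["twin_correlations"] = corr
    except Exception:
        log.exception("twin-correlation stage failed")

    options = FitOptions(restarts=config.restarts, seed=config.seed)

    def battery(tag: str, covariates: tuple[str, ...]) -> None:
        ladder = model_ladder(
            logged, options=options, alpha=config.alpha, covariates=covariates
        )
        _write_table(ladder.to_frame(), out_dir / f"ladder{tag}.csv", stamp)
        (out_dir / f"ladder{tag}.txt").write_text(stamp + ladder.to_text())
        results[f"ladder{tag}"] = ladder
        final = ladder.final_fit
        stats_rec = compute_derived(final.params).to_record()
        for q in config.ci_quantities:
            try:
                ci = profile_ci(logged, final, q, level=config.ci_level, options=options)
                stats_rec[f"{q}_ci_lower"] = ci.lower
                stats_rec[f"{q}_ci_upper"] = ci.upper
            except Exception:
                log.exception("profile CI for %s failed", q)
        stats_rec["deviance"] = final.deviance
        stats_rec["n_free"] = final.n_free
        stats_rec["converged"] = final.converged
        frame = pd.DataFrame([stats_rec])
        _write_table(frame, out_dir / f"derived_stats{tag}.csv", stamp)
        results[f"derived{tag}"] = stats_rec
        log.info(
            "%s: selected %s, deviance %.3f",
            f"battery{tag}",
            ladder.selected,
            final.deviance,
        )

    try:
        battery("", ())
    except Exception:
        log.exception("unadjusted model battery failed")
    if config.adjust_map:
        try:
            battery("_map_adjusted", ("map",))
        except Exception:
            log.exception("MAP-adjusted model battery failed")

    log.info("report bundle written to %s", out_dir)
    return results
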