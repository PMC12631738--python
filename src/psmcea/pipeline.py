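"""End-to-end orchestration: load, reconstruct, fit, valuate, analyze, write.

``run_all`` executes the complete pipeline for one configuration and writes
every artifact as CSV (plus a markdown report and a JSON run log) to an
output directory.  Stage failures are wrapped in :class:`PipelineError`
carrying the stage name, so the CLI can exit non-zero with a stage-tagged
message.
"""

from __future__ import annotations

import hashlib
import json
import platform
from pathlib import Path

import pandas as pd

from . import __version__, cea
from .config import ModelBundle, load_config
from .kmdata import read_curves, read_risk_tables, write_curves, write_ipd, write_risk_tables
from .model import FittedBundle, evaluate, fit_bundle
from .report import assemble_report

__all__ = ["PipelineError", "load_bundle", "run_all"]

SCENARIO_FAMILY = "lognormal"


class PipelineError(RuntimeError):
    """A pipeline stage failed; ``stage`` names the failing step."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"[{stage}] {cause}")
        self.stage = stage
        self.cause = cause


def load_bundle(config_path) -> ModelBundle:
    """Load and validate a configuration and its curves into a bundle."""
    cfg = load_config(config_path)
    if cfg.curves.fixture is not None:
        from .synthetic import make_fixture

        bundle = make_fixture(cfg.curves.fixture)
        # the fixture supplies curves; the user's economics replace the packaged ones
        cfg = cfg.model_copy(deep=True)
        return ModelBundle(cfg, bundle.curves, bundle.risk_tables)
    base = Path(config_path).parent
    curves = read_curves(base / cfg.curves.curves_csv)
    risk = read_risk_tables(base / cfg.curves.risk_csv)
    return ModelBundle(cfg, curves, risk)


def _stage(name):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(name, exc) from exc

        return wrapper

    return deco


@_stage("load")
def _load(config_path) -> ModelBundle:
    return load_bundle(config_path)


@_stage("reconstruct-fit")
def _fit(bundle) -> FittedBundle:
    return fit_bundle(bundle)


def run_all(
    config_path,
    out_dir,
    seed: int = 0,
    n_psa: int = 1000,
    wtp: float | None = None,
) -> dict:
    """Run the whole pipeline; returns a summary dict and writes artifacts.

    Artifacts: ``curves.csv``, ``risk_tables.csv``, ``ipd_<endpoint>_<arm>.csv``,
    ``fits.csv``, ``trace_<arm>.csv``, ``report.csv``, ``report.md``,
    ``tornado.csv``, ``psa_samples.csv``, ``ceac.csv``, ``scatter.csv``,
    ``scenario.csv`` and ``run_log.json``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    bundle = _load(config_path)
    cfg = bundle.config
    wtp = wtp if wtp is not None else cfg.wtp

    write_curves(bundle.curves, out / "curves.csv")
    write_risk_tables(bundle.risk_tables, out / "risk_tables.csv")

    fitted = _fit(bundle)
    for (endpoint, arm), df in fitted.ipd.items():
        write_ipd(df, out / f"ipd_{endpoint}_{arm}.csv")
    fitted.fit_table().to_csv(out / "fits.csv", index=False)

    try:
        results = evaluate(fitted)
        from .config import resolve_inputs
        from .engine import build_trace

        mi = resolve_inputs(cfg)
        for arm in results:
            trace = build_trace(
                fitted.selected[("PFS", arm)].survival,
                fitted.selected[("OS", arm)].survival,
                mi.engine,
            )
            trace.to_frame().to_csv(out / f"trace_{arm}.csv", index=False)
        table = assemble_report({cfg.population: results}, wtp)
        table.to_frame().to_csv(out / "report.csv", index=False)
        (out / "report.md").write_text(table.to_markdown())
        base_cea = table.incrementals[cfg.population]
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("valuate", exc) from exc

    try:
        tornado = cea.run_dsa(fitted, wtp)
        cea.tornado_frame(tornado).to_csv(out / "tornado.csv", index=False)
    except Exception as exc:
        raise PipelineError("dsa", exc) from exc

    try:
        psa = cea.run_psa(fitted, n_iter=n_psa, seed=seed)
        psa.samples.to_csv(out / "psa_samples.csv", index=False)
        psa.ceac.to_csv(out / "ceac.csv", index=False)
        psa.samples[["delta_qaly", "delta_cost"]].to_csv(out / "scatter.csv", index=False)
    except Exception as exc:
        raise PipelineError("psa", exc) from exc

    try:
        scen = cea.run_scenario(fitted, SCENARIO_FAMILY, wtp)
        pd.DataFrame(
            [
                {
                    "family": scen.family,
                    "icer_base": scen.base.icer,
                    "icer_scenario": scen.scenario.icer,
                    "relative_change": scen.relative_change,
                }
            ]
        ).to_csv(out / "scenario.csv", index=False)
    except Exception as exc:
        raise PipelineError("scenario", exc) from exc

    cfg_hash = hashlib.sha256(
        json.dumps(cfg.model_dump(), sort_keys=True, default=str).encode()
    ).hexdigest()
    summary = {
        "version": __version__,
        "python": platform.python_version(),
        "seed": seed,
        "n_psa": n_psa,
        "wtp": wtp,
        "population": cfg.population,
        "config_sha256": cfg_hash,
        "selected_families": {
            f"{e}_{a}": fit.family for (e, a), fit in fitted.selected.items()
        },
        "icer": base_cea.icer,
        "delta_cost": base_cea.delta_cost,
        "delta_qaly": base_cea.delta_qaly,
        "acceptability_at_wtp": psa.acceptability_at(wtp),
        "scenario_relative_change": scen.relative_change,
    }
    (out / "run_log.json").write_text(json.dumps(summary, indent=2))
    return summary
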