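"""Run orchestration: execute an analysis, write its artifacts and manifest.

Every command derives all randomness from a single root seed, writes numeric
outputs (JSON/CSV) deterministically given (config, seed), and records the
artifact list plus a config digest in ``manifest.json``.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Sequence

import numpy as np

from . import __version__
from .errors import CapeceaError
from .parameters import (
    ARMS,
    LifeTable,
    ParameterSet,
    default_life_table,
    load_parameters,
    serialize,
)
from .pipeline import BaseCaseResult, base_case
from .sensitivity import PSAResult, ceac, run_psa, tornado
from .survival_models import fit_all, goodness_of_fit, select_best
from .synthetic_trial import (
    TrialConfig,
    generate_trial,
    kaplan_meier,
    read_records,
    summarize_trial,
    write_records,
)
from .nnt_analysis import nnt_table


@dataclass
class RunManifest:
    command: str
    config_digest: str
    seed: int | None
    version: str = __version__
    timestamp: str = field(
        default_factory=lambda: datetime.now(timezone.utc).isoformat()
    )
    outputs: list[str] = field(default_factory=list)

    def add(self, path: Path) -> Path:
        self.outputs.append(path.name)
        return path

    def write(self, output_dir: Path) -> None:
        path = output_dir / "manifest.json"
        self.outputs.append(path.name)
        path.write_text(json.dumps(self.__dict__, indent=2, sort_keys=True))


def _setup(config_path, output_dir, command: str, seed: int | None):
    params = load_parameters(config_path)
    digest = hashlib.sha256(serialize(params).encode()).hexdigest()[:16]
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    return params, out, RunManifest(command=command, config_digest=digest, seed=seed)


def _dump_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True))


def run_base_case(
    config_path=None, output_dir="results", life_table: LifeTable | None = None
) -> BaseCaseResult:
    """Calibrate, trace both arms, accumulate, compare; write all artifacts."""
    params, out, manifest = _setup(config_path, output_dir, "base-case", None)
    life_table = life_table or default_life_table()
    result = base_case(params, life_table)
    summary = {
        "arms": {
            arm: {
                "total_cost": r.total_cost,
                "total_qaly": r.total_qaly,
                "breakdown": dict(r.breakdown),
                "total_cost_undiscounted": r.total_cost_undiscounted,
                "total_qaly_undiscounted": r.total_qaly_undiscounted,
            }
            for arm, r in result.arm_results.items()
        },
        "delta_cost": result.ce.delta_cost,
        "delta_qaly": result.ce.delta_qaly,
        "icer": result.ce.icer,
        "flag": result.ce.flag,
        "nmb_at_wtp": result.ce.nmb_at_wtp,
        "wtp": result.ce.wtp,
        "cost_effective": result.ce.cost_effective,
    }
    _dump_json(summary, manifest.add(out / "summary.json"))
    for arm in ARMS:
        result.traces[arm].to_frame().to_csv(
            manifest.add(out / f"trace_{arm}.csv"), index=False
        )
    manifest.write(out)
    return result


def run_tornado(config_path=None, output_dir="results") -> list:
    params, out, manifest = _setup(config_path, output_dir, "tornado", None)
    life_table = default_life_table()
    entries = tornado(params, life_table)
    base_icer = base_case(params, life_table).ce.icer
    import pandas as pd

    pd.DataFrame(
        [
            {
                "parameter": e.name,
                "icer_at_low": e.icer_at_low,
                "icer_at_high": e.icer_at_high,
                "spread": e.spread,
            }
            for e in entries
        ]
    ).to_csv(manifest.add(out / "tornado.csv"), index=False)
    from .plots import tornado_plot

    tornado_plot(entries, base_icer, manifest.add(out / "tornado.png"))
    manifest.write(out)
    return entries


def run_psa_cmd(
    config_path=None, n_iter: int = 10_000, seed: int = 0, output_dir="results"
) -> PSAResult:
    params, out, manifest = _setup(config_path, output_dir, "psa", seed)
    life_table = default_life_table()
    psa = run_psa(params, life_table, n_iter=n_iter, seed=seed)
    psa.to_frame().to_csv(manifest.add(out / "psa_draws.csv"), index=False)
    grid = np.linspace(0.0, 3.0e4, 121)
    import pandas as pd

    pd.DataFrame({"wtp": grid, "probability": ceac(psa, grid)}).to_csv(
        manifest.add(out / "ceac.csv"), index=False
    )
    lo, hi, crossers = psa.icer_ci()
    _dump_json(
        {
            "n_iter": psa.n_iter,
            "seed": seed,
            "base_icer": psa.base_icer,
            "prob_cost_effective_at_wtp": psa.prob_cost_effective(),
            "icer_ci_95": [lo, hi],
            "quadrant_crossers": crossers,
            "wtp": psa.wtp,
        },
        manifest.add(out / "psa_summary.json"),
    )
    from .plots import ce_plane, ceac_plot

    ce_plane(psa, manifest.add(out / "ce_plane.png"))
    ceac_plot(psa, manifest.add(out / "ceac.png"))
    manifest.write(out)
    return psa


def run_nnt_cmd(
    ipd_path=None,
    synthetic_seed: int | None = None,
    times: Sequence[float] = (12.0, 24.0, 60.0),
    n_boot: int = 500,
    output_dir="results",
):
    """Adjusted NNT table at landmark times for DFS and OS."""
    if ipd_path is None and synthetic_seed is None:
        raise CapeceaError("provide an IPD file or a synthetic seed")
    _, out, manifest = _setup(None, output_dir, "nnt", synthetic_seed)
    if ipd_path is not None:
        records = read_records(ipd_path)
    else:
        records = generate_trial(TrialConfig(seed=synthetic_seed))
    import pandas as pd

    if len(list(times)) == 0:
        table = pd.DataFrame(
            columns=["endpoint", "time", "arr", "nnt", "ci_low", "ci_high"]
        )
    else:
        table = nnt_table(records, list(times), n_boot=n_boot, seed=synthetic_seed or 0)
    table.to_csv(manifest.add(out / "nnt.csv"), index=False)
    manifest.write(out)
    return table


def run_simulate_trial(seed: int = 0, output_dir="results"):
    _, out, manifest = _setup(None, output_dir, "simulate-trial", seed)
    config = TrialConfig(seed=seed)
    records = generate_trial(config)
    write_records(records, manifest.add(out / "trial_records.csv"), config)
    manifest.outputs.append("trial_records.json")
    _dump_json(summarize_trial(records), manifest.add(out / "trial_summary.json"))
    manifest.write(out)
    return records


def run_fit_survival(ipd_path=None, seed: int = 0, output_dir="results"):
    """Fit all candidate distributions per arm/endpoint and rank them."""
    _, out, manifest = _setup(None, output_dir, "fit-survival", seed)
    records = (
        read_records(ipd_path) if ipd_path else generate_trial(TrialConfig(seed=seed))
    )
    report = {}
    for arm in records["arm"].unique():
        sub = records[records["arm"] == arm]
        report[arm] = {}
        for ep in ("dfs", "os"):
            fits = fit_all(sub[f"{ep}_time"], sub[f"{ep}_event"])
            km = kaplan_meier(records, ep, arm)
            gof = {name: goodness_of_fit(f, km) for name, f in fits.items()}
            best = select_best(fits, gof)
            report[arm][ep] = {
                "selected": best.distribution,
                "candidates": {
                    name: {
                        "params": dict(f.params),
                        "loglik": f.loglik,
                        "aic": gof[name].aic,
                        "bic": gof[name].bic,
                        "sse_vs_km": gof[name].sse_vs_km,
                    }
                    for name, f in fits.items()
                },
            }
    _dump_json(report, manifest.add(out / "survival_fits.json"))
    manifest.write(out)
    return report
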