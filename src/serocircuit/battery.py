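"""Condition battery: run the grid, write tidy tables, compare to reference.

Results are tidy data frames with one row per
(condition, treatment, variant, region, observable): observables are the
replicate-mean post-transient serotonin concentration (``serotonin_nM``)
and excitatory population rate (``rate_hz``), each with its standard error
over replicates.

A reference table of published model predictions for the same grid ships
with the package and backs a regression harness
(:func:`compare_to_reference`).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd

from .interventions import ConditionSpec, build_condition_grid, build_condition_params
from .params import ModelParams, SimulationSettings, params_to_dict
from .simulate import ConditionSummary, run_conditions_batch

__all__ = [
    "BatteryConfig", "run_battery", "summaries_to_table",
    "compare_to_reference", "load_reference_values", "write_results",
]

logger = logging.getLogger("serocircuit")

KEY_COLUMNS = ["condition", "treatment", "variant", "region", "observable"]


@dataclass
class BatteryConfig:
    """What to run and where to write it."""

    base_params: ModelParams = field(default_factory=ModelParams)
    settings: SimulationSettings = field(default_factory=SimulationSettings)
    degrees: list[str] | None = None      # None = all
    treatments: list[str] | None = None
    variants: list[str] | None = None
    out_dir: Path | None = None

    def selected_conditions(self) -> list[ConditionSpec]:
        grid = build_condition_grid()
        sel = [
            spec for spec in grid
            if (self.degrees is None or spec.degree_label in self.degrees)
            and (self.treatments is None or spec.treatment.name in self.treatments)
            and (self.variants is None or spec.variant.name in self.variants)
        ]
        if not sel:
            raise ValueError("selection matches no grid condition")
        return sel


def summaries_to_table(specs: list[ConditionSpec],
                       summaries: list[ConditionSummary]) -> pd.DataFrame:
    rows = []
    for spec, summ in zip(specs, summaries):
        for ridx, region in enumerate(("PFC", "SCC")):
            for obs, mean, sem in (
                ("serotonin_nM", summ.serotonin_mean[ridx], summ.serotonin_sem[ridx]),
                ("rate_hz", summ.rate_E_mean[ridx], summ.rate_E_sem[ridx]),
            ):
                rows.append({
                    "condition": spec.degree_label,
                    "treatment": spec.treatment.name,
                    "variant": spec.variant.name,
                    "region": region,
                    "observable": obs,
                    "mean": float(mean),
                    "sem": float(sem),
                    "n": summ.n_reps,
                    "seed": summ.base_seed,
                })
    return pd.DataFrame(rows)


def run_battery(config: BatteryConfig) -> pd.DataFrame:
    """Run every selected condition (n_reps replicates each).

    Deterministic given the base seed: each condition reuses the same
    replicate seed block, so the output is invariant to execution order
    and to which subset of conditions is selected.
    """
    specs = config.selected_conditions()
    params = [build_condition_params(s, config.base_params) for s in specs]
    logger.info("battery: %d conditions x %d replicates, base_seed=%d",
                len(specs), config.settings.n_reps, config.settings.base_seed)
    try:
        summaries = run_conditions_batch(
            params, config.settings,
            metas=[{"condition": s.key} for s in specs])
    except Exception as err:
        raise RuntimeError(f"battery failed: {err}") from err
    for s, summ in zip(specs, summaries):
        logger.info("condition %s: PFC 5HT %.2f nM, rate %.3f Hz",
                    s.key, summ.serotonin_mean[0], summ.rate_E_mean[0])
    table = summaries_to_table(specs, summaries)
    if config.out_dir is not None:
        write_results(table, config, Path(config.out_dir))
    return table


def write_results(table: pd.DataFrame, config: BatteryConfig,
                  out_dir: Path) -> None:
    """Write the tidy CSV plus a JSON provenance mirror."""
    out_dir.mkdir(parents=True, exist_ok=True)
    table.to_csv(out_dir / "results.csv", index=False)
    provenance = {
        "settings": {
            "dt_s": config.settings.dt,
            "duration_s": config.settings.duration,
            "transient_s": config.settings.transient,
            "sigma": config.settings.sigma,
            "n_reps": config.settings.n_reps,
            "base_seed": config.settings.base_seed,
        },
        "base_params": params_to_dict(config.base_params),
        "selection": {"degrees": config.degrees, "treatments": config.treatments,
                      "variants": config.variants},
    }
    with open(out_dir / "provenance.json", "w") as fh:
        json.dump(provenance, fh, indent=2)


def load_reference_values() -> pd.DataFrame:
    """Published model predictions (mean, sem) for the condition grid.

    Only the grid cells with published numerical values are present.
    """
    path = resources.files("serocircuit.data") / "reference_values.csv"
    with resources.as_file(path) as p:
        return pd.read_csv(p)


def compare_to_reference(table: pd.DataFrame, reference: pd.DataFrame,
                         rel_tol: float = 0.10) -> pd.DataFrame:
    """Row-wise relative deviation of ``table`` from ``reference``.

    Every reference key must be present in ``table``; a missing key raises
    with the offending keys listed.  Returns the merged frame with columns
    ``rel_dev`` and ``passed`` (|rel_dev| <= rel_tol); the summary counts
    live in ``df.attrs['n_pass']`` / ``df.attrs['n_fail']``.
    """
    merged = reference.merge(table, on=KEY_COLUMNS, how="left",
                             suffixes=("_ref", ""))
    missing = merged[merged["mean"].isna()]
    if len(missing):
        keys = missing[KEY_COLUMNS].to_records(index=False).tolist()
        raise KeyError(f"results table is missing reference keys: {keys}")
    merged["rel_dev"] = (merged["mean"] - merged["mean_ref"]) / merged["mean_ref"]
    merged["passed"] = merged["rel_dev"].abs() <= rel_tol
    merged.attrs["n_pass"] = int(merged["passed"].sum())
    merged.attrs["n_fail"] = int((~merged["passed"]).sum())
    merged.attrs["max_abs_rel_dev"] = float(merged["rel_dev"].abs().max())
    return merged


def grid_manifest(base_params: ModelParams | None = None) -> pd.DataFrame:
    """Effective key parameters for every grid condition (provenance export)."""
    rows = []
    for spec in build_condition_grid():
        p = build_condition_params(spec, base_params)
        rows.append({
            "condition": spec.degree_label, "treatment": spec.treatment.name,
            "variant": spec.variant.name, "degree": p.inflammation.degree,
            "Km_nM": p.kin_pfc.Km, "B": p.inflammation.B,
            "R_pfc": p.pfc.R, "R_scc": p.scc.R,
            "tau_NMDA_scc_ms": p.scc.tau_NMDA * 1e3,
        })
    return pd.DataFrame(rows)
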