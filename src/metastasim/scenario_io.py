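"""Scenario configuration files, packaged drug-case fixtures and reports.

A scenario file is a YAML document bundling the compartment graph, the
driver order, the kinetic parameters, the population constraints, the
run settings and an optional drug signature.  Three fixtures reproducing
the published drug cases for breast -> circulatory system -> bone ship with
the package (``case1``: kill every CTC with exactly one driver, ``case2``:
with exactly two drivers, ``case3``: every CTC carrying the CD47 mutation).

Fixture kinetic amplitudes, support windows, clock parameters, capacities
and times are calibrated to place the qualitative ordered-vs-unordered and
drug-response regimes at desk scale; they are flagged as calibrated, not
literature-derived, in each file's provenance field.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from fractions import Fraction
from importlib import resources
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from .ca_engine import EnsembleResult, SimulationConfig, run_ensemble
from .kinetics import EnergyModel, KineticsParams
from .path_model import CompartmentGraph, driver_order_from_path, most_probable_paths
from .state_space import ConfigurationError, DriverOrderSpec, DrugSignature, fraction_targeted

_TOP_KEYS = {
    "name",
    "description",
    "provenance",
    "compartments",
    "ordered_mode",
    "kinetics",
    "bounds",
    "constraints",
    "simulation",
    "drug",
}
VARIANTS = (
    ("ordered", "drug"),
    ("ordered", "no-drug"),
    ("unordered", "drug"),
    ("unordered", "no-drug"),
)


class ScenarioError(ConfigurationError):
    """Schema violation in a scenario file; message lists every failing field."""


@dataclass(frozen=True)
class Scenario:
    """A fully validated simulation scenario."""

    name: str
    description: str
    provenance: str
    graph: CompartmentGraph
    path: tuple[int, ...]
    order: DriverOrderSpec
    params: KineticsParams
    config: SimulationConfig

    def with_variant(self, mode: str, drug: str) -> tuple[DriverOrderSpec, SimulationConfig]:
        """Order spec and run config for one (mode, drug) variant."""
        order = replace(self.order, ordered_mode=(mode == "ordered"))
        if drug == "no-drug":
            config = replace(self.config, t_drug=None, drug=None)
        else:
            config = self.config
        return order, config


def _require(cond: bool, errors: list[str], msg: str) -> None:
    if not cond:
        errors.append(msg)


def scenario_from_dict(doc: Mapping[str, Any]) -> Scenario:
    """Build and cross-validate a Scenario from a parsed YAML document."""
    errors: list[str] = []
    unknown = set(doc) - _TOP_KEYS
    if unknown:
        raise ScenarioError(
            f"unknown scenario keys: {sorted(unknown)}; allowed: {sorted(_TOP_KEYS)}"
        )
    for key in ("name", "compartments", "kinetics", "bounds", "simulation"):
        _require(key in doc, errors, f"missing required section {key!r}")
    if errors:
        raise ScenarioError("; ".join(errors))

    comp = doc["compartments"]
    labels = tuple(comp["labels"])
    graph = CompartmentGraph(
        labels=labels,
        transition=tuple(tuple(row) for row in comp["transition_matrix"]),
        n_secondary=int(comp.get("n_secondary", 1)),
        required_drivers=tuple(
            tuple(comp["required_drivers"].get(lab, ())) for lab in labels
        ),
    )
    paths = most_probable_paths(graph)
    _require(bool(paths), errors, "compartment graph admits no positive-density path")
    path = paths[0][0] if paths else (1,)
    ordered_mode = bool(doc.get("ordered_mode", True))
    order = driver_order_from_path(graph, path, ordered_mode=ordered_mode)

    kin = doc["kinetics"]
    bounds = doc["bounds"]
    _require(
        bounds["m_d"] == order.n_loci,
        errors,
        f"bounds.m_d ({bounds['m_d']}) must equal the number of required driver genes "
        f"({order.n_loci})",
    )
    _require(
        bounds["k"] == len(path),
        errors,
        f"bounds.k ({bounds['k']}) must equal the path length ({len(path)})",
    )
    try:
        params = KineticsParams(
            alpha=float(kin["alpha"]),
            r=float(kin["r"]),
            amplitudes={a: float(v) for a, v in kin["amplitudes"].items()},
            centers={a: float(v) for a, v in kin["centers"].items()},
            width=float(kin["width"]),
            s_bar=float(kin["s_bar"]),
            driver_split_beta=float(kin.get("driver_split_beta", 1.0)),
            m_d_max=int(bounds["m_d"]),
            m_n_max=int(bounds["m_n"]),
            m_m_max=int(bounds["m_m"]),
            k_max=int(bounds["k"]),
        )
    except (ValueError, KeyError) as exc:
        errors.append(f"kinetics: {exc}")
        params = None  # type: ignore[assignment]

    cons = doc.get("constraints", {}) or {}
    e_map = cons.get("energy") or None
    if e_map:
        raw = e_map["E_max"]
        e_max = (
            {int(k): float(v) for k, v in raw.items()}
            if isinstance(raw, Mapping)
            else float(raw)
        )
    energy = EnergyModel(
        e={int(k): float(v) for k, v in e_map["e"].items()} if e_map else None,
        E_max=e_max if e_map else None,
        capacity=int(cons["capacity"]) if cons.get("capacity") else None,
    )

    drug_doc = doc.get("drug")
    drug = None
    t_drug = None
    if drug_doc is not None:
        drug = DrugSignature(
            d_drug=tuple(int(x) for x in drug_doc["d"]),
            m_n_drug=int(drug_doc.get("m_n", 0)),
            m_m_drug=int(drug_doc.get("m_m", 0)),
            k_drug=int(drug_doc.get("k", 0)),
            m_d_drug=int(drug_doc.get("m_d", 0)),
            t_drug=float(drug_doc["t"]),
        )
        t_drug = drug.t_drug
        _require(
            len(drug.d_drug) == bounds["m_d"],
            errors,
            f"drug.d has length {len(drug.d_drug)}, expected {bounds['m_d']}",
        )

    sim = doc["simulation"]
    _require(
        t_drug is None or t_drug < float(sim["t_end"]),
        errors,
        f"drug.t ({t_drug}) must precede simulation.t_end ({sim['t_end']})",
    )
    if errors:
        raise ScenarioError("; ".join(errors))

    config = SimulationConfig(
        initial_cells=int(sim["initial_cells"]),
        t_end=float(sim["t_end"]),
        record_dt=float(sim["record_dt"]),
        replicates=int(sim.get("replicates", 1)),
        seed=int(sim.get("seed", 0)),
        t_drug=t_drug,
        drug=drug,
        energy=energy,
    )
    return Scenario(
        name=str(doc["name"]),
        description=str(doc.get("description", "")),
        provenance=str(doc.get("provenance", "")),
        graph=graph,
        path=tuple(path),
        order=order,
        params=params,
        config=config,
    )


def scenario_to_dict(sc: Scenario) -> dict[str, Any]:
    """Inverse of :func:`scenario_from_dict` (round-trip identity)."""
    doc: dict[str, Any] = {
        "name": sc.name,
        "description": sc.description,
        "provenance": sc.provenance,
        "compartments": {
            "labels": list(sc.graph.labels),
            "transition_matrix": [list(row) for row in sc.graph.transition],
            "n_secondary": sc.graph.n_secondary,
            "required_drivers": {
                lab: list(req)
                for lab, req in zip(sc.graph.labels, sc.graph.required_drivers)
            },
        },
        "ordered_mode": sc.order.ordered_mode,
        "kinetics": {
            "alpha": sc.params.alpha,
            "r": sc.params.r,
            "amplitudes": dict(sc.params.amplitudes),
            "centers": dict(sc.params.centers),
            "width": sc.params.width,
            "s_bar": sc.params.s_bar,
            "driver_split_beta": sc.params.driver_split_beta,
        },
        "bounds": {
            "m_d": sc.params.m_d_max,
            "m_n": sc.params.m_n_max,
            "m_m": sc.params.m_m_max,
            "k": sc.params.k_max,
        },
        "constraints": {
            "capacity": sc.config.energy.capacity,
            "energy": (
                {
                    "e": dict(sc.config.energy.e),
                    "E_max": (
                        dict(sc.config.energy.E_max)
                        if isinstance(sc.config.energy.E_max, Mapping)
                        else sc.config.energy.E_max
                    ),
                }
                if sc.config.energy.e is not None
                else None
            ),
        },
        "simulation": {
            "initial_cells": sc.config.initial_cells,
            "t_end": sc.config.t_end,
            "record_dt": sc.config.record_dt,
            "replicates": sc.config.replicates,
            "seed": sc.config.seed,
        },
    }
    if sc.config.drug is not None:
        d = sc.config.drug
        doc["drug"] = {
            "d": list(d.d_drug),
            "m_n": d.m_n_drug,
            "m_m": d.m_m_drug,
            "k": d.k_drug,
            "m_d": d.m_d_drug,
            "t": d.t_drug,
        }
    return doc


def load_scenario(path: str | Path) -> Scenario:
    """Load and validate a scenario YAML file."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise ScenarioError(f"{path}: scenario file must be a YAML mapping")
    return scenario_from_dict(doc)


def save_scenario(sc: Scenario, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(scenario_to_dict(sc), fh, sort_keys=False)


def load_packaged(name: str) -> Scenario:
    """Load one of the packaged fixtures: 'case1', 'case2' or 'case3'."""
    ref = resources.files("metastasim") / "scenarios" / f"{name}.yaml"
    with resources.as_file(ref) as p:
        return load_scenario(p)


def run_case(
    scenario: Scenario,
    out_dir: str | Path | None = None,
    variants: tuple[tuple[str, str], ...] = VARIANTS,
    replicates: int | None = None,
    seed: int | None = None,
    make_plot: bool = True,
) -> dict[str, Any]:
    """Run the ordered/unordered x drug/no-drug ensembles of a scenario.

    Writes per-variant tidy CSV trajectories, a combined figure with a
    vertical marker at the drug time, and a JSON summary (final counts per
    compartment, extinction flag, time of first bone seeding).  Returns the
    summary together with the in-memory ensemble results.
    """
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    results: dict[str, EnsembleResult] = {}
    summary: dict[str, Any] = {"scenario": scenario.name, "variants": {}}
    for mode, drug in variants:
        order, config = scenario.with_variant(mode, drug)
        if replicates is not None:
            config = replace(config, replicates=replicates)
        if seed is not None:
            config = replace(config, seed=seed)
        key = f"{mode}_{drug.replace('-', '_')}"
        ens = run_ensemble(config, scenario.params, order)
        results[key] = ens
        k_last = scenario.params.k_max
        bone = ens.mean[:, k_last - 1, :].sum(axis=1)
        seeded = np.nonzero(bone > 0)[0]
        summary["variants"][key] = {
            "final_counts_per_compartment": {
                scenario.graph.labels[k - 1]: float(ens.mean[-1, k - 1, :].sum())
                for k in range(1, k_last + 1)
            },
            "final_total": float(ens.mean[-1].sum()),
            "extinct": bool(ens.mean[-1].sum() == 0),
            "first_bone_seeding_time": (
                float(ens.times[seeded[0]]) if seeded.size else None
            ),
        }
        if out is not None:
            ens.to_dataframe().to_csv(out / f"{key}.csv", index=False)
    if out is not None:
        with open(out / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2)
        if make_plot:
            plot_case(scenario, results, out / f"{scenario.name}.png")
    summary["results"] = results
    return summary


def plot_case(
    scenario: Scenario,
    results: Mapping[str, EnsembleResult],
    path: str | Path,
) -> None:
    """Figure: rows = variants, columns = compartments, one curve per m_d."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    k_max = scenario.params.k_max
    nrow = len(results)
    fig, axes = plt.subplots(
        nrow, k_max, figsize=(3.2 * k_max, 2.2 * nrow), sharex=True, squeeze=False
    )
    for i, (key, ens) in enumerate(results.items()):
        for k in range(k_max):
            ax = axes[i][k]
            for m_d in range(scenario.params.m_d_max + 1):
                ax.plot(ens.times, ens.mean[:, k, m_d], label=f"$m_d$={m_d}", lw=1)
            if scenario.config.t_drug is not None and not key.endswith("no_drug"):
                ax.axvline(scenario.config.t_drug, color="k", ls="--", lw=0.8)
            if i == 0:
                ax.set_title(scenario.graph.labels[k])
            if k == 0:
                ax.set_ylabel(key.replace("_", " "), fontsize=8)
    axes[0][-1].legend(fontsize=6)
    axes[-1][0].set_xlabel("time (simulation units)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def combinatorics_report(
    scenario: Scenario, m_d_values: tuple[int, ...] = (1, 2, 3)
) -> pd.DataFrame:
    """Exact fraction of viable driver combinations the drug targets.

    Evaluates :func:`~metastasim.state_space.fraction_targeted` in the
    drug's compartment for both ordered and unordered dynamics; fractions
    are exact rationals, printed alongside decimals.
    """
    if scenario.config.drug is None:
        raise ScenarioError(f"scenario {scenario.name!r} has no drug signature")
    sig = scenario.config.drug
    compartment = sig.k_drug or 1
    rows = []
    for mode in ("ordered", "unordered"):
        order = replace(scenario.order, ordered_mode=(mode == "ordered"))
        for m_d in m_d_values:
            frac = fraction_targeted(sig, order, m_d, compartment)
            rows.append(
                {
                    "mode": mode,
                    "m_d": m_d,
                    "fraction": str(frac) if frac is not None else "undefined",
                    "decimal": float(frac) if frac is not None else np.nan,
                }
            )
    return pd.DataFrame(rows)
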