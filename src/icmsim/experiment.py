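"""End-to-end in-silico experiment pipeline.

One repetition runs: initialise a relaxed spheroid of undifferentiated
cells -> grow to the fate-assignment count t0 -> back-solve the initial
proportions that will hit the target proportions at t1 under the chosen
heredity hypothesis -> assign fates i.i.d. -> grow (with heredity at each
division) to the t1 cell count (snapshot) and on to the t2 count
(snapshot).  The experiment repeats this over ``n_reps`` seeds and then
computes neighbourhood compositions, the effect size psi against a
reference dataset (user-supplied organoid tables, or a synthetic set),
rank-sum significance tables and radial profiles.

Per-repetition seeds are ``base_seed + repetition index``; completed
repetitions found on disk are not recomputed on rerun.
"""
from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as icmio
from .core_model import MechanicsParams, init_spheroid, run_until_count
from .fate_model import (HeredityModel, as_proportions, assign_initial_fates,
                         back_solve_t0, daughter_matrix, heredity_model,
                         inherit)
from .neighbourhood import (compare_compositions, delaunay_adjacency,
                            effect_size_psi, neighbourhood_composition,
                            same_type_enrichment)
from .spatial import radial_profile
from .synthetic import SyntheticSpec, generate_organoid_set
from .types import etype_codes

__all__ = ["ExperimentConfig", "simulate_replicate", "run_experiment",
           "composition_of_table"]

# Synthetic stand-in proportion targets (order NpGp, NnGn, NpGn, NnGp); the
# study's measured organoid proportions are not bundled with the package.
DEFAULT_P_T1 = (0.15, 0.10, 0.40, 0.35)
DEFAULT_P_T2 = (0.07, 0.05, 0.35, 0.53)


@dataclass
class ExperimentConfig:
    """Full configuration of one simulated experiment."""

    hypothesis: str = "H1"
    rates: dict = field(default_factory=dict)
    forced_asymmetric: bool = False
    init_count: int = 200
    t0_count: int = 200
    t1_count: int = 441
    t2_count: int = 1041
    n_reps: int = 100
    base_seed: int = 0
    p_t1: tuple = DEFAULT_P_T1
    p_t2: tuple = DEFAULT_P_T2
    mechanics: MechanicsParams = field(default_factory=MechanicsParams)
    relax_steps: int = 200
    packing: float = 0.4
    reference_dir: str | None = None
    n_reference: int = 10           # synthetic reference organoids if no dir
    reference_clustering: float = 0.5
    out_dir: str | None = None

    def __post_init__(self):
        if not (self.init_count <= self.t0_count <= self.t1_count
                <= self.t2_count):
            raise ValueError("need init_count <= t0_count <= t1_count "
                             "<= t2_count")
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")
        self.p_t1 = tuple(float(v) for v in as_proportions(self.p_t1))
        self.p_t2 = tuple(float(v) for v in as_proportions(self.p_t2))
        if isinstance(self.mechanics, dict):
            self.mechanics = MechanicsParams(**self.mechanics)

    def heredity(self) -> HeredityModel:
        return heredity_model(self.hypothesis, self.rates,
                              forced_asymmetric=self.forced_asymmetric)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["mechanics"] = asdict(self.mechanics)
        return d

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if "mechanics" in data and isinstance(data["mechanics"], dict):
            data["mechanics"] = MechanicsParams(**data["mechanics"])
        return cls(**data)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict()))


def simulate_replicate(config: ExperimentConfig, seed: int):
    """Run one repetition; returns (table_t1, table_t2, p0)."""
    model = config.heredity()
    p0 = back_solve_t0(config.p_t1, daughter_matrix(model),
                       config.t0_count, config.t1_count)
    state = init_spheroid(config.init_count, config.mechanics, seed=seed,
                          relax_steps=config.relax_steps,
                          packing=config.packing)
    if config.t0_count > state.n_cells:
        run_until_count(state, config.mechanics, config.t0_count)
    assign_initial_fates(state, p0)
    inherit_fn = lambda m, rng: inherit(m, model, rng)
    run_until_count(state, config.mechanics, config.t1_count, inherit_fn)
    t1 = icmio.state_to_table(state)
    run_until_count(state, config.mechanics, config.t2_count, inherit_fn)
    t2 = icmio.state_to_table(state)
    return t1, t2, p0


def composition_of_table(table: pd.DataFrame):
    """Delaunay neighbourhood composition of one cell table."""
    pos = table[["x", "y", "z"]].to_numpy(dtype=float)
    graph = delaunay_adjacency(pos)
    return neighbourhood_composition(table["etype"], graph)


def _load_reference(config: ExperimentConfig):
    """Reference organoid tables per timepoint label."""
    if config.reference_dir is not None:
        ref_dir = Path(config.reference_dir)
        manifest = pd.read_csv(ref_dir / "manifest.csv")
        tables = {"t1": [], "t2": []}
        for _, row in manifest.iterrows():
            table = icmio.read_cell_table(
                ref_dir / f"organoid_{int(row.organoid):03d}_{row.timepoint}.csv")
            tables[str(row.timepoint)].append(table)
        return tables, "experimental"
    spec1 = SyntheticSpec(n_cells=config.t1_count, proportions=config.p_t1,
                          clustering_strength=config.reference_clustering,
                          seed=config.base_seed + 10_000)
    spec2 = SyntheticSpec(n_cells=config.t2_count, proportions=config.p_t2,
                          clustering_strength=config.reference_clustering,
                          seed=config.base_seed + 10_000)
    raw, _ = generate_organoid_set(spec1, spec2, config.n_reference)
    tables = {"t1": [], "t2": []}
    for (org, label), table in raw.items():
        tables[label].append(table)
    return tables, "synthetic"


def run_experiment(config: ExperimentConfig) -> dict:
    """Run all repetitions plus analyses; returns the results bundle.

    If ``config.out_dir`` is set, snapshots, the manifest, the config and a
    summary are written there, and repetitions whose snapshot files already
    exist are skipped (resumable reruns are bit-identical because every
    repetition has its own derived seed).
    """
    out = None if config.out_dir is None else Path(config.out_dir)
    if out is not None:
        (out / "reps").mkdir(parents=True, exist_ok=True)
        config.to_yaml(out / "config.yaml")
    cfg_dict = config.to_dict()

    snapshots = {"t1": [], "t2": []}
    manifest_rows = []
    for rep in range(config.n_reps):
        seed = config.base_seed + rep
        paths = None
        if out is not None:
            paths = {lab: out / "reps" / f"rep{rep:04d}_{lab}.csv"
                     for lab in ("t1", "t2")}
        if paths is not None and all(p.exists() for p in paths.values()):
            t1 = icmio.read_cell_table(paths["t1"])
            t2 = icmio.read_cell_table(paths["t2"])
            status = "resumed"
        else:
            t1, t2, _ = simulate_replicate(config, seed)
            status = "computed"
            if paths is not None:
                for lab, table in (("t1", t1), ("t2", t2)):
                    table.to_csv(paths[lab], index=False)
                    meta = {"n_cells": int(len(table)), "seed": seed,
                            "config_hash": icmio.config_hash(cfg_dict)}
                    Path(str(paths[lab]) + ".meta.json").write_text(
                        json.dumps(meta))
        snapshots["t1"].append(t1)
        snapshots["t2"].append(t2)
        manifest_rows.append((rep, seed, len(t1), len(t2), status))
    manifest = pd.DataFrame(manifest_rows, columns=[
        "rep", "seed", "n_t1", "n_t2", "status"])

    reference, ref_kind = _load_reference(config)
    results: dict = {"config": cfg_dict, "reference_kind": ref_kind,
                     "manifest": manifest}
    for lab, target_p in (("t1", config.p_t1), ("t2", config.p_t2)):
        sim_stats = [composition_of_table(t) for t in snapshots[lab]]
        ref_stats = [composition_of_table(t) for t in reference[lab]]
        sim_mean = np.nanmean([s.composition for s in sim_stats], axis=0)
        ref_mean = np.nanmean([s.composition for s in ref_stats], axis=0)
        psi, psi_meta = effect_size_psi(sim_mean, ref_mean)
        report = compare_compositions(sim_stats, ref_stats)
        enrich = np.array([
            same_type_enrichment(s, _observed_proportions(t))
            for s, t in zip(sim_stats, snapshots[lab])])
        profile = radial_profile(snapshots[lab])
        results[lab] = {
            "psi": psi, "psi_meta": psi_meta,
            "composition_mean": sim_mean,
            "reference_composition_mean": ref_mean,
            "ranksum_report": report,
            "same_type_enrichment_mean": np.nanmean(enrich, axis=0),
            "radial_profile": profile,
        }
    if out is not None:
        manifest.to_csv(out / "manifest.csv", index=False)
        summary = {
            "reference_kind": ref_kind,
            "config_hash": icmio.config_hash(cfg_dict),
            **{lab: {
                "psi": results[lab]["psi"],
                "n_significant": int(results[lab]["ranksum_report"]
                                     ["significant"].sum()),
                "same_type_enrichment_mean":
                    results[lab]["same_type_enrichment_mean"].tolist(),
            } for lab in ("t1", "t2")},
        }
        (out / "summary.json").write_text(json.dumps(summary, indent=2))
        for lab in ("t1", "t2"):
            results[lab]["ranksum_report"].to_csv(
                out / f"ranksum_{lab}.csv", index=False)
            results[lab]["radial_profile"].to_frame().to_csv(
                out / f"radial_{lab}.csv", index=False)
    return results


def _observed_proportions(table: pd.DataFrame) -> np.ndarray:
    codes = etype_codes(table["etype"])
    counts = np.bincount(codes, minlength=4)
    return counts / counts.sum()
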