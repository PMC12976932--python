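"""End-to-end pipeline orchestration: maps -> GLM -> similarity ->
subspaces -> CCGP, with per-stage toggles, seed bookkeeping and a manifest.

Every source of randomness derives from one root seed through named
``numpy.random.SeedSequence`` child streams, so any stage can be reproduced
in isolation from the manifest.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd

from . import ccgp as ccgp_mod
from . import glm as glm_mod
from . import maps as maps_mod
from . import similarity as sim_mod
from . import subspaces as sub_mod
from .core import Session
from .grid import Grid
from .io import _jsonable

STAGES = ("maps", "glm", "similarity", "subspaces", "ccgp")


@dataclass
class PipelineConfig:
    variables: tuple[str, ...] = ("self", "chosen_prey")
    stages: tuple[str, ...] = STAGES
    smoothing_sd: float = 0.5
    alpha: float = 0.05
    k_pca: int = 10
    subspace_dims: int = 4
    chunk_s: float = 40.0
    ccgp_reps: int = 50
    ccgp_shuffles: int = 500
    n_perm: int = 1000
    n_splits: int = 200
    beta_grid: tuple[float, ...] = glm_mod.DEFAULT_BETA_GRID
    seed: int = 0

    def validate(self) -> None:
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stage(s): {sorted(unknown)}")


@dataclass
class RunManifest:
    config: dict
    stage_seconds: dict[str, float] = field(default_factory=dict)
    seed_ledger: dict[str, int] = field(default_factory=dict)
    output_hashes: dict[str, str] = field(default_factory=dict)
    skipped: list[str] = field(default_factory=list)
    dropped_counts: dict[str, int] = field(default_factory=dict)


def _hash_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _stage_seed(root: int, stage: str) -> int:
    h = hashlib.sha256(f"{root}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "little") % (2**31)


def run_pipeline(
    session: Session, config: PipelineConfig, out_dir: str | Path
) -> RunManifest:
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    grid = Grid(*session.field_size)
    manifest = RunManifest(config=_jsonable(config.__dict__))
    summary: dict = {}

    def _finish(stage: str, t0: float, files: list[Path]) -> None:
        manifest.stage_seconds[stage] = round(time.time() - t0, 3)
        for f in files:
            manifest.output_hashes[f.name] = _hash_file(f)

    variables = config.variables
    pop_mats = None
    rate_maps: dict[str, list] = {}

    if "maps" in config.stages:
        t0 = time.time()
        pop_mats = maps_mod.population_matrices(
            session, list(variables), grid, config.smoothing_sd
        )
        for v in variables:
            rate_maps[v] = maps_mod.session_rate_maps(
                session, v, grid, config.smoothing_sd
            )
        frames = [maps_mod.maps_frame(rate_maps[v]) for v in variables]
        f = out / "maps.csv"
        pd.concat(frames, ignore_index=True).to_csv(f, index=False)
        _finish("maps", t0, [f])
    else:
        manifest.skipped.append("maps")

    if "glm" in config.stages and pop_mats is not None:
        t0 = time.time()
        seed = _stage_seed(config.seed, "glm")
        manifest.seed_ledger["glm"] = seed
        bins = {
            v: maps_mod.bin_position(session.trajectories[v], grid, session)
            for v in variables
        }
        records = []
        for i in range(session.spikes.n_neurons):
            model = glm_mod.select_model(
                bins,
                session.spikes.counts[:, i],
                neuron_id=i,
                candidates=variables,
                alpha=config.alpha,
                beta_grid=config.beta_grid,
                dt=session.frame_dt,
            )
            pred_corr = np.nan
            if model.tuned:
                design = glm_mod.build_design_matrix(
                    [bins[v] for v in model.selected_variables]
                )
                pred_corr = glm_mod.model_prediction_quality(
                    model.fit, design, session.spikes.counts[:, i]
                )
            records.append(
                {
                    "neuron_id": i,
                    "tuned": model.tuned,
                    "selected_variables": ";".join(model.selected_variables),
                    "mean_cv_llh_bits_per_spike": model.mean_cv_llh,
                    "pred_corr": pred_corr,
                }
            )
        f = out / "tuning.csv"
        pd.DataFrame(records).to_csv(f, index=False)
        summary["tuned_fraction"] = float(np.mean([r["tuned"] for r in records]))
        summary["tuned_per_variable"] = {
            v: float(
                np.mean([v in r["selected_variables"].split(";") for r in records])
            )
            for v in variables
        }
        _finish("glm", t0, [f])
    elif "glm" in config.stages:
        manifest.skipped.append("glm")

    if "similarity" in config.stages and pop_mats is not None:
        t0 = time.time()
        seed = _stage_seed(config.seed, "similarity")
        manifest.seed_ledger["similarity"] = seed
        rows = []
        api_rows = []
        sim_summary = {}
        for a, b in combinations(variables, 2):
            raw_a, raw_b = pop_mats[a].raw, pop_mats[b].raw
            for j, nid in enumerate(pop_mats[a].neuron_ids):
                try:
                    s, p = sim_mod.spaef_permutation_p(
                        raw_a[j], raw_b[j], n_perm=config.n_perm,
                        seed=seed + j,
                    )
                except sim_mod.DegenerateMapError:
                    s, p = np.nan, np.nan
                rows.append(
                    {"neuron_id": int(nid), "pair": f"{a}-{b}",
                     "spaef": s, "p": p}
                )
            api = sim_mod.agent_preference_indices(
                raw_a, raw_b, pair=(a, b), seed=seed
            )
            for nid, val in zip(pop_mats[a].neuron_ids, api.api):
                api_rows.append(
                    {"neuron_id": int(nid), "pair": f"{a}-{b}", "api": val}
                )
            sim_summary[f"{a}-{b}"] = {
                "median_spaef": float(
                    np.nanmedian([r["spaef"] for r in rows
                                  if r["pair"] == f"{a}-{b}"])
                ),
                "dip": api.dip,
                "dip_p": api.dip_p,
            }
        corr = sim_mod.correlation_structure(pop_mats, reference=variables[0])
        sim_summary["cross_matrix_r2"] = {
            f"{a}-{b}": r for (a, b), r in corr.cross_matrix_r2.items()
        }
        f1 = out / "similarity.csv"
        pd.DataFrame(rows).to_csv(f1, index=False)
        f2 = out / "api.csv"
        pd.DataFrame(api_rows).to_csv(f2, index=False)
        f3 = out / "similarity_summary.json"
        f3.write_text(json.dumps(_jsonable(sim_summary), indent=1))
        summary["similarity"] = sim_summary
        _finish("similarity", t0, [f1, f2, f3])
    elif "similarity" in config.stages:
        manifest.skipped.append("similarity")

    if "subspaces" in config.stages and pop_mats is not None:
        t0 = time.time()
        seed = _stage_seed(config.seed, "subspaces")
        manifest.seed_ledger["subspaces"] = seed
        geo: dict = {"pairs": {}}
        c_list = [sub_mod.neuron_covariance(pop_mats[v]) for v in variables]
        d_list = [config.subspace_dims] * len(variables)
        basis = sub_mod.optimize_orthogonal_subspaces(
            c_list, d_list, variables=variables, seed=seed
        )
        geo["var_captured"] = basis.var_captured
        for a, b in combinations(variables, 2):
            ai = sub_mod.alignment_index(
                pop_mats[a], pop_mats[b], k=config.k_pca, seed=seed
            )
            x_a = sub_mod.project_onto_basis(pop_mats[a], basis.bases[a])
            x_b = sub_mod.project_onto_basis(pop_mats[b], basis.bases[b])
            lm = sub_mod.fit_linear_map(x_a, x_b, seed=seed)
            geo["pairs"][f"{a}-{b}"] = {
                "alignment_index": ai.ai,
                "alignment_p": ai.p,
                "linear_map_r2_train": lm.r2_train,
                "linear_map_r2_loocv": lm.r2_loocv,
                "linear_map_p": lm.p,
            }
        pca = sub_mod.pca_cross_variance(
            pop_mats[variables[0]],
            [pop_mats[v] for v in variables],
            k=config.k_pca,
        )
        geo["pca_var_explained"] = pca.var_explained
        f1 = out / "geometry.json"
        f1.write_text(json.dumps(_jsonable(geo), indent=1))
        loadings = []
        for v in variables:
            for j, nid in enumerate(pop_mats[v].neuron_ids):
                for dim in range(config.subspace_dims):
                    loadings.append(
                        {"variable": v, "neuron_id": int(nid), "dim": dim,
                         "loading": float(basis.bases[v][j, dim])}
                    )
        f2 = out / "bases.csv"
        pd.DataFrame(loadings).to_csv(f2, index=False)
        summary["geometry"] = geo
        _finish("subspaces", t0, [f1, f2])
    elif "subspaces" in config.stages:
        manifest.skipped.append("subspaces")

    if "ccgp" in config.stages:
        t0 = time.time()
        seed = _stage_seed(config.seed, "ccgp")
        manifest.seed_ledger["ccgp"] = seed
        chunks = ccgp_mod.chunk_session(session, config.chunk_s,
                                        variables, grid)
        designs = {
            v: ccgp_mod.build_ccgp_design(chunks, v) for v in variables
        }
        results = {}
        for a, b in combinations(variables, 2):
            res = ccgp_mod.ccgp_null(
                designs[a], designs[b],
                n_shuffles=config.ccgp_shuffles,
                n_reps=config.ccgp_reps, seed=seed,
            )
            results[f"{a}->{b}"] = {
                "ccgp": res.ccgp, "p": res.p, "direction": res.direction,
                "per_rep": res.per_rep,
            }
        geo_ax = ccgp_mod.axis_geometry(designs)
        f1 = out / "ccgp.json"
        f1.write_text(json.dumps(_jsonable(results), indent=1))
        f2 = out / "mds.csv"
        pd.DataFrame(
            {
                "variable": list(geo_ax.variables),
                "dim1": geo_ax.mds_coords[:, 0],
                "dim2": geo_ax.mds_coords[:, 1],
            }
        ).to_csv(f2, index=False)
        summary["ccgp"] = {
            k: {kk: vv for kk, vv in v.items() if kk != "per_rep"}
            for k, v in results.items()
        }
        manifest.dropped_counts["ccgp_rows"] = sum(
            d.n_dropped for d in designs.values()
        )
        _finish("ccgp", t0, [f1, f2])
    elif "ccgp" in config.stages:
        manifest.skipped.append("ccgp")

    (out / "summary.json").write_text(json.dumps(_jsonable(summary), indent=1))
    (out / "manifest.json").write_text(
        json.dumps(_jsonable(manifest.__dict__), indent=1)
    )
    return manifest
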