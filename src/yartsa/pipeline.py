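"""End-to-end orchestration: simulate -> distances -> IBD/sweeps ->
cophylogeny -> placement sensitivity/assignment -> biogeography.

One global seed is hashed into per-stage seeds (recorded in the manifest),
so any stage can be replayed in isolation and a full re-run with the same
seed is bit-identical apart from timestamps.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import numpy as np

from . import biogeo, cophylo, distances, ibd, placement, synthdata
from ._utils import derive_seed
from .containers import (
    AssociationMatrix,
    DistanceMatrix,
    read_multilocus_fasta,
    read_sample_table,
)
from .errors import ConfigError, YartsaError
from .trees import parse_newick

logger = logging.getLogger("yartsa")

__all__ = ["PipelineConfig", "run_pipeline"]

_DEFAULT_STAGES = {
    "distances": {},
    "mantel": {"n_perm": 999},
    "radius_sweep": {"n_perm": 199, "min_cluster": 5},
    "timeslice_sweep": {"n_perm": 199, "n_ages": 10},
    "cophylo": {"n_perm": 999},
    "sensitivity": {"loci_counts": None, "reps_per_count": 20, "max_tips": 30},
    "biogeo": {"n_maps": 3000, "max_range_size": 2},
}


@dataclass
class PipelineConfig:
    seed: int = 0
    out_dir: str = "yartsa_out"
    force: bool = False
    simulate: dict | None = field(default_factory=dict)
    inputs: dict | None = None  # {tree, samples, loci_dir, parasite?, assoc?}
    stages: dict = field(default_factory=dict)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        cfg = cls(
            seed=int(raw.get("seed", 0)),
            out_dir=str(raw.get("out_dir", "yartsa_out")),
            force=bool(raw.get("force", False)),
            simulate=raw.get("simulate", {}),
            inputs=raw.get("inputs"),
            stages=dict(raw.get("stages", {})),
        )
        if cfg.inputs is not None and cfg.simulate:
            raise ConfigError("give either a simulate block or an inputs block")
        unknown = set(cfg.stages) - set(_DEFAULT_STAGES)
        if unknown:
            raise ConfigError(f"unknown stages: {sorted(unknown)}")
        return cfg

    def stage_params(self, name: str) -> dict | None:
        """None if the stage is disabled; otherwise defaults + overrides."""
        block = self.stages.get(name, {})
        if block is False or (isinstance(block, dict) and block.get("enabled") is False):
            return None
        params = dict(_DEFAULT_STAGES[name])
        if isinstance(block, dict):
            params.update({k: v for k, v in block.items() if k != "enabled"})
        return params


def _write_json(path: Path, obj: Any) -> None:
    path.write_text(json.dumps(obj, indent=2, default=_jsonify) + "\n")


def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, frozenset):
        return sorted(obj)
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every enabled stage; returns the summary dict (also written to
    ``summary.json`` beside a full ``manifest.json``)."""
    out = Path(config.out_dir)
    if out.exists() and any(out.iterdir()) and not config.force:
        raise ConfigError(f"output directory {out} is not empty (use force)")
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {"seed": config.seed, "stages": {}, "versions": _versions()}
    summary: dict[str, Any] = {}

    def record(stage: str, seconds: float, seed: int | None, params: dict | None):
        manifest["stages"][stage] = {
            "seed": seed,
            "wall_time_s": round(seconds, 3),
            "params": params,
        }

    # ------------------------------------------------------------ stage: data
    t0 = time.time()
    if config.inputs is not None:
        paths = config.inputs
        host_tree = parse_newick(Path(paths["tree"]).read_text())
        samples = read_sample_table(paths["samples"])
        loci_dir = Path(paths["loci_dir"])
        aln = read_multilocus_fasta(
            {p.stem: p for p in sorted(loci_dir.glob("*.fasta"))}
        )
        parasite = (
            parse_newick(Path(paths["parasite"]).read_text())
            if "parasite" in paths
            else None
        )
        assoc = (
            AssociationMatrix.from_csv(paths["assoc"]) if "assoc" in paths else None
        )
        labelled = synthdata.annotate_region_clades(host_tree, samples)
        molecular_tree = host_tree  # input trees are assumed substitutions/site
        sim_cfg = None
        record("inputs", time.time() - t0, None, dict(paths))
    else:
        sim_kwargs = dict(config.simulate or {})
        sim_kwargs["seed"] = derive_seed(config.seed, "simulate")
        sim_cfg = synthdata.SimConfig(**sim_kwargs)
        bundle = synthdata.simulate_bundle(sim_cfg)
        synthdata.write_bundle(bundle, out / "data")
        host_tree = bundle.host_tree
        molecular_tree = bundle.host_molecular_tree
        samples = bundle.samples
        aln = bundle.alignment
        parasite = bundle.parasite_tree
        assoc = bundle.association
        labelled = bundle.labelled_tree
        par_aln = bundle.parasite_alignment
        summary["simulate"] = {
            "n_samples": len(samples),
            "n_loci": len(aln.loci),
            "mean_loci_per_sample": float(aln.presence_mask().sum(axis=1).mean()),
            "host_mean_divergence": synthdata.mean_pairwise_distance(
                bundle.full_alignment
            ),
            "parasite_mean_divergence": synthdata.mean_pairwise_distance(par_aln),
        }
        record("simulate", time.time() - t0, sim_cfg.seed, None)

    # ------------------------------------------------------- stage: distances
    params = config.stage_params("distances")
    if params is None:
        raise ConfigError("the distances stage is required")
    t0 = time.time()
    D_gen = distances.genetic_distance(aln)
    D_geo = distances.haversine_matrix(samples)
    D_cli = distances.climate_distance_matrix(samples)
    order = D_gen.labels
    D_geo = D_geo.submatrix(order)
    D_cli = D_cli.submatrix(order)
    D_gen.to_csv(out / "dist_genetic.csv")
    D_geo.to_csv(out / "dist_geographic.csv")
    D_cli.to_csv(out / "dist_climatic.csv")
    record("distances", time.time() - t0, None, params)

    # ---------------------------------------------------------- stage: mantel
    params = config.stage_params("mantel")
    if params is not None:
        t0 = time.time()
        seed = derive_seed(config.seed, "mantel")
        res_geo = ibd.mantel_test(D_gen, D_geo, n_perm=params["n_perm"], seed=seed)
        res_cli = ibd.mantel_test(D_gen, D_cli, n_perm=params["n_perm"], seed=seed)
        summary["mantel"] = {
            "genetic_vs_geographic": {"r": res_geo.r, "p": res_geo.p},
            "genetic_vs_climatic": {"r": res_cli.r, "p": res_cli.p},
        }
        record("mantel", time.time() - t0, seed, params)

    # ---------------------------------------------------------- stage: sweeps
    params = config.stage_params("radius_sweep")
    if params is not None:
        t0 = time.time()
        seed = derive_seed(config.seed, "radius_sweep")
        try:
            sweep = ibd.geographic_cluster_sweep(
                D_gen, D_geo, min_cluster=params["min_cluster"],
                n_perm=params["n_perm"], seed=seed,
            )
            sweep.to_frame().to_csv(out / "radius_sweep.csv", index=False)
            summary["radius_sweep"] = {
                "controls_km": [p.control for p in sweep.points],
                "mean_r": [p.mean_r for p in sweep.points],
            }
        except YartsaError as exc:
            logger.warning("radius sweep failed: %s", exc)
            summary["radius_sweep"] = {"error": str(exc)}
        record("radius_sweep", time.time() - t0, seed, params)

    params = config.stage_params("timeslice_sweep")
    if params is not None:
        t0 = time.time()
        seed = derive_seed(config.seed, "timeslice_sweep")
        try:
            height = host_tree.root_height
            ages = list(np.linspace(0.0, 0.9 * height, params["n_ages"]))
            sweep = ibd.time_slice_sweep(host_tree, D_geo, ages, n_perm=params["n_perm"], seed=seed)
            sweep.to_frame().to_csv(out / "timeslice_sweep.csv", index=False)
            summary["timeslice_sweep"] = {
                "ages": [p.control for p in sweep.points],
                "r": [p.mean_r for p in sweep.points],
            }
        except YartsaError as exc:
            logger.warning("time-slice sweep failed: %s", exc)
            summary["timeslice_sweep"] = {"error": str(exc)}
        record("timeslice_sweep", time.time() - t0, seed, params)

    # --------------------------------------------------------- stage: cophylo
    params = config.stage_params("cophylo")
    if params is not None and parasite is not None and assoc is not None:
        t0 = time.time()
        seed = derive_seed(config.seed, "cophylo")
        try:
            D_host_pat = distances.patristic_matrix(host_tree, assoc.hosts)
            D_par_pat = distances.patristic_matrix(parasite, assoc.parasites)
            pf = cophylo.parafit_test(
                D_host_pat, D_par_pat, assoc, n_perm=params["n_perm"], seed=seed
            )
            pc = cophylo.paco_test(
                D_host_pat, D_par_pat, assoc, n_perm=params["n_perm"], seed=seed
            )
            summary["cophylo"] = {
                "parafit": {"global": pf.global_stat, "p": pf.p_global},
                "paco": {"m2": pc.m2, "p": pc.p},
            }
        except YartsaError as exc:
            logger.warning("cophylogeny stage failed: %s", exc)
            summary["cophylo"] = {"error": str(exc)}
        record("cophylo", time.time() - t0, seed, params)

    # ----------------------------------------------------- stage: sensitivity
    params = config.stage_params("sensitivity")
    if params is not None:
        t0 = time.time()
        seed = derive_seed(config.seed, "sensitivity")
        try:
            ref_tree, ref_aln = molecular_tree, aln
            max_tips = params.get("max_tips")
            if max_tips and ref_tree.n_tips > max_tips:
                rng = np.random.default_rng(seed)
                keep = sorted(
                    rng.choice(ref_tree.tip_labels, size=max_tips, replace=False)
                )
                ref_tree = _subtree(molecular_tree, keep)
                ref_aln = aln.subset_samples(keep)
            table = placement.loci_sensitivity(
                ref_tree,
                ref_aln,
                loci_counts=params["loci_counts"],
                reps_per_count=params["reps_per_count"],
                seed=seed,
            )
            table.to_csv(out / "loci_sensitivity.csv", index=False)
            summary["sensitivity"] = {
                "n_loci": table["n_loci"].tolist(),
                "mean_confidence": table["mean_confidence"].tolist(),
                "frac_correct": table["frac_correct"].tolist(),
            }
        except YartsaError as exc:
            logger.warning("sensitivity stage failed: %s", exc)
            summary["sensitivity"] = {"error": str(exc)}
        record("sensitivity", time.time() - t0, seed, params)

    # ---------------------------------------------------------- stage: biogeo
    params = config.stage_params("biogeo")
    if params is not None:
        t0 = time.time()
        seed = derive_seed(config.seed, "biogeo")
        try:
            region_of = samples.frame["region"].to_dict()
            ranges = biogeo.RangeData(
                regions=tuple(samples.regions),
                tip_ranges={t: frozenset([region_of[t]]) for t in host_tree.tip_labels},
                max_range_size=params["max_range_size"],
            )
            fit_dec = biogeo.fit_range_model(host_tree, ranges, "DEC", seed=seed)
            fit_decj = biogeo.fit_range_model(host_tree, ranges, "DEC+J", seed=seed)
            maps = biogeo.mk_stochastic_maps(
                host_tree, region_of, tuple(samples.regions),
                n_maps=params["n_maps"], seed=seed,
            )
            np.savetxt(
                out / "mean_transition_counts.csv",
                maps.mean_counts,
                delimiter=",",
                header=",".join(maps.regions),
                comments="",
            )
            summary["biogeo"] = {
                "dec": {"d": fit_dec.d, "e": fit_dec.e, "lnL": fit_dec.loglik, "aic": fit_dec.aic},
                "dec_j": {
                    "d": fit_decj.d, "e": fit_decj.e, "j": fit_decj.j,
                    "lnL": fit_decj.loglik, "aic": fit_decj.aic,
                },
                "delta_aic_dec_minus_decj": fit_dec.aic - fit_decj.aic,
                "mean_total_range_changes": maps.mean_total_changes,
                "mk_rate": maps.rate,
            }
        except YartsaError as exc:
            logger.warning("biogeo stage failed: %s", exc)
            summary["biogeo"] = {"error": str(exc)}
        record("biogeo", time.time() - t0, seed, params)

    _write_json(out / "summary.json", summary)
    manifest["config"] = {
        "seed": config.seed,
        "simulate": config.simulate,
        "inputs": config.inputs,
        "stages": config.stages,
    }
    _write_json(out / "manifest.json", manifest)
    return summary


def _subtree(tree, keep: list[str]):
    """Restrict a tree to a tip subset by pruning the complement."""
    sub = tree
    for label in set(tree.tip_labels) - set(keep):
        sub, _ = sub.prune_tip(label)
    return sub


def _versions() -> dict:
    import scipy

    from . import __version__

    return {"yartsa": __version__, "numpy": np.__version__, "scipy": scipy.__version__}
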