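"""Run configuration, validation and end-to-end orchestration."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from . import __version__, clonality, clones, interactions, synthetic, transitions, vdj

logger = logging.getLogger(__name__)

KNOWN_TOP_KEYS = {"seed", "simulate", "inputs", "clonality", "interactions"}
KNOWN_CLONALITY_KEYS = {"intra_depth", "inter_depth", "reps"}
KNOWN_INTERACTION_KEYS = {"min_cells", "pairs", "include_self"}
KNOWN_INPUT_KEYS = {"contigs", "meta", "dialect"}


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    seed: int
    simulate: Optional[synthetic.SimConfig] = None
    inputs: Optional[dict] = None  # contigs/meta paths + dialect
    intra_depth: int = 5
    inter_depth: int = 50
    reps: int = 1000
    min_cells: int = 3
    pairs_path: Optional[str] = None
    include_self: bool = True
    raw: dict = field(default_factory=dict)

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.raw, sort_keys=True, default=str).encode()
        ).hexdigest()[:12]


def validate_config(path) -> tuple[Optional[RunConfig], list[str]]:
    """Parse and validate a YAML run config, collecting ALL violations."""
    errors: list[str] = []
    try:
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
    except (OSError, yaml.YAMLError) as exc:
        return None, [f"cannot read config: {exc}"]
    if not isinstance(raw, dict):
        return None, ["config must be a mapping"]

    for key in raw:
        if key not in KNOWN_TOP_KEYS:
            errors.append(f"unknown config key {key!r}")

    if "seed" not in raw:
        errors.append("seed is required (no wall-clock seeding)")
    elif not isinstance(raw["seed"], int):
        errors.append("seed must be an integer")

    sim_cfg = None
    if "simulate" in raw and "inputs" in raw:
        errors.append("config must set either 'simulate' or 'inputs', not both")
    if "simulate" in raw:
        try:
            sim = dict(raw["simulate"])
            sim.setdefault("seed", raw.get("seed", 0))
            sim_cfg = synthetic.SimConfig.from_dict(sim)
        except (TypeError, synthetic.ConfigurationError) as exc:
            errors.append(f"simulate: {exc}")
    inputs = None
    if "inputs" in raw:
        inputs = dict(raw["inputs"])
        for key in inputs:
            if key not in KNOWN_INPUT_KEYS:
                errors.append(f"inputs: unknown key {key!r}")
        for key in ("contigs", "meta"):
            if key not in inputs:
                errors.append(f"inputs: missing required key {key!r}")
            elif not Path(inputs[key]).exists():
                errors.append(f"inputs: path does not exist: {inputs[key]}")
        inputs.setdefault("dialect", "airr")
    if "simulate" not in raw and "inputs" not in raw:
        errors.append("config needs a 'simulate' or 'inputs' section")

    clon = raw.get("clonality", {})
    for key in clon:
        if key not in KNOWN_CLONALITY_KEYS:
            errors.append(f"clonality: unknown key {key!r}")
    for depth_key in ("intra_depth", "inter_depth"):
        if depth_key in clon and clon[depth_key] < 2:
            errors.append(f"clonality: {depth_key} must be >= 2")
    if "reps" in clon and clon["reps"] < 1:
        errors.append("clonality: reps must be >= 1")

    inter = raw.get("interactions", {})
    for key in inter:
        if key not in KNOWN_INTERACTION_KEYS:
            errors.append(f"interactions: unknown key {key!r}")
    if "pairs" in inter and inter["pairs"] is not None:
        if not Path(inter["pairs"]).exists():
            errors.append(f"interactions: pairs file does not exist: {inter['pairs']}")
    if "min_cells" in inter and inter["min_cells"] < 1:
        errors.append("interactions: min_cells must be >= 1")

    if errors:
        return None, errors
    return (
        RunConfig(
            seed=int(raw["seed"]),
            simulate=sim_cfg,
            inputs=inputs,
            intra_depth=int(clon.get("intra_depth", 5)),
            inter_depth=int(clon.get("inter_depth", 50)),
            reps=int(clon.get("reps", 1000)),
            min_cells=int(inter.get("min_cells", 3)),
            pairs_path=inter.get("pairs"),
            include_self=bool(inter.get("include_self", True)),
            raw=raw,
        ),
        [],
    )


def _provenance(config: RunConfig) -> str:
    return (f"# immunoclone {__version__} config_hash={config.config_hash()} "
            f"seed={config.seed}\n")


def _write_tsv(df: pd.DataFrame, path: Path, config: RunConfig,
               index: bool = False) -> None:
    with open(path, "w") as fh:
        fh.write(_provenance(config))
        df.to_csv(fh, sep="\t", index=index)


def run_pipeline(config: RunConfig, out_dir) -> dict:
    """Execute all stages in dependency order; returns the manifest.

    Outputs land under `out_dir`, each TSV carrying a provenance header.
    A failing stage aborts with the stage named; partial outputs are kept
    alongside a ``FAILED`` marker.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "tool": "immunoclone",
        "version": __version__,
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "outputs": {},
    }
    stage = "setup"
    try:
        # --- stage: inputs
        stage = "inputs"
        if config.simulate is not None:
            contigs, meta = synthetic.simulate_repertoire(config.simulate)
            synthetic.write_airr(contigs, out / "contigs.tsv")
            synthetic.write_meta(meta, out / "meta.tsv")
            manifest["outputs"]["contigs"] = "contigs.tsv"
            manifest["outputs"]["meta"] = "meta.tsv"
            expression = None
            if config.simulate.expr_fractions:
                expression = synthetic.simulate_expression(config.simulate, meta)
                synthetic.write_mtx(expression, out / "expression")
                manifest["outputs"]["expression"] = "expression/matrix.mtx"
            records = vdj.parse_contigs(out / "contigs.tsv", dialect="airr")
        else:
            records = vdj.parse_contigs(config.inputs["contigs"],
                                        dialect=config.inputs["dialect"])
            meta = pd.read_csv(config.inputs["meta"], sep="\t")
            expression = None

        # --- stage: chain assignment
        stage = "assign_chains"
        assignments = vdj.select_chains(records)
        chains = vdj.assignments_to_frame(assignments)
        _write_tsv(chains, out / "chains.tsv", config)
        manifest["outputs"]["chains"] = "chains.tsv"

        # --- stage: clone calling (per patient, per receptor class)
        stage = "call_clones"
        meta_idx = meta.set_index("cell_id")
        frames = []
        for patient, cell_ids in meta.groupby("patient")["cell_id"]:
            cells = set(cell_ids)
            b_rows, t_rows = [], []
            for cell_id, asg in assignments.items():
                if cell_id not in cells or asg.heavy_or_beta is None:
                    continue
                heavy = asg.heavy_or_beta
                if asg.receptor_class == "BCR":
                    b_rows.append({"cell_id": cell_id, "junction": heavy.junction,
                                   "v_call": heavy.v_call, "j_call": heavy.j_call})
                elif asg.receptor_class == "TCR":
                    alpha = asg.light_or_alpha
                    t_rows.append({"cell_id": cell_id,
                                   "trb_junction": heavy.junction,
                                   "trb_v": heavy.v_call, "trb_j": heavy.j_call,
                                   "tra_junction": alpha.junction if alpha else ""})
            if b_rows:
                table = clones.call_bcr_clones(pd.DataFrame(b_rows),
                                               clone_prefix=f"{patient}_B")
                frames.append(table.to_frame())
            if t_rows:
                table = clones.call_tcr_clones(pd.DataFrame(t_rows),
                                               clone_prefix=f"{patient}_T")
                frames.append(table.to_frame())
        clone_df = (pd.concat(frames, ignore_index=True) if frames
                    else pd.DataFrame(columns=["cell_id", "clone_id", "clone_size"]))
        _write_tsv(clone_df, out / "clones.tsv", config)
        manifest["outputs"]["clones"] = "clones.tsv"

        # --- stage: clonality
        stage = "clonality"
        merged = clone_df.merge(meta, on="cell_id", how="inner")
        results = []
        rng_seed = config.seed
        for (sample_id, subset), grp in merged.groupby(["sample_id", "subset"]):
            results.append(clonality.intra_subset_clonality(
                grp["clone_id"].tolist(), depth=config.intra_depth,
                reps=config.reps, seed=rng_seed, sample_id=str(sample_id),
                subset=str(subset)))
        for (sample_id, lineage), grp in merged.groupby(["sample_id", "lineage"]):
            results.extend(clonality.inter_subset_clonality(
                grp["clone_id"].tolist(), grp["subset"].tolist(),
                depth=config.inter_depth, reps=config.reps, seed=rng_seed,
                sample_id=str(sample_id)))
        _write_tsv(clonality.results_to_frame(results), out / "clonality.tsv", config)
        manifest["outputs"]["clonality"] = "clonality.tsv"

        # --- stage: transitions
        stage = "transitions"
        overlaps = {}
        for sample_id, grp in merged.groupby("sample_id"):
            overlaps[str(sample_id)] = transitions.clonal_overlap(
                grp[["cell_id", "clone_id", "subset"]])
        normed, excluded = transitions.normalize_overlap(overlaps)
        overlap_rows = []
        for sample_id, mat in sorted(normed.items()):
            long = mat.stack().rename("weight").rename_axis(
                ["subset_a", "subset_b"]).reset_index()
            long.insert(0, "sample_id", sample_id)
            overlap_rows.append(long)
        overlap_df = (pd.concat(overlap_rows, ignore_index=True) if overlap_rows
                      else pd.DataFrame(columns=["sample_id", "subset_a",
                                                 "subset_b", "weight"]))
        _write_tsv(overlap_df, out / "overlap.tsv", config)
        calls = transitions.classify_compartments(
            merged[["clone_id", "compartment"]])
        _write_tsv(calls.reset_index(), out / "compartment_calls.tsv", config)
        manifest["outputs"]["overlap"] = "overlap.tsv"
        manifest["outputs"]["compartment_calls"] = "compartment_calls.tsv"
        manifest["excluded_overlap_samples"] = sorted(excluded)

        # --- stage: interactions
        stage = "interactions"
        if expression is not None:
            pairs = (pd.read_csv(config.pairs_path) if config.pairs_path
                     else interactions.load_default_pairs())
            tensor = interactions.interaction_strengths(
                expression, meta_idx[["patient", "subset"]], pairs,
                min_cells=config.min_cells, include_self=config.include_self)
            _write_tsv(tensor, out / "interactions.tsv", config)
            _write_tsv(interactions.link_counts(tensor),
                       out / "link_counts.tsv", config)
            manifest["outputs"]["interactions"] = "interactions.tsv"
            manifest["outputs"]["link_counts"] = "link_counts.tsv"
    except Exception as exc:  # noqa: BLE001 - stage context is the contract
        (out / "FAILED").write_text(f"stage={stage}\nerror={exc}\n")
        raise PipelineError(stage, exc) from exc

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
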