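"""Configuration-driven orchestration of the analysis stages.

A TOML config names the stages to run and their parameter blocks; stages run
in dependency order (generation before analysis) under a single global seed
from which deterministic per-stage sub-seeds are derived by hashing, so
adding a stage never perturbs another stage's randomness.  Every run writes a
manifest (stages, parameters, seeds, version, per-output SHA-256 checksums)
and the same config + seed reproduces byte-identical outputs.

Example config::

    [run]
    seed = 42
    outdir = "out"
    stages = ["simulate_eye", "score_eye"]

    [simulate_eye]
    n_rows = 10
    n_cols = 10
    jitter_sigma = 1.5

    [score_eye]
    min_separation = 8.0
"""

from __future__ import annotations

import hashlib
import json
import logging
import tomllib
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from ._util import derive_seed
from .network_connectivity import (
    ThresholdParams,
    build_network,
    connectivity_report,
    read_edge_list,
    sample_connectivity_null,
    set_connectivity_profile,
)
from .ommatidia_score import DetectionParams, load_image, score_image
from .overlap_enrichment import (
    empirical_p,
    observed_overlap,
    read_gene_set,
    read_universe_tsv,
    simulate_overlap_null,
)
from .synthetic_data import (
    LatticeSpec,
    NetworkSpec,
    UniverseSpec,
    generate_eye_image,
    generate_network,
    generate_universe,
    write_centers_tsv,
    write_edges_tsv,
    write_gene_list,
    write_universe_tsv,
)

log = logging.getLogger("quantkit.pipeline")

STAGE_ORDER = [
    "simulate_eye",
    "simulate_network",
    "simulate_universe",
    "score_eye",
    "connectivity",
    "overlap",
]


class ConfigError(ValueError):
    pass


def load_config(path) -> dict:
    with open(path, "rb") as fh:
        return tomllib.load(fh)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def validate_config(config: dict, config_dir: Path) -> list[str]:
    """Schema + input-existence checks; raises before any work is done."""
    run = config.get("run")
    if not isinstance(run, dict):
        raise ConfigError("config must contain a [run] table")
    stages = run.get("stages")
    if not stages or not isinstance(stages, list):
        raise ConfigError("[run].stages must be a nonempty list")
    unknown = [s for s in stages if s not in STAGE_ORDER]
    if unknown:
        raise ConfigError(f"unknown stages: {unknown}")
    if "seed" in run and not isinstance(run["seed"], int):
        raise ConfigError("[run].seed must be an integer")
    # every referenced input path must exist before any stage launches
    for stage in stages:
        block = config.get(stage, {})
        for key in ("edges", "universe", "candidates"):
            if key in block and not (config_dir / block[key]).exists():
                raise ConfigError(
                    f"stage {stage!r}: input path {block[key]!r} does not exist"
                )
        for key in ("images", "gene_sets"):
            for p in block.get(key, []):
                if not (config_dir / p).exists():
                    raise ConfigError(
                        f"stage {stage!r}: input path {p!r} does not exist"
                    )
    return sorted(stages, key=STAGE_ORDER.index)


def run_pipeline(config_path, outdir=None) -> dict:
    """Run the configured stages; returns the manifest dict."""
    config_path = Path(config_path)
    config = load_config(config_path)
    stages = validate_config(config, config_path.parent)
    run = config["run"]
    seed = int(run.get("seed", 0))
    out = Path(outdir or config_path.parent / run.get("outdir", "quantkit_out"))
    out.mkdir(parents=True, exist_ok=True)

    artifacts: dict[str, list[str]] = {}
    state: dict[str, object] = {}
    for stage in stages:
        block = dict(config.get(stage, {}))
        sub_seed = derive_seed(seed, stage)
        log.info("stage %s (sub-seed %d)", stage, sub_seed)
        written = _STAGES[stage](block, sub_seed, out, config_path.parent, state)
        artifacts[stage] = [str(Path(p).relative_to(out)) for p in written]

    manifest = {
        "version": __version__,
        "config": str(config_path),
        "global_seed": seed,
        "stages": [
            {
                "name": s,
                "sub_seed": derive_seed(seed, s),
                "parameters": dict(config.get(s, {})),
                "outputs": {
                    rel: _sha256(out / rel) for rel in artifacts[s]
                },
            }
            for s in stages
        ],
    }
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest


# ---------------------------------------------------------------------------
# stage implementations: (params, sub_seed, outdir, config_dir, state) -> paths


def _stage_simulate_eye(params, sub_seed, out, _cfg_dir, state):
    spec = LatticeSpec(**{**params, "seed": params.get("seed", sub_seed)})
    image, centers = generate_eye_image(spec)
    import tifffile

    img_path = out / "synthetic_eye.tiff"
    tifffile.imwrite(img_path, image.pixels)
    centers_path = out / "synthetic_eye_centers.tsv"
    write_centers_tsv(centers_path, centers)
    state["eye_image"] = image
    return [img_path, centers_path]


def _stage_score_eye(params, _sub_seed, out, cfg_dir, state):
    params = dict(params)
    image_paths = params.pop("images", None)
    dark_threshold = params.pop("dark_threshold", None)
    det = DetectionParams(**params)
    records = []
    if image_paths:
        for p in image_paths:
            rec = {"file": str(p)}
            rec.update(score_image(load_image(cfg_dir / p), det, dark_threshold=dark_threshold))
            records.append(rec)
    elif "eye_image" in state:
        rec = {"file": "synthetic_eye.tiff"}
        rec.update(score_image(state["eye_image"], det, dark_threshold=dark_threshold))
        records.append(rec)
    else:
        raise ConfigError("score_eye: no images given and no simulate_eye stage ran")
    path = out / "eye_scores.tsv"
    pd.DataFrame(records).to_csv(path, sep="\t", index=False, float_format="%.6f")
    return [path]


def _stage_simulate_network(params, sub_seed, out, _cfg_dir, state):
    params = dict(params)
    params["planted_module"] = tuple(params.get("planted_module", ()))
    spec = NetworkSpec(**{**params, "seed": params.get("seed", sub_seed)})
    edges, module = generate_network(spec)
    edges_path = out / "synthetic_edges.tsv"
    write_edges_tsv(edges_path, edges)
    written = [edges_path]
    if module:
        module_path = out / "synthetic_module_genes.txt"
        write_gene_list(module_path, module)
        written.append(module_path)
    state["edges"] = edges
    return written


def _stage_connectivity(params, sub_seed, out, cfg_dir, state):
    params = dict(params)
    if "edges" in params:
        edges = read_edge_list(cfg_dir / params["edges"])
    elif "edges" in state:
        edges = state["edges"]
    else:
        raise ConfigError("connectivity: no edge list given and no network simulated")
    if "top_fraction" in params:
        thr = ThresholdParams(mode="top_fraction", top_fraction=params["top_fraction"])
    else:
        thr = ThresholdParams(mode="min_weight", min_weight=params.get("min_weight", 2.0))
    net = build_network(edges, thr)
    profiles = []
    for p in params.get("gene_sets", []):
        genes = read_gene_set(cfg_dir / p)
        profiles.append(set_connectivity_profile(net, genes, name=Path(p).stem))
    if not profiles:
        raise ConfigError("connectivity: at least one gene set is required")
    null = sample_connectivity_null(
        net,
        n_anchor_genes=min(params.get("null_anchors", 500), len(net.nodes)),
        n_replicates=params.get("null_reps", 100),
        partner_set_size=params.get("null_size", 20),
        seed=params.get("seed", sub_seed),
    )
    report = connectivity_report(profiles, null)
    tsv = out / "connectivity_report.tsv"
    report.to_csv(tsv, sep="\t", index=False, float_format="%.6g")
    js = out / "connectivity_report.json"
    js.write_text(report.to_json(orient="records", indent=2) + "\n")
    return [tsv, js]


def _stage_simulate_universe(params, sub_seed, out, _cfg_dir, state):
    spec = UniverseSpec(**{**params, "seed": params.get("seed", sub_seed)})
    universe, candidates = generate_universe(spec)
    upath = out / "synthetic_universe.tsv"
    write_universe_tsv(upath, universe)
    cpath = out / "synthetic_candidates.txt"
    write_gene_list(cpath, candidates)
    state["universe_path"] = upath
    state["candidates_path"] = cpath
    return [upath, cpath]


def _stage_overlap(params, sub_seed, out, cfg_dir, state):
    upath = cfg_dir / params["universe"] if "universe" in params else state.get("universe_path")
    cpath = cfg_dir / params["candidates"] if "candidates" in params else state.get("candidates_path")
    if upath is None or cpath is None:
        raise ConfigError("overlap: universe and candidates required")
    universe = read_universe_tsv(upath)
    candidates = read_gene_set(cpath)
    obs, missing = observed_overlap(candidates, universe)
    null = simulate_overlap_null(
        universe,
        k=len([g for g in candidates if g in set(universe.genes)]),
        n_sim=params.get("n_sim", 100_000),
        seed=params.get("seed", sub_seed),
    )
    ep = empirical_p(null, obs)
    result = {
        "observed": obs,
        "candidates_missing_from_universe": list(missing),
        "n_sim": null.n_sim,
        **{f"null_{k}": v for k, v in null.summary().items()},
        "p_estimate": ep.estimate,
        "p_is_lower_bound": ep.is_lower_bound,
        "p_string": ep.reported,
    }
    path = out / "overlap_enrichment.json"
    path.write_text(json.dumps(result, indent=2, sort_keys=True) + "\n")
    return [path]


_STAGES = {
    "simulate_eye": _stage_simulate_eye,
    "score_eye": _stage_score_eye,
    "simulate_network": _stage_simulate_network,
    "connectivity": _stage_connectivity,
    "simulate_universe": _stage_simulate_universe,
    "overlap": _stage_overlap,
}
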