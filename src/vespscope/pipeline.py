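"""End-to-end orchestration: occurrence -> clustering; trees -> TC -> depth.

A run is described by a JSON-serialisable config dict, validated up front
(unknown keys are rejected).  The occurrence arm builds the matrix, computes
prevalence, applies the ESP/vESP filters and clusters the profiles; the tree
arm screens each gene tree by relative tree certainty (strictly above the
threshold, default 0.5), then midpoint-roots, ultrametricizes, extracts viral
clades and scores their depths.  Every run writes a manifest with versions,
seeds, parameters, and input checksums so it can be reproduced exactly.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Any

import pandas as pd

from . import __version__
from .alignment import alignment_stats, read_alignment
from .clade_depth import (
    DepthRecord,
    clade_depth,
    depth_report,
    domains_from_labels,
    find_viral_clades,
    flag_long_branches,
    midpoint_root,
    read_tip_metadata,
    records_frame,
    ultrametricize,
)
from .occurrence import (
    OccurrenceMatrix,
    compute_prevalence,
    filter_esps,
    order_prevalence_table,
    parse_domtblout,
    read_genome_metadata,
)
from .som import cluster_profiles
from .tree_certainty import read_bootstrap_trees, read_tree, tree_certainty

log = logging.getLogger("vespscope")

#: Recognised config keys and their defaults (None = required / optional path).
CONFIG_DEFAULTS: dict[str, Any] = {
    "out_dir": None,                 # required
    "metadata": None,                # genome metadata TSV (occurrence arm)
    "matrix": None,                  # occurrence TSV, or
    "hits_dir": None,                # directory of domtblout files
    "euk_threshold": 0.95,
    "min_virus_genomes_vesp": 1,
    "min_virus_genomes_phylo": 11,
    "merge_asgard": False,
    "som_rows": None,
    "som_cols": None,
    "som_epochs": 50,
    "elbow_k_min": 2,
    "elbow_k_max": 10,
    "elbow_restarts": 20,
    "seed": 42,
    "trees": (),                     # list of {tree, bootstraps, tip_meta?, id?, category?}
    "tc_threshold": 0.5,
    "min_clade_tips": 1,
    "long_branch_factor": 10.0,
    "alignments": (),                # list of {fasta, tip_meta?, id?}
}

_TREE_KEYS = {"tree", "bootstraps", "tip_meta", "id", "category"}
_ALN_KEYS = {"fasta", "tip_meta", "id"}


class ConfigError(ValueError):
    """Invalid pipeline configuration."""


def validate_config(config: dict) -> dict:
    """Fill defaults and reject unknown keys; returns a complete config."""
    unknown = set(config) - set(CONFIG_DEFAULTS)
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    cfg = {**CONFIG_DEFAULTS, **config}
    if cfg["out_dir"] is None:
        raise ConfigError("config requires 'out_dir'")
    if cfg["matrix"] is not None and cfg["hits_dir"] is not None:
        raise ConfigError("give either 'matrix' or 'hits_dir', not both")
    has_occurrence = cfg["matrix"] is not None or cfg["hits_dir"] is not None
    if has_occurrence and cfg["metadata"] is None:
        raise ConfigError("occurrence inputs require 'metadata'")
    for i, spec in enumerate(cfg["trees"]):
        unknown = set(spec) - _TREE_KEYS
        if unknown:
            raise ConfigError(f"trees[{i}]: unknown keys {sorted(unknown)}")
        if "tree" not in spec or "bootstraps" not in spec:
            raise ConfigError(f"trees[{i}]: needs 'tree' and 'bootstraps'")
    for i, spec in enumerate(cfg["alignments"]):
        unknown = set(spec) - _ALN_KEYS
        if unknown:
            raise ConfigError(f"alignments[{i}]: unknown keys {sorted(unknown)}")
        if "fasta" not in spec:
            raise ConfigError(f"alignments[{i}]: needs 'fasta'")
    return cfg


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _input_paths(cfg: dict) -> list[str]:
    paths: list[str] = []
    for key in ("metadata", "matrix"):
        if cfg[key]:
            paths.append(cfg[key])
    if cfg["hits_dir"]:
        paths.extend(sorted(str(p) for p in Path(cfg["hits_dir"]).iterdir()))
    for spec in cfg["trees"]:
        paths.extend(str(spec[k]) for k in ("tree", "bootstraps") if spec.get(k))
        if spec.get("tip_meta"):
            paths.append(str(spec["tip_meta"]))
    for spec in cfg["alignments"]:
        paths.append(str(spec["fasta"]))
        if spec.get("tip_meta"):
            paths.append(str(spec["tip_meta"]))
    return paths


def _run_occurrence_arm(cfg: dict, out: Path, manifest: dict) -> None:
    metadata = read_genome_metadata(cfg["metadata"])
    if cfg["matrix"] is not None:
        matrix = OccurrenceMatrix.from_tsv(cfg["matrix"], metadata)
    else:
        paths = sorted(Path(cfg["hits_dir"]).iterdir())
        matrix = parse_domtblout(paths, metadata)
    log.info("occurrence: %d Pfams x %d genomes", *matrix.presence.shape)
    prev = compute_prevalence(matrix, merge_asgard=cfg["merge_asgard"])
    prev.to_tsv(out / "prevalence.tsv")
    flags = filter_esps(
        prev,
        euk_threshold=cfg["euk_threshold"],
        min_virus_genomes_vesp=cfg["min_virus_genomes_vesp"],
        min_virus_genomes_phylo=cfg["min_virus_genomes_phylo"],
    )
    flags.to_csv(out / "esp_flags.tsv", sep="\t", index_label="pfam")
    n_esp = int(flags["is_esp"].sum())
    n_vesp = int(flags["is_vesp"].sum())
    n_phylo = int(flags["phylo_selected"].sum())
    log.info("filters: %d ESPs, %d vESPs, %d phylo-selected", n_esp, n_vesp, n_phylo)
    vesps = flags.index[flags["is_vesp"]].tolist()
    if vesps:
        order_prevalence_table(matrix, vesps).to_csv(
            out / "order_prevalence.tsv", sep="\t", index=False
        )
    result = cluster_profiles(
        prev.prevalence,
        rows=cfg["som_rows"],
        cols=cfg["som_cols"],
        epochs=cfg["som_epochs"],
        k_min=cfg["elbow_k_min"],
        k_max=cfg["elbow_k_max"],
        restarts=cfg["elbow_restarts"],
        seed=cfg["seed"],
    )
    result.assignments.to_csv(out / "cluster_assignments.tsv", sep="\t")
    result.elbow.to_frame().to_csv(out / "elbow_curve.tsv", sep="\t", index=False)
    pd.DataFrame(result.som.codebook_).to_csv(
        out / "som_codebook.tsv", sep="\t", index_label="node"
    )
    log.info("clustering: selected k=%d", result.elbow.selected_k)
    manifest["stages"]["occurrence"] = {
        "n_pfams": int(matrix.presence.shape[0]),
        "n_genomes": int(matrix.presence.shape[1]),
        "n_esp": n_esp,
        "n_vesp": n_vesp,
        "n_phylo_selected": n_phylo,
        "selected_k": int(result.elbow.selected_k),
    }


def _tree_domains(tree, spec: dict) -> dict[str, str]:
    labels = [lf.taxon.label for lf in tree.leaf_node_iter()]
    if spec.get("tip_meta"):
        domains, _ = read_tip_metadata(spec["tip_meta"])
        return domains
    return domains_from_labels(labels)


def _run_tree_arm(cfg: dict, out: Path, manifest: dict) -> None:
    records: list[DepthRecord] = []
    tc_rows = []
    for i, spec in enumerate(cfg["trees"]):
        tree_id = spec.get("id", Path(spec["tree"]).stem)
        ref = read_tree(spec["tree"])
        boots = read_bootstrap_trees(spec["bootstraps"])
        report = tree_certainty(ref, boots)
        passed = report.passes(cfg["tc_threshold"])
        tc_rows.append(
            {
                "tree_id": tree_id,
                "tc": report.tc,
                "relative_tc": report.relative_tc,
                "n_internal": report.n_internal,
                "pass": passed,
            }
        )
        (out / f"tc_{tree_id}.json").write_text(
            json.dumps(report.to_dict(cfg["tc_threshold"]), indent=1)
        )
        if not passed:
            log.info(
                "tree %s: relative TC %.3f <= %.2f, excluded from depth report",
                tree_id, report.relative_tc, cfg["tc_threshold"],
            )
            continue
        rooted = midpoint_root(ref)
        long_tips = flag_long_branches(rooted, cfg["long_branch_factor"])
        if long_tips:
            log.info("tree %s: long-branch candidates %s", tree_id, long_tips)
        ultra = ultrametricize(rooted)
        ultra.write(path=str(out / f"{tree_id}.ultrametric.nwk"), schema="newick")
        domains = _tree_domains(ref, spec)
        clades = find_viral_clades(ultra, domains, cfg["min_clade_tips"])
        log.info("tree %s: %d viral clades", tree_id, len(clades))
        for j, clade in enumerate(clades, start=1):
            records.append(
                DepthRecord(
                    tree_id=tree_id,
                    clade_id=f"{tree_id}.c{j}",
                    n_tips=clade.size,
                    depth=clade_depth(ultra, clade),
                    category=spec.get("category"),
                )
            )
    if tc_rows:
        pd.DataFrame(tc_rows).to_csv(out / "tree_certainty.tsv", sep="\t", index=False)
    if records:
        records_frame(records).to_csv(out / "clade_depths.tsv", sep="\t", index=False)
        depth_report(records).to_csv(out / "depth_report.tsv", sep="\t", index=False)
    manifest["stages"]["trees"] = {
        "n_trees": len(cfg["trees"]),
        "n_passed_tc": sum(1 for r in tc_rows if r["pass"]),
        "n_clades": len(records),
    }


def _run_alignment_arm(cfg: dict, out: Path, manifest: dict) -> None:
    rows = []
    for spec in cfg["alignments"]:
        aln_id = spec.get("id", Path(spec["fasta"]).stem)
        aln = read_alignment(spec["fasta"])
        domains = None
        if spec.get("tip_meta"):
            domains, _ = read_tip_metadata(spec["tip_meta"])
        rows.append({"alignment": aln_id, **alignment_stats(aln, domains)})
    if rows:
        pd.DataFrame(rows).to_csv(out / "alignment_stats.tsv", sep="\t", index=False)
    manifest["stages"]["alignments"] = {"n_alignments": len(rows)}


def run_all(config: dict) -> dict:
    """Run every configured stage; returns (and writes) the run manifest."""
    cfg = validate_config(config)
    out = Path(cfg["out_dir"])
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "vespscope_version": __version__,
        "seed": cfg["seed"],
        "parameters": {
            k: v for k, v in cfg.items() if k not in ("trees", "alignments")
        },
        "input_checksums": {},
        "stages": {},
    }
    try:
        for p in _input_paths(cfg):
            manifest["input_checksums"][p] = _sha256(p)
        if cfg["matrix"] is not None or cfg["hits_dir"] is not None:
            _run_occurrence_arm(cfg, out, manifest)
        if cfg["trees"]:
            _run_tree_arm(cfg, out, manifest)
        if cfg["alignments"]:
            _run_alignment_arm(cfg, out, manifest)
    except Exception as exc:  # annotate the failing stage, then re-raise
        done = ", ".join(manifest["stages"]) or "none"
        raise RuntimeError(
            f"pipeline failed after stages [{done}]: {exc}"
        ) from exc
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
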