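"""End-to-end orchestration: simulate (optionally), quantify, profile
stoichiometry, compare, and write a report bundle.

A run is fully determined by (config, seed): every output TSV, the
manifest (config hash, seed, package version) and the plain-text summary
are byte-reproducible.  Per-stage counts (library entries loaded, peptides
removed at the FDR gate, conflict groups formed) are logged into the
manifest so the narrative numbers of any dataset are inspectable.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path

import pandas as pd

from . import __version__, ionlib, quant, stoich, synth
from .config import PipelineConfig


def run_pipeline(cfg: PipelineConfig, simulate: bool = False) -> dict:
    """Execute the pipeline and write the report bundle into
    cfg.output_dir.  Returns the manifest.  Raises before any computation
    when required inputs are missing; on a stage failure, partial outputs
    are retained and the manifest records the failing stage."""
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": asdict(cfg),
        "config_hash": hashlib.sha256(
            json.dumps(asdict(cfg), sort_keys=True).encode()
        ).hexdigest()[:16],
        "seed": cfg.seed,
        "version": __version__,
        "counts": {},
        "failed_stage": None,
    }
    stage = "configure"
    try:
        annotations = None
        if simulate:
            stage = "simulate"
            sc = synth.default_scenario(cfg.seed)
            library = synth.build_library(sc)
            table, truth, sim_manifest = synth.render_dataset(
                sc, synth.NoiseModel(), n_replicates=3, seed=cfg.seed
            )
            manifest["simulation"] = sim_manifest
            annotations = synth.class_table(sc).rename(columns={"class_id": "class_id"})
            table.to_csv(out / "transitions.tsv", sep="\t", index=False)
            truth.to_csv(out / "ground_truth.tsv", sep="\t", index=False)
        else:
            stage = "load"
            if not cfg.library or not Path(cfg.library).exists():
                raise FileNotFoundError(f"ion library not found: {cfg.library}")
            if not cfg.transitions or not Path(cfg.transitions).exists():
                raise FileNotFoundError(f"transition table not found: {cfg.transitions}")
            errors: list[str] = []
            library = ionlib.read_library(cfg.library, errors)
            manifest["counts"]["library_row_errors"] = len(errors)
            table = pd.read_csv(cfg.transitions, sep="\t")
        manifest["counts"]["library_entries"] = len(library)
        manifest["counts"]["transition_rows"] = len(table)

        stage = "quantify"
        scheme = ionlib.build_scheme(
            cfg.scheme_start, cfg.scheme_end, cfg.scheme_width, cfg.scheme_stride
        )
        groups = ionlib.detect_conflicts(library, scheme, cfg.rt_tolerance)
        manifest["counts"]["conflict_groups"] = len(groups)
        peptides, proteins, normalized = quant.quantify(
            table,
            library,
            scheme=scheme,
            profile=quant.PROFILES[cfg.profile],
            fdr_threshold=cfg.fdr_threshold,
            shared=cfg.shared_peptides,
        )
        manifest["counts"]["peptides_removed_at_fdr"] = int(peptides.attrs.get("n_removed", 0))
        manifest["counts"]["peptides_passing"] = len(peptides)
        peptides.to_csv(out / "peptides.tsv", sep="\t", index=False)
        proteins.to_csv(out / "proteins.tsv", sep="\t", index=False)
        normalized.to_csv(out / "proteins_normalized.tsv", sep="\t", index=False)

        stage = "stoichiometry"
        if annotations is not None:
            profiles = stoich.carboxyform_profiles(peptides, annotations)
            profiles.to_csv(out / "carboxyforms.tsv", sep="\t", index=False)
            manifest["counts"]["carboxyform_rows"] = len(profiles)

        stage = "report"
        lines = ["glaquant run summary", "====================", ""]
        for k, v in manifest["counts"].items():
            lines.append(f"{k}: {v}")
        (out / "summary.txt").write_text("\n".join(lines) + "\n")
    except Exception:
        manifest["failed_stage"] = stage
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
        raise
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
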