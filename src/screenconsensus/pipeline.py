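"""End-to-end orchestration: align -> label -> fit -> call -> compare.

`run_all` executes the whole analysis from either a synthetic
configuration or three user-supplied matrices, writing every stage's
tidy CSV outputs plus a machine-readable JSON manifest (config echo,
version, seed, iteration counts, convergence flags).  All randomness
flows from the single config seed through the synthetic generator;
the analysis itself is deterministic, so reruns are byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .calling import EssentialCallSet, call_final, count_unique_and_overlap
from .compare import (expression_density, expression_strata_counts,
                      essentiality_profile, group8_classify,
                      group_expression_summary, low_expression_report,
                      per_cellline_correlation)
from .consensus import ConsensusConfig, ConsensusFit, fit, rank_common
from .io import AlignedDataset, align_datasets, read_matrix, write_matrix
from .labeling import TriLabelMatrix, assign_labels, build_bipartite
from .synthetic import SyntheticConfig, generate

log = logging.getLogger("screenconsensus")


@dataclasses.dataclass
class RunConfig:
    """Full configuration of an end-to-end run."""

    out_dir: str
    # non-synthetic mode: three input paths
    crispr_path: str | None = None
    shrna_path: str | None = None
    expression_path: str | None = None
    # synthetic mode
    synthetic: SyntheticConfig | None = None
    frac: float = 0.10
    consensus: ConsensusConfig = dataclasses.field(default_factory=ConsensusConfig)
    x_fracs: tuple[float, ...] = (0.10, 0.20, 0.30, 0.40)
    compare_x_frac: float = 0.10
    strata_fracs: tuple[float, ...] = (0.10, 0.20, 0.30)
    expression_threshold: float = 1.8
    profile_top_k: int = 1000
    seed: int = 7
    log_level: str = "INFO"

    def validate(self) -> None:
        if self.synthetic is None:
            paths = (self.crispr_path, self.shrna_path, self.expression_path)
            if any(p is None for p in paths):
                raise ValueError(
                    "non-synthetic mode requires crispr_path, shrna_path "
                    "and expression_path")
            for p in paths:
                if not Path(p).exists():
                    raise FileNotFoundError(f"input file not found: {p}")
        if self.compare_x_frac not in self.x_fracs:
            raise ValueError("compare_x_frac must be one of x_fracs")


def _load_dataset(config: RunConfig) -> AlignedDataset:
    if config.synthetic is not None:
        syn = dataclasses.replace(config.synthetic, seed=config.seed)
        dataset, truth = generate(syn)
        truth.to_frame().to_csv(Path(config.out_dir) / "truth.csv", index=False)
        return dataset
    crispr = read_matrix(config.crispr_path, "essentiality", platform="CRISPR")
    shrna = read_matrix(config.shrna_path, "essentiality", platform="SHRNA")
    expression = read_matrix(config.expression_path, "expression")
    return align_datasets(crispr, shrna, expression)


def run_all(config: RunConfig) -> dict:
    """Execute the full pipeline; returns the manifest dictionary."""
    config.validate()
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": __version__, "seed": config.seed,
                      "config": _config_dict(config), "stages": {}}
    try:
        dataset = _load_dataset(config)
        manifest["stages"]["align"] = {"m": int(dataset.gene_ids.size),
                                       "n": int(dataset.cellline_ids.size)}

        platforms = {"CRISPR": dataset.crispr, "SHRNA": dataset.shrna}
        labels: dict[str, TriLabelMatrix] = {}
        fits: dict[str, ConsensusFit] = {}
        for name, scores in platforms.items():
            log.info("labeling and fitting %s", name)
            lab = assign_labels(scores, config.frac)
            labels[name] = lab
            lab.to_frame().to_csv(out / f"labels_{name}.csv", index=False)
            result = fit(build_bipartite(lab), config.consensus)
            fits[name] = result
            result.u_frame().to_csv(out / f"U_{name}.csv")
            result.q_frame().to_csv(out / f"Q_{name}.csv")
            pd.DataFrame({"iteration": np.arange(result.objective_trace.size),
                          "J": result.objective_trace}
                         ).to_csv(out / f"objective_{name}.csv", index=False)
            manifest["stages"][f"fit_{name}"] = {
                "n_iter": result.n_iter, "converged": bool(result.converged),
                "final_objective": float(result.objective_trace[-1])}

        call_frames = []
        calls: dict[tuple[str, str], EssentialCallSet] = {}
        for name, scores in platforms.items():
            for cls in ("E", "NE"):
                for x in config.x_fracs:
                    cs = call_final(scores, fits[name], cls, x)
                    frame = cs.to_frame()
                    frame.insert(2, "x_frac", x)
                    call_frames.append(frame)
                    if x == config.compare_x_frac:
                        calls[(name, cls)] = cs
                        u, w = count_unique_and_overlap(cs)
                        manifest["stages"][f"calls_{name}_{cls}"] = {
                            "x_frac": x, "unique": u, "with_overlap": w}
        pd.concat(call_frames, ignore_index=True).to_csv(
            out / "calls.csv", index=False)

        _compare_stage(config, dataset, labels, fits, calls, out, manifest)
        manifest["status"] = "ok"
    except Exception as exc:
        manifest["status"] = "error"
        manifest["error"] = f"{type(exc).__name__}: {exc}"
        _write_manifest(out, manifest)
        raise
    _write_manifest(out, manifest)
    return manifest


def _compare_stage(config: RunConfig, dataset: AlignedDataset,
                   labels: dict[str, TriLabelMatrix],
                   fits: dict[str, ConsensusFit],
                   calls: dict[tuple[str, str], EssentialCallSet],
                   out: Path, manifest: dict) -> None:
    platforms = {"CRISPR": dataset.crispr, "SHRNA": dataset.shrna}
    expr = dataset.expression

    # per-cell-line correlations: score vs expression (all genes, called
    # E genes, called NE genes) and CRISPR vs shRNA
    corr_rows = []
    for name, scores in platforms.items():
        for label, subset in (("all", None),
                              ("called_E", calls[(name, "E")].calls),
                              ("called_NE", calls[(name, "NE")].calls)):
            series, mean = per_cellline_correlation(scores, expr, subset=subset)
            corr_rows.append(series.rename_axis("cell_line").reset_index()
                             .assign(comparison=f"{name}_vs_expression",
                                     gene_set=label))
            manifest["stages"][f"corr_{name}_{label}"] = {"mean_r": mean}
    series, mean = per_cellline_correlation(dataset.crispr, dataset.shrna)
    corr_rows.append(series.rename_axis("cell_line").reset_index()
                     .assign(comparison="CRISPR_vs_SHRNA", gene_set="all"))
    manifest["stages"]["corr_CRISPR_vs_SHRNA"] = {"mean_r": mean}
    pd.concat(corr_rows, ignore_index=True).to_csv(
        out / "correlations.csv", index=False)

    strata = [expression_strata_counts(calls[(name, "E")], calls[(name, "NE")],
                                       expr, p, side).assign(platform=name)
              for name in platforms
              for p in config.strata_fracs
              for side in ("low", "high")]
    pd.concat(strata, ignore_index=True).to_csv(
        out / "strata_counts.csv", index=False)

    assignment = group8_classify(calls[("CRISPR", "E")], calls[("CRISPR", "NE")],
                                 calls[("SHRNA", "E")], calls[("SHRNA", "NE")])
    assignment.to_csv(out / "groups.csv", index=False)
    group_expression_summary(assignment, expr).to_csv(out / "group_summary.csv")
    manifest["stages"]["group8"] = {
        str(g): int(c) for g, c in
        assignment["group"].value_counts().sort_index().items()}

    dens_rows = []
    for (name, cls), cs in calls.items():
        values = [expr.data.at[g, cell]
                  for cell, gs in cs.calls.items() for g in gs]
        if len(set(values)) < 2:
            continue
        summary = expression_density(values)
        dens_rows.append(pd.DataFrame({"grid": summary.grid,
                                       "density": summary.density,
                                       "platform": name, "class": cls}))
        manifest["stages"][f"density_{name}_{cls}"] = {
            "bandwidth": summary.bandwidth, "n_peaks": int(summary.peaks.size)}
        u, w = low_expression_report(cs, expr, config.expression_threshold)
        manifest["stages"][f"low_expression_{name}_{cls}"] = {
            "threshold": config.expression_threshold,
            "unique": u, "with_overlap": w}
    if dens_rows:
        pd.concat(dens_rows, ignore_index=True).to_csv(
            out / "density.csv", index=False)

    profiles = []
    k = min(config.profile_top_k, int(dataset.gene_ids.size))
    for name in platforms:
        for cls in ("E", "NE"):
            top = rank_common(fits[name], cls, k)
            prof = essentiality_profile(labels[name], top)
            prof.insert(0, "platform", name)
            prof.insert(1, "ranked_class", cls)
            profiles.append(prof)
    pd.concat(profiles, ignore_index=True).to_csv(
        out / "profiles.csv", index=False)


def _config_dict(config: RunConfig) -> dict:
    d = dataclasses.asdict(config)
    return d


def _write_manifest(out: Path, manifest: dict) -> None:
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
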