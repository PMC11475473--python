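"""Planted-signal synthetic benchmark for the screening pipeline.

Generates paired knockout (CRISPR) and knockdown (shRNA) essentiality
matrices, a log2-TPM-scale expression matrix, and the ground truth
needed for recovery tests, with the statistical structure the analysis
assumes:

* a two-mode (low / high) expression model straddling the 1.8 log2 TPM
  threshold, shared across cell lines up to small jitter;
* a set of planted common essential genes whose scores receive a strong
  negative shift in every cell line on both platforms, with magnitude
  mildly increasing with expression (the planted negative
  essentiality-expression coupling);
* per-cell-line, per-platform false positives standing in for
  off-target effects;
* an expression-dependent knockout blind spot: below the attenuation
  threshold the CRISPR effect is multiplied by ``attenuation_factor``,
  and all lowly expressed genes additionally receive a gene-level
  positive CRISPR score bias (loss of an unexpressed locus scores
  neutral-to-beneficial), so low-expression essentials are detectable
  by the knockdown platform only and tend to be miscalled nonessential
  by knockout.

Everything is deterministic given the config seed.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable

import numpy as np
import pandas as pd
import yaml

from .io import AlignedDataset, ScreenMatrix


@dataclasses.dataclass
class SyntheticConfig:
    """Stated world of the synthetic benchmark.

    Defaults emulate a medium-sized screening panel: 2000 genes by 50
    cell lines with 200 planted common essentials, a quarter of them
    lowly expressed, per-platform score noise 0.3 and a 5% per-cell-line
    false-positive rate.
    """

    m: int = 2000
    n: int = 50
    n_essential: int = 200
    frac_low_expr_essential: float = 0.25
    effect_mean: float = 1.5
    effect_sd: float = 0.3
    noise_sd_crispr: float = 0.3
    noise_sd_shrna: float = 0.3
    fp_rate: float = 0.05
    attenuation_threshold: float = 1.8
    attenuation_factor: float = 0.1
    expr_low_mean: float = 1.0
    expr_low_sd: float = 0.5
    expr_high_mean: float = 6.0
    expr_high_sd: float = 1.5
    # background genes drawn from the low-expression mode
    frac_low_expr_background: float = 0.3
    # effect magnitude multiplier slope per unit expr / expr_high_mean
    expr_effect_coupling: float = 0.5
    # gene-level positive CRISPR score bias below the attenuation threshold
    low_expr_knockout_bias_mean: float = 0.5
    low_expr_knockout_bias_sd: float = 0.3
    expr_jitter_sd: float = 0.1
    seed: int = 7

    def __post_init__(self) -> None:
        if not 0 < self.n_essential < self.m:
            raise ValueError("need 0 < n_essential < m")
        for name in ("effect_sd", "noise_sd_crispr", "noise_sd_shrna",
                     "expr_low_sd", "expr_high_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.fp_rate < 0.5:
            raise ValueError("fp_rate must be in [0, 0.5)")
        if not 0.0 <= self.attenuation_factor <= 1.0:
            raise ValueError("attenuation_factor must be in [0, 1]")
        if not 0.0 <= self.frac_low_expr_essential <= 1.0:
            raise ValueError("frac_low_expr_essential must be in [0, 1]")

    @classmethod
    def from_yaml(cls, path) -> "SyntheticConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)


@dataclasses.dataclass
class SyntheticTruth:
    """Ground truth of a synthetic run."""

    planted_essential: frozenset[str]
    per_cellline_false_positives: dict[str, dict[str, frozenset[str]]]
    expression_mode: dict[str, str]  # gene -> "low" | "high"

    def to_frame(self) -> pd.DataFrame:
        rows = [("planted_essential", "", "", g)
                for g in sorted(self.planted_essential)]
        rows += [("expression_mode", "", mode, g)
                 for g, mode in sorted(self.expression_mode.items())]
        for platform, by_cell in sorted(self.per_cellline_false_positives.items()):
            for cell, genes in sorted(by_cell.items()):
                rows += [("false_positive", platform, cell, g)
                         for g in sorted(genes)]
        return pd.DataFrame(rows, columns=["record", "platform", "context", "gene"])


def _gene_ids(m: int) -> np.ndarray:
    return np.array([f"G{i:05d}" for i in range(m)])


def _cell_ids(n: int) -> np.ndarray:
    return np.array([f"C{j:04d}" for j in range(n)])


def generate(config: SyntheticConfig) -> tuple[AlignedDataset, SyntheticTruth]:
    """Generate an aligned synthetic dataset plus its ground truth."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    genes = _gene_ids(cfg.m)
    cells = _cell_ids(cfg.n)

    planted = np.sort(rng.choice(cfg.m, size=cfg.n_essential, replace=False))
    planted_mask = np.zeros(cfg.m, dtype=bool)
    planted_mask[planted] = True

    # expression modes: a fixed fraction of essentials and of background
    low_mode = np.zeros(cfg.m, dtype=bool)
    n_low_ess = int(round(cfg.frac_low_expr_essential * cfg.n_essential))
    if n_low_ess:
        low_mode[rng.choice(planted, size=n_low_ess, replace=False)] = True
    background = np.flatnonzero(~planted_mask)
    n_low_bg = int(round(cfg.frac_low_expr_background * background.size))
    if n_low_bg:
        low_mode[rng.choice(background, size=n_low_bg, replace=False)] = True

    base_expr = np.where(
        low_mode,
        rng.normal(cfg.expr_low_mean, cfg.expr_low_sd, cfg.m),
        rng.normal(cfg.expr_high_mean, cfg.expr_high_sd, cfg.m))
    base_expr = np.clip(base_expr, 0.0, None)
    expr = np.clip(base_expr[:, None]
                   + rng.normal(0.0, cfg.expr_jitter_sd, (cfg.m, cfg.n)),
                   0.0, None)

    # per-gene essential effect magnitude and knockout low-expression bias
    effect = np.zeros(cfg.m)
    effect[planted] = np.abs(rng.normal(cfg.effect_mean, cfg.effect_sd,
                                        cfg.n_essential))
    ko_bias = rng.normal(cfg.low_expr_knockout_bias_mean,
                         cfg.low_expr_knockout_bias_sd, cfg.m)

    crispr = rng.normal(0.0, cfg.noise_sd_crispr, (cfg.m, cfg.n))
    shrna = rng.normal(0.0, cfg.noise_sd_shrna, (cfg.m, cfg.n))

    # planted effects, stronger for higher-expressed genes
    coupling = 1.0 + cfg.expr_effect_coupling * expr / cfg.expr_high_mean
    shift = effect[:, None] * coupling
    low_cell = expr < cfg.attenuation_threshold
    shrna -= shift
    crispr -= shift * np.where(low_cell, cfg.attenuation_factor, 1.0)
    crispr += np.where(low_cell, ko_bias[:, None], 0.0)

    # per-cell-line, per-platform false positives among non-planted genes
    n_fp = int(round(cfg.fp_rate * background.size))
    fps: dict[str, dict[str, frozenset[str]]] = {"CRISPR": {}, "SHRNA": {}}
    for platform, mat in (("CRISPR", crispr), ("SHRNA", shrna)):
        for j, cell in enumerate(cells):
            if n_fp == 0:
                fps[platform][cell] = frozenset()
                continue
            hit = rng.choice(background, size=n_fp, replace=False)
            mat[hit, j] -= np.abs(rng.normal(cfg.effect_mean, cfg.effect_sd, n_fp))
            fps[platform][cell] = frozenset(genes[hit])

    def _matrix(values: np.ndarray, kind: str, platform: str) -> ScreenMatrix:
        return ScreenMatrix(pd.DataFrame(values, index=genes, columns=cells),
                            kind=kind, platform=platform)

    dataset = AlignedDataset(
        crispr=_matrix(crispr, "essentiality", "CRISPR"),
        shrna=_matrix(shrna, "essentiality", "SHRNA"),
        expression=_matrix(expr, "expression", ""))
    truth = SyntheticTruth(
        planted_essential=frozenset(genes[planted]),
        per_cellline_false_positives=fps,
        expression_mode={g: ("low" if lo else "high")
                         for g, lo in zip(genes, low_mode)})
    return dataset, truth


def recall_of_planted(ranked: Iterable[str], truth: SyntheticTruth) -> float:
    """Fraction of planted essentials present in a ranked gene list."""
    ranked = set(ranked)
    planted = truth.planted_essential
    return len(ranked & planted) / len(planted)
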