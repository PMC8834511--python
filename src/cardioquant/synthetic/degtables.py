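"""Paired synthetic differential-expression tables with controlled overlap.

Builds two DEG tables over one gene universe with exact counts of significant
genes in each, an exact number of shared significant genes, and a controlled
fraction of shared genes regulated in the same direction in both — the
structure needed to exercise set-overlap and direction-concordance analyses
against known ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["DegSimConfig", "generate_deg_tables"]


@dataclass
class DegSimConfig:
    """Counts and effect-size parameters for a paired DEG simulation.

    ``overlap_count`` significant genes are shared between the two tables;
    ``round(concordant_fraction * overlap_count)`` of those get same-signed
    log2 fold changes in both tables.  Significant genes receive adjusted
    p-values strictly below 0.05, all others at or above it.
    """

    n_genes: int = 20000
    n_deg_a: int = 1000
    n_deg_b: int = 1000
    overlap_count: int = 300
    concordant_fraction: float = 0.9
    log2fc_mean: float = 1.5
    log2fc_sd: float = 0.5
    alpha: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_genes, self.n_deg_a, self.n_deg_b, self.overlap_count) < 0:
            raise ValueError("counts must be non-negative")
        if self.overlap_count > min(self.n_deg_a, self.n_deg_b):
            raise ValueError("overlap_count exceeds a table's DEG count")
        if self.n_deg_a + self.n_deg_b - self.overlap_count > self.n_genes:
            raise ValueError("DEG sets do not fit in the gene universe")
        if not 0 <= self.concordant_fraction <= 1:
            raise ValueError("concordant_fraction must be in [0, 1]")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")


def _nonzero_signed(
    rng: np.random.Generator, sign: np.ndarray, mean: float, sd: float
) -> np.ndarray:
    mag = np.abs(rng.normal(mean, sd, size=sign.shape))
    mag = np.maximum(mag, 1e-3)  # concordance needs a definite sign
    return sign * mag


def generate_deg_tables(cfg: DegSimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Two DEG tables (gene_id, log2fc, padj) with exact set structure.

    Deterministic given ``cfg.seed``.  Gene ids are Ensembl-like
    (``SYNDARG00000000042``; synthetic, not real accessions).
    """
    rng = np.random.default_rng(cfg.seed)
    ids = np.array([f"SYNDARG{i:011d}" for i in range(cfg.n_genes)])
    perm = rng.permutation(cfg.n_genes)
    shared = perm[: cfg.overlap_count]
    only_a = perm[cfg.overlap_count : cfg.n_deg_a]
    only_b = perm[cfg.n_deg_a : cfg.n_deg_a + cfg.n_deg_b - cfg.overlap_count]

    def table(sig_idx: np.ndarray, sign_for: dict[int, float]) -> pd.DataFrame:
        padj = rng.uniform(cfg.alpha, 1.0, cfg.n_genes)
        padj[sig_idx] = rng.uniform(0.0, cfg.alpha * (1 - 1e-9), len(sig_idx))
        sign = rng.choice([-1.0, 1.0], cfg.n_genes)
        for idx, s in sign_for.items():
            sign[idx] = s
        log2fc = _nonzero_signed(rng, sign, cfg.log2fc_mean, cfg.log2fc_sd)
        return pd.DataFrame({"gene_id": ids, "log2fc": log2fc, "padj": padj})

    sign_shared_a = rng.choice([-1.0, 1.0], cfg.overlap_count)
    n_conc = int(round(cfg.concordant_fraction * cfg.overlap_count))
    sign_shared_b = np.concatenate(
        [sign_shared_a[:n_conc], -sign_shared_a[n_conc:]]
    )
    sig_a = np.concatenate([shared, only_a]).astype(int)
    sig_b = np.concatenate([shared, only_b]).astype(int)
    a = table(sig_a, {int(g): s for g, s in zip(shared, sign_shared_a)})
    b = table(sig_b, {int(g): s for g, s in zip(shared, sign_shared_b)})
    return a, b
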