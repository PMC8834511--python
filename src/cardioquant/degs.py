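"""Set-level comparisons of differential-expression (DEG) tables.

Consumes gene-level tables (gene_id, log2fc, padj) as produced by standard
differential-expression tools and performs the downstream set arithmetic:
significance calling at adjusted p < alpha (strict), overlap between two
studies with direction concordance, marker-panel reports, and
unique-marker intersections with a lineage rollup.  Gene identity is matched
by exact string on Ensembl-style ids, optionally after stripping version
suffixes (``ENSDARG...X.3`` -> ``ENSDARG...X``).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, NamedTuple

import numpy as np
import pandas as pd

__all__ = [
    "validate_deg_table",
    "call_degs",
    "overlap_degs",
    "panel_report",
    "unique_marker_intersection",
    "OverlapResult",
    "PanelReport",
    "MarkerIntersection",
]

REQUIRED_COLUMNS = ("gene_id", "log2fc", "padj")


def validate_deg_table(
    table: pd.DataFrame, strip_versions: bool = True
) -> pd.DataFrame:
    """Check schema and invariants; returns a normalized copy.

    Requires columns gene_id / log2fc / padj, unique gene ids and padj in
    [0, 1].  With ``strip_versions`` a trailing ``.N`` version suffix is
    removed from every id before matching.
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"DEG table missing columns: {missing}")
    out = table.loc[:, list(REQUIRED_COLUMNS)].copy()
    out["gene_id"] = out["gene_id"].astype(str)
    if strip_versions:
        out["gene_id"] = out["gene_id"].str.replace(r"\.\d+$", "", regex=True)
    if out["gene_id"].duplicated().any():
        dup = out.loc[out["gene_id"].duplicated(), "gene_id"].iloc[0]
        raise ValueError(f"duplicate gene_id in table (e.g. {dup!r})")
    pad = out["padj"].to_numpy(dtype=float)
    if np.any((pad < 0) | (pad > 1) | np.isnan(pad)):
        raise ValueError("padj values must lie in [0, 1]")
    return out


def call_degs(
    table: pd.DataFrame, alpha: float = 0.05, strip_versions: bool = True
) -> pd.DataFrame:
    """Significant genes (padj strictly below alpha) with their direction.

    Returns the significant rows with a ``direction`` column in
    {"up", "down", "zero"}; genes with log2fc exactly 0 are flagged "zero"
    and belong to neither sign set.
    """
    t = validate_deg_table(table, strip_versions)
    sig = t[t["padj"] < alpha].copy()
    sig["direction"] = np.select(
        [sig["log2fc"] > 0, sig["log2fc"] < 0], ["up", "down"], default="zero"
    )
    return sig.reset_index(drop=True)


@dataclass
class OverlapResult:
    """Overlap of two studies' significant gene sets.

    ``pct_concordant`` is the share of shared significant genes whose log2
    fold changes have the same sign in both tables; shared genes with a zero
    fold change in either table are excluded from the concordance denominator
    and counted in ``n_zero_fc_shared``.  ``None`` when no shared gene has a
    definite sign in both.
    """

    n_a: int
    n_b: int
    n_overlap: int
    pct_of_a: float
    pct_of_b: float
    n_concordant: int
    pct_concordant: float | None
    n_zero_fc_shared: int = 0


def overlap_degs(
    a: pd.DataFrame,
    b: pd.DataFrame,
    alpha: float = 0.05,
    strip_versions: bool = True,
) -> OverlapResult:
    """Intersection and direction concordance of two DEG tables."""
    sig_a = call_degs(a, alpha, strip_versions)
    sig_b = call_degs(b, alpha, strip_versions)
    set_a = set(sig_a["gene_id"])
    set_b = set(sig_b["gene_id"])
    shared = set_a & set_b
    n_overlap = len(shared)
    fa = sig_a.set_index("gene_id")["log2fc"]
    fb = sig_b.set_index("gene_id")["log2fc"]
    n_conc = 0
    n_zero = 0
    for g in shared:
        if fa[g] == 0 or fb[g] == 0:
            n_zero += 1
        elif np.sign(fa[g]) == np.sign(fb[g]):
            n_conc += 1
    denom = n_overlap - n_zero
    return OverlapResult(
        n_a=len(set_a),
        n_b=len(set_b),
        n_overlap=n_overlap,
        pct_of_a=100.0 * n_overlap / len(set_a) if set_a else 0.0,
        pct_of_b=100.0 * n_overlap / len(set_b) if set_b else 0.0,
        n_concordant=n_conc,
        pct_concordant=100.0 * n_conc / denom if denom > 0 else None,
        n_zero_fc_shared=n_zero,
    )


class PanelReport(NamedTuple):
    """Gene-level rows and per-annotation counts for a marker panel."""

    genes: pd.DataFrame
    summary: pd.DataFrame


def panel_report(
    table: pd.DataFrame,
    panel: pd.DataFrame,
    alpha: float = 0.05,
    strip_versions: bool = True,
) -> PanelReport:
    """Expression status of every panel gene.

    ``panel`` needs columns gene_id and annotation (e.g. a lineage or a panel
    name such as "complement").  Panel genes absent from the DEG table are
    kept as explicit "NA" rows, never dropped.  Per annotation the summary
    counts genes in the panel and how many are significantly up / down,
    unchanged, or absent.
    """
    if not {"gene_id", "annotation"}.issubset(panel.columns):
        raise ValueError("panel needs columns gene_id and annotation")
    pan = panel.loc[:, ["gene_id", "annotation"]].copy()
    pan["gene_id"] = pan["gene_id"].astype(str)
    if strip_versions:
        pan["gene_id"] = pan["gene_id"].str.replace(r"\.\d+$", "", regex=True)
    if pan["gene_id"].duplicated().any():
        raise ValueError("duplicate gene_id in panel")
    t = validate_deg_table(table, strip_versions).set_index("gene_id")

    rows = []
    for g, ann in zip(pan["gene_id"], pan["annotation"]):
        if g not in t.index:
            rows.append((g, ann, np.nan, np.nan, "NA"))
            continue
        fc, padj = float(t.at[g, "log2fc"]), float(t.at[g, "padj"])
        if padj < alpha and fc > 0:
            status = "up"
        elif padj < alpha and fc < 0:
            status = "down"
        else:
            status = "unchanged"
        rows.append((g, ann, fc, padj, status))
    genes = pd.DataFrame(
        rows, columns=["gene_id", "annotation", "log2fc", "padj", "status"]
    )
    summary = (
        genes.groupby("annotation", sort=True)
        .agg(
            n_in_panel=("gene_id", "size"),
            n_up=("status", lambda s: int((s == "up").sum())),
            n_down=("status", lambda s: int((s == "down").sum())),
            n_unchanged=("status", lambda s: int((s == "unchanged").sum())),
            n_na=("status", lambda s: int((s == "NA").sum())),
        )
        .reset_index()
    )
    return PanelReport(genes, summary)


@dataclass
class MarkerIntersection:
    """Unique-marker hits per population plus a lineage rollup."""

    per_population: dict[str, int]
    per_lineage: dict[str, int]
    n_hits: int
    n_unique_markers: int
    removed_non_unique: tuple[str, ...]


def unique_marker_intersection(
    up_degs: Iterable[str],
    marker_sets: Mapping[str, Iterable[str]],
    lineages: Mapping[str, str] | None = None,
) -> MarkerIntersection:
    """Intersect an up-regulated gene set with unique cell-population markers.

    A marker listed for more than one population is not unique to any and is
    removed before intersecting.  ``lineages`` maps population -> lineage
    (e.g. myeloid / lymphoid / erythroid) for the rollup; populations without
    a mapping roll up under "unassigned".
    """
    sets = {p: set(map(str, gs)) for p, gs in marker_sets.items()}
    counts: dict[str, int] = {}
    for p, gs in sets.items():
        for g in gs:
            counts[g] = counts.get(g, 0) + 1
    non_unique = tuple(sorted(g for g, c in counts.items() if c > 1))
    unique_sets = {p: {g for g in gs if counts[g] == 1} for p, gs in sets.items()}
    up = set(map(str, up_degs))
    per_pop = {p: len(gs & up) for p, gs in unique_sets.items()}
    per_lin: dict[str, int] = {}
    for p, n in per_pop.items():
        lin = (lineages or {}).get(p, "unassigned")
        per_lin[lin] = per_lin.get(lin, 0) + n
    return MarkerIntersection(
        per_population=per_pop,
        per_lineage=per_lin,
        n_hits=sum(per_pop.values()),
        n_unique_markers=sum(len(gs) for gs in unique_sets.values()),
        removed_non_unique=non_unique,
    )
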