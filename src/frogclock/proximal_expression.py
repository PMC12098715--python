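"""Expression of genes proximal to age-associated CpGs.

Each significant CpG is mapped to the nearest gene TSS within a distance
cutoff (5 kb by default), gene ids are translated through an orthology map
into the expression atlas's namespace, and per-tissue mean expression of the
resulting gene set is compared against all genes with a Wilcoxon rank-sum
test and a log2 fold change of means.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .age_association import bh_adjust
from .io_formats import GeneAnnotation

__all__ = [
    "ProximalGeneSet",
    "ExpressionComparison",
    "nearest_tss",
    "map_homologs",
    "compare_expression",
    "MAX_TSS_DISTANCE",
]

logger = logging.getLogger(__name__)

MAX_TSS_DISTANCE = 5000
_EXACT_MAX_N = 12


@dataclass
class ProximalGeneSet:
    direction: str                  # positive | negative
    genes: list[str]                # deduplicated, expression-table namespace
    cpg_to_gene: pd.DataFrame       # cpg-indexed: gene_id, signed_distance


@dataclass
class ExpressionComparison:
    table: pd.DataFrame  # (direction, tissue)-indexed: mean_expr_set,
    #                      mean_expr_all, log2_fc, wilcoxon_p, p_adj, n_set


def nearest_tss(
    cpgs: pd.DataFrame,
    ann: GeneAnnotation,
    max_distance: int = MAX_TSS_DISTANCE,
) -> pd.DataFrame:
    """Nearest-TSS assignment per CpG within ``max_distance``.

    ``cpgs`` needs columns site_id, chrom, pos. The signed distance is
    positive when the CpG lies downstream of the TSS in gene orientation,
    negative upstream. Exact distance ties resolve to the gene earliest in
    (chrom, tss_pos, gene_id) order. CpGs with no TSS within range (or on
    TSS-free chromosomes) are dropped.
    """
    if len(ann.genes) == 0:
        raise ValueError("gene annotation is empty")
    g = ann.genes.sort_values(["chrom", "tss_pos", "gene_id"], kind="mergesort")
    rows = []
    for c, grp in g.groupby("chrom", sort=False):
        sub = cpgs[cpgs["chrom"] == c]
        if sub.empty:
            continue
        tss = grp["tss_pos"].to_numpy()
        gene_ids = grp["gene_id"].to_numpy()
        strands = grp["strand"].to_numpy()
        pos = sub["pos"].to_numpy()
        right = np.searchsorted(tss, pos, side="left")
        left = right - 1
        for sid, p, l, r in zip(sub["site_id"], pos, left, right):
            candidates = []
            if l >= 0:
                candidates.append(l)
            if r < len(tss):
                candidates.append(r)
            if not candidates:
                continue
            dists = [abs(p - tss[i]) for i in candidates]
            best = min(dists)
            if best > max_distance:
                continue
            # tie-break: sorted (chrom, tss_pos, gene_id) order = smaller index
            i = candidates[int(np.argmin(dists))]
            if len(candidates) == 2 and dists[0] == dists[1]:
                i = candidates[0]
            signed = int(p - tss[i]) if strands[i] == "+" else int(tss[i] - p)
            rows.append({"cpg": sid, "gene_id": gene_ids[i], "signed_distance": signed})
    return pd.DataFrame(rows, columns=["cpg", "gene_id", "signed_distance"]).set_index(
        "cpg"
    )


def map_homologs(
    genes: list[str],
    homolog_map: pd.DataFrame,
    expression_genes: pd.Index | None = None,
) -> list[str]:
    """Translate gene ids through the orthology map, deduplicating.

    Genes missing from the map, or (optionally) from the expression table,
    are dropped; counts are logged.
    """
    lookup = dict(zip(homolog_map["gene_id"], homolog_map["homolog_id"]))
    translated = []
    n_unmapped = n_missing = 0
    seen = set()
    for gid in genes:
        hom = lookup.get(gid)
        if hom is None:
            n_unmapped += 1
            continue
        if expression_genes is not None and hom not in expression_genes:
            n_missing += 1
            continue
        if hom not in seen:
            seen.add(hom)
            translated.append(hom)
    if n_unmapped or n_missing:
        logger.info(
            "map_homologs: dropped %d unmapped and %d absent-from-expression gene(s)",
            n_unmapped, n_missing,
        )
    return translated


def build_proximal_gene_set(
    cpg_sites: pd.DataFrame,
    ann: GeneAnnotation,
    homolog_map: pd.DataFrame,
    expression_genes: pd.Index,
    direction: str,
    max_distance: int = MAX_TSS_DISTANCE,
) -> ProximalGeneSet:
    """Full CpG -> nearest gene -> homolog -> expression-namespace pipeline."""
    mapping = nearest_tss(cpg_sites, ann, max_distance)
    genes = map_homologs(
        mapping["gene_id"].tolist(), homolog_map, expression_genes
    )
    return ProximalGeneSet(direction=direction, genes=genes, cpg_to_gene=mapping)


def _rank_sum_p(set_vals: np.ndarray, bg_vals: np.ndarray) -> float:
    """Two-sided Wilcoxon rank-sum p: exact enumeration for small untied
    groups, normal approximation with tie correction otherwise."""
    small = len(set_vals) <= _EXACT_MAX_N and len(bg_vals) <= _EXACT_MAX_N
    no_ties = len(np.unique(np.concatenate([set_vals, bg_vals]))) == len(set_vals) + len(
        bg_vals
    )
    method = "exact" if (small and no_ties) else "asymptotic"
    return float(
        stats.mannwhitneyu(set_vals, bg_vals, alternative="two-sided", method=method).pvalue
    )


def compare_expression(
    sets: list[ProximalGeneSet],
    expr: pd.DataFrame,
    exclude_set_from_background: bool = False,
) -> ExpressionComparison:
    """Per-tissue comparison of each gene set's expression against all genes.

    The background is every gene in the expression table (including set
    members unless ``exclude_set_from_background``). BH adjustment runs
    across tissues within each direction. log2 fold change is defined only
    when both means are positive.
    """
    rows = []
    for gs in sets:
        if not gs.genes:
            logger.warning("empty %s gene set; comparison skipped", gs.direction)
            continue
        missing = [g for g in gs.genes if g not in expr.index]
        if missing:
            raise ValueError(f"gene set contains genes absent from expression: {missing[:5]}")
        pvals = []
        for tissue in expr.columns:
            set_vals = expr.loc[gs.genes, tissue].to_numpy(dtype=float)
            bg = expr.drop(index=gs.genes) if exclude_set_from_background else expr
            bg_vals = bg[tissue].to_numpy(dtype=float)
            mean_set = float(set_vals.mean())
            mean_all = float(bg_vals.mean())
            log2_fc = (
                float(np.log2(mean_set / mean_all))
                if mean_set > 0 and mean_all > 0
                else np.nan
            )
            p = _rank_sum_p(set_vals, bg_vals)
            pvals.append(p)
            rows.append(
                {
                    "direction": gs.direction,
                    "tissue": tissue,
                    "n_set": len(gs.genes),
                    "mean_expr_set": mean_set,
                    "mean_expr_all": mean_all,
                    "log2_fc": log2_fc,
                    "wilcoxon_p": p,
                }
            )
    table = pd.DataFrame(
        rows,
        columns=[
            "direction", "tissue", "n_set", "mean_expr_set", "mean_expr_all",
            "log2_fc", "wilcoxon_p",
        ],
    )
    if len(table):
        table["p_adj"] = np.nan
        for d in table["direction"].unique():
            mask = table["direction"] == d
            table.loc[mask, "p_adj"] = bh_adjust(table.loc[mask, "wilcoxon_p"].to_numpy())
    else:
        table["p_adj"] = pd.Series(dtype=float)
    return ExpressionComparison(table=table.set_index(["direction", "tissue"]))
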