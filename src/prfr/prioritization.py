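"""SNP prioritization and downstream annotation.

Ranks SNPs by permutation importance, LASSO selection frequency, or
univariate association p, takes top fractions (25/50/75% with a
round-half-up count and all boundary ties included), maps SNPs to genes
within a 50 kb window, runs hypergeometric over-representation against gene
sets with Benjamini-Hochberg FDR, and joins LD-pair/eQTL tables to expand the
modeling SNPs to eQTL target genes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_formats import GeneInterval, GeneSetCollection, SNPInfo


@dataclass
class PrioritizedSNPSet:
    method: str  # prfr_vim | lasso_freq | univariate_p
    fraction: float
    snp_ids: list[str]  # ordered by rank


def rank_by_univariate_p(assoc: pd.DataFrame) -> pd.DataFrame:
    """Ranking table (snp_id, value, rank) by ascending p, ties by snp_id."""
    df = assoc[["snp_id", "p"]].copy()
    df = df.sort_values(["p", "snp_id"], kind="mergesort").reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    return df.rename(columns={"p": "value"})


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def top_fraction(
    ranking: pd.DataFrame, fraction: float, method: str = "ranking"
) -> PrioritizedSNPSet:
    """Top-``fraction`` of a ranking, including all ties at the boundary.

    ``ranking`` needs columns snp_id and rank (1 = best) plus the ranked
    value column ('vim', 'frequency', or 'value'); the cutoff count is
    round-half-up(fraction * n), then every SNP whose ranked value ties the
    last included one is also included.
    """
    if ranking.empty:
        raise ValueError("empty ranking")
    if not (0 < fraction <= 1):
        raise ValueError("fraction must lie in (0, 1]")
    value_col = next(
        c for c in ("vim", "frequency", "value") if c in ranking.columns
    )
    df = ranking.sort_values("rank", kind="mergesort").reset_index(drop=True)
    k = max(1, _round_half_up(fraction * len(df)))
    if k < len(df):
        boundary = df.loc[k - 1, value_col]
        while k < len(df) and df.loc[k, value_col] == boundary:
            k += 1
    return PrioritizedSNPSet(
        method=method, fraction=fraction, snp_ids=df["snp_id"].head(k).tolist()
    )


# ---------------------------------------------------------------------------
# SNP -> gene mapping
# ---------------------------------------------------------------------------


def map_snps_to_genes(
    snps: list[SNPInfo], genes: list[GeneInterval], window: int = 50_000
) -> pd.DataFrame:
    """Genes within ``window`` bp of each SNP (inclusive; 0 bp inside a gene).

    Distance is from the SNP position to the nearest gene boundary on the
    same chromosome.  Returns a long DataFrame (snp_id, gene_id, distance);
    intergenic SNPs appear once with gene_id "" and distance NaN.
    """
    by_chrom: dict[str, list[GeneInterval]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    rows = []
    for snp in snps:
        hits = []
        for g in by_chrom.get(snp.chrom, ()):
            if g.start <= snp.pos <= g.end:
                d = 0
            elif snp.pos < g.start:
                d = g.start - snp.pos
            else:
                d = snp.pos - g.end
            if d <= window:
                hits.append((g.gene_id, d))
        if hits:
            for gene_id, d in sorted(hits, key=lambda t: (t[1], t[0])):
                rows.append((snp.snp_id, gene_id, d))
        else:
            rows.append((snp.snp_id, "", np.nan))
    return pd.DataFrame(rows, columns=["snp_id", "gene_id", "distance"])


def mapped_genes(mapping: pd.DataFrame) -> list[str]:
    """Unique mapped gene ids (intergenic rows excluded), sorted."""
    return sorted(set(mapping.loc[mapping["gene_id"] != "", "gene_id"]))


# ---------------------------------------------------------------------------
# Over-representation analysis
# ---------------------------------------------------------------------------


def hypergeometric_enrichment(
    query_genes: set[str],
    collection: GeneSetCollection,
    universe: set[str],
    fdr_cutoff: float = 0.05,
) -> pd.DataFrame:
    """Upper-tail hypergeometric over-representation of ``query_genes`` in
    each gene set, with Benjamini-Hochberg FDR across all tested sets.

    Sets are intersected with the universe before testing; the query must be
    a subset of the universe.  Records with fdr_p <= ``fdr_cutoff``
    (inclusive) are flagged significant.
    """
    if not universe:
        raise ValueError("empty gene universe")
    if not query_genes <= universe:
        extra = sorted(query_genes - universe)[:5]
        raise ValueError(f"query genes outside the universe: {extra}")
    rows = []
    for set_id, (description, members) in sorted(collection.items()):
        in_universe = set(members) & universe
        if not in_universe:
            continue
        overlap = len(in_universe & query_genes)
        m, nq, nu = len(in_universe), len(query_genes), len(universe)
        p = float(stats.hypergeom.sf(overlap - 1, nu, m, nq))
        rows.append((set_id, description, overlap, m, nq, nu, p))
    df = pd.DataFrame(
        rows,
        columns=[
            "set_id",
            "description",
            "overlap",
            "set_size",
            "query_size",
            "universe_size",
            "p",
        ],
    )
    if df.empty:
        df["fdr_p"] = []
        df["significant"] = []
        return df
    _, fdr, _, _ = multipletests(df["p"].to_numpy(), method="fdr_bh")
    df["fdr_p"] = fdr
    df["significant"] = df["fdr_p"] <= fdr_cutoff
    return df.sort_values(["p", "set_id"], kind="mergesort").reset_index(drop=True)


# ---------------------------------------------------------------------------
# LD expansion and eQTL join
# ---------------------------------------------------------------------------


def join_ld_eqtl(
    model_snps: list[str],
    ld_pairs: pd.DataFrame,
    eqtl: pd.DataFrame,
    r2_min: float = 0.8,
) -> pd.DataFrame:
    """Expand the modeling SNPs through LD (r2 >= ``r2_min``, undirected) and
    collect the eQTL target genes of the expanded set.

    Returns a DataFrame (gene_id, via_snp, model_snp) retaining, per target
    gene, which expanded SNP carried the eQTL and which modeling SNP it is
    linked to (itself, if the eQTL SNP is a modeling SNP).
    """
    r2 = ld_pairs["r2"].to_numpy(dtype=float) if len(ld_pairs) else np.array([])
    if r2.size and ((r2 < 0) | (r2 > 1)).any():
        raise ValueError("r2 outside [0,1]")
    model_set = set(model_snps)
    # expanded SNP -> the modeling SNP that brought it in
    provenance: dict[str, str] = {s: s for s in model_snps}
    for rec in ld_pairs.itertuples(index=False):
        if rec.r2 < r2_min:
            continue
        a, b = str(rec.snp_a), str(rec.snp_b)
        if a in model_set and b not in provenance:
            provenance[b] = a
        if b in model_set and a not in provenance:
            provenance[a] = b
    rows = []
    for rec in eqtl.itertuples(index=False):
        snp = str(rec.snp)
        if snp in provenance:
            rows.append((str(rec.target_gene), snp, provenance[snp]))
    df = pd.DataFrame(rows, columns=["gene_id", "via_snp", "model_snp"])
    return (
        df.drop_duplicates()
        .sort_values(["gene_id", "via_snp"], kind="mergesort")
        .reset_index(drop=True)
    )
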