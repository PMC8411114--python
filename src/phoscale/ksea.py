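"""Kinase-substrate enrichment (KSEA) and gene-set overrepresentation.

KSEA scores a kinase by how far the mean log2 fold change of its reported
substrate sites departs from the dataset background, weighted by the number
of matched substrates:

    z = (s_bar - p_bar) * sqrt(m) / delta

where ``s_bar`` is the mean over the kinase's m matched site-level fold
changes, and ``p_bar`` / ``delta`` are the mean / standard deviation of all
site-level fold changes in the chosen background.  When several
phospho-events (different multiplicities) cover the same substrate site,
their fold changes are averaged into one site-level value first.  p-values
are two-sided standard-normal tails of z, corrected by Benjamini-Hochberg
across kinases.

The overrepresentation test is the classical hypergeometric upper tail on
user-supplied gene sets, run separately for up- and down-regulated
phosphoprotein sets when directions are provided.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InputError
from .io import GeneSet, KinaseSubstrateRelation
from .diffreg import bh_adjust

MIN_SUBSTRATES = 1

SiteKey = tuple[str, str, int]  # (casefolded gene, residue, position)


@dataclass
class SubstrateMap:
    """Site-level fold changes matched to kinases."""

    #: kinase gene -> {site key -> site-level log2fc}
    kinase_sites: dict[str, dict[SiteKey, float]]
    #: all site-level log2fc values in the background
    background: dict[SiteKey, float]
    n_unmatched_relations: int


def site_level_values(event_log2fc: pd.Series, genes: pd.Series) -> dict[SiteKey, float]:
    """Collapse event-level fold changes (one per multiplicity) to one value
    per (gene, residue, position) site by averaging."""
    sums: dict[SiteKey, float] = {}
    counts: dict[SiteKey, int] = {}
    for key, fc in event_log2fc.items():
        if np.isnan(fc):
            continue
        protein, position, residue, _mult = key
        gene = str(genes.get(key, "")).casefold()
        site: SiteKey = (gene, residue, int(position))
        sums[site] = sums.get(site, 0.0) + float(fc)
        counts[site] = counts.get(site, 0) + 1
    return {site: sums[site] / counts[site] for site in sums}


def map_substrates(
    event_log2fc: pd.Series,
    genes: pd.Series,
    relations: list[KinaseSubstrateRelation],
) -> SubstrateMap:
    """Match kinase-substrate relations to site-level fold changes.

    Matching is on (case-folded substrate gene, residue, position).
    Relations with no matching site are counted but excluded.
    """
    background = site_level_values(event_log2fc, genes)
    kinase_sites: dict[str, dict[SiteKey, float]] = {}
    unmatched = 0
    for rel in relations:
        site: SiteKey = (rel.substrate_gene.casefold(), rel.residue, rel.position)
        if site in background:
            kinase_sites.setdefault(rel.kinase_gene.casefold(), {})[site] = background[site]
        else:
            unmatched += 1
    return SubstrateMap(kinase_sites=kinase_sites, background=background, n_unmatched_relations=unmatched)


def kinase_zscore(
    substrate_map: SubstrateMap, min_substrates: int = MIN_SUBSTRATES
) -> pd.DataFrame:
    """Kinase Z-scores for all kinases with >= ``min_substrates`` matched
    substrate sites, BH-corrected across kinases."""
    values = np.array(list(substrate_map.background.values()), dtype=float)
    if values.size == 0:
        raise InputError("empty background: no site-level fold changes")
    p_bar = float(values.mean())
    delta = float(values.std(ddof=1)) if values.size > 1 else 0.0
    if delta == 0.0:
        raise InputError("degenerate background: zero standard deviation")
    rows = []
    for kinase in sorted(substrate_map.kinase_sites):
        sites = substrate_map.kinase_sites[kinase]
        m = len(sites)
        if m < min_substrates:
            continue
        s_bar = float(np.mean(list(sites.values())))
        z = (s_bar - p_bar) * np.sqrt(m) / delta
        p = 2.0 * float(stats.norm.sf(abs(z)))
        rows.append({"kinase": kinase, "m": m, "s_bar": s_bar, "p_bar": p_bar, "delta": delta, "z": z, "p": p})
    table = pd.DataFrame(rows, columns=["kinase", "m", "s_bar", "p_bar", "delta", "z", "p"])
    table["q"] = bh_adjust(table["p"].to_numpy()) if len(table) else []
    return table


def hypergeom_enrich(
    foreground: set[str],
    background: set[str],
    gene_sets: list[GeneSet],
    fdr: float = 0.01,
) -> pd.DataFrame:
    """Hypergeometric overrepresentation of gene sets in a foreground.

    For each term: k foreground hits, n foreground size, K background
    members of the term, N background size; p = P(X >= k) with
    X ~ Hypergeometric(N, K, n); BH correction across terms.
    """
    fg = {g.casefold() for g in foreground}
    bg = {g.casefold() for g in background}
    if not fg <= bg:
        raise InputError(f"foreground not contained in background: {sorted(fg - bg)[:10]}")
    N, n = len(bg), len(fg)
    rows = []
    for gs in gene_sets:
        members = gs.members & bg
        K = len(members)
        if K == 0:
            continue
        k = len(members & fg)
        p = float(stats.hypergeom.sf(k - 1, N, K, n)) if n else 1.0
        fold = (k / n) / (K / N) if n else 0.0
        rows.append(
            {"term_id": gs.term_id, "term_name": gs.term_name, "k": k, "n": n, "K": K, "N": N,
             "fold_enrichment": fold, "p": p}
        )
    table = pd.DataFrame(
        rows, columns=["term_id", "term_name", "k", "n", "K", "N", "fold_enrichment", "p"]
    )
    table["q"] = bh_adjust(table["p"].to_numpy()) if len(table) else []
    table["enriched"] = (table["q"] < fdr) if len(table) else []
    return table


def enrich_by_direction(
    diff: pd.DataFrame,
    genes: pd.Series,
    gene_sets: list[GeneSet],
    background: set[str],
    fdr: float = 0.01,
) -> dict[str, pd.DataFrame]:
    """Run the overrepresentation test separately on proteins with up- and
    down-regulated phospho-events (the split-by-direction convention)."""
    out: dict[str, pd.DataFrame] = {}
    reg = diff[diff["regulated"].astype(bool)]
    for direction in ("up", "down"):
        keys = reg.index[reg["direction"] == direction]
        fg = {str(genes.get(k, "")).casefold() for k in keys} - {""}
        out[direction] = hypergeom_enrich(fg & background, background, gene_sets, fdr=fdr)
    return out
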