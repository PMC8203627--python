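"""Transcriptomic spatial decoding of a parcel statistic map.

Given a parcel-wise t-statistic map and a donor-wise gene expression
panel, the decoding chain is:

1. gene_map_association — per-donor Pearson correlation of each gene's
   parcel profile with the map, aggregated across donors by Fisher-z
   mean, with a parametric one-sample test on the donor z-values;
2. spin_significance_filter — genes surviving parametric FDR are
   re-tested against spatial nulls built from randomly rotated maps;
3. donor_consistency_filter — only genes whose expression profiles
   agree across donors (all pairwise donor-donor correlations, Fisher-z
   one-sample test, FDR) are kept;
4. enrichment of the surviving list against user-supplied gene sets
   (hypergeometric / Fisher test) and against nested cell-type
   specificity sets at the four pSI stringency rings.
"""

from __future__ import annotations

import itertools
import warnings

import numpy as np
import pandas as pd
import scipy.stats

from .stats import fdr_bh, spin_nulls
from .synthetic import (
    CellTypeSpecificity,
    GeneExpressionPanel,
    ParcelAtlas,
    PSI_THRESHOLDS,
)

__all__ = [
    "gene_map_association",
    "spin_significance_filter",
    "donor_consistency_filter",
    "fisher_enrichment",
    "csea_enrichment",
]

_Z_CLIP = 1.0 - 1e-7


def _corr_rows(E: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Pearson correlation of each row of E with vector v."""
    Ec = E - E.mean(axis=1, keepdims=True)
    vc = v - v.mean()
    denom = np.linalg.norm(Ec, axis=1) * np.linalg.norm(vc)
    with np.errstate(invalid="ignore", divide="ignore"):
        return (Ec @ vc) / denom


def _donor_z_matrix(panel: GeneExpressionPanel, t_map: np.ndarray) -> np.ndarray:
    """Gene x donor matrix of Fisher-z correlations (NaN where skipped)."""
    t_map = np.asarray(t_map, float)
    if t_map.shape != (panel.n_parcels,):
        raise ValueError("map length does not match panel parcels")
    Z = np.empty((panel.n_genes, len(panel.donors)))
    for d, donor in enumerate(panel.donors):
        r = _corr_rows(panel.expression[donor], t_map)
        Z[:, d] = np.arctanh(np.clip(r, -_Z_CLIP, _Z_CLIP))
    return Z


def gene_map_association(t_map, panel: GeneExpressionPanel) -> pd.DataFrame:
    """Per-gene association between a statistic map and expression.

    Per donor, the Pearson correlation of the gene's parcel profile with
    the map; the gene statistic is the back-transformed mean Fisher-z
    across donors and the p-value comes from a two-sided one-sample
    t-test of the donor z-values against zero. Constant-gene donors are
    skipped with a warning; a gene constant in every donor gets NaN.
    Returns a DataFrame indexed by gene with columns statistic, mean_z, p.
    """
    Z = _donor_z_matrix(panel, t_map)
    nan_rows = np.isnan(Z)
    if nan_rows.any():
        warnings.warn(
            f"{int(nan_rows.any(axis=1).sum())} gene(s) constant in some donor; "
            "those donors skipped",
            stacklevel=2,
        )
    stat = np.full(panel.n_genes, np.nan)
    mean_z = np.full(panel.n_genes, np.nan)
    pval = np.full(panel.n_genes, np.nan)
    for g in range(panel.n_genes):
        z = Z[g][~nan_rows[g]]
        if z.size == 0:
            continue
        mean_z[g] = z.mean()
        stat[g] = np.tanh(mean_z[g])
        if z.size == 1:
            pval[g] = 1.0
        elif z.std(ddof=1) == 0:
            pval[g] = 0.0 if mean_z[g] != 0 else 1.0
        else:
            pval[g] = scipy.stats.ttest_1samp(z, 0.0).pvalue
    return pd.DataFrame(
        {"statistic": stat, "mean_z": mean_z, "p": pval}, index=panel.gene_ids
    )


def spin_significance_filter(
    assoc: pd.DataFrame,
    t_map,
    atlas: ParcelAtlas,
    panel: GeneExpressionPanel,
    genes=None,
    n_rotations: int = 100,
    seed: int = 0,
    q: float = 0.05,
    return_details: bool = False,
):
    """Genes whose map association beats the spin null at FDR q.

    For each of ``n_rotations`` randomly rotated versions of the map the
    gene associations are recomputed; each gene's spin p is the add-one
    two-tailed exceedance fraction of |null mean z| over |observed
    mean z|, and BH-FDR at ``q`` runs across the tested genes. ``genes``
    restricts testing to a pre-selected list (e.g. parametric FDR
    survivors); default is every gene in ``assoc``.
    """
    if n_rotations < 10:
        warnings.warn("fewer than 10 rotations: spin p resolution is unstable",
                      stacklevel=2)
    if genes is None:
        genes = list(assoc.index)
    genes = [g for g in genes]
    if not genes:
        return []
    gidx = [panel.gene_ids.index(g) for g in genes]
    obs = assoc.loc[genes, "mean_z"].to_numpy()

    rotated_maps = spin_nulls(np.asarray(t_map, float), atlas,
                              n_rotations=n_rotations, seed=seed)
    null = np.empty((n_rotations, len(genes)))
    for i in range(n_rotations):
        Z = _donor_z_matrix(panel, rotated_maps[i])[gidx]
        null[i] = np.nanmean(Z, axis=1)
    exceed = (np.abs(null) >= np.abs(obs)[None, :]).sum(axis=0)
    p_spin = (1.0 + exceed) / (n_rotations + 1.0)
    _, rej = fdr_bh(p_spin, q)
    survivors = [g for g, r in zip(genes, rej) if r]
    if return_details:
        return survivors, pd.DataFrame(
            {"p_spin": p_spin, "reject": rej}, index=genes
        )
    return survivors


def donor_consistency_filter(
    panel: GeneExpressionPanel, genes=None, q: float = 0.05
) -> list[str]:
    """Genes expressed consistently across donors.

    For each gene, Pearson correlations between the parcel profiles of
    every donor pair are Fisher-z transformed and tested one-sided for a
    positive mean (one-sample t across pairs); BH-FDR across genes at
    ``q``; survivors are returned.
    """
    if len(panel.donors) < 2:
        raise ValueError("donor consistency needs at least 2 donors")
    if genes is None:
        genes = list(panel.gene_ids)
    genes = [g for g in genes]
    if not genes:
        return []
    gidx = np.array([panel.gene_ids.index(g) for g in genes])
    pairs = list(itertools.combinations(panel.donors, 2))
    Zp = np.empty((len(genes), len(pairs)))
    for j, (a, b) in enumerate(pairs):
        Ea = panel.expression[a][gidx]
        Eb = panel.expression[b][gidx]
        Ea = Ea - Ea.mean(axis=1, keepdims=True)
        Eb = Eb - Eb.mean(axis=1, keepdims=True)
        r = np.einsum("ij,ij->i", Ea, Eb) / (
            np.linalg.norm(Ea, axis=1) * np.linalg.norm(Eb, axis=1)
        )
        Zp[:, j] = np.arctanh(np.clip(r, -_Z_CLIP, _Z_CLIP))
    pvals = np.empty(len(genes))
    for g in range(len(genes)):
        z = Zp[g]
        if z.size < 2 or z.std(ddof=1) == 0:
            pvals[g] = 0.0 if z.mean() > 0 else 1.0
        else:
            pvals[g] = scipy.stats.ttest_1samp(z, 0.0, alternative="greater").pvalue
    _, rej = fdr_bh(pvals, q)
    return [g for g, r in zip(genes, rej) if r]


def fisher_enrichment(gene_list, gene_sets: dict, universe) -> pd.DataFrame:
    """One-sided hypergeometric enrichment of a gene list in each set.

    For each set, p = P(overlap >= observed) under the hypergeometric
    null on the 2x2 table; the odds ratio comes from the same table
    (inf when a zero cell makes it unbounded) and a normal-approximation
    z-score is reported alongside. q-values are BH across sets.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    hits = set(gene_list) & universe
    N = len(universe)
    n = len(hits)
    rows = []
    for set_id, members in gene_sets.items():
        K = len(set(members) & universe)
        ov = len(hits & set(members))
        p = float(scipy.stats.hypergeom.sf(ov - 1, N, K, n)) if K else 1.0
        a, b = ov, n - ov
        c, d = K - ov, N - K - (n - ov)
        odds = (a * d) / (b * c) if b * c > 0 else np.inf
        mean = n * K / N
        var = n * K * (N - K) * (N - n) / (N**2 * (N - 1)) if N > 1 else 0.0
        zscore = (ov - mean) / np.sqrt(var) if var > 0 else 0.0
        rows.append(
            dict(set_id=set_id, overlap=ov, set_size=K, list_size=n,
                 universe=N, odds_ratio=odds, z=zscore, p=min(p, 1.0))
        )
    table = pd.DataFrame(rows)
    if len(table):
        table["q"], _ = fdr_bh(table["p"].to_numpy())
    return table


def csea_enrichment(
    gene_list, specificity: CellTypeSpecificity, universe=None
) -> pd.DataFrame:
    """Cell-type enrichment at the nested pSI stringency rings.

    Runs fisher_enrichment per (cell type, threshold) cell of the
    hexagon layout — the loosest threshold is the outer ring — with a
    single BH-FDR correction across all cells. Membership sets must be
    nested (stricter subset of looser) per cell type.
    """
    if universe is None:
        universe = set(specificity.gene_ids)
    for ct in specificity.cell_types:
        prev = None
        for thr in sorted(PSI_THRESHOLDS, reverse=True):  # loosest first
            cur = specificity.membership[ct][thr]
            if prev is not None and not (cur <= prev):
                raise ValueError(f"membership sets not nested for {ct!r}")
            prev = cur
    rows = []
    for ct in specificity.cell_types:
        for thr in PSI_THRESHOLDS:
            sets = {f"{ct}@{thr}": specificity.membership[ct][thr]}
            row = fisher_enrichment(gene_list, sets, universe).iloc[0]
            rows.append(dict(cell_type=ct, threshold=thr, overlap=int(row.overlap),
                             set_size=int(row.set_size), list_size=int(row.list_size),
                             universe=int(row.universe), odds_ratio=row.odds_ratio,
                             z=row.z, p=row.p))
    table = pd.DataFrame(rows)
    table["q"], _ = fdr_bh(table["p"].to_numpy())
    return table
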