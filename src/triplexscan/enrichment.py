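"""miRNA-mRNA correlation meta-analysis around graded triplex sites.

For every (miRNA, gene-probe) pair of interest a Spearman rank correlation
is computed in each expression cohort separately, the per-cohort results are
combined with an equal-weight inverse-normal (Stouffer) meta-analysis on
direction-oriented one-sided p-values, and pairs anchored to a top-grade
triplex site within a +/-5000 bp window of the gene are split into positive
and negative significant correlations.  The headline quantity is the
positive:negative fold among associated pairs at meta p < alpha, tested
against a 50/50 split with the continuity-corrected proportion test.

No multiple-testing correction is applied at the alpha stage: the raw-count
fold comparison is itself the significance statement.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .characterize import proportion_test

logger = logging.getLogger(__name__)


@dataclass
class ExpressionCohort:
    """One cohort's paired expression matrices, aligned on shared samples.

    Both matrices are samples x features.  ``from_frames`` accepts either
    orientation and transposes to whichever axis shares sample keys.
    """

    cohort_id: str
    genes: pd.DataFrame
    mirnas: pd.DataFrame

    def __post_init__(self):
        shared = self.genes.index.intersection(self.mirnas.index)
        if len(shared) < 4:
            raise ValueError(
                f"cohort {self.cohort_id}: only {len(shared)} shared samples"
            )
        for df, what in ((self.genes, "gene"), (self.mirnas, "miRNA")):
            if df.index.has_duplicates or df.columns.has_duplicates:
                raise ValueError(f"cohort {self.cohort_id}: duplicated {what} identifiers")
        self.genes = self.genes.loc[shared]
        self.mirnas = self.mirnas.loc[shared]

    @classmethod
    def from_frames(
        cls, cohort_id: str, genes: pd.DataFrame, mirnas: pd.DataFrame
    ) -> "ExpressionCohort":
        best = None
        for g in (genes, genes.T):
            for m in (mirnas, mirnas.T):
                n = len(g.index.intersection(m.index))
                if best is None or n > best[0]:
                    best = (n, g, m)
        return cls(cohort_id, best[1], best[2])

    @property
    def n_samples(self) -> int:
        return len(self.genes.index)


def spearman(x: Sequence[float], y: Sequence[float]) -> Tuple[float, float]:
    """Spearman rho with average ranks for ties; two-sided p via the t
    approximation.  Constant input yields (nan, nan); the caller should flag
    and exclude such records."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 4:
        raise ValueError("need paired vectors of length >= 4")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan"), float("nan")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def _rank_standardize(mat: np.ndarray) -> np.ndarray:
    """Column-wise average ranks, centered and scaled; constant -> nan."""
    ranks = stats.rankdata(mat, axis=0)
    ranks -= ranks.mean(axis=0, keepdims=True)
    norm = np.sqrt((ranks**2).sum(axis=0, keepdims=True))
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(norm > 0, ranks / norm, np.nan)


def correlate_pairs(
    cohort: ExpressionCohort, pairs: Sequence[Tuple[str, str]]
) -> pd.DataFrame:
    """Spearman rho and p for each (mirna_id, gene_id) pair in one cohort.

    Vectorized: rank-standardize the needed columns once, then rho is a dot
    product and p follows from the t approximation with n-2 df.  Pairs with
    a constant vector are flagged (``valid`` False) with nan statistics.
    """
    mids = sorted({m for m, _ in pairs})
    gids = sorted({g for _, g in pairs})
    missing_m = [m for m in mids if m not in cohort.mirnas.columns]
    missing_g = [g for g in gids if g not in cohort.genes.columns]
    if missing_m or missing_g:
        raise KeyError(
            f"cohort {cohort.cohort_id}: unknown identifiers "
            f"{(missing_m + missing_g)[:5]}"
        )
    n = cohort.n_samples
    M = _rank_standardize(cohort.mirnas[mids].to_numpy(float))
    G = _rank_standardize(cohort.genes[gids].to_numpy(float))
    midx = {m: i for i, m in enumerate(mids)}
    gidx = {g: i for i, g in enumerate(gids)}
    mi = np.array([midx[m] for m, _ in pairs])
    gi = np.array([gidx[g] for _, g in pairs])
    rho = np.einsum("ij,ij->j", M[:, mi], G[:, gi])
    rho = np.clip(rho, -1.0, 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.abs(rho) >= 1.0, 0.0, p)
    valid = ~np.isnan(rho)
    return pd.DataFrame(
        {
            "mirna_id": [m for m, _ in pairs],
            "gene_id": [g for _, g in pairs],
            "rho": rho,
            "p": p,
            "valid": valid,
        }
    )


def meta_combine(
    rhos: Sequence[float],
    pvals: Sequence[float],
    weights: Optional[Sequence[float]] = None,
) -> Tuple[float, int]:
    """Stouffer combination of direction-oriented one-sided p-values.

    Each cohort's two-sided p is halved and oriented by the sign of its rho
    (one-sided toward positive correlation), converted to a z-score, and the
    z-scores are combined with equal weights (or the given weights, e.g.
    sample sizes).  Returns the two-sided meta p and the direction (sign of
    the combined z).  A single cohort maps back to its own two-sided p.
    Cohorts with strong opposite signs cancel to non-significance.
    """
    rhos = np.asarray(rhos, dtype=float)
    pvals = np.asarray(pvals, dtype=float)
    keep = ~(np.isnan(rhos) | np.isnan(pvals))
    rhos, pvals = rhos[keep], pvals[keep]
    if rhos.size == 0:
        raise ValueError("no cohort with a defined correlation")
    if weights is None:
        w = np.ones(rhos.size)
    else:
        w = np.asarray(weights, dtype=float)[keep]
    one_sided = np.where(rhos > 0, pvals / 2.0, 1.0 - pvals / 2.0)
    one_sided = np.clip(one_sided, 1e-300, 1 - 1e-16)
    z = stats.norm.isf(one_sided)
    z_comb = float((w * z).sum() / np.sqrt((w**2).sum()))
    meta_p = float(2.0 * stats.norm.sf(abs(z_comb)))
    meta_p = min(max(meta_p, 5e-324), 1.0)
    direction = 0 if z_comb == 0 else (1 if z_comb > 0 else -1)
    return meta_p, direction


def meta_table(
    cohort_records: Sequence[pd.DataFrame],
    weights: Optional[Sequence[float]] = None,
) -> pd.DataFrame:
    """Combine per-cohort correlation tables into one meta record per pair.

    Pairs flagged invalid (constant vectors) in a cohort are excluded from
    that cohort's contribution; pairs invalid everywhere are dropped.  The
    result is invariant to cohort order.
    """
    frames = []
    for i, rec in enumerate(cohort_records):
        rec = rec[rec["valid"]].copy()
        rec["cohort"] = i
        frames.append(rec)
    merged = pd.concat(frames, ignore_index=True)
    rows = []
    for (mid, gid), grp in merged.groupby(["mirna_id", "gene_id"], sort=True):
        w = None if weights is None else [weights[c] for c in grp["cohort"]]
        meta_p, direction = meta_combine(grp["rho"].to_numpy(), grp["p"].to_numpy(), w)
        rows.append(
            {
                "mirna_id": mid,
                "gene_id": gid,
                "n_cohorts": len(grp),
                "meta_p": meta_p,
                "direction": direction,
            }
        )
    return pd.DataFrame(rows, columns=["mirna_id", "gene_id", "n_cohorts", "meta_p", "direction"])


def gene_window_sites(
    sites: pd.DataFrame,
    genes: pd.DataFrame,
    window: int = 5000,
    grades: Iterable[int] = (1,),
) -> pd.DataFrame:
    """(gene, miRNA) associations: top-grade site within the gene window.

    A gene is associated with a site when the site interval lies within
    ``window`` bp of the gene body (inclusive of a gap of exactly
    ``window``), on either strand.  Intervals are 0-based half-open.
    """
    grades = set(int(g) for g in grades)
    sel = sites[sites["grade"].astype(int).isin(grades)]
    rows = []
    for chrom, gsub in genes.groupby("chrom"):
        ssub = sel[sel["chrom"].astype(str) == str(chrom)]
        if ssub.empty:
            continue
        s_start = ssub["start"].to_numpy(int)
        s_end = ssub["end"].to_numpy(int)
        s_mirna = ssub["mirna_id"].to_numpy(str)
        for g in gsub.itertuples():
            gap = np.maximum(
                0, np.maximum(g.start - s_end, s_start - g.end)
            )
            hit = gap <= window
            for m, ss, se in zip(s_mirna[hit], s_start[hit], s_end[hit]):
                rows.append(
                    {
                        "gene_id": g.gene_id,
                        "mirna_id": m,
                        "chrom": chrom,
                        "site_start": int(ss),
                        "site_end": int(se),
                    }
                )
    return pd.DataFrame(
        rows, columns=["gene_id", "mirna_id", "chrom", "site_start", "site_end"]
    )


@dataclass
class EnrichmentResult:
    """Positive vs negative correlation counts among associated pairs."""

    n_genes_with_grade1: int
    n_pairs_tested: int
    n_positive: int
    n_negative: int
    fold: float
    test_p: float
    flags: List[str] = field(default_factory=list)


def enrichment(
    records: pd.DataFrame,
    associations: pd.DataFrame,
    alpha: float = 0.01,
) -> EnrichmentResult:
    """Count significant positive vs negative pairs among associated pairs.

    ``records`` is a meta table; ``associations`` the gene-window table.
    Pairs are restricted to (miRNA, gene) combinations with an association;
    the fold is n_positive/n_negative at meta_p < alpha and the test p-value
    comes from the proportion test of the positive vs negative split
    against 50/50.
    """
    assoc_pairs = set(zip(associations["mirna_id"], associations["gene_id"]))
    mask = [
        (m, g) in assoc_pairs
        for m, g in zip(records["mirna_id"], records["gene_id"])
    ]
    sub = records[np.asarray(mask, dtype=bool)] if len(records) else records
    sig = sub[sub["meta_p"] < alpha]
    n_pos = int((sig["direction"] > 0).sum())
    n_neg = int((sig["direction"] < 0).sum())
    flags: List[str] = []
    if n_neg == 0:
        fold = float("inf") if n_pos > 0 else float("nan")
        flags.append("zero_negative_pairs")
    else:
        fold = n_pos / n_neg
    tot = n_pos + n_neg
    if tot == 0:
        test_p = 1.0
        flags.append("no_significant_pairs")
    else:
        _, test_p = proportion_test(n_pos, tot, n_neg, tot)
    return EnrichmentResult(
        n_genes_with_grade1=int(associations["gene_id"].nunique()),
        n_pairs_tested=int(len(sub)),
        n_positive=n_pos,
        n_negative=n_neg,
        fold=fold,
        test_p=test_p,
        flags=flags,
    )


def run_enrichment(
    sites: pd.DataFrame,
    genes: pd.DataFrame,
    cohorts: Sequence[ExpressionCohort],
    window: int = 5000,
    alpha: float = 0.01,
    grades: Iterable[int] = (1,),
    weights: Optional[Sequence[float]] = None,
) -> Tuple[pd.DataFrame, EnrichmentResult]:
    """Full pipeline: window association -> per-cohort Spearman -> meta ->
    positive/negative enrichment.  Returns the meta record table (restricted
    to associated pairs) and the enrichment summary."""
    associations = gene_window_sites(sites, genes, window=window, grades=grades)
    if associations.empty:
        logger.warning("no grade-%s sites within %d bp of any gene", sorted(grades), window)
        empty = pd.DataFrame(columns=["mirna_id", "gene_id", "n_cohorts", "meta_p", "direction"])
        return empty, enrichment(empty, associations, alpha)
    pairs = sorted(set(zip(associations["mirna_id"], associations["gene_id"])))
    per_cohort = [correlate_pairs(c, pairs) for c in cohorts]
    records = meta_table(per_cohort, weights=weights)
    return records, enrichment(records, associations, alpha)
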