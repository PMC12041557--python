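"""Sensitivity and group-comparison diagnostics.

The leave-one-out (LOO) scan asks whether any single species drives the
genome-wide association signal: each species is removed in turn, the
two-predictor PGLS scan is refit on the pruned tree and data, and the vector
of per-family effect sizes (over the families significant in the full-data
scan) is compared with the full-data vector via Cohen's d and a Wilcoxon
rank-sum test. One d and one p per species, BH-corrected across species.

Also provides the expression/alternative-splicing comparison: Wilcoxon
rank-sum between focal and background genes for each measured quantity.
"""

from __future__ import annotations

import logging
import math
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .pgls import ScanResult, bh_adjust, scan_families
from .phylo import PhyloTree

__all__ = [
    "cohens_d",
    "wilcoxon_rank_sum",
    "loo_scan",
    "compare_expression",
]

log = logging.getLogger(__name__)


def cohens_d(a, b) -> float:
    """Standardized mean difference (pooled-SD denominator)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("both samples need at least two observations")
    na, nb = len(a), len(b)
    pooled = math.sqrt(((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1))
                       / (na + nb - 2))
    if pooled == 0:
        raise ValueError("degenerate samples")
    return (a.mean() - b.mean()) / pooled


def wilcoxon_rank_sum(a, b) -> tuple:
    """Mann-Whitney U with a two-sided p-value.

    Exact enumeration when the combined sample has at most 12 tie-free
    observations; otherwise the normal approximation with midranks, tie
    correction and continuity correction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 1 or len(b) < 1:
        raise ValueError("both samples must be non-empty")
    combined = np.concatenate([a, b])
    ties = len(np.unique(combined)) < len(combined)
    method = "exact" if (len(combined) <= 12 and not ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method,
                             use_continuity=True)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def loo_scan(counts: pd.DataFrame, traits: pd.DataFrame, tree: PhyloTree,
             reference: ScanResult, alpha: float = 0.05,
             d_threshold: float = 0.2) -> pd.DataFrame:
    """Leave-one-out influence analysis of a multi-predictor scan.

    For every species in the reference analysis set, the scan is re-run with
    that species removed, over the *same family universe* as the reference
    (the family filters are frozen at the full-data stage so effect sizes
    stay comparable across iterations). The effect sizes of the first
    predictor, restricted to the families significant in the reference scan,
    are compared against the reference values.

    Returns a table with columns species_dropped, n_families, cohens_d,
    wilcoxon_p, wilcoxon_q, influential.
    """
    if len(reference.species) < 4:
        raise ValueError("need at least four species for leave-one-out")
    pred = reference.predictors[0]
    universe = list(reference.family_ids)
    sig = sorted(reference.significant_families(pred))
    if not sig:
        raise ValueError("reference scan has no significant families to track")
    full_r = reference.effect_map(pred).loc[sig]
    rows = []
    for sp in reference.species:
        kept_cols = [c for c in counts.columns if c != sp]
        loo = scan_families(counts.loc[universe, kept_cols], traits, tree,
                            reference.predictors, alpha=alpha)
        loo_r = loo.effect_map(pred)
        common = [f for f in sig if f in loo_r.index]
        dropped = len(sig) - len(common)
        if dropped:
            log.warning("species %s: %d families degenerate after removal",
                        sp, dropped)
        d = cohens_d(loo_r.loc[common].to_numpy(), full_r.loc[common].to_numpy())
        _, p = wilcoxon_rank_sum(loo_r.loc[common].to_numpy(),
                                 full_r.loc[common].to_numpy())
        rows.append({"species_dropped": sp, "n_families": len(common),
                     "cohens_d": d, "wilcoxon_p": p})
    out = pd.DataFrame(rows)
    out["wilcoxon_q"] = bh_adjust(out["wilcoxon_p"].to_numpy())
    out["influential"] = (out["wilcoxon_q"] < alpha) & \
        (out["cohens_d"].abs() >= d_threshold)
    return out


def compare_expression(values: pd.DataFrame, focal_genes: Iterable,
                       background_genes: Iterable,
                       measures: Sequence[str] = ("expression_level",
                                                  "transcript_count")
                       ) -> pd.DataFrame:
    """Wilcoxon rank-sum comparison of per-gene measurements between groups.

    ``values`` is indexed by gene id. Focal and background sets must be
    disjoint; genes missing a measure are dropped pairwise for that measure.
    Direction is reported via the difference of group medians.
    """
    focal = set(focal_genes)
    background = set(background_genes)
    if focal & background:
        raise ValueError("focal and background gene sets must be disjoint")
    rows = []
    for measure in measures:
        col = values[measure]
        fv = col.loc[col.index.intersection(sorted(focal))].dropna().to_numpy(float)
        bv = col.loc[col.index.intersection(sorted(background))].dropna().to_numpy(float)
        n_expected = len(focal) + len(background)
        if (len(fv) + len(bv)) < 0.5 * n_expected:
            log.warning("measure %s missing for more than half of the genes",
                        measure)
        stat, p = wilcoxon_rank_sum(fv, bv)
        rows.append({"measure": measure, "n_focal": len(fv),
                     "n_background": len(bv), "statistic": stat, "p": p,
                     "median_difference": float(np.median(fv) - np.median(bv))})
    return pd.DataFrame(rows)
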