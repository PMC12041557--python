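"""Phylogenetic generalized least squares and the per-family genome scan.

The central model: for each gene family, the vector of per-species gene
counts y is regressed on one or more traits X under Gaussian errors with
covariance sigma^2 * V, where V is the Brownian-motion covariance implied by
the phylogeny. Coefficients are the GLS estimator
``(X' V^-1 X)^-1 X' V^-1 y``; the Brownian rate sigma^2 is reported at the
maximum-likelihood scale (residual quadratic form over n) while standard
errors use the unbiased n-k scale so that on a star phylogeny the t-tests
coincide exactly with textbook OLS.

Each coefficient's effect size is the t-to-partial-correlation conversion
``r = t / sqrt(t^2 + df)``, a correlation-scale summary bounded in (-1, 1)
with the sign of the estimated slope. Families are called *expanding* when
the trait coefficient has r > 0 at Benjamini-Hochberg q below alpha, and
*contracting* for r < 0.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import linalg, stats
from statsmodels.stats.multitest import multipletests

from .phylo import CovMatrix, PhyloTree, brownian_covariance

__all__ = [
    "GLSFit",
    "ScanResult",
    "fit_gls",
    "effect_size_r",
    "bh_adjust",
    "scan_families",
    "total_count_regression",
]

log = logging.getLogger(__name__)

_JITTER = 1e-10


class CollinearDesignError(np.linalg.LinAlgError):
    pass


@dataclass(frozen=True)
class GLSFit:
    """Per-coefficient summaries of one generalized least squares fit."""

    names: tuple
    beta: np.ndarray
    se: np.ndarray
    t: np.ndarray
    df: int
    p: np.ndarray
    sigma2: float          # ML scale: e' V^-1 e / n
    loglik: float
    r: np.ndarray          # effect size per coefficient

    def coef(self, name: str) -> dict:
        i = self.names.index(name)
        return {"beta": self.beta[i], "se": self.se[i], "t": self.t[i],
                "p": self.p[i], "r": self.r[i], "df": self.df}


def _whitener(V: np.ndarray) -> np.ndarray:
    """Lower Cholesky factor of V, with a diagonal jitter fallback."""
    V = np.asarray(V, dtype=float)
    try:
        return linalg.cholesky(V, lower=True)
    except linalg.LinAlgError:
        warnings.warn("covariance not positive definite; adding 1e-10 jitter",
                      stacklevel=3)
        return linalg.cholesky(V + _JITTER * np.eye(len(V)), lower=True)


def effect_size_r(t: float, df: int) -> float:
    """Correlation-scale effect size of a single coefficient: t/sqrt(t^2+df)."""
    if df <= 0:
        raise ValueError("df must be positive")
    if math.isinf(t):
        return math.copysign(1.0, t)
    return t / math.sqrt(t * t + df)


def fit_gls(y: np.ndarray, X: np.ndarray, V, names: Sequence[str] | None = None
            ) -> GLSFit:
    """GLS fit of ``y`` on design ``X`` under error covariance proportional to ``V``.

    Rows of ``y``, ``X`` and ``V`` must be aligned on the same species order;
    ``V`` may be a :class:`~famscan.phylo.CovMatrix` or a plain array.
    """
    if isinstance(V, CovMatrix):
        V = V.matrix
    y = np.asarray(y, dtype=float).ravel()
    X = np.asarray(X, dtype=float)
    n, k = X.shape
    if len(y) != n or V.shape != (n, n):
        raise ValueError("y, X and V must share the same species dimension")
    if n <= k:
        raise ValueError("more coefficients than observations")
    L = _whitener(V)
    yw = linalg.solve_triangular(L, y, lower=True)
    Xw = linalg.solve_triangular(L, X, lower=True)
    XtX = Xw.T @ Xw
    if np.linalg.cond(XtX) > 1e12:
        raise CollinearDesignError("collinear design")
    C = np.linalg.inv(XtX)
    beta = C @ (Xw.T @ yw)
    resid = yw - Xw @ beta
    rss = float(resid @ resid)
    # an exact fit leaves only round-off in the residual; snap it to zero so
    # that se = 0 triggers the degenerate t handling instead of t = noise/noise
    if rss <= 1e-24 * max(float(yw @ yw), 1.0):
        rss = 0.0
    df = n - k
    s2_unbiased = rss / df
    se = np.sqrt(np.maximum(s2_unbiased * np.diag(C), 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta / np.where(se > 0, se, 1.0),
                     np.where(np.abs(beta) < 1e-12, 0.0,
                              np.sign(beta) * np.inf))
    p = 2.0 * stats.t.sf(np.abs(t), df)
    sigma2_ml = rss / n
    logdetV = 2.0 * float(np.sum(np.log(np.diag(L))))
    if sigma2_ml > 0:
        loglik = -0.5 * (n * math.log(2 * math.pi * sigma2_ml) + n + logdetV)
    else:
        loglik = math.inf
    r = np.array([effect_size_r(ti, df) for ti in t])
    if names is None:
        names = ["intercept"] + [f"x{i}" for i in range(1, k)]
    return GLSFit(tuple(names), beta, se, t, df, p, sigma2_ml, loglik, r)


# ---------------------------------------------------------------------------
# Multiple testing
# ---------------------------------------------------------------------------

def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# Genome scan
# ---------------------------------------------------------------------------

@dataclass
class ScanResult:
    """Per-family PGLS scan output.

    ``table`` has one row per (family, predictor) with columns
    family_id, predictor, beta, se, t, df, p, q, r, call; rows are sorted by
    (family_id, predictor) for deterministic output.
    """

    table: pd.DataFrame
    predictors: tuple
    alpha: float
    species: tuple
    skipped: tuple = field(default_factory=tuple)

    @property
    def family_ids(self) -> tuple:
        return tuple(self.table["family_id"].unique())

    def rows_for(self, predictor: str | None = None) -> pd.DataFrame:
        predictor = predictor or self.predictors[0]
        return self.table[self.table["predictor"] == predictor]

    def significant_families(self, predictor: str | None = None,
                             direction: str | None = None) -> set:
        """Families with q < alpha for a predictor; optionally one direction."""
        rows = self.rows_for(predictor)
        sig = rows[rows["q"] < self.alpha]
        if direction is not None:
            sig = sig[sig["call"] == direction]
        return set(sig["family_id"])

    def call_counts(self, predictor: str | None = None) -> dict:
        rows = self.rows_for(predictor)
        counts = rows["call"].value_counts().to_dict()
        return {"expanding": counts.get("expanding", 0),
                "contracting": counts.get("contracting", 0),
                "none": counts.get("none", 0)}

    def effect_map(self, predictor: str | None = None) -> pd.Series:
        rows = self.rows_for(predictor)
        return rows.set_index("family_id")["r"]

    def write_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def _align_species(counts: pd.DataFrame, traits: pd.DataFrame,
                   tree: PhyloTree, predictors: Sequence[str]):
    """Intersect counts columns, complete trait rows and tree tips."""
    have_traits = traits.index[traits[list(predictors)].notna().all(axis=1)]
    sp = set(counts.columns) & set(tree.tip_labels) & set(have_traits)
    if len(sp) < len(predictors) + 2:
        raise ValueError("too few species shared by counts, traits and tree")
    n_union = len(set(counts.columns) | set(tree.tip_labels))
    if len(sp) < n_union:
        log.warning("species intersection: analysis runs on %d species", len(sp))
    sub = tree if sp == set(tree.tip_labels) else tree.prune_to(sp)
    order = [s for s in sub.tip_labels]  # canonical tip order of pruned tree
    return sub, order


def scan_families(counts: pd.DataFrame, traits: pd.DataFrame, tree: PhyloTree,
                  predictors: Sequence[str], alpha: float = 0.05,
                  log1p_response: bool = False) -> ScanResult:
    """Fit one PGLS per gene family and correct across families.

    The response is the family's per-species count vector (optionally
    log1p-transformed); the design is an intercept plus the listed trait
    columns. Benjamini-Hochberg correction is applied per predictor across
    all scanned families. Families with zero count variance on the analysis
    species are skipped with a warning.
    """
    predictors = tuple(predictors)
    if not predictors:
        raise ValueError("need at least one predictor")
    for pr in predictors:
        if pr not in traits.columns:
            raise KeyError(f"trait column {pr!r} not found")
    sub, order = _align_species(counts, traits, tree, predictors)
    V = brownian_covariance(sub).matrix
    X = np.column_stack([np.ones(len(order)),
                         traits.loc[order, list(predictors)].to_numpy(float)])
    Y = counts[order].to_numpy(float).T  # n_species x n_families
    if log1p_response:
        Y = np.log1p(Y)
    fam_ids = np.asarray(counts.index)
    variable = Y.var(axis=0) > 0
    skipped = tuple(fam_ids[~variable])
    if skipped:
        log.warning("skipping %d zero-variance families", len(skipped))
    Y = Y[:, variable]
    fam_ids = fam_ids[variable]
    n, k = X.shape
    df = n - k
    if df <= 0:
        raise ValueError("not enough species for the requested design")

    L = _whitener(V)
    Xw = linalg.solve_triangular(L, X, lower=True)
    Yw = linalg.solve_triangular(L, Y, lower=True)
    XtX = Xw.T @ Xw
    if np.linalg.cond(XtX) > 1e12:
        raise CollinearDesignError("collinear design")
    C = np.linalg.inv(XtX)
    B = C @ (Xw.T @ Yw)                      # k x m
    E = Yw - Xw @ B
    rss = np.einsum("ij,ij->j", E, E)
    # snap exact fits (residual is pure round-off) to zero, as in fit_gls
    yss = np.maximum(np.einsum("ij,ij->j", Yw, Yw), 1.0)
    rss = np.where(rss <= 1e-24 * yss, 0.0, rss)
    s2 = rss / df
    SE = np.sqrt(np.outer(np.diag(C), s2))   # k x m
    with np.errstate(divide="ignore", invalid="ignore"):
        T = np.where(SE > 0, B / np.where(SE > 0, SE, 1.0),
                     np.where(np.abs(B) < 1e-12, 0.0, np.sign(B) * np.inf))
    P = 2.0 * stats.t.sf(np.abs(T), df)
    with np.errstate(invalid="ignore"):
        R = T / np.sqrt(T * T + df)
    R = np.where(np.isinf(T), np.sign(T), R)

    frames = []
    for j, pred in enumerate(predictors, start=1):
        q = bh_adjust(P[j]) if P.shape[1] else np.array([])
        call = np.where(q < alpha, np.where(R[j] > 0, "expanding", "contracting"),
                        "none")
        frames.append(pd.DataFrame({
            "family_id": fam_ids, "predictor": pred, "beta": B[j],
            "se": SE[j], "t": T[j], "df": df, "p": P[j], "q": q,
            "r": R[j], "call": call,
        }))
    table = (pd.concat(frames, ignore_index=True)
             .sort_values(["family_id", "predictor"], kind="stable")
             .reset_index(drop=True))
    return ScanResult(table, predictors, alpha, tuple(order), skipped)


def total_count_regression(counts: pd.DataFrame, trait: str,
                           traits: pd.DataFrame, tree: PhyloTree) -> GLSFit:
    """Control analysis: total gene count per species regressed on one trait.

    Guards against a genome-wide drift in protein-coding gene number among
    long-lived species masquerading as family-specific expansion.
    """
    sub, order = _align_species(counts, traits, tree, [trait])
    V = brownian_covariance(sub)
    y = counts[order].sum(axis=0).to_numpy(float)
    X = np.column_stack([np.ones(len(order)),
                         traits.loc[order, trait].to_numpy(float)])
    return fit_gls(y, X, V, names=["intercept", trait])
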