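"""Functional enrichment: resampling Z-scores and curated-list overlap.

Two statistics are provided. For GO-style term annotations, the observed
proportion of focal elements (gene families, or genes) carrying each term is
compared against the mean and standard deviation of that proportion in many
equally sized random samples drawn from the background, yielding a Z-score
and a two-sided normal-tail p-value. For curated gene lists, a plain 2x2
chi-square test (no continuity correction) over a harmonized background
measures over- or under-representation, summarized as a log2 observed/expected
fold.

Terms are opaque labels throughout — no ontology-graph propagation is done;
annotations are used exactly as supplied.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .pgls import bh_adjust

__all__ = [
    "AnnotationMap",
    "OverlapResult",
    "lift_go_to_families",
    "filter_terms",
    "sampling_enrichment",
    "chi_square_overlap",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class AnnotationMap:
    """Element -> set-of-terms mapping over an explicit background universe.

    ``background`` may contain unannotated elements; every annotated element
    must belong to it.
    """

    mapping: dict
    background: frozenset

    def __post_init__(self):
        extra = set(self.mapping) - self.background
        if extra:
            raise ValueError(f"annotated elements outside background: "
                             f"{sorted(extra)[:5]}")
        for el, terms in self.mapping.items():
            if any(not t for t in terms):
                raise ValueError(f"empty term on element {el!r}")

    @property
    def terms(self) -> frozenset:
        out: set = set()
        for ts in self.mapping.values():
            out |= set(ts)
        return frozenset(out)

    def term_counts(self) -> dict:
        counts: dict = {}
        for ts in self.mapping.values():
            for t in ts:
                counts[t] = counts.get(t, 0) + 1
        return counts

    @staticmethod
    def from_pairs(pairs: Iterable[tuple], background: Iterable | None = None
                   ) -> "AnnotationMap":
        mapping: dict = {}
        for el, term in pairs:
            mapping.setdefault(el, set()).add(term)
        mapping = {el: frozenset(ts) for el, ts in mapping.items()}
        bg = frozenset(background) if background is not None else frozenset(mapping)
        return AnnotationMap(mapping, bg)


def lift_go_to_families(gene_terms: AnnotationMap,
                        membership: Mapping[str, str]) -> AnnotationMap:
    """Lift gene-level annotations to families by set union.

    A family is annotated with a term whenever that term is assigned to any
    of its member genes. Annotated genes missing from the membership map are
    skipped with a warning. The family background is the full set of families
    in the membership map (annotated or not), so downstream resampling draws
    from the same universe the scan used.
    """
    fam_terms: dict = {}
    orphans = 0
    for gene, terms in gene_terms.mapping.items():
        fam = membership.get(gene)
        if fam is None:
            orphans += 1
            continue
        fam_terms.setdefault(fam, set()).update(terms)
    if orphans:
        log.warning("skipped %d annotated genes with no family membership", orphans)
    background = frozenset(membership.values())
    mapping = {f: frozenset(ts) for f, ts in fam_terms.items()}
    return AnnotationMap(mapping, background)


def filter_terms(ann: AnnotationMap, min_elements: int) -> AnnotationMap:
    """Drop terms annotated to fewer than ``min_elements`` elements."""
    if min_elements < 1:
        raise ValueError("min_elements must be >= 1")
    counts = ann.term_counts()
    keep = {t for t, c in counts.items() if c >= min_elements}
    mapping = {}
    for el, ts in ann.mapping.items():
        kept = frozenset(t for t in ts if t in keep)
        if kept:
            mapping[el] = kept
    return AnnotationMap(mapping, ann.background)


def sampling_enrichment(focal: Iterable, ann: AnnotationMap,
                        n_samples: int = 1000, seed: int = 0,
                        replace: bool = False) -> pd.DataFrame:
    """Resampling Z-score enrichment of terms among a focal element set.

    For each term, the proportion of focal elements carrying the term is
    compared with the mean and standard deviation of the proportion across
    ``n_samples`` random background samples of the same size (without
    replacement by default). p-values are two-sided standard-normal tails of
    the Z-score, BH-corrected across terms; an empirical resampling p-value
    is reported alongside as a diagnostic.

    Degenerate terms (zero resampling standard deviation) get p = 1 when the
    observed proportion equals the null mean, and the 1/n_samples resolution
    floor otherwise, with a flag.
    """
    focal = set(focal)
    bg = sorted(ann.background)
    if not focal:
        raise ValueError("focal set is empty")
    if not focal <= set(bg):
        raise ValueError("focal set must be a subset of the background")
    if len(focal) > len(bg):
        raise ValueError("focal set larger than background")
    if n_samples < 2:
        raise ValueError("need at least two resamples")
    terms = sorted(ann.terms)
    if not terms:
        return pd.DataFrame(columns=[
            "term", "n_background", "n_focal_observed", "observed_proportion",
            "null_mean", "null_sd", "z", "p", "p_empirical", "q",
            "direction", "degenerate"])
    bg_pos = {el: i for i, el in enumerate(bg)}
    term_pos = {t: j for j, t in enumerate(terms)}
    M = np.zeros((len(bg), len(terms)), dtype=bool)
    for el, ts in ann.mapping.items():
        i = bg_pos[el]
        for t in ts:
            M[i, term_pos[t]] = True

    k = len(focal)
    focal_idx = np.fromiter((bg_pos[e] for e in sorted(focal)), dtype=int)
    obs = M[focal_idx].mean(axis=0)
    rng = np.random.default_rng(seed)
    if replace:
        samples = rng.integers(0, len(bg), size=(n_samples, k))
    else:
        # argsort of uniform noise = vectorized sampling without replacement
        samples = np.argsort(rng.random((n_samples, len(bg))), axis=1)[:, :k]
    null = M[samples].mean(axis=1)          # n_samples x n_terms
    mean = null.mean(axis=0)
    sd = null.std(axis=0, ddof=1)

    # proportions are multiples of 1/k, so any genuine variation yields an sd
    # far above this; smaller values are accumulation round-off on a constant
    degenerate = sd < 1e-12
    sd = np.where(degenerate, 0.0, sd)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(degenerate, 0.0, (obs - mean) / np.where(degenerate, 1.0, sd))
    p = 2.0 * stats.norm.sf(np.abs(z))
    p = np.where(degenerate,
                 np.where(np.isclose(obs, mean, atol=1e-12), 1.0, 1.0 / n_samples),
                 p)
    # empirical two-sided tail from the resampled null itself
    p_emp = ((np.abs(null - mean) >= np.abs(obs - mean)[None, :]).sum(axis=0) + 1
             ) / (n_samples + 1)
    q = bh_adjust(p)
    direction = np.where(obs >= mean, "over", "under")
    out = pd.DataFrame({
        "term": terms,
        "n_background": M.sum(axis=0),
        "n_focal_observed": M[focal_idx].sum(axis=0),
        "observed_proportion": obs,
        "null_mean": mean,
        "null_sd": sd,
        "z": z,
        "p": p,
        "p_empirical": p_emp,
        "q": q,
        "direction": direction,
        "degenerate": degenerate,
    })
    out.attrs["n_samples"] = n_samples
    out.attrs["seed"] = seed
    return out


@dataclass(frozen=True)
class OverlapResult:
    """Chi-square overlap of a curated gene list with the focal gene set."""

    table: np.ndarray       # [[in-list&focal, in-list&rest], [focal-only, rest]]
    chi2: float
    p: float
    direction: str          # "over" | "under"
    log2_fold: float
    n_background: int
    expected_focal_in_list: float
    unreliable: bool = False


def chi_square_overlap(gene_list: Iterable, list_background: Iterable | None,
                       focal_genes: Iterable, study_background: Iterable
                       ) -> OverlapResult:
    """Pearson chi-square (df=1, no continuity correction) on a 2x2 overlap table.

    The background is harmonized to the intersection of the study background
    with the list's own background when the list supplies one; the focal set
    and the list are both restricted to that harmonized universe. The fold is
    log2(observed/expected) for the in-list, in-focal cell. Results with any
    expected cell below 1 are flagged unreliable but still reported.
    """
    study = set(study_background)
    focal = set(focal_genes)
    if not focal <= study:
        raise ValueError("focal genes must be a subset of the study background")
    bg = study & set(list_background) if list_background is not None else study
    lst = set(gene_list) & bg
    foc = focal & bg
    n = len(bg)
    a = len(lst & foc)
    b = len(lst - foc)
    c = len(foc - lst)
    d = n - a - b - c
    table = np.array([[a, b], [c, d]], dtype=float)
    expected_a = len(lst) * len(foc) / n if n else math.nan
    row = table.sum(axis=1)
    col = table.sum(axis=0)
    if n == 0 or 0 in row or 0 in col:
        return OverlapResult(table, 0.0, 1.0, "over", math.nan, n,
                             expected_a, unreliable=True)
    chi2, p, _, expected = stats.chi2_contingency(table, correction=False)
    chi2, p = float(chi2), float(p)
    direction = "over" if a >= expected_a else "under"
    with np.errstate(divide="ignore"):
        log2_fold = float(np.log2(a / expected_a)) if expected_a > 0 else math.nan
    unreliable = bool((expected < 1).any())
    return OverlapResult(table, chi2, p, direction, log2_fold, n,
                         expected_a, unreliable)
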