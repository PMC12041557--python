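"""Input filtering and trait preparation.

Covers the data-quality gates applied before any comparative model is fit:
dropping species with incomplete genome annotations (BUSCO-style completeness
scores), the three-predicate gene-family filter cascade, log10 trait
transformation, and the allometric residualisation that turns brain mass into
relative brain size.
"""

from __future__ import annotations

import logging
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "TRAIT_COLUMNS",
    "read_trait_table",
    "read_counts",
    "read_completeness",
    "read_annotation_tsv",
    "filter_species_by_completeness",
    "filter_families",
    "log10_traits",
    "relative_brain_size",
]

log = logging.getLogger(__name__)

#: Raw life-history / morphology columns expected in a trait table.
#: Units: mlsp in years, masses in grams, times in days.
TRAIT_COLUMNS = ("mlsp", "body_mass", "brain_mass",
                 "gestation_time", "age_sexual_maturity")


# ---------------------------------------------------------------------------
# TSV I/O (header row; first column is the identifier; "NA" marks missing)
# ---------------------------------------------------------------------------

def read_trait_table(path) -> pd.DataFrame:
    """Species-indexed trait table with raw (untransformed) values."""
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
    df.index = df.index.astype(str)
    return df


def read_counts(path) -> pd.DataFrame:
    """Family-by-species integer count matrix."""
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
    df.index = df.index.astype(str)
    if (df.to_numpy() < 0).any():
        raise ValueError("gene family counts must be non-negative")
    return df.astype(int)


def read_completeness(path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
    s = df.iloc[:, 0].astype(float)
    if ((s < 0) | (s > 1)).any():
        raise ValueError("completeness scores must lie in [0, 1]")
    return s


def read_annotation_tsv(path) -> pd.DataFrame:
    """Two-column (element_id, term_id) annotation table; duplicates allowed."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    df.columns = ["element_id", "term_id"][: len(df.columns)]
    return df


# ---------------------------------------------------------------------------
# Filters
# ---------------------------------------------------------------------------

def filter_species_by_completeness(scores: pd.Series,
                                   threshold: float = 0.80) -> set:
    """Species whose genome completeness is *strictly* above ``threshold``."""
    if not 0 < threshold < 1:
        raise ValueError("threshold must lie in (0, 1)")
    kept = set(scores.index[scores > threshold])
    if not kept:
        raise ValueError("no species passes the completeness threshold")
    dropped = len(scores) - len(kept)
    if dropped:
        log.info("completeness filter: kept %d of %d species", len(kept), len(scores))
    return kept


def filter_families(counts: pd.DataFrame, presence_fraction: float = 0.80,
                    min_max_count: int = 3) -> pd.DataFrame:
    """Three-predicate gene-family filter.

    A family is retained when (i) its counts vary across species, (ii) at
    least one species carries ``min_max_count`` or more genes, and (iii) the
    family is present (count >= 1) in at least
    ``ceil(presence_fraction * n_species)`` species — the last rule removes
    lineage-specific families. The predicates are independent, so the filter
    is idempotent and order-insensitive.
    """
    if counts.shape[0] == 0 or counts.shape[1] == 0:
        return counts.copy()
    m = counts.to_numpy()
    n_species = counts.shape[1]
    need = int(np.ceil(presence_fraction * n_species))
    has_variance = m.var(axis=1) > 0
    big_enough = m.max(axis=1) >= min_max_count
    widespread = (m >= 1).sum(axis=1) >= need
    keep = has_variance & big_enough & widespread
    out = counts.loc[keep]
    log.info("family filter: kept %d of %d families", len(out), len(counts))
    return out


# ---------------------------------------------------------------------------
# Trait transforms
# ---------------------------------------------------------------------------

def log10_traits(traits: pd.DataFrame,
                 columns: Iterable[str] = TRAIT_COLUMNS) -> pd.DataFrame:
    """Add ``log10_<col>`` columns; missing values stay missing."""
    out = traits.copy()
    for col in columns:
        if col not in out.columns:
            continue
        vals = out[col]
        bad = vals.index[(vals <= 0) & vals.notna()]
        if len(bad):
            raise ValueError(
                f"non-positive value for trait {col!r} in species {bad[0]!r}")
        out[f"log10_{col}"] = np.log10(vals)
    return out


def relative_brain_size(traits: pd.DataFrame) -> pd.DataFrame:
    """Residual of an ordinary log-log regression of brain mass on body mass.

    The residual quantifies brain mass after removing the allometric scaling
    with body size; it is computed by ordinary (non-phylogenetic) least
    squares over the species that have both masses, and left missing
    elsewhere. Residuals over the fitted species sum to zero by the OLS
    normal equations.
    """
    out = traits.copy()
    mask = out["brain_mass"].notna() & out["body_mass"].notna()
    if mask.sum() < 3:
        raise ValueError("need at least three species with brain and body mass")
    x = np.log10(out.loc[mask, "body_mass"].to_numpy(float))
    y = np.log10(out.loc[mask, "brain_mass"].to_numpy(float))
    if np.ptp(x) == 0:
        raise ValueError("all body masses identical: allometric slope undefined")
    slope, intercept = np.polyfit(x, y, 1)
    out["relative_brain_size"] = np.nan
    out.loc[mask, "relative_brain_size"] = y - (slope * x + intercept)
    return out
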