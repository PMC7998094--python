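"""Cervicotype classification of genus-level vaginal microbiome profiles.

Cervicovaginal communities fall into four recurring classes: dominated
by non-iners *Lactobacillus* species (mainly *L. crispatus*; CT1), by
*Lactobacillus iners* (CT2), by *Gardnerella* (CT3), or polymicrobial /
high-diversity (CT4).  Classification operates on genus-level relative
abundances in which the *Lactobacillus* genus is split into
"Lactobacillus iners" and "Lactobacillus non-iners".

A sample is "dominant" for a taxon when that taxon is the most abundant
and its relative abundance reaches the dominance threshold (default
0.5).  A sample whose most abundant taxon is any other genus, or whose
maximum abundance falls below the threshold, is CT4.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "NONINERS",
    "INERS",
    "GARDNERELLA",
    "Cervicotype",
    "classify_cervicotype",
    "classify_table",
    "ct_counts",
    "ct_frequency_table",
    "load_abundance_table",
]

logger = logging.getLogger(__name__)

NONINERS = "Lactobacillus non-iners"
INERS = "Lactobacillus iners"
GARDNERELLA = "Gardnerella"

#: tie-break priority when several taxa share the maximum abundance
_PRIORITY = (NONINERS, INERS, GARDNERELLA)
_CT_OF_TAXON = {NONINERS: "CT1", INERS: "CT2", GARDNERELLA: "CT3"}
CT_LABELS = ("CT1", "CT2", "CT3", "CT4")


@dataclass(frozen=True)
class Cervicotype:
    """Assigned community class with the taxon that drove it."""

    label: str
    dominant_taxon: str
    dominant_abundance: float


def classify_cervicotype(sample, dominance_threshold: float = 0.5) -> Cervicotype:
    """Assign one genus-level composition to CT1–CT4.

    ``sample`` maps taxon name -> relative abundance (dict or
    :class:`pandas.Series`).  The composition is renormalized to sum to
    one, so the rule is scale-invariant.  Ties at the maximum are broken
    by the fixed priority (L. non-iners, L. iners, Gardnerella) and
    logged.
    """
    s = pd.Series(sample, dtype=float)
    if s.empty:
        raise ValueError("empty composition")
    if s.index.has_duplicates:
        raise ValueError("duplicate taxa names")
    if (s < 0).any() or not np.isfinite(s.to_numpy()).all():
        raise ValueError("abundances must be finite and >= 0")
    total = s.sum()
    if total <= 0:
        raise ValueError("composition sums to zero")
    s = s / total

    mx = s.max()
    at_max = list(s.index[s == mx])
    taxon = at_max[0]
    if len(at_max) > 1:
        for p in _PRIORITY:
            if p in at_max:
                taxon = p
                break
        logger.info("abundance tie among %s resolved to %r", at_max, taxon)

    if taxon in _CT_OF_TAXON and mx >= dominance_threshold:
        label = _CT_OF_TAXON[taxon]
    else:
        label = "CT4"
    return Cervicotype(label=label, dominant_taxon=str(taxon), dominant_abundance=float(mx))


def classify_table(table: pd.DataFrame, dominance_threshold: float = 0.5) -> pd.DataFrame:
    """Classify every row of a samples x taxa abundance table.

    Returns a DataFrame indexed by sample with columns ``cervicotype``,
    ``dominant_taxon``, ``dominant_abundance``.
    """
    recs = {}
    for sid, row in table.iterrows():
        ct = classify_cervicotype(row, dominance_threshold)
        recs[sid] = (ct.label, ct.dominant_taxon, ct.dominant_abundance)
    return pd.DataFrame.from_dict(
        recs, orient="index",
        columns=["cervicotype", "dominant_taxon", "dominant_abundance"],
    )


def _resolve_groups(labels: pd.Series, groups) -> pd.Series:
    g = pd.Series(groups)
    missing = [str(s) for s in labels.index if s not in g.index]
    if missing:
        raise KeyError(f"samples without a group assignment: {missing}")
    return g.loc[labels.index]


def ct_counts(labels: pd.Series, groups) -> pd.DataFrame:
    """Per-group cervicotype counts (groups x CT1..CT4)."""
    g = _resolve_groups(labels, groups)
    tab = pd.crosstab(g, labels)
    return tab.reindex(columns=CT_LABELS, fill_value=0)


def ct_frequency_table(labels: pd.Series, groups) -> pd.DataFrame:
    """Per-group cervicotype percentages, rounded to integer percent.

    Denominator is the group size.  Use :func:`ct_counts` for the raw
    counts behind the rounding.
    """
    counts = ct_counts(labels, groups)
    pct = 100.0 * counts.div(counts.sum(axis=1), axis=0)
    return pct.round(0).astype(int)


def load_abundance_table(path) -> pd.DataFrame:
    """Read a samples x taxa CSV (first column sample_id).

    Rows that do not sum to 1 (e.g. raw counts) are renormalized with a
    logged warning.
    """
    df = pd.read_csv(path, index_col=0)
    if df.empty:
        raise ValueError(f"abundance table {path} is empty")
    sums = df.sum(axis=1)
    off = ~np.isclose(sums, 1.0, atol=1e-6)
    if off.any():
        logger.warning(
            "%d/%d rows of %s do not sum to 1; renormalizing",
            int(off.sum()), len(df), path,
        )
        df = df.div(sums, axis=0)
    return df
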