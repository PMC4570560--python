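"""Serum-withdrawal response classification.

Each phosphosite quantified in both genetic backgrounds yields a pair of
serum-response ratios: x = log2(high serum / serum starvation) in proficient
cells, y = the same in deficient cells.  Sites responding the same way in
both backgrounds ("correlated") carry no genotype-specific information and
are excluded; the informative sites are the anti-correlated ones:

* ``persistent_in_deficient`` (the scatter's blue group) -- dephosphorylated
  on starvation in proficient cells (large x) but retained in deficient
  cells (y near zero);
* ``lost_in_deficient`` (gray) -- the mirror image.

The cut is parameterized by two thresholds: ``tau_change``, the minimum
log2 response that counts as a real change, and ``tau_null``, the maximum
response still considered "no change".
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Set, Tuple

import pandas as pd

from .phosphodata import site_key

__all__ = [
    "CORRELATED",
    "PERSISTENT_IN_DEFICIENT",
    "LOST_IN_DEFICIENT",
    "UNCLASSIFIED",
    "LABELS",
    "SerumResponseClass",
    "classify_serum_response",
    "join_serum_pairs",
    "partition_sites",
]

CORRELATED = "correlated"
PERSISTENT_IN_DEFICIENT = "persistent_in_deficient"
LOST_IN_DEFICIENT = "lost_in_deficient"
UNCLASSIFIED = "unclassified"
LABELS = (CORRELATED, PERSISTENT_IN_DEFICIENT, LOST_IN_DEFICIENT, UNCLASSIFIED)


@dataclass
class SerumResponseClass:
    site_id: str
    gene: str
    residue: str
    x: float
    y: float
    label: str


def classify_serum_response(
    x: float, y: float, tau_change: float = 1.0, tau_null: float = 0.5
) -> str:
    """Label one site's (x, y) serum-response pair.

    * correlated: same sign, both responses at least ``tau_null`` in
      magnitude, and the two responses within ``tau_change`` of each other;
    * persistent_in_deficient: x >= tau_change and y <= tau_null;
    * lost_in_deficient:       y >= tau_change and x <= tau_null;
    * unclassified otherwise.

    Labels are checked in that order, so they are mutually exclusive.
    """
    if not (math.isfinite(x) and math.isfinite(y)):
        raise ValueError(f"non-finite serum-response pair ({x}, {y})")
    if not tau_change > tau_null >= 0:
        raise ValueError("thresholds must satisfy tau_change > tau_null >= 0")
    same_sign = (x > 0 and y > 0) or (x < 0 and y < 0)
    if same_sign and min(abs(x), abs(y)) >= tau_null and abs(x - y) < tau_change:
        return CORRELATED
    if x >= tau_change and y <= tau_null:
        return PERSISTENT_IN_DEFICIENT
    if y >= tau_change and x <= tau_null:
        return LOST_IN_DEFICIENT
    return UNCLASSIFIED


def join_serum_pairs(ratios_proficient: pd.DataFrame, ratios_deficient: pd.DataFrame) -> pd.DataFrame:
    """Join the two serum comparisons on (gene, residue) into (x, y) pairs.

    Sites missing either ratio are omitted (they cannot be classified, and
    carrying them as "unclassified" would conflate missingness with an
    ambiguous response).
    """
    a = ratios_proficient[["site_id", "gene", "residue", "log2_ratio"]].rename(
        columns={"log2_ratio": "x"}
    )
    b = ratios_deficient[["gene", "residue", "log2_ratio"]].rename(columns={"log2_ratio": "y"})
    a = a.assign(_key=[site_key(g, r) for g, r in zip(a["gene"], a["residue"])])
    b = b.assign(_key=[site_key(g, r) for g, r in zip(b["gene"], b["residue"])])
    joined = a.merge(b[["_key", "y"]], on="_key", how="inner").drop(columns="_key")
    return joined


def partition_sites(
    pairs: pd.DataFrame, tau_change: float = 1.0, tau_null: float = 0.5
) -> Tuple[Dict[str, Set[str]], pd.DataFrame]:
    """Classify every joined (x, y) pair and collapse labels to protein sets.

    ``pairs`` must have columns gene, residue, x, y (see
    :func:`join_serum_pairs`).  Returns a map label -> deduplicated set of
    gene symbols (upper-cased), and the per-site classification table with a
    ``label`` column appended.
    """
    table = pairs.copy()
    table["label"] = [
        classify_serum_response(x, y, tau_change, tau_null)
        for x, y in zip(table["x"], table["y"])
    ]
    proteins: Dict[str, Set[str]] = {label: set() for label in LABELS}
    for gene, label in zip(table["gene"], table["label"]):
        proteins[label].add(gene.upper())
    return proteins, table
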