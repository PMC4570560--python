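"""SILAC ratio computation and intensity-binned outlier significance.

Differential phosphosites are called as *outliers* of the overall log-ratio
distribution, not by replicate-based tests: with a single quantified ratio
per site, the population of ratios is its own null.  Two statistics are
implemented:

* **Significance A** -- an asymmetric robust z-score.  With r0 the median
  log2 ratio, the right-hand scale is the 84.13th percentile minus r0 and
  the left-hand scale is r0 minus the 15.87th percentile (the +/-1 sigma
  quantiles of a normal).  A ratio r is scored against its own side's
  scale, z = (r - r0)/s+ or (r0 - r)/s-, and p = 1/2 erfc(z / sqrt 2).

* **Significance B** -- Significance A computed within contiguous
  equal-occupancy bins of sites ordered by summed intensity.  Because ratio
  scatter shrinks with intensity in MS data, binning judges high-intensity
  sites against a correspondingly tighter null.

Ratios are median-centered per comparison before scoring, and cross-set
comparisons are chained through the shared anchor condition.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Dict, Iterable, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy.special import erfc
from statsmodels.stats.multitest import multipletests

from .errors import ConfigurationError, StatisticError
from .phosphodata import ExperimentDesign, PhosphoSiteRecord, site_key

__all__ = [
    "RATIO_COLUMNS",
    "VennCounts",
    "compute_ratios",
    "significance_A",
    "significance_B",
    "add_significance",
    "bh_adjust",
    "significant_sites",
    "site_signs",
    "venn_counts",
    "volcano_table",
]

#: columns of the per-comparison ratio table
RATIO_COLUMNS = ("site_id", "gene", "residue", "log2_ratio", "summed_intensity")

_SQRT2 = math.sqrt(2.0)
# +/- 1 sigma quantiles of the normal distribution, in percent
_P_HI = 84.13
_P_LO = 15.87


def compute_ratios(
    records: Sequence[PhosphoSiteRecord],
    design: ExperimentDesign,
    comparison: str,
    center: bool = True,
) -> pd.DataFrame:
    """Compute normalized log2 ratios for one named comparison.

    A site contributes only if every channel the comparison needs is present
    (for chained comparisons that includes the anchor channel in both sets).
    Direct comparisons use ``log2(first/second)`` with the summed intensity
    of the two channels; chained ones compose two anchor-relative ratios and
    carry the *minimum* of the two legs' summed intensities as a
    conservative weight.  With ``center=True`` (default) the ratios are
    median-centered so the comparison's median log2 ratio is zero.

    Returns a DataFrame with :data:`RATIO_COLUMNS`; ``df.attrs`` records the
    comparison name and the centering offset.
    """
    plan = design.comparison_plan(comparison)
    rows = []
    for rec in records:
        if plan[0] == "direct":
            _, ch_a, ch_b = plan
            ia, ib = rec.intensity(*ch_a), rec.intensity(*ch_b)
            if ia is None or ib is None:
                continue
            ratio = math.log2(ia / ib)
            sintens = ia + ib
        else:
            _, (ch_a, anchor_a), (ch_b, anchor_b) = plan
            ia, ra = rec.intensity(*ch_a), rec.intensity(*anchor_a)
            ib, rb = rec.intensity(*ch_b), rec.intensity(*anchor_b)
            if None in (ia, ra, ib, rb):
                continue
            ratio = math.log2(ia / ra) - math.log2(ib / rb)
            sintens = min(ia + ra, ib + rb)
        rows.append((rec.site_id, rec.gene, rec.residue, ratio, sintens))
    df = pd.DataFrame(rows, columns=list(RATIO_COLUMNS))
    offset = 0.0
    if center and len(df):
        offset = float(df["log2_ratio"].median())
        df["log2_ratio"] = df["log2_ratio"] - offset
    df.attrs["comparison"] = comparison
    df.attrs["center_offset"] = offset
    return df


def _sig_a(ratios: np.ndarray) -> np.ndarray:
    r0 = float(np.median(ratios))
    s_plus = float(np.percentile(ratios, _P_HI)) - r0
    s_minus = r0 - float(np.percentile(ratios, _P_LO))
    if s_plus <= 0 or s_minus <= 0:
        raise StatisticError(
            "degenerate percentile scale (zero spread on one side); "
            "jitter the ratios or provide a larger input"
        )
    z = np.where(ratios > r0, (ratios - r0) / s_plus, (r0 - ratios) / s_minus)
    return 0.5 * erfc(z / _SQRT2)


def significance_A(log_ratios: Iterable[float]) -> np.ndarray:
    """Asymmetric robust-z outlier p-values for a set of log ratios.

    p lies in (0, 0.5], with p = 0.5 at the median.  Requires at least 3
    finite ratios and non-degenerate spread on both sides of the median.
    """
    r = np.asarray(list(log_ratios), dtype=float)
    if r.size < 3 or not np.all(np.isfinite(r)):
        raise StatisticError("significance_A needs >= 3 finite log ratios")
    return _sig_a(r)


def significance_B(
    log_ratios: Iterable[float],
    intensities: Iterable[float],
    min_bin: int = 300,
    keys: Optional[Sequence] = None,
) -> np.ndarray:
    """Intensity-binned Significance A.

    Sites are ordered by summed intensity (ties broken by ``keys`` when
    given, else by input position, so binning is deterministic) and cut into
    contiguous equal-occupancy bins of at least ``min_bin`` sites; the
    remainder is merged into the last (highest-intensity) bin.  Significance
    A is then applied within each bin.  The output is aligned to the input
    order.  With fewer than ``min_bin`` sites a single bin is used -- i.e.
    Significance B degrades gracefully to Significance A -- with a warning.
    """
    r = np.asarray(list(log_ratios), dtype=float)
    inten = np.asarray(list(intensities), dtype=float)
    if r.shape != inten.shape:
        raise StatisticError("ratios and intensities must align")
    n = r.size
    if n < 3 or not np.all(np.isfinite(r)):
        raise StatisticError("significance_B needs >= 3 finite log ratios")
    if min_bin < 3:
        raise StatisticError("min_bin must be >= 3")

    tiebreak = np.asarray(keys) if keys is not None else np.arange(n)
    order = np.lexsort((tiebreak, inten))
    n_bins = n // min_bin
    if n_bins == 0:
        warnings.warn(
            f"only {n} sites (< min_bin={min_bin}); falling back to a single bin "
            "(Significance B == Significance A)",
            stacklevel=2,
        )
        n_bins = 1
    p = np.empty(n, dtype=float)
    for b in range(n_bins):
        start = b * min_bin
        stop = (b + 1) * min_bin if b < n_bins - 1 else n
        idx = order[start:stop]
        p[idx] = _sig_a(r[idx])
    return p


def bh_adjust(p_values: Iterable[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values (empty in, empty out)."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1)):
        raise StatisticError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def add_significance(
    ratios: pd.DataFrame,
    method: str = "B",
    alpha: float = 0.05,
    min_bin: int = 300,
    adjust: bool = False,
) -> pd.DataFrame:
    """Attach p-values (and optionally BH q-values) plus a significance flag.

    ``method`` is "A" or "B".  The flag is ``p < alpha`` (or ``q < alpha``
    when ``adjust=True``); by default no multiple-testing correction is
    applied to the outlier p-values, matching the straight p < 0.05 cut the
    statistic is normally used with.
    """
    df = ratios.copy()
    if method.upper() == "B":
        p = significance_B(
            df["log2_ratio"], df["summed_intensity"], min_bin=min_bin, keys=df["site_id"]
        )
    elif method.upper() == "A":
        p = significance_A(df["log2_ratio"])
    else:
        raise ConfigurationError(f"unknown significance method {method!r}")
    df["p_value"] = p
    if adjust:
        df["q_value"] = bh_adjust(p)
        df["significant"] = df["q_value"] < alpha
    else:
        df["significant"] = df["p_value"] < alpha
    df.attrs.update(ratios.attrs)
    df.attrs["alpha"] = alpha
    return df


def significant_sites(ratios: pd.DataFrame, alpha: Optional[float] = None) -> Set[Tuple[str, str]]:
    """Set of (GENE, residue) keys called significant in a scored ratio table."""
    if alpha is None:
        mask = ratios["significant"]
    else:
        mask = ratios["p_value"] < alpha
    return {site_key(g, r) for g, r in zip(ratios.loc[mask, "gene"], ratios.loc[mask, "residue"])}


def site_signs(ratios: pd.DataFrame) -> Dict[Tuple[str, str], int]:
    """Map (GENE, residue) -> sign of the log2 ratio (+1, -1 or 0)."""
    return {
        site_key(g, r): int(np.sign(v))
        for g, r, v in zip(ratios["gene"], ratios["residue"], ratios["log2_ratio"])
    }


@dataclass
class VennCounts:
    """Two-set overlap with per-side sign splits.

    ``up``/``down`` count positive / negative log2 ratios among each set's
    significant sites (positive = higher in the comparison's first
    condition).
    """

    only_a: int
    only_b: int
    both: int
    up_a: int = 0
    down_a: int = 0
    up_b: int = 0
    down_b: int = 0

    @property
    def size_a(self) -> int:
        return self.only_a + self.both

    @property
    def size_b(self) -> int:
        return self.only_b + self.both


def venn_counts(
    set_a: Set[Tuple[str, str]],
    set_b: Set[Tuple[str, str]],
    signs_a: Optional[Mapping[Tuple[str, str], int]] = None,
    signs_b: Optional[Mapping[Tuple[str, str], int]] = None,
) -> VennCounts:
    """Exact set algebra over two significant-site sets keyed by (gene, residue)."""
    both = set_a & set_b
    signs_a = signs_a or {}
    signs_b = signs_b or {}
    return VennCounts(
        only_a=len(set_a - set_b),
        only_b=len(set_b - set_a),
        both=len(both),
        up_a=sum(1 for k in set_a if signs_a.get(k, 0) > 0),
        down_a=sum(1 for k in set_a if signs_a.get(k, 0) < 0),
        up_b=sum(1 for k in set_b if signs_b.get(k, 0) > 0),
        down_b=sum(1 for k in set_b if signs_b.get(k, 0) < 0),
    )


def volcano_table(scored: pd.DataFrame) -> pd.DataFrame:
    """Volcano-plot export: log2 ratio, -log10 p and the significance flag."""
    df = scored[["gene", "residue", "log2_ratio", "p_value", "significant"]].copy()
    df["neg_log10_p"] = -np.log10(df["p_value"])
    df["comparison"] = scored.attrs.get("comparison", "")
    return df[["gene", "residue", "comparison", "log2_ratio", "p_value", "neg_log10_p", "significant"]]
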