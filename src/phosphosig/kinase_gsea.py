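"""Residue-level kinase-target-set enrichment on a pre-ranked site list.

Kinase activity leaves a coordinated footprint: if a kinase is more active
in one condition, its known substrate residues shift together in the SILAC
ratio ranking even when no single site passes a per-site significance cut.
This module scores that footprint with the pre-ranked GSEA procedure using
unweighted (classic Kolmogorov-Smirnov) running-sum increments:

* walk the ranked list, adding 1/k at each set member ("hit") and
  subtracting 1/(N-k) at each non-member; the enrichment score ES is the
  signed maximum-magnitude excursion, and the *leading edge* is the hits at
  or before (after, for negative ES) the extremum;
* the null is gene-set permutation: random member sets of the same
  effective size drawn from the ranked universe;
* NES divides ES by the mean magnitude of same-sign null scores, and the
  permutation p-value and FDR follow the standard GSEA tail-ratio
  conventions.

Ranking orientation is configurable; the default puts the most-negative
log2(proficient/deficient) ratios -- sites most phosphorylated in deficient
cells -- at the top, so a kinase hyperactive in deficient cells earns a
positive NES.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DegenerateSetError
from .phosphodata import KinaseTargetRecord, site_key

__all__ = [
    "KinaseTargetSet",
    "RankedList",
    "EnrichmentResult",
    "build_target_sets",
    "rank_sites",
    "enrichment_score",
    "normalized_enrichment",
    "gsea_fdr",
    "results_table",
]

Key = Tuple[str, str]


@dataclass
class KinaseTargetSet:
    """Residue-level target set for one kinase, restricted to the universe."""

    kinase: str
    members: FrozenSet[Key]

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass
class RankedList:
    """Strictly ordered site keys with their ranking metric.

    ``orientation`` is ``"deficient_first"`` (most-negative metric first,
    the default) or ``"proficient_first"`` (reversed).
    """

    keys: Tuple[Key, ...]
    metric: np.ndarray
    orientation: str = "deficient_first"

    def __post_init__(self) -> None:
        if len(self.keys) != len(set(self.keys)):
            raise ConfigurationError("ranked list keys must be unique")

    def __len__(self) -> int:
        return len(self.keys)


@dataclass
class EnrichmentResult:
    """Scored enrichment of one kinase target set."""

    kinase: str
    size: int
    es: float
    nes: float
    p_perm: float
    fdr: float
    leading_edge: Tuple[Key, ...]
    n_perm: int
    seed: Optional[int]
    degenerate_null: bool = False
    null_es: np.ndarray = field(default_factory=lambda: np.empty(0), repr=False)


def build_target_sets(
    records: Sequence[KinaseTargetRecord],
    ranked_universe: Sequence[Key],
    min_size: int = 3,
) -> Tuple[List[KinaseTargetSet], Dict[str, int]]:
    """Group kinase-substrate records into scorable residue-level sets.

    Members are intersected with the ranked universe on (gene, residue);
    duplicate kinase-substrate rows collapse.  Sets whose effective size
    falls below ``min_size`` are dropped; the returned report maps each
    dropped kinase to its (too small) effective size.
    """
    universe = set(ranked_universe)
    if not universe:
        raise ConfigurationError("ranked universe is empty")
    by_kinase: Dict[str, Set[Key]] = {}
    for rec in records:
        by_kinase.setdefault(rec.kinase, set()).add(rec.substrate_key)
    sets: List[KinaseTargetSet] = []
    dropped: Dict[str, int] = {}
    for kinase in sorted(by_kinase):
        members = frozenset(by_kinase[kinase] & universe)
        if len(members) >= min_size:
            sets.append(KinaseTargetSet(kinase=kinase, members=members))
        else:
            dropped[kinase] = len(members)
    return sets, dropped


def rank_sites(ratios: pd.DataFrame, orientation: str = "deficient_first") -> RankedList:
    """Build the pre-ranked list from a per-comparison ratio table.

    Sites are ordered by log2 ratio -- ascending for ``deficient_first``
    (negative ratios, i.e. deficient-high sites, at the top), descending
    otherwise -- with ties broken by site key for determinism.  Duplicate
    (gene, residue) keys keep the entry with the largest summed intensity.
    """
    if orientation not in ("deficient_first", "proficient_first"):
        raise ConfigurationError(f"unknown orientation {orientation!r}")
    df = ratios.copy()
    df["_key"] = [site_key(g, r) for g, r in zip(df["gene"], df["residue"])]
    if "summed_intensity" in df.columns:
        df = df.sort_values("summed_intensity", kind="mergesort").drop_duplicates("_key", keep="last")
    else:
        df = df.drop_duplicates("_key", keep="first")
    if not np.all(np.isfinite(df["log2_ratio"])):
        raise ConfigurationError("ranking metric must be finite")
    ascending = orientation == "deficient_first"
    df = df.sort_values(["log2_ratio", "_key"], ascending=[ascending, True], kind="mergesort")
    return RankedList(
        keys=tuple(df["_key"]),
        metric=df["log2_ratio"].to_numpy(dtype=float),
        orientation=orientation,
    )


def _signed_extremum(candidates: np.ndarray) -> float:
    """Signed maximum-magnitude value; a positive value wins exact ties."""
    hi = float(candidates.max())
    lo = float(candidates.min())
    return hi if hi >= -lo else lo


def enrichment_score(
    ranked: RankedList, members: FrozenSet[Key]
) -> Tuple[float, np.ndarray, Tuple[Key, ...]]:
    """Unweighted KS running-sum enrichment of one set over the ranked list.

    Returns (ES, running sum over all N positions, leading edge).  The set
    must be non-empty and must not cover the whole list.
    """
    n = len(ranked)
    hits = np.fromiter((k in members for k in ranked.keys), dtype=bool, count=n)
    k = int(hits.sum())
    if k == 0 or k == n:
        raise DegenerateSetError(f"set covers {k} of {n} ranked sites")
    steps = np.where(hits, 1.0 / k, -1.0 / (n - k))
    running = np.cumsum(steps)
    es = _signed_extremum(running)
    if es >= 0:
        peak = int(np.argmax(running))
        leading = tuple(key for i, key in enumerate(ranked.keys[: peak + 1]) if hits[i])
    else:
        trough = int(np.argmin(running))
        leading = tuple(key for i, key in enumerate(ranked.keys) if i >= trough and hits[i])
    return es, running, leading


def _es_from_hit_positions(pos: np.ndarray, n: int) -> float:
    """ES from sorted 0-based hit positions without materializing the walk.

    The running sum attains its extrema only at hit positions (local maxima)
    or immediately before them (local minima), so scanning those candidates
    reproduces the full cumulative-sum extremum exactly.
    """
    k = pos.size
    j = np.arange(1, k + 1, dtype=float)
    miss = 1.0 / (n - k)
    at_hit = j / k - (pos + 1 - j) * miss
    before_hit = (j - 1) / k - (pos - (j - 1)) * miss
    # the walk ends at 0; include it so an all-early set's minimum is bounded
    return _signed_extremum(np.concatenate([at_hit, before_hit, [0.0]]))


def _null_es(
    n: int, k: int, n_perm: int, rng: np.random.Generator
) -> np.ndarray:
    out = np.empty(n_perm, dtype=float)
    for i in range(n_perm):
        pos = np.sort(rng.choice(n, size=k, replace=False))
        out[i] = _es_from_hit_positions(pos.astype(float), n)
    return out


def normalized_enrichment(
    ranked: RankedList,
    sets: Sequence[KinaseTargetSet],
    n_perm: int = 1000,
    seed: Optional[int] = None,
) -> List[EnrichmentResult]:
    """Score every target set with permutation-normalized ES and FDR.

    For each set, ``n_perm`` random member sets of equal effective size are
    drawn from the ranked universe (gene-set permutation).  NES is the
    observed ES divided by the mean |ES| of same-sign null scores;
    ``p_perm = (1 + #{same-sign nulls at least as extreme}) / (1 + #same-sign
    nulls)``.  FDR is computed over the whole collection by
    :func:`gsea_fdr`.  Results are reproducible bit-for-bit given ``seed``
    and are returned sorted by descending NES.
    """
    if n_perm < 100:
        raise ConfigurationError("n_perm must be >= 100")
    n = len(ranked)
    results: List[EnrichmentResult] = []
    root = np.random.SeedSequence(seed)
    # one substream per set, in deterministic (sorted-kinase) order
    ordered = sorted(sets, key=lambda s: s.kinase)
    streams = root.spawn(len(ordered))
    for tset, stream in zip(ordered, streams):
        es, _, leading = enrichment_score(ranked, tset.members)
        null = _null_es(n, tset.size, n_perm, np.random.default_rng(stream))
        same_sign = null > 0 if es >= 0 else null < 0
        n_sign = int(same_sign.sum())
        degenerate = n_sign == 0
        if degenerate:
            denom = float(np.abs(null).mean()) if null.size else 1.0
            p_perm = 1.0
        else:
            denom = float(np.abs(null[same_sign]).mean())
            n_extreme = int((np.abs(null[same_sign]) >= abs(es)).sum())
            p_perm = (1 + n_extreme) / (1 + n_sign)
        results.append(
            EnrichmentResult(
                kinase=tset.kinase,
                size=tset.size,
                es=es,
                nes=es / denom,
                p_perm=p_perm,
                fdr=np.nan,
                leading_edge=leading,
                n_perm=n_perm,
                seed=seed,
                degenerate_null=degenerate,
                null_es=null,
            )
        )
    gsea_fdr(results)
    results.sort(key=lambda r: (-r.nes, r.kinase))
    return results


def gsea_fdr(results: Sequence[EnrichmentResult]) -> None:
    """Permutation FDR over a collection of scored sets (in place).

    Each set's null ES values are normalized by that set's own same-sign
    mean magnitude, then pooled.  For an observed NES, FDR is the fraction
    of pooled same-sign null NES at least as extreme divided by the fraction
    of observed same-sign NES at least as extreme, clipped to [0, 1] and
    monotone-adjusted so FDR never decreases as |NES| decreases.  With a
    single scored set the permutation p-value is used as a fallback.
    """
    if not results:
        return
    if len(results) == 1:
        results[0].fdr = results[0].p_perm
        return
    null_nes_pool: List[np.ndarray] = []
    for r in results:
        null = r.null_es
        pos = null[null > 0]
        neg = null[null < 0]
        normalized = np.empty_like(null)
        pos_mean = pos.mean() if pos.size else np.nan
        neg_mean = np.abs(neg).mean() if neg.size else np.nan
        normalized[null > 0] = null[null > 0] / pos_mean
        normalized[null < 0] = null[null < 0] / neg_mean
        normalized[null == 0] = 0.0
        null_nes_pool.append(normalized[np.isfinite(normalized)])
    pool = np.concatenate(null_nes_pool)
    obs = np.array([r.nes for r in results])
    for r in results:
        if r.nes >= 0:
            null_side, obs_side = pool[pool >= 0], obs[obs >= 0]
        else:
            null_side, obs_side = pool[pool < 0], obs[obs < 0]
        if null_side.size == 0:
            r.fdr = r.p_perm
            continue
        frac_null = (np.abs(null_side) >= abs(r.nes)).mean()
        frac_obs = (np.abs(obs_side) >= abs(r.nes)).sum() / obs_side.size
        r.fdr = float(np.clip(frac_null / frac_obs, 0.0, 1.0))
    # monotone adjustment per sign: larger |NES| never has larger FDR, so
    # walk from the weakest score upward carrying the running minimum
    for side in (1, -1):
        group = [r for r in results if (r.nes >= 0) == (side == 1)]
        group.sort(key=lambda r: abs(r.nes))
        best = np.inf
        for r in group:
            best = min(best, r.fdr)
            r.fdr = best


def results_table(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    """Flatten enrichment results for TSV export."""
    return pd.DataFrame(
        [
            {
                "kinase": r.kinase,
                "size": r.size,
                "es": r.es,
                "nes": r.nes,
                "p_perm": r.p_perm,
                "fdr": r.fdr,
                "leading_edge": ";".join(f"{g}_{res}" for g, res in r.leading_edge),
            }
            for r in results
        ],
        columns=["kinase", "size", "es", "nes", "p_perm", "fdr", "leading_edge"],
    )
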