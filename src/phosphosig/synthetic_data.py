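"""Synthetic phosphoproteomics inputs with known planted truth.

The generator emulates the statistical structure of a two-set triple-SILAC
phosphosite quantification experiment:

* per-site base abundances are log-normal (normal on the log2 scale);
* channel noise is additive on the log2 scale, with a standard deviation
  that *decays with intensity* -- sigma(I) = a + b exp(-c (I - I_min)) --
  so log-ratio scatter is wide for faint sites and tight for intense ones,
  the regime the intensity-binned outlier statistic is built for;
* the anchor condition (proficient cells, high serum) shares its true
  abundance across both labeling sets, with independent channel noise;
* planted effects: differential phosphosites in the high-serum and/or
  low-serum genotype comparison, serum-response classes (correlated /
  persistent-in-deficient / lost-in-deficient), and kinase target sets
  whose members receive a coherent shift in the low-serum comparison;
* companion kinase-substrate, annotation (GMT) and scored-edge tables carry
  planted enriched sets and densely connected, term-coherent network
  modules.

Everything is driven by one integer seed; tables for the three input kinds
come from independent substreams, so regenerating one never perturbs the
others.

The four biological conditions and their default channel assignment::

    set 1: light = proficient/high-serum (anchor), medium = deficient/high,
           heavy = deficient/low
    set 2: light = proficient/high-serum (anchor), medium = proficient/low,
           heavy = deficient/low

A site's true condition values on the log2 scale are parameterized by its
base abundance ``base``, the genotype effects ``d_high`` and ``d_low``
(log2 proficient/deficient under high and low serum) and the proficient
serum response ``x`` (log2 high/low serum):

    proficient/high = base            deficient/high = base - d_high
    proficient/low  = base - x        deficient/low  = base - x - d_low

which fixes the deficient serum response at ``y = x + d_low - d_high``.
Because only three of the four pairwise contrasts are free, planted
differential sites, serum-response sites and kinase-set sites are drawn
from disjoint site populations, keeping each kind of planted truth clean.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .phosphodata import (
    AnnotationMap,
    CHANNELS,
    ExperimentDesign,
    KinaseTargetRecord,
    NetworkEdge,
    PhosphoSiteRecord,
    SETS,
    format_residue,
)

__all__ = [
    "SyntheticConfig",
    "default_design",
    "generate_phosphoproteome",
    "generate_kinase_substrates",
    "generate_annotations_and_network",
]

# biological condition labels
PROF_HIGH = "proficient_high_serum"
DEF_HIGH = "deficient_high_serum"
PROF_LOW = "proficient_low_serum"
DEF_LOW = "deficient_low_serum"

# planted site categories in the truth table
CAT_NULL = "null"
CAT_DIFF_BOTH = "diff_both"
CAT_DIFF_HIGH = "diff_high_only"
CAT_DIFF_LOW = "diff_low_only"
CAT_CORRELATED = "serum_correlated"
CAT_BLUE = "serum_persistent_in_deficient"
CAT_GRAY = "serum_lost_in_deficient"
CAT_KINASE = "kinase_planted"

SERUM_CLASS_OF_CATEGORY = {
    CAT_CORRELATED: "correlated",
    CAT_BLUE: "persistent_in_deficient",
    CAT_GRAY: "lost_in_deficient",
    CAT_NULL: "unclassified",
}


def default_design() -> ExperimentDesign:
    """Two triple-SILAC sets sharing the proficient/high-serum light anchor."""
    return ExperimentDesign(
        conditions={
            (1, "light"): PROF_HIGH,
            (1, "medium"): DEF_HIGH,
            (1, "heavy"): DEF_LOW,
            (2, "light"): PROF_HIGH,
            (2, "medium"): PROF_LOW,
            (2, "heavy"): DEF_LOW,
        },
        anchor=PROF_HIGH,
        comparisons={
            "smarcb1_high": (PROF_HIGH, DEF_HIGH),
            "smarcb1_low": (PROF_LOW, DEF_LOW),
            "serum_proficient": (PROF_HIGH, PROF_LOW),
            "serum_deficient": (DEF_HIGH, DEF_LOW),
        },
    )


@dataclass
class SyntheticConfig:
    """Generator parameters; defaults reflect the scale of the emulated study.

    Intensity and noise parameters are on the log2 scale.  ``pi_*`` are
    per-site probabilities of the planted categories; whatever is left over
    is unperturbed background ("null") sites.
    """

    seed: int
    # proteome shape: ~3655 proteins x ~2.9 sites/protein ~ 10700 sites
    n_proteins: int = 3655
    sites_per_protein_mean: float = 2.93
    # log2 intensity model
    mu_intensity: float = 23.0
    sigma_intensity: float = 2.0
    # ratio-noise model sigma(I) = a + b exp(-c (I - I_min)); I_min defaults
    # to mu - 3 sigma.  Channel noise sd is sigma(I)/sqrt(2) so the log-ratio
    # of two channels has sd sigma(I).
    noise_a: float = 0.15
    noise_b: float = 1.2
    noise_c: float = 0.4
    noise_I_min: Optional[float] = None
    # planted genotype-differential fractions (fractions of all sites)
    pi_diff_both: float = 0.019
    pi_diff_high_only: float = 0.064
    pi_diff_low_only: float = 0.038
    effect_mean: float = 2.0
    effect_sd: float = 0.5
    effect_min: float = 0.75
    # planted serum-response classes
    pi_correlated: float = 0.25
    pi_blue: float = 0.03
    pi_gray: float = 0.03
    serum_effect_mean: float = 2.0
    serum_effect_sd: float = 0.5
    serum_effect_min: float = 1.5
    # planted kinase target sets
    n_planted_kinase_sets: int = 1
    planted_kinase_size: int = 10
    planted_kinase_delta: float = -2.0
    n_decoy_kinase_sets: int = 20
    decoy_kinase_size: int = 10
    offspecies_kinase_rows: int = 20
    # missingness
    missing_rate: float = 0.05
    # annotation / network planting
    n_modules: int = 3
    module_size: int = 8
    p_intra: float = 0.9
    intra_score_low: float = 0.91
    intra_score_high: float = 1.0
    n_background_edges: int = 3000
    background_score_low: float = 0.05
    background_score_high: float = 0.9
    n_background_terms: int = 20
    background_term_size: int = 40

    def __post_init__(self) -> None:
        pis = (
            self.pi_diff_both,
            self.pi_diff_high_only,
            self.pi_diff_low_only,
            self.pi_correlated,
            self.pi_blue,
            self.pi_gray,
        )
        if any(p < 0 or p > 1 for p in pis) or sum(pis) > 1:
            raise ConfigurationError("planted-category probabilities must be in [0,1] and sum <= 1")
        if self.noise_a <= 0 or self.noise_b < 0 or self.noise_c < 0:
            raise ConfigurationError("noise model requires a > 0 and b, c >= 0")
        if not (0 <= self.missing_rate < 1):
            raise ConfigurationError("missing_rate must lie in [0, 1)")
        if self.seed is None:
            raise ConfigurationError("seed is mandatory")

    def sigma_ratio(self, log2_intensity: np.ndarray) -> np.ndarray:
        """Intensity-dependent log2-ratio noise sd."""
        i_min = (
            self.noise_I_min
            if self.noise_I_min is not None
            else self.mu_intensity - 3 * self.sigma_intensity
        )
        return self.noise_a + self.noise_b * np.exp(
            -self.noise_c * (np.asarray(log2_intensity, dtype=float) - i_min)
        )

    def _streams(self) -> Dict[str, np.random.SeedSequence]:
        phospho, kinase, network = np.random.SeedSequence(self.seed).spawn(3)
        return {"phospho": phospho, "kinase": kinase, "network": network}


_CATEGORIES = (
    CAT_DIFF_BOTH,
    CAT_DIFF_HIGH,
    CAT_DIFF_LOW,
    CAT_CORRELATED,
    CAT_BLUE,
    CAT_GRAY,
)


def _signed_effect(rng: np.random.Generator, mean: float, sd: float, lo: float) -> float:
    mag = max(lo, rng.normal(mean, sd))
    return mag if rng.random() < 0.5 else -mag


def generate_phosphoproteome(
    config: SyntheticConfig, design: Optional[ExperimentDesign] = None
) -> Tuple[List[PhosphoSiteRecord], pd.DataFrame]:
    """Generate the site table and its truth table.

    Returns records (readable/writable by the site-table I/O unchanged) and
    a truth DataFrame keyed by site_id with columns: gene, residue,
    category, serum_class (planted label or "" where no class was planted),
    kinase (planted kinase name or ""), base, d_high, d_low, x, y.
    """
    design = design or default_design()
    rng = np.random.default_rng(config._streams()["phospho"])

    # --- proteome layout -------------------------------------------------
    n_sites_per = 1 + rng.poisson(max(config.sites_per_protein_mean - 1.0, 0.0), config.n_proteins)
    letters = np.array(list("STY"))
    rows: List[Tuple[str, str, str, str]] = []  # site_id, protein, gene, residue
    for p in range(config.n_proteins):
        protein = f"P{p + 1:05d}"
        gene = f"G{p + 1:05d}"
        k = int(n_sites_per[p])
        positions = rng.choice(np.arange(1, 2001), size=k, replace=False)
        for pos in sorted(positions):
            letter = letters[rng.choice(3, p=[0.62, 0.30, 0.08])]
            residue = format_residue(str(letter), int(pos))
            rows.append((f"site{len(rows) + 1:06d}", protein, gene, residue))
    n = len(rows)

    # --- planted categories ----------------------------------------------
    probs = [
        config.pi_diff_both,
        config.pi_diff_high_only,
        config.pi_diff_low_only,
        config.pi_correlated,
        config.pi_blue,
        config.pi_gray,
    ]
    probs.append(1.0 - sum(probs))
    cat_idx = rng.choice(len(_CATEGORIES) + 1, size=n, p=probs)
    categories = np.array(list(_CATEGORIES) + [CAT_NULL])[cat_idx]

    # kinase-planted members are recruited from null sites so the kinase
    # shift never collides with another planted effect
    kinase_label = np.array([""] * n, dtype=object)
    null_idx = np.flatnonzero(categories == CAT_NULL)
    need = config.n_planted_kinase_sets * config.planted_kinase_size
    if need > 0:
        if need > null_idx.size:
            raise ConfigurationError("not enough background sites for planted kinase sets")
        chosen = rng.choice(null_idx, size=need, replace=False)
        for s in range(config.n_planted_kinase_sets):
            members = chosen[s * config.planted_kinase_size : (s + 1) * config.planted_kinase_size]
            categories[members] = CAT_KINASE
            kinase_label[members] = f"PKIN{s + 1}"

    # --- true effects ----------------------------------------------------
    base = rng.normal(config.mu_intensity, config.sigma_intensity, n)
    d_high = np.zeros(n)
    d_low = np.zeros(n)
    x = np.zeros(n)
    for i, cat in enumerate(categories):
        if cat == CAT_DIFF_BOTH:
            e = _signed_effect(rng, config.effect_mean, config.effect_sd, config.effect_min)
            d_high[i] = d_low[i] = e
        elif cat == CAT_DIFF_HIGH:
            d_high[i] = _signed_effect(rng, config.effect_mean, config.effect_sd, config.effect_min)
        elif cat == CAT_DIFF_LOW:
            d_low[i] = _signed_effect(rng, config.effect_mean, config.effect_sd, config.effect_min)
        elif cat == CAT_CORRELATED:
            s = _signed_effect(
                rng, config.serum_effect_mean, config.serum_effect_sd, config.serum_effect_min
            )
            x[i] = s  # y = x because d_low = d_high = 0
        elif cat == CAT_BLUE:
            # loses phosphorylation on starvation only in proficient cells:
            # x large positive, y = 0 => d_low = d_high - x
            s = max(config.serum_effect_min, rng.normal(config.serum_effect_mean, config.serum_effect_sd))
            x[i] = s
            d_low[i] = -s
        elif cat == CAT_GRAY:
            # y large positive, x = 0 => d_low = d_high + y
            s = max(config.serum_effect_min, rng.normal(config.serum_effect_mean, config.serum_effect_sd))
            d_low[i] = s
        elif cat == CAT_KINASE:
            d_low[i] = config.planted_kinase_delta
    y = x + d_low - d_high

    condition_truth = {
        PROF_HIGH: base,
        DEF_HIGH: base - d_high,
        PROF_LOW: base - x,
        DEF_LOW: base - x - d_low,
    }

    # --- channel intensities with heteroscedastic noise -------------------
    sigma_channel = config.sigma_ratio(base) / np.sqrt(2.0)
    records: List[PhosphoSiteRecord] = []
    channel_keys = [(s, ch) for s in SETS for ch in CHANNELS]
    for i, (site_id, protein, gene, residue) in enumerate(rows):
        intensities: Dict[Tuple[int, str], float] = {}
        for s, ch in channel_keys:
            cond = design.conditions.get((s, ch))
            if cond is None:
                continue
            if rng.random() < config.missing_rate:
                continue
            log2_val = condition_truth[cond][i] + rng.normal(0.0, sigma_channel[i])
            intensities[(s, ch)] = float(2.0 ** log2_val)
        if not intensities:  # keep the record well-formed: re-draw one channel
            s, ch = channel_keys[int(rng.integers(len(channel_keys)))]
            cond = design.conditions[(s, ch)]
            log2_val = condition_truth[cond][i] + rng.normal(0.0, sigma_channel[i])
            intensities[(s, ch)] = float(2.0 ** log2_val)
        records.append(
            PhosphoSiteRecord(
                site_id=site_id,
                protein_id=protein,
                gene=gene,
                residue=residue,
                intensities=intensities,
                localization_prob=float(np.round(rng.uniform(0.6, 1.0), 4)),
            )
        )

    truth = pd.DataFrame(
        {
            "site_id": [r[0] for r in rows],
            "gene": [r[2] for r in rows],
            "residue": [r[3] for r in rows],
            "category": categories,
            "serum_class": [SERUM_CLASS_OF_CATEGORY.get(c, "") for c in categories],
            "kinase": kinase_label,
            "base": base,
            "d_high": d_high,
            "d_low": d_low,
            "x": x,
            "y": y,
        }
    )
    return records, truth


def generate_kinase_substrates(
    config: SyntheticConfig,
    site_universe: Sequence[Tuple[str, str]],
    truth: Optional[pd.DataFrame] = None,
) -> Tuple[List[KinaseTargetRecord], Dict[str, FrozenSet[Tuple[str, str]]]]:
    """Emit a kinase-substrate table with planted and decoy sets.

    Planted sets are the kinase-labeled sites of the truth table (which
    received the configured shift in the low-serum comparison); decoy sets
    sample uniformly from the site universe with no shift.  A handful of
    off-species rows exercise the species filter downstream.  Returns the
    record list and the planted/decoy membership truth.
    """
    rng = np.random.default_rng(config._streams()["kinase"])
    universe = sorted(set(site_universe))
    if not universe:
        raise ConfigurationError("site universe is empty")
    sets: Dict[str, FrozenSet[Tuple[str, str]]] = {}
    if truth is not None:
        for kin in sorted(set(truth.loc[truth["kinase"] != "", "kinase"])):
            sub = truth[truth["kinase"] == kin]
            sets[kin] = frozenset(
                (g.upper(), res) for g, res in zip(sub["gene"], sub["residue"])
            )
    for d in range(config.n_decoy_kinase_sets):
        idx = rng.choice(len(universe), size=min(config.decoy_kinase_size, len(universe)), replace=False)
        sets[f"DKIN{d + 1:02d}"] = frozenset(universe[i] for i in sorted(idx))

    records: List[KinaseTargetRecord] = []
    for kin in sorted(sets):
        for gene, residue in sorted(sets[kin]):
            records.append(
                KinaseTargetRecord(
                    kinase=kin,
                    substrate_gene=gene,
                    substrate_residue=residue,
                    species_kinase="mouse",
                    species_substrate="mouse",
                )
            )
    for j in range(config.offspecies_kinase_rows):
        gene, residue = universe[int(rng.integers(len(universe)))]
        records.append(
            KinaseTargetRecord(
                kinase=f"HKIN{j + 1:02d}",
                substrate_gene=gene,
                substrate_residue=residue,
                species_kinase="human",
                species_substrate="human",
            )
        )
    return records, sets


def generate_annotations_and_network(
    config: SyntheticConfig,
    proteins: Sequence[str],
    focus_proteins: Optional[Sequence[str]] = None,
) -> Tuple[AnnotationMap, List[NetworkEdge], Dict[str, Tuple[str, ...]]]:
    """Emit a GMT annotation map and a scored edge list with planted modules.

    Each planted module is a clique-like group: its internal edges score
    above the high-confidence cutoff (uniform on the configured intra-score
    range, present with probability ``p_intra``) and it carries one
    dedicated annotation term.  Background edges score below the cutoff.
    Modules are sampled from ``focus_proteins`` when given (e.g. the
    proteins of a planted serum-response class) so they survive downstream
    protein-set filtering; otherwise from the whole universe.
    Returns (annotations, edges, module truth: term -> members).
    """
    rng = np.random.default_rng(config._streams()["network"])
    universe = sorted(set(proteins))
    if len(universe) < config.n_modules * config.module_size:
        raise ConfigurationError("protein universe too small for the requested modules")
    pool = sorted(set(focus_proteins)) if focus_proteins else universe
    if len(pool) < config.n_modules * config.module_size:
        pool = universe

    chosen = rng.choice(len(pool), size=config.n_modules * config.module_size, replace=False)
    modules: Dict[str, Tuple[str, ...]] = {}
    edge_scores: Dict[Tuple[str, str], float] = {}
    for m in range(config.n_modules):
        members = tuple(
            sorted(pool[i] for i in chosen[m * config.module_size : (m + 1) * config.module_size])
        )
        modules[f"MODULE_{m + 1}"] = members
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                if rng.random() < config.p_intra:
                    edge_scores[(members[i], members[j])] = float(
                        rng.uniform(config.intra_score_low, config.intra_score_high)
                    )

    for _ in range(config.n_background_edges):
        i, j = rng.choice(len(universe), size=2, replace=False)
        a, b = sorted((universe[i], universe[j]))
        if (a, b) in edge_scores:
            continue
        edge_scores[(a, b)] = float(
            rng.uniform(config.background_score_low, config.background_score_high)
        )
    edges = [NetworkEdge(a, b, s) for (a, b), s in sorted(edge_scores.items())]

    terms: Dict[str, FrozenSet[str]] = {
        f"TERM_{name}": frozenset(members) for name, members in modules.items()
    }
    for t in range(config.n_background_terms):
        size = min(config.background_term_size, len(universe))
        idx = rng.choice(len(universe), size=size, replace=False)
        terms[f"TERM_BG{t + 1:02d}"] = frozenset(universe[i] for i in idx)
    annotations = AnnotationMap(terms=terms, background=frozenset(universe))
    return annotations, edges, modules
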