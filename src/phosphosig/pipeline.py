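"""End-to-end pipeline: inputs -> ratios -> significance -> serum classes ->
kinase enrichment -> functional context, with a manifest for auditability.

Every stage writes plain TSV/JSON into the output directory and appends a
row-count entry to the manifest, so "records surviving each filter" can be
audited after the fact.  A fixed seed makes the whole run reproducible,
including the permutation-based enrichment stage.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Dict, List, Optional, Tuple

import pandas as pd
import yaml

from . import functional_context, kinase_gsea, serum_response, significance, synthetic_data
from .errors import ConfigurationError, PhosphosigError
from .phosphodata import (
    ExperimentDesign,
    read_annotations,
    read_edges,
    read_kinase_substrates,
    read_site_table,
    site_key,
    write_annotations,
    write_edges,
    write_kinase_substrates,
    write_site_table,
)

__all__ = ["PipelineConfig", "run_pipeline", "summarize_counts"]


@dataclass
class PipelineConfig:
    """Declarative configuration of one pipeline run.

    Exactly one of ``synthetic`` (a :class:`SyntheticConfig` kwargs block)
    or ``inputs`` (paths to site/kinase/annotation/edge tables) must be
    given.  All statistical thresholds are surfaced here; the defaults are
    alpha = 0.05 and intensity bins of 300 for differential calling, a
    strict 0.9 cutoff for network edges, and 1000 permutations for kinase
    enrichment.
    """

    outdir: str
    seed: int = 0
    synthetic: Optional[Dict[str, Any]] = None
    inputs: Optional[Dict[str, str]] = None
    design: Optional[Dict[str, Any]] = None
    comparisons_high: str = "smarcb1_high"
    comparisons_low: str = "smarcb1_low"
    serum_proficient: str = "serum_proficient"
    serum_deficient: str = "serum_deficient"
    alpha: float = 0.05
    min_bin: int = 300
    sig_method: str = "B"
    bh_adjust: bool = False
    min_localization: Optional[float] = None
    tau_change: float = 1.0
    tau_null: float = 0.5
    n_perm: int = 1000
    gsea_min_size: int = 3
    gsea_orientation: str = "deficient_first"
    network_threshold: float = 0.9
    species: str = "mouse"

    def __post_init__(self) -> None:
        if (self.synthetic is None) == (self.inputs is None):
            raise ConfigurationError("exactly one of 'synthetic' or 'inputs' must be set")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, "rt", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_dict(self) -> Dict[str, Any]:
        return dataclasses.asdict(self)

    def build_design(self) -> ExperimentDesign:
        if self.design is None:
            return synthetic_data.default_design()
        conditions = {
            (int(s), ch): cond
            for key, cond in self.design["conditions"].items()
            for s, ch in [key.split("/")]
        }
        comparisons = {name: tuple(pair) for name, pair in self.design["comparisons"].items()}
        return ExperimentDesign(
            conditions=conditions, anchor=self.design["anchor"], comparisons=comparisons
        )


def _config_hash(config: PipelineConfig) -> str:
    # outdir is excluded: the hash identifies the analysis, not its location
    payload = {k: v for k, v in config.to_dict().items() if k != "outdir"}
    canon = json.dumps(payload, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def summarize_counts(
    scored_high: pd.DataFrame,
    scored_low: pd.DataFrame,
    venn: significance.VennCounts,
    class_table: Optional[pd.DataFrame] = None,
) -> Dict[str, Any]:
    """Counts report: quantified/significant sites, sign splits, overlap,
    distinct proteins and serum-class sizes."""

    def _distinct_proteins(df: pd.DataFrame) -> int:
        return int(df.loc[df["significant"], "gene"].str.upper().nunique())

    report = {
        "sites_quantified_high": int(len(scored_high)),
        "sites_quantified_low": int(len(scored_low)),
        "significant_high": venn.size_a,
        "significant_low": venn.size_b,
        "significant_both": venn.both,
        "significant_high_only": venn.only_a,
        "significant_low_only": venn.only_b,
        "high_up_in_proficient": venn.up_a,
        "high_up_in_deficient": venn.down_a,
        "low_up_in_proficient": venn.up_b,
        "low_up_in_deficient": venn.down_b,
        "distinct_proteins_high": _distinct_proteins(scored_high),
        "distinct_proteins_low": _distinct_proteins(scored_low),
    }
    if class_table is not None:
        report["serum_pairs"] = int(len(class_table))
        for label in serum_response.LABELS:
            report[f"class_{label}"] = int((class_table["label"] == label).sum())
    return report


def run_pipeline(config: PipelineConfig) -> Dict[str, Any]:
    """Run every stage in order and write the report bundle.

    Returns the manifest dict (also written as ``manifest.json``).  Any
    stage failure marks the manifest incomplete with the stage name and the
    error's machine-readable code before the exception propagates.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: Dict[str, Any] = {
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "stages": [],
        "skipped": [],
        "counts": {},
        "complete": False,
    }
    design = config.build_design()

    def _stage(name: str, **info) -> None:
        manifest["stages"].append({"stage": name, **info})

    def _fail(name: str, exc: Exception) -> None:
        manifest["complete"] = False
        manifest["failed_stage"] = name
        manifest["error_code"] = getattr(exc, "exit_code", 1)
        manifest["error"] = str(exc)
        _write_manifest(outdir, manifest)

    truth = None
    kinase_path = annotations_path = edges_path = None
    try:
        # ---------------- stage 1: load or generate -----------------------
        if config.synthetic is not None:
            syn = synthetic_data.SyntheticConfig(**{"seed": config.seed, **config.synthetic})
            records, truth = synthetic_data.generate_phosphoproteome(syn, design)
            write_site_table(records, outdir / "site_table.tsv")
            truth.to_csv(outdir / "truth_sites.tsv", sep="\t", index=False)
            universe = sorted({r.key for r in records})
            kin_records, kin_truth = synthetic_data.generate_kinase_substrates(syn, universe, truth)
            kinase_path = outdir / "kinase_substrates.tsv"
            write_kinase_substrates(kin_records, kinase_path)
            focus = sorted(
                set(
                    truth.loc[
                        truth["category"].isin(
                            [synthetic_data.CAT_BLUE, synthetic_data.CAT_GRAY]
                        ),
                        "gene",
                    ].str.upper()
                )
            )
            proteins = sorted({r.gene.upper() for r in records})
            annotations, edges, modules = synthetic_data.generate_annotations_and_network(
                syn, proteins, focus_proteins=focus
            )
            annotations_path = outdir / "annotations.gmt"
            edges_path = outdir / "edges.tsv"
            write_annotations(annotations, annotations_path)
            write_edges(edges, edges_path)
            with open(outdir / "truth_modules.json", "wt", encoding="utf-8") as fh:
                json.dump({k: list(v) for k, v in modules.items()}, fh, indent=1)
            _stage("generate", n_sites=len(records), n_kinase_rows=len(kin_records),
                   n_edges=len(edges), n_terms=len(annotations.terms))
        else:
            records, report = read_site_table(
                config.inputs["site_table"], min_localization=config.min_localization
            )
            kinase_path = config.inputs.get("kinase_table")
            annotations_path = config.inputs.get("annotations")
            edges_path = config.inputs.get("edges")
            _stage("load", n_kept=report.n_kept, n_dropped=report.n_dropped)

        # ---------------- stage 2: ratios + significance ------------------
        scored: Dict[str, pd.DataFrame] = {}
        for comparison in (config.comparisons_high, config.comparisons_low):
            ratios = significance.compute_ratios(records, design, comparison)
            scored[comparison] = significance.add_significance(
                ratios,
                method=config.sig_method,
                alpha=config.alpha,
                min_bin=config.min_bin,
                adjust=config.bh_adjust,
            )
            scored[comparison].to_csv(outdir / f"ratios_{comparison}.tsv", sep="\t", index=False)
            significance.volcano_table(scored[comparison]).to_csv(
                outdir / f"volcano_{comparison}.tsv", sep="\t", index=False
            )
            _stage(
                "significance",
                comparison=comparison,
                n_ratios=len(ratios),
                n_significant=int(scored[comparison]["significant"].sum()),
            )
        high, low = scored[config.comparisons_high], scored[config.comparisons_low]

        # ---------------- stage 3: intersection ---------------------------
        set_high = significance.significant_sites(high)
        set_low = significance.significant_sites(low)
        venn = significance.venn_counts(
            set_high, set_low, significance.site_signs(high), significance.site_signs(low)
        )
        _stage("venn", both=venn.both, only_high=venn.only_a, only_low=venn.only_b)

        # ---------------- stage 4: serum-response classes -----------------
        class_table = None
        try:
            x_ratios = significance.compute_ratios(records, design, config.serum_proficient)
            y_ratios = significance.compute_ratios(records, design, config.serum_deficient)
            pairs = serum_response.join_serum_pairs(x_ratios, y_ratios)
            protein_sets, class_table = serum_response.partition_sites(
                pairs, config.tau_change, config.tau_null
            )
            class_table.to_csv(outdir / "serum_classes.tsv", sep="\t", index=False)
            _stage(
                "serum_response",
                n_pairs=len(class_table),
                **{f"n_{k}": len(v) for k, v in protein_sets.items()},
            )
        except ConfigurationError:
            protein_sets = {}
            manifest["skipped"].append("serum_response")

        # ---------------- stage 5: kinase enrichment ----------------------
        enrichment = None
        if kinase_path is not None:
            kin_records, kin_report = read_kinase_substrates(kinase_path, config.species)
            ranked = kinase_gsea.rank_sites(low, orientation=config.gsea_orientation)
            sets, dropped = kinase_gsea.build_target_sets(
                kin_records, ranked.keys, min_size=config.gsea_min_size
            )
            if sets:
                enrichment = kinase_gsea.normalized_enrichment(
                    ranked, sets, n_perm=config.n_perm, seed=config.seed
                )
                kinase_gsea.results_table(enrichment).to_csv(
                    outdir / "kinase_enrichment.tsv", sep="\t", index=False
                )
            _stage(
                "kinase_gsea",
                n_species_rows=kin_report.n_kept,
                n_sets_scored=len(sets),
                n_sets_dropped=len(dropped),
            )
        else:
            manifest["skipped"].append("kinase_gsea")

        # ---------------- stage 6: functional context ---------------------
        if annotations_path is not None and edges_path is not None:
            annotations = read_annotations(annotations_path)
            edges, _ = read_edges(edges_path)
            sig_proteins = sorted(
                {g for g, _ in set_high | set_low} & annotations.background
            )
            if sig_proteins:
                functional_context.enrichment_table(
                    functional_context.term_enrichment(sig_proteins, annotations)
                ).to_csv(outdir / "term_enrichment_significant.tsv", sep="\t", index=False)
            for label in (
                serum_response.PERSISTENT_IN_DEFICIENT,
                serum_response.LOST_IN_DEFICIENT,
            ):
                proteins = protein_sets.get(label, set())
                if not proteins:
                    continue
                subnet = functional_context.high_confidence_subnetwork(
                    proteins, edges, threshold=config.network_threshold
                )
                pd.DataFrame(
                    [
                        {"a": e.protein_a, "b": e.protein_b, "score": e.score}
                        for e in subnet.edges
                    ],
                    columns=["a", "b", "score"],
                ).to_csv(outdir / f"subnetwork_{label}.tsv", sep="\t", index=False)
                comp_rows = []
                for comp, terms in functional_context.component_enrichment(
                    subnet, annotations
                ).items():
                    for t in terms:
                        comp_rows.append(
                            {"component": ";".join(comp), "term": t.term, "k": t.k,
                             "K": t.K, "p": t.p, "q": t.q}
                        )
                pd.DataFrame(
                    comp_rows, columns=["component", "term", "k", "K", "p", "q"]
                ).to_csv(outdir / f"component_enrichment_{label}.tsv", sep="\t", index=False)
                _stage(
                    "functional_context",
                    label=label,
                    n_proteins=len(proteins),
                    n_edges=len(subnet.edges),
                )
        else:
            manifest["skipped"].append("functional_context")

        # ---------------- stage 7: counts report --------------------------
        counts = summarize_counts(high, low, venn, class_table)
        if enrichment is not None:
            counts["top_kinase"] = enrichment[0].kinase
            counts["top_kinase_nes"] = float(enrichment[0].nes)
            counts["top_kinase_fdr"] = float(enrichment[0].fdr)
        manifest["counts"] = counts
        with open(outdir / "counts_report.json", "wt", encoding="utf-8") as fh:
            json.dump(counts, fh, indent=1, sort_keys=True)
        manifest["complete"] = True
        _write_manifest(outdir, manifest)
        return manifest
    except PhosphosigError as exc:
        _fail(manifest["stages"][-1]["stage"] if manifest["stages"] else "init", exc)
        raise


def _write_manifest(outdir: Path, manifest: Dict[str, Any]) -> None:
    with open(outdir / "manifest.json", "wt", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
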