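"""Domain model and readers/writers for phosphoproteomic analysis tables.

The analysis unit throughout is the *phosphosite*: a specific phosphorylated
serine, threonine or tyrosine on a protein, written in the field's usual
letter+position notation ("Y1197", "T695").  Quantification comes from two
triple-SILAC labeling sets (light / medium / heavy channels), tied together
by an *anchor*: one biological condition measured in both sets, which allows
log-ratios to be chained across sets.

All on-disk formats are plain TSV (UTF-8, '.' decimal):

* site table       -- one row per phosphosite, per-channel intensities,
                      modeled on a search engine's site-level output;
* kinase-substrate -- flat kinase / substrate-gene / residue / species rows;
* annotations      -- GMT (term, description, member proteins);
* edges            -- scored undirected protein-protein interactions.
"""

from __future__ import annotations

import math
import re
import warnings
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Mapping, Optional, Sequence, Tuple

import pandas as pd

from .errors import ConfigurationError, FormatError

__all__ = [
    "CHANNELS",
    "SETS",
    "SITE_COLUMNS",
    "PhosphoSiteRecord",
    "ExperimentDesign",
    "KinaseTargetRecord",
    "NetworkEdge",
    "AnnotationMap",
    "LoadReport",
    "parse_residue",
    "format_residue",
    "site_key",
    "read_site_table",
    "write_site_table",
    "read_kinase_substrates",
    "write_kinase_substrates",
    "read_edges",
    "write_edges",
    "read_annotations",
    "write_annotations",
]

SETS: Tuple[int, ...] = (1, 2)
CHANNELS: Tuple[str, ...] = ("light", "medium", "heavy")

#: canonical column order of the site-table TSV
SITE_COLUMNS: Tuple[str, ...] = (
    "site_id",
    "protein_id",
    "gene",
    "residue",
    "localization_prob",
    "int_set1_light",
    "int_set1_medium",
    "int_set1_heavy",
    "int_set2_light",
    "int_set2_medium",
    "int_set2_heavy",
)

_RESIDUE_RE = re.compile(r"^([STY])([1-9][0-9]*)$")


def parse_residue(residue: str) -> Tuple[str, int]:
    """Parse "T695" into ``("T", 695)``.

    Only S/T/Y residues with 1-based positive positions are valid; anything
    else raises :class:`FormatError`.
    """
    m = _RESIDUE_RE.match(residue.strip()) if isinstance(residue, str) else None
    if m is None:
        raise FormatError(f"malformed residue string: {residue!r}")
    return m.group(1), int(m.group(2))


def format_residue(letter: str, position: int) -> str:
    """Inverse of :func:`parse_residue`."""
    if letter not in "STY" or position < 1:
        raise FormatError(f"invalid residue ({letter!r}, {position})")
    return f"{letter}{position}"


def site_key(gene: str, residue: str) -> Tuple[str, str]:
    """Cross-table join key: (uppercased gene symbol, residue string)."""
    return gene.upper(), residue


@dataclass
class LoadReport:
    """Accounting of a table load: rows kept, rows dropped, warnings."""

    n_kept: int = 0
    n_dropped: int = 0
    warnings: List[str] = field(default_factory=list)

    def warn(self, message: str) -> None:
        self.warnings.append(message)
        warnings.warn(message, stacklevel=3)


@dataclass
class PhosphoSiteRecord:
    """One quantified phosphosite with per-channel intensities.

    ``intensities`` maps ``(set, channel)`` -> intensity; absent entries mean
    the channel was not quantified for this site.  Zero intensities are never
    stored -- they are treated as missing at load time because a zero would
    corrupt every log-ratio downstream.
    """

    site_id: str
    protein_id: str
    gene: str
    residue: str
    intensities: Dict[Tuple[int, str], float]
    localization_prob: Optional[float] = None

    def __post_init__(self) -> None:
        parse_residue(self.residue)  # raises on malformed residue
        if not self.intensities:
            raise FormatError(f"site {self.site_id!r}: no intensity present")
        for (s, ch), v in self.intensities.items():
            if s not in SETS or ch not in CHANNELS:
                raise FormatError(f"site {self.site_id!r}: unknown channel ({s}, {ch})")
            if not math.isfinite(v) or v <= 0:
                raise FormatError(
                    f"site {self.site_id!r}: non-positive intensity {v} in ({s}, {ch})"
                )
        if self.localization_prob is not None and not (0.0 <= self.localization_prob <= 1.0):
            raise FormatError(
                f"site {self.site_id!r}: localization_prob {self.localization_prob} not in [0,1]"
            )

    @property
    def key(self) -> Tuple[str, str]:
        return site_key(self.gene, self.residue)

    def intensity(self, set_index: int, channel: str) -> Optional[float]:
        return self.intensities.get((set_index, channel))


@dataclass
class ExperimentDesign:
    """Links SILAC channels to biological conditions.

    ``conditions`` assigns a condition label to each quantified
    ``(set, channel)`` pair.  The ``anchor`` condition must be measured in
    both sets; it is the bridge for cross-set ("chained") comparisons.
    ``comparisons`` are ordered condition pairs; the first condition is the
    ratio numerator, so positive log2 ratios mean "higher in the first
    condition".
    """

    conditions: Dict[Tuple[int, str], str]
    anchor: str
    comparisons: Dict[str, Tuple[str, str]]

    def __post_init__(self) -> None:
        sets_with_anchor = {s for (s, _), cond in self.conditions.items() if cond == self.anchor}
        if not set(SETS) <= sets_with_anchor:
            raise ConfigurationError(
                f"anchor condition {self.anchor!r} must be assigned in both sets "
                f"(found in sets {sorted(sets_with_anchor)})"
            )
        for name, (a, b) in self.comparisons.items():
            for cond in (a, b):
                if cond not in self.conditions.values():
                    raise ConfigurationError(
                        f"comparison {name!r}: condition {cond!r} not assigned to any channel"
                    )

    def channels_for(self, condition: str) -> List[Tuple[int, str]]:
        return sorted(sc for sc, cond in self.conditions.items() if cond == condition)

    def anchor_channel(self, set_index: int) -> Tuple[int, str]:
        for (s, ch), cond in sorted(self.conditions.items()):
            if s == set_index and cond == self.anchor:
                return (s, ch)
        raise ConfigurationError(f"anchor {self.anchor!r} not in set {set_index}")

    def comparison_plan(self, name: str):
        """Resolve a named comparison to channel arithmetic.

        Returns ``("direct", (s, ch_first), (s, ch_second))`` when both
        conditions share a set (the lowest-numbered shared set is used), or
        ``("chained", (first, anchor_1), (second, anchor_2))`` where each
        element is a (set, channel) pair and the comparison is
        ``log2(first/anchor_1) - log2(second/anchor_2)``.
        """
        if name not in self.comparisons:
            raise ConfigurationError(f"comparison {name!r} not defined in design")
        cond_a, cond_b = self.comparisons[name]
        chans_a = self.channels_for(cond_a)
        chans_b = self.channels_for(cond_b)
        for s in SETS:
            in_a = [c for c in chans_a if c[0] == s]
            in_b = [c for c in chans_b if c[0] == s]
            if in_a and in_b:
                return ("direct", in_a[0], in_b[0])
        ca, cb = chans_a[0], chans_b[0]
        return (
            "chained",
            (ca, self.anchor_channel(ca[0])),
            (cb, self.anchor_channel(cb[0])),
        )


@dataclass(frozen=True)
class KinaseTargetRecord:
    """One kinase -> substrate-residue relationship."""

    kinase: str
    substrate_gene: str
    substrate_residue: str
    species_kinase: str
    species_substrate: str

    def __post_init__(self) -> None:
        parse_residue(self.substrate_residue)
        if not self.species_kinase or not self.species_substrate:
            raise FormatError("species labels must be non-empty")

    @property
    def substrate_key(self) -> Tuple[str, str]:
        return site_key(self.substrate_gene, self.substrate_residue)


@dataclass(frozen=True)
class NetworkEdge:
    """Undirected scored interaction; endpoints stored in canonical order."""

    protein_a: str
    protein_b: str
    score: float

    def __post_init__(self) -> None:
        if self.protein_a == self.protein_b:
            raise FormatError(f"self-edge on {self.protein_a!r}")
        if not (0.0 <= self.score <= 1.0):
            raise FormatError(f"edge score {self.score} outside [0, 1]")
        if self.protein_a > self.protein_b:
            a, b = self.protein_b, self.protein_a
            object.__setattr__(self, "protein_a", a)
            object.__setattr__(self, "protein_b", b)

    @property
    def key(self) -> Tuple[str, str]:
        return (self.protein_a, self.protein_b)


@dataclass
class AnnotationMap:
    """Term -> protein-set annotations over an explicit background."""

    terms: Dict[str, FrozenSet[str]]
    background: FrozenSet[str]

    def __post_init__(self) -> None:
        self.terms = {t: frozenset(m) for t, m in self.terms.items()}
        self.background = frozenset(self.background)
        for term, members in self.terms.items():
            if not members:
                raise FormatError(f"term {term!r} has no members")
            stray = members - self.background
            if stray:
                raise FormatError(
                    f"term {term!r}: members outside background: {sorted(stray)[:5]}"
                )


# ---------------------------------------------------------------------------
# site table I/O
# ---------------------------------------------------------------------------

#: default dialect maps canonical names onto themselves; alternative layouts
#: (e.g. versioned upstream column names) supply their own mapping
DEFAULT_DIALECT: Dict[str, str] = {c: c for c in SITE_COLUMNS}

_MANDATORY = ("site_id", "protein_id", "gene", "residue")
_INTENSITY_KEYS = [(s, ch) for s in SETS for ch in CHANNELS]


def _intensity_column(set_index: int, channel: str) -> str:
    return f"int_set{set_index}_{channel}"


def read_site_table(
    path,
    dialect: Optional[Mapping[str, str]] = None,
    min_localization: Optional[float] = None,
) -> Tuple[List[PhosphoSiteRecord], LoadReport]:
    """Read a phosphosite quantification TSV.

    ``dialect`` maps canonical column names to the file's actual column
    names.  Rows with malformed residues, no usable intensity, or (when
    ``min_localization`` is set) a localization probability below the cutoff
    are dropped and counted in the returned :class:`LoadReport`.  Zero or
    negative intensities are treated as missing.
    """
    dialect = dict(DEFAULT_DIALECT, **(dialect or {}))
    report = LoadReport()
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError:
        report.warn(f"{path}: empty site table")
        return [], report
    if df.empty:
        report.warn(f"{path}: site table has a header but no rows")
    for canon in _MANDATORY:
        if dialect[canon] not in df.columns:
            raise FormatError(f"{path}: missing mandatory column {dialect[canon]!r}")

    records: List[PhosphoSiteRecord] = []
    seen_ids = set()
    for _, row in df.iterrows():
        sid = row[dialect["site_id"]]
        try:
            if sid in seen_ids:
                raise FormatError(f"duplicate site_id {sid!r}")
            intensities: Dict[Tuple[int, str], float] = {}
            for s, ch in _INTENSITY_KEYS:
                col = dialect.get(_intensity_column(s, ch), _intensity_column(s, ch))
                if col not in df.columns:
                    continue
                raw = row[col]
                if pd.isna(raw) or raw == "":
                    continue
                v = float(raw)
                if v > 0 and math.isfinite(v):
                    intensities[(s, ch)] = v
            loc_col = dialect.get("localization_prob", "localization_prob")
            loc = None
            if loc_col in df.columns and not pd.isna(row[loc_col]) and row[loc_col] != "":
                loc = float(row[loc_col])
            if min_localization is not None and (loc is None or loc < min_localization):
                raise FormatError(f"site {sid!r}: localization below {min_localization}")
            rec = PhosphoSiteRecord(
                site_id=str(sid),
                protein_id=str(row[dialect["protein_id"]]),
                gene=str(row[dialect["gene"]]),
                residue=str(row[dialect["residue"]]).strip(),
                intensities=intensities,
                localization_prob=loc,
            )
        except (FormatError, ValueError) as exc:
            report.n_dropped += 1
            report.warnings.append(f"row dropped: {exc}")
            continue
        seen_ids.add(sid)
        records.append(rec)
        report.n_kept += 1
    return records, report


def write_site_table(records: Sequence[PhosphoSiteRecord], path) -> None:
    """Write records to TSV in canonical column order (lossless round-trip)."""
    rows = []
    for rec in records:
        row: Dict[str, object] = {
            "site_id": rec.site_id,
            "protein_id": rec.protein_id,
            "gene": rec.gene,
            "residue": rec.residue,
            "localization_prob": "" if rec.localization_prob is None else repr(rec.localization_prob),
        }
        for s, ch in _INTENSITY_KEYS:
            v = rec.intensities.get((s, ch))
            row[_intensity_column(s, ch)] = "" if v is None else repr(v)
        rows.append(row)
    df = pd.DataFrame(rows, columns=list(SITE_COLUMNS))
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# kinase-substrate table I/O
# ---------------------------------------------------------------------------

KINASE_COLUMNS = ("kinase", "species_kinase", "substrate_gene", "species_substrate", "residue")


def read_kinase_substrates(path, species: str) -> Tuple[List[KinaseTargetRecord], LoadReport]:
    """Read a kinase-substrate flat table, keeping one species only.

    A record survives only if *both* the kinase and the substrate species
    match ``species`` (case-insensitive) -- i.e. sites phosphorylated by a
    kinase of that species in cells of that species.  Rows with malformed
    residue strings are dropped with a warning.
    """
    report = LoadReport()
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError:
        report.warn(f"{path}: empty kinase-substrate table")
        return [], report
    for col in KINASE_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"{path}: missing mandatory column {col!r}")
    records: List[KinaseTargetRecord] = []
    want = species.lower()
    for _, row in df.iterrows():
        if str(row["species_kinase"]).lower() != want or str(row["species_substrate"]).lower() != want:
            report.n_dropped += 1
            continue
        try:
            rec = KinaseTargetRecord(
                kinase=str(row["kinase"]),
                substrate_gene=str(row["substrate_gene"]),
                substrate_residue=str(row["residue"]).strip(),
                species_kinase=str(row["species_kinase"]),
                species_substrate=str(row["species_substrate"]),
            )
        except FormatError as exc:
            report.n_dropped += 1
            report.warn(f"row dropped: {exc}")
            continue
        records.append(rec)
        report.n_kept += 1
    return records, report


def write_kinase_substrates(records: Sequence[KinaseTargetRecord], path) -> None:
    df = pd.DataFrame(
        [
            {
                "kinase": r.kinase,
                "species_kinase": r.species_kinase,
                "substrate_gene": r.substrate_gene,
                "species_substrate": r.species_substrate,
                "residue": r.substrate_residue,
            }
            for r in records
        ],
        columns=list(KINASE_COLUMNS),
    )
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# edge list and annotation I/O
# ---------------------------------------------------------------------------


def read_edges(path) -> Tuple[List[NetworkEdge], LoadReport]:
    """Read a scored edge TSV; collapse duplicate undirected edges (max score).

    Self-edges are dropped with a warning; a score outside [0, 1] is a format
    error.
    """
    report = LoadReport()
    df = pd.read_csv(path, sep="\t", dtype={"a": str, "b": str, "score": float})
    for col in ("a", "b", "score"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing mandatory column {col!r}")
    best: Dict[Tuple[str, str], float] = {}
    for _, row in df.iterrows():
        score = float(row["score"])
        if not (0.0 <= score <= 1.0):
            raise FormatError(f"{path}: edge score {score} outside [0, 1]")
        a, b = str(row["a"]), str(row["b"])
        if a == b:
            report.n_dropped += 1
            report.warn(f"self-edge on {a!r} dropped")
            continue
        key = (a, b) if a < b else (b, a)
        if key not in best or score > best[key]:
            best[key] = score
    edges = [NetworkEdge(a, b, s) for (a, b), s in sorted(best.items())]
    report.n_kept = len(edges)
    return edges, report


def write_edges(edges: Sequence[NetworkEdge], path) -> None:
    df = pd.DataFrame(
        [{"a": e.protein_a, "b": e.protein_b, "score": repr(e.score)} for e in edges],
        columns=["a", "b", "score"],
    )
    df.to_csv(path, sep="\t", index=False)


def read_annotations(path, background: Optional[Iterable[str]] = None) -> AnnotationMap:
    """Read a GMT file (term <tab> description <tab> member...).

    ``background`` defaults to the union of all members.
    """
    terms: Dict[str, FrozenSet[str]] = {}
    with open(path, "rt", encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}: GMT line with fewer than 3 fields: {line[:60]!r}")
            term, _desc, *members = parts
            members = [m for m in members if m]
            if not members:
                raise FormatError(f"{path}: term {term!r} has no members")
            terms[term] = frozenset(members)
    if background is None:
        background = frozenset().union(*terms.values()) if terms else frozenset()
    return AnnotationMap(terms=terms, background=frozenset(background))


def write_annotations(annotations: AnnotationMap, path) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        for term in sorted(annotations.terms):
            members = "\t".join(sorted(annotations.terms[term]))
            fh.write(f"{term}\tna\t{members}\n")
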