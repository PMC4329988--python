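"""Readers and writers for protein-group tables, experiment designs and FASTA proteomes.

This module is deliberately free of any scoring logic: it turns external
files into validated in-memory records and back.  Protein-group tables are
expected in a MaxQuant-``proteinGroups``-like dialect (tab-separated, one row
per protein group, with a normalized H/L ratio and per-channel intensities);
the exact column names are declared in a :class:`TableDialect` so other
vendors' headers can be mapped without code changes.
"""

from __future__ import annotations

import math
import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO

__all__ = [
    "TableDialect",
    "MAXQUANT_13",
    "ProteinGroupRecord",
    "DesignEntry",
    "StudyDesign",
    "ProteomeRecord",
    "TableFormatError",
    "RecordParseError",
    "DesignError",
    "read_protein_groups",
    "write_protein_groups",
    "read_design",
    "write_design",
    "read_fasta",
    "write_verdicts",
    "read_verdicts",
    "write_beadome",
    "read_beadome",
]

CANONICAL_AA = frozenset("ACDEFGHIKLMNPQRSTVWY")
ORIENTATIONS = ("tagged_heavy", "tagged_light")

#: Cell contents treated as "unquantified" rather than parse errors.
_NA_TOKENS = frozenset({"", "nan", "na", "n/a", "none", "null"})


class TableFormatError(ValueError):
    """A table is structurally unusable (missing column, duplicate keys)."""


class RecordParseError(ValueError):
    """A single cell could not be parsed; the message cites the file row."""


class DesignError(ValueError):
    """The experiment-design table violates its invariants."""


# ---------------------------------------------------------------------------
# dialects
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TableDialect:
    """Column-name mapping for a protein-group table.

    The defaults follow MaxQuant 1.3 ``proteinGroups.txt`` conventions.  A
    table may be *long* (one row per group x experiment, with an explicit
    experiment column) or *wide* (per-experiment columns suffixed with the
    experiment name, e.g. ``"Ratio H/L normalized F1"``); both are accepted
    and melted to long form on reading.

    ``ratio`` may be pointed at the raw ``"Ratio H/L"`` column instead of the
    normalized one when the normalization step is to be bypassed.
    """

    group_id: str = "Protein IDs"
    gene_id: str | None = "Gene names"
    peptides: str = "Unique + razor peptides"
    ratio: str = "Ratio H/L normalized"
    intensity_h: str = "Intensity H"
    intensity_l: str = "Intensity L"
    experiment: str = "Experiment"
    sep: str = "\t"


MAXQUANT_13 = TableDialect()


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class ProteinGroupRecord:
    """One quantified protein group in one experiment.

    ``ratio_hl`` is ``None`` when the group was identified but not
    quantified (blank cell, or a 0/inf ratio encoding single-channel
    detection); such records are candidates for exclusive-detection handling
    downstream.
    """

    group_id: str
    accessions: tuple[str, ...]
    unique_razor_peptides: int
    experiment_id: str
    ratio_hl: float | None = None
    intensity_h: float = 0.0
    intensity_l: float = 0.0
    gene_id: str | None = None

    def __post_init__(self) -> None:
        if not self.accessions:
            raise ValueError(f"protein group {self.group_id!r} has no accessions")
        if self.unique_razor_peptides < 0:
            raise ValueError(
                f"group {self.group_id!r}: negative peptide count "
                f"{self.unique_razor_peptides}"
            )
        if self.ratio_hl is not None and not (
            self.ratio_hl > 0 and math.isfinite(self.ratio_hl)
        ):
            raise ValueError(
                f"group {self.group_id!r}: ratio_hl must be finite and > 0, "
                f"got {self.ratio_hl!r}"
            )
        if self.intensity_h < 0 or self.intensity_l < 0:
            raise ValueError(f"group {self.group_id!r}: negative intensity")

    @property
    def representative(self) -> str:
        """First accession of the group (the representative protein)."""
        return self.accessions[0]


@dataclass(frozen=True)
class DesignEntry:
    """One experiment: resin, labelling orientation, replicate and bait."""

    experiment_id: str
    resin: str
    orientation: str
    replicate: int
    bait_accession: str
    is_control_only: bool = False

    def __post_init__(self) -> None:
        if self.orientation not in ORIENTATIONS:
            raise DesignError(
                f"experiment {self.experiment_id!r}: unknown orientation "
                f"{self.orientation!r}; allowed: {', '.join(ORIENTATIONS)}"
            )
        if self.replicate < 1:
            raise DesignError(
                f"experiment {self.experiment_id!r}: replicate must be >= 1"
            )


class StudyDesign:
    """Validated collection of :class:`DesignEntry`, indexed by experiment id.

    Reciprocal pairs are matched per resin and replicate index: replicate
    *j* with the tagged cells heavy pairs with replicate *j* with the tagged
    cells light.
    """

    def __init__(self, entries: Iterable[DesignEntry], *, warn_no_reciprocal: bool = True):
        entries = list(entries)
        seen: set[str] = set()
        for e in entries:
            if e.experiment_id in seen:
                raise DesignError(f"duplicate experiment_id {e.experiment_id!r}")
            seen.add(e.experiment_id)
        self._entries = entries
        self._by_id = {e.experiment_id: e for e in entries}
        if warn_no_reciprocal and self.analysis_entries and not self.reciprocal_pairs:
            warnings.warn(
                "design contains no reciprocal labelling pairs; "
                "orientation-reproducibility ranks will be limited",
                stacklevel=2,
            )

    def __iter__(self):
        return iter(self._entries)

    def __len__(self) -> int:
        return len(self._entries)

    def __getitem__(self, experiment_id: str) -> DesignEntry:
        try:
            return self._by_id[experiment_id]
        except KeyError:
            raise KeyError(f"experiment {experiment_id!r} not in design") from None

    def __contains__(self, experiment_id: str) -> bool:
        return experiment_id in self._by_id

    @property
    def entries(self) -> list[DesignEntry]:
        return list(self._entries)

    @property
    def analysis_entries(self) -> list[DesignEntry]:
        """Entries that are SILAC mixes (not control-only pull-downs)."""
        return [e for e in self._entries if not e.is_control_only]

    @property
    def resins(self) -> tuple[str, ...]:
        out: list[str] = []
        for e in self.analysis_entries:
            if e.resin not in out:
                out.append(e.resin)
        return tuple(out)

    def experiments_for(self, resin: str) -> list[DesignEntry]:
        return [e for e in self.analysis_entries if e.resin == resin]

    @property
    def reciprocal_pairs(self) -> dict[str, list[tuple[str, str]]]:
        """Per resin, (tagged_heavy, tagged_light) experiment-id pairs."""
        pairs: dict[str, list[tuple[str, str]]] = {}
        for resin in self.resins:
            heavy = {e.replicate: e for e in self.experiments_for(resin)
                     if e.orientation == "tagged_heavy"}
            light = {e.replicate: e for e in self.experiments_for(resin)
                     if e.orientation == "tagged_light"}
            matched = [
                (heavy[r].experiment_id, light[r].experiment_id)
                for r in sorted(set(heavy) & set(light))
            ]
            if matched:
                pairs[resin] = matched
        return pairs

    @property
    def bait_accessions(self) -> frozenset[str]:
        return frozenset(e.bait_accession for e in self.analysis_entries
                         if e.bait_accession)


@dataclass
class ProteomeRecord:
    """One FASTA entry: accession, free-text description, residue string."""

    accession: str
    description: str
    sequence: str
    nonstandard: bool = False

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"proteome record {self.accession!r} has empty sequence")


# ---------------------------------------------------------------------------
# protein-group tables
# ---------------------------------------------------------------------------

def _open_table(path: str | Path, sep: str) -> pd.DataFrame:
    # keep everything as strings so that cell-level errors can cite rows
    return pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False,
                       compression="infer")


def _parse_ratio(cell: str, row: int, column: str) -> float | None:
    text = cell.strip()
    if text.lower() in _NA_TOKENS:
        return None
    try:
        value = float(text)
    except ValueError:
        raise RecordParseError(
            f"column {column!r}, file row {row}: cannot parse ratio {cell!r}"
        ) from None
    if value == 0 or math.isinf(value):
        warnings.warn(
            f"column {column!r}, file row {row}: ratio {value} encodes "
            "single-channel detection; treated as unquantified",
            stacklevel=3,
        )
        return None
    if math.isnan(value):
        return None
    if value < 0:
        raise RecordParseError(
            f"column {column!r}, file row {row}: negative ratio {value}"
        )
    return value


def _parse_float(cell: str, row: int, column: str, default: float = 0.0) -> float:
    text = cell.strip()
    if text.lower() in _NA_TOKENS:
        return default
    try:
        return float(text)
    except ValueError:
        raise RecordParseError(
            f"column {column!r}, file row {row}: cannot parse number {cell!r}"
        ) from None


def _parse_int(cell: str, row: int, column: str) -> int:
    return int(round(_parse_float(cell, row, column)))


def read_protein_groups(
    path: str | Path,
    dialect: TableDialect = MAXQUANT_13,
    *,
    collapse_genes: bool = False,
) -> list[ProteinGroupRecord]:
    """Read a protein-group table into long-form records.

    Long tables (explicit experiment column) and wide tables (per-experiment
    column suffixes such as ``"Ratio H/L normalized F1"``) are both accepted;
    wide tables are melted so that each record carries one experiment id.
    Blank or NaN ratio cells become absent ratios.  With
    ``collapse_genes=True``, groups sharing a gene id are collapsed to the
    member with the most unique+razor peptides (useful against redundant
    proteome databases where one protein is represented by many accessions).
    """
    df = _open_table(path, dialect.sep)
    if dialect.group_id not in df.columns:
        raise TableFormatError(f"missing mandatory column {dialect.group_id!r}")

    wide_suffixes = sorted(
        c[len(dialect.ratio) + 1:]
        for c in df.columns
        if c.startswith(dialect.ratio + " ")
    )
    long_form = dialect.ratio in df.columns

    if not long_form and not wide_suffixes:
        raise TableFormatError(
            f"missing mandatory column {dialect.ratio!r} "
            f"(or per-experiment variants {dialect.ratio + ' <exp>'!r})"
        )

    def percol(base: str, exp: str | None, mandatory: bool) -> str | None:
        if exp is not None and f"{base} {exp}" in df.columns:
            return f"{base} {exp}"
        if base in df.columns:
            return base
        if mandatory:
            raise TableFormatError(f"missing mandatory column {base!r}")
        return None

    records: list[ProteinGroupRecord] = []
    seen: set[tuple[str, str]] = set()

    if long_form:
        if dialect.experiment not in df.columns:
            raise TableFormatError(
                f"missing mandatory column {dialect.experiment!r} "
                "(long-form table needs an experiment column)"
            )
        experiments: list[str | None] = [None]
    else:
        experiments = list(wide_suffixes)

    pep_cols = {e: percol(dialect.peptides, e, True) for e in experiments}
    ih_cols = {e: percol(dialect.intensity_h, e, True) for e in experiments}
    il_cols = {e: percol(dialect.intensity_l, e, True) for e in experiments}
    ratio_cols = {
        e: (dialect.ratio if e is None else f"{dialect.ratio} {e}")
        for e in experiments
    }
    gene_col = dialect.gene_id if dialect.gene_id in df.columns else None

    for i, row in enumerate(df.itertuples(index=False)):
        row_map = dict(zip(df.columns, row))
        file_row = i + 2  # 1-based, after the header
        for exp in experiments:
            exp_id = row_map[dialect.experiment].strip() if exp is None else exp
            ratio = _parse_ratio(row_map[ratio_cols[exp]], file_row, ratio_cols[exp])
            rec = ProteinGroupRecord(
                group_id=row_map[dialect.group_id].strip(),
                accessions=tuple(
                    a.strip() for a in row_map[dialect.group_id].split(";") if a.strip()
                ),
                unique_razor_peptides=_parse_int(
                    row_map[pep_cols[exp]], file_row, pep_cols[exp]
                ),
                experiment_id=exp_id,
                ratio_hl=ratio,
                intensity_h=_parse_float(row_map[ih_cols[exp]], file_row, ih_cols[exp]),
                intensity_l=_parse_float(row_map[il_cols[exp]], file_row, il_cols[exp]),
                gene_id=(row_map[gene_col].strip() or None) if gene_col else None,
            )
            key = (rec.group_id, rec.experiment_id)
            if key in seen:
                raise TableFormatError(
                    f"duplicate (group_id, experiment_id) = {key!r} at file row {file_row}"
                )
            seen.add(key)
            records.append(rec)

    if collapse_genes:
        records = _collapse_by_gene(records)
    return records


def _collapse_by_gene(records: list[ProteinGroupRecord]) -> list[ProteinGroupRecord]:
    """Keep, per (gene, experiment), the group with most peptide evidence."""
    best: dict[tuple[str, str], ProteinGroupRecord] = {}
    order: list[tuple[str, str]] = []
    for rec in records:
        key = (rec.gene_id or rec.group_id, rec.experiment_id)
        if key not in best:
            best[key] = rec
            order.append(key)
        elif rec.unique_razor_peptides > best[key].unique_razor_peptides:
            best[key] = rec
    return [best[k] for k in order]


def write_protein_groups(
    records: Iterable[ProteinGroupRecord],
    path: str | Path,
    dialect: TableDialect = MAXQUANT_13,
) -> None:
    """Write records as a long-form table in the given dialect."""
    rows = []
    for r in records:
        rows.append(
            {
                dialect.group_id: ";".join(r.accessions),
                dialect.gene_id or "Gene names": r.gene_id or "",
                dialect.peptides: r.unique_razor_peptides,
                dialect.ratio: "" if r.ratio_hl is None else repr(r.ratio_hl),
                dialect.intensity_h: repr(r.intensity_h),
                dialect.intensity_l: repr(r.intensity_l),
                dialect.experiment: r.experiment_id,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep=dialect.sep, index=False)


# ---------------------------------------------------------------------------
# experiment design
# ---------------------------------------------------------------------------

_DESIGN_COLUMNS = ("experiment_id", "resin", "orientation", "replicate",
                   "bait_accession")
_TRUE_TOKENS = frozenset({"1", "true", "yes", "y"})


def read_design(path: str | Path) -> StudyDesign:
    """Read a tab- or comma-separated experiment-design table."""
    with open(path, "rb") as fh:
        first = fh.readline().decode("utf-8", errors="replace")
    sep = "\t" if "\t" in first else ","
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    for col in _DESIGN_COLUMNS:
        if col not in df.columns:
            raise DesignError(f"design table missing column {col!r}")
    entries = []
    for _, row in df.iterrows():
        entries.append(
            DesignEntry(
                experiment_id=row["experiment_id"].strip(),
                resin=row["resin"].strip(),
                orientation=row["orientation"].strip(),
                replicate=int(row["replicate"]),
                bait_accession=row["bait_accession"].strip(),
                is_control_only=(
                    row.get("is_control_only", "").strip().lower() in _TRUE_TOKENS
                ),
            )
        )
    return StudyDesign(entries)


def write_design(design: StudyDesign, path: str | Path) -> None:
    rows = [
        {
            "experiment_id": e.experiment_id,
            "resin": e.resin,
            "orientation": e.orientation,
            "replicate": e.replicate,
            "bait_accession": e.bait_accession,
            "is_control_only": int(e.is_control_only),
        }
        for e in design
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def _unwrap_accession(header_token: str) -> str:
    """Extract the accession from a UniProt-style ``db|ACC|NAME`` token."""
    parts = header_token.split("|")
    if len(parts) >= 3 and parts[0] in {"sp", "tr", "gi", "ref"}:
        return parts[1]
    return header_token


def read_fasta(path: str | Path) -> list[ProteomeRecord]:
    """Read a FASTA proteome; records with non-canonical residues are flagged
    (not dropped), empty sequences are an error."""
    records: list[ProteomeRecord] = []
    path = Path(path)
    if path.suffix == ".gz":
        import gzip

        handle = gzip.open(path, "rt")
    else:
        handle = open(path)
    with handle:
        for seq_record in SeqIO.parse(handle, "fasta"):
            sequence = str(seq_record.seq).upper()
            accession = _unwrap_accession(seq_record.id)
            if not sequence:
                raise ValueError(f"FASTA record {accession!r} has an empty sequence")
            records.append(
                ProteomeRecord(
                    accession=accession,
                    description=seq_record.description,
                    sequence=sequence,
                    nonstandard=not set(sequence) <= CANONICAL_AA,
                )
            )
    if not records:
        raise ValueError(f"FASTA file {path} contains no records")
    return records


# ---------------------------------------------------------------------------
# verdict / beadome reports
# ---------------------------------------------------------------------------

_VERDICT_COLUMNS = ("accession", "verdict", "confidence", "in_beadome",
                    "resin_evidence")


def write_verdicts(verdicts, path: str | Path, *, header_lines: Sequence[str] = ()) -> None:
    """Write interaction verdicts as a deterministic TSV report.

    Rows are ordered by verdict class (bait first), then descending
    confidence, then accession, so that re-runs are byte-identical.
    Per-resin evidence is serialized as JSON in the last column so the file
    round-trips through :func:`read_verdicts`.
    """
    from .ipac_classify import sort_verdicts, evidence_to_jsonable

    rows = []
    for v in sort_verdicts(verdicts):
        rows.append(
            {
                "accession": v.protein,
                "verdict": v.verdict,
                "confidence": v.confidence,
                "in_beadome": int(v.in_beadome),
                "resin_evidence": json.dumps(
                    evidence_to_jsonable(v.per_resin), sort_keys=True
                ),
            }
        )
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        pd.DataFrame(rows, columns=_VERDICT_COLUMNS).to_csv(
            fh, sep="\t", index=False
        )


def read_verdicts(path: str | Path):
    """Read a verdict report written by :func:`write_verdicts`."""
    from .ipac_classify import InteractionVerdict, evidence_from_jsonable

    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False, comment="#")
    out = []
    for _, row in df.iterrows():
        out.append(
            InteractionVerdict(
                protein=row["accession"],
                verdict=row["verdict"],
                confidence=row["confidence"],
                per_resin=evidence_from_jsonable(json.loads(row["resin_evidence"])),
                in_beadome=row["in_beadome"].strip() in _TRUE_TOKENS,
            )
        )
    return out


def write_beadome(entries, path: str | Path, *, header_lines: Sequence[str] = ()) -> None:
    """Write beadome entries (one row per sticky protein) as TSV."""
    rows = [
        {
            "accession": e.accession,
            "resins_observed": ";".join(sorted(e.resins_observed)),
            "n_resins": e.n_resins,
            "in_abundome": int(e.in_abundome),
        }
        for e in sorted(entries, key=lambda e: (-e.n_resins, e.accession))
    ]
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        pd.DataFrame(
            rows, columns=("accession", "resins_observed", "n_resins", "in_abundome")
        ).to_csv(fh, sep="\t", index=False)


def read_beadome(path: str | Path):
    from .beadome import BeadomeEntry

    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False, comment="#")
    out = []
    for _, row in df.iterrows():
        resins = frozenset(r for r in row["resins_observed"].split(";") if r)
        out.append(
            BeadomeEntry(
                accession=row["accession"],
                resins_observed=resins,
                in_abundome=row["in_abundome"].strip() in _TRUE_TOKENS,
            )
        )
    return out
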