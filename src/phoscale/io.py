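"""Readers and writers for every table dialect the pipeline touches.

The upstream search engine (MaxQuant-style output) uses a handful of
conventions that this module pins down explicitly:

* booleans are encoded as ``"+"`` (true) / empty (false);
* multi-accession protein fields are ``";"``-separated, with the first
  (leading razor) accession taken as the record's protein key;
* an intensity of exactly ``0`` means *not quantified* and is converted to
  missing at parse time — no downstream code ever sees a raw zero;
* phosphosite intensity columns are named ``Intensity <sample>___<k>`` for
  multiplicity slot ``k`` in {1, 2, 3}; protein-level columns are named
  ``LFQ intensity <sample>``.

All files are tab-separated UTF-8 with ``.`` as the decimal point.  Pipeline
output tables use ``NA`` for missing values and round-trip losslessly to 12
significant digits.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .errors import DesignMismatchError, FormatError

logger = logging.getLogger(__name__)

TREATMENTS = ("bic", "ttx", "control")
TIMEPOINTS = ("5min", "15min", "24h")
MULTIPLICITY_SLOTS = (1, 2, 3)

#: MaxQuant-dialect mandatory columns of a phosphosite table.
SITE_COLUMNS = (
    "Proteins",
    "Gene names",
    "Position",
    "Amino acid",
    "Localization prob",
    "Reverse",
    "Potential contaminant",
)

#: Mandatory columns of a protein-groups table.
PROTEIN_COLUMNS = (
    "Protein IDs",
    "Gene names",
    "Unique peptides",
    "Reverse",
    "Potential contaminant",
    "Only identified by site",
)

#: PhosphoSitePlus-style kinase-substrate table columns.
KS_COLUMNS = ("GENE", "KIN_ORGANISM", "SUB_GENE", "SUB_ORGANISM", "SUB_MOD_RSD")

_SITE_RE = re.compile(r"^([A-Za-z])(\d+)$")


# ---------------------------------------------------------------------------
# record types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SampleDesign:
    """One LC-MS run: a (treatment, timepoint, biological rep, technical rep)
    cell of the experiment design."""

    sample_id: str
    treatment: str  # bic | ttx | control
    timepoint: str  # 5min | 15min | 24h
    bio_rep: int  # 1..4
    tech_rep: int  # 1..3

    def __post_init__(self) -> None:
        if self.treatment not in TREATMENTS:
            raise FormatError(f"unknown treatment {self.treatment!r}")
        if self.timepoint not in TIMEPOINTS:
            raise FormatError(f"unknown timepoint {self.timepoint!r}")


@dataclass
class SiteRecord:
    """One row of a phosphosite table (pre-expansion)."""

    protein_ids: list[str]
    gene_name: str
    position: int
    residue: str
    localization_prob: float
    reverse_flag: bool
    contaminant_flag: bool
    #: (sample_id, multiplicity slot) -> raw intensity; absent key == missing.
    intensities: dict[tuple[str, int], float]
    source_row: int = -1

    @property
    def protein(self) -> str:
        """Leading (razor) accession used as the record's protein key."""
        return self.protein_ids[0]


@dataclass
class ProteinRecord:
    """One row of a protein-groups table."""

    protein_ids: list[str]
    gene_name: str
    unique_peptides: int
    reverse_flag: bool
    contaminant_flag: bool
    only_by_site_flag: bool
    #: sample_id -> LFQ intensity; absent key == missing.
    lfq_intensities: dict[str, float]
    source_row: int = -1

    @property
    def protein(self) -> str:
        return self.protein_ids[0]


@dataclass(frozen=True)
class KinaseSubstrateRelation:
    """A reported kinase -> substrate-site relationship."""

    kinase_gene: str
    substrate_gene: str
    residue: str
    position: int
    organism: str
    predicted_flag: bool = False

    @property
    def substrate_site(self) -> str:
        return f"{self.residue}{self.position}"


@dataclass(frozen=True)
class GeneSet:
    """A named annotation term with its (case-folded) member gene symbols."""

    term_id: str
    term_name: str
    members: frozenset[str]


@dataclass
class ParseReport:
    """Loss accounting for a single read operation."""

    n_rows: int = 0
    n_parsed: int = 0
    n_skipped: int = 0
    skipped: list[str] = field(default_factory=list)

    def skip(self, reason: str) -> None:
        self.n_skipped += 1
        self.skipped.append(reason)
        logger.warning("row skipped: %s", reason)


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------


def _flag(value: object) -> bool:
    """MaxQuant boolean: '+' is true, anything else (empty/NaN) false."""
    return str(value).strip() == "+"


def _is_missing(value: object) -> bool:
    if value is None:
        return True
    if isinstance(value, float) and math.isnan(value):
        return True
    return str(value).strip() in ("", "NA", "NaN", "nan")


def _intensity(value: object) -> float | None:
    """Parse an intensity cell; 0 and empty both mean not quantified."""
    if _is_missing(value):
        return None
    x = float(value)
    if x == 0.0:
        return None
    if x < 0:
        raise FormatError(f"negative intensity {x!r}")
    return x


def _require_columns(columns: Iterable[str], mandatory: Iterable[str], path: object) -> None:
    have = set(columns)
    for col in mandatory:
        if col not in have:
            raise FormatError(f"{path}: missing mandatory column {col!r}")


def parse_site_string(site: str) -> tuple[str, int]:
    """Parse a residue+position string like ``"T286"`` -> ``("T", 286)``."""
    m = _SITE_RE.match(str(site).strip())
    if not m:
        raise FormatError(f"unparseable site string {site!r}")
    residue, pos = m.group(1).upper(), int(m.group(2))
    if pos < 1:
        raise FormatError(f"non-positive site position in {site!r}")
    return residue, pos


# ---------------------------------------------------------------------------
# design
# ---------------------------------------------------------------------------


def read_design(path: str | Path) -> list[SampleDesign]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    _require_columns(df.columns, ("sample_id", "treatment", "timepoint", "bio_rep", "tech_rep"), path)
    design = [
        SampleDesign(
            sample_id=row["sample_id"],
            treatment=row["treatment"],
            timepoint=row["timepoint"],
            bio_rep=int(row["bio_rep"]),
            tech_rep=int(row["tech_rep"]),
        )
        for _, row in df.iterrows()
    ]
    keys = [(d.treatment, d.timepoint, d.bio_rep, d.tech_rep) for d in design]
    if len(set(keys)) != len(keys):
        raise FormatError(f"{path}: duplicate (treatment, timepoint, bio_rep, tech_rep) entries")
    return design


def write_design(design: list[SampleDesign], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "sample_id": [d.sample_id for d in design],
            "treatment": [d.treatment for d in design],
            "timepoint": [d.timepoint for d in design],
            "bio_rep": [d.bio_rep for d in design],
            "tech_rep": [d.tech_rep for d in design],
        }
    )
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# phosphosite table
# ---------------------------------------------------------------------------


def read_phospho_sites(
    path: str | Path,
    design: list[SampleDesign],
    report: ParseReport | None = None,
) -> list[SiteRecord]:
    """Read a phosphosite table into :class:`SiteRecord` rows (file order).

    Intensity cells of ``0`` are converted to missing.  Every designed sample
    must have at least one ``Intensity <sample>___<k>`` column; slots absent
    from the header are treated as never quantified.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    _require_columns(df.columns, SITE_COLUMNS, path)
    slot_cols: dict[tuple[str, int], str] = {}
    for d in design:
        found = False
        for k in MULTIPLICITY_SLOTS:
            col = f"Intensity {d.sample_id}___{k}"
            if col in df.columns:
                slot_cols[(d.sample_id, k)] = col
                found = True
        if not found:
            raise DesignMismatchError(f"{path}: no intensity columns for designed sample {d.sample_id!r}")

    if report is None:
        report = ParseReport()
    report.n_rows += len(df)
    records: list[SiteRecord] = []
    for i, row in enumerate(df.itertuples(index=False)):
        row_map = dict(zip(df.columns, row))
        try:
            residue = str(row_map["Amino acid"]).strip().upper()
            if residue not in ("S", "T", "Y"):
                raise FormatError(f"residue {residue!r} not in {{S,T,Y}}")
            position = int(float(row_map["Position"]))
            if position < 1:
                raise FormatError(f"position {position} < 1")
            prob = float(row_map["Localization prob"])
            if not 0.0 <= prob <= 1.0:
                raise FormatError(f"localization prob {prob} outside [0,1]")
            intensities: dict[tuple[str, int], float] = {}
            for key, col in slot_cols.items():
                val = _intensity(row_map[col])
                if val is not None:
                    intensities[key] = val
            proteins = str(row_map["Proteins"]).split(";")
            gene = "" if _is_missing(row_map["Gene names"]) else str(row_map["Gene names"]).split(";")[0]
            records.append(
                SiteRecord(
                    protein_ids=[p.strip() for p in proteins if p.strip()],
                    gene_name=gene,
                    position=position,
                    residue=residue,
                    localization_prob=prob,
                    reverse_flag=_flag(row_map["Reverse"]),
                    contaminant_flag=_flag(row_map["Potential contaminant"]),
                    intensities=intensities,
                    source_row=i,
                )
            )
        except (FormatError, ValueError) as exc:
            report.skip(f"{path} row {i}: {exc}")
    report.n_parsed += len(records)
    return records


def write_phospho_sites(records: list[SiteRecord], design: list[SampleDesign], path: str | Path) -> None:
    """Write site records back in the MaxQuant dialect (missing -> 0)."""
    sample_ids = list(dict.fromkeys(d.sample_id for d in design))
    cols: dict[str, list] = {c: [] for c in SITE_COLUMNS}
    intensity_cols = [(sid, k) for sid in sample_ids for k in MULTIPLICITY_SLOTS]
    for c in intensity_cols:
        cols[f"Intensity {c[0]}___{c[1]}"] = []
    for r in records:
        cols["Proteins"].append(";".join(r.protein_ids))
        cols["Gene names"].append(r.gene_name)
        cols["Position"].append(r.position)
        cols["Amino acid"].append(r.residue)
        cols["Localization prob"].append(repr(float(r.localization_prob)))
        cols["Reverse"].append("+" if r.reverse_flag else "")
        cols["Potential contaminant"].append("+" if r.contaminant_flag else "")
        for c in intensity_cols:
            val = r.intensities.get(c)
            cols[f"Intensity {c[0]}___{c[1]}"].append("0" if val is None else repr(float(val)))
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# protein groups
# ---------------------------------------------------------------------------


def read_protein_groups(
    path: str | Path,
    design: list[SampleDesign],
    report: ParseReport | None = None,
) -> list[ProteinRecord]:
    """Read a protein-groups table; flagged rows are retained but marked."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    _require_columns(df.columns, PROTEIN_COLUMNS, path)
    sample_ids = sorted({d.sample_id for d in design})
    for sid in sample_ids:
        if f"LFQ intensity {sid}" not in df.columns:
            raise DesignMismatchError(f"{path}: no LFQ intensity column for designed sample {sid!r}")

    if report is None:
        report = ParseReport()
    report.n_rows += len(df)
    records: list[ProteinRecord] = []
    for i, row in enumerate(df.itertuples(index=False)):
        row_map = dict(zip(df.columns, row))
        try:
            lfq: dict[str, float] = {}
            for sid in sample_ids:
                val = _intensity(row_map[f"LFQ intensity {sid}"])
                if val is not None:
                    lfq[sid] = val
            proteins = str(row_map["Protein IDs"]).split(";")
            gene = "" if _is_missing(row_map["Gene names"]) else str(row_map["Gene names"]).split(";")[0]
            records.append(
                ProteinRecord(
                    protein_ids=[p.strip() for p in proteins if p.strip()],
                    gene_name=gene,
                    unique_peptides=int(float(row_map["Unique peptides"])),
                    reverse_flag=_flag(row_map["Reverse"]),
                    contaminant_flag=_flag(row_map["Potential contaminant"]),
                    only_by_site_flag=_flag(row_map["Only identified by site"]),
                    lfq_intensities=lfq,
                    source_row=i,
                )
            )
        except (FormatError, ValueError) as exc:
            report.skip(f"{path} row {i}: {exc}")
    report.n_parsed += len(records)
    return records


def write_protein_groups(records: list[ProteinRecord], design: list[SampleDesign], path: str | Path) -> None:
    sample_ids = list(dict.fromkeys(d.sample_id for d in design))
    cols: dict[str, list] = {c: [] for c in PROTEIN_COLUMNS}
    for sid in sample_ids:
        cols[f"LFQ intensity {sid}"] = []
    for r in records:
        cols["Protein IDs"].append(";".join(r.protein_ids))
        cols["Gene names"].append(r.gene_name)
        cols["Unique peptides"].append(r.unique_peptides)
        cols["Reverse"].append("+" if r.reverse_flag else "")
        cols["Potential contaminant"].append("+" if r.contaminant_flag else "")
        cols["Only identified by site"].append("+" if r.only_by_site_flag else "")
        for sid in sample_ids:
            val = r.lfq_intensities.get(sid)
            cols[f"LFQ intensity {sid}"].append("0" if val is None else repr(float(val)))
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# kinase-substrate relations
# ---------------------------------------------------------------------------


def read_kinase_substrate_table(
    path: str | Path,
    organism: str,
    exclude_predicted: bool = True,
    report: ParseReport | None = None,
) -> list[KinaseSubstrateRelation]:
    """Read kinase-substrate relations, keeping rows whose kinase AND
    substrate organism match ``organism`` (case-insensitive).

    An optional ``Source`` column marks in-silico predictions (any value
    containing ``networkin``, case-insensitive); predicted rows are excluded
    by default.  Rows with unparseable site strings are skipped and counted.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    _require_columns(df.columns, KS_COLUMNS, path)
    has_source = "Source" in df.columns
    if report is None:
        report = ParseReport()
    report.n_rows += len(df)
    org = organism.strip().casefold()
    relations: list[KinaseSubstrateRelation] = []
    for i, row in enumerate(df.itertuples(index=False)):
        row_map = dict(zip(df.columns, row))
        kin_org = str(row_map["KIN_ORGANISM"]).strip().casefold()
        sub_org = str(row_map["SUB_ORGANISM"]).strip().casefold()
        if kin_org != org or sub_org != org:
            continue
        predicted = has_source and "networkin" in str(row_map["Source"]).casefold()
        if exclude_predicted and predicted:
            continue
        try:
            residue, position = parse_site_string(row_map["SUB_MOD_RSD"])
        except FormatError as exc:
            report.skip(f"{path} row {i}: {exc}")
            continue
        relations.append(
            KinaseSubstrateRelation(
                kinase_gene=str(row_map["GENE"]).strip().casefold(),
                substrate_gene=str(row_map["SUB_GENE"]).strip().casefold(),
                residue=residue,
                position=position,
                organism=org,
                predicted_flag=predicted,
            )
        )
    report.n_parsed += len(relations)
    return relations


def write_kinase_substrate_table(relations: list[KinaseSubstrateRelation], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "GENE": [r.kinase_gene for r in relations],
            "KIN_ORGANISM": [r.organism for r in relations],
            "SUB_GENE": [r.substrate_gene for r in relations],
            "SUB_ORGANISM": [r.organism for r in relations],
            "SUB_MOD_RSD": [r.substrate_site for r in relations],
            "Source": ["NetworKIN" if r.predicted_flag else "PhosphoSitePlus" for r in relations],
        }
    )
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# gene sets (GMT)
# ---------------------------------------------------------------------------


def read_gene_sets(path: str | Path, report: ParseReport | None = None) -> list[GeneSet]:
    """Read GMT gene sets; member symbols are case-folded at load time.
    Terms with no members are rejected with a warning."""
    if report is None:
        report = ParseReport()
    sets: list[GeneSet] = []
    with open(path, encoding="utf-8") as fh:
        for i, line in enumerate(fh):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            report.n_rows += 1
            parts = line.split("\t")
            if len(parts) < 2:
                report.skip(f"{path} line {i}: fewer than 2 fields")
                continue
            members = frozenset(m.strip().casefold() for m in parts[2:] if m.strip())
            if not members:
                report.skip(f"{path} line {i}: gene set {parts[0]!r} has no members")
                continue
            sets.append(GeneSet(term_id=parts[0], term_name=parts[1], members=members))
    report.n_parsed += len(sets)
    return sets


def write_gene_sets(sets: list[GeneSet], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for s in sets:
            fh.write("\t".join([s.term_id, s.term_name, *sorted(s.members)]) + "\n")


# ---------------------------------------------------------------------------
# generic result tables
# ---------------------------------------------------------------------------


def write_table(frame: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    """Write a result table as tab-separated UTF-8: fixed column order as
    given, ``NA`` for missing, floats at 12 significant digits."""
    frame.to_csv(path, sep="\t", index=index, na_rep="NA", float_format="%.12g")


def read_table(path: str | Path, index_col: int | list[int] | None = None) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=["NA"], keep_default_na=True, index_col=index_col)


def sample_ids(design: list[SampleDesign]) -> list[str]:
    return [d.sample_id for d in design]


def design_frame(design: list[SampleDesign]) -> pd.DataFrame:
    """Design as a DataFrame indexed by sample_id (convenience for joins)."""
    return pd.DataFrame(
        {
            "treatment": [d.treatment for d in design],
            "timepoint": [d.timepoint for d in design],
            "bio_rep": [d.bio_rep for d in design],
            "tech_rep": [d.tech_rep for d in design],
        },
        index=pd.Index([d.sample_id for d in design], name="sample_id"),
    )


def default_design(
    treatments: tuple[str, ...] = TREATMENTS,
    timepoints: tuple[str, ...] = TIMEPOINTS,
    n_bio: int = 4,
    n_tech: int = 3,
) -> list[SampleDesign]:
    """The study layout: every treatment x timepoint x 4 bio x 3 tech run."""
    design = []
    for trt in treatments:
        for tp in timepoints:
            for b in range(1, n_bio + 1):
                for t in range(1, n_tech + 1):
                    design.append(
                        SampleDesign(
                            sample_id=f"{trt}_{tp}_b{b}_t{t}",
                            treatment=trt,
                            timepoint=tp,
                            bio_rep=b,
                            tech_rep=t,
                        )
                    )
    return design
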