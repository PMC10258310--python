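"""Clonotype and clinical-table I/O with productive-rearrangement QC.

Reads clonotype tables in AIRR Rearrangement TSV or a MiXCR-export dialect
into :class:`Clonotype` records, applies the productive-clonotype filter
(CDR3aa length >= 4, CDR3nt length a multiple of 3, no stop codon), and
loads clinical metadata with early/advanced TNM-stage grouping.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio.Seq import Seq

logger = logging.getLogger(__name__)

CHAINS = ("TRA", "TRB", "TRG", "TRD", "IGH")
ISOTYPES = ("IgA", "IgG", "IgM")

#: Stop/frameshift markers in amino-acid CDR3 strings.
STOP_CHARS = frozenset("*_")


class ConfigurationError(ValueError):
    """A required column or configuration entry is missing."""


class ValidationError(ValueError):
    """Input rows violate a data invariant."""


@dataclass(frozen=True, slots=True)
class Clonotype:
    """One rearrangement record (a clonotype) with its read weight.

    ``count`` is the duplicate/read count reported by the upstream clonotype
    caller, not a cell count; downstream metrics use it as-is.
    ``v_mismatches`` is the number of nucleotide mismatches of the V-region
    alignment to germline (``None`` when the caller did not report it).
    """

    clone_id: str
    count: int
    cdr3_nt: str
    cdr3_aa: str
    v_call: str
    j_call: str
    d_call: str = ""
    chain: str = ""
    isotype: str | None = None
    v_mismatches: int | None = None

    def __post_init__(self) -> None:
        if self.count < 0:
            raise ValidationError(f"negative count for clone {self.clone_id!r}")


@dataclass(slots=True)
class RepertoireSample:
    """A set of clonotypes for one (patient, tissue, chain) library."""

    patient_id: str
    tissue: str  # "tumor" | "non_tumor"
    chain: str
    clonotypes: list[Clonotype] = field(default_factory=list)
    isotype_view: str | None = None

    @property
    def sample_id(self) -> str:
        parts = [self.patient_id, self.tissue, self.chain]
        if self.isotype_view:
            parts.append(self.isotype_view)
        return "_".join(parts)

    def restrict_isotype(self, isotype: str) -> "RepertoireSample":
        """View of an IGH sample containing a single isotype."""
        return RepertoireSample(
            patient_id=self.patient_id,
            tissue=self.tissue,
            chain=self.chain,
            clonotypes=[c for c in self.clonotypes if c.isotype == isotype],
            isotype_view=isotype,
        )


@dataclass(slots=True)
class ClinicalRecord:
    patient_id: str
    sex: str = ""
    age_band: str = ""
    stage_group: str = ""  # "early" | "advanced"
    recurrence: str = "unknown"  # "yes" | "no" | "unknown"
    pfs_months: float | None = None
    rfs_months: float | None = None
    os_months: float | None = None
    pfs_event: int | None = None
    rfs_event: int | None = None
    os_event: int | None = None


# Default column maps: target Clonotype field -> source column name.
AIRR_COLUMNS: dict[str, str] = {
    "clone_id": "sequence_id",
    "count": "duplicate_count",
    "cdr3_nt": "junction",
    "cdr3_aa": "junction_aa",
    "v_call": "v_call",
    "d_call": "d_call",
    "j_call": "j_call",
    "chain": "locus",
    "isotype": "c_call",
    "v_mismatches": "v_mismatches",
}

MIXCR_COLUMNS: dict[str, str] = {
    "clone_id": "cloneId",
    "count": "cloneCount",
    "cdr3_nt": "nSeqCDR3",
    "cdr3_aa": "aaSeqCDR3",
    "v_call": "allVHitsWithScore",
    "d_call": "allDHitsWithScore",
    "j_call": "allJHitsWithScore",
    "chain": "chain",
    "isotype": "isotype",
    "v_mismatches": "vMismatches",
}

_REQUIRED = ("count", "cdr3_nt", "cdr3_aa", "v_call", "j_call")
_OPTIONAL = ("clone_id", "d_call", "chain", "isotype", "v_mismatches")

#: Fixed column order of the normalized clonotype TSV this package writes.
NORMALIZED_COLUMNS = (
    "clone_id",
    "count",
    "cdr3_nt",
    "cdr3_aa",
    "v_call",
    "d_call",
    "j_call",
    "chain",
    "isotype",
    "v_mismatches",
)


def strip_allele(call: str) -> str:
    """Truncate a gene call to gene level.

    Drops the ``*01`` allele suffix, keeps only the first (top-scoring) hit of
    comma-separated multi-hit lists, and strips MiXCR ``(score)`` decorations.
    """
    if not call:
        return ""
    first = call.split(",")[0].strip()
    first = re.sub(r"\(.*?\)", "", first)
    return first.split("*")[0].strip()


def harmonize_isotype(raw: str | None) -> str | None:
    """Map a constant-region call (e.g. ``IGHG1``) onto {IgA, IgG, IgM}."""
    if raw is None:
        return None
    raw = str(raw).strip()
    if not raw or raw.upper() in {"NA", "NAN", "NONE"}:
        return None
    s = raw.upper()
    for prefix in ("IGH", "IG"):
        if s.startswith(prefix):
            s = s[len(prefix):]
            break
    if s and s[0] in "AGM":
        return {"A": "IgA", "G": "IgG", "M": "IgM"}[s[0]]
    return None


def infer_chain(v_call: str) -> str:
    """Infer the receptor chain from a V-gene name (``TRBV19`` -> ``TRB``)."""
    for chain in CHAINS:
        if v_call.upper().startswith(chain):
            return chain
    return ""


def _parse_int(value: object) -> int | None:
    try:
        f = float(value)
    except (TypeError, ValueError):
        return None
    if f != int(f) and abs(f - round(f)) > 1e-9:
        return None
    return int(round(f))


def read_airr_table(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
) -> list[Clonotype]:
    """Read a clonotype TSV into :class:`Clonotype` records.

    ``column_map`` maps Clonotype field names to source column names; defaults
    to the AIRR Rearrangement schema (:data:`AIRR_COLUMNS`). Pass
    :data:`MIXCR_COLUMNS` (or your own map) for other dialects. Rows whose
    count cannot be parsed are rejected with a warning. Gene calls are
    truncated to gene level.
    """
    path = Path(path)
    cmap = dict(AIRR_COLUMNS)
    if column_map:
        cmap.update(column_map)
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        logger.warning("empty clonotype table: %s", path)
        return []
    if df.empty and len(df.columns) == 0:
        logger.warning("empty clonotype table: %s", path)
        return []

    for fieldname in _REQUIRED:
        if cmap[fieldname] not in df.columns:
            raise ConfigurationError(
                f"required column {cmap[fieldname]!r} (for field {fieldname!r}) "
                f"missing from {path}"
            )
    present = {f: cmap[f] for f in _REQUIRED + _OPTIONAL if cmap.get(f) in df.columns}

    clonotypes: list[Clonotype] = []
    n_rejected = 0
    col_pos = {f: df.columns.get_loc(c) for f, c in present.items()}
    for i, row in enumerate(df.itertuples(index=False)):
        values = tuple(row)
        rec = {f: values[pos] for f, pos in col_pos.items()}
        count = _parse_int(rec.get("count"))
        if count is None or count < 0:
            n_rejected += 1
            continue
        v_call = strip_allele(str(rec.get("v_call", "")))
        chain = str(rec.get("chain", "")).strip() or infer_chain(v_call)
        isotype = harmonize_isotype(rec.get("isotype")) if chain == "IGH" else None
        vmm = _parse_int(rec.get("v_mismatches")) if rec.get("v_mismatches", "") != "" else None
        clonotypes.append(
            Clonotype(
                clone_id=str(rec.get("clone_id") or f"row{i}"),
                count=count,
                cdr3_nt=str(rec.get("cdr3_nt", "")).upper(),
                cdr3_aa=str(rec.get("cdr3_aa", "")),
                v_call=v_call,
                d_call=strip_allele(str(rec.get("d_call", ""))),
                j_call=strip_allele(str(rec.get("j_call", ""))),
                chain=chain,
                isotype=isotype,
                v_mismatches=vmm,
            )
        )
    if n_rejected:
        logger.warning("%d rows with unparseable counts rejected in %s", n_rejected, path)
    if not clonotypes:
        logger.warning("no clonotypes parsed from %s", path)
    return clonotypes


def _has_stop(c: Clonotype) -> bool:
    if c.cdr3_aa:
        return any(ch in STOP_CHARS for ch in c.cdr3_aa)
    nt = c.cdr3_nt
    usable = nt[: len(nt) - len(nt) % 3]
    if not usable:
        return False
    return "*" in str(Seq(usable).translate())


def is_productive(c: Clonotype) -> bool:
    """The three productive-rearrangement rules.

    A clonotype is kept iff its CDR3 amino-acid length is at least 4, its
    CDR3 nucleotide length is a multiple of 3, and the CDR3 carries no stop
    codon (``*``/``_`` in the amino-acid string, or an in-frame stop when
    only nucleotides are available).
    """
    return (
        len(c.cdr3_aa) >= 4
        and len(c.cdr3_nt) % 3 == 0
        and not _has_stop(c)
    )


def filter_productive(clonotypes: Iterable[Clonotype]) -> list[Clonotype]:
    """Retain productive clonotypes, preserving order and counts."""
    return [c for c in clonotypes if is_productive(c)]


def write_clonotypes(clonotypes: Sequence[Clonotype], path: str | Path) -> None:
    """Write the normalized clonotype TSV (fixed column order, UTF-8, \\n)."""
    rows = []
    for c in clonotypes:
        rows.append(
            {
                "clone_id": c.clone_id,
                "count": c.count,
                "cdr3_nt": c.cdr3_nt,
                "cdr3_aa": c.cdr3_aa,
                "v_call": c.v_call,
                "d_call": c.d_call,
                "j_call": c.j_call,
                "chain": c.chain,
                "isotype": c.isotype if c.isotype is not None else "NA",
                "v_mismatches": "" if c.v_mismatches is None else c.v_mismatches,
            }
        )
    df = pd.DataFrame(rows, columns=list(NORMALIZED_COLUMNS))
    df.to_csv(path, sep="\t", index=False, lineterminator="\n", encoding="utf-8")


def write_airr_table(clonotypes: Sequence[Clonotype], path: str | Path) -> None:
    """Write clonotypes using AIRR Rearrangement column names."""
    rows = []
    for c in clonotypes:
        rows.append(
            {
                "sequence_id": c.clone_id,
                "duplicate_count": c.count,
                "junction": c.cdr3_nt,
                "junction_aa": c.cdr3_aa,
                "v_call": c.v_call,
                "d_call": c.d_call,
                "j_call": c.j_call,
                "locus": c.chain,
                "c_call": c.isotype if c.isotype is not None else "",
                "v_mismatches": "" if c.v_mismatches is None else c.v_mismatches,
            }
        )
    cols = ["sequence_id", "duplicate_count", "junction", "junction_aa", "v_call",
            "d_call", "j_call", "locus", "c_call", "v_mismatches"]
    pd.DataFrame(rows, columns=cols).to_csv(
        path, sep="\t", index=False, lineterminator="\n", encoding="utf-8"
    )


def stage_group_from_tnm(tnm: object) -> str:
    """TNM stage 1 is early-stage; stage 2 and above is advanced-stage."""
    s = str(tnm).strip().upper()
    roman = {"I": 1, "II": 2, "III": 3, "IV": 4}
    m = re.match(r"(IV|III|II|I)", s)
    if m and not s[0].isdigit():
        num = roman[m.group(1)]
    else:
        m2 = re.match(r"(\d+)", s)
        if not m2:
            raise ValidationError(f"unparseable TNM stage {tnm!r}")
        num = int(m2.group(1))
    return "early" if num == 1 else "advanced"


_TIME_COLS = ("pfs_months", "rfs_months", "os_months")
_EVENT_COLS = ("pfs_event", "rfs_event", "os_event")


def read_clinical(path: str | Path) -> list[ClinicalRecord]:
    """Read a clinical CSV/TSV into :class:`ClinicalRecord` rows.

    ``stage_group`` is derived from a ``tnm_stage`` column when present
    (stage 1 -> early, >= 2 -> advanced); an explicit ``stage_group`` column
    wins. Negative survival times raise a :class:`ValidationError` naming the
    offending rows.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    if "patient_id" not in df.columns:
        raise ConfigurationError(f"required column 'patient_id' missing from {path}")

    bad_rows = []
    records: list[ClinicalRecord] = []
    for i, row in df.iterrows():
        kwargs: dict = {"patient_id": str(row["patient_id"])}
        for col in ("sex", "age_band"):
            if col in df.columns:
                kwargs[col] = str(row[col])
        if "stage_group" in df.columns and str(row["stage_group"]).strip():
            kwargs["stage_group"] = str(row["stage_group"]).strip().lower()
        elif "tnm_stage" in df.columns and str(row["tnm_stage"]).strip():
            kwargs["stage_group"] = stage_group_from_tnm(row["tnm_stage"])
        if "recurrence" in df.columns:
            rec = str(row["recurrence"]).strip().lower()
            kwargs["recurrence"] = rec if rec in {"yes", "no"} else "unknown"
        for col in _TIME_COLS:
            if col in df.columns and str(row[col]).strip():
                t = float(row[col])
                if t < 0:
                    bad_rows.append((i, col, t))
                kwargs[col] = t
        for col in _EVENT_COLS:
            if col in df.columns and str(row[col]).strip():
                kwargs[col] = int(float(row[col]))
        records.append(ClinicalRecord(**kwargs))
    if bad_rows:
        raise ValidationError(f"negative survival times in rows: {bad_rows}")
    return records


def clinical_frame(records: Sequence[ClinicalRecord]) -> pd.DataFrame:
    """Clinical records as a DataFrame indexed by patient_id."""
    from dataclasses import asdict

    df = pd.DataFrame([asdict(r) for r in records])
    return df.set_index("patient_id", drop=False)


def group_by_sample(
    clonotypes: Iterable[Clonotype],
    patient_id: str,
    tissue: str,
) -> list[RepertoireSample]:
    """Split a mixed-chain clonotype list into per-chain samples."""
    by_chain: dict[str, list[Clonotype]] = {}
    for c in clonotypes:
        by_chain.setdefault(c.chain or infer_chain(c.v_call), []).append(c)
    return [
        RepertoireSample(patient_id=patient_id, tissue=tissue, chain=ch, clonotypes=cl)
        for ch, cl in sorted(by_chain.items())
    ]
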