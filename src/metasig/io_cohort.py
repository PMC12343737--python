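"""Readers and typed records for mutation (MAF-like), clinical, CNV and ICI tables.

All readers are tolerant of extra columns, skip ``#`` comment lines, and
preserve input row order. Records with missing optional values keep an
explicit ``None`` marker; they are only excluded at model-fit time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .errors import FormatError, RowParseError, ValidationError

BASES = frozenset("ACGT")

#: Variant classifications retained by :func:`filter_nonsynonymous`.
NONSYNONYMOUS_CLASSES = frozenset(
    {
        "Missense_Mutation",
        "Nonsense_Mutation",
        "Frame_Shift_Ins",
        "Frame_Shift_Del",
        "In_Frame_Ins",
        "In_Frame_Del",
        "Splice_Site",
    }
)

#: Classifications recognised on input; anything else maps to "other".
KNOWN_CLASSES = NONSYNONYMOUS_CLASSES | {"Silent"}

#: Default logical-column -> MAF v2.4 header mapping; override per dataset.
DEFAULT_MAF_DIALECT: Mapping[str, str] = {
    "sample": "Tumor_Sample_Barcode",
    "gene": "Hugo_Symbol",
    "chrom": "Chromosome",
    "pos": "Start_Position",
    "ref": "Reference_Allele",
    "alt": "Tumor_Seq_Allele2",
    "classification": "Variant_Classification",
    "type": "Variant_Type",
    # optional columns
    "context3": "Ref_Tri",
    "germline": "Germline_Flag",
    "protein_change": "Protein_Change",
}

_REQUIRED_LOGICAL = ("sample", "gene", "chrom", "pos", "ref", "alt", "classification", "type")


@dataclass(frozen=True)
class MutationRecord:
    sample_id: str
    gene: str
    chrom: str
    pos: int
    ref: str
    alt: str
    variant_classification: str
    variant_type: str
    context3: Optional[str] = None
    germline_flag: bool = False
    protein_change: Optional[str] = None

    def __post_init__(self):
        if self.pos < 1:
            raise ValidationError(f"pos must be >= 1, got {self.pos}")
        if self.variant_type == "SNP":
            if self.ref not in BASES or self.alt not in BASES:
                raise ValidationError(
                    f"SNP alleles must be single bases, got {self.ref}>{self.alt}"
                )
            if self.ref == self.alt:
                raise ValidationError(f"SNP ref == alt ({self.ref})")
            if self.context3 is not None and self.context3[1] != self.ref:
                raise ValidationError(
                    f"context3 middle base {self.context3[1]!r} != ref {self.ref!r}"
                )
        if self.context3 is not None:
            if len(self.context3) != 3 or any(b not in BASES for b in self.context3):
                raise ValidationError(f"context3 must be a 3-base ACGT string, got {self.context3!r}")


@dataclass(frozen=True)
class ClinicalRecord:
    sample_id: str
    os_months: Optional[float]
    os_event: Optional[int]
    age: Optional[float] = None
    sex: Optional[str] = None
    tumor_type: Optional[str] = None
    tmb: Optional[float] = None
    fga: Optional[float] = None
    msi: Optional[float] = None

    def __post_init__(self):
        if self.os_months is not None and self.os_months < 0:
            raise ValidationError(f"os_months must be >= 0, got {self.os_months}")
        if self.fga is not None and not (0.0 <= self.fga <= 1.0):
            raise ValidationError(f"fga must lie in [0, 1], got {self.fga}")
        if self.os_event is not None and self.os_event not in (0, 1):
            raise ValidationError(f"os_event must be 0/1, got {self.os_event}")


@dataclass(frozen=True)
class CnvRecord:
    sample_id: str
    gene: str
    call: str

    _CALLS = ("amplification", "deletion", "neutral")

    def __post_init__(self):
        if self.call not in self._CALLS:
            raise ValidationError(f"call must be one of {self._CALLS}, got {self.call!r}")


@dataclass(frozen=True)
class IciRecord:
    sample_id: str
    response: str
    os_months: Optional[float]
    os_event: Optional[int]
    cohort: str = ""

    _RESPONSES = ("CR", "PR", "SD", "PD", "NE")

    def __post_init__(self):
        if self.response not in self._RESPONSES:
            raise ValidationError(f"response must be one of {self._RESPONSES}, got {self.response!r}")


def _read_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False)
    if df.columns.size == 1 and "," in df.columns[0]:
        df = pd.read_csv(path, sep=",", comment="#", dtype=str, keep_default_na=False)
    return df


_TRUTHY = {"1", "true", "t", "yes", "y"}


def read_maf(path, dialect: Optional[Mapping[str, str]] = None) -> list[MutationRecord]:
    """Parse a MAF-like tab-separated file into :class:`MutationRecord` objects.

    ``dialect`` maps logical column names (``sample``, ``gene``, ``chrom``,
    ``pos``, ``ref``, ``alt``, ``classification``, ``type`` plus optional
    ``context3``/``germline``/``protein_change``) to header names; it defaults
    to standard MAF v2.4 headers. Unknown classifications map to ``"other"``,
    germline-flagged rows are retained but marked.
    """
    dia = dict(DEFAULT_MAF_DIALECT)
    if dialect:
        dia.update(dialect)
    df = _read_table(path)
    for logical in _REQUIRED_LOGICAL:
        col = dia[logical]
        if col not in df.columns:
            raise FormatError(f"missing required column {col!r} (logical {logical!r})")

    ctx_col = dia.get("context3")
    germ_col = dia.get("germline")
    prot_col = dia.get("protein_change")
    has_ctx = ctx_col in df.columns
    has_germ = germ_col in df.columns
    has_prot = prot_col in df.columns

    records: list[MutationRecord] = []
    for i, row in enumerate(df.itertuples(index=False)):
        line_no = i + 2  # header occupies line 1
        row = dict(zip(df.columns, row))
        raw_pos = row[dia["pos"]]
        try:
            pos = int(raw_pos)
        except (TypeError, ValueError):
            raise RowParseError(f"non-integer position {raw_pos!r}", line=line_no) from None
        classification = row[dia["classification"]]
        if classification not in KNOWN_CLASSES:
            classification = "other"
        ctx = row[ctx_col].upper() if has_ctx and row[ctx_col] else None
        germ = row[germ_col].strip().lower() in _TRUTHY if has_germ else False
        prot = row[prot_col] or None if has_prot else None
        try:
            records.append(
                MutationRecord(
                    sample_id=row[dia["sample"]],
                    gene=row[dia["gene"]],
                    chrom=str(row[dia["chrom"]]),
                    pos=pos,
                    ref=row[dia["ref"]].upper(),
                    alt=row[dia["alt"]].upper(),
                    variant_classification=classification,
                    variant_type=row[dia["type"]].upper(),
                    context3=ctx,
                    germline_flag=germ,
                    protein_change=prot,
                )
            )
        except ValidationError as exc:
            raise RowParseError(str(exc), line=line_no) from exc
    return records


def write_maf(records: Sequence[MutationRecord], path, dialect: Optional[Mapping[str, str]] = None) -> None:
    """Serialize records back to a tab-separated MAF with the dialect's headers."""
    dia = dict(DEFAULT_MAF_DIALECT)
    if dialect:
        dia.update(dialect)
    cols = {
        dia["sample"]: [r.sample_id for r in records],
        dia["gene"]: [r.gene for r in records],
        dia["chrom"]: [r.chrom for r in records],
        dia["pos"]: [r.pos for r in records],
        dia["ref"]: [r.ref for r in records],
        dia["alt"]: [r.alt for r in records],
        dia["classification"]: [r.variant_classification for r in records],
        dia["type"]: [r.variant_type for r in records],
    }
    if any(r.context3 for r in records):
        cols[dia["context3"]] = [r.context3 or "" for r in records]
    if any(r.germline_flag for r in records):
        cols[dia["germline"]] = [int(r.germline_flag) for r in records]
    if any(r.protein_change for r in records):
        cols[dia["protein_change"]] = [r.protein_change or "" for r in records]
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False)


def filter_nonsynonymous(
    records: Iterable[MutationRecord],
    extra_classes: Sequence[str] = (),
) -> list[MutationRecord]:
    """Keep nonsynonymous records and drop germline-flagged ones, preserving order.

    Retained classes: missense, nonsense, frameshift indels, inframe indels and
    splice-site. ``extra_classes`` lets callers additionally retain e.g.
    Translation_Start_Site, which is excluded by default.
    """
    keep = NONSYNONYMOUS_CLASSES | set(extra_classes)
    return [r for r in records if r.variant_classification in keep and not r.germline_flag]


def _opt_float(value: str, column: str, line: int) -> Optional[float]:
    if value is None or value == "" or value.upper() in ("NA", "NAN", "NONE"):
        return None
    try:
        out = float(value)
    except ValueError:
        raise RowParseError(f"non-numeric {column} value {value!r}", line=line) from None
    return None if math.isnan(out) else out


def read_clinical(path) -> list[ClinicalRecord]:
    df = _read_table(path)
    for col in ("sample_id", "os_months", "os_event"):
        if col not in df.columns:
            raise FormatError(f"missing required column {col!r}")
    records = []
    for i, row in enumerate(df.to_dict("records")):
        line = i + 2
        ev = _opt_float(row.get("os_event", ""), "os_event", line)
        try:
            records.append(
                ClinicalRecord(
                    sample_id=row["sample_id"],
                    os_months=_opt_float(row["os_months"], "os_months", line),
                    os_event=int(ev) if ev is not None else None,
                    age=_opt_float(row.get("age", ""), "age", line),
                    sex=row.get("sex") or None,
                    tumor_type=row.get("tumor_type") or None,
                    tmb=_opt_float(row.get("tmb", ""), "tmb", line),
                    fga=_opt_float(row.get("fga", ""), "fga", line),
                    msi=_opt_float(row.get("msi", ""), "msi", line),
                )
            )
        except ValidationError as exc:
            raise ValidationError(f"line {line}: {exc}") from exc
    return records


def read_cnv(path) -> list[CnvRecord]:
    df = _read_table(path)
    for col in ("sample_id", "gene", "call"):
        if col not in df.columns:
            raise FormatError(f"missing required column {col!r}")
    seen = set()
    records = []
    for i, row in enumerate(df.to_dict("records")):
        key = (row["sample_id"], row["gene"])
        if key in seen:
            raise ValidationError(f"line {i + 2}: duplicate CNV call for {key}")
        seen.add(key)
        try:
            records.append(CnvRecord(sample_id=row["sample_id"], gene=row["gene"], call=row["call"]))
        except ValidationError as exc:
            raise ValidationError(f"line {i + 2}: {exc}") from exc
    return records


def read_ici(path) -> list[IciRecord]:
    df = _read_table(path)
    for col in ("sample_id", "response", "os_months", "os_event"):
        if col not in df.columns:
            raise FormatError(f"missing required column {col!r}")
    records = []
    for i, row in enumerate(df.to_dict("records")):
        line = i + 2
        ev = _opt_float(row.get("os_event", ""), "os_event", line)
        try:
            records.append(
                IciRecord(
                    sample_id=row["sample_id"],
                    response=row["response"],
                    os_months=_opt_float(row["os_months"], "os_months", line),
                    os_event=int(ev) if ev is not None else None,
                    cohort=row.get("cohort", "") or "",
                )
            )
        except ValidationError as exc:
            raise ValidationError(f"line {line}: {exc}") from exc
    return records


def clinical_frame(records: Sequence[ClinicalRecord]) -> pd.DataFrame:
    """Clinical records as a DataFrame indexed by sample_id (missing -> NaN)."""
    df = pd.DataFrame(
        {
            "sample_id": [r.sample_id for r in records],
            "os_months": [r.os_months for r in records],
            "os_event": [r.os_event for r in records],
            "age": [r.age for r in records],
            "sex": [r.sex for r in records],
            "tumor_type": [r.tumor_type for r in records],
            "tmb": [r.tmb for r in records],
            "fga": [r.fga for r in records],
            "msi": [r.msi for r in records],
        }
    )
    return df.set_index("sample_id")
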