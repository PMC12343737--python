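"""96-channel trinucleotide substitution catalogs, TMB and tCw burden.

Channel labels follow the standard ``X[R>A]Y`` convention with a pyrimidine
reference base (purine-reference substitutions are reverse-complemented onto
the opposite strand). The channel order is substitution-class major
(C>A, C>G, C>T, T>A, T>C, T>G), then 5' flank, then 3' flank — the layout
used by the common v2 signature probability files.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ContextError, ParameterError, UnsupportedVariantError
from .io_cohort import MutationRecord

SUBSTITUTIONS = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
CHANNELS: tuple[str, ...] = tuple(
    f"{five}[{sub}]{three}" for sub in SUBSTITUTIONS for five in "ACGT" for three in "ACGT"
)
CHANNEL_INDEX = {c: i for i, c in enumerate(CHANNELS)}

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class MutationCatalog:
    """Samples x 96 count matrix (the matrix V) with fixed channel order."""

    samples: list[str]
    counts: np.ndarray  # shape (n_samples, 96), non-negative ints

    channels: tuple[str, ...] = CHANNELS

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.samples), 96):
            raise ParameterError(
                f"counts shape {self.counts.shape} != ({len(self.samples)}, 96)"
            )
        if (self.counts < 0).any():
            raise ParameterError("catalog counts must be non-negative")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=pd.Index(self.samples, name="sample_id"), columns=list(self.channels))

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path) -> "MutationCatalog":
        df = pd.read_csv(path, sep="\t", index_col=0)
        if tuple(df.columns) != CHANNELS:
            raise ContextError("catalog TSV does not carry the 96 channels in canonical order")
        return cls(samples=list(df.index.astype(str)), counts=df.to_numpy())


@dataclass(frozen=True)
class TcwSummary:
    sample_id: str
    tcw_count: int
    total_c_mut: int

    def __post_init__(self):
        if not (0 <= self.tcw_count <= self.total_c_mut):
            raise ParameterError("tcw_count must lie in [0, total_c_mut]")


def classify_channel(ref: str, alt: str, context3: str) -> str:
    """Map an SNV with its trinucleotide context to one of the 96 channel labels.

    Purine-reference mutations are reverse-complemented (bases and flank order)
    so that every channel carries a pyrimidine reference.
    """
    if len(ref) != 1 or len(alt) != 1 or ref not in "ACGT" or alt not in "ACGT":
        raise UnsupportedVariantError(f"channel classification is defined for SNVs only ({ref}>{alt})")
    if len(context3) != 3 or context3[1] != ref:
        raise ContextError(f"context {context3!r} does not center on ref {ref!r}")
    if ref in "AG":
        context3 = _revcomp(context3)
        ref = ref.translate(_COMPLEMENT)
        alt = alt.translate(_COMPLEMENT)
    return f"{context3[0]}[{ref}>{alt}]{context3[2]}"


def resolve_context(record: MutationRecord, reference=None) -> str:
    """Return the uppercase 3-mer around an SNV.

    The record's ``context3`` column wins; otherwise the base and its
    neighbours are read from ``reference`` (a pyfaidx ``Fasta`` or any mapping
    of chrom -> sliceable sequence). The reference base must match ``ref``.
    """
    if record.variant_type != "SNP":
        raise UnsupportedVariantError("context resolution is defined for SNVs only")
    if record.context3 is not None:
        return record.context3.upper()
    if reference is None:
        raise ContextError(
            f"no context3 column and no reference FASTA for {record.chrom}:{record.pos}"
        )
    try:
        seq = str(reference[record.chrom][record.pos - 2 : record.pos + 1]).upper()
    except KeyError as exc:
        raise ContextError(f"chromosome {record.chrom!r} absent from reference") from exc
    if len(seq) != 3:
        raise ContextError(f"position {record.chrom}:{record.pos} too close to contig edge")
    if seq[1] != record.ref:
        raise ContextError(
            f"reference mismatch at {record.chrom}:{record.pos}: FASTA has {seq[1]!r}, record says {record.ref!r}"
        )
    return seq


def build_catalog(
    records: Iterable[MutationRecord],
    samples: Sequence[str],
    min_sample_frac: float = 0.01,
    reference=None,
) -> MutationCatalog:
    """Aggregate SNV records into the samples x 96 catalog.

    Channels that are nonzero in fewer than ``min_sample_frac`` of samples are
    zeroed out (low-frequency noise filter); column positions are retained so
    the matrix stays 96-wide. Samples without SNVs appear as zero rows.
    """
    if not (0.0 <= min_sample_frac <= 1.0):
        raise ParameterError(f"min_sample_frac must lie in [0, 1], got {min_sample_frac}")
    sample_idx = {s: i for i, s in enumerate(samples)}
    counts = np.zeros((len(samples), 96), dtype=np.int64)
    for rec in records:
        if rec.variant_type != "SNP":
            continue
        if rec.sample_id not in sample_idx:
            raise ParameterError(f"record sample {rec.sample_id!r} not in sample list")
        ctx = resolve_context(rec, reference)
        channel = classify_channel(rec.ref, rec.alt, ctx)
        counts[sample_idx[rec.sample_id], CHANNEL_INDEX[channel]] += 1
    if min_sample_frac > 0 and len(samples) > 0:
        present_frac = (counts > 0).sum(axis=0) / len(samples)
        counts[:, present_frac < min_sample_frac] = 0
    return MutationCatalog(samples=list(samples), counts=counts)


def compute_tmb(records: Sequence[MutationRecord], panel_mb: float = 1.14) -> float:
    """Mutations per megabase for one sample's (already filtered) records."""
    if panel_mb <= 0:
        raise ParameterError(f"panel_mb must be > 0, got {panel_mb}")
    return len(records) / panel_mb


def compute_tcw(records: Sequence[MutationRecord], sample_id: Optional[str] = None, reference=None) -> TcwSummary:
    """Count C>T / C>G substitutions in tCw context (5' T, 3' A/T), pyrimidine-collapsed."""
    tcw = 0
    total_c = 0
    sid = sample_id
    for rec in records:
        if rec.variant_type != "SNP":
            continue
        sid = sid or rec.sample_id
        ctx = resolve_context(rec, reference)
        channel = classify_channel(rec.ref, rec.alt, ctx)
        five, sub, three = channel[0], channel[2:5], channel[6]
        if sub.startswith("C>"):
            total_c += 1
            if sub in ("C>T", "C>G") and five == "T" and three in "AT":
                tcw += 1
    return TcwSummary(sample_id=sid or "", tcw_count=tcw, total_c_mut=total_c)
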