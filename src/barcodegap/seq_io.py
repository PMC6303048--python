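"""Reading, quality control and validation of COI barcode datasets.

A dataset is a FASTA file of (pre-aligned or equal-length) barcode
sequences plus a tab-separated specimen metadata table in the style of a
BOLD export: one row per specimen with its morphospecies, genus, family
and collection-site labels, optionally carrying an externally assigned
cluster/BIN identifier.

This module deliberately does not align: sequences that survive QC must
already be of equal length, mirroring a workflow where alignment happened
upstream (BioEdit/MEGA-style) before analysis.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

logger = logging.getLogger(__name__)

#: IUPAC ambiguity codes (anything that is not a concrete base or a gap).
AMBIGUITY_CODES = frozenset("RYSWKMBDHVN")
VALID_CHARS = frozenset("ACGT-") | AMBIGUITY_CODES

#: Stop codons scanned during QC, by genetic code. The vertebrate
#: mitochondrial code reads AGA/AGG as stops in addition to TAA/TAG.
STOP_CODONS = {
    "vertebrate_mitochondrial": frozenset({"TAA", "TAG", "AGA", "AGG"}),
    "standard": frozenset({"TAA", "TAG", "TGA"}),
}

#: numpy code for each concrete base; anything else encodes as 255 and is
#: treated as non-comparable by the distance machinery.
_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}
_ENCODE_TABLE = np.full(256, 255, dtype=np.uint8)
for _b, _c in _BASE_CODE.items():
    _ENCODE_TABLE[ord(_b)] = _c


class DatasetError(ValueError):
    """Raised for malformed or inconsistent input datasets."""


@dataclass(frozen=True)
class SequenceRecord:
    """One barcode sequence with its specimen identifier."""

    specimen_id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.specimen_id or any(ch.isspace() for ch in self.specimen_id):
            raise DatasetError(
                f"invalid specimen_id {self.specimen_id!r}: must be a non-empty "
                "whitespace-free token"
            )
        if not self.sequence:
            raise DatasetError(f"empty sequence for specimen {self.specimen_id!r}")
        bad = set(self.sequence) - VALID_CHARS
        if bad:
            raise DatasetError(
                f"specimen {self.specimen_id!r}: invalid characters {sorted(bad)}"
            )

    @property
    def ungapped(self) -> str:
        return self.sequence.replace("-", "")

    @property
    def ambiguous_fraction(self) -> float:
        """Fraction of ambiguous characters among non-gap positions."""
        ung = self.ungapped
        if not ung:
            return 1.0
        n_amb = sum(1 for ch in ung if ch in AMBIGUITY_CODES)
        return n_amb / len(ung)


@dataclass(frozen=True)
class QCConfig:
    """Sequence quality filters applied before any distance work.

    Defaults follow the usual barcode-compliance rules: at least 500
    informative sites, at most 1% ambiguous bases, no indels, and no
    premature stop codon in any forward reading frame under the
    vertebrate mitochondrial code.
    """

    min_length: int = 500
    max_ambiguous_fraction: float = 0.01
    genetic_code: str = "vertebrate_mitochondrial"
    require_no_indels: bool = True
    check_stop_codons: bool = True

    def __post_init__(self) -> None:
        if self.min_length < 1:
            raise ValueError("min_length must be >= 1")
        if not 0.0 <= self.max_ambiguous_fraction <= 1.0:
            raise ValueError("max_ambiguous_fraction must lie in [0, 1]")
        if self.check_stop_codons and self.genetic_code not in STOP_CODONS:
            raise ValueError(
                f"unknown genetic code {self.genetic_code!r}; "
                f"known: {sorted(STOP_CODONS)}"
            )


class Alignment:
    """Equal-length nucleotide matrix keyed by specimen IDs.

    The container is intentionally minimal: ordered IDs, the raw string
    sequences, and an integer encoding used by the distance code (A/C/G/T
    map to 0..3, every gap or ambiguity to 255).
    """

    def __init__(self, records: Sequence[SequenceRecord]):
        records = list(records)
        if not records:
            raise DatasetError("alignment needs at least one sequence")
        lengths = {len(r.sequence) for r in records}
        if len(lengths) != 1:
            raise DatasetError(
                f"sequences differ in length ({sorted(lengths)}); supply aligned "
                "or equal-length input — this package does not align"
            )
        seen: set[str] = set()
        for r in records:
            if r.specimen_id in seen:
                raise DatasetError(f"duplicate specimen_id {r.specimen_id!r}")
            seen.add(r.specimen_id)
        self.records: list[SequenceRecord] = records
        self.length: int = lengths.pop()

    @property
    def ids(self) -> list[str]:
        return [r.specimen_id for r in self.records]

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def codes(self) -> np.ndarray:
        """(n_sequences, length) uint8 matrix; non-ACGT encodes as 255."""
        buf = np.frombuffer(
            "".join(r.sequence for r in self.records).encode("ascii"), dtype=np.uint8
        ).reshape(len(self.records), self.length)
        return _ENCODE_TABLE[buf]

    def subset(self, keep_ids: Iterable[str]) -> "Alignment":
        keep = set(keep_ids)
        return Alignment([r for r in self.records if r.specimen_id in keep])

    def resampled_columns(self, column_indices: np.ndarray) -> "Alignment":
        """New alignment with columns taken (with repeats) from this one."""
        recs = [
            SequenceRecord(r.specimen_id, "".join(r.sequence[i] for i in column_indices))
            for r in self.records
        ]
        return Alignment(recs)


METADATA_REQUIRED = ("specimen_id", "species", "genus", "family")


@dataclass
class TaxonomyTable:
    """Specimen → species/genus/family/site mapping (BOLD-export style)."""

    frame: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        df = self.frame
        missing = [c for c in METADATA_REQUIRED if c not in df.columns]
        if missing:
            raise DatasetError(f"metadata missing required columns: {missing}")
        if "site" not in df.columns:
            df = df.assign(site="")
        if "external_cluster_id" not in df.columns:
            df = df.assign(external_cluster_id=pd.NA)
        dup = df["specimen_id"][df["specimen_id"].duplicated()]
        if len(dup):
            raise DatasetError(f"duplicate specimen_id in metadata: {sorted(set(dup))}")
        if (df["species"].astype(str).str.strip() == "").any():
            raise DatasetError("empty species label in metadata")
        self.frame = df.set_index("specimen_id", drop=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "TaxonomyTable":
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str).fillna("")
        df["external_cluster_id"] = df.get("external_cluster_id", "")
        return cls(df)

    def to_tsv(self, path: str | Path) -> None:
        cols = ["specimen_id", "species", "genus", "family", "site", "external_cluster_id"]
        self.frame[cols].to_csv(path, sep="\t", index=False)

    @property
    def ids(self) -> list[str]:
        return list(self.frame.index)

    def species_of(self, specimen_id: str) -> str:
        return str(self.frame.at[specimen_id, "species"])

    def column(self, name: str, ids: Sequence[str]) -> list[str]:
        return [str(self.frame.at[i, name]) for i in ids]

    def subset(self, keep_ids: Iterable[str]) -> "TaxonomyTable":
        keep = [i for i in self.frame.index if i in set(keep_ids)]
        return TaxonomyTable(self.frame.loc[keep].reset_index(drop=True))


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a FASTA file into records; the header token before the first
    whitespace is the specimen ID and sequences are uppercased."""
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        sid = entry.id
        if sid in seen:
            raise DatasetError(f"duplicate specimen_id in FASTA: {sid!r}")
        seen.add(sid)
        records.append(SequenceRecord(sid, str(entry.seq).upper()))
    if not records:
        raise DatasetError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    bio = [
        _BioSeqRecord(Seq(r.sequence), id=r.specimen_id, description="")
        for r in records
    ]
    SeqIO.write(bio, str(path), "fasta")


def _has_open_forward_frame(ungapped: str, stops: frozenset[str]) -> bool:
    # A frame is open when none of its complete codons, excluding the
    # terminal one, is a stop. Codons containing ambiguities cannot be
    # called as stops.
    for frame in range(3):
        codons = [
            ungapped[i : i + 3]
            for i in range(frame, len(ungapped) - 2, 3)
        ]
        if not codons:
            return True
        if all(c not in stops for c in codons[:-1]):
            return True
    return False


def qc_filter(
    records: Sequence[SequenceRecord], config: QCConfig = QCConfig()
) -> tuple[list[SequenceRecord], pd.DataFrame]:
    """Apply barcode-compliance filters.

    Returns the passing records plus a per-record report with the first
    failed criterion (``length``, ``ambiguous``, ``indel``, ``stop_codon``)
    for each failing record. Criteria are checked in that order.
    """
    if not records:
        raise DatasetError("qc_filter requires at least one record")
    stops = STOP_CODONS.get(config.genetic_code, frozenset())
    passed: list[SequenceRecord] = []
    rows: list[dict] = []
    for rec in records:
        ung = rec.ungapped
        reason = ""
        if len(ung) < config.min_length:
            reason = "length"
        elif rec.ambiguous_fraction > config.max_ambiguous_fraction:
            reason = "ambiguous"
        elif config.require_no_indels and "-" in rec.sequence:
            reason = "indel"
        elif config.check_stop_codons and not _has_open_forward_frame(ung, stops):
            reason = "stop_codon"
        if reason:
            rows.append({"specimen_id": rec.specimen_id, "status": "fail", "reason": reason})
        else:
            passed.append(rec)
            rows.append({"specimen_id": rec.specimen_id, "status": "pass", "reason": ""})
    report = pd.DataFrame(rows, columns=["specimen_id", "status", "reason"])
    return passed, report


def load_dataset(
    fasta_path: str | Path,
    metadata_path: str | Path,
    config: QCConfig = QCConfig(),
) -> tuple[Alignment, TaxonomyTable, pd.DataFrame]:
    """Load, QC-filter and cross-validate a FASTA + metadata dataset.

    Returns ``(alignment, taxonomy, qc_report)`` restricted to specimens
    that survive QC. Specimens present in only one of the two inputs are
    an error, as is unequal sequence length after filtering.
    """
    records = read_fasta(fasta_path)
    tax = TaxonomyTable.from_tsv(metadata_path)

    fasta_ids = {r.specimen_id for r in records}
    meta_ids = set(tax.ids)
    only_fasta = sorted(fasta_ids - meta_ids)
    only_meta = sorted(meta_ids - fasta_ids)
    if only_fasta or only_meta:
        raise DatasetError(
            "specimen ID mismatch between FASTA and metadata; "
            f"FASTA-only: {only_fasta}; metadata-only: {only_meta}"
        )

    passed, report = qc_filter(records, config)
    if not passed:
        raise DatasetError("no sequences passed QC")
    n_fail = int((report["status"] == "fail").sum())
    if n_fail:
        logger.info("QC removed %d of %d sequences", n_fail, len(records))
    aln = Alignment(passed)
    return aln, tax.subset(aln.ids), report
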