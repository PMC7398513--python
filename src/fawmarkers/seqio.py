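"""FASTA and sample-sheet I/O: validated sequence records joined to metadata."""

from __future__ import annotations

import csv
import datetime
import enum
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO as _BioSeqIO

from ._iupac import ALPHABET

logger = logging.getLogger(__name__)


class Marker(str, enum.Enum):
    """The three amplicon segments handled by the pipeline."""

    COIB = "COIB"
    TPIE4 = "TPIE4"
    TPII4 = "TPII4"


class Host(str, enum.Enum):
    SOFT_CORN = "soft_corn"
    HARD_CORN = "hard_corn"
    RICE = "rice"
    OTHER = "other"


class Region(str, enum.Enum):
    COAST = "Coast"
    ANDES = "Andes"
    AMAZON = "Amazon"
    OTHER = "other"


class ParseError(ValueError):
    """Raised on malformed FASTA/TSV input."""


@dataclass(frozen=True)
class SeqRecord:
    """One named nucleotide sequence, stored uppercase.

    The alphabet is A/C/G/T/N plus the IUPAC ambiguity codes
    (R, Y, S, W, K, M, B, D, H, V) and the gap character ``-``
    (alignments may be re-ingested; gaps are stripped before
    classification).
    """

    id: str
    sequence: str
    marker: Marker | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ParseError("sequence record with empty id")
        if not self.sequence:
            raise ParseError(f"record {self.id!r}: empty sequence")
        seq = self.sequence.upper()
        for offset, ch in enumerate(seq):
            if ch not in ALPHABET:
                raise ParseError(
                    f"record {self.id!r}: illegal character {ch!r} at offset {offset}"
                )
        object.__setattr__(self, "sequence", seq)

    def ungapped(self) -> str:
        return self.sequence.replace("-", "")


@dataclass
class SpecimenRecord:
    """One collected individual: metadata plus its per-marker sequences."""

    specimen_id: str
    site_code: str = ""
    province: str = ""
    host: Host = Host.OTHER
    region: Region = Region.OTHER
    date: datetime.date | None = None
    sex: str = ""
    sequences: dict[Marker, SeqRecord] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str | Path, marker: Marker | None = None) -> list[SeqRecord]:
    """Read a FASTA file into validated :class:`SeqRecord` objects.

    Order is preserved, sequences are uppercased and trailing whitespace
    stripped.  Malformed headers or illegal characters raise
    :class:`ParseError` naming the record and offset; an empty file is an
    error.
    """
    path = Path(path)
    text = path.read_text()
    if not text.strip():
        raise ParseError(f"{path}: empty FASTA file")
    if text.lstrip()[0] != ">":
        raise ParseError(f"{path}: malformed FASTA, first record lacks '>' header")
    records = []
    with path.open() as fh:
        for rec in _BioSeqIO.parse(fh, "fasta"):
            records.append(SeqRecord(id=rec.id, sequence=str(rec.seq).strip(), marker=marker))
    if not records:
        raise ParseError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Iterable[SeqRecord], path: str | Path, width: int = 70) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Sample sheet

SAMPLE_SHEET_COLUMNS = ("specimen_id", "site_code", "province", "host", "region", "date")

_HOST_VOCAB = {
    "soft_corn": Host.SOFT_CORN,
    "soft corn": Host.SOFT_CORN,
    "hard_corn": Host.HARD_CORN,
    "hard corn": Host.HARD_CORN,
    "rice": Host.RICE,
    "other": Host.OTHER,
}

_REGION_VOCAB = {
    "coast": Region.COAST,
    "coastal": Region.COAST,  # sheet label for the coastal lowlands
    "andes": Region.ANDES,
    "amazon": Region.AMAZON,
    "other": Region.OTHER,
}


def _map_vocab(value: str, vocab: dict, kind: str, specimen_id: str):
    key = value.strip().lower()
    if key in vocab:
        return vocab[key]
    logger.warning("specimen %s: unknown %s %r mapped to 'other'", specimen_id, kind, value)
    return vocab["other"]


def read_sample_sheet(path: str | Path) -> list[SpecimenRecord]:
    """Read the tab-separated sample sheet (sequences left unset).

    Required header: specimen_id, site_code, province, host, region, date.
    Unknown host/region vocabulary maps to ``other`` with a logged warning;
    duplicate specimen ids and missing columns are errors.  A sheet that
    parses as a single column (e.g. a CSV misread as TSV) is rejected.
    """
    path = Path(path)
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        header = reader.fieldnames or []
        if len(header) < 2:
            raise ParseError(
                f"{path}: sample sheet parsed as a single column; expected TSV"
            )
        missing = [c for c in SAMPLE_SHEET_COLUMNS if c not in header]
        if missing:
            raise ParseError(f"{path}: missing required column(s): {', '.join(missing)}")
        records: list[SpecimenRecord] = []
        seen: set[str] = set()
        for row in reader:
            sid = (row["specimen_id"] or "").strip()
            if not sid:
                raise ParseError(f"{path}: row with empty specimen_id")
            if sid in seen:
                raise ParseError(f"{path}: duplicate specimen_id {sid!r}")
            seen.add(sid)
            raw_date = (row.get("date") or "").strip()
            date = datetime.date.fromisoformat(raw_date) if raw_date else None
            records.append(
                SpecimenRecord(
                    specimen_id=sid,
                    site_code=(row.get("site_code") or "").strip(),
                    province=(row.get("province") or "").strip(),
                    host=_map_vocab(row.get("host") or "other", _HOST_VOCAB, "host", sid),
                    region=_map_vocab(row.get("region") or "other", _REGION_VOCAB, "region", sid),
                    date=date,
                    sex=(row.get("sex") or "").strip(),
                )
            )
    return records


def write_sample_sheet(specimens: Iterable[SpecimenRecord], path: str | Path) -> None:
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(SAMPLE_SHEET_COLUMNS)
        for sp in specimens:
            writer.writerow(
                [
                    sp.specimen_id,
                    sp.site_code,
                    sp.province,
                    sp.host.value,
                    sp.region.value,
                    sp.date.isoformat() if sp.date else "",
                ]
            )


# ---------------------------------------------------------------------------
# Joining

@dataclass
class AttachReport:
    attached: int = 0
    unmatched_ids: list[str] = field(default_factory=list)
    duplicate_ids: list[str] = field(default_factory=list)


def attach_sequences(
    specimens: Sequence[SpecimenRecord],
    fasta_records: Iterable[SeqRecord],
    marker: Marker,
) -> tuple[list[SpecimenRecord], AttachReport]:
    """Attach FASTA records to specimens by id for one marker.

    Never fails: unmatched FASTA ids and duplicate occurrences are reported,
    specimens lacking this marker are left unset.
    """
    report = AttachReport()
    by_id: dict[str, SeqRecord] = {}
    for rec in fasta_records:
        if rec.id in by_id:
            report.duplicate_ids.append(rec.id)
            continue
        by_id[rec.id] = rec
    known = {sp.specimen_id for sp in specimens}
    report.unmatched_ids = sorted(set(by_id) - known)
    out = []
    for sp in specimens:
        rec = by_id.get(sp.specimen_id)
        if rec is not None:
            seqs = dict(sp.sequences)
            seqs[marker] = replace(rec, marker=marker)
            sp = replace_specimen(sp, sequences=seqs)
            report.attached += 1
        out.append(sp)
    if report.unmatched_ids:
        logger.warning("%d FASTA id(s) matched no specimen: %s",
                       len(report.unmatched_ids), ", ".join(report.unmatched_ids[:10]))
    return out, report


def replace_specimen(sp: SpecimenRecord, **kwargs) -> SpecimenRecord:
    fields = dict(
        specimen_id=sp.specimen_id,
        site_code=sp.site_code,
        province=sp.province,
        host=sp.host,
        region=sp.region,
        date=sp.date,
        sex=sp.sex,
        sequences=sp.sequences,
    )
    fields.update(kwargs)
    return SpecimenRecord(**fields)
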