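"""Bundled reference segments carrying the diagnostic marker sites.

The shipped sequences are synthetic stand-ins (no reference amplicon
sequences are distributed with the package's source data): they were
generated once from a fixed random seed and carry the diagnostic sites at
the documented spacings.  Classification reads bases off reference offsets,
so amplicon trimming and flanking bases never shift a call.  Real reference
segments can be swapped in via :func:`load_references` (FASTA + sites TSV).

Site labels follow the marker nomenclature: ``mCOI1164D``/``mCOI1287R`` are
numbered from the predicted translational start of the mitochondrial gene
(the bundled COIB amplicon starts at coding position 924), ``gTpi183Y``
from the 5' start of the exon.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

from .seqio import Marker, read_fasta


@dataclass(frozen=True)
class Site:
    name: str
    ref_offset: int  # 0-based offset on the reference segment
    allowed_bases: frozenset[str]


@dataclass(frozen=True)
class ReferenceSegment:
    marker: Marker
    sequence: str  # ungapped A/C/G/T
    sites: tuple[Site, ...] = ()
    #: half-open [start, end) window of the intron on the reference, if any
    intron_window: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if set(self.sequence) - set("ACGT"):
            raise ValueError("reference sequence must be ungapped A/C/G/T")
        names = [s.name for s in self.sites]
        if len(names) != len(set(names)):
            raise ValueError("duplicate site names")
        for s in self.sites:
            if not 0 <= s.ref_offset < len(self.sequence):
                raise ValueError(f"site {s.name} offset outside reference")
            if not s.allowed_bases <= frozenset("ACGT"):
                raise ValueError(f"site {s.name}: allowed bases must be concrete")

    def site(self, name: str) -> Site:
        for s in self.sites:
            if s.name == name:
                return s
        raise KeyError(name)


# COIB amplicon stand-in, 380 bp; strain sites at amplicon offsets 240 and
# 363 (coding positions 1164 and 1287 for an amplicon starting at 924).
COIB_SEQ = (
    "GTTCCGCGGAAGATAGCATTACGAGAATGATTACGTGCTCGTTCGCTTTGGAACAATACG"
    "ACCCCTCCGCAAGCTACACACTCAAGAGATAGTCTACTCACCAGTGGCTCATGAGCGTTT"
    "GGGGGCATAGGGATCTCGGATCCTGTTTGTAGGACTTCGATGTGTTAACCCACGTAGTCT"
    "TGGCAACTGGGTCCGTATAGAGGCCGTGATGAGAACTGCTAGGATCCAGGGCTCCGCTGC"
    "AGCATTGATCTCGTCGGGCTATCGTTGAAGGACGTGCCATTGTCACTCGGCTCCTCCCTA"
    "ATGTCAAGGGCCGTTGATGAGAACGGACACAGTATGTGGAGCTGTCACCACGTCGCCCCC"
    "CGGGTGCGGGCTTGGACAGA"
)

# Tpi region stand-in: 240 bp of exon (polymorphic site at exon position
# 183, offset 182), a 172 bp intron at [240, 412), then 40 bp of the next
# exon.
TPI_SEQ = (
    "TCGACCAAGTCAAAATTCGTATAACCATACCACTAGTATGGTTTAAGTGCGCACCCTGAA"
    "CCTCTCCCATTTAAATACAAGCGCTGTGGCGTAAACGGTGCCATTATTAAGTGCTCTAAG"
    "CTCTGGGAGCGGTTCGAAATTAGAGCGGCACGTACGGAAGACGCCTGTTTCGCGCACAAT"
    "TCCAGGGTATGTGACCGAAAGCATGCCAGAGGTATCTGCCTTGCTGTGGGGCAAGCGGGG"
    "GCTTGGGTATCAATGTTCATATCCAGTGCCCATCGGTACGTAGTTGCTTGGGAATTAAAC"
    "GAGACCCAGTCCTCATCACACACCAACTGACTTGGGGCAAACCACTTTCCACGGCTTGAG"
    "GTATGGGTCAACATCGCGAATGTTGCGAAACGATATTAACCCTAAAGCTAGAAAGGTCAA"
    "AGAGTGGCGAAGTGTCACGTTCTCATGTCCCG"
)

TPI_INTRON_WINDOW = (240, 412)

SITE_COI_1164 = "mCOI1164D"
SITE_COI_1287 = "mCOI1287R"
SITE_TPI_183 = "gTpi183Y"

COIB_REFERENCE = ReferenceSegment(
    marker=Marker.COIB,
    sequence=COIB_SEQ,
    sites=(
        Site(SITE_COI_1164, 240, frozenset("AGT")),
        Site(SITE_COI_1287, 363, frozenset("AG")),
    ),
)

# Both Tpi markers align to the one exon+intron reference.
TPI_REFERENCE = ReferenceSegment(
    marker=Marker.TPIE4,
    sequence=TPI_SEQ,
    sites=(Site(SITE_TPI_183, 182, frozenset("CT")),),
    intron_window=TPI_INTRON_WINDOW,
)

DEFAULT_REFERENCES: dict[Marker, ReferenceSegment] = {
    Marker.COIB: COIB_REFERENCE,
    Marker.TPIE4: TPI_REFERENCE,
    Marker.TPII4: TPI_REFERENCE,
}


def write_references(directory: str | Path) -> None:
    """Export the bundled references as FASTA plus a sites TSV."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    with (directory / "references.fasta").open("w") as fh:
        for name, ref in (("COIB", COIB_REFERENCE), ("TPI", TPI_REFERENCE)):
            fh.write(f">{name}\n{ref.sequence}\n")
    with (directory / "sites.tsv").open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["site_name", "marker", "ref_offset_0based", "allowed_bases"])
        for marker, ref in (("COIB", COIB_REFERENCE), ("TPI", TPI_REFERENCE)):
            for s in ref.sites:
                writer.writerow([s.name, marker, s.ref_offset, "".join(sorted(s.allowed_bases))])


def load_references(fasta_path: str | Path, sites_path: str | Path,
                    intron_window: tuple[int, int] | None = None,
                    ) -> dict[Marker, ReferenceSegment]:
    """Load replacement references from FASTA (ids COIB, TPI) + sites TSV."""
    seqs = {rec.id: rec.sequence for rec in read_fasta(fasta_path)}
    sites: dict[str, list[Site]] = {"COIB": [], "TPI": []}
    with Path(sites_path).open(newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            sites[row["marker"]].append(
                Site(row["site_name"], int(row["ref_offset_0based"]),
                     frozenset(row["allowed_bases"]))
            )
    coib = ReferenceSegment(Marker.COIB, seqs["COIB"], tuple(sites["COIB"]))
    tpi = ReferenceSegment(Marker.TPIE4, seqs["TPI"], tuple(sites["TPI"]),
                           intron_window=intron_window)
    return {Marker.COIB: coib, Marker.TPIE4: tpi, Marker.TPII4: tpi}
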