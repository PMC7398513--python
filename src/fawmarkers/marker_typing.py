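"""Diagnostic-site classification of COIB, TpiE4 and TpiI4 amplicons.

Each query is placed onto a bundled reference segment by anchored
alignment — an exact ungapped anchor scan with a semi-global affine-gap
dynamic program as fallback — and the diagnostic bases are read off
homologous reference offsets, so flanking bases and amplicon trimming
never shift a call.
"""

from __future__ import annotations

import enum
import logging
import re
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np

from ._iupac import AMBIGUITY_CODES, IUPAC_SETS, compatible, reverse_complement
from .references import DEFAULT_REFERENCES, ReferenceSegment, SITE_COI_1164, SITE_COI_1287, SITE_TPI_183
from .seqio import Marker, SeqRecord, SpecimenRecord

logger = logging.getLogger(__name__)

# Alignment scoring; integer-valued so DP scores compare exactly.
MATCH = 2.0
MISMATCH = -1.0
GAP_OPEN = -4.0   # cost of the first gap character
GAP_EXTEND = -1.0  # each additional gap character

MIN_IDENTITY = 0.70
MIN_ALIGNED_COLUMNS = 50
_FAST_PATH_IDENTITY = 0.90
_NEG_INF = -1e18


class NotHomologousError(ValueError):
    """Query does not align to the marker reference (wrong marker/species)."""


@dataclass(frozen=True)
class Alignment:
    """Mapping of reference offsets onto query offsets.

    ``ref_to_query[i]`` is the query offset homologous to reference offset
    ``i``, or None where the reference position is deleted from / not
    covered by the query.  ``identity`` is computed over aligned columns
    only.  ``oriented_query`` is the query in the orientation that aligned
    (reverse-complemented when ``reverse_complemented`` is set).
    """

    ref_to_query: tuple[int | None, ...]
    identity: float
    reverse_complemented: bool
    oriented_query: str

    def query_base(self, ref_offset: int) -> str:
        q = self.ref_to_query[ref_offset]
        return "-" if q is None else self.oriented_query[q]


def _clean_query(query: str | SeqRecord) -> str:
    seq = query.sequence if isinstance(query, SeqRecord) else query
    return seq.upper().replace("-", "")


def _ungapped_candidate(query: str, ref: str) -> Alignment | None:
    """Try an exact-anchor ungapped placement of the query on the reference.

    Returns None when no anchor produces a high-identity ungapped overlap,
    in which case the caller falls back to the dynamic program.
    """
    m, n = len(ref), len(query)
    k = 20
    deltas: list[int] = []
    for off in range(0, max(1, m - k), 50):
        pos = query.find(ref[off : off + k])
        if pos >= 0:
            delta = pos - off
            if delta not in deltas:
                deltas.append(delta)
    for delta in deltas:
        lo = max(0, -delta)
        hi = min(m, n - delta)
        if hi - lo < MIN_ALIGNED_COLUMNS:
            continue
        matches = sum(
            1 for i in range(lo, hi) if compatible(query[i + delta], ref[i])
        )
        identity = matches / (hi - lo)
        if identity >= _FAST_PATH_IDENTITY:
            mapping: list[int | None] = [None] * m
            for i in range(lo, hi):
                mapping[i] = i + delta
            return Alignment(tuple(mapping), identity, False, query)
    return None


def _score_row(ref_char: str, query_arr: np.ndarray, codes: np.ndarray) -> np.ndarray:
    # +MATCH where the query code is IUPAC-compatible with the ref base
    comp = codes[query_arr, _BASE_INDEX[ref_char]]
    return np.where(comp, MATCH, MISMATCH)


_BASE_INDEX = {b: i for i, b in enumerate("ACGT")}
_CODE_ORDER = "ACGTRYSWKMBDHVN-"
_CODE_INDEX = {c: i for i, c in enumerate(_CODE_ORDER)}
_COMPAT = np.zeros((len(_CODE_ORDER), 4), dtype=bool)
for _c, _i in _CODE_INDEX.items():
    if _c != "-":
        for _b in IUPAC_SETS[_c]:
            _COMPAT[_i, _BASE_INDEX[_b]] = True


def _gotoh_semiglobal(ref: str, query: str) -> tuple[tuple[int | None, ...], float]:
    """Affine-gap overlap alignment (free end gaps on both sequences).

    Gaps open from the match state only; scores are integer-valued floats so
    traceback decisions recompute exactly.  Returns the ref->query mapping
    and identity over aligned columns.
    """
    m, n = len(ref), len(query)
    qarr = np.array([_CODE_INDEX[c] for c in query], dtype=np.intp)
    M = np.full((m + 1, n + 1), _NEG_INF)
    Ix = np.full((m + 1, n + 1), _NEG_INF)  # gap in ref (consumes query)
    Iy = np.full((m + 1, n + 1), _NEG_INF)  # gap in query (consumes ref)
    M[0, :] = 0.0  # free leading end gaps
    M[:, 0] = 0.0
    j_idx = np.arange(n + 1)
    for i in range(1, m + 1):
        s = _score_row(ref[i - 1], qarr, _COMPAT)
        best_prev = np.maximum(np.maximum(M[i - 1, :-1], Ix[i - 1, :-1]), Iy[i - 1, :-1])
        M[i, 1:] = best_prev + s
        Iy[i, :] = np.maximum(M[i - 1, :] + GAP_OPEN, Iy[i - 1, :] + GAP_EXTEND)
        # Ix via prefix-max scan: gap of length L=j-k costs OPEN + (L-1)*EXT
        t = M[i, :] - j_idx * GAP_EXTEND
        run = np.maximum.accumulate(t)
        Ix[i, 1:] = run[:-1] + (j_idx[1:] - 1) * GAP_EXTEND + GAP_OPEN
    # free trailing end gaps: best cell on bottom row or right column
    bottom = np.maximum(np.maximum(M[m, :], Ix[m, :]), Iy[m, :])
    right = np.maximum(np.maximum(M[:, n], Ix[:, n]), Iy[:, n])
    jb = int(np.argmax(bottom))
    ib = int(np.argmax(right))
    if bottom[jb] >= right[ib]:
        i, j = m, jb
    else:
        i, j = ib, n
    state_scores = {"M": M, "X": Ix, "Y": Iy}
    state = max("MXY", key=lambda st: state_scores[st][i, j])  # prefer M on ties

    mapping: list[int | None] = [None] * m
    matches = aligned = 0
    while i > 0 and j > 0:
        if state == "M":
            mapping[i - 1] = j - 1
            aligned += 1
            if compatible(query[j - 1], ref[i - 1]):
                matches += 1
            prev = (M[i - 1, j - 1], Ix[i - 1, j - 1], Iy[i - 1, j - 1])
            state = "MXY"[int(np.argmax(prev))]  # ties prefer mismatch over gap
            i, j = i - 1, j - 1
        elif state == "X":
            if Ix[i, j] == M[i, j - 1] + GAP_OPEN:
                state = "M"
            j -= 1
        else:  # Y: reference position skipped in query
            if Iy[i, j] == M[i - 1, j] + GAP_OPEN:
                state = "M"
            i -= 1
    identity = matches / aligned if aligned else 0.0
    if aligned < min(MIN_ALIGNED_COLUMNS, min(m, n)):
        identity = 0.0
    return tuple(mapping), identity


def anchor_align(
    query: str | SeqRecord,
    reference: ReferenceSegment,
    *,
    min_identity: float = MIN_IDENTITY,
    try_revcomp: bool = True,
) -> Alignment:
    """Place a query amplicon onto a reference segment.

    Tries an exact-anchor ungapped placement first, then a semi-global
    affine-gap alignment; if forward identity stays below ``min_identity``
    the reverse complement is tried before raising
    :class:`NotHomologousError`.
    """
    seq = _clean_query(query)
    if len(seq) < 50:
        raise NotHomologousError(f"query too short ({len(seq)} < 50 bases)")
    ref = reference.sequence
    best: Alignment | None = None
    for rc in ((False, True) if try_revcomp else (False,)):
        oriented = reverse_complement(seq) if rc else seq
        aln = _ungapped_candidate(oriented, ref)
        if aln is None:
            mapping, identity = _gotoh_semiglobal(ref, oriented)
            aln = Alignment(mapping, identity, rc, oriented)
        else:
            aln = replace(aln, reverse_complemented=rc)
        if aln.identity >= min_identity:
            return aln
        if best is None or aln.identity > best.identity:
            best = aln
    raise NotHomologousError(
        f"query not homologous to {reference.marker.value} reference "
        f"(best identity {best.identity:.2f} < {min_identity:.2f})"
    )


# ---------------------------------------------------------------------------
# Call types

class CoiValue(str, enum.Enum):
    COI_RS = "COI_RS"
    COI_H1 = "COI_h1"
    COI_H2 = "COI_h2"
    COI_H3 = "COI_h3"
    COI_H4 = "COI_h4"
    UNDETERMINED = "UNDETERMINED"


#: C-strain haplotype values (everything but the rice-strain configuration).
COI_CS_VALUES = frozenset(
    {CoiValue.COI_H1, CoiValue.COI_H2, CoiValue.COI_H3, CoiValue.COI_H4}
)

_COI_TABLE = {
    ("T", "A"): CoiValue.COI_RS,
    ("A", "A"): CoiValue.COI_H1,
    ("A", "G"): CoiValue.COI_H2,
    ("G", "A"): CoiValue.COI_H3,
    ("G", "G"): CoiValue.COI_H4,
}


class TpiValue(str, enum.Enum):
    TPI_C = "TpiC"
    TPI_R = "TpiR"
    TPI_H = "TpiH"
    UNDETERMINED = "UNDETERMINED"


_TPI_TABLE = {"C": TpiValue.TPI_C, "T": TpiValue.TPI_R, "Y": TpiValue.TPI_H}


class IntronStatus(str, enum.Enum):
    HAPLOTYPE = "HAPLOTYPE"
    HET_INDEL_EXCLUDED = "HET_INDEL_EXCLUDED"
    UNDETERMINED = "UNDETERMINED"


@dataclass(frozen=True)
class CoiCall:
    value: CoiValue
    base1164: str = "-"
    base1287: str = "-"


@dataclass(frozen=True)
class TpiCall:
    value: TpiValue
    base183: str = "-"


@dataclass(frozen=True)
class IntronCall:
    status: IntronStatus
    haplotype_seq: str = ""
    haplotype_id: str = ""


# ---------------------------------------------------------------------------
# Per-marker classifiers

def call_coib(query: str | SeqRecord,
              reference: ReferenceSegment | None = None) -> CoiCall:
    """Classify a COIB amplicon from the two strain-diagnostic sites.

    (T,A) is the rice-strain configuration; (A/G, A/G) are the four
    corn-strain haplotypes h1-h4.  Any other base pair, including ambiguity
    codes or a site falling in a query gap, is UNDETERMINED.
    """
    reference = reference or DEFAULT_REFERENCES[Marker.COIB]
    aln = anchor_align(query, reference)
    b1 = aln.query_base(reference.site(SITE_COI_1164).ref_offset)
    b2 = aln.query_base(reference.site(SITE_COI_1287).ref_offset)
    return CoiCall(_COI_TABLE.get((b1, b2), CoiValue.UNDETERMINED), b1, b2)


def call_tpie4(query: str | SeqRecord,
               reference: ReferenceSegment | None = None) -> TpiCall:
    """Classify a TpiE4 amplicon from the exon strain site.

    C -> TpiC, T -> TpiR, the C/T overlap code Y -> TpiH (heterozygous
    male); anything else is UNDETERMINED (logged, since heterozygosity at
    this site is expected to be limited to C/T).
    """
    reference = reference or DEFAULT_REFERENCES[Marker.TPIE4]
    aln = anchor_align(query, reference)
    b = aln.query_base(reference.site(SITE_TPI_183).ref_offset)
    value = _TPI_TABLE.get(b, TpiValue.UNDETERMINED)
    if value is TpiValue.UNDETERMINED and b not in "-ACGT":
        logger.warning("unexpected ambiguity %r at exon strain site", b)
    return TpiCall(value, b)


_AMBIG_RUN_CACHE: dict[int, re.Pattern] = {}


def _has_ambiguity_run(seq: str, k: int) -> bool:
    pat = _AMBIG_RUN_CACHE.get(k)
    if pat is None:
        pat = re.compile("[%s]{%d,}" % ("".join(sorted(AMBIGUITY_CODES)), k))
        _AMBIG_RUN_CACHE[k] = pat
    return pat.search(seq) is not None


def resolve_ambiguities(seq: str) -> str:
    """Resolve isolated point ambiguities to the lexicographically smallest
    compatible base, for deterministic haplotype identity."""
    if not (set(seq) & AMBIGUITY_CODES):
        return seq
    return "".join(min(IUPAC_SETS[c]) if c in AMBIGUITY_CODES else c for c in seq)


def call_tpii4(
    query: str | SeqRecord,
    reference: ReferenceSegment | None = None,
    *,
    het_run_k: int = 5,
    min_intron_len: int = 50,
) -> IntronCall:
    """Extract and classify the TpiI4 intron haplotype.

    A run of >= ``het_run_k`` consecutive ambiguity codes inside the intron
    window marks a specimen heterozygous for an intron frameshift (the
    superposed frame-shifted alleles yield sustained mixed base calls) and
    the record is excluded from haplotype analysis.  Isolated point
    ambiguities are resolved deterministically and the haplotype retained.
    """
    reference = reference or DEFAULT_REFERENCES[Marker.TPII4]
    if reference.intron_window is None:
        raise ValueError("reference has no intron window configured")
    aln = anchor_align(query, reference)
    start, end = reference.intron_window
    covered = [q for q in aln.ref_to_query[start:end] if q is not None]
    if not covered:
        return IntronCall(IntronStatus.UNDETERMINED)
    window = aln.oriented_query[min(covered) : max(covered) + 1]
    if len(window) < min_intron_len:
        return IntronCall(IntronStatus.UNDETERMINED)
    if _has_ambiguity_run(window, het_run_k):
        return IntronCall(IntronStatus.HET_INDEL_EXCLUDED)
    hap = resolve_ambiguities(window.replace("-", ""))
    if hap != window:
        logger.info("resolved point ambiguities in intron haplotype")
    return IntronCall(IntronStatus.HAPLOTYPE, haplotype_seq=hap)


def project_to_reference(
    query: str | SeqRecord,
    reference: ReferenceSegment | None = None,
    window: tuple[int, int] | None = None,
) -> str:
    """Project a query onto reference columns (one character per reference
    offset in ``window``; deletions become '-', query insertions are
    dropped).  Gives variable-length haplotypes a common coordinate system
    for diversity and distance computations."""
    reference = reference or DEFAULT_REFERENCES[Marker.TPII4]
    if window is None:
        window = reference.intron_window or (0, len(reference.sequence))
    aln = anchor_align(query, reference)
    start, end = window
    return "".join(aln.query_base(i) for i in range(start, end))


# ---------------------------------------------------------------------------
# Haplotype registry

class HaplotypeRegistry:
    """Stable sequence -> id mapping; identical sequences share one id.

    New sequences get the next id in the series in first-seen order; a
    pre-seeded registry (e.g. a fixture panel) is honored, so re-running on
    the same input is idempotent.
    """

    def __init__(self, seed: dict[str, str] | None = None, prefix: str = "Hap") -> None:
        self.prefix = prefix
        self._by_seq: dict[str, str] = {}
        self._next = 1
        if seed:
            for seq, hap_id in seed.items():
                self._by_seq[seq.upper().replace("-", "")] = hap_id
                m = re.search(r"(\d+)$", hap_id)
                if m:
                    self._next = max(self._next, int(m.group(1)) + 1)

    def assign(self, seq: str) -> str:
        key = seq.upper().replace("-", "")
        hap_id = self._by_seq.get(key)
        if hap_id is None:
            hap_id = f"{self.prefix}{self._next:02d}"
            self._by_seq[key] = hap_id
            self._next += 1
        return hap_id

    def items(self) -> list[tuple[str, str]]:
        return list(self._by_seq.items())

    def __len__(self) -> int:
        return len(self._by_seq)


def assign_haplotype_ids(
    calls: Sequence[IntronCall],
    registry: HaplotypeRegistry | None = None,
) -> tuple[list[IntronCall], HaplotypeRegistry]:
    """Assign haplotype ids to HAPLOTYPE-status intron calls."""
    registry = registry or HaplotypeRegistry()
    out = []
    for call in calls:
        if call.status is IntronStatus.HAPLOTYPE:
            out.append(replace(call, haplotype_id=registry.assign(call.haplotype_seq)))
        else:
            out.append(call)
    return out, registry


# ---------------------------------------------------------------------------
# Collection-level driver

@dataclass(frozen=True)
class MarkerCall:
    """Per-specimen classification outcome across all markers present."""

    specimen_id: str
    coi: CoiCall | None = None
    tpi: TpiCall | None = None
    intron: IntronCall | None = None


def classify_specimen(
    specimen: SpecimenRecord,
    references: dict[Marker, ReferenceSegment] | None = None,
    *,
    het_run_k: int = 5,
) -> MarkerCall:
    refs = references or DEFAULT_REFERENCES
    coi = tpi = intron = None
    if Marker.COIB in specimen.sequences:
        coi = call_coib(specimen.sequences[Marker.COIB], refs[Marker.COIB])
    if Marker.TPIE4 in specimen.sequences:
        tpi = call_tpie4(specimen.sequences[Marker.TPIE4], refs[Marker.TPIE4])
    if Marker.TPII4 in specimen.sequences:
        intron = call_tpii4(specimen.sequences[Marker.TPII4], refs[Marker.TPII4],
                            het_run_k=het_run_k)
    return MarkerCall(specimen.specimen_id, coi=coi, tpi=tpi, intron=intron)


def classify_collection(
    specimens: Iterable[SpecimenRecord],
    references: dict[Marker, ReferenceSegment] | None = None,
    *,
    registry: HaplotypeRegistry | None = None,
    het_run_k: int = 5,
) -> tuple[list[MarkerCall], HaplotypeRegistry]:
    """Classify every specimen; alignment failures downgrade to UNDETERMINED
    with a warning rather than aborting the whole collection."""
    registry = registry or HaplotypeRegistry()
    refs = references or DEFAULT_REFERENCES
    # identical amplicons are common (shared haplotypes); classify each
    # distinct sequence once
    cache: dict[tuple[Marker, str], CoiCall | TpiCall | IntronCall] = {}

    def cached(marker: Marker, seq: SeqRecord):
        key = (marker, seq.sequence)
        if key not in cache:
            if marker is Marker.COIB:
                cache[key] = call_coib(seq, refs[Marker.COIB])
            elif marker is Marker.TPIE4:
                cache[key] = call_tpie4(seq, refs[Marker.TPIE4])
            else:
                cache[key] = call_tpii4(seq, refs[Marker.TPII4], het_run_k=het_run_k)
        return cache[key]

    calls: list[MarkerCall] = []
    for sp in specimens:
        try:
            call = MarkerCall(
                sp.specimen_id,
                coi=cached(Marker.COIB, sp.sequences[Marker.COIB])
                if Marker.COIB in sp.sequences else None,
                tpi=cached(Marker.TPIE4, sp.sequences[Marker.TPIE4])
                if Marker.TPIE4 in sp.sequences else None,
                intron=cached(Marker.TPII4, sp.sequences[Marker.TPII4])
                if Marker.TPII4 in sp.sequences else None,
            )
        except NotHomologousError as exc:
            logger.warning("specimen %s: %s", sp.specimen_id, exc)
            call = MarkerCall(
                sp.specimen_id,
                coi=CoiCall(CoiValue.UNDETERMINED) if Marker.COIB in sp.sequences else None,
                tpi=TpiCall(TpiValue.UNDETERMINED) if Marker.TPIE4 in sp.sequences else None,
                intron=IntronCall(IntronStatus.UNDETERMINED) if Marker.TPII4 in sp.sequences else None,
            )
        if call.intron is not None and call.intron.status is IntronStatus.HAPLOTYPE:
            call = MarkerCall(
                call.specimen_id, coi=call.coi, tpi=call.tpi,
                intron=replace(call.intron, haplotype_id=registry.assign(call.intron.haplotype_seq)),
            )
        calls.append(call)
    return calls, registry
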