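"""Synthetic specimen collections with known ground truth.

Generates per-marker amplicon FASTA, a sample sheet and a latent-truth
table for multi-population scenarios: strain category frequencies at the
two COIB diagnostic sites, Z-linked exon heterozygotes (TpiH requires two
Z copies, so only males can carry it), and an intron haplotype panel with
substitutions and indels, including heterozygous-frameshift specimens that
are emitted with a sustained ambiguity run after the indel point.

Also ships a deterministic fixture collection whose marginal counts mirror
a published Ecuador survey (492 COIB specimens over three host plants with
exactly four rice-strain exceptions, 7 TpiH among the 153 Manabi hard-corn
Tpi records, and zero TpiR overall).
"""

from __future__ import annotations

import datetime
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .references import COIB_SEQ, TPI_SEQ, TPI_INTRON_WINDOW
from .seqio import Host, Marker, Region, SeqRecord, SpecimenRecord, write_fasta, write_sample_sheet

# COIB site offsets and category -> (base1164, base1287)
_COI_OFFSETS = (240, 363)
COI_BASES = {
    "COI_RS": ("T", "A"),
    "COI_h1": ("A", "A"),
    "COI_h2": ("A", "G"),
    "COI_h3": ("G", "A"),
    "COI_h4": ("G", "G"),
}
TPI_BASES = {"TpiC": "C", "TpiR": "T", "TpiH": "Y"}
_TPI_SITE = 182

_INTRON_START, _INTRON_END = TPI_INTRON_WINDOW
BASE_INTRON = TPI_SEQ[_INTRON_START:_INTRON_END]
_TPI_EXON = TPI_SEQ[:_INTRON_START]
_TPI_LEAD = TPI_SEQ[150:_INTRON_START]   # exon context emitted before the intron
_TPI_TRAIL = TPI_SEQ[_INTRON_END:]       # downstream exon context

_AMBIG_RUN_CODES = "RYSWKMN"


# ---------------------------------------------------------------------------
# Haplotype panels

Edit = tuple  # ("sub", pos, base) | ("ins", pos, seq) | ("del", pos, length)


@dataclass(frozen=True)
class HaplotypePanel:
    """Base sequence plus per-haplotype edit lists (substitutions/indels)."""

    marker: Marker
    base_sequence: str
    variants: dict[str, tuple[Edit, ...]]

    def sequence(self, hap_id: str) -> str:
        return apply_edits(self.base_sequence, self.variants[hap_id])

    def sequences(self) -> dict[str, str]:
        return {h: self.sequence(h) for h in self.variants}

    def registry_seed(self) -> dict[str, str]:
        """seq -> id mapping for pre-seeding a haplotype registry."""
        return {seq: h for h, seq in self.sequences().items()}


def apply_edits(base: str, edits: Sequence[Edit]) -> str:
    seq = base
    for edit in sorted(edits, key=lambda e: e[1], reverse=True):
        kind, pos = edit[0], edit[1]
        if kind == "sub":
            seq = seq[:pos] + edit[2] + seq[pos + 1 :]
        elif kind == "ins":
            seq = seq[:pos] + edit[2] + seq[pos:]
        elif kind == "del":
            seq = seq[:pos] + seq[pos + edit[2] :]
        else:
            raise ValueError(f"unknown edit kind {kind!r}")
    return seq


def build_panel(
    n_haplotypes: int,
    n_substitutions: int = 3,
    n_indels: int = 1,
    seed: int = 0,
    *,
    base_sequence: str = BASE_INTRON,
    marker: Marker = Marker.TPII4,
    prefix: str = "Hap",
    avoid_offsets: Iterable[int] = (),
    boundary_margin: int = 12,
    max_attempts: int = 200,
) -> HaplotypePanel:
    """Build a panel of distinct haplotype variants of a base sequence.

    Deterministic for a fixed seed.  Edits avoid ``avoid_offsets`` (e.g.
    diagnostic sites) and keep ``boundary_margin`` bases at either end
    untouched so anchored extraction recovers variants exactly.  Raises if
    the requested number of distinct haplotypes is unreachable with the
    given edit budget.
    """
    if n_haplotypes < 1:
        raise ValueError("n_haplotypes must be >= 1")
    if n_haplotypes > 1 and n_substitutions == 0 and n_indels == 0:
        raise ValueError("cannot build >1 distinct haplotype with no edits")
    rng = np.random.default_rng(seed)
    avoid = set(avoid_offsets)
    lo, hi = boundary_margin, len(base_sequence) - boundary_margin
    if hi - lo < 10:
        raise ValueError("base sequence too short for the boundary margin")
    variants: dict[str, tuple[Edit, ...]] = {_hap_name(prefix, 1): ()}
    seen = {base_sequence}
    idx = 2
    attempts = 0
    while len(variants) < n_haplotypes:
        edits: list[Edit] = []
        positions = rng.choice(np.arange(lo, hi), size=n_substitutions + n_indels,
                               replace=False)
        for p in sorted(int(x) for x in positions[:n_substitutions]):
            if p in avoid:
                continue
            old = base_sequence[p]
            new = str(rng.choice([b for b in "ACGT" if b != old]))
            edits.append(("sub", p, new))
        for p in sorted(int(x) for x in positions[n_substitutions:]):
            if p in avoid:
                continue
            if rng.random() < 0.5:
                length = int(rng.integers(1, 7))
                ins = "".join(rng.choice(list("ACGT"), size=length))
                edits.append(("ins", p, ins))
            else:
                length = int(min(rng.integers(1, 7), hi - p))
                edits.append(("del", p, length))
        seq = apply_edits(base_sequence, tuple(edits))
        if seq in seen:
            attempts += 1
            if attempts > max_attempts:
                raise ValueError(
                    f"could not reach {n_haplotypes} distinct haplotypes with the "
                    f"given edit budget"
                )
            continue
        seen.add(seq)
        variants[_hap_name(prefix, idx)] = tuple(edits)
        idx += 1
    return HaplotypePanel(marker=marker, base_sequence=base_sequence, variants=variants)


def _hap_name(prefix: str, i: int) -> str:
    return f"{prefix}{i:02d}"


# ---------------------------------------------------------------------------
# Population specs

@dataclass
class PopulationSpec:
    """Sampling recipe for one simulated population."""

    population_id: str
    n: int
    coi_freqs: Mapping[str, float]
    tpi_freqs: Mapping[str, float]
    intron_hap_freqs: Mapping[str, float]
    het_indel_rate: float = 0.0
    male_fraction: float = 0.5
    seed: int = 0
    site_code: str = ""
    province: str = ""
    host: Host = Host.OTHER
    region: Region = Region.OTHER
    date: datetime.date | None = None
    markers: tuple[Marker, ...] = (Marker.COIB, Marker.TPIE4, Marker.TPII4)
    flank_max: int = 10  # random flank length cap for COIB/TpiE4 amplicons

    def validate(self) -> None:
        for name, freqs in (("coi_freqs", self.coi_freqs),
                            ("tpi_freqs", self.tpi_freqs),
                            ("intron_hap_freqs", self.intron_hap_freqs)):
            if freqs and abs(sum(freqs.values()) - 1.0) > 1e-9:
                raise ValueError(f"{name} must sum to 1")
        unknown = set(self.coi_freqs) - set(COI_BASES)
        if unknown:
            raise ValueError(f"unknown COI categories: {sorted(unknown)}")
        unknown = set(self.tpi_freqs) - set(TPI_BASES)
        if unknown:
            raise ValueError(f"unknown Tpi categories: {sorted(unknown)}")
        if self.male_fraction == 0.0 and self.tpi_freqs.get("TpiH", 0.0) > 0.0:
            raise ValueError("TpiH requires males (two Z copies); "
                             "male_fraction is 0")
        if not 0.0 <= self.het_indel_rate <= 1.0:
            raise ValueError("het_indel_rate must be a probability")


@dataclass
class SimulatedCollection:
    """In-memory simulated collection: specimens with attached sequences
    plus the latent truth table."""

    specimens: list[SpecimenRecord]
    truth: pd.DataFrame
    panel: HaplotypePanel | None = None

    def fasta_records(self, marker: Marker) -> list[SeqRecord]:
        return [sp.sequences[marker] for sp in self.specimens if marker in sp.sequences]

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Emit FASTA per marker, sample sheet TSV and truth CSV."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths: dict[str, Path] = {}
        for marker in Marker:
            recs = self.fasta_records(marker)
            if recs:
                p = outdir / f"{marker.value.lower()}.fasta"
                write_fasta(recs, p)
                paths[marker.value] = p
        sheet = outdir / "sample_sheet.tsv"
        write_sample_sheet(self.specimens, sheet)
        paths["sample_sheet"] = sheet
        truth_path = outdir / "truth.csv"
        self.truth.to_csv(truth_path, index=False)
        paths["truth"] = truth_path
        return paths


def _coib_sequence(category: str, rng: np.random.Generator, flank_max: int) -> str:
    b1, b2 = COI_BASES[category]
    seq = COIB_SEQ[: _COI_OFFSETS[0]] + b1 + COIB_SEQ[_COI_OFFSETS[0] + 1 : _COI_OFFSETS[1]] \
        + b2 + COIB_SEQ[_COI_OFFSETS[1] + 1 :]
    return _with_flanks(seq, rng, flank_max)


def _tpie4_sequence(category: str, rng: np.random.Generator, flank_max: int) -> str:
    base = TPI_BASES[category]
    seq = _TPI_EXON[:_TPI_SITE] + base + _TPI_EXON[_TPI_SITE + 1 :]
    return _with_flanks(seq, rng, flank_max)


def _tpii4_sequence(intron: str) -> str:
    return _TPI_LEAD + intron + _TPI_TRAIL


def _with_flanks(seq: str, rng: np.random.Generator, flank_max: int) -> str:
    if flank_max <= 0:
        return seq
    left = int(rng.integers(0, flank_max + 1))
    right = int(rng.integers(0, flank_max + 1))
    lf = "".join(rng.choice(list("ACGT"), size=left)) if left else ""
    rf = "".join(rng.choice(list("ACGT"), size=right)) if right else ""
    return lf + seq + rf


def _het_indel_intron(intron: str, rng: np.random.Generator) -> str:
    """Emit a heterozygous-frameshift read: a sustained ambiguity run
    (length uniform in [10, 40]) starting at the indel point."""
    p = int(rng.integers(10, max(11, len(intron) - 45)))
    run_len = int(rng.integers(10, 41))
    run = "".join(rng.choice(list(_AMBIG_RUN_CODES), size=run_len))
    return intron[:p] + run + intron[p + run_len :] if p + run_len <= len(intron) \
        else intron[:p] + run


def simulate_population(
    spec: PopulationSpec,
    panel: HaplotypePanel,
    *,
    id_start: int = 1,
    id_prefix: str = "SIM",
) -> SimulatedCollection:
    """Draw one population's specimens independently from the spec.

    Every latent draw (sex, COI category, Tpi genotype, intron haplotype,
    het-indel flag) is recorded in the truth table.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    coi_cats = sorted(spec.coi_freqs)
    tpi_cats = sorted(spec.tpi_freqs)
    hap_ids = sorted(spec.intron_hap_freqs)
    specimens: list[SpecimenRecord] = []
    truth_rows = []
    for i in range(spec.n):
        sid = f"{id_prefix}{id_start + i:05d}"
        sex = "M" if rng.random() < spec.male_fraction else "F"
        coi_cat = str(rng.choice(coi_cats, p=[spec.coi_freqs[c] for c in coi_cats])) \
            if coi_cats else ""
        tpi_cat = str(rng.choice(tpi_cats, p=[spec.tpi_freqs[c] for c in tpi_cats])) \
            if tpi_cats else ""
        if tpi_cat == "TpiH":
            sex = "M"  # heterozygotes need two Z copies
        hap_id = str(rng.choice(hap_ids, p=[spec.intron_hap_freqs[h] for h in hap_ids])) \
            if hap_ids else ""
        het_indel = bool(sex == "M" and hap_id and rng.random() < spec.het_indel_rate)
        sequences: dict[Marker, SeqRecord] = {}
        if Marker.COIB in spec.markers and coi_cat:
            sequences[Marker.COIB] = SeqRecord(
                sid, _coib_sequence(coi_cat, rng, spec.flank_max), Marker.COIB)
        if Marker.TPIE4 in spec.markers and tpi_cat:
            sequences[Marker.TPIE4] = SeqRecord(
                sid, _tpie4_sequence(tpi_cat, rng, spec.flank_max), Marker.TPIE4)
        if Marker.TPII4 in spec.markers and hap_id:
            intron = panel.sequence(hap_id)
            if het_indel:
                intron = _het_indel_intron(intron, rng)
            sequences[Marker.TPII4] = SeqRecord(
                sid, _tpii4_sequence(intron), Marker.TPII4)
        specimens.append(SpecimenRecord(
            specimen_id=sid, site_code=spec.site_code, province=spec.province,
            host=spec.host, region=spec.region, date=spec.date, sex=sex,
            sequences=sequences,
        ))
        truth_rows.append({
            "specimen_id": sid, "population_id": spec.population_id, "sex": sex,
            "coi_truth": coi_cat, "tpi_truth": tpi_cat,
            "intron_hap_truth": hap_id, "het_indel": het_indel,
        })
    return SimulatedCollection(specimens, pd.DataFrame(truth_rows), panel)


def simulate_collection(
    specs: Sequence[PopulationSpec],
    panel: HaplotypePanel,
    *,
    id_prefix: str = "SIM",
) -> SimulatedCollection:
    """Simulate several populations into one collection (ids sequential)."""
    parts = []
    start = 1
    for spec in specs:
        part = simulate_population(spec, panel, id_start=start, id_prefix=id_prefix)
        parts.append(part)
        start += spec.n
    specimens = [sp for p in parts for sp in p.specimens]
    truth = pd.concat([p.truth for p in parts], ignore_index=True)
    return SimulatedCollection(specimens, truth, panel)


# ---------------------------------------------------------------------------
# Deterministic fixture

ECUADOR_PANEL_SEED = 20180301
_FIXTURE_SEED = 492153

#: (group key, province, site_code, host, region, n_coib, n_tpi, n_intron,
#:  n_het_indel, has_coi_rs)
_FIXTURE_GROUPS = (
    ("a", "Azuay", "a", Host.SOFT_CORN, Region.ANDES, 28, 22, 12, 0, True),
    ("b", "Bolivar", "b", Host.SOFT_CORN, Region.ANDES, 22, 17, 10, 0, False),
    ("c", "Imbabura", "c1", Host.SOFT_CORN, Region.ANDES, 28, 22, 13, 0, True),
    ("d", "Loja", "d1", Host.HARD_CORN, Region.ANDES, 40, 30, 20, 3, True),
    ("e", "Manabi", "e", Host.HARD_CORN, Region.COAST, 160, 153, 110, 20, False),
    ("f", "Morona-Santiago", "f1", Host.HARD_CORN, Region.AMAZON, 30, 25, 15, 3, False),
    ("g", "Napo", "g", Host.HARD_CORN, Region.AMAZON, 25, 14, 10, 2, False),
    ("h", "Sucumbios", "h1", Host.HARD_CORN, Region.AMAZON, 35, 20, 15, 3, True),
    ("i", "Guayas", "i1", Host.RICE, Region.COAST, 60, 62, 38, 6, False),
    ("j", "Loja", "j1", Host.RICE, Region.ANDES, 30, 31, 20, 2, False),
    ("k", "Manabi", "k", Host.RICE, Region.COAST, 34, 35, 22, 2, False),
)

_H2_FRACTION = {Host.SOFT_CORN: 0.88, Host.HARD_CORN: 0.75, Host.RICE: 0.81}
_MANABI_HARDCORN_TPIH = 7

#: Intron haplotype frequencies for the fixture: hap 02 dominant, hap 13
#: second, four rare haplotypes (01, 05, 06, 15) jointly < 4%.
_FIXTURE_HAP_FREQS = {
    "Ecu01": 0.008, "Ecu02": 0.33, "Ecu03": 0.05, "Ecu04": 0.05,
    "Ecu05": 0.008, "Ecu06": 0.008, "Ecu07": 0.05, "Ecu08": 0.05,
    "Ecu09": 0.05, "Ecu10": 0.05, "Ecu11": 0.05, "Ecu12": 0.05,
    "Ecu13": 0.20, "Ecu14": 0.04, "Ecu15": 0.006,
}


def ecuador_panel() -> HaplotypePanel:
    """The 15-haplotype intron fixture panel (Ecu01-Ecu15)."""
    return build_panel(15, n_substitutions=4, n_indels=1,
                       seed=ECUADOR_PANEL_SEED, prefix="Ecu")


def _largest_remainder(total: int, fracs: Sequence[float]) -> list[int]:
    raw = [total * f for f in fracs]
    out = [int(x) for x in raw]
    rem = total - sum(out)
    order = sorted(range(len(raw)), key=lambda i: (-(raw[i] - out[i]), i))
    for i in order[:rem]:
        out[i] += 1
    return out


def ecuador_fixture() -> SimulatedCollection:
    """Deterministic collection reproducing the survey's marginal counts.

    492 COIB specimens split 78/290/124 across soft corn/hard corn/rice
    with exactly four COI_RS (one each in provinces a, c, d and h); 431
    TpiE4 specimens split 61/242/128 with 7 TpiH among the 153 Manabi
    hard-corn records and zero TpiR; 285 TpiI4 records of which 41 are
    heterozygous-frameshift (excluded downstream), leaving 244 analyzable
    intron sequences over the Ecu01-Ecu15 panel.
    """
    panel = ecuador_panel()
    rng = np.random.default_rng(_FIXTURE_SEED)
    hap_ids = list(_FIXTURE_HAP_FREQS)
    hap_p = np.array([_FIXTURE_HAP_FREQS[h] for h in hap_ids])
    hap_p = hap_p / hap_p.sum()

    specimens: list[SpecimenRecord] = []
    truth_rows = []
    next_id = 1
    for (key, province, site_code, host, region,
         n_coib, n_tpi, n_intron, n_het, has_rs) in _FIXTURE_GROUPS:
        n_specimens = max(n_coib, n_tpi)
        # exact COI category counts: optional single RS, CS split h1..h4
        n_cs = n_coib - (1 if has_rs else 0)
        n_h2 = round(_H2_FRACTION[host] * n_cs)
        n_h1, n_h3, n_h4 = _largest_remainder(n_cs - n_h2, (0.5, 0.3, 0.2))
        coi_pool = (["COI_RS"] if has_rs else []) + ["COI_h2"] * n_h2 + \
            ["COI_h1"] * n_h1 + ["COI_h3"] * n_h3 + ["COI_h4"] * n_h4
        rng.shuffle(coi_pool)
        # exact Tpi category counts: TpiH only in the Manabi hard-corn group
        n_tpih = _MANABI_HARDCORN_TPIH if (province, host) == ("Manabi", Host.HARD_CORN) else 0
        tpi_pool = ["TpiH"] * n_tpih + ["TpiC"] * (n_tpi - n_tpih)
        rng.shuffle(tpi_pool)
        het_flags = [True] * n_het + [False] * (n_intron - n_het)
        rng.shuffle(het_flags)
        for i in range(n_specimens):
            sid = f"EC{next_id:04d}"
            next_id += 1
            coi_cat = coi_pool[i] if i < n_coib else ""
            tpi_cat = tpi_pool[i] if i < n_tpi else ""
            hap_id = str(rng.choice(hap_ids, p=hap_p)) if i < n_intron else ""
            het_indel = het_flags[i] if i < n_intron else False
            sex = "M" if (tpi_cat == "TpiH" or het_indel or rng.random() < 0.5) else "F"
            sequences: dict[Marker, SeqRecord] = {}
            if coi_cat:
                sequences[Marker.COIB] = SeqRecord(
                    sid, _coib_sequence(coi_cat, rng, 10), Marker.COIB)
            if tpi_cat:
                sequences[Marker.TPIE4] = SeqRecord(
                    sid, _tpie4_sequence(tpi_cat, rng, 10), Marker.TPIE4)
            if hap_id:
                intron = panel.sequence(hap_id)
                if het_indel:
                    intron = _het_indel_intron(intron, rng)
                sequences[Marker.TPII4] = SeqRecord(
                    sid, _tpii4_sequence(intron), Marker.TPII4)
            specimens.append(SpecimenRecord(
                specimen_id=sid, site_code=site_code, province=province,
                host=host, region=region, date=None, sex=sex, sequences=sequences))
            truth_rows.append({
                "specimen_id": sid, "population_id": key, "sex": sex,
                "coi_truth": coi_cat, "tpi_truth": tpi_cat,
                "intron_hap_truth": hap_id if not het_indel else "",
                "het_indel": het_indel,
            })
    return SimulatedCollection(specimens, pd.DataFrame(truth_rows), panel)
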