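# fawmarkers

Marker-based strain typing and population comparison for fall armyworm
(*Spodoptera frugiperda*) amplicon panels.

The package classifies per-specimen amplicon sequences from three marker
segments into strain/haplotype categories and compares populations:

- **COIB** (mitochondrial COI segment, ~380 bp): the base pair at two
  diagnostic sites distinguishes the rice-strain configuration (T, A) from
  the four corn-strain haplotypes h1–h4 (A/G at both sites).
- **TpiE4** (Z-linked Tpi exon segment): C at the exon strain site → TpiC,
  T → TpiR, the C/T overlap code Y → TpiH (a heterozygous male; Tpi is
  Z-linked, so only ZZ males can carry two alleles).
- **TpiI4** (~172 bp Tpi intron): fine-scale haplotyping with
  substitution/indel variants; specimens heterozygous for an intron
  frameshift are detected as a sustained run of ambiguity codes (≥ 5 by
  default) and excluded from haplotype analysis.

Downstream analyses: per-population haplotype frequency profiles with
Pearson profile correlation and one-way ANOVA; haplotype diversity (Hd),
nucleotide diversity (Pi) and Hudson-style pairwise Fst
(1 − π_within/π_between, which can be slightly negative by sampling); and
a TN93 + neighbor-joining phylogeny of unique intron haplotypes with
Newick export.

Queries are placed onto bundled reference segments by anchored alignment
(exact-anchor scan with a semi-global affine-gap fallback, reverse
complement retried automatically), so amplicon trimming and flanking bases
never shift a call. The bundled references are synthetic stand-ins
carrying the diagnostic sites at the documented spacings; real references
can be swapped in via `fawmarkers.references.load_references` (FASTA +
sites TSV).

A synthetic-data module generates multi-population collections with known
ground truth — strain frequencies, Z-linked heterozygotes, intron
substitution/indel structure, heterozygous-frameshift reads — so every
stage is testable end to end, plus a deterministic fixture collection
whose marginal counts mirror a published Ecuador survey (492 COIB
specimens with four rice-strain exceptions, 7 TpiH among 153 Manabi
hard-corn Tpi records, 285 intron records of which 41 are
frameshift-excluded).

## CLI

```sh
# full pipeline on the bundled deterministic fixture
fawmarkers all --out out/ --seed 1

# simulate a custom scenario, then run stage by stage
fawmarkers simulate --config scenario.yaml --out sim/
fawmarkers classify --coib sim/coib.fasta --tpie4 sim/tpie4.fasta \
    --tpii4 sim/tpii4.fasta --sheet sim/sample_sheet.tsv --out out/
fawmarkers profile   --calls out/calls.csv --out out/ --group-by host
fawmarkers diversity --calls out/calls.csv --out out/ --group-by region
fawmarkers tree      --calls out/calls.csv --out out/
fawmarkers report    --out out/
```

Outputs are plain text (FASTA, TSV, CSV, Newick, JSON); the same config
and seed always produce byte-identical files. `out/calls.csv` is the
central intermediate — every number in `report.json` is recomputable from
it.

A scenario config is YAML (or JSON) with an intron haplotype `panel`
section and a list of `populations`, each giving `n`, category frequency
maps (`coi_freqs`, `tpi_freqs`, `intron_hap_freqs`), `het_indel_rate`,
`male_fraction`, a `seed` and sample-sheet metadata; see
`tests/test_cli.py` for a worked example.

## Layout

- `src/fawmarkers/seqio.py` — FASTA / sample-sheet I/O and validation
- `src/fawmarkers/references.py` — bundled reference segments + site map
- `src/fawmarkers/marker_typing.py` — anchored alignment and per-marker
  classifiers, haplotype registry
- `src/fawmarkers/profiles.py` — frequency profiles, Pearson, ANOVA
- `src/fawmarkers/popgen_stats.py` — Hd, Pi, pairwise Fst
- `src/fawmarkers/phylo.py` — TN93 distances, neighbor joining, Newick
- `src/fawmarkers/synthetic_data.py` — simulator and fixture collection
- `src/fawmarkers/cli.py` — the `fawmarkers` command
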