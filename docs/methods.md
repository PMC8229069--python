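# Methods

## The data being modelled

Each accession contributes one Sanger-derived consensus per satDNA family
(CON1, CON2, COM2), obtained by PCR amplification of a monomer fragment.
Within-amplicon variation — whether allelic heterozygosity or variation among
tandem monomer copies in one genome — appears in the consensus as IUPAC
ambiguity codes. The package deliberately treats a call purely as an
*ambiguity state* (a set of 1–4 bases) and attaches no biological
interpretation to "heterozygous": the distinction it preserves is the size of
the base set (1 = homozygous, 2 = heterozygous, 3 = triplet, 4/gap = missing)
and its relation to the reference allele.

## IUPAC algebra and zygosity

`base_set`/`encode_set` implement the bijection between the 15 IUPAC codes and
the nonempty subsets of {A,C,G,T}. Zygosity relative to a canonical reference
base r follows the state table: {r} → HOM_REF; other singleton → HOM_ALT;
two-base set containing r → HET_WITH_REF; two-base set excluding r →
HET_ALT_ONLY; three-base set → HET3; N or gap → MISSING. `U` is accepted and
mapped to `T` with a warning (everything runs in DNA space); gap and N both
map to MISSING because neither asserts a base call.

The reference consensus may itself be heterozygous at a column (the CON2
reference is, at five of its eight alteration columns). Where a single
canonical "reference base" is needed — zygosity labels in reports — the
convention is the alphabetically first base of the reference state's base
set. This is a labelling convention only; all detection and distance
computations compare full base sets.

## Alignment and homology

Samples are aligned to the family reference with a three-state (Gotoh)
affine-gap dynamic programme in **free-end-gap** (semi-global) mode: terminal
gaps in either sequence cost nothing. Monomer fragments are near-full-length
copies of the reference, so this recovers the alignable core exactly while
letting primer flanks and ragged ends overhang freely; it is deterministic
and avoids the heuristics of local search.

Scoring defaults: match +1, mismatch −1, gap open −2 (charged on the first
column of a gap), gap extension −0.5 (each further column). Two states score
as a match when their base sets intersect, so heterozygous consensus calls
are not penalized against a reference allele they contain. Determinism: the
traceback prefers diagonal over up (gap in reference) over left (gap in
sample), closes gaps as early as possible, and among tied end cells takes the
bottom-row cell consuming the longest reference prefix. All default scores
are exactly representable in binary floating point, so ties are exact;
comparisons nevertheless use a 1e-9 tolerance so user-supplied scores behave.

**Homologous region**: initially the reference interval covered by the sample
(0-based, half-open). `trim_homologous_region` narrows it either (a) exactly,
when flank lengths are known (for simulated data the truth table supplies
them), or (b) adaptively, dropping terminal columns while the terminal
10-column window has identity below 0.5 — a rule aimed at non-homologous
primer tails, which align at ≈25% identity by chance. Identity, and the
integer **percent homology** (rounded half up, matching the whole-percent
granularity such homology figures are reported at), are computed over
homologous-region columns only. The published homology figures for the real
accessions came from BLAST HSPs of undeposited sequences, so they are not
reproducible quantities; this package defines homology over the trimmed
homologous region and documents that difference rather than emulating BLAST.

**Anchored MSA**: each pairwise alignment is projected onto reference
coordinates. Sample insertions relative to the reference are dropped from the
matrix and counted in the log — alteration columns are positions *of the
reference*, and no insertion alterations are part of the profile model.
Deletions appear as missing cells inside the coverage mask.

## Alteration columns and profiles

A column is an alteration column when at least one covered, non-missing
sample state has a base set different from the reference state's base set.
MISSING never triggers a column. A HET_WITH_REF state (set ⊋ {ref allele}) is
an alteration — the set differs even though it contains the reference allele.
Adjacent alteration positions are reported as separate columns (and logged);
column indices are 1-based in reading order, positions 0-based on the
reference. The profile matrix serializes to TSV (comment lines carry family
and reference id; the header row carries reference positions; cells are IUPAC
codes) and to JSON with full zygosity annotations; the TSV round-trips
exactly.

## Grouping and schematic trees

At tolerance 0 (the default and the analysis mode) groups are equivalence
classes of exact profile equality, reported in order of first-appearing
member; the reference row is not a sample. A positive tolerance (first-fit
with a complete-linkage admission test) is exposed for exploration only.

Profile distance is the columnwise mean, over columns where both profiles
assert a call, of the Jaccard distance between base sets. On missing-free
profiles it is a metric (the mean of per-column metrics). Trees are built by
UPGMA: merge the closest pair, node height = half the merge distance,
distances updated by size-weighted averages, giving an ultrametric tree whose
heights are non-decreasing rootward. No algorithm was stated for the original
schematic trees; UPGMA was chosen because it deterministically produces
exactly this style of ultrametric profile-similarity dendrogram. Tie-break:
among equally close pairs, merge the pair whose lexicographically smallest
member label is smallest. Newick output quotes labels containing spaces and
round-trips through standard parsers to 1e-9 in branch length.

## Synthetic generator

The generator defines the study conditions the package is tested under:

- **Fragment lengths** 333/538/322 bp (CON1/CON2/COM2) — the published PCR
  product lengths.
- **Reference**: seeded pseudo-random canonical bases, with each planted
  column's reference state (homozygous allele or two-base code) substituted.
- **Planted columns**: position, reference allele r, alternative allele a,
  optional third allele, and a per-accession state name (`ref`, `hom_ref`,
  `hom_alt`, `het`, `het_alt`, `het3`). One shared alternative allele per
  column across groups, so zygosity — not allele identity — drives the
  grouping; that is exactly what is provable from the published description.
  Alleles are chosen with r < a alphabetically so the nominal-reference-base
  convention recovers r.
- **Flanks**: optional; default material is the one primer pair printed in
  the source protocol (COM1_F1 forward, reverse complement of COM1_R1),
  attached outside the homologous core.
- **Noise**: background substitution and indel rates default to 0 (the worked
  example is exact); when enabled, noise never lands on planted columns, so
  truth tables remain exact.
- Determinism: every random draw flows from the config seed through named
  substreams (one per accession), so identical configs give byte-identical
  FASTA and truth tables.

### Fixtures

- **CON2** (packaged TSV + JSON): the fully text-reconstructable worked
  example — 8 columns × 13 accessions, reference heterozygous at columns
  {1,3,4,5,8} and homozygous at {2,6,7}; group 1 = reference except
  heterozygous at column 2; group 2 homozygous-alternative at {1,3,4,5,8} and
  heterozygous at {6,7}; group 3 all homozygous; group 4 heterozygous at {6}
  only. This reproduces every published match/difference count (1 difference
  for group 1; 1 match for group 2; 3 matches for group 3; 2 matches and 6
  differences for group 4). Base identities and column positions are **not**
  recoverable from text; positions are evenly spaced placeholders and alleles
  a fixed convention, flagged as synthetic in the packaged JSON.
- **CON1-style**: 11 columns over the same 13-accession panel; the three
  *D. antarctica* accessions and *D. parvula* share a profile except one extra
  alteration in KEW-0521613; the other nine accessions are pairwise unique;
  *D. sukatschewii*, *D. cespitosa* PI-371724, *D. cespitosa* PI-562652 and
  *H. pubescens* carry triplet (three-base) states. Everything beyond those
  published statements is synthetic convention.
- **COM2-style**: 9 columns over the six accessions with clean COM2
  amplicons, all profiles unique — again the published column count and
  uniqueness statement with synthetic detail.
- The CON2 grouping covers 13 named samples although 14 accessions were
  studied (*T. phleoides* is absent from the published CON2 grouping); the
  fixture uses exactly the 13 named samples.

### What the generator does not emulate

Chromatogram-level noise, PCR artefacts, basecalling errors correlated along
the read, multi-band amplicons, and the actual CON/COM sequences (which are
not printed in the text). Passing tests therefore demonstrate that the
pipeline recovers planted alteration structure exactly under the published
fragment geometry and zygosity patterns — not that it would reproduce
base-level results on the original, undeposited traces.

## Pipeline

A run configuration (YAML or JSON; unknown keys rejected) names one input
block (FASTA + reference) or one simulate block per family. Per-family seeds
are derived from the single run seed via SHA-256 of `"{seed}:{family}"`, so
module-level tests and pipeline runs agree and reruns are byte-identical.
All families are computed in memory before any artifact is written, so a
failing run leaves no partial outputs. Emitted per family: samples/reference
FASTA and truth table (simulated inputs), anchored-MSA FASTA, profile
TSV/JSON, groups JSON, Newick tree; plus `report.json` (every number
recomputable from the artifacts) and `run.log` (one line per dropped
insertion, trimmed flank, and group merge).

## Problem sizes and tolerances

The shipped analyses run 13 samples × ≤538 bp per family (≈25 ms per
alignment); the exhaustive-enumeration alignment oracle in the test suite
covers sequence pairs up to length 8, where all ~2.7 × 10⁵ gapped alignments
of an 8×8 pair are enumerable. Floating-point comparisons in tree and
distance code use absolute tolerances of 1e-9 to 1e-12; alignment scores
under the default scheme are exact in binary floating point.

## Known limitations

- Homology percentages are alignment-identity figures, not BLAST HSP
  statistics; on real, diverged material the two can differ.
- Insertion alterations are not typed; samples with large structural
  differences from the reference will lose those regions from the profile.
- The adaptive trim rule assumes flanks are non-homologous; flanks that
  partially match the reference should be trimmed by explicit lengths.
- UPGMA assumes rate-uniform divergence of profiles; the schematic tree is a
  similarity summary, and no support values are computed.
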