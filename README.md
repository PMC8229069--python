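# satprofile

Alteration-profile analysis of satellite-DNA monomer consensi.

Satellite DNAs (satDNA) are tandemly repeated sequences whose monomers evolve
in near-identical arrays. When a monomer family (here the CON1/CON2/COM2
families of the grass tribe Aveneae/Poeae, shared across *Deschampsia* and
related genera) is PCR-amplified from different accessions and Sanger
sequenced, each accession yields one consensus sequence in which variable
positions appear as IUPAC ambiguity codes: a single base is a *homozygous*
state, a two-base code a *heterozygous* state, a three-base code a *triplet*
state. `satprofile` turns a set of such consensi plus a family reference
monomer into:

1. **Percent homology** per accession, from ambiguity-aware free-end-gap
   (semi-global) pairwise alignment — two states count as identical when their
   base sets intersect, so a heterozygous call is never penalized against the
   reference allele it contains.
2. **Alteration columns** — reference positions where at least one accession's
   base set differs from the reference state's base set — each annotated with
   every sample's state and zygosity (HOM_REF, HOM_ALT, HET_WITH_REF,
   HET_ALT_ONLY, HET3, MISSING).
3. **Profile groups** — equivalence classes of accessions with identical
   alteration profiles.
4. **Schematic trees** — UPGMA dendrograms over the profile distance
   d(p, q) = mean over shared columns of the Jaccard distance
   1 − |B₁∩B₂|/|B₁∪B₂| between IUPAC base sets; ultrametric summaries of
   profile similarity, not model-based phylogenies.

Because the original accession sequences are not publicly deposited, the
package ships a seeded synthetic generator that emulates the study conditions
(fragment lengths 333/538/322 bp for CON1/CON2/COM2, primer flanks, planted
column states) together with a packaged fixture encoding the fully
text-specified CON2 worked example: 8 alteration columns over 13 accessions
falling into four groups of sizes 4/6/2/1.

Intended users: plant cytogeneticists and repeat-genomics researchers who want
a reproducible, scriptable version of this consensus-profiling workflow.

## Worked example

```
python examples/03_con2_worked_example.py
```

prints

```
8 alteration columns at reference positions [59, 119, 179, 239, 299, 358, 418, 478]
reference profile: R C M K W C A Y

group 1 (4 samples): R Y M K W C A Y
    D. antarctica KEW-0522816
    D. antarctica KEW-0661919
    D. antarctica KEW-0521613
    D. parvula
group 2 (6 samples): G C C T T S R T
    ...
```

The reference CON2 consensus is heterozygous at columns 1, 3, 4, 5, 8
(codes R/M/K/W/Y) and homozygous at columns 2, 6, 7. Group 1 (the three
*D. antarctica* accessions and *D. parvula*) differs from the reference at a
single column — column 2 is heterozygous (Y = C/T) where the reference is
homozygous C — while group 4 (*D. danthonioides*) differs at six of the eight
columns. In the UPGMA schematic tree (`examples/04_schematic_tree.py`) the
four group-1 accessions form one clade.

The same analysis is available from the shell:

```
satprofile run --config cfg.yaml          # full pipeline, all families
satprofile simulate --fixture con2 --seed 1 --out sim
satprofile align --fasta sim_samples.fasta --reference sim_reference.fasta --out msa.fasta
satprofile profile --msa msa.fasta --family CON2 --out profile.tsv
satprofile group --profile profile.tsv --out groups.json
satprofile tree --profile profile.tsv --out tree.nwk
```

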