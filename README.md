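# mhcgraft

Fixed-backbone design of **chimeric MHC class I molecules**: graft the
peptide-binding groove of one HLA allotype (the *template* or *groove*
allele) onto the framework of another (the *base* allele), so that the
chimera presents the template's peptide while keeping the base allele's
T-cell-receptor (TCR) interaction surface.

Chimeric HLAs of this kind are screening probes for peptide-centric
receptors (TCR-mimic antibodies, CARs) and tools for dissecting how much of
TCR recognition rides on HLA framework residues rather than on the peptide
itself. This package implements the computational side of that workflow as
a tested library plus a CLI, with deterministic synthetic fixtures so every
stage runs and is verifiable without any structure downloads.

## The method

1. **Surface classification.** Over a collection of pMHC-I structures, a
   heavy-chain position *P* (within the first 180 residues, the α1/α2
   domains) is a *peptide contact* in one structure when its minimum
   heavy-atom distance to the peptide is ≤ 4 Å; the peptide-contact
   frequency is the percentage of structures where that holds, and likewise
   for TCR contacts over pMHC–TCR structures. Positions classify as
   **PB** (peptide-only binding), **TB** (TCR-only) or **PTB** (dual) with a
   10 % frequency cutoff; per-position consensus (modal-residue frequency
   over an allele family) and variability = 100 − consensus flag which
   positions tolerate substitution.
2. **Groove grafting.** The template structure is preprocessed (α1/α2 +
   peptide retained, renumbered from 1), the groove is the set of positions
   within 5 Å of a peptide heavy atom, and a global pairwise alignment
   (BLOSUM62, gap 10/0.5) maps template positions onto the base allele.
   Every groove position where the alleles differ yields a substitution,
   written `G62Q`-style in base-allele numbering.
3. **Exhaustive combinatorial sampling.** All 2^N substitution subsets
   (N = 9 → 512 variants) are threaded onto the fixed template backbone and
   scored with a deterministic contact potential over side-chain centers
   (Cβ; Cα for Gly). Variants rank by peptide:MHC binding energy; the
   **enrichment score** of a substitution is the fraction of the top 2.5 %
   lowest-energy variants carrying it.
4. **Minimal set.** A substitution survives iff it changes chemical
   character (charged ↔ neutral — always kept) or its enrichment reaches
   θ = 0.5, and, at PTB positions, only if it has a peptide heavy-atom
   contact within a stricter 3.5 Å.
5. **Reporting.** Peptide-specificity summaries (PSSM + Shannon
   information content, in bits) from a binder list, and a neighbor-joining
   tree over TCR-contact residues (p-distance) for choosing maximally
   dissimilar base frameworks.

The scoring stand-in is intentionally simple and fully deterministic; an
adapter contract (`mhcgraft.energy.ExternalScorer`) plugs any external
per-variant scorer into the identical pipeline. See `docs/methods.md` for
the model, its assumptions and its limits.

## Worked example

Generate the bundled miniature design problem (a 20-residue groove trace
presenting the 9-mer `GGGGGGGGK`; the Lys anchor pocket is Asp in the
groove allele, Ser in the base, plus one decoy difference outside the
interaction shell), then design, sample and prune:

```sh
$ mhcgraft fixtures --scenario design --seed 7 --out-dir fx
wrote fixtures to fx
$ mhcgraft design --template fx/template.pdb --groove-seq groove.fasta \
    --base-seq base.fasta --span 20 --out design.json
2 groove positions, 2 substitutions (A4V,S16D)
$ mhcgraft sample --template fx/template.pdb --base-seq base.fasta \
    --subs "A4V,S16D" --span 20 --out-dir sample
4 variants, pool 1; wrote sample
$ cat sample/enrichment.tsv
position  from  to  enrichment
4         A     V   0.000000
16        S     D   1.000000
$ head -4 sample/ranked.tsv
mask_hex  substitutions_applied  E_bind     E_total
2         S16D                   -2.000000  -2.000000
3         A4V,S16D               -2.000000  -2.000000
0         -                      -0.500000  -0.500000
$ mhcgraft minimal-set --subs "A4V,S16D" --enrichment sample/enrichment.tsv
S16D
```

Reading the numbers: both variants carrying `S16D` score −2.0 (the
introduced Asp forms the charge-complementary contact with the peptide's
Lys anchor; Ser gives only −0.5), so `S16D` appears in 100 % of the
top-energy pool (enrichment 1.0) while the energetically inert decoy `A4V`
appears in none — and the minimal set is exactly the anchor substitution.
Energy units are arbitrary; only the ranking matters.

`mhcgraft run --config run.yaml` executes the whole workflow
(preprocess → groove → align → substitutions → enumerate → score → enrich →
minimal set) into a run directory where every artifact carries the
configuration hash; a rerun with the same configuration is bit-identical.

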