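# Methods

This note documents the models and procedures implemented in `mhcgraft`,
the parameters that matter, the design choices made where the design was
genuinely open, and what the synthetic fixtures do and do not demonstrate.

## Scope and model

MHC class I molecules present 8–15-mer peptides in a groove formed by the
α1/α2 domains (the first ~180 residues of the mature heavy chain); TCRs
read out both the peptide and polymorphic heavy-chain "framework"
residues. The package designs *chimeric* class I molecules: starting from
the structure of a template allele bound to a desired peptide and the
sequence of a base allele, it transfers the template's peptide-binding
groove onto the base by substitution, under a fixed-backbone assumption —
the template backbone (and the peptide conformation observed in it) is
never moved; only residue identities change.

### Surface classification

For each groove position `p` (1..180 after renumbering), the
peptide-contact frequency is the percentage of structures in a collection
where the minimum heavy-atom distance between residue `p` and the peptide
is ≤ 4 Å; the TCR-contact frequency is defined analogously over pMHC–TCR
complexes. Classification with cutoff `c = 10 %`:

- **PTB** if both frequencies exceed `c`;
- **PB** / **TB** if only the peptide / TCR surface is engaged
  (nonzero frequency on one side, the other below `c`);
- when both frequencies are positive but below `c`, the larger one decides
  (exact ties go to PB — peptide binding is the design target, and the
  choice is exposed as a parameter);
- a frequency exactly at the cutoff blocks the "-only" labels and falls
  through to the larger-frequency rule;
- `(0, 0)` is unclassified.

The rule is total over `[0, 100]²` (property-tested on a grid). Residues
disordered in a given structure count as non-contacting in that structure,
keeping the denominator constant across positions; this is a choice, not a
necessity, and is documented here because collections with systematic
disorder would bias frequencies downward.

Consensus at a position is the percentage frequency of the modal residue
across an allele family mapped onto a reference frame by pairwise global
alignment (gaps excluded from the denominator; modal ties break
alphabetically); variability is `100 − consensus`. Reference-anchored
pairwise mapping replaces a full multiple alignment: class I α1/α2 domains
are indel-free in practice, so the two coincide there, and the output is
indexed in reference coordinates either way.

### Groove definition and substitution construction

The groove of a processed template is the set of positions whose minimum
heavy-atom distance to the peptide is ≤ 5 Å. Minimum distances are
recorded for *all* positions so the stricter 3.5 Å rule (below) needs no
recomputation. Template and base alleles are aligned globally with
BLOSUM62, gap open 10, extension 0.5, free end gaps — the defaults of the
standard Needleman–Wunsch web tool this mirrors. (Our aligner charges
`open + (L−1)·extend` for a gap of length `L` rather than
`open + L·extend`; for these indel-free domains the distinction never
materializes, and determinism, not a particular gap model, is what the
workflow needs.) Each groove position where the mapped residues differ
yields a substitution reported in base-allele numbering (`G62Q` style);
positions opposite an alignment gap are skipped with a warning. Each
substitution also carries its template-frame position for threading; the
two coincide in the absence of indels.

### Energy model

The published workflows in this space delegate variant evaluation to an
external all-atom suite (threading, restrained relaxation, interface
analysis). This package instead ships a deterministic, desk-scale
statistical contact potential — deliberately simple, fully testable, and
replaceable. **This is the package's single largest simplification**; the
`ExternalScorer` adapter contract preserves the pipeline unchanged for
users with an all-atom scorer installed (one executable call per variant,
JSON out, per-variant failures recorded without aborting the run).

- **Interaction centers.** One per residue: the Cβ coordinate; Cα for
  glycine; when Cβ is absent it is rebuilt from N/Cα/C with bond 1.53 Å and
  tetrahedral angles of 110.5°, on the L-configuration side of the backbone
  plane. Centers derive from template geometry only, so they are identical
  across all variants (fixed backbone): a variant differing only outside
  the contact shell has *exactly* the base's binding energy (tested).
- **Pair potential.** Residues fall into five classes: positive {K,R,H},
  negative {D,E}, polar {S,T,N,Q,Y,C}, hydrophobic {A,V,L,I,M,F,W},
  special {G,P}. Pairs within 8 Å of center distance score by a symmetric
  class matrix: opposite charges −2.0, like charges +2.0,
  hydrophobic–hydrophobic −1.0, polar–polar and polar–charged −0.5,
  hydrophobic–charged +0.5, everything involving the special class and
  hydrophobic–polar 0. Centers closer than 3 Å add a +10 clash penalty.
  Nonstandard residues ('X', e.g. photolabile positions) are retained
  geometrically but score zero everywhere. Units are arbitrary: the
  workflow consumes rankings, not physical ΔG.
- **Scoring.** `E_bind` sums the pair potential over all peptide–groove
  center pairs; `E_total` adds intra-chain pairs separated by ≥ 3 sequence
  positions. Identical inputs give bit-identical outputs.

The matrix values and cutoffs are this package's own calibration of the
qualitative chemistry the design rules require (salt bridges attract, like
charges repel, hydrophobic packing is mildly favorable); they are
config-file parameters, not fitted constants.

An open point in the source workflows is which structure carries the
threading (the template's or the base's). Here all threading uses the
template (groove) structure: the design goal is the peptide in the
template conformation, and the fixed backbone makes any other choice
internally inconsistent.

### Combinatorial sampling and enrichment

All `2^N` substitution subsets are enumerated as bit masks (bit *i* =
substitution *i*, little-endian; mask 0 = pure base), scored, and ranked
by ascending `E_bind` with ties broken by mask integer. A hard cap of
N ≤ 22 (~4M variants) guards the exhaustive internal scorer. The
enrichment score of a substitution is the fraction of the top
`max(1, ceil(0.025·M))` variants carrying it (512 × 0.025 = 12.8 → a pool
of 13; the rounding is a pinned choice). Enrichment 1.0 means the
template residue is present in every top model; 0 means it never helps.

Because the contact potential ties far more often than an all-atom scorer
would, the mask-integer tie-break is load-bearing: enrichment is invariant
to substitution relabeling only when no tie straddles the pool boundary
(tested in that regime), and expected enrichment of an energetically inert
substitution over the full pool is exactly 0.5.

### Minimal set

A substitution is kept iff

```
(class_change OR enrichment ≥ θ) AND (label ≠ PTB OR min_dist ≤ 3.5 Å)
```

with θ = 0.5 by default. `class_change` means the swap crosses chemical
classes with a charged class involved (charged in place of neutral or vice
versa) — such substitutions are always included; same-class ("similar")
swaps are excluded exactly when the sampling gives them no support. The
stricter 3.5 Å peptide-distance requirement at PTB positions limits
collateral changes to the TCR surface. The operation is deterministic,
idempotent, and returns a subset of its input. The class partition itself
is configurable; the one above is this package's operationalization of
"chemical properties", which the source principle names but does not
define.

### Specificity summaries and TCR-surface phylogenetics

`build_pssm` computes position frequencies `(count + α)/(n + 20α)` with
pseudocount α = 0.05 by default (α = 0 reproduces raw counts; the logos in
this field are typically drawn from hundreds of binders, where α is
negligible — it exists to keep downstream log-scores finite on small
lists). Information content per position is `log2(20) + Σ f·log2 f` bits
(0 for uniform, ~4.32 for invariant positions); letter heights are
`f · IC`. The package computes the logo *matrix* from a user-supplied
binder list; it performs no binding prediction and no graphical rendering.

TCR-surface dissimilarity between allotypes is the p-distance (fraction
differing) over the TB-classified positions, fed to neighbor joining
(Saitou–Nei Q-criterion; ties broken by the lowest taxon-index pair;
negative branch lengths clamped to zero with the deficit moved to the
sister branch; unrooted tree serialized as newick with a trifurcating
root). NJ is exact on additive matrices (tested against an independent
implementation); it stands in for model-selected maximum-likelihood trees
because the use case is similarity clustering, not evolutionary inference.

### Structure handling

PDB/mmCIF parsing and PDB writing go through gemmi. Altloc groups
collapse to the highest-occupancy conformer (file order breaks ties);
insertion codes resolve to a strictly increasing internal numbering;
waters and non-protein heteroatoms are dropped at read time. Template
preprocessing keeps the first `groove_span` (default 180) residues of the
heavy chain — the α1/α2 domains — plus the peptide, renumbered from 1;
an optional reference sequence strips leading expression tags by sequence
scan before counting. Superposition is a standard Kabsch least-squares
fit (proper rotation enforced) on groove Cα atoms paired by renumbered
position and atom name, with RMSD measured over peptide backbone, peptide
heavy atoms, or everything; atoms missing on either side are dropped
pairwise with a warning.

## Synthetic fixtures: what they show and what they do not

The fixture generators build idealized complexes: straight Cα traces at
3.8 Å spacing for groove and peptide (plus an optional TCR trace), ideal
backbone and Cβ geometry, and one pseudo side-chain atom per *planned*
contact, placed by root-finding so the residue's minimum heavy-atom
distance to the partner chain equals the planned value to 1e-6 Å.
Generators are pure functions of their spec (seeded jitter of 0.05 Å on
trace coordinates; byte-identical files for identical specs) and emit the
ground truth that tests consume — no test hand-codes geometry.

The design scenario is a 20-residue groove presenting `GGGGGGGGK` at a
9 Å chain separation tuned so that exactly one inter-chain center pair
falls inside the 8 Å shell: the Lys anchor against groove position 16
(Asp in the groove allele, Ser in the base), with a decoy substitution at
position 4 that the groove definition picks up (planted 4.5 Å contact) but
whose center is energetically inert. Exhaustive sampling must enrich the
anchor substitution to 1.0 and the minimal set must reduce to it alone.

Passing on these fixtures demonstrates the *logic* of every stage —
distances, counting, enumeration, ranking, enrichment arithmetic, rule
application — under known ground truth. It does not demonstrate that the
contact potential predicts real peptide-binding energetics, that real
grooves behave like straight traces, or that the minimal sets found for
real allele pairs match experimentally validated constructs; those checks
require deposited structures (the optional real-data tests) or the
external scorer.

## Numerical choices and degenerate inputs

- Distances in Å throughout; groove and peptide positions 1-based.
- Empty groove (no residue within the cutoff) is an error — it means the
  peptide chain was misassigned, not that the groove is empty.
- `classify` rejects frequencies outside [0, 100]; `enrichment` requires a
  non-empty ranking and a top fraction in (0, 1].
- Pool size rounds up and is never below 1.
- Stale substitution lists (from-residue mismatch) abort application with
  the offending position named.
- Newick branch lengths print with 10 significant digits; reconstructed
  path lengths are exact to ~1e-9 on additive inputs.
- The peptide length check (8–15) is an explicit override, not a silent
  default, because non-canonical ligand lengths exist but usually indicate
  a chain-assignment mistake.

## Known limitations

- The contact potential ranks variants; it does not estimate stability or
  affinity, and clash handling is a flat penalty, not sterics.
- Fixed backbone means genuinely backbone-remodeling substitutions are
  invisible to the scorer.
- Indel-containing allele pairs are handled by skipping gap-opposed groove
  positions, which is correct bookkeeping but no substitute for structural
  modeling of length variation.
- Classification quality is entirely downstream of the structure
  collection supplied; the package does not curate one.
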