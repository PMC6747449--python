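# Methods

This note records the models, conventions and parameter choices behind
`mitocmp`, the places where a convention had to be chosen, and what the
tests do and do not establish.

## Coordinates and annotation arithmetic

All public coordinates are 1-based, fully closed. A feature may wrap the
circular origin (`start > end`, flagged). Gene size is `end − start + 1`,
or `(L − start + 1) + end` across the origin. Intergenic nucleotides
between circular neighbours are `next_start − prev_end − 1`; a raw value
below `−L/2` is interpreted as the origin-spanning pair and shifted by one
genome length, so genuine short overlaps keep their negative sign. The
organization table starts at *cox1*; its first row's intergenic value is
the circular-closure gap after the last gene, which published tables
usually leave blank — we compute it, and the identity
Σ size + Σ intergenic = L then holds exactly for any record.

Non-coding regions are maximal unannotated circular spans at or above an
inclusive threshold (default 200 bp), found on a per-base coverage mask so
overlapping gene annotations cannot create phantom gaps. Regions are
numbered NCR1, NCR2, … by circular position downstream of *cox1*, which
reproduces the conventional naming (major NCR between *nad5* and *trnK*,
second between *trnG* and *cox3*).

## Composition, skews, codon usage

AT skew = (A−T)/(A+T), GC skew = (G−C)/(G+C), on plus-strand counts.
`N` positions (unsequenced gaps) are excluded from every denominator; a
skew with zero denominator is reported as missing. Full precision is kept
internally; the reporting layer rounds percentages to 0.1 and skews to
0.001. Note that percentages printed at 0.1 determine a recomputed skew
only to about ±0.001 — published three-decimal skews are therefore checked
at that tolerance, not digit-for-digit.

Codon usage follows translation table 9. RSCU is normalized within codon
families, with six-fold Leu and Ser split into isoacceptor sub-families
(Leu1 = CUN, Leu2 = UUR, Ser1 = AGN, Ser2 = UCN), matching how mitogenome
codon-usage tables are conventionally reported; a family with zero counts
has undefined RSCU. Stop codons, codons containing ambiguous bases, and
the incomplete trailing codon of an abbreviated-stop gene (`T--`/`TA-`)
are excluded from counts; whether stops are included shifts composition
values by well under 0.1% either way. Start codons outside
ATG/GTG/TTG/ATT are flagged non-canonical (TTG and ATT are admitted as
documented flatworm alternatives).

## Gene-order common intervals

The published similarity uses an unstated counting convention; the printed
identity value 1254 for 36 genes pins it down. We count gene sets of size
2..n−2 that are contiguous in both circular orders after linearizing at a
shared cut gene, once per relative orientation of the (unsigned) match —
every common interval therefore counts twice — and maximize over cut
genes. On identical orders every window qualifies, giving
f(n) = 2·(n(n−1)/2 − 3) = n(n−1) − 6, which is 1254 at n = 36. Singletons
and the near-full sizes n−1, n are excluded (they are common for any pair
of orders and carry no signal). The fast path uses the permutation
min/max-window characterization, O(n³) per pair over cut genes; an
exponential subset-enumeration oracle locks the convention in tests for
n = 4..10. The score is symmetric, rotation- and relabeling-invariant, and
strictly maximal on self-comparison. Strand orientation is carried but not
scored by default, since all 36 genes are co-oriented in these taxa; a
``signed=True`` mode counts an interval only in the directions where the
strands agree (forward) or are jointly flipped (reverse).

## Tandem repeats

The detector targets the repeat structure described for monogenean control
regions: units of tens to hundreds of bp, nearly exact copies, occasional
point substitutions, a deletion, or a truncated final copy. For each
candidate period p (default 10 ≤ p ≤ L/2), exact self-matches at lag p
seeded by runs of ≥ 8 matching bases are grown unit-by-unit in both
directions, accepting each adjacent unit at ≥ 90% identity (the
`max_mismatch_frac = 0.1` default). A truncated final copy is the longest
consensus prefix whose edit distance to the array tail stays within
max(2, ⌊0.1·i⌋) edits and ends on a matched base, preferring length but
not at the price of extra edits (score i − 3d); this keeps fractional
copies from drifting into flanking sequence, which in these AT-rich
genomes matches a unit surprisingly often by chance. Among overlapping
candidate arrays the one with the most full-copy coverage wins, ties to
the shortest period, so a p-array is never reported as its 2p harmonic;
exact multiples of an already-found period are skipped outright. Per-unit
deviations are called against the per-column-majority consensus (ties to
the first unit) by edit-distance alignment. `N` never matches. The
detected grid may be phase-shifted by a few bases when flanking sequence
happens to extend a seed; period and copy number are unaffected.

## Hairpin folding

A deliberately simple nearest-neighbour model: stacked pairs contribute
−2.0 (G:C), −1.5 (A:T), −1.0 (G:T wobble) kcal/mol; each hairpin loop
(minimum 3 unpaired bases) costs +3.0; helices are perfect (no bulges, no
pseudoknots, no multiloops). Because every helix is self-contained, the
optimal structure is a minimum-energy tiling of the sequence with
non-overlapping stem-loops, computed by an O(n²) dynamic program; ties
prefer the emptier structure, so the energy estimate is 0 exactly when no
pairs are worth forming. The estimates rank structures and count
stem-loops (the published consensus units fold into two to six); they are
not calibrated free energies, and no attempt is made to reproduce
published dG values computed with full thermodynamic parameter tables.

## Identity and clustering

Identity uses a global pairwise alignment (match +1, mismatch 0, linear
gap −1) with gap columns counted in the denominator; the 762/767 = 99.35%
worked example fixes this ratio convention. The exact parameters behind
the published per-gene identity column are not recoverable without the
deposited sequences, so per-gene identities are treated as properties of
the method, not as reproduction targets. Clustering standardizes feature
columns (z-scores), uses euclidean distance with average linkage by
default (complete available), and pre-sorts rows by taxon label so tie
handling is deterministic; the dendrogram is emitted as Newick.

## Synthetic genomes

The generator's defaults are the published study conditions: the shared
36-gene order; gene sizes, start/stop codons (including one abbreviated
stop adjacent to a downstream gene) from the two annotation tables;
codon-position base frequencies from the PCG composition table (position 2
heavily T-biased, giving AT skew ≈ −0.42 there); tRNA lengths 57–69 bp,
rRNA lengths in the published ranges; whole-genome base frequencies for
all non-coding sequence; and the four published NCR repeat regimes
(132 bp × 23, 63 bp × 11 with one substitution in unit 1 at position 10,
166 bp × 2 + a 53 bp truncated copy with three substitutions, 48 bp × 4 +
a 13 bp truncated copy with one substitution and one deletion). The
complete `thaparocleidus` preset plants 13 copies of the 132 bp unit in
its 2020 bp NCR1 counterpart, matching the sequenced (not the estimated)
extent of that region. Intergenic spacers are drawn from 0–5 bp so no
spurious NCR can reach the 200 bp threshold.

PCGs are sampled codon-wise from the per-position frequencies; internal
stops (TAA/TAG) are avoided by resampling position 3 from the renormalized
pyrimidines whenever positions 1–2 read TA. Positions 1–2 keep their
nominal frequencies; the induced position-3 shift is computed in closed
form and declared in the ground truth, so parameter-recovery checks
compare observed composition against the effective frequencies within
3 standard errors of multinomial noise. An optional central N-run in an
NCR emulates an unsequenceable repeat core.

What the generator does **not** emulate: tRNA cloverleaf structure, rRNA
secondary structure, codon autocorrelation along genes, gene overlaps,
and phylogenetically realistic divergence between taxa. Passing tests
therefore establish the pipeline's arithmetic and detection behaviour on
genomes with the published architecture and composition, not annotation
accuracy on real reads or evolutionary realism.

## Problem sizes and determinism

Generated genomes are full-size (≈ 14–16 kb); repeat-recovery checks run
all four published regimes across 20 seeds each; the gene-order oracle
enumerates subsets up to n = 10; the folding oracle enumerates structures
up to ~25 nt. All randomness flows through numpy generators seeded from a
single integer; equal seeds give byte-identical records and report
bundles.

## Known limitations

- GenBank location parsing covers simple and origin-wrapping joins only,
  not fuzzy/partial location syntax.
- The repeat detector assumes largely co-phased arrays; heavily diverged
  (< 90% identity) or nested repeats are out of scope.
- The signed gene-order mode is carried through the data model but the
  score is unsigned, as all genes are co-oriented in the target taxa.
- De novo annotation (tRNA/ORF finding) is a non-goal; records must come
  annotated.
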