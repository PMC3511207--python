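# Methods

This note documents the models, conventions and numerical choices behind
`pinpi`, and what the synthetic benchmarks do and do not demonstrate.

## Precursor model and segmentation

A Pin-II precursor is modelled as

```
SP(25) · [ linker · IRD ]×k · linker        k ∈ 1..8
```

with 0-based, half-open coordinates throughout. The signal peptide is a
fixed-length prefix (`sp_length`, default 25 residues) rather than a
predicted cleavage site: Pin-II SPs are uniform in length, and a fixed
rule keeps the segmentation deterministic and dependency-free. A
precursor shorter than the SP is an error unless flagged `partial`, in
which case the SP is reported absent and the whole sequence is scanned.

Each IRD carries one reactive site, the pentapeptide
`C-[P/T]-P1-X-C`, classified purely by its P1 residue: Lys/Arg → TI,
Leu/Pro → CI, anything else (including the unknown code X) →
UNCLASSIFIED. The regex is deliberately broader than the six motifs seen
in nature (`CPRNC, CPKNC, CPRYC, CPRDC, CTLNC, CTPNC`) because natural
variation also touches the P1′ position; classification by P1 alone
captures the specificity rule without enumerating variants. Matches are
taken non-overlapping, left to right.

### Boundary rule

No published coordinate convention exists for IRD boundaries, so the
package defines one and applies it uniformly:

* The eight scaffold cysteines are described by a spacing template,
  default offsets `(2, 8, 17, 22, 26, 33, 38, 43)` from the domain
  start. The reactive-site cysteines are template positions 4 and 5
  (offsets 22/26) — by construction the only cysteine pair exactly four
  residues apart, so the pentapeptide anchor cannot collide with the
  rest of the scaffold.
* Every reactive-site match anchors a candidate window placed so the
  anchor cysteine falls on its template offset. A candidate is accepted
  when at least *(template positions inside the sequence − 2)* scaffold
  positions have a cysteine within ±2 residues of their expected
  location. The two-miss allowance admits natural cysteine variants
  (lost, displaced or extra cysteines) while rejecting windows seeded by
  chance motifs, whose cysteine content never resembles the scaffold.
* Overlapping accepted candidates are resolved greedily left to right by
  anchor position — deterministic and order-independent.
* The domain start is the anchor-derived window start (template lead of
  2 residues before the first scaffold cysteine). The domain end is a
  fixed tail (`tail_length`, default 6 residues, giving the canonical
  50-residue domain) after the *located* last scaffold cysteine, which
  is searched within ±`end_search` (default 4) residues of its template
  offset. Keying the end off the located cysteine rather than the
  template makes C-terminal length variation (±4 residues) recoverable.
  When no end cysteine is found the nominal template end is used.
* Everything between accepted domains (and before the first / after the
  last) is linker. Segments always reconstruct the input exactly.
* A domain whose window runs off either end of the sequence is flagged
  `is_partial`; a sequence with no reactive-site match annotates as
  `n_irds = 0` with a warning record, not an exception.

The `scaffold_deviation` flag marks cysteine variants: count ≠ 8, or any
cysteine (compared in template order) off its offset by more than the
per-position tolerance (±2; ±4 for the last position, which legitimately
floats with domain length).

## Catalog

"Unique" means exact amino-acid identity — single-residue variants are
distinct entries, which is how variant domains are counted in this
family. Labels are opaque integers in first-occurrence order; permuting
the input permutes labels but not the multiset of (sequence, class)
pairs. Identical compositions under different gene names stay distinct
genes. For a transcribed composition table (no sequences), label-only
catalogs support the same summary; a partial trailing domain counts
toward the gene's domain number whether or not its label is known.

## Clone-library statistics

The study design sequences a fixed number of clones per treatment (60
induced, 25 uninduced); this sequencing depth, not the tabulated column
sum, is the denominator for abundance percentages and gene frequencies.
The distinction matters because published count tables can tabulate
fewer clones than were sequenced; `validate_table` reports per-column
observed vs expected totals and flags mismatches without repairing
anything. In the packaged reference table the AI and W+W columns sum to
54 and 46 against a depth of 60; percentages computed against depth
reproduce the published 38/12/17 (4-IRD) and 10% (2-IRD, W+OS) values,
which a column-sum denominator does not.

Percentages are rounded half-up to integers (the published convention).
Pre-rounding percentages per column sum to 100 only where the column is
completely tabulated. IRD occurrence counts respect multiplicity: a
label appearing twice in one gene counts twice per clone. The
presence/absence Venn partition ("expressed" = count > 0) defaults to
the three induced treatments, the comparison the uninduced column is
excluded from; every expressed gene falls in exactly one region. All
statistics are linear in the counts: doubling every count doubles totals
and preserves percentages.

## Processed-peptide masses

`average_mass` sums a residue table (computed from elemental
compositions with IUPAC 2021 conventional atomic weights: H 1.008,
C 12.011, N 14.007, O 15.999, S 32.06) plus one water, minus
2 × 1.008 Da per disulfide bond. Average mass is the default because
linear-mode MALDI of ~6 kDa peptides reports average masses; a
monoisotopic table sits behind a flag. X has no defined mass and is
rejected by name.

Candidate processed peptides are each annotated domain plus every flank
extension of 0..`max_flank` residues per side, bounded by the residues
actually present in the adjacent linkers (differential processing at the
linkers is what releases single-IRD species). Peaks are assigned to the
candidate with minimal |Δm| within tolerance (default ±3 Da, matching
the spacing of the natural peak set); ties go to the smaller candidate
mass; whether observed peaks are neutral or [M+H]+ species, and whether
the species are oxidized, are exposed as options and asserted nowhere,
because the acquisition protocol does not pin them down.

## Distances and dendrograms

`p_distance` computes a global alignment under unit edit costs (match 0,
mismatch 1, gap 1) with a vectorized DP matrix and a deterministic
traceback preferring diagonal, then gap-in-second, then gap-in-first
moves; the distance is differing columns (mismatches + gaps) divided by
alignment length. The traceback preference matters: optimal alignments
of equal cost can differ in length, and fixing the preference makes the
statistic reproducible. The mean off-diagonal entry of the pairwise
matrix is reported as the family's average variance.

`upgma` is the textbook unweighted pair-group method: cluster distance
is the mean of original leaf-pair distances, merge height is half that
distance (hence ultrametric output), and ties are broken by the
lexicographically smallest pair of cluster representatives, making the
tree invariant to input order. Newick output carries branch lengths
(parent height − child height). The method reconstructs grouping style,
not any particular published topology — topology reproduction would
require the original GenBank sequences, which are deliberately not
bundled.

## Synthetic data generator

The generator emulates the study conditions; its defaults are the
observed family parameters: a 28-entry IRD pool with a 21:7 TI:CI split
and 4 cysteine variants, 47 genes with architecture probabilities
(3, 15, 20, 9)/47 for 1/2/3/4 domains, 10 signal-peptide variants, clone
depths 25 (UL) / 60 (AI, W+W, W+OS). One integer seed drives a single
`numpy.random.Generator` through every draw.

Realism choices, and their limits:

* **Pool construction.** Entries derive from one canonical body with
  position-weighted mutations concentrated in the reactive-site loop and
  the C-terminal tail (where natural variation concentrates), one motif
  from the natural six per entry, and per-entry scaffold jitter: ±1 on
  interior cysteines, up to ±`ird_length_jitter` (default 4) on the last
  one, giving 50 ± 4-residue domains. Body and linker residues come from
  the 19 non-cysteine letters, so the scaffold is the only source of
  cysteines and the anchor stays unambiguous; accidental second motifs
  (a cysteine pair four apart with P/T between) are scrubbed.
* **Mass realism.** Uniform residue draws are heavier than natural IRD
  composition, so the canonical body is redrawn until a nominal-length
  domain weighs 114–118 Da per residue — placing processed-peptide
  masses in the 5.5–6.3 kDa band observed for natural single-IRD
  species. Pool entries are additionally kept ≥ 10 Da apart
  (`min_mass_separation`), as resolvable natural species are; without
  this, near-isobaric variants make peak identity unrecoverable in
  principle.
* **Cysteine variants** are explicit mechanisms (delete, move beyond
  tolerance, add), never random side effects, and never touch the
  first, last, or reactive-site cysteines — so variant domains stay
  annotatable, as the natural variants are.
* **Linkers** share one canonical sequence per run, truncated to a
  per-site random length (4–12 residues): linker propeptides are
  conserved protease targets, and conserved linkers are what lets
  sequence distance reflect shared domain content.
* **Ground truth** records every segment's coordinates, labels and
  classes; substitution noise (`mutation_rate`, default 0 — genes in
  this family share IRDs exactly) avoids scaffold cysteines and reactive
  sites, so recorded boundaries remain valid, and draws only non-cysteine
  replacements, so it can neither create nor destroy anchors.

What passing the synthetic benchmarks shows: the annotator inverts the
generator's construction exactly at zero noise, tolerates ≤ 2 incidental
substitutions, recovers pool size, class mix, architecture and clone
proportions at the study's sampling depths, and re-identifies noisy
peaks. What it does not show: performance on real precursors with
diverged scaffolds, linker cysteines, non-standard signal peptides, or
reactive sites outside the `C-[P/T]-X-X-C` pattern — real-data use
should start from the annotation TSV and the deviation flags, not from
blind trust in the defaults.

## Numerical and degenerate-input conventions

* Percentages: half-up rounding (`floor(x + 0.5)`), not banker's.
* Proportion-recovery checks use 3 multinomial standard errors on the
  count scale with a half-count continuity correction, since Dirichlet
  proportions near zero break the plain normal approximation.
* Sequences admit the 20 standard codes plus X; X never matches a
  scaffold cysteine, never anchors a motif, and classifies as
  UNCLASSIFIED at P1.
* Blank cells in composition/count tables are zeros, not missing data.
* Empty candidate lists, zero-motif sequences and under-full count
  columns produce warnings/flags; negative counts, malformed motifs,
  duplicate identifiers and asymmetric distance matrices raise.

## Known limitations

* The boundary convention (template lead/tail) is this package's, not a
  community standard; absolute coordinates of reported domains are only
  meaningful relative to it.
* Signal peptides are a fixed-length prefix; atypical SPs are silently
  mis-split.
* UPGMA and p-distance are intentionally simple (no substitution model,
  no bootstrap); they support family-structure exploration, not
  phylogenetic inference.
* The clone-count fixture is a transcription of a published table whose
  AI and W+W columns are incomplete at source; statistics against
  sequencing depth are exact, per-column sums are not.
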