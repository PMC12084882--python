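# Methods

## The problem

Deposited cryo-EM models of the rabbit (*Oryctolagus cuniculus*) ribosome
disagree with one another in their rRNA sequences: different entries carry
different single-nucleotide variants, some inherit human or boar sequences
from their starting models, one widely used 18S numbering is shifted by +1,
and the 1982 rabbit 18S RefSeq itself lacks two bases (G183, C1513) that are
visible in every high-resolution map. `riboaudit` turns the manual audit a
structural biologist would perform — download the chain sequence, align it
to a trusted template, record the differences, fix the model — into a
reproducible pipeline with explicit conventions.

The designated standard is the Broad Institute OryCun2.0 whole-genome
shotgun assembly, via its curated RNA Central entries (28S
URS00009AB771_9986, 18S URS00006F07B6_9986, 5.8S URS00006CE1FB_9986, 5S
URS00006C8ED4_9986). The built-in manifest records these and the comparison
schemes (human/yeast/*K. lactis* 18S RefSeqs, the 1982 rabbit 18S RefSeq,
boar and human 28S); sequences are attached from FASTA so the package works
fully offline, with an optional fetcher for networked machines.

## Alignment model

Every reported comparison is one model chain against one template, so the
pipeline uses deterministic *pairwise* global alignment with affine gap
penalties rather than a multiple aligner. A gap of length L costs
`gap_open + (L-1)·gap_extend`. Defaults: match +5, mismatch −4, gap open
−10, gap extend −1, end gaps penalized. The exact values are not critical
for near-identical rRNA chains (>99% identity leaves the optimal alignment
essentially unique); they are configurable everywhere, and an alternative
`end_gap_policy="free"` (semi-global) is available for fragment-vs-template
comparisons. The dynamic program is `Bio.Align.PairwiseAligner` (exact and
C-implemented) under a custom A/C/G/U/N matrix; determinism comes from
taking the aligner's canonical first traceback, which is stable across runs
and platforms for fixed inputs. Correctness of the scores is checked in the
test suite against an independent brute-force recursion over all monotone
alignments on short sequences.

`N` marks a residue whose chemical component could not be mapped to a
parent base. N aligned to anything — including N — counts as a mismatch in
identity accounting, and never as a substitution event (see below).

### Identity conventions

Published identity percentages are ambiguous about gap columns, and the
printed figures for the rabbit entries are not internally consistent under
any single divisor. Reports therefore always carry both conventions:

* gap-excluded: `100 · matches / (matches + mismatches)`
* gap-included: `100 · matches / total columns`

Headline numbers default to gap-included; both appear in every report, so
either reading of a published figure is recoverable.

## Discrepancy audit

Alignment columns are classified as match, mismatch, or gap. The audit
then reports:

* **substitutions** — definite-base mismatch columns, in 1-based template
  coordinates. This is the headline "single-nucleotide changes" count;
  indels are excluded from it.
* **insertion/deletion runs** — maximal runs of contiguous gap columns,
  counted as runs (features of a model), not per-base events. Insertions
  carry the preceding template coordinate as an anchor (0 at the start).
* **modified/unknown residues** — components mapped to N are tallied
  separately (`n_modified_unknown`): unknown chemistry is not evidence of
  a sequence change. Components with a known parent (pseudouridine → U,
  2′-O-methyl-G → G, ...) are compared as that parent, so a modification is
  never mistaken for a substitution. The parent table ships with the
  package and falls back to gemmi's tabulated components.

Region-restricted audits (for models verified only in high-confidence
stretches) drop events outside the given 1-based inclusive intervals and
recompute identity over in-region columns only, with insertion columns
attributed to their anchor.

Chain-to-template assignment is automatic: each extracted chain is aligned
to every loaded reference and assigned to the argmax of gap-excluded
identity. The low-identity warning (default floor 80%) uses gap-included
identity instead, because a short fragment can align its few bases almost
perfectly while covering none of the reference; deposited entries do not
say which chain IDs correspond to which rRNA, so the classification is
reported rather than assumed.

## Liftover and register offsets

A pairwise alignment of two reference schemes induces a monotone position
map; functional sites (the A/P-site nucleotides, diagnostic positions) are
lifted through it. Positions in gap columns are reported as an explicit
`unmapped` marker, never 0 or −1, to avoid silent coordinate corruption.

Register-offset detection votes over aligned residue pairs: if
`auth_number − template_pos` takes one value for ≥95% of pairs (residues
with insertion codes abstain), that value is the chain's offset; otherwise
none. The 95% threshold tolerates local indels while still flagging the
systematic +1 numbering pathology.

## Correction

A correction plan is bookkeeping derived from an audit, applied with gemmi:

* substitutions become relabels to the template base; when the base
  identity changes, only atoms whose names exist in the new base's
  standard atom set (backbone/ribose plus base atoms) are kept, and the
  dropped names are logged;
* every aligned residue is renumbered to its template coordinate, making
  the chain's numbering match the reference scheme (and hence rabbit 18S
  numbering match human);
* insertion-run residues keep their anchor's number with insertion codes
  A, B, ... and are flagged unresolved; deletions are recorded unresolved.
  No residues are fabricated or deleted — resolving an indel requires
  density, which sequence auditing cannot verify, so residue count is
  conserved and no coordinates are rebuilt or refined.

Corrected models are written as mmCIF with a provenance line (template,
change count, date) embedded in `_struct.title`, plus a TSV/JSON change
log whose length is exactly |relabels| + number of renumbered residues.
For chains without indels the procedure is idempotent: re-auditing a
corrected model yields zero substitutions and zero offset, and re-planning
yields an empty plan.

## Synthetic data

The generator makes every stage testable offline: a random reference with
target GC content (default 0.55, typical of mammalian rRNA), a model chain
derived from it by planted substitutions, insertions, deletions and an
optional numbering offset, and a minimal mmCIF fixture (one phosphorus
pseudo-atom per residue) that exercises the real reader. Planted events
are kept ≥3 nt apart and ≥25 nt from the ends, and indel boundaries are
constrained so the planted placement is the unique optimal one — otherwise
an equally scoring shifted gap would make exact truth-table comparison
ill-posed. Identical seeds give byte-identical fixtures.

What the generator does *not* emulate: real rRNA base composition and
repeat structure, expansion-segment length variation, chemically plausible
modification patterns, multi-chain entries, or atom-level geometry.
Passing the synthetic closure tests therefore demonstrates that the
pipeline's event recovery, coordinate arithmetic and file round-trips are
exact under unambiguous-alignment conditions, not that alignment choices
are correct for arbitrarily diverged real sequences.

## Problem sizes and defaults

Synthetic study runs (`scripts/acceptance.py`) mirror the published study
conditions: a 1869-nt 18S-scale template with six model chains carrying
the per-entry substitution loads 3/6/9/6/2/11; a 5070-nt 28S-scale
template ("over 5000 nt") with seven chains spanning the observed
none-to-47 range (intermediate loads 3/8/15/21/33 chosen once as a spread,
since only the extremes are published per entry); a 144-nt 5S template
against a 119-nt model chain (one 25-nt deletion); a +1-offset chain; and
liftover across schemes differing by known indels. Property tests use
800-nt references over 20 seeds, which exercises the identical code paths
at a size where the whole suite runs in seconds.

## Known limitations

* Published identity divisors cannot be reproduced exactly (they are
  internally inconsistent); both conventions are reported instead.
* Legacy PDB input is best-effort; mmCIF is canonical. Written output is
  always mmCIF.
* Insertion codes are preserved and reported but ignored in coordinate
  arithmetic.
* Comparisons against the real accessions and PDB entries require network
  access to RNA Central/NCBI/RCSB (the package's fetcher); the
  corresponding tests report a clear failure when those services are
  unreachable.
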