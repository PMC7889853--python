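# Methods

This note documents the models, conventions and numerical choices behind
`loopcraft`, and what the synthetic fixtures do and do not establish.

## Conservation scoring and loop-candidate detection

Each alignment column is scored `s = 1 − H/H_max`, where `H` is the Shannon
entropy of the empirical amino-acid distribution among non-gap, non-X symbols
and `H_max = ln 20`.  The score is 1 for a single-symbol column, 0 for a
uniform one.  Gaps are excluded from the entropy and reported separately as a
per-column gap fraction: in the loop regions this tool targets, homolog
indels are precisely the signal of interest, so folding them into the
entropy would conflate two different phenomena (substitution tolerance and
length variability).  All-gap columns score 0.  The consensus residue is the
most frequent non-gap symbol, ties broken alphabetically so profiles are
deterministic.

Candidate detection runs on the subsequence of columns where the reference
row has a residue; columns where the reference is gapped are skipped.  A
candidate is a maximal run of at least `min_loop_len` consecutive
reference-mapped columns with score `< low_thr`, immediately preceded and
followed by at least `min_flank_len` consecutive reference-mapped columns
with score `≥ high_thr`.  Runs touching the alignment edge have no flank and
are never reported.  Defaults: `low_thr = 0.4`, `high_thr = 0.8`,
`min_loop_len = 4`, `min_flank_len = 4`.  These are heuristics, not fitted
values: 0.4 is comfortably below what a column with a handful of coinciding
residues among ~16 homologs can reach, and 0.8 demands near-identity of the
framing motifs; all four are exposed as parameters.

The scan skips reference-gapped columns because flank and run contiguity
would otherwise depend on how much insertion material *other* homologs carry
— a property of the alignment, not of the reference protein being
engineered.  One consequence worth knowing: an isolated well-conserved
column *inside* a loop (e.g. an anchored catalytic residue) splits the run,
and the fragments are only reported if they are long enough and
well-flanked.

A known property of entropy scoring: adding a sequence to the alignment can
lower a column's score if its residue was in the minority there (the
distribution becomes more even).  The monotone guarantee — scores never
decrease — holds only when the added row matches the column consensus.

## B-factor flexibility

"Backbone" means the conventional atom set {N, CA, C, O}.  A residue's value
is the arithmetic mean over its backbone atoms present; a region's mean
averages the per-residue means (the pooled-atom alternative is available via
`pooled=True`, since published loop averages do not always state which of the
two was used).  The max and its residue number always come from per-residue
means.  Altloc'd atoms contribute their highest-occupancy location (ties:
first encountered); HETATM records are excluded; insertion-coded residues
are rejected because the variant model numbers residues as plain integers.

## Variant model and nomenclature

A variant is a single independent edit — substitution, deletion or insertion
— whose positions always refer to the unmodified reference (1-based, with an
explicit `numbering_offset` for constructs that do not start at residue 1).
Insertions are anchored between two existing residues; terminal insertions
are rejected because the two-anchor naming grammar (`Q286_A287ins…`) has no
form for them.  Multi-residue substitutions and delins are not modelled.
Names follow the den Dunnen & Antonarakis protein conventions without the
strict-HGVS `p.` prefix (the prefix is accepted on parse).  Parsing
validates every stated reference residue and round-trips exactly with
naming; this round-trip is property-tested over random references.

Codon-level edits replace/insert whole codons.  New residues are encoded
with the most frequent codon of highly expressed *E. coli* genes (class II),
the expression host this workflow targets; the table is a plain dict
parameter, so any usage table can be substituted.  The CDS must translate
exactly to the reference protein (one trailing stop allowed); the first
discordant codon is reported otherwise.

## Library generators

* **Alanine scan** — one substitution per region residue, X→A and A→G, so
  the library size always equals the summed region length (29 + 13 = 42 for
  the default loops).
* **NNK sizing** — coverage counts *codons* (V = 32, equiprobable), not
  amino acids: `1 − (1 − 1/V)^N`.  This is the convention under which
  92 clones give 94.6% ("almost 95%"); amino-acid-level coverage, which
  exceeds 99% at N = 92 because of codon multiplicities (8 residues × 3
  codons, 9 × 2, 3 × 1), is reported as a separate statistic.
  `clones_for_coverage` is the exact integer inverse (N − 1 fails, N
  succeeds).
* **Consensus library** — at region columns conserved at `cons_thr` (default
  0.8, shared by both rules for parsimony): substitute the reference to the
  consensus where they differ; delete the reference residue where ≥
  `cons_thr` of the *other* rows are gapped.  Positions already matching
  consensus are skipped and counted, so no emitted variant equals wild type.
* **Fill-up insertions** — within the region's alignment block, the
  `n_donors` (default 2) homologs with the most non-gap residues donate the
  residues they carry at reference-gap columns, in column order.  Insertions
  grow left-anchored from the reference residue immediately left of the
  donor's first gap-column residue, in steps of `step` (default 2, i.e.
  residue pairs; set 1 for single-residue insertions), with a final
  full-length variant when the total is not a multiple of the step.
  Left-anchored growth is an assumption — the direction of stepwise growth
  is genuinely open — and is stated here as the package's choice.
* **Nested deletions** — for each centre `c` and half-width `h` in
  {0, 1, 3}, delete `[c − h, c + h]`: the 1/3/7-residue series in which
  each step removes the two neighbours of the previous deletion.
* **LILI** — the four linker chemistries G, GS, PA, GP (flexible, flexible,
  stiff/non-helical, polar/unstructured); a length-L insertion is the first
  L characters of the repeated unit, so each linker is a prefix of the next.
  Defaults: lengths 2–6 after each site → 20 variants per site, 60 for the
  three canonical sites.  Same-name duplicates across sets are dropped.

## Primer design

QuikChange pairs are `[left flank][edited segment][right flank]` on the
coding strand and their exact reverse complement.  Flanks start at 10 nt and
grow symmetrically (ties grow left) until `Tm ≥ tm_min` (default 78 °C),
capped at 60 nt total.  Tm uses the QuikChange-manual formula
`81.5 + 0.41·%GC − 675/N − %mismatch`; for substitutions N is the full
primer length and %mismatch counts the substituted bases; for InDels the
mismatch term is 0 and N counts only template-matching bases, with %GC
computed over those same bases (the convention is not fully specified
anywhere authoritative, so the in-silico oracle tests product identity, not
Tm).  Degenerate N/K bases in saturation primers contribute 50% GC.  Edits
above 18 nt (replaced + inserted) — e.g. 7-residue linker insertions — fall
back to a two-amplicon overlap design: junction primers carry the edit and
share an exact overlap window (default 25 nt, grown to edit + 6 when the
edit is longer); their 3′ arms and the outer primers are sized to a 55 °C
stand-alone Tm.

The in-silico mutagenesis simulator is deliberately construction-blind: it
locates annealing arms by maximal prefix/suffix string match on the
template (seeded at 8 nt and extended, longest extension wins), then splices
the primer in, PCRs the two amplicons, and joins them on their exact
terminal overlap.  It never reads flank lengths recorded during design, so
the product-identity property test is an independent check of both sides.

## Screening reduction

Concentrations follow internal-standard practice:
`c_i = (A_i/A_IS)/rf_i · [IS]`.  Response factors default to 1.0 with a loud
warning when no calibration is supplied.  Product formation is Σ products /
initial substrate × 100 (clipped at 100% with a warning) — i.e. moles of
product over initial substrate, matching the reaction-equation framing of
endpoint biotransformations; conversion of recovered substrate is computable
when substrate areas are provided.  Distribution normalises each product to
the total and is empty when nothing formed.  ee and de are
`|a − b|/(a + b) × 100` with the major-isomer label (a 50/50 pair reports 0,
"racemic"); the alternative "fraction of major isomer" reading is available
as `stereo_fraction` but never used by default.  Hit calling subtracts the
empty-vector blank from every well (floored at 0) before dividing by the
wild-type mean; a zero wild-type mean flags folds as infinite, which rank
first, with ties broken by variant name.

## Synthetic fixtures

The fixture generators are pure functions of (spec, seed).  The homolog
family places fully conserved framing motifs (conservation level 1.0 by
default — the framing motifs this workflow relies on are near-invariant, and
a parameter lowers it) around loops whose residues are resampled per homolog
and whose lengths vary by 0–6 extra residues, left-aligned in a gap block at
the loop midpoint.  Keeping indels inside loop columns keeps the flanks
alignable without running an aligner, which is what lets recovery tests
assert ground truth by construction.  Engineered "consensus mismatch" and
"consensus gap" positions give the consensus generator deterministic work.
The plate model draws true concentrations uniformly per well (92 variant +
3 wild-type + 1 empty-vector wells by default, 1 mM internal standard,
20 mM substrate), then computes areas with mean-one lognormal noise at 5% CV
— the standard multiplicative model for chromatographic area variability.

The bundled reference is **synthetic**: a 460-residue sequence carrying the
canonical anchor residues (G236, H240, E251, V257, P260, N264,
F278–N279–D280–D281–F282–A283–L284–Q286–A287–I288–M289–G290) at their
published positions with seeded-random filler elsewhere.  Every count and
name the tests assert (42-variant scan, 9-deletion series, 60 LILI variants,
the printed variant names) is pure position arithmetic and therefore
independent of the filler; nothing here claims to reproduce wet-lab product
formations, which are measurement outcomes, not computations.  Passing tests
on these fixtures demonstrate correctness of the arithmetic, the edit
algebra, the primer logic and the plate reduction — not biological realism
of the sequences or noise beyond the stated models.

## Problem sizes

The test suite and acceptance script run small: a 460-residue reference,
16-homolog alignments, ~130-variant primer sweeps, one 96-well plate,
10⁴ nomenclature round-trips and a 10⁵-replicate Monte-Carlo check of the
NNK coverage formula — sizes chosen to exercise every code path while
keeping a full run in seconds.

## Known limitations

* No secondary-structure assignment, MD-based flexibility or tunnel
  analysis; B-factors are the only structural signal.
* Primer design ignores hairpins/self-dimers and vendor-specific scoring.
* The conservation model is column-independent (no phylogenetic weighting);
  closely related homolog sets will overstate conservation.
* mmCIF, compressed formats and chromatogram raw files are out of scope; the
  tool consumes integrated peak areas only.
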