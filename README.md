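# loopcraft

Active-site loops are the flexible, poorly conserved segments that decorate
the entrance of an enzyme's catalytic pocket.  In Rieske non-heme iron
oxygenases (and many other families) they steer substrate access, positioning
and therefore activity, regio- and stereoselectivity — yet their flexibility
makes them hard to target rationally.  `loopcraft` is a toolkit for the
loop-engineering workflow on such enzymes: it identifies loop hot-spot
regions from sequence conservation and structural flexibility, enumerates the
standard loop variant libraries, names every variant systematically, designs
the mutagenic primers, and reduces variant-screening plate data to the
numbers an enzyme engineer reports.

It is written for protein engineers who work with a reference enzyme (e.g. a
dioxygenase α-subunit), a multiple sequence alignment of homologs, optionally
a crystal structure, and GC/HPLC peak-area tables from whole-cell screens.

## What it computes

**Hot-spots.** Per-column conservation of an MSA is scored as
`s = 1 − H/ln 20`, where `H` is the Shannon entropy of the amino-acid
distribution among non-gap symbols (gaps are reported separately as a gap
fraction — in loops, homolog indels are signal).  Loop candidates are maximal
runs of low-conservation reference columns framed on both sides by conserved
motifs.  Structural flexibility comes from per-residue backbone B-factors
(mean over {N, CA, C, O}) of a PDB chain.

**Libraries.** Five generators return validated, uniquely named variant sets:

| strategy | edit pattern |
|---|---|
| `alanine_scan` | every loop residue → Ala; wild-type Ala → Gly |
| `nnk_saturation` | per-position NNK (32-codon) saturation with clone sizing |
| `consensus_library` | substitutions/deletions toward the homolog consensus |
| `fillup_insertions` | stepwise insertion of residues longer homolog loops carry |
| `nested_deletions` | 1/3/7-residue deletion series around chosen centres |
| `lili_library` | Linker In Loop Insertion: 2–6-mer G/GS/PA/GP linkers after hot-spots |

NNK sizing uses the coupon-collector expectation: picking `N` clones from `V`
equiprobable codons covers `1 − (1 − 1/V)^N` of the library in expectation;
its exact inverse gives the clones needed for a target coverage.

**Nomenclature.** Variants are named in the den Dunnen & Antonarakis protein
style used throughout the loop-engineering literature — `F282A`, `A283del`,
`F282_L284del`, `Q286_A287insGSGSG` — with a bidirectional parser
(`parse(name(v)) == v`) and an optional strict-HGVS `p.` prefix.

**Primers.** QuikChange-style complementary pairs
(`Tm = 81.5 + 0.41·%GC − 675/N − %mismatch`, flanks grown until Tm ≥ 78 °C)
for edits up to 18 nt, with automatic fallback to two-amplicon overlap-PCR /
Gibson designs whose junction primers share an exact 25 nt overlap spanning
the edit.  A construction-blind in-silico mutagenesis simulator verifies that
every designed primer set reproduces the intended codon-level edit.

**Screens.** Internal-standard quantification
(`c_i = (A_i/A_IS)/rf_i · [IS]`), product formation as % of initial
substrate, product distribution, enantiomeric/diastereomeric excess
(`|a−b|/(a+b)·100` with the major-isomer label), empty-vector blank
subtraction and wild-type-relative fold-change hit calling.

## Worked example

```python
from loopcraft import (LoopRegion, alanine_scan, nested_deletions,
                       lili_library, nnk_coverage, clones_for_coverage)
from loopcraft.synthetic import make_cdo_like_reference

ref = make_cdo_like_reference()          # synthetic α-subunit-like reference
loop1 = LoopRegion("loop1", 236, 264)    # 29 residues
loop2 = LoopRegion("loop2", 278, 290)    # 13 residues

scan = alanine_scan(ref, [loop1, loop2])
print(f"alanine scan: {len(scan)} variants, e.g. {scan.names[:3]} ... {scan.names[-2:]}")

dels = nested_deletions(ref, centers=[251, 257, 283])
print(f"nested deletions: {len(dels)} variants: {dels.names[6:]}")

print(f"NNK coverage with 92 clones: {100 * nnk_coverage(32, 92):.1f}%")
print(f"clones for 95% coverage: {clones_for_coverage(32, 0.95)}")
```

prints

```
alanine scan: 42 variants, e.g. ['G236A', 'F237A', 'L238A'] ... ['M289A', 'G290A']
nested deletions: 9 variants: ['A283del', 'F282_L284del', 'D280_Q286del']
NNK coverage with 92 clones: 94.6%
clones for 95% coverage: 95
```

The 42 scan variants are one per loop residue (29 + 13); the deletion series
around centre A283 removes 1, 3 and 7 residues (`A283del`, `F282_L284del`,
`D280_Q286del`); 92 clones at one NNK-saturated position give an expected
94.6% codon coverage — "almost 95%" — while hitting 95% exactly needs 95
clones.

## Command line

```
loopcraft fixtures       --out demo --seed 1        # synthetic demo workspace
loopcraft find-loops     --alignment demo/family_alignment.fasta \
                         --reference-id CDO_alpha_synthetic \
                         --pdb demo/structure_synthetic.pdb --chain A --out demo/loops
loopcraft design         --strategy alascan --reference demo/reference.fasta \
                         --regions 236-264,278-290 --out demo/ala
loopcraft primers        --library demo/ala/alascan_library.tsv \
                         --reference demo/reference.fasta --cds demo/cds.fasta \
                         --out demo/primers
loopcraft analyze-screen --plate demo/plate.csv --substrate-mm 20 --out demo/screen
```

Every run echoes its effective configuration into the output directory and is
byte-deterministic given config + seed.

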