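# framefix

Sequence-aware repair of register errors in multiple protein structure
alignments, plus the full evaluation toolbox for comparing such alignments.

## The problem

Multiple structure aligners work almost entirely from the geometry of the
C&alpha; backbone: they assemble tightly superposed *anchor blocks* (runs of
5–9 residues per chain in close spatial agreement) and extend greedily
between them on RMSD alone. In the loops between blocks, several residue
correspondences are often geometrically near-tied, and a purely geometric
aligner picks among them arbitrarily — discarding an obvious sequence match
for a negligible RMSD gain. The result is a *frame-offset (register) error*:
an alignment shifted by one or two residues in a loop that is geometrically
plausible but evolutionarily wrong.

`framefix` repairs these regions. For every region between anchor blocks it
builds two candidate sub-alignments —

* a **sequence candidate**: a multiple sequence alignment of the region's
  subsequences (built-in deterministic progressive aligner with BLOSUM62 and
  affine gaps, or an external tool: MAFFT, CLUSTAL-W, MUSCLE, ProbCons), and
* a **structural candidate**: a greedy extension inward from the flanking
  blocks, appending one column at a time while the refit superposition stays
  within a 5 Å RMSD threshold —

and keeps whichever scores better under the combined conservation score.

## Scores

For an alignment *A* of *N* structures with scored columns *c* (core columns
— those without gaps — unless noted), with sequence weights
*w<sub>i</sub>* = Σ<sub>j≠i</sub> d(i,j)/(N−1),
d(i,j) = 1 − PID(S<sub>i</sub>,S<sub>j</sub>)/100 and
W = Σ<sub>i&lt;j</sub> w<sub>i</sub>w<sub>j</sub>:

* **Seq** = 9 × (1 − (Seq′ + 4)/9.75), clamped into [0, 9], where
  Seq′ = Σ<sub>c</sub> Σ<sub>i&lt;j</sub> w<sub>i</sub>w<sub>j</sub>
  S(c<sub>i</sub>,c<sub>j</sub>) / (W·|A|) and S is BLOSUM62 off the
  diagonal and a configurable identical-residue value on it (default: the
  BLOSUM62 diagonal mean, 116/20 = 5.8).
* **Str** = mean over columns of the mean per-pair structural term: 9 for
  C&alpha; distances above 22.62 Å, and a monotone ramp 9·d/22.62 below it.
* **Cons** = ω·Seq + (1−ω)·Str with ω = 0.5.

Lower is better throughout. The toolbox also computes the core length,
partial core length (total length × the average fraction of realized
structure pairs per column), a partial Seq variant in which gap pairs score
zero, the average pairwise core RMSD under iterative consensus
superposition, and percent-correct (reference-pair recall) against a
curated reference alignment. Because these conservation scores favor
shorter alignments, two length-aware comparisons are included: greedy
truncation of the worst-Cons core columns down to a target core length, and
ranking (Cons, core length) points by the y-intercept of a fixed-slope line
(0.126 score units per column) through each point.

## Worked example

Generate a synthetic two-chain family with a planted one-residue register
error in its loop, then score and repair it:

```sh
framefix simulate --n 1 --out demo
framefix score demo/family_0000/corrupted.fasta \
    -s demo/family_0000/structures.pdb:A -s demo/family_0000/structures.pdb:B \
    --ref demo/family_0000/true.fasta --out corrupted.tsv
framefix refine demo/family_0000/corrupted.fasta \
    -s demo/family_0000/structures.pdb:A -s demo/family_0000/structures.pdb:B \
    --ref demo/family_0000/true.fasta \
    --out repaired.fasta --report repaired.tsv --log decisions.json
```

The corrupted alignment scores

```
Core length  RMSD    Seq     Str     Cons    Partial length  Partial Seq  % Correct
22           1.6572  1.0196  0.5192  0.7694  22.0000         1.2060       81.8182
```

and after repair

```
Core length  RMSD    Seq     Str     Cons    Partial length  Partial Seq  % Correct
22           2.0421  0.0000  0.6452  0.3226  22.0000         0.1866       100.0000
```

The decision log shows why: on the single inter-block region the sequence
candidate's Cons (0.927) beat the structural candidate's (1.799), so the
sequence alignment of the loop was spliced in. The repaired alignment
recovers the ground-truth correspondence exactly (% Correct 100): the
conserved loop motif is re-aligned in register, which drives Seq from 1.02
to 0.00 and halves Cons, at the cost of a slightly higher RMSD (1.66 →
2.04 Å) — the planted error is geometrically *favored*, which is exactly
why a purely geometric aligner commits it.

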