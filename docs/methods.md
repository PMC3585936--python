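# Methods

## Model and procedure

`framefix` operates on a gapped multiple alignment of k ≥ 2 protein chains,
each reduced to its C&alpha; trace. Internally an alignment is a k × n
integer matrix of residue indices (gap = −1) whose non-gap row entries
enumerate each chain's residues in order — every residue of every chain
appears in exactly one column, so residue conservation is a structural
invariant of the container, not a convention. A *core* column has no gaps.

The repair pipeline runs once, left to right:

1. **Superposition.** All chains are superposed over the core columns by
   iterative consensus fitting: each chain is fitted (least-squares Kabsch,
   via `scipy`'s `Rotation.align_vectors`) onto the running mean coordinate
   set until the mean moves less than 10⁻⁶ Å (at most 100 iterations). The
   frame is anchored at the first chain's placement, so the procedure is
   deterministic given input order. The reported RMSD is the mean over all
   chain pairs of the core-column RMSD in this common frame — a single
   rigid frame per chain. Aligners that bend chains into several local
   frames will report somewhat different RMSDs for the same correspondence;
   this is a known systematic difference, not an error.
2. **Anchor inference.** Within every maximal run of consecutive core
   columns long enough to hold a block, a column is *tight* when its RMS
   pair distance is at most `block_rmsd_threshold` in the global core frame;
   the tight set is then confirmed under a run-local refit, which may demote
   columns but never re-admit rejected ones. Maximal tight sub-runs of at
   least `block_min_length` columns become anchor blocks; everything else
   becomes regions (inter-block or terminal). The initial mask deliberately
   uses the global frame: a run-local fit over a long tight stretch joined
   to a misregistered loop splits the displacement between the two and can
   hide the misregistration entirely, which would freeze register errors
   inside anchors — the failure mode the tool exists to fix. The one-way
   refit guards the opposite failure, a contaminated global frame
   re-admitting loose columns.
3. **Candidates.** Each region owns, per chain, exactly the residues between
   its flanking blocks. The *sequence candidate* aligns the region's
   subsequences with a deterministic progressive aligner (guide order =
   input order; profile columns scored as the mean BLOSUM62 score against
   the column, affine gaps; Gotoh DP with backpointer traceback and a fixed
   match &gt; gap-in-profile &gt; gap-in-sequence tie-break), or with an
   external tool through a subprocess contract (FASTA in, aligned FASTA from
   stdout or a declared output file). The *structural candidate* extends
   greedily inward from the flanking blocks, alternating sides, each trial
   column taking the next unconsumed residue of every chain; the column is
   kept only while the consensus refit over flank block + accepted extension
   stays within `extension_rmsd_threshold` average pairwise RMSD. A side
   closes on its first rejection; extension stops entirely when any chain is
   exhausted, and unconsumed residues are emitted as single-residue
   non-core columns. A region with no flanking block at all (an alignment
   without anchors) keeps its incoming columns as the structural candidate,
   since there is nothing to extend from.
4. **Choice and splice.** Both candidates are scored by Cons over their core
   columns — sequence weights from the *full* alignment (region-local
   identity is unstable on 2–5 residue fragments) and distances in the full
   alignment's superposed frame. Core here means all k chains present; a
   candidate with no core column scores the worst value, 9. The lower Cons
   wins; exact ties keep the structural candidate, reproducing the
   unmodified geometric alignment when sequence adds nothing. The winner is
   spliced in; block columns are byte-identical before and after, and the
   container invariants verify residue conservation on every splice.

The pipeline makes one pass. Iterating to convergence was considered and
rejected: anchors are fixed, regions are disjoint, and candidate scores use
the frozen input frame and weights, so a second pass could only change a
region via second-order effects of its neighbors' choices — not worth the
loss of predictability.

## Scores

Definitions are in the README. Numerical decisions worth recording:

* The sub-cap branch of the per-pair structural term is the linear ramp
  9·d/22.62 — continuous at the cap (value 9 exactly at 22.62 Å), monotone,
  zero at zero. The branch is pluggable (`StaccatoParams.str_branch`), and
  the scale constant f = 0.07 is retained in the parameters for alternative
  branch functions.
* The identical-residue substitution score defaults to the mean of the 20
  BLOSUM62 diagonal entries (116/20 = 5.8). The Seq normalization
  9.75 = 4 + 5.75 anchors the score's zero near that mean; the literal
  diagonal sum (116) is available as an override
  (`BLOSUM62_DIAGONAL_SUM`) but saturates Seq absurdly for any
  identity-rich alignment. Because 5.8 sits slightly above 5.75, perfectly
  identical columns would score marginally below zero; Seq is therefore
  clamped into [0, 9].
* Percent identity divides by the number of columns in which both sequences
  have residues (the common convention), and is 0 for sequence pairs
  sharing no column. When all sequences are mutually identical, the weight
  normalizer W would vanish; the fallback assigns uniform weights w = 1,
  W = C(k, 2).
* |A| in the Seq and Str denominators is the number of *scored* columns:
  core columns for the core variants, all columns for the partial Seq
  variant (in which any pair involving a gap contributes 0).
* Percent-correct is reference-pair recall: the fraction of the reference's
  aligned residue pairs (over all chain pairs and columns) recovered by the
  test alignment.
* Cons-ranked truncation drops whole core columns, ranked once by
  single-column Cons under the starting superposition (no refit between
  removals; ties to the leftmost column); removed residues are kept as
  single-residue non-core columns so no residue is lost. Per-chain partial
  dropping is not implemented.
* The separator ranking's default slope is 0.126 score units per core
  column — the slope of the separating line itself; it is configurable.

## Parameters

| parameter | default | units | role |
|---|---|---|---|
| ω (`omega`) | 0.5 | — | sequence weight in Cons; raise toward 1 for closely homologous sets |
| `cap_distance` | 22.62 | Å | distance at which the structural term saturates at 9 |
| `f` | 0.07 | — | scale constant for alternative structural branches |
| `identical_residue_score` | 5.8 | score | S on the diagonal |
| `extension_rmsd_threshold` | 5.0 | Å | greedy extension acceptance bound |
| `block_min_length` | 5 | columns | minimum anchor block (lower end of the 5–9 fragment window) |
| `block_rmsd_threshold` | 2.5 | Å | per-column tightness bound for anchors; this package's own choice |
| `gap_open` / `gap_extend` | −11 / −1 | score | built-in aligner affine penalties (first / subsequent gap position) |
| separator `slope` | 0.126 | score/column | length-quality trade-off ranking |

## Synthetic families

The generator builds toy families from ideal C&alpha; traces (helix: 2.3 Å
radius, 1.5 Å rise, 100°/residue; strand: 3.3 Å extended zigzag; loop: an
open ~3.2 Å-step walk), copied across k chains with Gaussian coordinate
noise (σ = 0.10–0.20 Å in the standard suite), per-chain random rigid
placement, and loop-confined deletions. Loop residues are drawn without
replacement so the loop sequence is informative even without a planted
motif.

A planted register error deletes `offset` residues at a loop start of one
chain and displaces that chain's remaining loop residues 4.5 Å sideways off
the trace position one register step back. Both the wrong register (4.5 Å)
and the true register (≈ 5.6 Å, the displacement plus one 3.2 Å step in
quadrature) fall inside the greedy acceptance window once diluted by the
flanking block in the refit, so the error is geometrically committable and
repairable either way — while the conserved loop sequence (optionally a
planted WWH motif) makes the true register strictly better under Seq. The
displacement is chosen to sit clearly outside the 2.5 Å anchor tightness
bound even for k = 3, where one clean chain pair dilutes the per-column RMS
pair distance; the generator verifies on construction that the corruption
changed the alignment and that the sequence candidate scores strictly lower,
and refuses uninformative specs.

The standard suite is 20 families (seeds 0–19; k ∈ {2, 3}, loop lengths
5–8, helix lengths 9–11, one family variant with an extra mid-loop deletion
in a third chain). Each family is ~25–30 columns, so the whole suite
refines in a few seconds. What passing on this suite shows: the pipeline
recovers planted register errors whose sequence signal is decisive, and
never degrades a family. What it does not show: behavior on real backbones
(no side chains, idealized secondary structure, single-domain topology, no
bent-frame geometry), on large k, or on the curated benchmark collections
used to evaluate aligners at scale.

## Degenerate inputs and tie-breaks

Alignments need ≥ 2 chains and ≥ 1 column; scoring and refinement need ≥ 3
core columns. Residues without a C&alpha; are dropped at parse time and
counted. Unknown residue codes score as 'X'. Columns with fewer than two
residues contribute no distances. Superposition needs ≥ 3 points. Exact
candidate ties go structural; truncation ties go leftmost; the DP tie-break
is fixed as stated above. All randomness in the generator flows from a
single integer seed; repeated runs are byte-identical.

## Known limitations

* Anchor blocks are inferred from the input alignment's geometry, not from
  the upstream aligner's own fragment assembly; an alignment whose register
  error is geometrically *perfect* over a whole block-length run cannot be
  distinguished from an anchor and will not be repaired.
* A single rigid frame per chain throughout; no bent/flexible
  superposition.
* The built-in progressive aligner is adequate for the short inter-block
  regions it serves; it is not a general-purpose MSA tool.
* Only MAFFT among the external aligners is exercised end-to-end in this
  repository's tests; the other adapters follow the same subprocess
  contract but are verified only for their error paths.
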