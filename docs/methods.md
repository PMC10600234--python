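# Methods

## Problem setting

Structure-prediction-driven binder design generates candidate peptide or
miniprotein sequences against a chosen receptor interface, predicts each
candidate in complex with the receptor, and must then decide — without
experiments — which designs actually bind where they were intended to.
This package implements that evaluation layer: interface geometry, the
bind-score loss used to rank designs, seed-backbone selection, sequence
recovery metrics, and the campaign-level statistics used to choose
selection thresholds.

## Interface definition

The interface between a receptor chain and a binder chain is the set of
cross-chain residue pairs whose β-carbons lie within 8 Å; glycine (and any
residue with a truncated side chain) substitutes its Cα. The comparison is
inclusive at exactly 8 Å — "within" is read as ≤, and the boundary
behaviour is pinned by tests at 7.9/8.0/8.1 Å. Interface residue sets are
the projections of this pair set. Contact density is the number of such
pairs divided by the binder length, in contacts per binder residue.

The Cα surrogate for glycine is a deliberate convention rather than a
virtual-Cβ construction: it is simple, total, and applied identically to
native and predicted structures, so metric differences cancel.

## Superposition and interface RMSD

Native and predicted receptors are superposed by a least-squares (Kabsch)
fit over Cα atoms paired by author residue number; only proper rotations
are admitted, so mirror images produce a large residual instead of a
reflection. Interface RMSD is then the RMSD over the effective-Cβ atoms of
the *native binder interface residues*, with predicted partners found by
sequence position (1..N) — designed sequences carry no meaningful author
numbering. Receptor atoms influence the value only through the
superposition. A design is called successful when this RMSD is ≤ 2 Å
(inclusive, configurable).

An open choice here was whether receptor interface Cβs also belong in the
deviation set; the binder-only reading is implemented because the reported
quantity is the *binder's* placement accuracy, and the receptor is already
fixed by the superposition.

## The bind score

For a predicted complex, a set of receptor target residues, and a
reference binder (the seed backbone, or the native binder when evaluating
against a solved complex):

    loss = plDDT⁻¹ · ( (1/m) Σᵢ dᵢ  +  (1/n) Σⱼ dⱼ · ½ · ΔCOM )

- `plDDT` — mean per-residue predicted lDDT over the binder, 0–100 scale.
- `dᵢ` — for each of the m heavy atoms of the receptor target residues,
  the shortest distance to any binder heavy atom (Å).
- `dⱼ` — for each of the n binder heavy atoms, the shortest distance back
  to any receptor target atom (Å).
- `ΔCOM` — distance between the Cα centroids of the predicted and
  reference binders, measured after carrying the prediction into the
  reference frame by receptor superposition (Å). It penalises placements
  at symmetry-equivalent sites (e.g. the far side of the receptor) that
  the distance terms alone cannot distinguish.

Two readings of the printed formula are possible; the literal operator
precedence — ½·ΔCOM multiplying only the binder→target mean — is the
default, and `compute_loss(..., com_scales_sum=True)` switches to the
alternative (½·ΔCOM scaling the whole parenthesis) so the interpretive
risk is isolated behind one flag. ΔCOM is computed as an *unweighted* Cα
centroid distance: the centroid is the minimal consistent reading, and the
choice is confined to one operation. Hydrogens are ignored everywhere;
plDDT values on a 0–1 scale are rejected with an explicit error rather
than rescaled, because every published threshold assumes 0–100.

Selection thresholds (all inclusive): loss ≤ 0.11 for zero-shot
campaigns; loss ≤ 1.0 together with binder plDDT ≥ 80 for convergence
campaigns; success RMSD ≤ 2 Å.

## Seed cropping

Scaffold hits (e.g. from a Foldseek search, ingested as tab-separated
tables plus structures — the search itself is out of scope) are cropped to
contiguous windows of length L ∈ {10, 20, 30, 40, 50}; a scaffold shorter
than L is used whole. The window maximising the Cβ contact count to the
*chosen* target interface residues wins; ties break to the smallest start
index, then input order. Ranking across hits compares best windows per L
(pooling across L is left to the caller). The assembled inverse-folding
input concatenates receptor backbone → 10 masked positions → seed
backbone, in that order; binder-first ordering is refused because
single-chain-trained sequence models place methionine at position 1 of
the leading block at grossly inflated frequency.

## Recovery metrics

Contact recovery groups amino acids into five physically motivated
categories — Hydrophobic (A F I L M P V W Y), Small (G), Polar (N C Q S
T), Positive (R H K), Negative (D E) — which partition the 20 standard
residues. For each receptor interface position, the unique categories of
its contacting binder residues are annotated (contacts to A, F and R
annotate {Hydrophobic, Positive}: repeats within a category collapse);
the score is the fraction of native annotations preserved by the design.
It is deliberately a recall: categories the design adds are ignored,
because the question is whether native interactions survive, not whether
new ones appear. Non-standard residues map to "X" and carry no category.

Interface sequence recovery is plain positional identity over the native
binder interface positions, assuming equal-length native and design
binders (true by construction for the designs this targets).

The mutation scan emits, for each k in 1..L contact positions, a fixed
number (default 10) of sequences mutated at exactly k randomly chosen
contact positions, substitutions drawn uniformly from the 19 non-identical
standard amino acids ("randomly alter" is not further specified; uniform
is the least-informative choice). The scan is deterministic under its
seed.

## Campaign statistics

ROC curves sweep unique score thresholds (tied scores give one vertex);
AUC is the trapezoidal area and equals the Mann-Whitney pairwise
probability with half credit for ties — the test suite pins this
equivalence to 1e-12. For loss-based selection the orientation flag is
"lower is positive". Success-rate convergence reports, for each n, the
fraction of targets whose first n designs (generation order) contain at
least one success; it is non-decreasing in n by construction. The
density–success profile sorts designs by seed contact density, splits
them into 30 near-equal contiguous partitions (remainder assigned to the
leading blocks, the exact published remainder policy being undocumented),
and reports per-block mean density, success rate, and the Spearman rank
correlation across blocks (mid-ranks for ties; constant vectors are an
error, not a silent NaN). Secondary-structure interface composition
consumes precomputed DSSP labels, reducing 8 classes to three (H/G/I →
Helix, E/B → Sheet, rest → Loop).

## Synthetic fixtures

`make_ideal_complex` builds a receptor strand along z (4 Å per residue)
whose Cβs face the binder, and a binder whose first k residues sit in
register at an engineered 7.5 Å Cβ–Cβ distance — inside the 8 Å cutoff,
while the 4 Å axial stagger puts every off-register pair at ≈8.5 Å,
outside it. The contact count is therefore *exactly* k, with feasibility
bounded by min(receptor, binder) length; remaining binder residues trail
past the receptor's end, out of range. Cα traces carry a small
100°-twist helical wobble (0.9 Å radius) purely so the receptor Cαs are
never collinear and the Kabsch fit is well-conditioned; the wobble does
not touch the Cβ lattice. The "predicted" complex is the native one with
the binder rigidly displaced and the whole complex optionally rotated,
giving analytic ground truth: interface RMSD = ΔCOM = |displacement|.

`make_design_table` plants a campaign with the study's structure:
per-target seed contact density uniform on [0.5, 9], per-target success
probability scaled around a campaign-wide 6.5% default (the realistic
rate for heteromeric interfaces), successful designs drawing interface
RMSD below 2 Å and failures above 2.5 Å, binder plDDT falling with RMSD,
and loss a noisy monotone function of RMSD over plDDT.

What the fixtures do **not** emulate: real side-chain packing and
chemistry (every residue is alanine-like), partial interface
displacements (the predicted binder moves rigidly, so RMSD equals ΔCOM
exactly — real predictions decouple them), correlated per-residue plDDT
profiles, and the heavy class imbalance and annotation noise of
PDB-derived campaigns. Passing tests therefore demonstrate correctness of
the *metrics and statistics*, not predictive performance on real design
campaigns.

## Reproduction script

`scripts/acceptance.py` re-runs the full stack from scratch at fixed
problem sizes — 100 random complexes for the loss-oracle agreement, 100
rigid-transform trials for invariance, 100 scaffolds for crop search, a
2000-target zero-shot campaign and a 300-target × 100-design convergence
campaign — sizes chosen to exercise every code path in seconds on one
CPU while keeping the campaign statistics stable to a few percent across
seeds. All randomness derives from the single `--seed` argument.

## Known limitations

- The evaluator consumes predicted structures; it cannot flag a
  confidently wrong predictor (garbage-in applies to plDDT especially).
- Pairing by sequence position assumes equal-length native and design
  binders; indels are unsupported.
- mmCIF input, multi-model ensembles beyond model 1, and
  solvent-accessibility interface definitions are out of scope.
- ΔCOM as an unweighted Cα centroid slightly differs from a true
  mass-weighted centre for glycine-rich binders; the difference is well
  under the scale of the ΔCOM term's role (mirror-site discrimination).
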