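# Methods

This note documents the models and numerical choices behind `pocketcons`:
what each stage computes, which parts are faithful reimplementations of
published procedure and which are documented surrogates for proprietary
tools, and what the synthetic generators do and do not emulate.

## 1. Sequence curation and distances (`seqcons`)

Length-outlier filtering removes sequences whose ungapped length is strictly
below `fraction × mean` (default 0.6); the boundary sequence is retained.
Representative selection keeps one record per organism — the longest
sequence, ties broken by lexicographically smallest id — so that heavily
sequenced species do not dominate the alignment.

Pairwise distance between two aligned rows is `1 − similarity`, where
similarity is the mean BLOSUM62 score over columns ungapped in both rows,
rescaled to [0, 1] between the pair's own attainable extremes: per column the
maximum is the larger of the two letters' self-scores and the minimum is the
larger of the two letters' worst-case scores. Identical sequences therefore
sit at distance 0 and a worst-scoring pairing at 1. A pair sharing no
ungapped column is an error rather than a guess.

## 2. Neighbor joining

Standard Saitou–Nei agglomeration on the distance matrix. Two determinism
choices: Q-matrix ties are broken by the smallest label pair in sorted
order, and negative branch lengths are clamped to zero (standard practice).
The implementation is hand-written so these tie-breaks are guaranteed; the
test suite cross-checks topologies against an independent NJ implementation
and verifies exact recovery of additive matrices (Robinson–Foulds distance 0,
branch lengths to machine precision).

## 3. Conservation scoring and grading

The published workflow used an empirical-Bayesian rate model (ConSurf).
That inference is out of scope; the surrogate is deterministic and preserves
the ordering properties the downstream analysis needs:

- **Sequence weights** are Gerstein–Sonnhammer–Chothia weights computed from
  the NJ tree: each branch length is shared among the leaves below it in
  proportion to their accumulated weights, which suppresses redundant
  near-duplicate sequences (duplicating a sequence shifts standardized
  column scores by < 0.25 sd on the packaged fixtures).
- **Column score** is the weighted mean over non-gap pairs of the *rescaled*
  BLOSUM62 pair score (the same per-pair [0, 1] rescaling as the distance
  matrix). The rescaling matters: on raw half-bit scores an invariant
  alanine column (self-score 4) lands mid-scale while an invariant
  tryptophan column (11) tops it, which would break the required properties
  that any fully conserved column grades 9 and that planted slow columns
  outrank fast ones. With rescaling, every invariant column scores exactly 1
  before standardisation.
- **Gaps**: pairs involving a gap are skipped; columns with more than 50%
  gaps (or fewer than two residues) are flagged and forced to grade 1.
- **Standardisation** to mean 0 / sd 1 across scorable columns, then nine
  equal-width bins over the observed range; grade 9 is the most conserved.
  Degenerate case (all scores equal): grade 9 if every column is invariant,
  otherwise grade 5. Binning is configurable but equal-width is the default
  because it is reproducible and monotone in the score.

Projection onto a structure is a global pairwise alignment (BLOSUM62, gap
open −11, extend −1) of the row's ungapped sequence against the
structure-derived sequence; matched positions inherit the column grade,
unmatched structure residues are flagged ungraded, and an alignment identity
below 30% is treated as a wrong-chain error.

## 4. Structure ingest and ensembles (`structio`)

Ingest keeps one chain (default A), first model, altloc A/blank, heavy atoms
only; waters, ligands and other heteroatoms are removed except magnesium,
which is kept as a cofactor; selenomethionine is read as methionine. (The
published preparation text contains a contradictory sentence about waters
being *added*; this implementation removes all waters and documents the
discrepancy.) Hydrogens, protonation and restrained minimisation are out of
scope — no implemented descriptor needs them. HELIX/SHEET records become
per-residue annotations (anything else is loop); resolution, missing-residue
count (REMARK 465) and mean B-factor feed representative selection.

Superposition matches C-alpha atoms by author residue number, falling back
to sequence alignment when fewer than 30 numbers coincide, and solves the
least-squares problem by SVD (proper rotation enforced). The pairwise RMSD
matrix is embedded by classical (Torgerson) MDS into min(8, n−1) dimensions
— k-means needs coordinates, and classical MDS of a Euclidean-like distance
matrix is the standard deterministic choice — then clustered with seeded
k-means (10 restarts, k capped at the number of structures). The
representative of each cluster is chosen by resolution, then fewest missing
residues, then lowest mean B-factor, then label.

## 5. Pocket detection and descriptors (`sitefind`)

The original tool's per-point energetics are proprietary; the surrogate is
purely geometric and documented:

- **Grid**: axis-aligned, default spacing 0.35 Å with a 6 Å margin. The
  test suite and synthetic end-to-end runs use 0.7 Å to keep each fixture
  under a few seconds; all monotonicity properties are spacing-robust.
- **Site point**: outside every Bondi vdW sphere + 0.5 Å probe offset,
  within 4 Å of some atom, and buried — at least half of 110 quasi-uniform
  rays (golden-spiral lattice) hit an atom within 8 Å. The 110-ray
  quadrature puts a flat half-space at burial 0.46–0.48 depending on height,
  within the 0.5 ± 0.05 band used for validation.
- **Sites**: connected components under 26-neighbour grid adjacency;
  components under 15 points dropped; points 4 Å or farther from every
  other point of their site truncated as satellites; at most 10 sites
  reported, ranked by SiteScore with ties broken by larger point count then
  lexicographic centroid.
- **Descriptors**: volume = n·spacing³ exactly; enclosure = mean burial;
  exposure = mean open-ray fraction restricted to the hemisphere around the
  site's principal opening (the net direction of open rays; flagged when no
  opening exists). Contact, hydrophobic and hydrophilic character are
  Gaussian-kernel (σ = 2.5 Å, 8 Å cutoff) proximity sums over protein atoms
  — apolar = C/S not within 1.8 Å of an N/O of the same residue (a
  connectivity-free bond proxy), polar = N/O — divided by calibration
  constants (11.36, 5.77, 5.60) frozen once so the packaged reference pocket
  (enclosed, mixed lining, `sitefind.reference_pocket_spec`) sits at
  contact = phobic = philic = 1.0; the hydrophilic/lipophilic balance is
  1.6 × philic/phobic so the reference matches the published average
  submicromolar profile. Donor/acceptor character is the kernel-weighted
  ratio of protein oxygens (acceptors) to nitrogens (donors); on the
  synthetic structures this ratio is oxygen-skewed relative to real pockets
  because polar side chains are single-atom proxies. Charged lining
  fraction counts D/E/K/R (histidine neutral at pH 7) among residues within
  4 Å of any site point.

**Score equations.** The printed equations are linear in the capped
site-point count, but 0.0733 × 100 alone would put every full-size site near
7–8, contradicting the published score scale (threshold 0.8, reference
profile scores of ~1, best enzyme 1.13). The site-point term is therefore
implemented on √min(n, 100), which reproduces the printed scale exactly
(reference profile → SiteScore 1.0547, DScore 1.084); the literal linear
reading remains available via `n_transform="linear"`.

## 6. Probe mapping (`probemap`)

FFT rigid-body docking with molecular-mechanics energetics is replaced by a
single-sphere-per-probe surrogate: the 16 classic probes carry an effective
radius, donor/acceptor counts and an apolar flag; candidate centres are a
2 Å surface lattice outside the vdW volume; the score (lower = better) is
−(apolar contact density) − 0.8·(probe donors × protein acceptor density +
probe acceptors × protein donor density), plus a 0.5 × polar-density
desolvation penalty for apolar probes and an infinite clash penalty inside
the vdW volume. The best 50 poses per probe are kept. This preserves
exactly what the analysis consumes: cluster locations, contact-based ranks
and 4 Å linings. Clustering is greedy (best-scoring unassigned pose seeds a
3 Å cluster); consensus clusters are ranked by total nonbonded contacts
(protein heavy atoms within 4.5 Å of a pose centre, a standard contact
distance), ties by distinct probe-type count then centroid — a total order.
Predicted binding sites are the top three merged groups (5 Å centroid
merge), each with residues within 4 Å of any member pose.

## 7. Assessment and statistics (`assess`)

Site typing: orthosteric if any lining residue is within 4 Å of a ligand
atom, cofactor if within 4 Å of a cofactor atom, orthosteric-with-merged-flag
if both (colliding pockets). Conserved fraction = conserved (grade ≥ 8)
graded lining residues / graded lining residues — ungraded residues are
excluded from the denominator. Quadrants split the SiteScore × DScore plane
at 0.8/0.8 with boundaries inclusive toward the upper-right, matching the
inclusive reading of every published threshold here ("at least 15 site
points"); the 26.3% charged flag is raised only strictly above the
threshold. The combined filter applies scores first, then conservation, and
reports survivors plus stage counts.

Group comparison reports a Kolmogorov–Smirnov statistic against a normal fit
(descriptive; with fitted parameters the p-value is conservative) and always
uses the Mann–Whitney U test for the decision: exact by full enumeration of
rank assignments (tie-aware, two-sided, deviation-from-mean ordering) when
both groups have ≤ 8 values, tie-corrected normal approximation otherwise.

## 8. Synthetic world (`synthdata`)

- **Structures**: pseudo-residues are a C-alpha plus one side-chain proxy
  atom typed by class (C hydrophobic, O polar, N/O charged). Lining
  residues (60% of the residue count by default) sit with proxy atoms
  exactly on the cavity surface; the rest sit on the outer shell. The mouth
  removes residues inside a spherical cap of the stated solid-angle
  fraction, giving monotone control of enclosure. Defaults (12 Å shell,
  4 Å cavity, 90 residues, 50/30/20 hydrophobic/polar/charged lining) give
  a pocket of realistic burial and mixed chemistry whose descriptors fall
  in the published submicromolar ranges.
- **Alignments**: a continuous-time Markov chain with BLOSUM62-derived
  exchangeabilities (2^(score/2), consistent with half-bit log-odds) and
  uniform equilibrium frequencies by default, normalised to one expected
  substitution per site per unit branch length, with discrete relative-rate
  classes per column (default 0.1 vs 5.0 in equal proportion — a clearly
  separated slow/fast world). Zero-rate columns are invariant by
  construction. The root sequence and per-column classes can be pinned so
  the end-to-end fixture evolves an alignment from the synthetic structure's
  own sequence with slow columns at the cavity lining.
- **Ensembles**: family centroids are coherent random deformations of RMSD
  magnitude `between_shift`; members add i.i.d. coordinate noise.
- **Candidate tables**: eight pinned rows cover both sides of every filter
  threshold; the rest are uniform over threshold-spanning ranges.

What the generators do *not* emulate: real folds, side-chain rotamers,
solvent, crystallographic artefacts, alignment gaps, or realistic
donor/acceptor balance. A green test therefore establishes that the
pipeline's decision logic, orderings and thresholds behave as specified on
controlled geometry and evolution — not that descriptor values match any
proprietary tool's on real proteins. The published enzyme-specific numbers
(per-enzyme conservation percentages, site counts, survival rates) require
the real structure sets and external tools and are deliberately not targets.

## 9. Known limitations

- The exposure/contact/balance definitions of the original tool are
  proprietary; the surrogate's calibration constants are package choices,
  not published values.
- The donor/acceptor descriptor is element-based (N vs O) without
  protonation states; histidine is treated as neutral.
- The conservation surrogate has no rate posterior; grades are relative to
  the alignment at hand, as in the visual nine-grade convention.
- mmCIF input, nucleotide alignments and hidden/cryptic site detection are
  out of scope.
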