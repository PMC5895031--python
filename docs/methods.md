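# Methods

This note documents the models implemented in `varstab`, the defaults and
why they were chosen, what the synthetic generators do and do not emulate,
and the numerical decisions a user auditing results will want to know.

## Consensus triage of missense variants

Each variant carries one call from each of eight effect predictors. Calls
are binarized to damaging/benign per tool:

| tool | damaging when | benign when |
|---|---|---|
| PROVEAN | "Deleterious" | "Neutral" |
| SIFT | "Damaging" / score < 0.05 | "Tolerated" / score ≥ 0.05 |
| PolyPhen-2 | "probably damaging" / score ≥ 0.85 | "benign", "possibly damaging" / score < 0.85 |
| PhD-SNP | "Disease" | "Neutral" |
| SNAP2 | "Effect" | "Neutral" |
| SNPs&GO | "Disease" / score > 0.5 (strict) | "Neutral" / score ≤ 0.5 |
| FATHMM | "Damaging" | "Tolerated" |
| I-Mutant 3 | "Large decrease of/in stability" / ΔΔG < −0.5 kcal/mol | "Neutral", increases / −0.5 ≤ ΔΔG |

Category matching is case-insensitive and tolerant of the "of stability" /
"in stability" wording variants that appear in published tables.

The consensus label is **D** (deleterious) when at least 5 of the 8 votes
are damaging, **N** otherwise. Two boundary decisions are fixed by
row-level evidence in the packaged panel: rows with exactly 5 damaging
votes are published as D, so the implemented rule is votes ≥ 5; and
PolyPhen-2's "possibly damaging" must count as a benign vote, because the
A94V row (possibly damaging plus four damaging calls) is published N while
counting it as damaging would force D. Under these rules the re-derived
labels match 51 of the 52 published rows. The remaining row, G63S, has
only 4 damaging votes under *every* binarization consistent with the other
51 rows yet is published D; whether that is a transcription slip in the
source table is unknowable from the data, so the concordance report flags
it and the published label is left standing. Published labels are never
overwritten — discrepancies are always surfaced, not corrected.

Region enrichment counts deleterious variants whose residue position falls
in given 1-based closed intervals, with union semantics (a variant in two
overlapping intervals counts once). The conservation overlay intersects
the deleterious set with residues whose conservation grade (integer 1–9,
9 = most conserved) reaches a cutoff; the default "highly conserved"
cutoff is grade ≥ 8 and is exposed as a parameter because no standard
cutoff exists.

## Variant catalogs

Coordinates are 1-based and intervals closed on both ends throughout,
matching residue-numbering conventions. A variant with a genomic position
is classified by interval membership; inside the CDS the reference and
alternative codons are translated to split synonymous from non-synonymous
changes, which is why catalog records carry optional reference/alternative
alleles. The 5' and 3' UTR classes are pooled as "utr" in summaries but
kept distinct in the gene model. Only plus-strand single-transcript gene
models are supported.

Composition percentages are rounded half-up to one decimal, the convention
of published tables. Note that consistent rounding cannot reproduce every
published one-decimal figure simultaneously when the source itself rounds
inconsistently; percentages here always sum to 100.0 ± 0.2 (rounding
slack). Malformed table rows are collected into a rejects report with the
line number and reason — counts are audit quantities, so nothing is
silently dropped.

## Codon-usage relative adaptiveness

For amino acid a with synonymous codons j, relative adaptiveness is
w_aj = 100 · f_aj / max_j f_aj, where f is the usage frequency
(occurrences per 1000 codons). The embedded default table is a standard
Homo sapiens codon-usage summary (CUTG-style, GenBank coding sequences),
shipped as package data; with it the leucine family scales CTG = 100 and
CTA = 18 (integer display rounding; computations keep full precision).
Ties for a family maximum give every tied codon 100 and are flagged. Stop
codons carry no adaptiveness (NaN in profiles) and are excluded from
cluster statistics.

Rare-codon clusters: position i's window covers
[i − ⌊w/2⌋, i + ⌊w/2⌋] clipped to the profile; positions whose window
mean falls below the threshold are flagged, runs of flagged positions are
expanded to the union of their windows' extents, and overlapping or
adjacent extents merge. Reporting window extents rather than window
centres makes the reported interval cover the actual low stretch. The
defaults — window 15 codons, threshold 40% — are exposed parameters: no
standard windowing exists, and these values cleanly separate a planted
~20%-adaptiveness block from a family-maximal background. Because edge
windows mix block and background codons, a detected cluster extends up to
half a window beyond the true block; recovery tests therefore assert ≥90%
coverage of the planted block, not exact bounds.

## Trajectory statistics

Superposition uses the weighted Kabsch algorithm (SVD of the weighted
covariance; the smallest singular direction is sign-corrected so only
proper rotations, det R = +1, are returned). Fewer than 3 atoms or
collinear point sets raise a geometry error. The test suite checks the
result against an independent rotation-space search oracle (multi-start
Nelder–Mead over rotation vectors) to 10⁻³ Å on small instances.

- **RMSD series**: per frame, the minimal RMSD of the selected atoms
  against a reference after superposition. Default selection is the
  backbone preset {N, CA, C, O}; Cα-only is the `calpha` preset. Default
  reference is the first frame (a common convention; exposed as a
  parameter).
- **RMSF**: frames at or after the equilibration start are superposed
  onto the time-averaged structure, iterated until the mean structure
  moves less than 10⁻⁶ Å (max 20 iterations); RMSF_i is the RMS
  displacement of atom i from its mean position. Superposing onto the
  first frame instead is available (`reference="first"`) since either
  convention appears in practice. For isotropic per-coordinate Gaussian
  fluctuations of amplitude σ the expected RMSF is σ√3; the rigid-body
  fit absorbs ~6 degrees of freedom, deflating the estimate by a factor
  ≈ √(1 − 2/N) for N fitted atoms — negligible for a 169-residue chain,
  which is why recovery tests use chains of that size.
- **Radius of gyration**: Rg = √(Σ mᵢ|rᵢ − r_com|²/Σ mᵢ), mass-weighted,
  rotation/translation invariant by construction.
- **Equilibrium statistics**: mean and sample SD (ddof = 1) over frames
  at/after the window start; the default window start of 12 ns reflects
  when membrane-protein simulations of this size typically equilibrate,
  and is always overridable.
- **Group comparison**: both samples are Shapiro–Wilk tested at 0.05;
  if both pass, Student's t-test (equal variances), otherwise the
  Mann–Whitney U test. The rank branch uses Mann–Whitney rather than the
  signed-rank test because the compared windows are independent samples,
  not paired measurements. Significance is p < 0.05. Calibration is
  checked by simulation: the type-I error over 2000 null comparisons must
  stay within [0.03, 0.07].
- **Model quality**: the combined homology-model Z-score is the fixed
  linear combination 0.1456·Dihedrals + 0.3906·Packing1D +
  0.4656·Packing3D of the component Z-scores.

Multi-model PDB files are read through Biopython's parser; atom identity
(residue index, atom name) must be consistent across models, and frame
times are assigned as model index × 25 ps by default (the snapshot spacing
of the simulations this layout mirrors; PDB carries no time axis). The
writer emits fixed-column ATOM records with occupancy 1.00 and B-factor
0.00; coordinates round-trip to the format's three decimals.

This module analyses trajectories; it contains no force field, integrator
or membrane/solvent construction, and no attempt is made to reproduce any
specific simulation's absolute RMSD/RMSF/Rg values — those depend on the
physical system and sampling, not on the statistics computed here.

## Chase kinetics

Normalisation: value(r, t) = 100 · (target(r,t)/loading(r,t)) /
(target(r,0)/loading(r,0)) per replicate r, so t = 0 is exactly 100% and
arbitrary density units cancel. Replicates are summarised as mean ± SEM
(SEM = SD/√n over replicates).

The decay fit is nonlinear least squares of N(t) = 100·e^(−kt) with
k ≥ 0 on the pooled normalized points — nonlinear rather than log-linear
to avoid log-transform bias at low signal, with the intercept pinned at
100 because the normalisation anchors it (a free-intercept variant is
available). A fitted k below 10⁻⁴/h is reported as "no detectable decay
within the window" (half-life ∞): over a 24 h chase that rate would move
the signal by <0.3%, below densitometry resolution. The 95% CI for k
comes from the curve-fit covariance.

Half-life change is 100·(1 − t½_mut/t½_ref), positive = faster
degradation. Degenerate cases are flagged rather than silently computed:
a non-decaying reference with a decaying mutant reports 100%; a
non-decaying mutant against a decaying reference reports a non-positive
value with a flag; two non-decaying fits report 0 with a flag. Because a
study can derive a "percent destabilised" figure either from fitted
half-lives or from endpoint ratios, the kinetics report carries both the
fitted comparison and the model-predicted 24 h endpoint.

## Synthetic data

Every generator is seeded (`numpy.random.default_rng`), returns a truth
manifest recording exactly what was planted, and is byte-deterministic
for a fixed spec. Downstream recovery tests read truth only from the
manifest.

- **Catalog**: a single-gene model (100 bp 5'UTR, four CDS exons, three
  300 bp introns, 200 bp 3'UTR; plus strand) with a stop-free random CDS;
  classes drawn per the requested fractions (defaults 82.4 / 6.4 / 6.4 /
  4.8% intronic/UTR/nsSNP/sSNP, the composition of a real gene-body
  catalog); coding variants are realised as single-base changes of the
  requested synonymy; a requested number of residues carry exactly two
  distinct substitutions, all others one. MAFs are lognormal around 10⁻⁴
  (most variants in population catalogs are rare), with 10% missing.
- **Panels**: eight calls per row drawn from each tool's published
  vocabulary so the damaging-vote count equals the planted count.
- **CDS**: family-maximal codons outside planted blocks, family-minimal
  codons (from families whose minimum is ≤ 30%) inside.
- **Trajectories**: frames are rigid motion (random rotation ≤ 20°,
  translation ≤ 5 Å per frame) applied to the reference plus per-atom
  isotropic Gaussian noise with a per-residue amplitude profile; 25 ps
  frame spacing. The default reference is a 169-residue ideal helical
  dummy chain (rise 1.5 Å, 100°/residue) — the subject protein's length —
  so nothing needs downloading.
- **Chase**: triplicate series over 0–24 h; target = loading × 100 ×
  e^(−t ln2/t½) × lognormal noise of chosen CV (10% default, a realistic
  densitometry error); loading densities vary uniformly per lane.

What the generators do **not** emulate — and hence what passing recovery
tests do not show: trajectories have no physical correlations (no
secondary-structure coupling, no anisotropy, no time correlation between
frames), the helical dummy chain is extended rather than compact (its Rg
is far larger than a folded protein's), synthetic CDSs have codon-level
but not sequence-level realism, panel votes are independent across tools
whereas real predictors are strongly correlated, and chase noise is
independent across lanes whereas real blots share systematic transfer
effects. Recovery of planted parameters demonstrates estimator
correctness, not robustness to structured real-world error.

## Problem sizes used in the checks

Recovery checks run at sizes where sampling error is comfortably inside
the asserted tolerances: RMSF recovery uses 2000 frames × 169 residues per
amplitude (per-residue sampling error ≈ 1.6%, asserted band ±5%); the
superposition oracle comparison uses 100 random ≤6-atom instances; decay
recovery uses 200 series of 7 time points × 3 replicates at 10% noise; the
comparison-test calibration uses 2000 null simulations of n = 30 samples.

## Known limitations

- Single-transcript, plus-strand gene models; no liftover or multi-build
  handling; no VCF parsing beyond plain columns.
- The consensus rules cover the vocabularies and thresholds of the eight
  supported tools only; other predictors need explicit rules.
- The codon analysis implements relative adaptiveness only — no tRNA
  adaptation index, codon-pair bias or ramp models.
- The chase model is single-exponential; multi-phase decay or
  compartment-specific turnover is out of scope.
- The trajectory module assumes constant atom identity across frames
  (no grand-canonical or alchemical trajectories).
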