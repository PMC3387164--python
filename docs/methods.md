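# Methods

## Scope and model

The package implements the in-silico arm of a transgene allergenicity
assessment: sequence comparison of a candidate protein against an allergen
panel under the two FAO/WHO Codex criteria, a physicochemical peptide
similarity index (PD), codon-level design and verification of
allergenicity-reducing point substitutions, and the group-comparison
statistics used on the validating immunology and antifungal assays.
Structural work (homology modelling, secondary-structure validation,
Ramachandran assessment) and all wet-lab procedures are out of scope; where
the original study consumed results from a remote allergen database server,
this package substitutes its own explicit, configurable alignment model and
seeded synthetic inputs.

## Coordinates and sequence conventions

All positions are 1-based and inclusive at both ends (`47GDGGVG52` is six
residues); 0-based half-open conversion happens only at I/O boundaries.
Alphabets are strict (20 amino acids, ACGT) by default; a permissive parse
maps ambiguity codes to a wildcard (`X`/`N`) that never counts as an
identity. ORFs must start with ATG and carry exactly one, terminal, stop
codon; a 3k-nt ORF translates to k−1 residues. Molecular masses use
average (not monoisotopic) residue masses, since the experimental reference
point is a gel estimate (~19 kDa for the His-tagged protein).

## Allergen screen

**k-mer criterion.** `find_contiguous_matches` walks every diagonal of the
comparison matrix and reports each *maximal* run of identities of length
≥ k (default 6). Maximality suppresses nested shorter matches, matching how
screening reports list each shared region once. The criterion is symmetric
in query/subject up to coordinate roles.

**Window criterion.** The scan runs over alignment columns of the single
optimal local alignment, gaps counting as mismatches — not over re-aligned
raw-sequence windows. This is a deliberate, documented dialect: it is
deterministic, O(columns), and consistent with FASTA-style database
reports. A window of 80 columns slides in steps of one; identity is
`100·identities/80`; the criterion is *strictly* greater than 35%, so a
window with 28/80 = 35.00% does not flag and 29/80 = 36.25% does.
Alignments shorter than the window are scored as one truncated window with
the column count as denominator.

**Alignment model.** Local alignment via Smith–Waterman with a configurable
substitution matrix (default BLOSUM62) and affine gaps in the BLAST
convention: a gap of length L costs `open + L·extend` (defaults 11/1).
Among co-optimal alignments the one with the smallest query start, then
smallest subject start, is selected (up to 32 co-optima inspected) for
reproducibility. Full-alignment identity uses all aligned columns,
including gap columns, as denominator; the original report's exact
convention is unrecoverable, so this choice is explicit and configurable
code, not an emulation claim.

**E-value.** Karlin–Altschul `E = K·m·n·exp(−λS)` with configurable K and λ
(defaults 0.041 and 0.267, the customary gapped BLOSUM62 values). m·n is
the query×subject length product; no database-size correction is applied
since panels here are explicit sequence lists. E-values and identity
percentages of the original database server are *not* reproduced — its
aligner and parameters are unpublished — and the shipped reference report
rows carry those columns as context only.

## Property distance

PD between equal-length gap-free peptides is the eigenvalue-weighted
Euclidean distance in the E1–E5 descriptor space (five components from
multidimensional scaling of 237 physicochemical amino-acid properties).
The descriptor table ships as a versioned TSV
(`data/aa_descriptors_e1e5.tsv`); the loader refuses to run without it and
every PD result records the table version. The eigenvalue weights are the
decreasing component eigenvalues of that scaling (0.796, 0.361, 0.301,
0.277, 0.240). No length normalisation is applied — the defining equation
has none — but a per-residue-normalised variant is available behind a flag
because full-sequence PD values in database reports (range ≈ 6–16) likely
reflect windowing conventions not stated anywhere; absolute agreement with
those printed PD values is therefore not claimed, and the package's tests
assert the metric's properties (identity, symmetry, triangle inequality,
λ-scaling) instead. For alignments, gap columns are dropped before PD is
computed (the metric is undefined on gaps), and a minimum-PD window of
configurable width is reported alongside the whole-alignment value.

On the shipped table the chemically conservative substitution I↔V has a
smaller single-residue PD (0.135) than the cross-class substitution H↔S
(0.359), as a physicochemical distance should.

## Mutagenesis

Residue position p occupies CDS nucleotides (3p−2, 3p), frame anchored at
the first base of the start codon — the convention consistent with the
published primer spans (codon 10 at 28–30 inside the 22–43 primer window).
`apply_mutations` replaces each target codon with the mutant-residue codon
minimising the Hamming distance to the wild codon; ties prefer preserving
the wild third position, then lexicographic order (deterministic, and the
choice mutagenesis primers typically make). Minimality is verified
exhaustively against a brute-force oracle over all 61 sense codons × 20
target residues. Primer verification is purely sequence-level (exact
matching outside declared edit positions; no thermodynamic model), because
the design being checked is specified at the sequence level; melting
temperatures use the Wallace rule `2(A+T)+4(G+C)` as a convenience only.
The published H45S primer pair contains a one-base internal inconsistency;
the verifier reports the discordant position (it cannot attribute it to
forward or reverse without the deposited CDS) and never silently repairs
input data.

## Statistics

Normality is screened per group (Shapiro–Wilk), not on pooled residuals —
the screen-then-branch reading of the original analysis plan. If every
group passes at α (default 0.05) the groups are compared by one-way ANOVA
with Tukey HSD pairwise verdicts at the same α; otherwise by the
Kruskal–Wallis omnibus with no post-hoc (none is defined for this
pipeline; the omnibus p is reported with a note). Groups need n ≥ 3 and
non-zero variance; verdicts are invariant to group order.

Percent contrasts between group means follow the convention that
reproduces the study's reported values: `100·(ref − other)/ref` with the
*larger (treated)* mean as reference. Report rounding is nearest integer,
except magnitudes below 15 keep two decimals (so a 12.81% contrast is not
flattened to 13%); unrounded values are always retained. One reported
contrast ("about 27%") is approximate in the source (exact value 27.8) and
is matched only within ±1 point. Dose-wise antifungal inhibition is
`100·(1 − treated/control)` on survival counts.

## Synthetic data

Generators are pure functions of spec + seed (byte-identical reruns) and
emit ground-truth tables sufficient to assert every downstream flag.

- *Allergen panel*: uniform-background random proteins (natural-composition
  backgrounds available; fixtures use uniform, whose 6-mer collision
  probability between two ~160-mers is ≈ 4·10⁻⁴, making clean fixtures
  easy to verify) in the 137–161 length range of PR-10 homologs, with
  motifs planted at recorded spans. The default panel mirrors the
  published screen: 19 sequences with the reference lengths and the five
  epitope-region motifs (GDGGVG, TSHYHT, EEEIKAGK, FPEGSHFK(Y), DSDNLI) at
  their reported subject positions.
- *Window pairs*: identity columns are W/W and every other column a
  positively scoring non-identical pair (K/R), so the gapless full-length
  pairing is the unique optimal local alignment and the 80-column window
  contains exactly the requested number of identities — the 35% boundary
  can be probed exactly.
- *Immunology groups*: normal draws at the study's printed group summaries
  (control 1.80 ± 0.32, wild 3.02 ± 0.16, mutant 2.18 ± 0.34 OD units,
  n = 5), normal by construction to match the parametric route the study
  took after its normality screen.
- *Survival counts*: binomial thinning of a control colony count (default
  200) with dose-dependent survival probabilities calibrated so expected
  inhibition matches the reported dose response (e.g. 73% at 8 µg/mL,
  91% at 10 µg/mL for the wild protein) — the simplest mechanism
  consistent with percent-inhibition summaries.

What the generators do *not* emulate: true PR-10 homolog evolution (real
panels share far more than planted motifs), ELISA measurement error
structure, or fungal growth kinetics. Passing tests therefore demonstrate
the correctness of the criteria, metrics and statistical routing — not
database-level recall on real allergen panels.

## Problem sizes and determinism

The test suite uses panels of 19 sequences (~137–161 residues), 200 random
pairs ≤ 60 residues for the brute-force match oracle, 1000 random peptide
triples for the PD metric axioms, and 500–1000 seeded replicates for the
statistical power and type-I simulations; these sizes give stable Monte
Carlo estimates (binomial SE ≈ 0.7% at 1000 replicates) while keeping the
suite fast. All randomness flows through explicit seeds; property tests
run derandomised. Under identical groups the pipeline's family-wise
false-positive rate was estimated at 0.051 (4000 replicates), so the
acceptance check asserts |rate − 0.05| ≤ 3 binomial standard errors.

## Known limitations

- The original screen's E-values, identity percentages and absolute PD
  values are not reproducible without the database server's unpublished
  aligner settings; agreement is claimed at the level of criteria,
  motifs and properties only.
- The exact residues of the study's own protein require its deposited
  accession; the packaged query generator produces a synthetic 159-residue
  stand-in carrying the documented motifs at their reported positions.
- One coordinate ambiguity in the source (the DSDNLI span printed once as
  25–30 and once as 26–31) is handled by reporting matches in both query
  and subject coordinate frames rather than adjudicating.
- The Kruskal–Wallis route reports no pairwise verdicts; small-n chi-square
  approximation caveats apply.
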