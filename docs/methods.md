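# Methods

## The analysis in one paragraph

One liganded reference structure defines two residue sets: *binding* residues
(any heavy atom within 5.0 Å, inclusive, of any ligand heavy atom; hydrogens
ignored because crystal structures rarely resolve them) and *surface*
residues (relative solvent accessibility strictly above 0.20). Both sets are
carried to every member of an ortholog-family alignment through the columns
of the reference sequence. Per ortholog group, the pipeline counts surface
columns whose charge class — positive {K,R}, negative {D,E}, neutral
otherwise, histidine included — differs in at least one species, and tallies
binding residues by side-chain size class: small {S,T,C,G,P,A,V},
intermediate {H,D,E,N,Q,I,L,M}, large {R,K,F,Y,W}. Heterogeneity across
groups and between pocket size profiles is tested with Pearson's chi-square;
enrichment of charge variation at positively selected surface sites with
Fisher's exact test.

## Solvent accessibility

SASA uses the Shrake–Rupley construction: each heavy atom's sphere of radius
(van der Waals + probe) is covered with a Fibonacci (golden-angle) lattice of
test points; the accessible fraction is the share of points outside every
neighbour's expanded sphere, found with an exact k-d-tree candidate search
(verified equal to all-pairs in tests).

* probe radius 1.4 Å (water); 960 points per atom by default (≥92 enforced);
* van der Waals radii: C 1.70, N 1.55, O 1.52, S 1.80, Br 1.85, H 1.20 Å;
  unknown elements fall back to 1.70 Å;
* relative accessibility divides per-residue SASA by the Tien et al. (2013)
  theoretical maximum for the residue type; values are *not* clamped at 1
  (extended termini legitimately exceed the folded-context maximum, and
  classification only uses the strict > 0.20 rule);
* bound ligands do not occlude the polymer by default (`occlude_ligands`
  turns that on);
* altloc duplicates keep the highest-occupancy conformer, ties broken by the
  alphabetically first identifier; waters are dropped at parse time.

Numerical behaviour, measured on the synthetic bundle: the lattice is
deterministic and orientation-fixed, so rigid motion of the molecule changes
per-atom areas only through the lattice (totals move <0.1%, individual
near-buried residues up to a few percent); rotating the lattice together with
the molecule reproduces areas to 1e-9. Doubling the lattice to 1920 points
moves totals <0.5% and per-residue areas by at most ~1.5 Å²; relative changes
on partly buried residues can reach ~4% because their areas are small. Tests
therefore assert total agreement within 0.5% and per-residue agreement within
max(2%, 2 Å²), plus ≤3% agreement with an independent Monte-Carlo
point-sampling oracle. Borderline residues near the 0.20 threshold can
classify differently from tools with other point sets or max-ASA tables; both
are configurable.

## Binding pocket

The 5.0 Å rule is inclusive (≤) and pools all ligand copies. The core set
removes two user-identified bridge cysteines and a user-supplied last-helix
residue range — supplied, not inferred, because helix boundaries are a
modeling decision; the packaged 34-residue reference list uses its three
C-terminal members. Size-class comparisons drop classes empty in both
profiles before the chi-square (the statistic is undefined on zero margins);
degrees of freedom follow the retained table.

The three size classes as implemented follow the classification that covers
all 20 amino acids (methionine intermediate); an alternative published
wording omits M. The class sets are asserted at import to partition the
standard alphabet exactly.

## Family mapping

Reference numbering starts at 1 at the first non-gap reference position
(offset configurable for precursor-numbered constructs). Pairwise identity
divides identical matches by shared non-gap columns (alternative
shorter-sequence denominator by flag); because alignment tools document their
denominators loosely, identity values are comparable only within one
convention. A gap at an analyzed column never constitutes a charge state:
the column is evaluated on the non-gap species and dropped when fewer than
two remain (a `gap_is_change` mode treats gaps as their own state instead).

## Statistics

* Chi-square: Pearson, no Yates correction, p from the χ² upper tail,
  df = (R−1)(C−1). The asymptotic p agrees with an exact margin-preserving
  permutation Monte-Carlo to within ~0.01 absolute at per-cell counts of a
  few dozen; tests calibrate against a 100,000-rep permutation oracle with a
  band of max(3 MC standard errors, 0.015) — the slack measures the χ²
  approximation, not the implementation.
* Fisher's exact test: one-sided is the upper (enrichment) tail; two-sided
  sums hypergeometric point probabilities at most (1+1e-7)× the observed
  one — the minimum-likelihood convention. Verified against full enumeration
  over the hypergeometric support for every 2×2 table with grand total ≤ 40.
  Being a discrete conditional test, it is conservative: in null simulations
  at the study's size (8 selected vs 57 background sites, 7 species,
  background flip rate 0.1) the empirical rejection rate at α = 0.05 is
  ~0.02. With a fivefold selected flip rate, power exceeds 0.9.
* Percentages are formatted half-up at 2 decimals; variation fractions always
  recompute from their own counts. Two historical rows (12/63 and 8/63)
  print as 19.05% and 12.70% here, which differs in the last digit from some
  published renderings of the same counts.

## Synthetic generators

The bundle generator places ideal backbone geometry (N–CA 1.458, CA–C 1.525,
C–N 1.329 Å; N-CA-C 111.2°, CA-C-N 116.2°, C-N-CA 121.7°; ω = 180°) by
internal-coordinate chain extension from the spec's φ/ψ (default −57/−47,
the α-helix), arranges helices antiparallel on a circle of `bundle_radius`
(default 8 Å, six helices of 18 residues — a CSP-sized fold), and threads a
linear pseudo-ligand along the axis. Residues carry backbone N/CA/C/O plus
one pseudo-CB; no packed side chains, no loops connecting helices, no
disulfides — enough to exercise every geometric code path, not a physical
model. A radius that brings inter-chain atoms closer than 1 Å is rejected.

The family simulator draws a base sequence per group (letter-uniform) and
flips each column in each species, with probability q, to a letter drawn
uniformly outside the current charge class (elevated rate `q_selected` on
designated columns; optional gap injection). Defaults mirror the study
conditions: 69 columns, 7 species, background q = 0.1 — the rate at which
1−(1−q)⁷ reproduces the observed background variable fraction of ≈0.56.
Because flip targets are letter-uniform, size classes vary alongside charge,
so size-profile code is exercised too. Star topology only: species are
independent given the base sequence, with no phylogenetic correlation — real
families will show correlated, tree-shaped variation, so passing tests here
validate the machinery, not evolutionary realism.

The variable-column probability has a closed form and is *unimodal* in q
(at q→1 all species flip and can land in one common class), so the flip-rate
estimator inverts it on the increasing branch up to its maximizer
(q ≈ 0.59 for 7 species); observed fractions at or above the achievable
maximum return the maximizer. Recovery should be done by inverting a pooled
fraction — inverting noisy per-replicate fractions and averaging is biased
where the curve flattens.

## Ramachandran classification

A deliberately coarse 10°×10° three-level grid built from rectangular regions:
right-handed α and β/PPII favored regions for the general case, a ±20°
allowed halo, a left-handed-α allowed box (favored for glycine, whose grid
adds the point-mirror of the general regions), a narrow proline grid, and an
extra allowed band for pre-proline. It classifies canonical secondary
structure correctly and is deterministic, but does not reproduce any
published contour bit-exactly; favored/allowed/outlier percentages from this
grid are comparable only within this package. φ/ψ are undefined at termini,
at missing backbone atoms, and across chain breaks (numbering gap or
Cα–Cα > 4.5 Å).

## Problem sizes used in tests and the acceptance script

Simulation-based checks use the study-shaped sizes: 69-column, 7-species
families; 2,000 replicates for test size and power; 200 replicates for
flip-rate recovery; 100 random structures for contact brute-force equality;
the default bundle (108 residues, 540 atoms) for SASA properties. The
acceptance script derives every stochastic input from `--seed` and uses the
published count tables only as inputs.

## Known limitations

* PDB dialect only; no mmCIF, no multi-model ensembles, no hydrogens added.
* Surface "charge" is residue-identity based; no electrostatics.
* The last-helix exclusion is user-supplied, not detected from geometry.
* Identity scores depend on the denominator convention (see above).
* The Ramachandran grid is an approximation (see above).
* The enrichment test inherits Fisher conservatism at small site counts.
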