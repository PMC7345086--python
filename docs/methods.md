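# Methods

## Data model

The package ships four plain-TSV reference tables, validated on load:

* **Standard genetic code** (64 codons). Internally the alphabet is RNA
  (U, never T); DNA input is normalized on read. Amino acids are
  identified by 3-letter codes internally, 1-letter codes accepted at
  I/O boundaries. Validation enforces 64 entries, 20 amino acids, the
  stop set {UAA, UAG, UGA}, and that the codon families partition the
  61 sense codons. A test cross-checks every entry against Biopython's
  NCBI standard table. Alternative (e.g. mitochondrial) codes are out of
  scope; `CodonTable.from_records` is the extension point.
* **aaRS class map**: class I charges Met, Val, Ile, Leu, Cys, Glu, Gln,
  Lys, Arg, Trp, Tyr (11); class II charges Ala, His, Pro, Thr, Ser,
  Gly, Phe, Asp, Asn, Lys (10); Lys alone is dual. The noncanonical
  SepRS/SepCysS route by which some prokaryotes make Cys-tRNA is kept as
  a boolean annotation on Cys only — it never enters the class counts,
  since the canonical CysRS is class I.
* **Prebiotic abundance** relative to Gly, two panels:
  (a) atmospheric/hydrothermal simulation experiments (16 amino acids),
  (b) interstellar/meteorite data (6). Ranges are stored exactly as
  printed (lo ≤ hi); point summaries (midpoint by default) are computed
  on demand and labeled derived, never stored. Amino acids the
  compilation does not report are absent, never imputed.
* **Published chronologies**: Trifonov's consensus order and his N6′
  ("stability of complementary interactions") order, transcribed
  verbatim with parenthesized groups stored as shared ranks. The
  transcription follows the printed lists, not Trifonov's original
  publication, where they might differ.

## The arrangement

Rule 1 groups each entry by its highest-priority codon ("best block"):
GC-rich if some codon has G/C in both the middle and first position;
middle if the best codon has a G/C middle base but A/U first base;
AU-rich if every codon has an A/U middle base. The middle base outranks
the first base throughout, and multi-block amino acids (Arg, Ser, Leu)
are classified by their best block — Arg is GC-rich via CGN despite
AGA/AGG.

Rule 2 orders entries within a group by total codon-family size,
descending; equal sizes are tied and share a column. Total family size —
rather than wobble-position degeneracy of the best block alone — is the
default because it uniquely reproduces the published within-group
orders (6-codon Arg before the 4-codon Gly/Pro/Ala column; Ser 6 > Thr
4 > Cys 2 > Trp/UGA 1; Leu 6 > Val 4 > Ile 3 > the 2-codon column >
Met). The wobble-only variant remains available
(`arrange(..., tie_rule="wobble-only")`) for sensitivity analysis; its
visible effect is that Arg (best block CGN, 4 codons) falls into the
4-codon column with Gly/Pro/Ala.

Stops: UGA is its own 1-codon entry in the middle group; UAA and UAG
form a single 2-codon entry in the AU-rich group by default
(`stops="merged"`), since they entered as a late pair; `stops="split"`
keeps three 1-codon entries.

Flattening ties is deliberately arbitrary — the underlying claim is only
column-resolution — so the package uses a documented deterministic
tie-break: alphabetical by 3-letter code within a column, stop entries
last. Downstream statistics that care about ties (the rank comparisons)
use column indices, not flattened ranks. The exact left-to-right order
within published figure columns is not recoverable from the text, so no
attempt is made to reproduce it.

## Zone statistics

The class overlay is a pure relabeling of the flattened order. For run
counting, STOP positions (no synthetase) are always dropped; the
dual-class Lys is dropped by default (`dual_policy="exclude"`, the most
conservative choice for a clustering claim), or can extend the
neighboring run (`"either"`) or count as its own label (`"own"`).

The clustering statistic is the number of maximal same-class runs. The
null model permutes the observed labels uniformly over positions
(labels exchangeable); the one-sided p-value for the clustering
alternative (fewer runs than random) uses the add-one estimator
p = (1 + #{permutations with runs ≤ observed}) / (N + 1), which cannot
return 0. Default N = 10,000; the seed is part of the returned
statistic. On the standard sequence the observed 7 runs over 19
effective positions give p ≈ 0.08: the zonal structure is visually
striking but, with only 19 exchangeable positions, does not clear a
conventional 0.05 threshold — the package reports the number rather
than a verdict. Tests verify the Monte-Carlo estimator against exact
enumeration over all distinct label arrangements on short sequences.

UGA boundary annotation: in the flattened order UGA sits in the
Trp/UGA column, after the class II zone ends (Thr) and inside the span
of the first class I zone (Cys…Ile). "Near the boundary" is therefore
operationalized as: UGA's column lies within the transition span from
the last column of the class II zone to the last column of the first
class I zone, inclusive. This is true on the standard inputs and false
for, e.g., an order in which UGA precedes all class II entries (reported
as a degenerate annotation instead).

## Rank comparisons

Kendall's τ_b with tie correction is the headline statistic because
every list involved contains ties; Spearman's ρ on mid-ranks is
reported alongside. Implementation is scipy.stats; an independent
brute-force concordant/discordant pair-count oracle in the test suite
checks τ_b exactly on all small rankings. The GC-order ranks entering a
comparison are column indices restricted to amino acids (stops
dropped), preserving ties. An all-tied ranking makes τ_b undefined; it
is reported as 0.0 with a warning. Comparisons require ≥ 3 shared amino
acids.

The abundance-versus-order comparison is a report, not a test: the
scientific claim is qualitative (abundance does not explain the order).
On panel (a) midpoints it gives τ_b ≈ −0.29 over 16 amino acids —
abundant amino acids lean early, but far too weakly to account for the
arrangement.

## Bridge-peptide world simulator

The simulator is the package's synthetic-data component: it emulates
the structure the analysis presumes — GC-biased short RNA pools,
abundance-driven ("chemical code") incorporation, and bridge-peptide
(BP) biased Arg charging — as a discrete-cycle stochastic process. The
mechanism it implements is qualitative in origin; **every rate and
functional form here is a modeling choice of this package**, selected
once to give a visible signal at desk scale.

State: `n_rna` RNAs of `rna_length` i.i.d. bases (G or C with
probability `p_gc`, split evenly; A/U likewise), each optionally charged
with one amino acid; a peptide pool tracked by BP flag; cumulative
incorporation counts. Per cycle:

1. **Aminoacylation.** Each uncharged RNA is charged. With probability
   q = min(1, β · n_BP/n_rna · gc_fraction) the charge is Arg
   (BP-mediated: BP concentration relative to the RNA pool times the
   molecule's GC content); otherwise the amino acid is drawn from the
   chemical-code weights. β = 0 reduces exactly to multinomial
   chemical-code charging.
2. **HDP formation.** Charged RNAs are shuffled and partitioned into
   groups of size L ~ Uniform{`peptide_len_range`} (the final group may
   be truncated but never below the minimum; a remainder below the
   minimum stays charged). Each group's residues form one peptide; a
   peptide of length ≥ 3 containing Arg and Asp is a BP (Arg-only
   variant configurable — the canonical seed motif is
   Arg-Gly-Gly-Ala-Asp). Constituent RNAs return uncharged.
3. **Degradation and replenishment.** Peptides survive with probability
   `base_survival`, times `survival_bonus` for BPs (capped at 1). RNAs
   survive with probability clip(`base_survival` +
   `gc_stability_slope` · (gc_fraction − ½), 0, 1) — the GC-stability
   term — and dead RNAs are replaced by fresh synthesis, so the pool
   size is conserved exactly.

Defaults: n_rna = 1000, rna_length = 20, p_gc = 0.7, β = 5,
peptide_len_range = (2, 6), base_survival = 0.8, survival_bonus = 1.25,
gc_stability_slope = 0.5, n_cycles = 200, with 5 seeded BPs at cycle 0.
Chemical-code weights are the panel (a) abundance midpoints with a
0.005 floor for unreported amino acids (a floor avoids structural
zeros). Note that 0.8 × 1.25 = 1: at the defaults BPs do not decay,
which is the intended strong-stabilization reading of the BP survival
advantage. The trajectory records, per cycle: BP count, BP fraction of
the peptide pool, the Arg share of that cycle's incorporated residues,
mean pool GC fraction, and pool size (record 0 is the initial state;
its Arg share is 0 by convention).

Emergent behavior at the defaults: the β = 5 run ends with a clearly
higher BP fraction than its paired β = 0 control (≈ 0.24 vs ≈ 0.15
averaged over 20 seeds) and an Arg-dominated incorporation stream,
while the control stays at the chemical-code Arg share (≈ 1%); the
positive GC-stability slope holds the equilibrium pool GC mean above
the synthesis mean (≈ 0.77–0.82 vs 0.7). What the simulator does *not*
model, by design: sequence-specific BP–RNA binding (reduced to the
scalar GC fraction), thermodynamic hybridization, codon/anticodon
structure, or the emergence of actual codons. Passing simulator tests
therefore show internal consistency of the feedback mechanism, not
evidence about prebiotic chemistry.

## Determinism and problem sizes

Every stochastic routine takes an explicit seed (numpy `default_rng`);
the permutation test and simulator are bit-reproducible given
(inputs, seed). Test and reproduction scripts use 10,000 permutations
for the clustering test, exact enumeration only on sequences of length
≤ 10 (≤ 252 distinct arrangements at the composition used), 20 paired
simulation seeds at the default 200 cycles for the feedback contrast,
and ~12 cycles (≈ 10⁴ incorporations) for the chemical-code
goodness-of-fit check — sizes at which the Monte-Carlo standard errors
are far below the effect sizes being checked.

## Known limitations

* The analysis is relative ordering only; no absolute timing and no
  optimization over alternative rule weightings.
* In-column order is undefined by construction; any consumer of the
  flattened ranks inherits the alphabetical tie-break.
* The mixed late region's internal structure (and the known Trp/UGG
  stop-codon reassignment caveat, which places TrpRS anomalously early
  relative to TyrRS phylogenies) is taken as-is; the run statistic is
  computed on the order without adjustment.
* aaRS phylogenetic-tree reconstruction (superclusters, structural
  subclasses) is out of scope; the zone statistics use only the class
  partition.
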