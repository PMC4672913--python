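# Methods

## Read processing and coordinate conventions

All transcript coordinates are 1-based and inclusive. Reverse transcription
proceeds 3'→5' along the RNA template, so a read whose local alignment starts
at transcript position *a* implies the polymerase failed to copy position
*t = a − 1* ("the next base"); *t = 0* marks a run-off past the 5' end and
contributes no termination count. Raw reads carry a random trinucleotide at
their 5' end and are clipped by exactly 3 nt before alignment (reads shorter
than 4 nt are skipped and counted). Alignments with fewer than 60 aligned
nucleotides (reference span minus deletions; soft clips never count) or more
than two mismatches are discarded, each under its own tally; records lacking
a mismatch field are discarded under a distinct tally rather than guessed.
Reads reported at *k* alignment sites receive weight 1/*k* per site (NH tag;
absent tag ⇒ unique, logged), so each read contributes total weight 1.

Reads are assigned to the primer whose annealing interval their
high-coordinate (primer-proximal) end overlaps or abuts within a slack of
5 nt; unassignable reads are off-target and dropped. Read-through counts are
zeroed (and flagged) at positions within 25 nt of the primer's annealing
site — the exclusion is strict (> 25 nt kept), measured from the annealing
edge nearest the read. No read contributes read-through at its own
termination position, and counts are exactly additive over read lists.

## Reactivity estimation

P_term, P_spont and P_DMS are simple count ratios per primer and position
(see README); positions with zero read-through in either condition are NaN
with the coverage flag unset, and negative P_DMS values are retained in data
files (a −0.01 sentinel is a plotting convention only, never computed with).
The combined profile averages per-primer P_DMS over primers for which the
position lies 100–380 nt from the annealing site *and* read-through exceeds
1000 in **both** conditions at that position. Both-condition eligibility is
our reading of the protocol's ">1000 read-through" rule: both denominators
must be stable, and a per-position (rather than per-primer-total) check is
what actually bounds the estimator's variance at that base. Classification:
strong P_DMS ≥ 0.008, moderate 0.004 < P_DMS < 0.008 (strict bounds as
printed), low otherwise; NA positions are never classified. QC ranking sorts
by descending P_DMS with ties broken by ascending position so reports are
deterministic; inter-profile agreement (Pearson r, least-squares slope) uses
positions defined and non-zero in both profiles, excluding zeros *before*
correlation.

## Thermodynamic z-score scan

Windows of 150 nt every 10 nt (trailing partial window dropped — a strict
sliding scheme); each window's native MFE is compared against 25
mononucleotide shuffles (uniform permutations; sequence composition is the
stated null, and a dinucleotide-preserving Eulerian shuffle is available as
an option). z = (ΔG°_native − mean)/σ with the population (n-denominator)
standard deviation; σ = 0 (e.g. a homopolymer window) gives z = NA, and an
engine failure marks the window NA without aborting the scan. Shuffle RNG
streams are derived per window from (seed, window start), so scans are
bit-reproducible and parallelizable. The automatic region cutoff is
mean(z) − sd(z) over non-NA windows — one standard deviation of the window
z distribution below the transcript average. Below-cutoff windows sharing at
least one nucleotide are merged by interval union; abutting windows are kept
separate unless `gap_join` is set (off by default; joining two adjacent
domains is a curation decision, exposed only as a generic option).

## Folding engines and the modification constraint

The chemical-modification constraint is implemented exactly as stated: a
flagged nucleotide may not occupy a Watson–Crick pair flanked on **both**
sides by Watson–Crick pairs. Helix-terminal pairs, wobble pairs, pairs next
to wobble pairs, and unpaired states all remain allowed; it is *not* a
force-single-stranded constraint.

Two engines satisfy a common interface (`mfe_fold`, `energy_of`, 37 °C,
deterministic):

* **ViennaRNA adapter** — Turner-model folding via the RNAfold python
  bindings; used for z-scans (fast, full parameter set) and unconstrained
  folding/evaluation. Vienna's constraint language cannot express the
  flanked-pair rule, so this adapter refuses non-empty modification
  constraint sets instead of silently approximating them.
* **Built-in engine** — a self-contained Zuker-style MFE dynamic program
  over a compact embedded nearest-neighbor table: classic Watson–Crick
  stacking free energies, a category rule for wobble-containing stacks
  (reversal-symmetric by construction), Jacobson–Stockmayer logarithmic
  loop-size extrapolation (hairpin ≥ 3 unpaired, bulge, internal), and an
  affine multibranch penalty; no dangles, no coaxial stacking. Energies are
  integers in 0.01 kcal/mol so the DP, the loop-decomposition evaluator, and
  exhaustive enumeration agree exactly. The constraint is handled with a
  split value matrix (pair vs pair-without-stacked-child): the triple-stack
  term is suppressed whenever outer, middle and inner pairs would all be
  Watson–Crick and the middle pair holds a flagged base. Because a flanked
  pair can only arise through two consecutive stack decompositions, this is
  the complete set of forbidden configurations, and the engine is verified
  against brute-force enumeration of *all* nested structures on random
  sequences ≤ 18 nt, with and without constraints.

The built-in table is intentionally small: it exists so constrained folding,
bootstrap analysis and all tests run with no external engine, not to
reproduce full Turner-2004 energies. Constraint files export both as a plain
position list and in the chemical-modification dialect consumed by external
Turner-model folders (`Mod:` block of a CON file).

## Bootstrap support

Each of n = 1000 replicates refolds the fragment with ⌈fraction·|C|⌉
constraints sampled without replacement (default fraction 0.5 — the subset
size is not dictated by the protocol, so it is a documented default recorded
in output metadata). Support of a pair is the fraction of replicates whose
MFE contains it; consensus pairs exceed 0.5. An empty constraint set has no
resampling variance, so every MFE pair reports support 1.0. Identical
subsets are folded once and cached — folding is deterministic, so this is a
pure speed optimization that leaves frequencies unchanged.

## Conservation and mutation classes

Model pairs are mapped through the reference row's gap structure to
alignment columns (injective by construction). A species' pair is canonical
iff both residues are present and form AU/UA/GC/CG/GU/UG; gapped pairs count
in the denominator as non-canonical (the conservative choice; the protocol
does not state gap handling). The reference row is included in the
denominator (also a documented choice). Mutation classes are evaluated per
species against the reference, with no ancestral reconstruction: consistent
= exactly one residue differs and the pair is canonical; compensatory = both
differ and the pair is canonical — the classes are disjoint per species per
pair. Summary counts tally *pairs* exhibiting each class in at least one
species. Row-subset filters support scoring against taxonomic subsets (e.g.
rodents vs all mammals) of one alignment.

## The simulator

`simdata` emulates the probing chemistry the estimator assumes: a transcript
with a planted structure (Watson–Crick hairpins written into random
sequence, or a user structure), modification probability p_hit at accessible
(unpaired) A/C positions, p_bg at protected A/C, 0 at G/U in the default
A/C-only mode, and a per-nucleotide spontaneous drop-off p_spont in both
conditions. Reverse transcription is a 3'→5' walk with per-position hazard
h(i) = p_spont (+ modification probability when treated); reads are drawn
from the exact categorical stop-position distribution this walk implies,
which is equivalent to simulating the walk read by read but vectorizable,
and makes the expectation of the n/r estimator exactly the planted hazard at
every covered position. Products shorter than 100 nt are discarded,
emulating library size selection.

Defaults are chosen to resemble the regime the protocol operates in:
p_hit = 0.02 (strong-site reactivity ~2%, the upper range of observed
P_DMS), p_bg = 5×10⁻⁴, p_spont = 4×10⁻³ (median product length a few
hundred nt, matching the clustering of terminations ~200 nt from RT start
sites), 10⁴ reads per primer, primers every 200 nt with 20-nt annealing
sites. `dose_scale` multiplies the modification probabilities to emulate
harsher treatment; because harsher treatment shortens products, deeper
sequencing is needed to keep per-position read-through above the
eligibility bar, exactly as in real dose comparisons.

What the simulator does **not** model: PCR duplication, ligation and priming
bias, sequence-dependent RT processivity, misalignment (an optional uniform
mismatch injection exists only to exercise the alignment filter), and
partial accessibility (planted sites are fully accessible or fully
protected). Passing recovery tests therefore demonstrates the estimator and
plumbing are correct under the stated noise model, not that real libraries
are free of these biases.

## Problem sizes in tests and the acceptance script

The test suite and `scripts/acceptance.py` use a 600-nt transcript with two
primers at 10⁴ reads per primer for end-to-end recovery, a ~1400-nt
composite transcript (two 250-nt structured blocks in random background) for
the 150/10/25 z-scan, 200 random sequences of 8–18 nt for the
enumeration-equivalence check, and 1000 bootstrap replicates on a 14-nt
planted case. These sizes were chosen so each check carries clear
statistical power while the whole acceptance run completes in about a
minute on one CPU.

## Known limitations

* The built-in energy model is deliberately compact; absolute ΔG° values
  from it are not comparable with Turner-2004 engines (relative comparisons,
  constraint semantics, and all invariants are).
* The Vienna adapter cannot fold under modification constraints (see above).
* Region boundaries from the z-scan are shuffle-seed sensitive near the
  cutoff, as expected for any stochastic null; window scores themselves are
  reproducible given the seed.
* Pseudoknots and partition-function/base-pair-probability folding are out
  of scope throughout.
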