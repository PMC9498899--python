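# Methods

## Motif model

A CCCH zinc finger is represented by its anchor positions (c1, c2, c3, h)
and spacing signature (d1, d2, d3) — the residue counts strictly between
C1–C2, C2–C3 and C3–H. The subtype label is the signature written in the
field's notation, `C-X{d1}-C-X{d2}-C-X{d3}-H`, and the class
`C-X7-8-C-X5-C-X3-H` (d1 ∈ {7, 8}, d2 = 5, d3 = 3) is tracked separately
because it dominates plant families.

The broad family consensus is `C-X4-15-C-X4-6-C-X3-H`. The scanner's
default inventory bounds are widened to d2 ≤ 7 and d3 ≤ 4 so that rare
variants (e.g. `C-X11-C-X7-C-X4-H`) are counted in the same pass; the
bounds are a `SpacingBounds` parameter and the narrow consensus is
available as `CONSENSUS_BOUNDS`.

### Matching semantics

Matching mirrors a text-editor regex search, which is how such surveys are
done in practice: left-to-right, non-overlapping, the match starting at the
leftmost eligible cysteine wins, and scanning resumes after the matched
histidine. At a given start the greedy mode selects the lexicographically
largest feasible (d1, d2, d3) — exactly the backtracking order of greedy
bounded quantifiers — and the lazy mode the smallest. Greediness can shift
counts when cysteines are dense, so both modes are exposed; subtype
conflicts are resolved purely by scan order, never by subtype priority.
The implementation compiles the grammar to a bounded-quantifier regular
expression; the test suite checks it against an independent
exhaustive-enumeration oracle on dense reduced-alphabet sequences
(property-based, {A,C,H}, length ≤ 60) and on thousands of random
500-mers, in both modes.

## Tandem architectures

* **Plant RR-TZF**: first finger `C-X7-8-C-X5-C-X3-H`, second finger
  `C-X5-C-X4-C-X3-H`, linker exactly 16 residues. The linker is counted
  strictly between the H of the first finger and the C of the second
  (`motif_b.start - motif_a.end`). Only adjacent motifs can satisfy the
  bound, so detection walks consecutive motif pairs in coordinate order
  and returns the first hit.
* **Animal-type TZF**: two identical `C-X8-C-X5-C-X3-H` fingers, linker
  18 or 19.

Classification order: a plant pair with an upstream arginine-rich region
is `RR_TZF`; otherwise an animal pair is `TZF`; otherwise `NON_TZF`. A
plant pair lacking RR evidence cannot satisfy the animal spacings and
falls through to `NON_TZF` with the note "tandem without RR region".
Because the literature treats the plant form as the primary class, a
protein carrying both arrangements is called `RR_TZF`.

"Arginine-rich" is nowhere quantified in the source literature, so the
thresholds are this package's own calibration: the 30 residues immediately
upstream of the first finger (truncated at the sequence start) must
contain ≥ 3 arginines at a fraction ≥ 0.2. All three values are
`RrParams` fields, reported with every call; `require_rr=False` classifies
from the finger pair alone, since published family counts do not always
state whether RR evidence was required.

## NES scanning

The consensus `[LV]-x(2,3)-[LIVFM]-x(2,3)-L-x-[LIMTKD]` (NESbase) spans
9–11 residues. One published rendering inserts a space before the final
class; it is read as no extra gap (a single wildcard between the mandatory
L and the final class), consistent with the consensus as cited elsewhere.
Matching is greedy and non-overlapping as for CCCH motifs; an
all-overlapping mode exists for sensitivity analyses, and the
protein-level NES-positive statistic is invariant to the overlap policy.

## Physicochemical profiling

Molecular weight is the sum of average isotopic residue masses plus one
water (18.0153 Da); 'X' is rejected unless a fallback mass is supplied
(the pipeline default is 110 Da, a typical residue mass). The isoelectric
point solves net_charge(pH) = 0 with the Bjellqvist pKa set, including its
residue-dependent terminal pKas, via Henderson–Hasselbalch terms: basic
groups (N-terminus, K, R, H) contribute +1/(1+10^(pH−pKa)), acidic groups
(C-terminus, D, E, C, Y) −1/(1+10^(pKa−pH)). The charge is strictly
decreasing in pH and changes sign on [0, 14] for any peptide with both
termini, so bisection converges to the unique root; iteration stops at
|charge| < 1e-4 and the table is swappable (`PkaTable`). Tests cross-check
the bisection against a dense pH grid and against an independent
implementation of the same pKa set.

Note one subtlety the test suite respects: because terminal pKas depend on
the terminal residue, literally appending D/E to a sequence also shifts
the C-terminal pKa; the monotone-perturbation property (extra R never
lowers pI, extra D never raises it) is exact when the perturbing residue
is inserted behind a fixed terminus.

## Expression arithmetic

`relative_expression` implements the comparative-Ct method: per replicate
ΔCt = Ct_target − Ct_reference; per condition ΔΔCt = mean ΔCt(condition) −
mean ΔCt(control); fold = 2^(−ΔΔCt). The averaging level is not fixed by
the method's usual one-line statement, so both readings are provided:
the default aggregates mean ΔCt per condition (control fold ≡ 1 exactly);
`per_replicate_fold` averages replicate-level folds (larger under
replicate noise, by Jensen's inequality). Replicate-level fold mean and
sample SD are always reported.

`heatmap_transform` is elementwise log2(FPKM + 0.01) followed by per-row
z-scoring with sample SD (ddof = 1, matching R's `scale()` behind the
usual heatmap tools). Constant rows map to zero with a warning.

## Synthetic data

The generator emulates the grammar of real family members — planted CCCH
motifs with chosen spacings, full RR-TZF/TZF cassettes, RR regions, NES
elements — inside i.i.d. random background, with a `PlantedTruth` record
(coordinates, parameters, exact planted string) for every element.

**Background alphabet.** The default excludes {C, H, L, V, I, F, M}:

* no C and no H ⇒ no spurious CCCH match, and the greedy parse of each
  planted motif is forced onto its own anchors;
* no L ⇒ the NES consensus' mandatory L cannot occur in background, and no
  V/I/F/M ⇒ background residues can never serve as the consensus' first
  or internal class positions, which would otherwise shift greedy spans
  across planted-element boundaries.

With this alphabet, planted-element recovery is exact (recall = precision
= 1 on spans), which is what the end-to-end tests assert. The trade-off is
a reduced-composition background (13 residue types); a full-alphabet
"realistic" mode exists for false-positive-rate studies, where truth
comparison must switch to superset semantics. Elements are separated by at
least 31 background residues (one more than the widest admissible motif
span) so no scanner match can bridge elements; positions are drawn by
distributing the free residues multinomially over the gaps, with element
order randomized. A fixed seed makes output byte-identical.

What the generator does **not** emulate: realistic amino-acid composition,
homology between family members (dedup on generator output removes
nothing), sequencing or assembly artifacts, and evolutionarily degraded
motifs. Passing recovery tests therefore demonstrates the scanners'
correctness on the stated grammar, not their behavior on borderline
biological variants.

**Study profile.** `study_family()` is a fixed 46-protein composition
encoding a published pine family census as generator conditions: 119
motifs total — 100 in `C-X7-8-C-X5-C-X3-H` (44 of (7,5,3), 44 of (8,5,3),
6 RR-TZF first fingers, 6 animal-cassette fingers) and 19 others (6
RR-TZF second fingers (5,4,3); 3 × (7,6,3); 6 × (7,4,3); 1 × (11,7,4);
1 × (9,5,3) as a protein's only motif; 2 standalone (5,4,3)) — distributed
as copy numbers {7:2, 6:1, 5:3, 4:5, 3:7, 2:15, 1:13} over 46 proteins,
with 6 RR-TZF cassettes, 3 animal cassettes (linkers 18/19/18), 22
NES-positive proteins, and lengths spanning exactly 126–956 aa. The
published remainder does not fully decompose the 19 non-class motifs; the
two standalone `C-X5-C-X4-C-X3-H` fingers close the gap, chosen as the
subtype that already occurs as the RR-TZF second finger. Derived MW/pI
values reflect the synthetic background composition (~118 Da mean residue
mass), not any real family's.

## Deduplication

"More than 97% similarity" is implemented as global-alignment
(Needleman–Wunsch) identity: identical aligned columns / alignment length,
with ambiguity codes (X, N) never counting as identical; scoring defaults
are match +1, mismatch 0, gap open −10, gap extend −0.5 and are
configurable. Retention is greedy longest-first (ties by id), keeping the
most complete isoform of each near-duplicate group; the result is a fixed
point of the filter, and both protein- and CDS-level filtering are
supported (protein is the pipeline default).

## Pipeline conventions

Stages run read → translate (CDS input) → dedup → motif scan →
architecture → NES → physchem. Internal coordinates are 0-based half-open;
every emitted table is 1-based inclusive, converted only in the writer
layer. Logs go to stderr, results to files/stdout, iteration order is
fixed, and floats are written with fixed formats, so identical inputs and
configuration reproduce outputs byte-for-byte.

## Problem sizes used in the checks

The oracle-equivalence suites use 200 seeded random 500-mers per mode plus
property-based dense sequences for the CCCH scanner (1000 × 500-mers in
the acceptance suite), 100–1000 random 1000-mers for the NES scanner, and
a 200-protein default generator dataset for end-to-end recovery; the whole
suite runs in well under a minute.
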