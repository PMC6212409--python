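# Methods

## Mass model

Peptide masses are residue sums: Σ residue masses + water, minus
2·m_H per intact disulfide, plus one adduct mass per alkylated
cysteine.  Residue monoisotopic masses are computed from elemental
monoisotopic masses (H 1.0078250319, C 12, N 14.0030740052,
O 15.9949146221, S 31.9720707) and stored to ≥ 9 decimals; a test
checks equivalence with independent per-atom elemental summation to
1e-6 Da on random sequences.  Termini are free amine/acid; no
modifications other than cysteine alkylation (NEM +125.0477 Da,
iodoacetamide/carbamidomethyl +57.0215 Da) are modeled, and charge
states are pure protonation ([M+zH]z+), matching the MALDI regime the
package targets.  Average-mass mode uses standard average residue
masses for instrument comparisons at chemical resolution.

The published calculated mass of oxidized TP1 (3053.10) sits 0.06 Da
above the physical monoisotopic value computed here (3053.0399,
i.e. −2·m_H per bond rather than −2.00); the package computes
physically and tests accept the published value within ±0.10 Da.  The
published chymotryptic fragment m/z 2459 does not equal the reduced
unlabeled [M+H]+ of residues 1–25 (≈2477.9) under any label state we
can justify, so no code path asserts that number; the fragment's
*sequence* is what the assembly uses.

## Digestion and fragment ions

Cleavage is C-terminal to the rule residues (trypsin K/R suppressed
before proline; chymotrypsin F/W/Y in the default high-specificity
form, F/W/Y/L/M as an alternative rule object; pepsin F/L as the low-pH
form), with 0..5 missed cleavages, fragments deduplicated by 1-based
inclusive coordinates.  Fragment species inherit per-cysteine labels
from the parent; fragments always carry `n_disulfides = 0` because the
digestion experiments modeled here operate on fully reduced (and
usually alkylated) material — intra-fragment bond assignment of a
partially oxidized parent is not derivable from a linear digest and is
out of scope.  b/y ions are singly protonated, indices 1..L−1; label
deltas ride on every ion containing the labeled cysteine.  Peak
matching is greedy by ascending absolute error with each observed peak
consumed at most once; this is deliberately simple and deterministic
rather than probabilistic.

## Ladder reading and assembly

Consecutive ladder differences are mapped to the nearest residue mass
within a tolerance (default 0.02 Da, TOF/TOF scale).  The terminal
residues come from the first ion (b1 − proton; y1 − water − proton)
and, when the precursor [M+H]+ is supplied, from the gap beyond the
last ion — without a precursor mass the final residue of a 1..L−1
ladder is unobservable.  Unmatched differences accumulate into gap
tokens carrying the unexplained mass (note that gaps can be isobaric
with residues: a Gly+Ala gap equals a Gln residue exactly, an
irreducible chemistry fact, not a parser defect).  Ile/Leu are
rendered as L and always flagged; Lys/Gln are flagged when the
tolerance reaches their 0.0364 Da separation; flags can be resolved
against a reference (transcript-derived) sequence.  Merging uses
maximal exact suffix/prefix overlap in both orientations with
containment short-circuit; equal-length distinct merges are an
explicit ambiguity error listing candidates, and anything below the
minimum overlap (default 3; 5 in the CLI) is a no-overlap error.

## Connectivity deduction

Cysteines are indexed by order of appearance (Roman numerals I..VIII
map to 1..8).  The search space is all perfect matchings, enumerated
canonically ((n−1)!!; n ≤ 16 keeps this ≤ 2 027 025 and instantaneous
for the n ≤ 8 regime the chemistry supports).  An intermediate with k
intact bonds contributes the constraint that its first-tag (NEM) set
is a union of complete bonds; a matching survives iff no bond
straddles the tag partition.  The nested-unfolding constraint —
first-tag sets totally ordered by inclusion, reflecting sequential
reduction along one pathway — is ON by default with a flag to
disable; observation sets violating it yield an empty consistent set.
Ambiguity is a first-class result: more than one survivor returns a
report enumerating candidates (CLI exit status 3), not an exception;
zero survivors raise an inconsistency error.  The reduction order
ranks bonds by the largest k at which they were already observed
reduced (earliest-opened first); bonds never observed reduced rank
last; ties are kept as groups (a partial order) rather than broken
arbitrarily.

Label localization inverts fragment masses: a fragment with c
cysteines fits observed = base + a·Δ_first + (c−a)·Δ_second for a in
0..c (tolerance default 0.05 Da; 0.5 Da would suit integer-MALDI
data).  Counting constraints propagate to per-cysteine assignments
when fragments are homogeneous or single-cysteine; otherwise the
surviving constraints and unresolved ordinals are returned explicitly.
Because the fragment-level raw data behind the original experiments is
not part of the package, localization is validated against the
simulator's ground truth rather than against published fragment
tables.

## Family rules

Loop i is the residue run strictly between Cys i and Cys i+1, so the
tandem CC pair is loop 3 of length 0 and CXC is loop 5 of length 1 in
the eight-cysteine ginsentide numbering.  Ginsentide-like requires
n_cys = 8, loop bounds (6, 6–7, 0, 2–4, 1, 4–6, 1–4), terminal flanks
≤ 2, and no chitin-binding domain.  The chitin-binding domain is the
S-X-Φ-X-Φ element (Φ ∈ {F, W, Y} by default; H excluded unless
configured) in the loop immediately after the CC pair plus an aromatic
residue in the following loop; in the hevein literature those loops
are numbered 3 and 4 (the CC counts as one node there), which is why
the rule engine stores the two loop indices as configuration
(defaults 4 and 5 in per-cysteine numbering) rather than hard-coding
either convention.  Six cysteines with a CC pair fall back to
6C-HLP-like; everything else is unclassified.  Every rule's verdict is
recorded in the returned call, so near-misses are auditable.

Conservation offers two definitions — strict (all rows equal the
reference residue) and majority (> 50 %) — because published
family-conservation percentages rarely state one; on the bundled TP
alignment the two give 32.3 % and 87.1 %, bracketing typical reported
intermediate values, and the package asserts no specific figure.  The
bundled alignment pads three rows (TP6/TP12/TP13) with one trailing
gap to equalize row lengths; family calls always use ungapped
sequences, for which loop lengths are gap-invariant (tested).

## Precursor annotation and scanning

The mature boundary is the start of the rightmost suffix that
classifies ginsentide-like, scanning candidate starts at each cysteine
minus up to 2 residues of flank.  If no suffix qualifies but an
internal window does, the sequence is flagged as
"non-C-terminal mature" (cargo-style architecture) — a distinct error
type, since that architecture belongs to a different biosynthetic
family.  The signal boundary is an explicitly labeled heuristic: the
15–30-residue N-terminal window maximizing mean Kyte–Doolittle
hydropathy subject to a small residue (A/G/S/C/T) at the cleavage
position; it is recorded as "heuristic" in the model and any
user-supplied boundary overrides it.  This is intentionally not a
trained signal-peptide predictor.

Nucleotide scanning translates six frames with the standard code
(partial codons trimmed), extracts stop-to-stop ORFs trimmed to the
first Met (partial ORFs at record edges behind a flag), and applies
the same annotation.  Machine coordinates are 0-based half-open on the
forward strand and exclude the stop codon; the CLI states this in its
header.

## Ensemble validation

PDB ensembles are read through biotite (altloc resolved by occupancy,
hydrogens dropped by default); model-wise atom consistency is enforced
by stack construction.  Disulfides are Sγ–Sγ pairs within 2.5 Å
(covalent S–S ≈ 2.05 Å); consensus keeps pairs present in > 50 % of
models, and a cysteine in two consensus pairs is flagged, not
silently resolved.  Ensemble precision is the mean ± SD of per-model
RMSD to the mean structure, where the mean is refined iteratively:
superpose all models on the current mean by closed-form least-squares
rigid fit (SVD with reflection correction), recompute, repeat until
the mean shifts < 1e-6 Å.  Backbone = {N, CA, C, O} (a {N, CA, C}
variant is a one-line mask change); heavy = all non-hydrogen.
Pseudocyclicity is a property of the topology: ordinals 1 and n_cys
each in a bond, with the two anchoring bonds reported.

## Synthetic study conditions

Generators are seeded (`numpy` PCG64); one global seed fans out via
fixed documented offsets per component, and identical configurations
are byte-identical (tested).  Non-cysteine residues are sampled from
the pooled composition of the 14 natural TP sequences, so synthetic
peptides share the family's Gly-rich background.  Loop lengths are
uniform within preset bounds (ginsentide bounds above; a hevein preset
with room for the forced SXΦXΦ element and aromatic loop).  Mapping
experiments draw the topology uniformly from all matchings and the
reduction order uniformly from permutations, then emit the ideal
sequential-unfolding intermediates — the identifiability property
(full series k = n−1..0 always recovers the truth) is a theorem for
this noise-free generator, and the tests confirm the implementation
realizes it over ≥ 200 seeds.  Ladder generators default to coverage
1.0 and zero noise peaks, with knobs for both.  Decoy databases
shuffle generated peptides (composition preserved, cysteine spacing
destroyed) and embed known precursors at recorded positions/strands;
database flanks are sampled to avoid upstream in-frame start codons so
truth coordinates are exact.  Structure fixtures place backbone atoms
on a smooth self-avoiding CA walk with SG atoms of bonded pairs at
2.05 Å and all other SG pairs kept ≥ max(4 Å, 2.05 + 6σ) apart
(rejection sampling), then add isotropic Gaussian noise of SD σ per
coordinate; the expected RMSD to the sample mean is
σ·sqrt(3(1 − 1/M)) for M models (superposition removes 6 of 3N degrees
of freedom, an O(1/N) correction absorbed by the 15 % test tolerance).

What the generators do not emulate: peak intensities and isotope
envelopes, disulfide scrambling and reduction kinetics, HPLC behavior,
real signal-peptide sequence statistics, and physically refined
side-chain geometry.  Passing tests therefore demonstrate algorithmic
correctness under clean, well-posed conditions, not robustness to
instrument noise or biological edge cases.

## Problem sizes and determinism

The test suite and the acceptance script run on desk-scale inputs: the
31-residue reference peptide, n_cys ≤ 8 matchings (≤ 105), ~200-seed
property sweeps, 20-model ensembles of ~130 atoms, and databases of
~40–100 records — sizes chosen because they already exercise every
code path and keep the whole suite in seconds.  All randomness flows
through explicit seeds; reruns are bit-reproducible.
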