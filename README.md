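# ginsentides

Mass-spectrometry workflows for disulfide-rich plant peptides, built
around the ginsentide (TP) family — 31–33-residue, cysteine- and
glycine-rich peptides from *Panax* species with eight cysteines, four
disulfide bonds, and a pseudocyclic cystine-knot fold.

The package is for peptide chemists and proteomics bioinformaticians
who characterize cysteine-rich peptides (CRPs) the way these peptides
are characterized in practice:

1. **Mass arithmetic** (`ginsentides.chem`) — disulfide- and
   label-aware neutral masses and m/z. A species with *n* cysteines,
   fully oxidized, shifts by *n*·(m<sub>H</sub> + Δ<sub>label</sub>) on
   full reduction and alkylation; with N-ethylmaleimide (Δ = 125.0477 Da)
   and eight cysteines that is the diagnostic integer shift of
   **+1008 Da** used to count cysteines from MALDI-TOF spectra.
2. **In-silico proteolysis and b/y ladders** (`ginsentides.digest`) —
   trypsin/chymotrypsin/pepsin rules with missed cleavages, singly
   protonated b/y fragment-ion series (b<sub>i</sub> + y<sub>L−i</sub> =
   [M+H]⁺ + H⁺), and tolerance-based peak matching.
3. **De novo reading and assembly** (`ginsentides.assembly`) — residue
   sequences from ladder mass differences (Ile/Leu isobars and
   Lys/Gln near-isobars flagged), merged across overlapping digests by
   maximal exact suffix/prefix overlap.
4. **Disulfide connectivity mapping** (`ginsentides.connectivity`) —
   the partial-reduction / dual-alkylation experiment as constraint
   satisfaction: each trapped intermediate's first-tag cysteine set
   must be a union of complete bonds, pruning the (n−1)!! perfect
   matchings (105 for n = 8) to — ideally — one topology, plus the
   reduction order of the unfolding pathway.
5. **Motif classification** (`ginsentides.motifs`) — cysteine position
   and inter-cysteine loop-length profiling, the eight-cysteine
   hevein-like (8C-HLP) family rules (ginsentide-like
   CX₆CX₆₋₇CCX₂₋₄CXCX₄₋₆CX₁₋₄C vs. chitin-binding SXΦXΦ domain),
   composition and alignment conservation.
6. **Precursor scanning** (`ginsentides.precursor`) — three-domain
   (signal / pro / mature) precursor annotation and motif scanning of
   protein or nucleotide FASTA (six-frame translation, ORF
   extraction).
7. **Ensemble validation** (`ginsentides.structure`) — Sγ–Sγ disulfide
   detection in multi-model PDB ensembles, iterative mean-structure
   RMSD (Kabsch superposition), and the pseudocyclicity test (both
   terminal cysteines disulfide-anchored).
8. **Synthetic data** (`ginsentides.synth`) — seeded generators for
   every input above, each with machine-readable ground truth.

## Worked example

```python
from ginsentides import chem, data, digest, assembly, connectivity

tp1 = data.TP1  # CKSGGAWCGFDPHGCCGNCGCLVGFCYGTGC

# cysteine counting by reduction/alkylation mass shift
chem.reduction_alkylation_shift(tp1, chem.NEM)        # 1008.444  -> +1008 Da
chem.peptide_mass(chem.PeptideSpecies(tp1, 4))        # 3053.040  (4 disulfides)

# dual-enzyme digest fragments and their assembly
[(f.start, f.end, round(f.mh)) for f in digest.digest(tp1, digest.TRYPSIN)]
# [(1, 2, 250), (3, 31, 2831)]
assembly.overlap_merge(data.CHYMOTRYPTIC_FRAGMENT_TP1,
                       data.TRYPTIC_FRAGMENT_TP1, min_overlap=5)
# 'CKSGGAWCGFDPHGCCGNCGCLVGFCYGTGC'  (31 residues)

# connectivity from three partial-reduction intermediates
obs = [connectivity.LabelObservation(8, 3, first_tag=frozenset({1, 4})),
       connectivity.LabelObservation(8, 2, first_tag=frozenset({1, 4, 5, 8})),
       connectivity.LabelObservation(8, 1, second_tag=frozenset({2, 6}))]
result = connectivity.deduce_connectivity(8, obs)
str(result.topology)            # 'CysI-CysIV, CysII-CysVI, CysIII-CysVII, CysV-CysVIII'
result.topology.reduction_order # ((1, 4), (5, 8), (3, 7), (2, 6))
```

The numbers mean: the +1008 Da shift counts 8 cysteines; the oxidized
monoisotopic mass 3053.04 Da identifies the [M+H]⁺ 3054 species; the
tryptic fragment at [M+H]⁺ 2831 overlaps the chymotryptic fragment to
assemble the full 31-residue sequence; and the three intermediates
reduce 105 candidate pairings to the single topology I–IV, II–VI,
III–VII, V–VIII, opened in the order I–IV → V–VIII → III–VII → II–VI.

A `crp` console script exposes the same operations
(`crp mass`, `crp digest`, `crp ions`, `crp assemble`, `crp map-ss`,
`crp simulate-ss`, `crp classify`, `crp conserve`, `crp scan`,
`crp structure`, `crp gen`); `crp map-ss` exits with status 3 when the
observations leave the topology ambiguous, printing all candidates.

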