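"""Reference sequences for the ginsentide (TP) family.

The 14 mature ginsentides TP1-TP14 from *Panax ginseng*, *Panax
quinquefolius* and *Panax notoginseng*, stored as the published gapped
alignment ('-' gaps).  Ungapped sequences are derived by stripping gaps.
TP1 (31 residues, 8 cysteines, 4 disulfides) is the structurally and
chemically best-characterized member and serves as the worked example
throughout the package.
"""

from __future__ import annotations

__all__ = [
    "TP_ALIGNMENT",
    "TP_SEQUENCES",
    "TP1",
    "TP1_TOPOLOGY_BONDS",
    "TP1_REDUCTION_ORDER",
    "CHYMOTRYPTIC_FRAGMENT_TP1",
    "TRYPTIC_FRAGMENT_TP1",
    "pooled_residue_frequencies",
]

# Published family alignment. Rows are padded on the right to equal
# length where the source table leaves the final column implicit.
TP_ALIGNMENT: dict[str, str] = {
    "TP1": "CKSGGAWCGFD-PHGCCG--NCGCLV--GFCYGTGC-",
    "TP2": "CKSSGAWCGFD-PHGCCG--NCGCLV--GFCYGTGC-",
    "TP3": "CKSAGTWCGFD-PHGCCG--SCGCLV--GFCYGVSC-",
    "TP4": "CLKNGEFCWGD-PSGCCG--NCGCLIIPGVCYGTGC-",
    "TP5": "CKSSGAWCGFD-PHGCCG--NCGCLV--GFCYGTDC-",
    "TP6": "CIPGGGFCMFE-PLSCCV--NCGCILVPGVCY--CG-",
    "TP7": "CKSGGTWCGFD-PHGCCG--NCGCLV--GFCYGTGC-",
    "TP8": "CISSGGWCGFD-LHGCCG--NCGCLV--GFCYGTGC-",
    "TP9": "CKSGGSWCGFD-PHGCCG--NCGCLV--GFCYGTGC-",
    "TP10": "CIFSGGWCGFD-LHGCCG--NCGCLV--GFCYGTGC-",
    "TP11": "CLKNGQFCWGN-PSGCCG--NCGCLIIPGVCYGTGC-",
    "TP12": "CIPGGGFCMFE-PLSCCH--NCGCLLVPGVCY--CG-",
    "TP13": "CIPNGGFCMFE-PLSCCV--NCGCILVPGVCY--CG-",
    "TP14": "CLKVGKICLGRGLKECCPSATCGCLL--GFCIK--C-",
}

#: Ungapped mature sequences.
TP_SEQUENCES: dict[str, str] = {
    name: aligned.replace("-", "") for name, aligned in TP_ALIGNMENT.items()
}

TP1 = TP_SEQUENCES["TP1"]

#: Chemically mapped disulfide topology of TP1, as cysteine ordinals
#: (order of appearance; Cys I-IV, II-VI, III-VII, V-VIII).
TP1_TOPOLOGY_BONDS = frozenset({(1, 4), (2, 6), (3, 7), (5, 8)})

#: Reduction order observed under partial TCEP reduction: Cys I-IV
#: opens first, then V-VIII, then III-VII, and II-VI last.
TP1_REDUCTION_ORDER = ((1, 4), (5, 8), (3, 7), (2, 6))

#: Major fragments of S-reduced TP1 observed after single-enzyme digests,
#: the overlap of which assembles the full-length sequence.
CHYMOTRYPTIC_FRAGMENT_TP1 = "CKSGGAWCGFDPHGCCGNCGCLVGF"
TRYPTIC_FRAGMENT_TP1 = "SGGAWCGFDPHGCCGNCGCLVGFCYGTGC"


def pooled_residue_frequencies(exclude: str = "C") -> dict[str, float]:
    """Residue frequencies pooled over the ungapped TP family.

    Residues in ``exclude`` (cysteine by default, since cysteine
    placement is what motif generators control explicitly) are left out
    and the remaining frequencies renormalized.  Used as the background
    composition when sampling synthetic cysteine-rich peptides.
    """
    counts: dict[str, int] = {}
    for seq in TP_SEQUENCES.values():
        for aa in seq:
            if aa in exclude:
                continue
            counts[aa] = counts.get(aa, 0) + 1
    total = sum(counts.values())
    return {aa: n / total for aa, n in sorted(counts.items())}
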