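"""Peptide mass arithmetic for disulfide-rich, thiol-labeled species.

All masses are in daltons (Da).  A peptide species is an amino-acid
sequence together with its redox state (number of intact disulfide
bonds) and any per-cysteine alkylation labels.  The neutral mass of a
species is

    sum(residue masses) + water - 2 * n_disulfides * m_H + sum(label deltas)

i.e. every intact disulfide removes two hydrogen atoms, and every
alkylated cysteine gains the adduct mass of its reagent.  This is the
algebra behind the diagnostic mass shifts seen when cysteine-rich
peptides are reduced and alkylated: a peptide with n cysteines, fully
oxidized, shifts by ``n * (m_H + label delta)`` on full reduction and
labeling (1008.44 Da for 8 cysteines with N-ethylmaleimide, hence the
integer "+1008" signature of eight-cysteine peptides on MALDI-TOF).
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "MONOISOTOPIC",
    "AVERAGE",
    "WATER_MONO",
    "WATER_AVG",
    "PROTON",
    "HYDROGEN_MONO",
    "HYDROGEN_AVG",
    "ThiolLabel",
    "NEM",
    "IAM",
    "NO_LABEL",
    "PeptideSpecies",
    "cysteine_positions",
    "residue_mass",
    "peptide_mass",
    "reduction_alkylation_shift",
    "mz_from_mass",
    "neutral_mass_from_mz",
]

# Monoisotopic residue (amino-acid minus water) masses, Da.
# Computed from elemental monoisotopic masses (CODATA/AME):
# H 1.0078250319, C 12, N 14.0030740052, O 15.9949146221, S 31.9720707.
MONOISOTOPIC: dict[str, float] = {
    "G": 57.02146372057,
    "A": 71.03711378471,
    "S": 87.03202840427,
    "P": 97.05276384885,
    "V": 99.06841391299,
    "T": 101.04767846841,
    "C": 103.00918478471,
    "L": 113.08406397713,
    "I": 113.08406397713,
    "N": 114.04292744114,
    "D": 115.02694302383,
    "Q": 128.05857750528,
    "K": 128.09496301399,
    "E": 129.04259308797,
    "M": 131.04048491299,
    "H": 137.05891185845,
    "F": 147.06841391299,
    "R": 156.10111102359,
    "Y": 163.06332853255,
    "W": 186.07931294986,
}

# Average (chemical) residue masses, Da.
AVERAGE: dict[str, float] = {
    "G": 57.0519,
    "A": 71.0788,
    "S": 87.0782,
    "P": 97.1167,
    "V": 99.1326,
    "T": 101.1051,
    "C": 103.1388,
    "L": 113.1594,
    "I": 113.1594,
    "N": 114.1038,
    "D": 115.0886,
    "Q": 128.1307,
    "K": 128.1741,
    "E": 129.1155,
    "M": 131.1926,
    "H": 137.1411,
    "F": 147.1766,
    "R": 156.1875,
    "Y": 163.1760,
    "W": 186.2132,
}

WATER_MONO = 18.01056468403
WATER_AVG = 18.01528
PROTON = 1.00727646688
HYDROGEN_MONO = 1.0078250319
HYDROGEN_AVG = 1.00794

_MASS_TABLES = {"monoisotopic": MONOISOTOPIC, "average": AVERAGE}
_WATER = {"monoisotopic": WATER_MONO, "average": WATER_AVG}
_HYDROGEN = {"monoisotopic": HYDROGEN_MONO, "average": HYDROGEN_AVG}


@dataclass(frozen=True)
class ThiolLabel:
    """A cysteine alkylation reagent: name plus mass added per labeled thiol."""

    name: str
    delta: float  # Da added to each labeled cysteine


#: N-ethylmaleimide adduct, C6H7NO2.
NEM = ThiolLabel("NEM", 125.04767846841)
#: Iodoacetamide / carbamidomethyl adduct, C2H3NO.
IAM = ThiolLabel("IAM", 57.02146372057)
#: Unlabeled free thiol.
NO_LABEL = ThiolLabel("NONE", 0.0)


def cysteine_positions(sequence: str) -> list[int]:
    """1-based positions of cysteines, in order of appearance.

    The i-th entry is the residue position of cysteine ordinal i (the
    "Roman numeral" indexing used when naming disulfide bonds Cys I-IV
    etc.).
    """
    return [i + 1 for i, aa in enumerate(sequence) if aa == "C"]


def _validate_sequence(sequence: str, table: dict[str, float]) -> None:
    if not sequence:
        raise ValueError("empty peptide")
    for aa in sequence:
        if aa not in table:
            raise ValueError(f"unknown residue letter {aa!r}")


@dataclass(frozen=True)
class PeptideSpecies:
    """A peptide sequence plus redox/label state.

    Parameters
    ----------
    sequence:
        Uppercase one-letter residue string.
    n_disulfides:
        Number of intact disulfide bonds (each removes 2 H from the mass).
    cys_labels:
        Map from cysteine ordinal (1-based order of appearance) to the
        :class:`ThiolLabel` carried by that cysteine.  Labeled cysteines
        must be free thiols, so ``2 * n_disulfides + len(cys_labels)``
        cannot exceed the cysteine count.

    Termini are assumed free (alpha-amine, alpha-carboxyl); no other
    modifications are modeled.
    """

    sequence: str
    n_disulfides: int = 0
    cys_labels: dict[int, ThiolLabel] = field(default_factory=dict)

    def __post_init__(self) -> None:
        _validate_sequence(self.sequence, MONOISOTOPIC)
        if self.n_disulfides < 0:
            raise ValueError("n_disulfides must be >= 0")
        n_cys = self.n_cys
        labeled = {k: v for k, v in self.cys_labels.items() if v.delta != 0.0 or v.name != "NONE"}
        for ordinal in self.cys_labels:
            if not 1 <= ordinal <= n_cys:
                raise ValueError(
                    f"cysteine ordinal {ordinal} out of range: sequence has {n_cys} cysteines"
                )
        if 2 * self.n_disulfides + len(labeled) > n_cys:
            raise ValueError(
                f"species over-constrained: 2*{self.n_disulfides} disulfide cysteines "
                f"+ {len(labeled)} labeled > {n_cys} total cysteines"
            )

    @property
    def n_cys(self) -> int:
        return self.sequence.count("C")

    @property
    def cys_positions(self) -> list[int]:
        return cysteine_positions(self.sequence)

    def label_at(self, ordinal: int) -> ThiolLabel:
        return self.cys_labels.get(ordinal, NO_LABEL)


def residue_mass(letter: str, mode: str = "monoisotopic") -> float:
    """Residue (amino acid minus water) mass of a single letter."""
    table = _MASS_TABLES[mode]
    if letter not in table:
        raise ValueError(f"unknown residue letter {letter!r}")
    return table[letter]


def peptide_mass(species: PeptideSpecies | str, mode: str = "monoisotopic") -> float:
    """Neutral mass of a peptide species in Da.

    ``species`` may be a bare sequence string, treated as fully reduced
    and unlabeled.  ``mode`` selects the monoisotopic or average table.
    """
    if isinstance(species, str):
        species = PeptideSpecies(species)
    if mode not in _MASS_TABLES:
        raise ValueError(f"unknown mass mode {mode!r}")
    table = _MASS_TABLES[mode]
    _validate_sequence(species.sequence, table)
    total = sum(table[aa] for aa in species.sequence) + _WATER[mode]
    total -= 2 * species.n_disulfides * _HYDROGEN[mode]
    total += sum(label.delta for label in species.cys_labels.values())
    return total


def reduction_alkylation_shift(
    sequence: str,
    label: ThiolLabel = NEM,
    mode: str = "monoisotopic",
    allow_odd: bool = False,
) -> float:
    """Mass shift between the fully oxidized and fully reduced+labeled forms.

    For a sequence with ``n`` cysteines, all engaged in disulfides, full
    reduction restores ``n`` hydrogens and labeling adds ``n`` adducts:
    the shift is ``n * (m_H + delta)``.  An odd cysteine count cannot be
    fully disulfide-bonded; by default this is an error, but with
    ``allow_odd=True`` the shift is still reported treating every
    cysteine as reduced-and-labeled (useful for species with a free
    thiol).  Rounding to integer Da is left to the caller.
    """
    _validate_sequence(sequence, _MASS_TABLES[mode])
    n_cys = sequence.count("C")
    if n_cys == 0:
        raise ValueError("no cysteines")
    if n_cys % 2 and not allow_odd:
        raise ValueError(
            f"odd cysteine count ({n_cys}); cannot be fully disulfide-bonded "
            "(pass allow_odd=True to compute the per-thiol shift anyway)"
        )
    return n_cys * (_HYDROGEN[mode] + label.delta)


def mz_from_mass(neutral_mass: float, charge: int = 1) -> float:
    """m/z of the [M+zH]z+ ion of a neutral mass."""
    if charge < 1:
        raise ValueError(f"charge must be a positive integer, got {charge}")
    return (neutral_mass + charge * PROTON) / charge


def neutral_mass_from_mz(mz: float, charge: int = 1) -> float:
    """Inverse of :func:`mz_from_mass`."""
    if charge < 1:
        raise ValueError(f"charge must be a positive integer, got {charge}")
    return mz * charge - charge * PROTON
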