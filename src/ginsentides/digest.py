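"""In-silico proteolysis and b/y fragment-ion ladders.

Digestion follows the classical C-terminal-side cleavage rules
(trypsin: after K/R unless the next residue is proline; chymotrypsin:
after F/W/Y in its high-specificity form) with configurable missed
cleavages.  Fragment and ion masses are label-aware: per-cysteine
alkylation adducts of the parent species are carried into the
fragments and into every b/y ion that contains the labeled cysteine.
Ions are singly protonated, matching MALDI-TOF/TOF practice.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .chem import (
    PROTON,
    MONOISOTOPIC,
    WATER_MONO,
    PeptideSpecies,
    ThiolLabel,
    cysteine_positions,
    mz_from_mass,
    peptide_mass,
)

__all__ = [
    "EnzymeRule",
    "TRYPSIN",
    "CHYMOTRYPSIN",
    "CHYMOTRYPSIN_LOW_SPECIFICITY",
    "PEPSIN_PH2",
    "ENZYMES",
    "DigestFragment",
    "IonLadder",
    "cleavage_sites",
    "digest",
    "fragment_ions",
    "match_peaks",
]


@dataclass(frozen=True)
class EnzymeRule:
    """C-terminal-side cleavage specificity.

    Cleavage occurs after any residue in ``cleave_after`` unless the
    following residue is in ``not_before``.
    """

    name: str
    cleave_after: frozenset[str]
    not_before: frozenset[str] = frozenset()
    max_missed: int = 0

    def __post_init__(self) -> None:
        if not self.cleave_after:
            raise ValueError("cleavage residue set must be non-empty")
        if not 0 <= self.max_missed <= 5:
            raise ValueError("max_missed must be in 0..5")


TRYPSIN = EnzymeRule("trypsin", frozenset("KR"), frozenset("P"))
CHYMOTRYPSIN = EnzymeRule("chymotrypsin", frozenset("FWY"))
CHYMOTRYPSIN_LOW_SPECIFICITY = EnzymeRule("chymotrypsin-low", frozenset("FWYLM"))
PEPSIN_PH2 = EnzymeRule("pepsin-pH2", frozenset("FL"))

ENZYMES = {
    "trypsin": TRYPSIN,
    "chymotrypsin": CHYMOTRYPSIN,
    "chymotrypsin-low": CHYMOTRYPSIN_LOW_SPECIFICITY,
    "pepsin": PEPSIN_PH2,
}


@dataclass(frozen=True)
class DigestFragment:
    """One proteolytic fragment, 1-based inclusive coordinates on the parent."""

    parent_id: str
    start: int
    end: int
    species: PeptideSpecies
    missed: int

    @property
    def sequence(self) -> str:
        return self.species.sequence

    @property
    def neutral_mass(self) -> float:
        return peptide_mass(self.species)

    @property
    def mh(self) -> float:
        """Singly protonated [M+H]+ m/z."""
        return mz_from_mass(self.neutral_mass, 1)


def cleavage_sites(sequence: str, rule: EnzymeRule) -> list[int]:
    """Positions i (1-based) such that the enzyme cleaves between i and i+1."""
    sites = []
    for i in range(len(sequence) - 1):
        if sequence[i] in rule.cleave_after and sequence[i + 1] not in rule.not_before:
            sites.append(i + 1)
    return sites


def _fragment_species(parent: PeptideSpecies, start: int, end: int) -> PeptideSpecies:
    # Digestion in these workflows operates on fully reduced material, so
    # fragments carry no disulfides; per-cysteine labels are remapped from
    # parent cysteine ordinals to fragment-local ordinals.
    sub = parent.sequence[start - 1 : end]
    parent_cys = cysteine_positions(parent.sequence)
    labels: dict[int, ThiolLabel] = {}
    local = 0
    for ordinal, pos in enumerate(parent_cys, start=1):
        if start <= pos <= end:
            local += 1
            if ordinal in parent.cys_labels:
                labels[local] = parent.cys_labels[ordinal]
    return PeptideSpecies(sub, n_disulfides=0, cys_labels=labels)


def digest(
    parent: PeptideSpecies | str,
    rule: EnzymeRule,
    max_missed: int | None = None,
    parent_id: str = "peptide",
) -> list[DigestFragment]:
    """All fragments with 0..max_missed missed cleavages.

    Fragments are deduplicated by coordinates and sorted by start, then
    length.  A sequence with no cleavage site yields the full-length
    peptide as its single fragment.
    """
    if isinstance(parent, str):
        parent = PeptideSpecies(parent)
    if max_missed is None:
        max_missed = rule.max_missed
    if not 0 <= max_missed <= 5:
        raise ValueError("max_missed must be in 0..5")
    seq = parent.sequence
    sites = cleavage_sites(seq, rule)
    bounds = [0] + sites + [len(seq)]  # fragment k spans bounds[k]+1..bounds[k+1]
    frags: dict[tuple[int, int], DigestFragment] = {}
    n = len(bounds) - 1
    for i in range(n):
        for j in range(i, min(i + max_missed + 1, n)):
            start, end = bounds[i] + 1, bounds[j + 1]
            if (start, end) not in frags:
                frags[(start, end)] = DigestFragment(
                    parent_id, start, end, _fragment_species(parent, start, end), j - i
                )
    return sorted(frags.values(), key=lambda f: (f.start, f.end - f.start))


@dataclass(frozen=True)
class IonLadder:
    """Singly protonated b- or y-ion series of one peptide species."""

    species: PeptideSpecies
    series: str  # "b" or "y"
    ions: tuple[tuple[int, float], ...] = field(default=())

    @property
    def mz_values(self) -> list[float]:
        return [mz for _, mz in self.ions]


def fragment_ions(peptide: PeptideSpecies | str, series: str) -> IonLadder:
    """b- or y-ion ladder (indices 1..L-1, singly protonated).

    b_i = sum of the first i residue masses (+ any cysteine label deltas
    among them) + proton; y_i = sum of the last i residues (+ deltas)
    + water + proton.  The species must be reduced (no intact
    disulfides): fragment ions of a cross-linked species are not simple
    prefix/suffix masses.
    """
    if isinstance(peptide, str):
        peptide = PeptideSpecies(peptide)
    if series not in ("b", "y"):
        raise ValueError(f"series must be 'b' or 'y', got {series!r}")
    if peptide.n_disulfides:
        raise ValueError("fragment ions require a reduced species (n_disulfides=0)")
    seq = peptide.sequence
    if len(seq) < 2:
        raise ValueError("peptide too short for fragment ions (length >= 2 required)")
    # per-position mass including any label on a cysteine at that position
    pos_mass = [MONOISOTOPIC[aa] for aa in seq]
    for ordinal, pos in enumerate(cysteine_positions(seq), start=1):
        pos_mass[pos - 1] += peptide.label_at(ordinal).delta
    ions = []
    if series == "b":
        acc = PROTON
        for i in range(len(seq) - 1):
            acc += pos_mass[i]
            ions.append((i + 1, acc))
    else:
        acc = WATER_MONO + PROTON
        for i in range(len(seq) - 1):
            acc += pos_mass[len(seq) - 1 - i]
            ions.append((i + 1, acc))
    return IonLadder(peptide, series, tuple(ions))


@dataclass(frozen=True)
class PeakMatch:
    index: int
    theoretical_mz: float
    observed_mz: float | None
    delta: float | None

    @property
    def matched(self) -> bool:
        return self.observed_mz is not None


def match_peaks(
    ladder: IonLadder,
    peaks: list[tuple[float, float]],
    tol: float = 0.02,
) -> list[PeakMatch]:
    """Greedy nearest-peak assignment of ladder ions to observed peaks.

    Candidate (ion, peak) pairs within ``tol`` are assigned in order of
    ascending absolute mass error; each peak is consumed at most once.
    Unmatched ions are reported with ``observed_mz=None``.  An empty
    peak list simply leaves every ion unmatched.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    candidates = []
    for idx, mz in ladder.ions:
        for p, (pmz, _intensity) in enumerate(peaks):
            d = pmz - mz
            if abs(d) <= tol:
                candidates.append((abs(d), idx, mz, p, pmz, d))
    candidates.sort(key=lambda c: (c[0], c[1]))
    used_peaks: set[int] = set()
    assigned: dict[int, tuple[float, float, float]] = {}
    for _, idx, mz, p, pmz, d in candidates:
        if idx in assigned or p in used_peaks:
            continue
        assigned[idx] = (mz, pmz, d)
        used_peaks.add(p)
    out = []
    for idx, mz in ladder.ions:
        if idx in assigned:
            _, pmz, d = assigned[idx]
            out.append(PeakMatch(idx, mz, pmz, d))
        else:
            out.append(PeakMatch(idx, mz, None, None))
    return out
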