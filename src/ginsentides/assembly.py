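"""De novo sequence reading from ion ladders and overlap assembly.

A b- or y-ion ladder encodes a peptide as cumulative prefix (or
suffix) masses: consecutive differences are residue masses.  Reading a
ladder therefore maps each difference to the nearest residue mass
within a tolerance.  Two residue pairs need care at MALDI-TOF/TOF
accuracy: Ile/Leu are exactly isobaric (always reported as 'L' with an
ambiguity flag), and Lys/Gln differ by only 0.0364 Da (flagged when
the tolerance cannot separate them).  Missing interior ions produce
unknown blocks carrying the summed residue mass of the gap.

Full-length sequences are then reconstructed by merging overlapping
fragment reads from complementary enzymatic digests via maximal exact
suffix/prefix overlap.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .chem import MONOISOTOPIC, PROTON, WATER_MONO

__all__ = [
    "Gap",
    "SequenceRead",
    "ladder_to_sequence",
    "resolve_ambiguities",
    "overlap_merge",
    "NoOverlapError",
    "AmbiguousOverlapError",
]

# Isoleucine and leucine share a residue mass; 'L' is the canonical
# rendering of the pair in de novo reads.
_CANONICAL = {"I": "L"}

# Candidate residues keyed by canonical letter (I folded into L).
_READ_MASSES = {aa: m for aa, m in MONOISOTOPIC.items() if aa != "I"}

KQ_MASS_GAP = MONOISOTOPIC["K"] - MONOISOTOPIC["Q"]  # 0.0364 Da


@dataclass(frozen=True)
class Gap:
    """An unread stretch of a ladder: summed residue mass, unknown residues."""

    mass: float


@dataclass
class SequenceRead:
    """A de novo read: residues and gaps, with per-position ambiguity flags.

    ``tokens`` is a list of single residue letters and :class:`Gap`
    objects in N-to-C order.  ``ambiguities`` maps token index to the
    set of residues consistent with the observed mass at that position
    (only present where more than one residue fits).
    """

    tokens: list
    ambiguities: dict[int, frozenset[str]] = field(default_factory=dict)
    source: str = "ladder"

    @property
    def is_complete(self) -> bool:
        return all(isinstance(t, str) for t in self.tokens)

    @property
    def sequence(self) -> str:
        """Residue string; raises if the read contains unknown blocks."""
        if not self.is_complete:
            raise ValueError("read contains unresolved gaps")
        return "".join(self.tokens)

    def __str__(self) -> str:
        parts = []
        for t in self.tokens:
            parts.append(t if isinstance(t, str) else f"[+{t.mass:.4f}]")
        return "".join(parts)


def _residue_from_mass(mass: float, tol: float) -> tuple[str | None, frozenset[str]]:
    """Nearest residue within tol, plus the full set of candidates within tol."""
    hits = [(abs(mass - m), aa) for aa, m in _READ_MASSES.items() if abs(mass - m) <= tol]
    if not hits:
        return None, frozenset()
    hits.sort()
    best = hits[0][1]
    alts = {aa for _, aa in hits}
    if "L" in alts:
        alts |= {"I"}
    return best, frozenset(alts)


def ladder_to_sequence(
    peaks: list[float],
    series: str = "b",
    tol: float = 0.02,
    precursor_mh: float | None = None,
) -> SequenceRead:
    """Read a residue sequence from a sorted singly-charged ion ladder.

    ``peaks`` are the m/z values of the b- or y-series ions in ascending
    order.  The first peak yields the terminal residue (b1 minus proton;
    y1 minus water and proton); consecutive differences yield interior
    residues.  If ``precursor_mh`` (the [M+H]+ of the whole peptide) is
    supplied, the residue beyond the last ladder ion is recovered too,
    completing the sequence.  Differences matching no residue within
    ``tol`` become :class:`Gap` tokens carrying the unexplained mass.
    Reads from y-ladders are returned in N-to-C orientation.
    """
    if series not in ("b", "y"):
        raise ValueError(f"series must be 'b' or 'y', got {series!r}")
    if tol <= 0:
        raise ValueError("tol must be positive")
    if len(peaks) < 2 and not (len(peaks) == 1 and precursor_mh is not None):
        raise ValueError("ladder too short")
    if any(b <= a for a, b in zip(peaks, peaks[1:])):
        raise ValueError("ladder peaks must be strictly ascending")

    offset = PROTON if series == "b" else WATER_MONO + PROTON
    deltas = [peaks[0] - offset]
    deltas.extend(b - a for a, b in zip(peaks, peaks[1:]))
    if precursor_mh is not None:
        # [M+H]+ minus the last ladder ion: residue + water for b, residue for y.
        tail = precursor_mh - peaks[-1]
        deltas.append(tail - WATER_MONO if series == "b" else tail)

    tokens: list = []
    ambiguities: dict[int, frozenset[str]] = {}
    pending_gap = 0.0
    for d in deltas:
        aa, alts = _residue_from_mass(d, tol)
        if aa is None:
            pending_gap += d
            continue
        if pending_gap:
            tokens.append(Gap(pending_gap))
            pending_gap = 0.0
        idx = len(tokens)
        tokens.append(aa)
        flagged = set(alts)
        if aa == "L":
            flagged |= {"I", "L"}
        if aa in ("K", "Q") and tol >= KQ_MASS_GAP:
            flagged |= {"K", "Q"}
        if len(flagged) > 1:
            ambiguities[idx] = frozenset(flagged)
    if pending_gap:
        tokens.append(Gap(pending_gap))

    read = SequenceRead(tokens, ambiguities)
    if series == "y":  # y ladders read C-to-N; flip to N-to-C
        n = len(read.tokens)
        read = SequenceRead(
            list(reversed(read.tokens)),
            {n - 1 - i: alts for i, alts in read.ambiguities.items()},
            source=read.source,
        )
    return read


def resolve_ambiguities(read: SequenceRead, reference: str) -> SequenceRead:
    """Resolve flagged positions against a reference sequence.

    Mirrors resolving Ile/Leu and Lys/Gln calls against a transcript-
    derived sequence: wherever the read is flagged and the reference
    residue (aligned positionally; the read must be gap-free and the
    same length as the reference) is among the alternatives, the
    reference residue is adopted and the flag cleared.
    """
    if not read.is_complete:
        raise ValueError("cannot resolve a read with gaps against a reference")
    if len(read.tokens) != len(reference):
        raise ValueError("reference length does not match read length")
    tokens = list(read.tokens)
    remaining: dict[int, frozenset[str]] = {}
    for i, alts in read.ambiguities.items():
        if reference[i] in alts:
            tokens[i] = reference[i]
        else:
            remaining[i] = alts
    return SequenceRead(tokens, remaining, source=read.source)


class NoOverlapError(ValueError):
    pass


class AmbiguousOverlapError(ValueError):
    def __init__(self, candidates: list[str]):
        self.candidates = candidates
        super().__init__(
            "ambiguous overlap; candidate merges: " + ", ".join(candidates)
        )


def _suffix_prefix_overlap(a: str, b: str) -> int:
    """Longest k with a[-k:] == b[:k]."""
    best = 0
    for k in range(1, min(len(a), len(b)) + 1):
        if a[-k:] == b[:k]:
            best = k
    return best


def overlap_merge(frag_a: str, frag_b: str, min_overlap: int = 3) -> str:
    """Merge two fragments by maximal exact suffix/prefix overlap.

    Both orientations (A then B, B then A) are considered; the merge
    with the longer overlap wins, ties breaking toward the A-first
    orientation.  If one fragment contains the other, the containing
    sequence is returned.  Distinct merges at the same maximal overlap
    raise :class:`AmbiguousOverlapError` listing the candidates; no
    overlap of at least ``min_overlap`` raises :class:`NoOverlapError`.
    """
    if min_overlap < 3:
        raise ValueError("min_overlap must be >= 3")
    if frag_b in frag_a:
        return frag_a
    if frag_a in frag_b:
        return frag_b
    k_ab = _suffix_prefix_overlap(frag_a, frag_b)
    k_ba = _suffix_prefix_overlap(frag_b, frag_a)
    best = max(k_ab, k_ba)
    if best < min_overlap:
        raise NoOverlapError("no consistent overlap")
    merges = []
    if k_ab == best:
        merges.append(frag_a + frag_b[k_ab:])
    if k_ba == best:
        merges.append(frag_b + frag_a[k_ba:])
    distinct = sorted(set(merges))
    if len(distinct) > 1:
        raise AmbiguousOverlapError(distinct)
    return merges[0]
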