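"""Cysteine-motif profiling and family classification of cysteine-rich peptides.

A cysteine spacing motif is summarized by the loop-length vector: loop
i is the run of residues strictly between cysteine i and cysteine i+1
(order of appearance).  Under this numbering the diagnostic tandem CC
pair of hevein-like peptides is a zero-length loop, and a CXC pair a
length-one loop.

Family rules (eight-cysteine hevein-like peptides, 8C-HLPs):

* ginsentide-like 8C: eight cysteines with loop vector inside
  CX6 CX6-7 CC X2-4 CXC X4-6 CX1-4 C, short terminal flanks, and no
  chitin-binding domain;
* chitin-binding 8C-HLP: eight cysteines with the S-X-aromatic-X-
  aromatic element in the loop directly after the CC pair and a
  conserved aromatic in the following loop.  (In the hevein literature
  these are called loop 3 and loop 4, counting the CC pair as a single
  node; with our per-cysteine numbering they are loops 4 and 5.)
* 6C-HLP-like: six cysteines with a CC pair.

Loop bounds and the chitin-domain loop indices are configuration, not
code, so other presets can be expressed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from .chem import MONOISOTOPIC

__all__ = [
    "CysMotifProfile",
    "cys_profile",
    "FamilyRules",
    "GINSENTIDE_RULES",
    "RuleCheck",
    "FamilyCall",
    "classify_family",
    "composition",
    "conservation",
    "GINSENTIDE_LIKE",
    "CHITIN_BINDING_8C",
    "SIX_C_HLP",
    "UNCLASSIFIED",
]

AROMATIC_DEFAULT = frozenset("FWY")

GINSENTIDE_LIKE = "ginsentide-like 8C"
CHITIN_BINDING_8C = "chitin-binding 8C-HLP"
SIX_C_HLP = "6C-HLP-like"
UNCLASSIFIED = "unclassified"


@dataclass(frozen=True)
class CysMotifProfile:
    """Cysteine positions and inter-cysteine loop lengths of one sequence."""

    sequence: str
    positions: tuple[int, ...]  # 1-based
    loops: tuple[int, ...]  # len = n_cys - 1
    leading_flank: int
    trailing_flank: int

    @property
    def n_cys(self) -> int:
        return len(self.positions)

    @property
    def has_CC(self) -> bool:
        return 0 in self.loops

    @property
    def has_CXC(self) -> bool:
        return 1 in self.loops

    def loop_sequence(self, i: int) -> str:
        """Residues of loop i (between Cys i and Cys i+1), 1-based loop index."""
        if not 1 <= i <= len(self.loops):
            raise ValueError(f"loop index {i} out of range")
        return self.sequence[self.positions[i - 1] : self.positions[i] - 1]


def _clean_sequence(sequence: str) -> str:
    if not sequence:
        raise ValueError("empty sequence")
    if "-" in sequence:
        warnings.warn("gaps ('-') stripped from sequence", stacklevel=3)
        sequence = sequence.replace("-", "")
        if not sequence:
            raise ValueError("sequence is all gaps")
    bad = [aa for aa in sequence if aa not in MONOISOTOPIC]
    if bad:
        raise ValueError(f"non-residue characters in sequence: {bad[0]!r}")
    return sequence


def cys_profile(sequence: str) -> CysMotifProfile:
    """Exact cysteine positions, loop lengths and flank lengths."""
    seq = _clean_sequence(sequence)
    positions = tuple(i + 1 for i, aa in enumerate(seq) if aa == "C")
    loops = tuple(b - a - 1 for a, b in zip(positions, positions[1:]))
    lead = positions[0] - 1 if positions else len(seq)
    trail = len(seq) - positions[-1] if positions else 0
    return CysMotifProfile(seq, positions, loops, lead, trail)


@dataclass(frozen=True)
class FamilyRules:
    """Loop-bound and domain rules for 8C-HLP subfamily classification.

    ``loop_bounds`` are inclusive (lo, hi) ranges for the 7 loops of an
    8-cysteine motif.  ``chitin_motif_loop`` / ``chitin_aromatic_loop``
    are the loop indices (per-cysteine numbering) searched for the
    S-X-aromatic-X-aromatic element and the conserved aromatic.
    """

    loop_bounds: tuple[tuple[int, int], ...] = (
        (6, 6), (6, 7), (0, 0), (2, 4), (1, 1), (4, 6), (1, 4),
    )
    max_flank: int = 2
    aromatic: frozenset[str] = AROMATIC_DEFAULT
    chitin_motif_loop: int = 4
    chitin_aromatic_loop: int = 5


GINSENTIDE_RULES = FamilyRules()


@dataclass(frozen=True)
class RuleCheck:
    name: str
    passed: bool
    detail: str = ""


@dataclass(frozen=True)
class FamilyCall:
    """Classification verdict with the full per-rule audit trail."""

    label: str
    profile: CysMotifProfile
    checks: tuple[RuleCheck, ...]
    chitin_domain: tuple[int, int] | None  # (loop index, offset in loop) or None

    def check(self, name: str) -> RuleCheck:
        for c in self.checks:
            if c.name == name:
                return c
        raise KeyError(name)


def _find_sxpxp(loop_seq: str, aromatic: frozenset[str]) -> int | None:
    """Offset of an S-X-aromatic-X-aromatic match inside a loop, else None."""
    for i in range(len(loop_seq) - 4):
        w = loop_seq[i : i + 5]
        if w[0] == "S" and w[2] in aromatic and w[4] in aromatic:
            return i
    return None


def classify_family(sequence: str, rules: FamilyRules = GINSENTIDE_RULES) -> FamilyCall:
    """Classify one sequence against the 8C-HLP subfamily rules.

    Every configured rule is recorded pass/fail in the returned
    :class:`FamilyCall` so that near-misses are auditable.
    """
    profile = cys_profile(sequence)
    checks: list[RuleCheck] = []
    n8 = profile.n_cys == 8
    checks.append(RuleCheck("n_cys==8", n8, f"n_cys={profile.n_cys}"))

    # chitin-binding domain: S-X-Phi-X-Phi in the post-CC loop plus an
    # aromatic in the next loop
    chitin_domain = None
    aromatic_next = False
    if n8:
        motif_loop = rules.chitin_motif_loop
        if motif_loop <= len(profile.loops):
            off = _find_sxpxp(profile.loop_sequence(motif_loop), rules.aromatic)
            if off is not None:
                chitin_domain = (motif_loop, off + 1)
        ar_loop = rules.chitin_aromatic_loop
        if ar_loop <= len(profile.loops):
            aromatic_next = any(
                aa in rules.aromatic for aa in profile.loop_sequence(ar_loop)
            )
    if chitin_domain:
        detail = "SXPhiXPhi at loop %d offset %d; aromatic in next loop: %s" % (
            chitin_domain + (aromatic_next,)
        )
    else:
        detail = "absent"
    checks.append(RuleCheck("chitin_domain_absent", chitin_domain is None, detail))

    loops_ok = True
    if n8:
        for i, ((lo, hi), length) in enumerate(zip(rules.loop_bounds, profile.loops), start=1):
            ok = lo <= length <= hi
            loops_ok &= ok
            checks.append(RuleCheck(f"loop{i} in [{lo},{hi}]", ok, f"loop{i}={length}"))
    else:
        loops_ok = False
        checks.append(RuleCheck("loop bounds", False, "not evaluated: n_cys != 8"))

    flanks_ok = (
        profile.leading_flank <= rules.max_flank
        and profile.trailing_flank <= rules.max_flank
    )
    checks.append(
        RuleCheck(
            f"flanks<={rules.max_flank}",
            flanks_ok,
            f"lead={profile.leading_flank}, trail={profile.trailing_flank}",
        )
    )
    checks.append(RuleCheck("has_CC", profile.has_CC))

    if n8 and chitin_domain is not None and aromatic_next:
        label = CHITIN_BINDING_8C
    elif n8 and loops_ok and flanks_ok and chitin_domain is None:
        label = GINSENTIDE_LIKE
    elif profile.n_cys == 6 and profile.has_CC:
        label = SIX_C_HLP
    else:
        label = UNCLASSIFIED
    return FamilyCall(label, profile, tuple(checks), chitin_domain)


def composition(sequence: str) -> dict[str, tuple[int, float]]:
    """Per-residue counts and percentages (2-decimal), keyed by letter."""
    seq = _clean_sequence(sequence)
    out: dict[str, tuple[int, float]] = {}
    for aa in sorted(set(seq)):
        n = seq.count(aa)
        out[aa] = (n, round(100.0 * n / len(seq), 2))
    return out


def conservation(
    alignment: dict[str, str],
    reference: str,
    mode: str = "strict",
) -> tuple[list[bool], float]:
    """Column conservation of an alignment relative to a reference row.

    Only columns where the reference has a residue (not a gap) are
    scored.  ``strict``: conserved iff every row carries the reference
    residue; ``majority``: iff more than half do.  Returns per-column
    flags (in reference-column order) and the summary percentage
    100 * conserved / reference non-gap columns.
    """
    if mode not in ("strict", "majority"):
        raise ValueError(f"mode must be 'strict' or 'majority', got {mode!r}")
    if reference not in alignment:
        raise ValueError(f"reference {reference!r} not in alignment")
    rows = list(alignment.values())
    width = len(rows[0])
    if any(len(r) != width for r in rows):
        raise ValueError("ragged alignment: rows differ in length")
    ref_row = alignment[reference]
    flags: list[bool] = []
    for col in range(width):
        ref_aa = ref_row[col]
        if ref_aa == "-":
            continue
        same = sum(1 for r in rows if r[col] == ref_aa)
        if mode == "strict":
            flags.append(same == len(rows))
        else:
            flags.append(same > len(rows) / 2)
    pct = 100.0 * sum(flags) / len(flags) if flags else 0.0
    return flags, pct
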