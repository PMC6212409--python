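"""Three-domain precursor annotation and FASTA motif scanning.

Mature ginsentide-class peptides are synthesized as three-domain
precursors: an N-terminal secretion signal, a pro-domain, and the
mature cysteine-rich domain at the C-terminus.  This module annotates
that architecture on protein sequences and scans FASTA databases
(protein, or nucleotide via six-frame translation and ORF extraction)
for sequences carrying it.

The signal-peptide boundary is an explicitly heuristic call — a
Kyte-Doolittle hydropathy window of 15-30 residues ending in a small
residue — recorded as such; a user-supplied boundary always overrides
it.  The mature boundary is the start of the rightmost suffix that
classifies as ginsentide-like, allowing a configurable N-terminal
slack before its first cysteine.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio.Seq import Seq
from Bio import SeqIO

from .motifs import (
    GINSENTIDE_LIKE,
    FamilyCall,
    FamilyRules,
    GINSENTIDE_RULES,
    classify_family,
)

__all__ = [
    "PrecursorModel",
    "annotate_precursor",
    "NoMatureDomainError",
    "NonCTerminalMatureError",
    "ScanHit",
    "Orf",
    "six_frame_orfs",
    "scan_fasta",
    "KYTE_DOOLITTLE",
]

# Kyte-Doolittle hydropathy scale.
KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}

_SMALL_AT_CLEAVAGE = frozenset("AGSCT")


class NoMatureDomainError(ValueError):
    pass


class NonCTerminalMatureError(ValueError):
    """A motif-positive region exists but not at the C-terminus (cargo-style)."""

    def __init__(self, start: int, end: int):
        self.start, self.end = start, end
        super().__init__(
            f"mature-like domain at residues {start}-{end} is not C-terminal; "
            "architecture differs from the signal/pro/mature layout"
        )


@dataclass(frozen=True)
class PrecursorModel:
    """Three-domain split of a precursor; 1-based inclusive coordinates.

    ``signal_end`` of 0 means no signal segment; ``mature_start`` of 1
    means the whole sequence is mature.  ``boundary_methods`` records
    per boundary whether it came from the heuristic or the user.
    """

    sequence: str
    signal_end: int
    mature_start: int
    boundary_methods: dict

    @property
    def signal(self) -> str:
        return self.sequence[: self.signal_end]

    @property
    def pro(self) -> str:
        return self.sequence[self.signal_end : self.mature_start - 1]

    @property
    def mature(self) -> str:
        return self.sequence[self.mature_start - 1 :]


def _signal_boundary_heuristic(sequence: str, mature_start: int) -> int | None:
    """Best signal length s in 15..30 by mean hydropathy of residues 1..s.

    Requires a small residue at position s (the P1 residue of a
    signal-peptidase site).  Returns None when no admissible window
    exists.
    """
    best_s, best_score = None, None
    limit = min(30, mature_start - 2)  # leave at least one pro residue
    for s in range(15, limit + 1):
        if sequence[s - 1] not in _SMALL_AT_CLEAVAGE:
            continue
        window = sequence[:s]
        score = sum(KYTE_DOOLITTLE.get(aa, 0.0) for aa in window) / s
        if best_score is None or score > best_score:
            best_s, best_score = s, score
    return best_s


def _mature_start(
    sequence: str, rules: FamilyRules, n_slack: int
) -> tuple[int, FamilyCall] | None:
    """Rightmost suffix start whose suffix classifies ginsentide-like.

    Candidate starts are each cysteine position minus a flank of up to
    ``n_slack`` residues, scanned right to left.
    """
    cys = [i + 1 for i, aa in enumerate(sequence) if aa == "C"]
    for c in reversed(cys):
        for flank in range(0, n_slack + 1):
            start = c - flank
            if start < 1:
                continue
            call = classify_family(sequence[start - 1 :], rules)
            if call.label == GINSENTIDE_LIKE:
                return start, call
    return None


def _internal_mature_region(
    sequence: str, rules: FamilyRules
) -> tuple[int, int] | None:
    """A ginsentide-like window that does not extend to the C-terminus."""
    cys = [i + 1 for i, aa in enumerate(sequence) if aa == "C"]
    for i, start_c in enumerate(cys):
        for end_c in cys[i + 7 :]:  # at least 8 cysteines inside
            for trail in range(0, rules.max_flank + 1):
                end = end_c + trail
                if end >= len(sequence):
                    continue
                window = sequence[start_c - 1 : end]
                if classify_family(window, rules).label == GINSENTIDE_LIKE:
                    return start_c, end
    return None


def annotate_precursor(
    sequence: str,
    signal_length: int | None = None,
    mature_start: int | None = None,
    n_slack: int = 2,
    rules: FamilyRules = GINSENTIDE_RULES,
) -> PrecursorModel:
    """Annotate the signal / pro / mature split of a precursor sequence.

    Raises :class:`NoMatureDomainError` when no C-terminal region
    classifies as ginsentide-like; if a motif-positive region exists
    internally instead, :class:`NonCTerminalMatureError` pinpoints it.
    """
    if sequence.count("C") < 8:
        raise NoMatureDomainError(
            f"sequence has {sequence.count('C')} cysteines; at least 8 required"
        )
    methods = {}
    if mature_start is None:
        found = _mature_start(sequence, rules, n_slack)
        if found is None:
            internal = _internal_mature_region(sequence, rules)
            if internal is not None:
                raise NonCTerminalMatureError(*internal)
            raise NoMatureDomainError("no mature domain")
        mature_start, _ = found
        methods["mature"] = "heuristic"
    else:
        methods["mature"] = "user-supplied"
        if classify_family(sequence[mature_start - 1 :], rules).label != GINSENTIDE_LIKE:
            raise NoMatureDomainError(
                f"user-supplied mature start {mature_start} does not yield a "
                "ginsentide-like domain"
            )

    if mature_start == 1:
        return PrecursorModel(sequence, 0, 1, {**methods, "signal": "none"})

    if signal_length is None:
        s = _signal_boundary_heuristic(sequence, mature_start)
        if s is None:
            s = 0
            methods["signal"] = "heuristic (no admissible window; empty signal)"
        else:
            methods["signal"] = "heuristic"
    else:
        if not 0 <= signal_length < mature_start:
            raise ValueError("signal_length must lie before the mature domain")
        s = signal_length
        methods["signal"] = "user-supplied"
    return PrecursorModel(sequence, s, mature_start, methods)


@dataclass(frozen=True)
class Orf:
    """An open reading frame on a nucleotide record.

    ``start``/``end`` are 0-based half-open coordinates on the forward
    strand of the source record; ``strand`` is '+' or '-'; ``frame`` is
    0..2 on the given strand.
    """

    start: int
    end: int
    strand: str
    frame: int
    protein: str


def six_frame_orfs(nt_seq: str, min_orf: int = 30, partial: bool = False) -> list[Orf]:
    """ORFs of length >= min_orf codons in all six reading frames.

    ORFs are stop-to-stop segments, trimmed to their first internal Met
    (preferred start).  With ``partial``, segments truncated at record
    edges are kept without requiring a Met.  Standard genetic code.
    """
    nt = nt_seq.upper().replace("U", "T")
    n = len(nt)
    orfs: list[Orf] = []
    for strand, seq in (("+", nt), ("-", str(Seq(nt).reverse_complement()))):
        for frame in range(3):
            usable = len(seq) - frame - (len(seq) - frame) % 3
            prot = str(Seq(seq[frame : frame + usable]).translate())
            # split on stops, tracking codon offsets
            seg_start = 0
            for seg in prot.split("*"):
                seg_end = seg_start + len(seg)
                candidate = seg
                cod_start = seg_start
                if not partial:
                    m = candidate.find("M")
                    if m < 0:
                        seg_start = seg_end + 1
                        continue
                    candidate = candidate[m:]
                    cod_start = seg_start + m
                if len(candidate) >= min_orf:
                    nt_start = frame + 3 * cod_start
                    nt_end = frame + 3 * seg_end
                    if strand == "+":
                        start, end = nt_start, min(nt_end, n)
                    else:
                        start, end = n - min(nt_end, n), n - nt_start
                    orfs.append(Orf(start, end, strand, frame, candidate))
                seg_start = seg_end + 1
    orfs.sort(key=lambda o: (o.start, o.end, o.strand, o.frame))
    return orfs


@dataclass(frozen=True)
class ScanHit:
    """A precursor-architecture hit in a scanned database."""

    record_id: str
    strand: str  # '+', '-' or '.' for protein input
    frame: int  # -1 for protein input
    orf_start: int  # 0-based half-open on the source record
    orf_end: int
    precursor: PrecursorModel
    family: FamilyCall


def _scan_protein(
    record_id: str,
    protein: str,
    rules: FamilyRules,
    strand: str = ".",
    frame: int = -1,
    orf_start: int = 0,
    orf_end: int | None = None,
) -> ScanHit | None:
    if protein.count("C") < 8:
        return None
    try:
        model = annotate_precursor(protein, rules=rules)
    except (NoMatureDomainError, NonCTerminalMatureError):
        return None
    call = classify_family(model.mature, rules)
    return ScanHit(
        record_id, strand, frame, orf_start,
        len(protein) if orf_end is None else orf_end, model, call,
    )


_AA_ONLY = set("EFILPQZ")  # letters valid in proteins but not nucleotides


def scan_fasta(
    path_or_records,
    input_type: str = "aa",
    min_orf: int = 30,
    rules: FamilyRules = GINSENTIDE_RULES,
) -> list[ScanHit]:
    """Scan a FASTA database for three-domain precursor architectures.

    ``path_or_records`` is a FASTA path/handle or an iterable of
    Bio.SeqRecord objects.  Nucleotide input is translated in six
    frames and ORFs of at least ``min_orf`` codons are scanned.  Hits
    are deduplicated by (record, coordinates, strand) and returned in
    deterministic order.  Records whose alphabet contradicts
    ``input_type`` are skipped with a warning.
    """
    import warnings as _warnings

    if input_type not in ("aa", "nt"):
        raise ValueError(f"input_type must be 'aa' or 'nt', got {input_type!r}")
    import os

    if isinstance(path_or_records, (str, bytes, os.PathLike)) or hasattr(
        path_or_records, "read"
    ):
        records = list(SeqIO.parse(path_or_records, "fasta"))
    else:
        records = list(path_or_records)
        if records and not hasattr(records[0], "seq"):
            raise ValueError("records must be Bio.SeqRecord objects")

    hits: dict[tuple, ScanHit] = {}
    for rec in records:
        seq = str(rec.seq).upper()
        if not seq:
            continue
        if input_type == "nt":
            if any(aa in _AA_ONLY for aa in seq):
                _warnings.warn(f"record {rec.id}: protein-only letters in nt scan; skipped")
                continue
            for orf in six_frame_orfs(seq, min_orf=min_orf):
                hit = _scan_protein(
                    rec.id, orf.protein, rules,
                    strand=orf.strand, frame=orf.frame,
                    orf_start=orf.start, orf_end=orf.end,
                )
                if hit is not None:
                    key = (rec.id, hit.orf_start, hit.orf_end, hit.strand)
                    hits.setdefault(key, hit)
        else:
            hit = _scan_protein(rec.id, seq, rules)
            if hit is not None:
                hits.setdefault((rec.id, 0, len(seq), "."), hit)
    return [hits[k] for k in sorted(hits, key=lambda k: (str(k[0]), k[1], k[2], k[3]))]
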