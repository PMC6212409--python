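"""Ensemble structure validation: disulfide detection, RMSD, pseudocyclicity.

Operates on multi-model PDB files (NMR-style ensembles).  Disulfide
bonds are detected geometrically from Sgamma-Sgamma distances; the
ensemble consensus is compared against chemically mapped topologies.
Ensemble precision is quantified as the average RMSD of each model to
the iteratively refined mean structure after least-squares rigid
superposition (reflections disallowed), the convention used for NMR
structural statistics.  Pseudocyclicity — both terminal cysteines
locked into disulfides, mimicking a cyclic backbone — is evaluated on
the topology.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

from .connectivity import DisulfideTopology, format_bonds

__all__ = [
    "StructureEnsemble",
    "read_ensemble",
    "write_ensemble",
    "SSBondReport",
    "detect_ss_bonds",
    "RmsdResult",
    "ensemble_rmsd",
    "PseudocyclicReport",
    "pseudocyclicity",
    "BACKBONE_ATOMS",
]

BACKBONE_ATOMS = ("N", "CA", "C", "O")


@dataclass
class StructureEnsemble:
    """Multi-model coordinates with shared atom annotation.

    Thin wrapper over a biotite ``AtomArrayStack``: every model shares
    residue/atom naming, so per-atom annotations are stored once.
    """

    stack: struc.AtomArrayStack

    @property
    def n_models(self) -> int:
        return self.stack.stack_depth()

    @property
    def n_atoms(self) -> int:
        return self.stack.array_length()

    def cys_ordinals(self) -> dict[int, int]:
        """Map cysteine ordinal (order of appearance) -> residue id."""
        res_ids = []
        for rid, rname in zip(self.stack.res_id, self.stack.res_name):
            if rname == "CYS" and rid not in res_ids:
                res_ids.append(int(rid))
        return {i + 1: rid for i, rid in enumerate(sorted(res_ids))}


def read_ensemble(path, drop_hydrogens: bool = True) -> StructureEnsemble:
    """Read a (multi-)model PDB file into an ensemble.

    Alternate locations are resolved to the highest-occupancy copy.
    Models with inconsistent atom sets raise a ValueError naming the
    mismatch (via biotite's stack construction).
    """
    pdb = PDBFile.read(path)
    try:
        stack = pdb.get_structure(altloc="occupancy")
    except Exception as exc:  # biotite raises various subclasses
        raise ValueError(f"inconsistent or unparsable ensemble: {exc}") from exc
    if isinstance(stack, struc.AtomArray):
        stack = struc.stack([stack])
    if drop_hydrogens:
        stack = stack[:, stack.element != "H"]
    if stack.array_length() == 0:
        raise ValueError("ensemble contains no atoms")
    return StructureEnsemble(stack)


def write_ensemble(ensemble: StructureEnsemble, path) -> None:
    pdb = PDBFile()
    pdb.set_structure(ensemble.stack)
    pdb.write(path)


@dataclass(frozen=True)
class SSBondReport:
    """Per-model and consensus disulfide bonds as cysteine-ordinal pairs."""

    per_model: tuple[frozenset[tuple[int, int]], ...]
    consensus: frozenset[tuple[int, int]]
    flagged: tuple[str, ...]  # warnings, e.g. a cysteine in two consensus pairs

    def __str__(self) -> str:
        return format_bonds(self.consensus)


def detect_ss_bonds(ensemble: StructureEnsemble, cutoff: float = 2.5) -> SSBondReport:
    """Disulfides from Sgamma-Sgamma distances.

    A pair is bonded in a model when the SG-SG distance is at most
    ``cutoff`` (default 2.5 A; covalent S-S is ~2.05 A).  The consensus
    keeps pairs present in more than half the models; a cysteine
    appearing in more than one consensus pair is flagged rather than
    silently resolved.  Cysteine residues lacking an SG atom are an
    error.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    stack = ensemble.stack
    ordinals = ensemble.cys_ordinals()
    if not ordinals:
        raise ValueError("no cysteine residues in ensemble")
    sg_index: dict[int, int] = {}
    missing = []
    for ordinal, rid in ordinals.items():
        mask = (stack.res_id == rid) & (stack.res_name == "CYS") & (stack.atom_name == "SG")
        idx = np.flatnonzero(mask)
        if len(idx) == 0:
            missing.append(f"CYS{rid}")
        else:
            sg_index[ordinal] = int(idx[0])
    if missing:
        raise ValueError("missing SG atoms for residues: " + ", ".join(missing))

    ords = sorted(sg_index)
    per_model = []
    for m in range(ensemble.n_models):
        coords = stack.coord[m]
        bonds = set()
        for i, a in enumerate(ords):
            for b in ords[i + 1 :]:
                d = np.linalg.norm(coords[sg_index[a]] - coords[sg_index[b]])
                if d <= cutoff:
                    bonds.add((a, b))
        per_model.append(frozenset(bonds))

    counts: dict[tuple[int, int], int] = {}
    for bonds in per_model:
        for b in bonds:
            counts[b] = counts.get(b, 0) + 1
    consensus = frozenset(b for b, c in counts.items() if c > ensemble.n_models / 2)
    flagged = []
    seen: dict[int, tuple[int, int]] = {}
    for bond in sorted(consensus):
        for cys in bond:
            if cys in seen:
                flagged.append(
                    f"cysteine ordinal {cys} participates in consensus pairs "
                    f"{seen[cys]} and {bond}"
                )
            seen[cys] = bond
    return SSBondReport(tuple(per_model), consensus, tuple(flagged))


def _atom_mask(ensemble: StructureEnsemble, atom_set: str, residue_range) -> np.ndarray:
    stack = ensemble.stack
    if atom_set == "backbone":
        mask = np.isin(stack.atom_name, BACKBONE_ATOMS)
    elif atom_set == "heavy":
        mask = stack.element != "H"
    else:
        raise ValueError(f"atom_set must be 'backbone' or 'heavy', got {atom_set!r}")
    if residue_range is not None:
        lo, hi = residue_range
        mask &= (stack.res_id >= lo) & (stack.res_id <= hi)
    if not mask.any():
        raise ValueError("atom selection is empty")
    return mask


def _kabsch_fit(mobile: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Least-squares rigid superposition of mobile onto target (no reflection)."""
    mc = mobile.mean(axis=0)
    tc = target.mean(axis=0)
    a = mobile - mc
    b = target - tc
    h = a.T @ b
    u, _s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(u @ vt))
    rot = u @ np.diag([1.0, 1.0, d]) @ vt
    return (a @ rot) + tc


@dataclass(frozen=True)
class RmsdResult:
    """Average per-model RMSD to the converged mean structure."""

    mean: float
    sd: float
    per_model: tuple[float, ...]
    n_atoms: int
    n_iterations: int

    def __str__(self) -> str:
        return f"{self.mean:.2f} +/- {self.sd:.2f} A ({self.n_atoms} atoms)"


def ensemble_rmsd(
    ensemble: StructureEnsemble,
    atom_set: str = "backbone",
    residue_range: tuple[int, int] | None = None,
    tol: float = 1e-6,
    max_iter: int = 200,
) -> RmsdResult:
    """Average RMSD of each model to the iteratively refined mean.

    All models are superposed onto the current mean coordinates, the
    mean is recomputed, and the cycle repeats until the mean shifts by
    less than ``tol`` A (RMS).  Reported as mean +/- SD of the
    per-model RMSD values over the chosen atom set and residue range.
    """
    if ensemble.n_models < 2:
        raise ValueError("ensemble RMSD requires at least 2 models")
    mask = _atom_mask(ensemble, atom_set, residue_range)
    coords = ensemble.stack.coord[:, mask, :].astype(float)
    mean = coords[0].copy()
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        fitted = np.array([_kabsch_fit(c, mean) for c in coords])
        new_mean = fitted.mean(axis=0)
        shift = float(np.sqrt(((new_mean - mean) ** 2).sum(axis=1).mean()))
        mean = new_mean
        coords = fitted
        if shift < tol:
            break
    rmsds = tuple(
        float(np.sqrt(((c - mean) ** 2).sum(axis=1).mean())) for c in coords
    )
    return RmsdResult(
        mean=float(np.mean(rmsds)),
        sd=float(np.std(rmsds)),
        per_model=rmsds,
        n_atoms=int(mask.sum()),
        n_iterations=n_iter,
    )


@dataclass(frozen=True)
class PseudocyclicReport:
    pseudocyclic: bool
    n_terminal_anchor: tuple[int, int] | None
    c_terminal_anchor: tuple[int, int] | None

    def __str__(self) -> str:
        if not self.pseudocyclic:
            return "not pseudocyclic"
        return (
            "pseudocyclic; anchors "
            + format_bonds([self.n_terminal_anchor])
            + " and "
            + format_bonds([self.c_terminal_anchor])
        )


def pseudocyclicity(topology: DisulfideTopology) -> PseudocyclicReport:
    """Terminal-cysteine anchoring test.

    A peptide is pseudocyclic when its first cysteine (ordinal 1, the
    N-terminal-most) and its last (ordinal n_cys) both participate in
    disulfide bonds, topologically closing the backbone into a
    macrocycle-like fold.
    """
    first = next((b for b in topology.bonds if 1 in b), None)
    last = next((b for b in topology.bonds if topology.n_cys in b), None)
    return PseudocyclicReport(
        pseudocyclic=first is not None and last is not None,
        n_terminal_anchor=tuple(sorted(first)) if first else None,
        c_terminal_anchor=tuple(sorted(last)) if last else None,
    )
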