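"""Seeded generators for every input the pipeline consumes, with ground truth.

Synthetic study conditions:

* cysteine-rich peptides whose loop-length vectors are drawn uniformly
  within a motif preset (ginsentide or chitin-binding hevein bounds),
  with non-cysteine residues sampled from the pooled composition of
  the natural TP family;
* partial-reduction / dual-alkylation experiments with a known
  topology and reduction order, emitting the ideal intermediate label
  observations and, optionally, labeled tryptic-fragment mass lists;
* decoy sequence databases (residue-shuffled peptides, which preserve
  composition but destroy cysteine spacing) with three-domain
  precursors embedded at recorded positions and strands;
* idealized multi-model structure ensembles with disulfides placed at
  bonding distance and isotropic Gaussian coordinate noise of known
  standard deviation, so the expected ensemble RMSD is analytic.

A single global seed fans out to per-component streams through fixed
offsets (see ``SEED_OFFSETS``), so artifacts are reproducible
individually and jointly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import biotite.structure as struc
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import data
from .chem import IAM, NEM, PeptideSpecies, ThiolLabel
from .connectivity import (
    DisulfideTopology,
    LabelObservation,
    enumerate_matchings,
    simulate_partial_reduction,
)
from .digest import TRYPSIN, DigestFragment, digest, fragment_ions
from .motifs import GINSENTIDE_RULES, cys_profile
from .structure import StructureEnsemble

__all__ = [
    "GeneratorConfig",
    "SEED_OFFSETS",
    "component_rng",
    "gen_crp",
    "gen_ss_experiment",
    "gen_ladder_peaks",
    "SSExperiment",
    "gen_database",
    "gen_ensemble",
    "EnsembleTruth",
    "HEVEIN_LOOP_BOUNDS",
]

#: Fixed offsets splitting one global seed into per-component streams.
SEED_OFFSETS = {"crp": 101, "ss": 211, "db": 307, "ensemble": 401, "ladder": 503}

#: Loop bounds emulating chitin-binding hevein-like peptides: room for
#: the S-X-aromatic-X-aromatic element after the CC pair and an
#: aromatic-bearing loop after that.
HEVEIN_LOOP_BOUNDS = ((7, 9), (3, 5), (0, 0), (5, 7), (5, 7), (4, 6), (2, 4))

_PRESETS: dict[str, tuple[tuple[int, int], ...]] = {
    "ginsentide": GINSENTIDE_RULES.loop_bounds,
    "hevein": HEVEIN_LOOP_BOUNDS,
}


@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs of the synthetic study conditions.

    Defaults mirror the natural system: eight-cysteine peptides with
    ginsentide loop bounds, full-coverage noiseless ladders, decoy
    databases of 100 shuffled sequences, 20-model ensembles with 0.3 A
    coordinate noise.
    """

    seed: int = 0
    preset: str = "ginsentide"
    loop_bounds: tuple[tuple[int, int], ...] | None = None  # overrides preset
    lead_flank: tuple[int, int] = (0, 0)
    trail_flank: tuple[int, int] = (0, 1)
    topology_mode: str = "uniform"  # or "fixed"
    fixed_bonds: tuple[tuple[int, int], ...] = ()
    fixed_order: tuple[tuple[int, int], ...] = ()
    ladder_coverage: float = 1.0
    noise_peaks: int = 0
    n_decoys: int = 100
    n_embedded: int = 1
    decoy_nt: bool = False
    signal_length_range: tuple[int, int] = (18, 25)
    pro_length_range: tuple[int, int] = (20, 35)
    n_models: int = 20
    coord_noise_sd: float = 0.3
    ss_bond_length: float = 2.05

    def bounds(self) -> tuple[tuple[int, int], ...]:
        if self.loop_bounds is not None:
            return self.loop_bounds
        if self.preset not in _PRESETS:
            raise ValueError(f"unknown preset {self.preset!r}")
        return _PRESETS[self.preset]


def component_rng(config: GeneratorConfig, component: str) -> np.random.Generator:
    return np.random.default_rng(config.seed + SEED_OFFSETS[component])


_BACKGROUND = data.pooled_residue_frequencies()
_BG_LETTERS = np.array(list(_BACKGROUND))
_BG_PROBS = np.array([_BACKGROUND[aa] for aa in _BG_LETTERS])


def _sample_loop(rng: np.random.Generator, length: int, forbid_cys: bool = True) -> str:
    return "".join(rng.choice(_BG_LETTERS, size=length, p=_BG_PROBS))


def gen_crp(config: GeneratorConfig):
    """One random cysteine-rich peptide satisfying the configured preset.

    Returns ``(sequence, profile)`` where the profile is the ground
    truth cysteine motif.  Ginsentide bounds require the tandem CC
    (loop 3 of length 0); configurations violating a preset's fixed
    loops are rejected as infeasible.
    """
    bounds = config.bounds()
    if config.preset == "ginsentide" and config.loop_bounds is not None:
        lo, hi = config.loop_bounds[2]
        if lo != 0 or hi != 0:
            raise ValueError("ginsentide preset requires loop 3 fixed at 0 (the CC pair)")
    for lo, hi in bounds:
        if lo < 0 or hi < lo:
            raise ValueError(f"infeasible loop bound ({lo},{hi})")
    rng = component_rng(config, "crp")
    loops = [int(rng.integers(lo, hi + 1)) for lo, hi in bounds]
    lead = int(rng.integers(config.lead_flank[0], config.lead_flank[1] + 1))
    trail = int(rng.integers(config.trail_flank[0], config.trail_flank[1] + 1))
    parts = [_sample_loop(rng, lead)]
    for i, L in enumerate(loops):
        parts.append("C")
        seg = _sample_loop(rng, L)
        if config.preset == "hevein" and i == 3 and L >= 5:
            # force the chitin-binding element right after the CC pair
            arom = "FWY"
            seg = (
                "S"
                + seg[1]
                + arom[int(rng.integers(3))]
                + seg[3]
                + arom[int(rng.integers(3))]
                + seg[5:]
            )
        if config.preset == "hevein" and i == 4 and L >= 1:
            pos = int(rng.integers(L))
            seg = seg[:pos] + "W" + seg[pos + 1 :]
        parts.append(seg)
    parts.append("C")
    parts.append(_sample_loop(rng, trail))
    seq = "".join(parts)
    return seq, cys_profile(seq)


@dataclass(frozen=True)
class SSExperiment:
    """Ground truth plus observables of one simulated mapping experiment."""

    sequence: str
    topology: DisulfideTopology
    observations: tuple[LabelObservation, ...]
    fragment_evidence: tuple[tuple[str, tuple[tuple[DigestFragment, float], ...]], ...]

    def truth_json(self) -> str:
        return json.dumps(
            {
                "sequence": self.sequence,
                "bonds": sorted(map(list, self.topology.bonds)),
                "order": list(map(list, self.topology.reduction_order)),
                "intermediates": [
                    {"k": o.n_intact, "first": sorted(o.first_tag)}
                    for o in self.observations
                ],
            }
        )


def gen_ss_experiment(
    sequence: str,
    config: GeneratorConfig,
    k_values: list[int] | None = None,
    labels: tuple[ThiolLabel, ThiolLabel] = (NEM, IAM),
    with_fragments: bool = False,
) -> SSExperiment:
    """Simulate a partial-reduction dual-alkylation experiment.

    Topology and reduction order are sampled uniformly (or fixed via
    the config); intermediates at each requested intact count k
    (default: the full series n_bonds-1 .. 0) are generated by
    sequential unfolding.  With ``with_fragments``, each intermediate
    also yields labeled tryptic fragments with exact [M+H]+ values, the
    input to label localization.
    """
    n_cys = sequence.count("C")
    if n_cys == 0 or n_cys % 2:
        raise ValueError(f"sequence must have an even, positive cysteine count; got {n_cys}")
    rng = component_rng(config, "ss")
    if config.topology_mode == "fixed":
        bonds = frozenset(tuple(sorted(b)) for b in config.fixed_bonds)
        order = tuple(tuple(sorted(b)) for b in config.fixed_order) or tuple(sorted(bonds))
    elif config.topology_mode == "uniform":
        matchings = enumerate_matchings(n_cys)
        bonds = matchings[int(rng.integers(len(matchings)))]
        order = tuple(rng.permutation(sorted(bonds)).tolist())
        order = tuple((int(a), int(b)) for a, b in order)
    else:
        raise ValueError(f"unknown topology_mode {config.topology_mode!r}")
    topology = DisulfideTopology(n_cys, bonds, reduction_order=order)
    n_bonds = topology.n_bonds
    if k_values is None:
        k_values = list(range(n_bonds - 1, -1, -1))
    observations = tuple(simulate_partial_reduction(topology, k_values))

    evidence = []
    if with_fragments:
        first_label, second_label = labels
        pos_to_ordinal = {
            p: o
            for o, p in enumerate(
                (i + 1 for i, aa in enumerate(sequence) if aa == "C"), start=1
            )
        }
        for obs in observations:
            species = PeptideSpecies(
                sequence,
                n_disulfides=0,
                cys_labels={
                    o: (first_label if o in obs.first_tag else second_label)
                    for o in range(1, n_cys + 1)
                },
            )
            frags = [f for f in digest(species, TRYPSIN, max_missed=0) if "C" in f.sequence]
            evidence.append(
                (obs.intermediate_id, tuple((f, f.mh) for f in frags))
            )
    return SSExperiment(sequence, topology, observations, tuple(evidence))


def gen_ladder_peaks(
    sequence: str,
    config: GeneratorConfig,
    series: str = "b",
) -> tuple[list[float], float]:
    """Synthetic ladder m/z list with configurable coverage and noise.

    Returns ``(peaks, precursor_mh)``.  Coverage < 1 drops interior
    ions (never the first or last) uniformly at random; ``noise_peaks``
    spurious peaks are added away from true ions.  Peaks come back
    sorted ascending.
    """
    from .chem import mz_from_mass, peptide_mass

    rng = component_rng(config, "ladder")
    ladder = fragment_ions(sequence, series)
    mz = [m for _, m in ladder.ions]
    precursor = mz_from_mass(peptide_mass(sequence), 1)
    keep = list(range(len(mz)))
    if config.ladder_coverage < 1.0 and len(mz) > 2:
        interior = list(range(1, len(mz) - 1))
        n_drop = int(round((1.0 - config.ladder_coverage) * len(interior)))
        drop = set(rng.choice(interior, size=min(n_drop, len(interior)), replace=False).tolist())
        keep = [i for i in keep if i not in drop]
    peaks = [mz[i] for i in keep]
    for _ in range(config.noise_peaks):
        while True:
            cand = float(rng.uniform(min(mz) - 50, max(mz) + 50))
            if all(abs(cand - m) > 0.5 for m in mz):
                peaks.append(cand)
                break
    return sorted(peaks), precursor


def _nt_flank(rng: np.random.Generator, forbid: tuple[str, ...]) -> str:
    """Short random nucleotide flank avoiding the given trinucleotides."""
    while True:
        flank = "".join(rng.choice(list("ACGT"), size=int(rng.integers(5, 30))))
        if not any(f in flank for f in forbid):
            return flank


def _random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_BG_LETTERS, size=length, p=_BG_PROBS))


def _reverse_translate(rng: np.random.Generator, protein: str) -> str:
    """One synonymous nucleotide encoding under the standard code."""
    table: dict[str, list[str]] = {}
    bases = "TCAG"
    for b1 in bases:
        for b2 in bases:
            for b3 in bases:
                codon = b1 + b2 + b3
                aa = str(Seq(codon).translate())
                table.setdefault(aa, []).append(codon)
    return "".join(rng.choice(table[aa]) for aa in protein) + rng.choice(table["*"])


def gen_database(config: GeneratorConfig):
    """Decoy FASTA database with embedded three-domain precursors.

    Decoys are residue shuffles of generated cysteine-rich peptides
    padded into protein-sized records: composition is preserved but
    cysteine spacing is destroyed.  ``n_embedded`` true precursors
    (signal + pro + mature ginsentide-like domain) are inserted at
    seeded positions; in nucleotide mode each record is a synonymous
    encoding, embedded on a random strand.  Returns ``(records,
    truth)`` where truth is a DataFrame of the embedded hits.
    """
    rng = component_rng(config, "db")
    records: list[SeqRecord] = []
    truth_rows = []
    mature_pool = list(data.TP_SEQUENCES.values())

    n_total = config.n_decoys + config.n_embedded
    embed_at = set(
        rng.choice(n_total, size=config.n_embedded, replace=False).tolist()
        if config.n_embedded
        else []
    )
    for i in range(n_total):
        rec_id = f"rec{i:04d}"
        if i in embed_at:
            mature = mature_pool[int(rng.integers(len(mature_pool)))]
            sig_len = int(rng.integers(*config.signal_length_range))
            pro_len = int(rng.integers(*config.pro_length_range))
            # hydrophobic-core signal ending in a small residue
            core = "".join(rng.choice(list("LIVFA"), size=sig_len - 2))
            signal = "M" + core[: sig_len - 2] + "A"
            pro = "".join(
                c for c in _random_protein(rng, pro_len * 2) if c != "C"
            )[:pro_len]
            protein = signal + pro + mature
            kind = "precursor"
        else:
            src, _ = gen_crp(replace(config, seed=config.seed + 7 * i + 13))
            pad = "".join(c for c in _random_protein(rng, 60) if c != "C")
            letters = list(src)
            rng.shuffle(letters)
            protein = "M" + pad[:30] + "".join(letters) + pad[30:]
            kind = "decoy"

        if config.decoy_nt:
            nt = _reverse_translate(rng, protein)
            strand = "+" if rng.random() < 0.5 else "-"
            flank5 = _nt_flank(rng, forbid=("ATG",))  # no upstream in-frame start
            flank3 = _nt_flank(rng, forbid=("CAT",))  # no upstream start on '-'
            insert = nt if strand == "+" else str(Seq(nt).reverse_complement())
            full = flank5 + insert + flank3
            records.append(SeqRecord(Seq(full), id=rec_id, description=kind))
            if kind == "precursor":
                # coordinates of the coding region excluding the stop codon,
                # matching stop-to-stop ORF extraction
                if strand == "+":
                    start, end = len(flank5), len(flank5) + len(nt) - 3
                else:
                    start, end = len(flank5) + 3, len(flank5) + len(nt)
                truth_rows.append(
                    {
                        "record": rec_id,
                        "kind": kind,
                        "strand": strand,
                        "orf_start": start,
                        "orf_end": end,
                        "protein": protein,
                        "mature": protein[len(signal) + len(pro):],
                    }
                )
        else:
            records.append(SeqRecord(Seq(protein), id=rec_id, description=kind))
            if kind == "precursor":
                truth_rows.append(
                    {
                        "record": rec_id,
                        "kind": kind,
                        "strand": ".",
                        "orf_start": 0,
                        "orf_end": len(protein),
                        "protein": protein,
                        "mature": mature,
                    }
                )
    truth = pd.DataFrame(
        truth_rows,
        columns=["record", "kind", "strand", "orf_start", "orf_end", "protein", "mature"],
    )
    return records, truth


@dataclass(frozen=True)
class EnsembleTruth:
    """Ground truth of a generated ensemble."""

    bonds: frozenset[tuple[int, int]]
    noise_sd: float
    n_models: int

    @property
    def expected_rmsd(self) -> float:
        """Closed-form expected RMSD to the sample mean.

        With isotropic Gaussian noise of SD sigma per coordinate, each
        atom's deviation from the M-model sample mean has variance
        3 sigma^2 (1 - 1/M); averaging over atoms, RMSD approaches
        sigma * sqrt(3 (1 - 1/M)).  Rigid-body superposition removes 6
        of 3N degrees of freedom, a correction of order 1/N that the
        tolerance absorbs.
        """
        m = self.n_models
        return self.noise_sd * float(np.sqrt(3.0 * (1.0 - 1.0 / m)))


def gen_ensemble(
    sequence: str,
    bonds,
    config: GeneratorConfig,
) -> tuple[StructureEnsemble, EnsembleTruth]:
    """Synthetic multi-model ensemble with known disulfides and noise.

    Builds an idealized mean structure: a smooth self-avoiding CA
    trace with 3.8 A virtual bonds, N/C/O backbone atoms at fixed
    local offsets, and cysteine SG atoms.  SG atoms of bonded pairs
    are placed at ``ss_bond_length`` (2.05 A) separation; free-cysteine
    SG atoms are kept away from all others.  Models are the mean plus
    isotropic Gaussian noise of ``coord_noise_sd``.  The geometry is a
    synthetic fixture for coordinate-analysis code paths, not a
    physically refined structure.
    """
    rng = component_rng(config, "ensemble")
    n = len(sequence)
    bonds = frozenset(tuple(sorted(b)) for b in bonds)
    cys_ordinals = [i for i, aa in enumerate(sequence) if aa == "C"]

    # Rejection loop: resample the trace until SG atoms of distinct bonds
    # are well separated, so geometric bond detection is unambiguous even
    # after coordinate noise.
    min_separation = max(4.0, config.ss_bond_length + 6 * config.coord_noise_sd)
    for _attempt in range(100):
        # Smooth CA trace: random-walk directions with persistence.
        ca = np.zeros((n, 3))
        direction = np.array([1.0, 0.0, 0.0])
        for i in range(1, n):
            while True:
                perturb = rng.normal(scale=0.6, size=3)
                new_dir = direction + perturb
                new_dir /= np.linalg.norm(new_dir)
                cand = ca[i - 1] + 3.8 * new_dir
                if all(np.linalg.norm(cand - ca[j]) > 3.5 for j in range(i - 1)):
                    break
            ca[i] = cand
            direction = new_dir

        sg: dict[int, np.ndarray] = {}
        same_bond: set[frozenset[int]] = set()
        for a, b in bonds:
            ra, rb = cys_ordinals[a - 1], cys_ordinals[b - 1]
            mid = (ca[ra] + ca[rb]) / 2
            d = ca[rb] - ca[ra]
            d = d / np.linalg.norm(d)
            half = config.ss_bond_length / 2
            sg[ra] = mid - half * d
            sg[rb] = mid + half * d
            same_bond.add(frozenset({ra, rb}))
        free_ok = True
        for res in cys_ordinals:
            if res in sg:
                continue
            for _ in range(200):
                u = rng.normal(size=3)
                u /= np.linalg.norm(u)
                cand = ca[res] + 1.8 * u
                if all(np.linalg.norm(cand - p) > min_separation for p in sg.values()):
                    sg[res] = cand
                    break
            else:
                free_ok = False
                break
        if not free_ok:
            continue
        placed = sorted(sg)
        clashing = any(
            np.linalg.norm(sg[p] - sg[q]) < min_separation
            for i_, p in enumerate(placed)
            for q in placed[i_ + 1 :]
            if frozenset({p, q}) not in same_bond
        )
        if not clashing:
            break
    else:
        raise RuntimeError("could not place separated disulfide geometry")

    atoms = []
    offsets = {"N": np.array([-1.2, 0.5, 0.0]), "C": np.array([1.2, 0.4, 0.0]),
               "O": np.array([1.6, 1.5, 0.3])}
    three = {
        "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS", "Q": "GLN",
        "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE", "L": "LEU", "K": "LYS",
        "M": "MET", "F": "PHE", "P": "PRO", "S": "SER", "T": "THR", "W": "TRP",
        "Y": "TYR", "V": "VAL",
    }
    coords = []
    for i, aa in enumerate(sequence):
        res_name = three[aa]
        for name in ("N", "CA", "C", "O"):
            pos = ca[i] + (offsets[name] if name != "CA" else 0.0)
            atoms.append((i + 1, res_name, name, "N" if name == "N" else ("O" if name == "O" else "C")))
            coords.append(pos)
        if aa == "C":
            atoms.append((i + 1, res_name, "SG", "S"))
            coords.append(sg[i])
    mean = np.array(coords)

    n_atoms = len(atoms)
    array = struc.AtomArray(n_atoms)
    array.res_id = np.array([a[0] for a in atoms], dtype=int)
    array.res_name = np.array([a[1] for a in atoms])
    array.atom_name = np.array([a[2] for a in atoms])
    array.element = np.array([a[3] for a in atoms])
    array.chain_id = np.full(n_atoms, "A")
    array.hetero = np.full(n_atoms, False)

    models = []
    for _ in range(config.n_models):
        model = array.copy()
        model.coord = (mean + rng.normal(scale=config.coord_noise_sd, size=mean.shape)).astype(
            np.float32
        )
        models.append(model)
    stack = struc.stack(models)
    truth = EnsembleTruth(bonds, config.coord_noise_sd, config.n_models)
    return StructureEnsemble(stack), truth
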