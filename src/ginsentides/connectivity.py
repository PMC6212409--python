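"""Disulfide connectivity deduction from partial reduction / dual alkylation.

The experiment behind this module: a disulfide-rich peptide is
partially reduced (TCEP), and newly freed cysteines are trapped with a
first alkylation tag (NEM).  Intermediates with k intact bonds ("kSS"
species) are isolated, then fully reduced and tagged with a second
reagent (IAM).  MS/MS of proteolytic fragments localizes which
cysteines carry which tag.  In each intermediate the first-tag set is
a union of complete disulfide pairs, so every intermediate constrains
the connectivity; combining intermediates prunes the space of perfect
matchings over the cysteines, ideally to a single topology, and the
intact-bond counts order the bonds by reduction susceptibility
(the unfolding pathway).

Cysteines are indexed by order of appearance, 1..n (the Roman-numeral
convention Cys I, II, ... used when naming bonds).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from .chem import IAM, NEM, PeptideSpecies, ThiolLabel, mz_from_mass, peptide_mass
from .digest import DigestFragment

__all__ = [
    "DisulfideTopology",
    "LabelObservation",
    "enumerate_matchings",
    "consistent_matchings",
    "deduce_connectivity",
    "Deduction",
    "InconsistentObservationsError",
    "simulate_partial_reduction",
    "localize_labels",
    "LabelLocalization",
    "LabelLocalizationError",
    "ROMAN",
    "format_bonds",
]

ROMAN = ["I", "II", "III", "IV", "V", "VI", "VII", "VIII", "IX", "X",
         "XI", "XII", "XIII", "XIV", "XV", "XVI"]

Bond = tuple[int, int]


def format_bonds(bonds) -> str:
    """Human-readable Roman-numeral bond list, e.g. 'CysI-CysIV, CysII-CysVI'."""
    parts = []
    for a, b in sorted(tuple(sorted(p)) for p in bonds):
        parts.append(f"Cys{ROMAN[a - 1]}-Cys{ROMAN[b - 1]}")
    return ", ".join(parts)


@dataclass(frozen=True)
class DisulfideTopology:
    """A set of disjoint cysteine-ordinal pairs, optionally with reduction order.

    For connectivity deduction the pairs form a perfect matching over
    ordinals 1..n_cys; partially bonded topologies (free cysteines) are
    permitted for geometric checks such as pseudocyclicity.
    """

    n_cys: int
    bonds: frozenset[Bond]
    reduction_order: tuple[Bond, ...] | None = None

    def __post_init__(self) -> None:
        seen: set[int] = set()
        norm = frozenset(tuple(sorted(b)) for b in self.bonds)
        object.__setattr__(self, "bonds", norm)
        for a, b in norm:
            if not (1 <= a <= self.n_cys and 1 <= b <= self.n_cys) or a == b:
                raise ValueError(f"invalid bond ({a},{b}) for n_cys={self.n_cys}")
            if a in seen or b in seen:
                raise ValueError("bonds must be disjoint (each cysteine in at most one)")
            seen |= {a, b}
        if self.reduction_order is not None:
            order = tuple(tuple(sorted(b)) for b in self.reduction_order)
            object.__setattr__(self, "reduction_order", order)
            if sorted(order) != sorted(norm):
                raise ValueError("reduction_order must list each bond exactly once")

    @property
    def is_perfect(self) -> bool:
        return 2 * len(self.bonds) == self.n_cys

    @property
    def n_bonds(self) -> int:
        return len(self.bonds)

    def partner(self, ordinal: int) -> int | None:
        for a, b in self.bonds:
            if ordinal == a:
                return b
            if ordinal == b:
                return a
        return None

    def __str__(self) -> str:
        return format_bonds(self.bonds)


@dataclass(frozen=True)
class LabelObservation:
    """One partial-reduction intermediate's tag pattern.

    ``first_tag`` holds the cysteine ordinals that were free in the
    intermediate (carrying the first tag, e.g. NEM); ``second_tag`` the
    ordinals freed only on full reduction (second tag, e.g. IAM).
    ``n_intact`` is the intact bond count k, so |first_tag| = n_cys - 2k.
    Either tag set may be given; the other is the complement.
    """

    n_cys: int
    n_intact: int
    first_tag: frozenset[int] = frozenset()
    second_tag: frozenset[int] = frozenset()
    intermediate_id: str = ""

    def __post_init__(self) -> None:
        all_ord = frozenset(range(1, self.n_cys + 1))
        first, second = frozenset(self.first_tag), frozenset(self.second_tag)
        if first and second:
            if first & second or first | second != all_ord:
                raise ValueError("first and second tag sets must partition the cysteines")
        elif first:
            second = all_ord - first
        elif second:
            first = all_ord - second
        elif self.n_intact * 2 == self.n_cys:
            pass  # native species: empty first tag is the observation
        else:
            raise ValueError("at least one tag set required")
        object.__setattr__(self, "first_tag", first)
        object.__setattr__(self, "second_tag", second if second else all_ord - first)
        if len(self.first_tag) % 2:
            raise ValueError(
                f"first-tag set size {len(self.first_tag)} is odd; freed cysteines come in pairs"
            )
        if len(self.first_tag) != self.n_cys - 2 * self.n_intact:
            raise ValueError(
                f"|first_tag|={len(self.first_tag)} inconsistent with "
                f"n_intact={self.n_intact} for n_cys={self.n_cys}"
            )


def enumerate_matchings(n_cys: int) -> list[frozenset[Bond]]:
    """All perfect matchings of {1..n_cys}: (n_cys-1)!! of them.

    Pairs are sorted within and matchings listed lexicographically.
    """
    if n_cys % 2 or not 2 <= n_cys <= 16:
        raise ValueError(f"n_cys must be even and in 2..16, got {n_cys}")

    def rec(free: tuple[int, ...]):
        if not free:
            yield ()
            return
        a = free[0]
        rest = free[1:]
        for i, b in enumerate(rest):
            for tail in rec(rest[:i] + rest[i + 1 :]):
                yield ((a, b),) + tail

    return [frozenset(m) for m in rec(tuple(range(1, n_cys + 1)))]


def _is_union_of_pairs(cys_set: frozenset[int], matching: frozenset[Bond]) -> bool:
    remaining = set(cys_set)
    for a, b in matching:
        if a in remaining and b in remaining:
            remaining -= {a, b}
        elif a in remaining or b in remaining:
            return False
    return not remaining


def _nested_chain(observations: list[LabelObservation]) -> bool:
    sets = sorted((o.first_tag for o in observations), key=len)
    return all(s <= t for s, t in zip(sets, sets[1:]))


def consistent_matchings(
    n_cys: int,
    observations: list[LabelObservation],
    nested: bool = True,
) -> list[DisulfideTopology]:
    """Matchings consistent with every intermediate's tag pattern.

    A matching is consistent with an observation when the first-tag set
    is a union of complete bonds (equivalently, no bond straddles the
    two tag sets).  With ``nested`` (the default, reflecting sequential
    unfolding under progressive reduction), the observations' first-tag
    sets must additionally form a chain under inclusion; observation
    sets violating that yield no consistent matching.  Contradictory
    observations return an empty list, not an error.
    """
    for obs in observations:
        if obs.n_cys != n_cys:
            raise ValueError("observation n_cys mismatch")
    if nested and not _nested_chain(observations):
        return []
    out = []
    for m in enumerate_matchings(n_cys):
        if all(_is_union_of_pairs(obs.first_tag, m) for obs in observations):
            out.append(DisulfideTopology(n_cys, m))
    return out


class InconsistentObservationsError(ValueError):
    pass


@dataclass(frozen=True)
class Deduction:
    """Outcome of connectivity deduction.

    ``unique`` is True when a single topology survives; otherwise
    ``candidates`` enumerates the surviving matchings (an ambiguity
    report, not an error).  For unique results ``order_groups`` gives
    the reduction order as a partial order: bonds grouped by the
    largest intact-bond count k at which they were already observed
    reduced, earliest-reduced group first, with bonds never observed
    reduced last.
    """

    n_cys: int
    candidates: tuple[DisulfideTopology, ...]
    order_groups: tuple[tuple[Bond, ...], ...] = ()

    @property
    def unique(self) -> bool:
        return len(self.candidates) == 1

    @property
    def topology(self) -> DisulfideTopology:
        if not self.unique:
            raise ValueError("deduction is ambiguous; inspect .candidates")
        return self.candidates[0]


def _reduction_order(
    topology: DisulfideTopology, observations: list[LabelObservation]
) -> tuple[DisulfideTopology, tuple[tuple[Bond, ...], ...]]:
    # A bond reduced earlier in the unfolding pathway appears in the
    # first-tag set of intermediates with larger intact counts k.
    first_seen: dict[Bond, int] = {}
    for bond in topology.bonds:
        a, b = bond
        ks = [o.n_intact for o in observations if a in o.first_tag and b in o.first_tag]
        first_seen[bond] = max(ks) if ks else -1
    groups: dict[int, list[Bond]] = {}
    for bond, k in first_seen.items():
        groups.setdefault(k, []).append(bond)
    ordered_keys = sorted((k for k in groups if k >= 0), reverse=True) + (
        [-1] if -1 in groups else []
    )
    order_groups = tuple(tuple(sorted(groups[k])) for k in ordered_keys)
    flat = tuple(b for g in order_groups for b in g)
    return (
        DisulfideTopology(topology.n_cys, topology.bonds, reduction_order=flat),
        order_groups,
    )


def deduce_connectivity(
    n_cys: int,
    observations: list[LabelObservation],
    nested: bool = True,
) -> Deduction:
    """Deduce the disulfide topology (and reduction order) from intermediates.

    Raises :class:`InconsistentObservationsError` when no matching
    survives.  Multiple survivors produce an ambiguity report (``unique``
    False) rather than an exception — downstream callers decide how to
    proceed (the CLI exits with a distinct status).
    """
    survivors = consistent_matchings(n_cys, observations, nested=nested)
    if not survivors:
        raise InconsistentObservationsError("observations inconsistent")
    if len(survivors) > 1:
        return Deduction(n_cys, tuple(survivors))
    topo, groups = _reduction_order(survivors[0], observations)
    return Deduction(n_cys, (topo,), groups)


def simulate_partial_reduction(
    topology: DisulfideTopology,
    k_values: list[int],
    drop: int | None = None,
) -> list[LabelObservation]:
    """Ideal intermediates of a sequential unfolding pathway.

    For each requested intact count k, the first (n_bonds - k) bonds of
    the topology's reduction order are open, so their cysteines carry
    the first tag.  ``drop``, if given, removes the observation at that
    list index (a missing HPLC peak).  Deterministic.
    """
    if topology.reduction_order is None:
        raise ValueError("topology must carry a reduction_order")
    if not topology.is_perfect:
        raise ValueError("simulation requires a perfect matching")
    n_bonds = topology.n_bonds
    obs = []
    for k in k_values:
        if not 0 <= k <= n_bonds:
            raise ValueError(f"k={k} out of range 0..{n_bonds}")
        open_bonds = topology.reduction_order[: n_bonds - k]
        first = frozenset(c for bond in open_bonds for c in bond)
        obs.append(
            LabelObservation(topology.n_cys, k, first_tag=first, intermediate_id=f"{k}SS")
        )
    if drop is not None and 0 <= drop < len(obs):
        obs.pop(drop)
    return obs


class LabelLocalizationError(ValueError):
    pass


@dataclass(frozen=True)
class FragmentConstraint:
    """Cysteine ordinals of one fragment and how many carry the first tag."""

    fragment: tuple[int, int]  # (start, end) on the parent
    cys_ordinals: frozenset[int]
    n_first: int


@dataclass(frozen=True)
class LabelLocalization:
    """Per-cysteine tag assignment inferred from fragment masses."""

    n_cys: int
    n_intact: int
    first_tag: frozenset[int]
    second_tag: frozenset[int]
    unresolved: frozenset[int]
    constraints: tuple[FragmentConstraint, ...]

    @property
    def resolved(self) -> bool:
        return not self.unresolved

    def observation(self, intermediate_id: str = "") -> LabelObservation:
        if not self.resolved:
            raise ValueError("localization has unresolved cysteines")
        return LabelObservation(
            self.n_cys, self.n_intact, first_tag=self.first_tag,
            intermediate_id=intermediate_id,
        )


def localize_labels(
    sequence: str,
    fragment_masses: list[tuple[DigestFragment, float]],
    labels: tuple[ThiolLabel, ThiolLabel] = (NEM, IAM),
    tol: float = 0.05,
) -> LabelLocalization:
    """Infer per-cysteine tag assignment from observed fragment [M+H]+ values.

    Each fragment with c cysteines has observed mass
    ``base + a*delta_first + (c-a)*delta_second`` for some a in 0..c,
    where base is the fully reduced unlabeled [M+H]+.  The best-fitting
    a per fragment becomes a counting constraint; constraints are
    propagated (homogeneous fragments assign all their cysteines,
    resolved cysteines are subtracted from overlapping constraints)
    until fixed point.  Cysteines still undetermined are reported in
    ``unresolved`` together with the surviving constraint set.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    first_label, second_label = labels
    parent_cys = [i + 1 for i, aa in enumerate(sequence) if aa == "C"]
    pos_to_ordinal = {p: o for o, p in enumerate(parent_cys, start=1)}
    covered: set[int] = set()
    constraints: list[FragmentConstraint] = []
    for frag, observed in fragment_masses:
        ords = frozenset(
            pos_to_ordinal[p]
            for p in range(frag.start, frag.end + 1)
            if p in pos_to_ordinal
        )
        c = len(ords)
        if c == 0:
            continue  # no cysteines, no constraint
        base = mz_from_mass(peptide_mass(PeptideSpecies(frag.sequence)), 1)
        fits = []
        for a in range(c + 1):
            theo = base + a * first_label.delta + (c - a) * second_label.delta
            err = abs(observed - theo)
            if err <= tol:
                fits.append((err, a))
        if not fits:
            raise LabelLocalizationError(
                f"fragment {frag.start}-{frag.end} ({frag.sequence}): observed "
                f"{observed:.4f} fits no labeling within {tol} Da"
            )
        fits.sort()
        constraints.append(FragmentConstraint((frag.start, frag.end), ords, fits[0][1]))
        covered |= ords
    if covered != set(range(1, len(parent_cys) + 1)):
        missing = sorted(set(range(1, len(parent_cys) + 1)) - covered)
        raise LabelLocalizationError(
            f"fragments do not cover cysteines {missing}; cannot localize"
        )

    first: set[int] = set()
    second: set[int] = set()
    active = list(constraints)
    changed = True
    while changed:
        changed = False
        next_active = []
        for con in active:
            ords = set(con.cys_ordinals)
            n_first = con.n_first - len(ords & first)
            ords -= first | second
            if n_first < 0 or n_first > len(ords):
                raise LabelLocalizationError(
                    f"fragment {con.fragment} constraint contradicts other fragments"
                )
            if not ords:
                continue
            if n_first == 0:
                second |= ords
                changed = True
            elif n_first == len(ords):
                first |= ords
                changed = True
            else:
                next_active.append(FragmentConstraint(con.fragment, frozenset(ords), n_first))
        active = next_active

    unresolved = frozenset(range(1, len(parent_cys) + 1)) - first - second
    n_first_total = len(first) + sum(c.n_first for c in active)
    n_intact = (len(parent_cys) - n_first_total) // 2
    return LabelLocalization(
        n_cys=len(parent_cys),
        n_intact=n_intact,
        first_tag=frozenset(first),
        second_tag=frozenset(second),
        unresolved=unresolved,
        constraints=tuple(active),
    )
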