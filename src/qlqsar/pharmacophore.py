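"""Pharmacophore extraction and structure mapping.

The pharmacophore is the set of highest-sensitivity fragment-pair descriptors
of the final QSAR model (four members by default).  Mapping a pharmacophore
onto a structure counts the entries of every member descriptor; a *complete*
pharmacophore means every member occurs at least once.

``REFERENCE_PHARMACOPHORE`` ships the calibrated four-descriptor model for
high NHE-1 inhibitory activity: {-N< ... -CH=}, {-N< ... >C(<)},
{-N< ... -C(Ar)<} and {-C(Ar)< ... CycAr06} (the last with a proximal
distance bin).  Its Sens annotations are fixture metadata from the original
sensitivity analysis, not values this package recomputes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

from .compound_set import CompoundSet
from .ql_descriptors import (
    DescriptorConfig,
    MolecularGraph,
    QLDescriptor,
    count_entries,
    default_config,
    perceive_graph,
)
from .nn_qsar import IterativeResult

__all__ = [
    "Pharmacophore", "PharmacophoreMapping", "ValidationSummary",
    "extract", "map_to_structure", "map_compound_set", "validate_external",
    "REFERENCE_PHARMACOPHORE",
]


@dataclass(frozen=True)
class Pharmacophore:
    """Ranked list of (descriptor, Sens) members, Sens descending."""

    members: tuple[tuple[QLDescriptor, float], ...]

    def __post_init__(self) -> None:
        if len(self.members) < 1:
            raise ValueError("a pharmacophore needs at least one member")
        ordered = tuple(sorted(self.members, key=lambda m: (-m[1], m[0].code)))
        object.__setattr__(self, "members", ordered)

    @property
    def size(self) -> int:
        return len(self.members)

    @property
    def descriptors(self) -> list[QLDescriptor]:
        return [d for d, _ in self.members]

    @property
    def codes(self) -> list[str]:
        return [d.code for d, _ in self.members]


#: Calibrated four-member pharmacophore of high NHE-1 inhibitory activity.
#: Sens values are reference metadata from the original model.
REFERENCE_PHARMACOPHORE = Pharmacophore(members=(
    (QLDescriptor(("-N<", "-C(Ar)<")), 90.8),
    (QLDescriptor(("-N<", ">C(<)")), 49.6),
    (QLDescriptor(("-C(Ar)<", "CycAr06"), (0, 4)), 46.3),
    (QLDescriptor(("-N<", "-CH=")), 26.9),
))


@dataclass
class PharmacophoreMapping:
    """Occurrence entries of each pharmacophore member in one structure."""

    compound_id: str
    entries: dict[str, int]            # member code -> entry count
    total_entries: int
    n_types_present: int
    complete: bool

    @classmethod
    def from_entries(cls, compound_id: str, entries: dict[str, int]) -> "PharmacophoreMapping":
        present = sum(1 for v in entries.values() if v > 0)
        return cls(
            compound_id=compound_id,
            entries=dict(entries),
            total_entries=sum(entries.values()),
            n_types_present=present,
            complete=(present == len(entries)),
        )


@dataclass
class ValidationSummary:
    mappings: list[PharmacophoreMapping]
    all_complete: bool


def extract(result: IterativeResult, top_n: int = 4) -> Pharmacophore:
    """Top-``top_n`` descriptors of the final sensitivity report.

    Ties at the rank boundary break by canonical descriptor code (the
    ranking in the report is already ordered that way).
    """
    report = result.final_sensitivity
    if top_n < 1:
        raise ValueError("top_n must be >= 1")
    if top_n > len(report.ranking):
        raise ValueError(
            f"top_n={top_n} exceeds the {len(report.ranking)} surviving descriptors"
        )
    by_code = {d.code: d for d in result.final_matrix.descriptors}
    members = tuple(
        (by_code[code], float(report.sens[code])) for code in report.top(top_n)
    )
    return Pharmacophore(members=members)


def map_to_structure(
    graph: MolecularGraph,
    ph: Pharmacophore,
    config: Optional[DescriptorConfig] = None,
    compound_id: str = "",
) -> PharmacophoreMapping:
    """Entry counts of every pharmacophore member in one structure."""
    config = config or default_config()
    entries = {d.code: count_entries(graph, d, config) for d in ph.descriptors}
    return PharmacophoreMapping.from_entries(compound_id or graph.smiles, entries)


def map_compound_set(
    cs: CompoundSet,
    ph: Pharmacophore,
    config: Optional[DescriptorConfig] = None,
    ids: Optional[Sequence[str]] = None,
) -> list[PharmacophoreMapping]:
    wanted = list(ids) if ids is not None else [c.id for c in cs.compounds]
    out = []
    for cid in wanted:
        comp = cs.compound(cid)
        out.append(map_to_structure(perceive_graph(comp.smiles), ph, config, cid))
    return out


def validate_external(
    ph: Pharmacophore,
    cs: CompoundSet,
    config: Optional[DescriptorConfig] = None,
) -> ValidationSummary:
    """Map the pharmacophore onto every external-validation (hold-out) compound."""
    holdout = cs.external_compounds
    if not holdout:
        raise ValueError("compound set has no external-validation compounds")
    mappings = map_compound_set(cs, ph, config, ids=[c.id for c in holdout])
    return ValidationSummary(
        mappings=mappings,
        all_complete=all(m.complete for m in mappings),
    )
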