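"""Q-label typing and rank-2 (fragment-pair) descriptor generation.

A *Q-label* is an atom-centered or ring fragment code (e.g. ``-N<`` for a
trisubstituted nitrogen, ``CycAr06`` for a six-membered aromatic ring).  A
rank-2 *QL-descriptor* is an unordered pair of Q-labels; its *entry count* in
a molecule is the number of occurrence pairs (one occurrence of each member,
optionally restricted to a shortest-path distance window).  Modeling features
are binary presence indicators of descriptors across a compound series.

The default grammar ships with the package (``data/grammar.yaml``); it was
calibrated so that a single configuration reproduces the reference entry
totals of the pharmacophore mapping (see ``docs/methods.md``).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml
from rdkit import Chem
from rdkit.Chem import rdmolops

from .compound_set import CompoundSet

PAIR_PRODUCT = "pair_product"
MIN_OF_COUNTS = "min_of_counts"
SUM_OF_COUNTS = "sum_of_counts"
_COUNTING_MODES = (PAIR_PRODUCT, MIN_OF_COUNTS, SUM_OF_COUNTS)


class StructureError(ValueError):
    """SMILES does not parse or fails valence rules."""


class GrammarError(ValueError):
    """Malformed typing grammar."""


# --------------------------------------------------------------------------
# Molecular graph
# --------------------------------------------------------------------------

_BOND_ORDER = {
    Chem.BondType.SINGLE: "single",
    Chem.BondType.DOUBLE: "double",
    Chem.BondType.TRIPLE: "triple",
    Chem.BondType.AROMATIC: "aromatic",
}


class MolecularGraph:
    """A perceived molecule: aromaticity assigned, implicit hydrogens counted.

    Thin wrapper around an RDKit molecule that exposes the atom/bond tuples
    used by the typing grammar and caches the topological distance matrix.
    """

    def __init__(self, mol: Chem.Mol, smiles: str = ""):
        self.mol = mol
        self.smiles = smiles or Chem.MolToSmiles(mol)
        self._dist: Optional[np.ndarray] = None

    @property
    def atoms(self) -> list[tuple[str, int, bool, int]]:
        """(element, formal charge, aromatic flag, total H count) per atom."""
        return [
            (a.GetSymbol(), a.GetFormalCharge(), a.GetIsAromatic(), a.GetTotalNumHs())
            for a in self.mol.GetAtoms()
        ]

    @property
    def bonds(self) -> list[tuple[tuple[int, int], str]]:
        return [
            ((b.GetBeginAtomIdx(), b.GetEndAtomIdx()),
             "aromatic" if b.GetIsAromatic() else _BOND_ORDER[b.GetBondType()])
            for b in self.mol.GetBonds()
        ]

    @property
    def n_atoms(self) -> int:
        return self.mol.GetNumAtoms()

    def distance_matrix(self) -> np.ndarray:
        if self._dist is None:
            self._dist = rdmolops.GetDistanceMatrix(self.mol)
        return self._dist

    def aromatic_rings(self, size: Optional[int] = None) -> list[frozenset[int]]:
        out = []
        for ring in self.mol.GetRingInfo().AtomRings():
            if size is not None and len(ring) != size:
                continue
            if all(self.mol.GetAtomWithIdx(i).GetIsAromatic() for i in ring):
                out.append(frozenset(ring))
        return out


def perceive_graph(smiles: str) -> MolecularGraph:
    """Parse SMILES into a :class:`MolecularGraph` (default aromaticity model)."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise StructureError(f"SMILES {smiles!r} does not parse")
    return MolecularGraph(mol, smiles)


# --------------------------------------------------------------------------
# Grammar
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class QLabel:
    """One fragment code of the typing grammar."""

    code: str
    kind: str  # "atom_centered" | "ring"
    element: Optional[str] = None
    h: Optional[int] = None
    degree: Optional[int] = None
    min_degree: Optional[int] = None
    aromatic: Optional[bool] = None
    single_only: bool = False
    has_double_bond: bool = False
    double_or_aromatic_to: Optional[str] = None
    forbid_double_to: Optional[str] = None
    ring_size: Optional[int] = None

    def matches_atom(self, mol: Chem.Mol, atom: Chem.Atom) -> bool:
        if self.kind != "atom_centered":
            return False
        if atom.GetSymbol() != self.element:
            return False
        if self.h is not None and atom.GetTotalNumHs() != self.h:
            return False
        if self.degree is not None and atom.GetDegree() != self.degree:
            return False
        if self.min_degree is not None and atom.GetDegree() < self.min_degree:
            return False
        if self.aromatic is not None and atom.GetIsAromatic() != self.aromatic:
            return False
        bonds = atom.GetBonds()
        if self.single_only and any(
            b.GetIsAromatic() or b.GetBondType() != Chem.BondType.SINGLE for b in bonds
        ):
            return False
        if self.has_double_bond and not any(
            b.GetBondType() == Chem.BondType.DOUBLE for b in bonds
        ):
            return False
        if self.double_or_aromatic_to is not None:
            if not any(
                (b.GetBondType() == Chem.BondType.DOUBLE or b.GetIsAromatic())
                and b.GetOtherAtom(atom).GetSymbol() == self.double_or_aromatic_to
                for b in bonds
            ):
                return False
        if self.forbid_double_to is not None:
            if any(
                b.GetBondType() == Chem.BondType.DOUBLE
                and b.GetOtherAtom(atom).GetSymbol() == self.forbid_double_to
                for b in bonds
            ):
                return False
        return True


@dataclass(frozen=True)
class Occurrence:
    """One matched instance of a Q-label: the label code and its atom set."""

    code: str
    atoms: frozenset[int]


@dataclass
class Grammar:
    labels: dict[str, QLabel]
    counting_mode: str = PAIR_PRODUCT

    def __post_init__(self) -> None:
        if self.counting_mode not in _COUNTING_MODES:
            raise GrammarError(f"unknown counting mode {self.counting_mode!r}")

    def label(self, code: str) -> QLabel:
        try:
            return self.labels[code]
        except KeyError:
            raise GrammarError(f"unknown label code {code!r}") from None


def _label_from_config(code: str, cfg: dict) -> QLabel:
    cfg = dict(cfg)
    kind = cfg.pop("kind", None)
    if kind == "atom":
        allowed = {"element", "h", "degree", "min_degree", "aromatic", "single_only",
                   "has_double_bond", "double_or_aromatic_to", "forbid_double_to"}
        unknown = set(cfg) - allowed
        if unknown:
            raise GrammarError(f"label {code!r}: unknown predicate fields {sorted(unknown)}")
        if "element" not in cfg:
            raise GrammarError(f"label {code!r}: atom label requires an element")
        return QLabel(code=code, kind="atom_centered", **cfg)
    if kind == "ring":
        if not cfg.get("aromatic", True):
            raise GrammarError(f"label {code!r}: only aromatic ring labels are supported")
        if "size" not in cfg:
            raise GrammarError(f"label {code!r}: ring label requires a size")
        return QLabel(code=code, kind="ring", ring_size=int(cfg["size"]))
    raise GrammarError(f"label {code!r}: unknown kind {kind!r}")


def load_grammar(path: str | Path | None = None) -> Grammar:
    """Load a typing grammar from YAML; default is the packaged grammar."""
    if path is None:
        text = resources.files("qlqsar").joinpath("data/grammar.yaml").read_text()
    else:
        text = Path(path).read_text()
    doc = yaml.safe_load(text)
    if not isinstance(doc, dict) or "labels" not in doc:
        raise GrammarError("grammar file must define a 'labels' mapping")
    labels = {code: _label_from_config(code, cfg) for code, cfg in doc["labels"].items()}
    return Grammar(labels=labels, counting_mode=doc.get("counting_mode", PAIR_PRODUCT))


# --------------------------------------------------------------------------
# Descriptors
# --------------------------------------------------------------------------

@dataclass(frozen=True, order=True)
class QLDescriptor:
    """Unordered pair of Q-label codes, optionally distance-binned.

    ``distance_bin`` is an inclusive shortest-path window (lo, hi) in bonds
    between the two fragment occurrences (nearest atoms for ring fragments).
    """

    pair: tuple[str, str]
    distance_bin: Optional[tuple[int, int]] = None

    def __post_init__(self) -> None:
        if tuple(sorted(self.pair)) != tuple(self.pair):
            object.__setattr__(self, "pair", tuple(sorted(self.pair)))

    @property
    def code(self) -> str:
        base = "{%s...%s}" % self.pair
        if self.distance_bin is not None:
            lo, hi = self.distance_bin
            return f"{base}|d{lo}-{hi}"
        return base

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.code


@dataclass
class DescriptorConfig:
    """Grammar + counting conventions used across the pipeline."""

    grammar: Grammar = field(default_factory=load_grammar)
    counting_mode: Optional[str] = None  # None -> grammar default
    distance_bins: Optional[list[tuple[int, int]]] = None  # None -> binning off

    @property
    def mode(self) -> str:
        return self.counting_mode or self.grammar.counting_mode


def default_config() -> DescriptorConfig:
    return DescriptorConfig()


def type_atoms(graph: MolecularGraph, grammar: Grammar) -> list[Occurrence]:
    """List every occurrence of every grammar label in the molecule.

    One atom may carry several labels; ring labels produce one occurrence per
    matching ring.  Occurrences are ordered by label code, then atom indices.
    """
    occ: list[Occurrence] = []
    mol = graph.mol
    for code in sorted(grammar.labels):
        lab = grammar.labels[code]
        if lab.kind == "atom_centered":
            for atom in mol.GetAtoms():
                if lab.matches_atom(mol, atom):
                    occ.append(Occurrence(code, frozenset([atom.GetIdx()])))
        elif lab.kind == "ring":
            for ring in graph.aromatic_rings(size=lab.ring_size):
                occ.append(Occurrence(code, ring))
        else:  # pragma: no cover - guarded at load
            raise GrammarError(f"label {code!r}: unknown kind")
    return occ


def _occurrence_distance(dist: np.ndarray, a: frozenset[int], b: frozenset[int]) -> int:
    return int(min(dist[i][j] for i in a for j in b))


def _pair_entries(
    occ_a: Sequence[Occurrence],
    occ_b: Sequence[Occurrence],
    same_label: bool,
    mode: str,
    dist: Optional[np.ndarray],
    window: Optional[tuple[int, int]],
) -> int:
    """Entry count for one descriptor, given the member occurrence lists."""
    if not occ_a or not occ_b:
        return 0
    if same_label and len(occ_a) < 2:
        return 0
    if mode == MIN_OF_COUNTS and window is None:
        return min(len(occ_a), len(occ_b)) if not same_label else len(occ_a) // 2
    if mode == SUM_OF_COUNTS and window is None:
        return len(occ_a) + len(occ_b) if not same_label else len(occ_a)
    # pair_product (and any windowed count): explicit double loop over pairs
    pairs = (
        itertools.combinations(occ_a, 2) if same_label else itertools.product(occ_a, occ_b)
    )
    n = 0
    for x, y in pairs:
        if window is not None:
            d = _occurrence_distance(dist, x.atoms, y.atoms)
            if not window[0] <= d <= window[1]:
                continue
        n += 1
    return n


def enumerate_descriptors(
    occurrences: Sequence[Occurrence],
    config: DescriptorConfig,
    graph: Optional[MolecularGraph] = None,
) -> dict[QLDescriptor, int]:
    """All rank-2 descriptors present in a molecule, with entry counts.

    Emits every unordered label pair whose members both occur (self-pairs
    require two occurrences of the label).  With ``config.distance_bins`` set,
    each pair is split into one descriptor per bin; ``graph`` is then required.
    """
    by_code: dict[str, list[Occurrence]] = {}
    for o in occurrences:
        by_code.setdefault(o.code, []).append(o)
    bins = config.distance_bins
    if bins is not None and graph is None:
        raise ValueError("distance binning requires the molecular graph")
    dist = graph.distance_matrix() if (graph is not None and bins is not None) else None

    out: dict[QLDescriptor, int] = {}
    codes = sorted(by_code)
    for i, ca in enumerate(codes):
        for cb in codes[i:]:
            same = ca == cb
            for window in (bins if bins is not None else [None]):
                n = _pair_entries(by_code[ca], by_code[cb], same, config.mode, dist, window)
                if n > 0:
                    out[QLDescriptor((ca, cb), window)] = n
    return out


def count_entries(
    graph: MolecularGraph, descriptor: QLDescriptor, config: DescriptorConfig
) -> int:
    """Entry count of one descriptor in one structure (0 if a member is absent)."""
    occ = type_atoms(graph, config.grammar)
    a, b = descriptor.pair
    occ_a = [o for o in occ if o.code == a]
    occ_b = [o for o in occ if o.code == b]
    window = descriptor.distance_bin
    dist = graph.distance_matrix() if window is not None else None
    return _pair_entries(occ_a, occ_b, a == b, config.mode, dist, window)


# --------------------------------------------------------------------------
# Descriptor matrix
# --------------------------------------------------------------------------

@dataclass
class DescriptorMatrix:
    """Binary presence matrix (compounds x descriptors) joined to activities.

    ``synonyms`` maps each retained column to the full group of descriptor
    codes sharing its presence pattern (including itself) when duplicate
    columns were collapsed at build time.
    """

    X: pd.DataFrame          # 0/1 ints, index = compound ids, columns = codes
    y: pd.Series             # activity percentages aligned with X.index
    descriptors: list[QLDescriptor]
    synonyms: dict[str, list[str]] = field(default_factory=dict)

    @property
    def compound_ids(self) -> list[str]:
        return list(self.X.index)

    @property
    def n_descriptors(self) -> int:
        return self.X.shape[1]

    def subset(self, codes: Sequence[str]) -> "DescriptorMatrix":
        codes = list(codes)
        keep = [d for d in self.descriptors if d.code in set(codes)]
        syn = {c: self.synonyms[c] for c in codes if c in self.synonyms}
        return DescriptorMatrix(self.X[codes].copy(), self.y.copy(), keep, syn)

    def to_csv(self, path: str | Path) -> None:
        df = self.X.copy()
        df["activity"] = self.y
        df.to_csv(path, index_label="compound_id")


def build_matrix(
    cs: CompoundSet,
    config: Optional[DescriptorConfig] = None,
    collapse_duplicates: bool = True,
) -> DescriptorMatrix:
    """Presence matrix over the union of descriptors of the train compounds.

    Columns constant across all train compounds (always absent or always
    present) carry no information for regression and are removed.  With
    ``collapse_duplicates`` (default), descriptors sharing an identical
    presence pattern across the series are collapsed to one input column (the
    lexicographically first code), with the full synonym group recorded; on a
    small series many fragment pairs are perfectly redundant, and duplicate
    inputs dilute ablation sensitivities.
    """
    config = config or default_config()
    train = cs.train_compounds
    if not train:
        raise ValueError("compound set has no training compounds")
    rows: dict[str, set[str]] = {}
    universe: dict[str, QLDescriptor] = {}
    for comp in train:
        graph = perceive_graph(comp.smiles)
        descs = enumerate_descriptors(type_atoms(graph, config.grammar), config, graph)
        rows[comp.id] = {d.code for d in descs}
        for d in descs:
            universe.setdefault(d.code, d)

    codes = sorted(universe)
    ids = [c.id for c in train]
    data = np.zeros((len(ids), len(codes)), dtype=int)
    for i, cid in enumerate(ids):
        for j, code in enumerate(codes):
            data[i, j] = 1 if code in rows[cid] else 0
    X = pd.DataFrame(data, index=ids, columns=codes)
    # drop constant columns
    keep = [c for c in X.columns if X[c].nunique() > 1]
    X = X[keep]
    synonyms: dict[str, list[str]] = {}
    if collapse_duplicates:
        groups: dict[tuple, list[str]] = {}
        for c in X.columns:  # columns are sorted, so group order is canonical
            groups.setdefault(tuple(X[c]), []).append(c)
        reps = [g[0] for g in groups.values()]
        synonyms = {g[0]: list(g) for g in groups.values()}
        X = X[sorted(reps)]
    y = pd.Series(
        {c.id: cs.activity(c.id).inhibition_pct for c in train}, name="activity"
    ).loc[ids]
    descriptors = [universe[c] for c in X.columns]
    return DescriptorMatrix(X, y, descriptors, synonyms)
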