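"""Compound/activity fixtures and tabular I/O.

The built-in dataset is the quinazoline NHE-1 inhibitor series (eleven novel
quinazoline-2,4(1H,3H)-dione / quinazolin-4(3H)-one derivatives carrying an
N-acylguanidine or 5-amino-1,2,4-triazol-3-yl side chain) together with the
reference acylguanidine inhibitors amiloride, rimeporide and zoniporide.
Activities are percent inhibition of NHE-1-dependent platelet shape change at
10 nM compound (mean +/- SD of six replicates); IC50 values in nM, where
determined, are carried as metadata.  Zoniporide is the external-validation
structure and never enters a training partition.

SMILES were transcribed once from the compounds' IUPAC names and are frozen
here; structures are never derived from names at runtime.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from rdkit import Chem
from rdkit import RDLogger

RDLogger.DisableLog("rdApp.*")

ROLE_TRAIN = "train"
ROLE_EXTERNAL = "external_validation"
ROLE_REFERENCE = "reference_only"
_ROLES = {ROLE_TRAIN, ROLE_EXTERNAL, ROLE_REFERENCE}

REPORT_SCHEMA_VERSION = "1.0"


class CompoundError(ValueError):
    """Raised for malformed compound definitions or tables."""


@dataclass(frozen=True)
class Compound:
    """A single structure: short label, SMILES and (optional) IUPAC name."""

    id: str
    smiles: str
    name: str = ""
    role: str = ROLE_TRAIN

    def __post_init__(self) -> None:
        if self.role not in _ROLES:
            raise CompoundError(f"unknown role {self.role!r} for compound {self.id!r}")
        mol = Chem.MolFromSmiles(self.smiles)
        if mol is None:
            raise CompoundError(f"compound {self.id!r}: SMILES {self.smiles!r} does not parse")
        if len(Chem.GetMolFrags(mol)) != 1:
            raise CompoundError(f"compound {self.id!r}: structure is not connected")


@dataclass(frozen=True)
class ActivityRecord:
    """NHE-1 inhibition at 10 nM (percent of control response) for one compound."""

    compound_id: str
    inhibition_pct: float
    inhibition_sd: Optional[float] = None
    n: int = 1
    ic50_nM: Optional[float] = None

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise CompoundError(f"activity for {self.compound_id!r}: n must be positive")
        if not -100.0 <= self.inhibition_pct <= 100.0:
            raise CompoundError(
                f"activity for {self.compound_id!r}: {self.inhibition_pct}% outside [-100, 100]"
            )
        if self.ic50_nM is not None and self.ic50_nM <= 0:
            raise CompoundError(f"activity for {self.compound_id!r}: IC50 must be positive")


@dataclass
class CompoundSet:
    """A joined collection of compounds and their activity records."""

    compounds: list[Compound] = field(default_factory=list)
    activities: list[ActivityRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [c.id for c in self.compounds]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise CompoundError(f"duplicate compound ids: {dupes}")
        known = set(ids)
        for rec in self.activities:
            if rec.compound_id not in known:
                raise CompoundError(f"activity for unknown compound {rec.compound_id!r}")

    def __len__(self) -> int:
        return len(self.compounds)

    def compound(self, compound_id: str) -> Compound:
        for c in self.compounds:
            if c.id == compound_id:
                return c
        raise KeyError(compound_id)

    def activity(self, compound_id: str) -> ActivityRecord:
        for rec in self.activities:
            if rec.compound_id == compound_id:
                return rec
        raise KeyError(compound_id)

    def with_role(self, role: str) -> list[Compound]:
        return [c for c in self.compounds if c.role == role]

    @property
    def train_compounds(self) -> list[Compound]:
        return self.with_role(ROLE_TRAIN)

    @property
    def external_compounds(self) -> list[Compound]:
        return self.with_role(ROLE_EXTERNAL)


# --------------------------------------------------------------------------
# Built-in dataset.
#
# (id, SMILES, IUPAC/common name, role, inhibition %, SD, n, IC50 nM or None)
# --------------------------------------------------------------------------
_BUILTIN = (
    # N-acylguanidine quinazoline-2,4(1H,3H)-diones
    ("3a", "CN1c2ccccc2C(=O)N(CC(=O)NC(N)=N)C1=O",
     "N-Carbamimidoyl-2-(1-methyl-2,4-dioxo-1,4-dihydroquinazolin-3(2H)-yl)acetamide",
     ROLE_TRAIN, 33.70, 10.23, 6, 292.7),
    ("3b", "CN1c2ccccc2C(=O)N(C(C)C(=O)NC(N)=N)C1=O",
     "N-Carbamimidoyl-2-(1-methyl-2,4-dioxo-1,4-dihydroquinazolin-3(2H)-yl)propanamide",
     ROLE_TRAIN, 1.49, 4.79, 6, None),
    ("3c", "O=C(NC(N)=N)CN1C(=O)N(Cc2ccccc2)c2ccccc2C1=O",
     "2-(1-Benzyl-2,4-dioxo-1,4-dihydroquinazolin-3(2H)-yl)-N-carbamimidoylacetamide",
     ROLE_TRAIN, 7.30, 5.00, 6, None),
    ("3d", "CN1c2ccc(Br)cc2C(=O)N(CC(=O)NC(N)=N)C1=O",
     "2-(6-Bromo-1-methyl-2,4-dioxo-1,4-dihydroquinazolin-3(2H)-yl)-N-carbamimidoylacetamide",
     ROLE_TRAIN, 33.21, 9.83, 6, 961.4),
    # 5-amino-1,2,4-triazol-3-yl quinazoline-2,4(1H,3H)-diones
    ("3e", "CN1c2ccccc2C(=O)N(Cc2nnc(N)[nH]2)C1=O",
     "3-[(5-Amino-4H-1,2,4-triazol-3-yl)methyl]-1-methylquinazoline-2,4(1H,3H)-dione",
     ROLE_TRAIN, 57.80, 3.45, 6, 5.8),
    ("3f", "CN1c2ccccc2C(=O)N(C(C)c2nnc(N)[nH]2)C1=O",
     "3-[1-(5-Amino-4H-1,2,4-triazol-3-yl)ethyl]-1-methylquinazoline-2,4(1H,3H)-dione",
     ROLE_TRAIN, 29.76, 9.03, 6, None),
    ("3g", "C=CCN1c2ccccc2C(=O)N(Cc2nnc(N)[nH]2)C1=O",
     "3-[(5-Amino-4H-1,2,4-triazol-3-yl)methyl]-1-(prop-2-en-1-yl)quinazoline-2,4(1H,3H)-dione",
     ROLE_TRAIN, 10.39, 4.42, 6, None),
    ("3h", "C=CCN1c2ccccc2C(=O)N(C(C)c2nnc(N)[nH]2)C1=O",
     "3-[1-(5-Amino-4H-1,2,4-triazol-3-yl)ethyl]-1-(prop-2-en-1-yl)quinazoline-2,4(1H,3H)-dione",
     ROLE_TRAIN, 33.24, 11.71, 6, None),
    ("3i", "O=C1N(Cc2nnc(N)[nH]2)C(=O)N(Cc2ccccc2)c2ccccc21",
     "3-[(5-Amino-4H-1,2,4-triazol-3-yl)methyl]-1-benzylquinazoline-2,4(1H,3H)-dione",
     ROLE_TRAIN, 12.94, 2.59, 6, None),
    # quinazolin-4(3H)-ones
    ("6a", "O=C1c2ccccc2N=CN1Cc1nnc(N)[nH]1",
     "3-[(5-Amino-4H-1,2,4-triazol-3-yl)methyl]quinazolin-4(3H)-one",
     ROLE_TRAIN, 54.06, 6.38, 6, 6.7),
    ("6b", "O=C1c2cc(Br)ccc2N=CN1Cc1nnc(N)[nH]1",
     "3-[(5-Amino-1H-1,2,4-triazol-3-yl)methyl]-6-bromoquinazolin-4(3H)-one",
     ROLE_TRAIN, 25.81, 6.15, 6, None),
    # reference acylguanidine NHE-1 inhibitors
    ("amiloride", "NC(=N)NC(=O)c1nc(Cl)c(N)nc1N",
     "3,5-Diamino-6-chloro-N-(diaminomethylidene)pyrazine-2-carboxamide",
     ROLE_TRAIN, 16.38, 2.72, 6, 1230.1),
    ("rimeporide", "Cc1cc(-n2cccc2)c(S(C)(=O)=O)cc1C(=O)NC(N)=N",
     "N-(Diaminomethylidene)-2-methyl-5-methanesulfonyl-4-(pyrrol-1-yl)benzamide",
     ROLE_TRAIN, 34.23, 5.91, 6, None),
    # external validation hold-out
    ("zoniporide", "NC(=N)NC(=O)c1cnn(-c2cccc3ncccc23)c1C1CC1",
     "N-(Diaminomethylidene)-5-cyclopropyl-1-(quinolin-5-yl)-1H-pyrazole-4-carboxamide",
     ROLE_EXTERNAL, 48.05, 7.09, 6, 7.3),
)


def load_builtin_dataset() -> CompoundSet:
    """Return the packaged 14-compound set (13 training + zoniporide hold-out)."""
    compounds = [Compound(i, s, n, r) for i, s, n, r, *_ in _BUILTIN]
    activities = [
        ActivityRecord(i, pct, sd, nrep, ic50)
        for i, _s, _n, _r, pct, sd, nrep, ic50 in _BUILTIN
    ]
    return CompoundSet(compounds, activities)


# --------------------------------------------------------------------------
# CSV compound tables
# --------------------------------------------------------------------------

def read_compound_table(path: str | Path) -> CompoundSet:
    """Read a CSV compound table (columns: id, smiles, activity[, sd, n, ic50_nM]).

    All rows get role=train.  Rows whose SMILES do not parse are rejected
    collectively, with their (1-based data) row numbers in the error message.
    """
    path = Path(path)
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise CompoundError(f"{path}: empty file")
        missing = {"id", "smiles", "activity"} - set(reader.fieldnames)
        if missing:
            raise CompoundError(f"{path}: missing required columns {sorted(missing)}")
        rows = list(reader)

    bad: list[int] = []
    compounds: list[Compound] = []
    activities: list[ActivityRecord] = []
    for i, row in enumerate(rows, start=1):
        smiles = (row["smiles"] or "").strip()
        if Chem.MolFromSmiles(smiles) is None:
            bad.append(i)
            continue
        sd = row.get("sd")
        nrep = row.get("n")
        ic50 = row.get("ic50_nM")
        compounds.append(Compound(row["id"].strip(), smiles, (row.get("name") or "").strip()))
        activities.append(
            ActivityRecord(
                row["id"].strip(),
                float(row["activity"]),
                float(sd) if sd not in (None, "") else None,
                int(nrep) if nrep not in (None, "") else 1,
                float(ic50) if ic50 not in (None, "") else None,
            )
        )
    if bad:
        raise CompoundError(f"{path}: unparseable SMILES in data row(s) {bad}")
    return CompoundSet(compounds, activities)


def write_compound_table(cs: CompoundSet, path: str | Path) -> None:
    """Write a CompoundSet as a CSV table readable by :func:`read_compound_table`."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["id", "smiles", "activity", "sd", "n", "ic50_nM", "name"])
        for c in cs.compounds:
            try:
                rec = cs.activity(c.id)
            except KeyError:
                continue
            w.writerow([
                c.id, c.smiles, f"{rec.inhibition_pct}",
                "" if rec.inhibition_sd is None else f"{rec.inhibition_sd}",
                rec.n, "" if rec.ic50_nM is None else f"{rec.ic50_nM}", c.name,
            ])


# --------------------------------------------------------------------------
# JSON analysis report
# --------------------------------------------------------------------------

#: Minimal structural schema for the analysis report: required keys and types.
REPORT_SCHEMA = {
    "schema_version": str,
    "seed": int,
    "config": dict,
    "matrix_summary": dict,
    "iterations": list,
    "pharmacophore": (dict, type(None)),
    "mappings": list,
    "external_validation": (dict, type(None)),
}


def validate_report(doc: dict) -> None:
    """Check a report document against :data:`REPORT_SCHEMA` (raises on failure)."""
    if not isinstance(doc, dict):
        raise CompoundError("report must be a JSON object")
    for key, typ in REPORT_SCHEMA.items():
        if key not in doc:
            raise CompoundError(f"report missing key {key!r}")
        if not isinstance(doc[key], typ):
            raise CompoundError(f"report key {key!r} has wrong type")


def canonical_json(doc: dict) -> str:
    """Canonical serialization: sorted keys, fixed separators, trailing newline."""
    return json.dumps(doc, sort_keys=True, indent=2, ensure_ascii=False) + "\n"


def write_report(bundle: dict, path: str | Path) -> None:
    """Write an analysis-result bundle as canonical, schema-checked JSON."""
    doc = dict(bundle)
    doc.setdefault("schema_version", REPORT_SCHEMA_VERSION)
    doc.setdefault("iterations", [])
    doc.setdefault("mappings", [])
    doc.setdefault("pharmacophore", None)
    doc.setdefault("external_validation", None)
    doc.setdefault("matrix_summary", {})
    doc.setdefault("config", {})
    doc.setdefault("seed", 0)
    validate_report(doc)
    Path(path).write_text(canonical_json(doc))


def read_report(path: str | Path) -> dict:
    doc = json.loads(Path(path).read_text())
    validate_report(doc)
    return doc
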