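"""Seeded generators for every statistical structure the pipeline assumes.

Three generators make all stages testable without external data:

* :func:`gen_planted_matrix` - binary descriptor matrices with a known
  ("planted") descriptor -> activity dependence plus Gaussian noise, used to
  benchmark network training and feature recovery;
* :func:`gen_molecule_library` - small combinatorial SMILES libraries on
  quinazoline-2,4(1H,3H)-dione / quinazolin-4(3H)-one cores, used to exercise
  the descriptor engine on realistic chemistry;
* :func:`gen_dose_response` - Hill-shaped concentration-response curves with
  multiplicative noise, used to benchmark IC50 recovery.

All generators are pure functions of their parameters and seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from rdkit import Chem

from .assay_models import DoseResponse
from .ql_descriptors import DescriptorMatrix, QLDescriptor

__all__ = [
    "PlantedDataset", "gen_planted_matrix",
    "gen_molecule_library", "enumerate_library", "gen_dose_response",
]


@dataclass
class PlantedDataset:
    """A planted-signal regression problem on binary descriptors.

    ``matrix`` is a :class:`DescriptorMatrix` whose activities follow
    ``50 + sum_j w_j x_j + N(0, noise_sd)`` over the planted columns exactly
    as configured; ``truth`` lists the planted column codes with weights.
    """

    matrix: DescriptorMatrix
    truth: dict[str, float]
    noise_sd: float
    seed: int

    @property
    def true_codes(self) -> list[str]:
        return sorted(self.truth)


def gen_planted_matrix(
    n_compounds: int,
    n_descriptors: int,
    n_true: int,
    effect_weights: Sequence[float],
    noise_sd: float,
    seed: int,
    density: float = 0.5,
) -> PlantedDataset:
    """Binary matrix with ``n_true`` planted activity-driving columns.

    All columns (planted and decoy) are independent Bernoulli(``density``);
    activity is ``50 + sum w_j x_j`` plus Gaussian noise of SD ``noise_sd``
    (percent).  The offset of 50 keeps synthetic activities in the percent
    range observed for this inhibitor class.
    """
    if n_compounds < 8:
        raise ValueError("n_compounds must be >= 8")
    if not 0 < density < 1:
        raise ValueError("density must be in (0, 1)")
    if n_true > n_descriptors:
        raise ValueError("n_true cannot exceed n_descriptors")
    if len(effect_weights) != n_true:
        raise ValueError("need one effect weight per planted descriptor")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")

    rng = np.random.default_rng(seed)
    X = (rng.random((n_compounds, n_descriptors)) < density).astype(int)
    w = np.zeros(n_descriptors)
    w[:n_true] = np.asarray(effect_weights, dtype=float)
    y = 50.0 + X @ w + rng.normal(0.0, noise_sd, size=n_compounds)

    width = max(3, len(str(n_descriptors)))
    codes = [f"T{j+1:0{width}d}" for j in range(n_true)] + [
        f"D{j+1:0{width}d}" for j in range(n_descriptors - n_true)
    ]
    ids = [f"S{i+1:04d}" for i in range(n_compounds)]
    Xdf = pd.DataFrame(X, index=ids, columns=codes)
    ys = pd.Series(y, index=ids, name="activity")
    descriptors = [QLDescriptor((c, c)) for c in codes]  # synthetic placeholder pairs
    matrix = DescriptorMatrix(Xdf, ys, descriptors)
    truth = {codes[j]: float(w[j]) for j in range(n_true)}
    return PlantedDataset(matrix=matrix, truth=truth, noise_sd=noise_sd, seed=seed)


# --------------------------------------------------------------------------
# Combinatorial quinazoline library
# --------------------------------------------------------------------------

# R1 decorates N1 of the dione core; R2 is the C6 substituent; R3 branches the
# N3-CH linker.  Fragments are written as SMILES prefixes.
_R1 = {"H": "", "CH3": "C", "allyl": "C=CC", "benzyl": "c1ccccc1C"}
_R2 = {"H": "", "Br": "Br"}
_R3 = {"H": "", "CH3": "C"}
_SIDE = "c3nnc(N)[nH]3"  # 5-amino-1,2,4-triazol-3-yl side chain


def enumerate_library() -> list[str]:
    """Full combinatorial enumeration over both cores and all substituents."""
    out: list[str] = []
    for r2 in _R2:
        for r3 in _R3:
            link = f"C({_R3[r3]})" if _R3[r3] else "C"
            # quinazolin-4(3H)-one core (no N1 substituent position)
            benzo_one = "c2cc(Br)ccc2" if _R2[r2] else "c2ccccc2"
            out.append(f"O=C1{benzo_one}N=CN1{link}{_SIDE}")
            # quinazoline-2,4(1H,3H)-dione core
            benzo_dione = "c2ccc(Br)cc2" if _R2[r2] else "c2ccccc2"
            for r1, frag in _R1.items():
                if frag:
                    smi = f"{frag}N1{benzo_dione}C(=O)N({link}{_SIDE})C1=O"
                else:
                    smi = f"O=C1N{benzo_dione}C(=O)N1{link}{_SIDE}"
                out.append(smi)
    # canonical-deduplicate, preserve order
    seen: set[str] = set()
    uniq: list[str] = []
    for smi in out:
        mol = Chem.MolFromSmiles(smi)
        if mol is None:  # pragma: no cover - templates are fixed
            raise ValueError(f"library template produced invalid SMILES {smi!r}")
        can = Chem.MolToSmiles(mol)
        if can not in seen:
            seen.add(can)
            uniq.append(smi)
    return uniq


def gen_molecule_library(n: int, seed: int) -> list[str]:
    """``n`` quinazoline-like SMILES sampled (with replacement beyond the
    enumeration) from the combinatorial library; all outputs parse."""
    if n < 1:
        raise ValueError("n must be >= 1")
    pool = enumerate_library()
    rng = np.random.default_rng(seed)
    if n <= len(pool):
        idx = rng.choice(len(pool), size=n, replace=False)
    else:
        idx = rng.choice(len(pool), size=n, replace=True)
    return [pool[i] for i in idx]


# --------------------------------------------------------------------------
# Dose-response curves
# --------------------------------------------------------------------------

def gen_dose_response(
    ic50: float,
    slope: float = 1.0,
    noise_pct: float = 0.0,
    n_points: int = 8,
    seed: int = 0,
    top: float = 100.0,
    bottom: float = 0.0,
    decades: float = 2.0,
) -> DoseResponse:
    """Synthetic logistic concentration-response curve.

    Concentrations are log-spaced over ``ic50 * 10**(-decades .. +decades)``;
    the noiseless response is the four-parameter logistic (decreasing from
    ``top`` toward ``bottom`` as concentration rises for ``slope > 0``);
    multiplicative Gaussian noise of SD ``noise_pct`` percent is applied.
    """
    if ic50 <= 0:
        raise ValueError("ic50 must be positive")
    if n_points < 4:
        raise ValueError("n_points must be >= 4")
    if noise_pct < 0:
        raise ValueError("noise_pct must be non-negative")
    logc = np.linspace(np.log10(ic50) - decades, np.log10(ic50) + decades, n_points)
    c = 10.0 ** logc
    y = bottom + (top - bottom) / (1.0 + (c / ic50) ** slope)
    if noise_pct > 0:
        rng = np.random.default_rng(seed)
        y = y * (1.0 + rng.normal(0.0, noise_pct / 100.0, size=n_points))
    return DoseResponse(concentrations=c, responses=y)
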