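"""Descriptor matrices: the 200-descriptor standard panel, element counts,
Ipc rescaling, named subsets, and per-descriptor max normalization.

The reference panel is the 200 low-dimensional (2D) RDKit descriptors of the
2019.09 release.  Newer RDKit builds ship additional descriptors (the eight
``BCUT2D_*`` terms, ``AvgIpc`` and ``SPS``); these are excluded so that the
panel, and every named subset defined over it, is stable across backend
versions.  The ``Ipc`` information-content index grows combinatorially with
size and is divided by 1e41 to keep it on a workable scale.  The twelve
element counts (nH … nX, with nX the total halogen count) extend the panel
to the 212-descriptor "Large212" set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import Descriptors

from .data_io import MoleculeRecord
from .errors import ConfigurationError, InvalidSmilesError

IPC_SCALE = 1e41

# Descriptors added to the RDKit panel after the 200-name 2019.09 release.
_POST_PANEL_DESCRIPTORS = frozenset(
    {
        "AvgIpc",
        "SPS",
        "NumAmideBonds",
        "NumAtomStereoCenters",
        "NumBridgeheadAtoms",
        "NumHeterocycles",
        "NumSpiroAtoms",
        "NumUnspecifiedAtomStereoCenters",
        "Phi",
    }
) | frozenset(n for n, _ in Descriptors._descList if n.startswith("BCUT2D_"))

_PANEL: list[tuple[str, object]] = [
    (name, fn) for name, fn in Descriptors._descList if name not in _POST_PANEL_DESCRIPTORS
]

RDKIT200: tuple[str, ...] = tuple(name for name, _ in _PANEL)

ELEMENT_COUNT_NAMES: tuple[str, ...] = (
    "nH", "nB", "nC", "nN", "nO", "nS", "nP", "nF", "nCl", "nBr", "nI", "nX",
)

_ELEMENT_SYMBOLS = {
    1: "nH", 5: "nB", 6: "nC", 7: "nN", 8: "nO", 16: "nS", 15: "nP",
    9: "nF", 17: "nCl", 35: "nBr", 53: "nI",
}

RDKIT61: tuple[str, ...] = (
    "MaxEStateIndex", "MinEStateIndex", "MinAbsEStateIndex", "qed", "MolWt",
    "MinPartialCharge", "MaxAbsPartialCharge", "FpDensityMorgan1", "BalabanJ",
    "BertzCT", "Chi0", "HallKierAlpha", "LabuteASA",
    "PEOE_VSA1", "PEOE_VSA10", "PEOE_VSA11", "PEOE_VSA12", "PEOE_VSA13",
    "PEOE_VSA14", "PEOE_VSA2", "PEOE_VSA3", "PEOE_VSA4", "PEOE_VSA5",
    "PEOE_VSA6", "PEOE_VSA7", "PEOE_VSA8", "PEOE_VSA9",
    "SMR_VSA1", "SMR_VSA10", "SMR_VSA2", "SMR_VSA3", "SMR_VSA4", "SMR_VSA5",
    "SMR_VSA6", "SMR_VSA7", "SMR_VSA9", "TPSA",
    "EState_VSA1", "EState_VSA10", "EState_VSA11", "EState_VSA2",
    "EState_VSA3", "EState_VSA4", "EState_VSA5", "EState_VSA6",
    "EState_VSA7", "EState_VSA8", "EState_VSA9",
    "VSA_EState1", "VSA_EState10", "VSA_EState2", "VSA_EState3",
    "VSA_EState4", "VSA_EState5", "VSA_EState6", "VSA_EState7",
    "VSA_EState8", "VSA_EState9",
    "FractionCSP3", "MolLogP", "MolMR",
)

FREE_V11: tuple[str, ...] = (
    "NumHeteroatoms", "NumHDonors", "NHOHCount", "NumHAcceptors",
    "NumSaturatedHeterocycles", "fr_Al_OH_noTert", "NumAliphaticHeterocycles",
    "nH", "NOCount", "qed", "nO",
)

FREE_TV10: tuple[str, ...] = (
    "NumHDonors", "NumSaturatedHeterocycles", "nO", "NumAliphaticRings",
    "MolWt", "MolLogP", "nN", "fr_Al_OH", "fr_SH", "fr_ketone",
)

BLOOD_V9: tuple[str, ...] = (
    "NumHeteroatoms", "MaxAbsPartialCharge", "NOCount", "NumHDonors",
    "NumAliphaticHeterocycles", "nS", "fr_C_S", "fr_unbrch_alkane", "fr_ester",
)

BLOOD_TV11: tuple[str, ...] = (
    "NOCount", "MaxAbsPartialCharge", "NumHDonors", "NumAliphaticHeterocycles",
    "nO", "MolWt", "NumHeteroatoms", "qed", "NumHAcceptors",
    "HeavyAtomCount", "nN",
)

LARGE: tuple[str, ...] = RDKIT200 + tuple(n for n in ELEMENT_COUNT_NAMES if n != "nB")
LARGE212: tuple[str, ...] = RDKIT200 + ELEMENT_COUNT_NAMES

DESCRIPTOR_SETS: Mapping[str, tuple[str, ...]] = {
    "RDKit200": RDKIT200,
    "RDKit61": RDKIT61,
    "FreeV11": FREE_V11,
    "FreeTV10": FREE_TV10,
    "BloodV9": BLOOD_V9,
    "BloodTV11": BLOOD_TV11,
    "Large": LARGE,
    "Large212": LARGE212,
}


@dataclass
class DescriptorMatrix:
    """Items x named numeric descriptors, with set provenance.

    ``frame`` is indexed by item num (strings) with descriptor-name columns.
    ``normalization`` stores per-column max-normalization constants when
    :func:`max_normalize` has been applied, for reuse on held-out rows.
    """

    frame: pd.DataFrame
    set_name: str = "custom"
    backend: str = field(default_factory=lambda: f"rdkit-{Chem.rdBase.rdkitVersion}")
    normalization: dict[str, float] | None = None

    @property
    def descriptor_names(self) -> list[str]:
        return list(self.frame.columns)

    @property
    def item_ids(self) -> list[str]:
        return list(self.frame.index)

    @property
    def values(self) -> np.ndarray:
        return self.frame.to_numpy(dtype=float)

    def __post_init__(self):
        if self.frame.columns.duplicated().any():
            dupes = self.frame.columns[self.frame.columns.duplicated()].tolist()
            raise ConfigurationError(f"duplicate descriptor names: {dupes}")


def _mol_from(smiles: str) -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise InvalidSmilesError(smiles)
    return mol


def element_counts(smiles: str) -> dict[str, int]:
    """Atom counts per element, including implicit hydrogens for nH.

    nX is the total halogen count nF + nCl + nBr + nI.
    """
    mol = Chem.AddHs(_mol_from(smiles))
    counts = dict.fromkeys(ELEMENT_COUNT_NAMES, 0)
    for atom in mol.GetAtoms():
        key = _ELEMENT_SYMBOLS.get(atom.GetAtomicNum())
        if key is not None:
            counts[key] += 1
    counts["nX"] = counts["nF"] + counts["nCl"] + counts["nBr"] + counts["nI"]
    return counts


def _panel_row(mol: Chem.Mol) -> list[float]:
    row = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for name, fn in _PANEL:
            try:
                v = float(fn(mol))
            except Exception:
                v = float("nan")
            if name == "Ipc":
                v = v / IPC_SCALE
            row.append(v)
    return row


def compute_panel(
    records: Sequence[MoleculeRecord],
    include_element_counts: bool = True,
) -> DescriptorMatrix:
    """Compute the standard descriptor panel (plus element counts) per record.

    Non-finite entries — e.g. partial-charge descriptors on degenerate
    molecules — are imputed to 0 and reported via a warning.  The Ipc column
    is rescaled by 1e41 at computation time.
    """
    names = list(RDKIT200) + (list(ELEMENT_COUNT_NAMES) if include_element_counts else [])
    rows = []
    for r in records:
        mol = _mol_from(r.smiles)
        row = _panel_row(mol)
        if include_element_counts:
            ec = element_counts(r.smiles)
            row.extend(ec[n] for n in ELEMENT_COUNT_NAMES)
        rows.append(row)
    frame = pd.DataFrame(rows, columns=names, index=[r.num for r in records], dtype=float)
    n_bad = int((~np.isfinite(frame.to_numpy())).sum())
    if n_bad:
        warnings.warn(f"imputed {n_bad} non-finite descriptor value(s) to 0", stacklevel=2)
        frame = frame.where(np.isfinite(frame), 0.0)
    set_name = "Large212" if include_element_counts else "RDKit200"
    return DescriptorMatrix(frame=frame, set_name=set_name)


def select_set(matrix: DescriptorMatrix, set_name: str) -> DescriptorMatrix:
    """Project the matrix onto a named descriptor set, in the set's order."""
    if set_name not in DESCRIPTOR_SETS:
        raise ConfigurationError(
            f"unknown descriptor set {set_name!r}; available: {sorted(DESCRIPTOR_SETS)}"
        )
    wanted = DESCRIPTOR_SETS[set_name]
    missing = [n for n in wanted if n not in matrix.frame.columns]
    if missing:
        raise ConfigurationError(f"matrix lacks descriptors for {set_name}: {missing}")
    return DescriptorMatrix(frame=matrix.frame.loc[:, list(wanted)], set_name=set_name)


def max_normalize(
    matrix: DescriptorMatrix,
    reference_rows: Sequence[int] | None = None,
) -> DescriptorMatrix:
    """Divide each column by its max |value| over the reference rows.

    Reference rows default to all rows; in model pipelines pass the training
    indices so held-out rows are scaled by training constants (their values
    may then exceed 1).  Columns whose reference max is 0 are left unchanged.
    """
    frame = matrix.frame
    if reference_rows is None:
        ref = frame
    else:
        if len(reference_rows) == 0:
            raise ValueError("reference_rows must be non-empty")
        ref = frame.iloc[list(reference_rows)]
    constants = ref.abs().max(axis=0)
    constants = constants.where(constants != 0, 1.0)
    out = frame / constants
    return DescriptorMatrix(
        frame=out,
        set_name=matrix.set_name,
        backend=matrix.backend,
        normalization={k: float(v) for k, v in constants.items()},
    )
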