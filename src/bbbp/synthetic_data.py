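"""Seeded generator of BBBP-like datasets for offline pipeline testing.

Molecules are assembled from a small vocabulary of ring scaffolds (plus
acyclic chains) decorated with common substituents, so Murcko scaffold
grouping is nondegenerate.  Labels follow a logistic model in descriptor
space with the drug-likeness sign structure: more H-bond donors and higher
molecular weight lower the penetration probability, moderate lipophilicity
raises it (quadratic in logP).  A minority of "glucose-like" molecules — an
aliphatic O-heterocycle carrying three or more non-tertiary aliphatic OH
groups — is labeled positive with high probability despite being
hydrophilic, emulating carrier-mediated transport that the descriptor-only
rule would miss.

The label model lives in descriptor space, not structure space: tests need
known feature-label relations, not chemical realism.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem
from rdkit.Chem import Descriptors

from .data_io import MoleculeRecord

RING_SCAFFOLDS: tuple[str, ...] = (
    "c1ccccc1",          # benzene
    "c1ccncc1",          # pyridine
    "c1cncnc1",          # pyrimidine
    "c1ccc2ccccc2c1",    # naphthalene
    "c1ccc2ncccc2c1",    # quinoline
    "c1ccc2[nH]ccc2c1",  # indole
    "c1ccsc1",           # thiophene
    "c1c[nH]cn1",        # imidazole
    "C1CCNCC1",          # piperidine
    "C1CCOCC1",          # tetrahydropyran
    "C1COCCN1",          # morpholine
    "C1CNCCN1",          # piperazine
    "C1CCNC1",           # pyrrolidine
    "C1CCOC1",           # tetrahydrofuran
    "C1CCCCC1",          # cyclohexane
    "C1CCCC1",           # cyclopentane
)

SUBSTITUENTS: tuple[str, ...] = (
    "O",            # hydroxyl
    "N",            # amino
    "C(=O)O",       # carboxylic acid
    "OC",           # methoxy
    "F",
    "Cl",
    "Br",
    "C",
    "CC",
    "CCC",
    "CC(C)C",       # isobutyl
    "C(F)(F)F",     # trifluoromethyl
    "C#N",          # nitrile
    "CO",           # hydroxymethyl
    "OCC",          # ethoxy
    "C(=O)N",       # amide
    "c1ccccc1",     # phenyl
    "Cc1ccccc1",    # benzyl
)

GLUCOSE_CORE = "C1CCOCC1"  # tetrahydropyran


@dataclass(frozen=True)
class GeneratorConfig:
    """Stated world of the generator; same config and seed give identical data."""

    n_molecules: int = 1000
    n_scaffolds: int = len(RING_SCAFFOLDS)
    fraction_acyclic: float = 0.15
    max_substituents: int = 5
    # Logistic label model over (H-bond donors, logP, molecular weight).
    # Coefficients are large on purpose: the emulated world is a
    # near-deterministic Lipinski-like rule, so the generator's Bayes rate
    # stays high and model tests measure the pipeline, not label noise.
    beta: dict = field(
        default_factory=lambda: {
            "intercept": 3.0,
            "donors": -4.0,
            "mw": -3.0,     # per 100 Da above 250
            "logp": 3.0,
            "logp2": -0.6,  # moderate-lipophilicity optimum
        }
    )
    glucose_motif_fraction: float = 0.08
    glucose_positive_prob: float = 0.9
    label_noise: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_molecules < 10:
            raise ValueError("n_molecules must be at least 10")
        for name in ("fraction_acyclic", "glucose_motif_fraction",
                     "glucose_positive_prob", "label_noise"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be within [0, 1], got {v}")
        if not 1 <= self.n_scaffolds <= len(RING_SCAFFOLDS):
            raise ValueError(f"n_scaffolds must be in [1, {len(RING_SCAFFOLDS)}]")


def _attach(mol: Chem.Mol, substituent: str, rng: np.random.Generator) -> Chem.Mol:
    """Bond a substituent's first atom to a random core carbon with a free H."""
    sub = Chem.MolFromSmiles(substituent)
    candidates = [
        a.GetIdx()
        for a in mol.GetAtoms()
        if a.GetAtomicNum() == 6 and a.GetTotalNumHs() >= 1
    ]
    if not candidates:
        return mol
    core_idx = int(rng.choice(candidates))
    combo = Chem.RWMol(Chem.CombineMols(mol, sub))
    combo.AddBond(core_idx, mol.GetNumAtoms(), Chem.BondType.SINGLE)
    out = combo.GetMol()
    try:
        Chem.SanitizeMol(out)
    except Exception:
        return mol
    return out


def _random_molecule(config: GeneratorConfig, rng: np.random.Generator) -> Chem.Mol:
    if rng.random() < config.fraction_acyclic:
        mol = Chem.MolFromSmiles("C" * int(rng.integers(3, 9)))
    else:
        vocab = RING_SCAFFOLDS[: config.n_scaffolds]
        mol = Chem.MolFromSmiles(vocab[int(rng.integers(len(vocab)))])
    for _ in range(int(rng.integers(1, config.max_substituents + 1))):
        mol = _attach(mol, SUBSTITUENTS[int(rng.integers(len(SUBSTITUENTS)))], rng)
    return mol


def _glucose_molecule(rng: np.random.Generator) -> Chem.Mol:
    """Tetrahydropyran core decorated with 3-5 hydroxyls (+ optional CH2OH).

    Each hydroxyl goes to a distinct ring carbon so every one is a secondary
    (non-tertiary) aliphatic OH, as on a pyranose.
    """
    core = Chem.MolFromSmiles(GLUCOSE_CORE)
    carbons = [a.GetIdx() for a in core.GetAtoms() if a.GetAtomicNum() == 6]
    n_oh = int(rng.integers(3, 6))
    chosen = rng.choice(carbons, size=n_oh, replace=False)
    mol = Chem.RWMol(core)
    for idx in chosen:
        o = mol.AddAtom(Chem.Atom(8))
        mol.AddBond(int(idx), o, Chem.BondType.SINGLE)
    out = mol.GetMol()
    Chem.SanitizeMol(out)
    if rng.random() < 0.5:
        out = _attach(out, "CO", rng)
    return out


def is_glucose_like(smiles: str) -> bool:
    """Aliphatic heterocycle bearing at least three non-tertiary aliphatic OH."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        return False
    return (
        Descriptors.NumAliphaticHeterocycles(mol) >= 1
        and Descriptors.fr_Al_OH_noTert(mol) >= 3
    )


def _label_probability(mol: Chem.Mol, beta: dict) -> float:
    donors = Descriptors.NumHDonors(mol)
    logp = Descriptors.MolLogP(mol)
    mw = Descriptors.MolWt(mol)
    z = (
        beta["intercept"]
        + beta["donors"] * donors
        + beta["mw"] * (mw - 250.0) / 100.0
        + beta["logp"] * logp
        + beta["logp2"] * logp * logp
    )
    return 1.0 / (1.0 + np.exp(-z))


def generate(config: GeneratorConfig) -> list[MoleculeRecord]:
    """Generate a BBBP-schema dataset of parseable SMILES with known structure."""
    rng = np.random.default_rng(config.seed)
    records = []
    for i in range(config.n_molecules):
        if rng.random() < config.glucose_motif_fraction:
            mol = _glucose_molecule(rng)
        else:
            mol = _random_molecule(config, rng)
        smiles = Chem.MolToSmiles(mol)
        if is_glucose_like(smiles):
            p = config.glucose_positive_prob
        else:
            p = _label_probability(mol, config.beta)
            if config.label_noise > 0:
                p = (1.0 - config.label_noise) * p + config.label_noise * 0.5
        label = int(rng.random() < p)
        records.append(
            MoleculeRecord(num=str(i + 1), name=f"SYN-{i + 1:05d}", p_np=label, smiles=smiles)
        )
    return records
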