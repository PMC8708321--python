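"""Rule-based standardization of SMILES into free-form and in-blood-form.

The *free form* is the neutral parent structure: counterions and co-crystal
fragments stripped, acid/base sites returned to the uncharged state, with
quaternary ammonium cations kept as permanent cations.  The *in-blood form*
is the dominant protonation state at blood pH (~7.4), obtained by applying
an ordered table of functional-group rules: acids well below blood pH are
deprotonated, bases well above it are protonated, and borderline sites
(|pKa - pH| within the margin) are deliberately left neutral.

The rule table is data, not code: the packaged default
(``rules/blood_ph.yaml``) approximates a manual expert curation and can be
replaced by the user.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import yaml
from rdkit import Chem

from .errors import ConfigurationError, InvalidSmilesError

BLOOD_PH = 7.4
PH_MARGIN = 1.0

# Positively charged atoms carrying at least one H, and negatively charged
# atoms not adjacent to a positive centre, are returned to neutral; a
# quaternary ammonium (+1, no H) never matches the first branch.
_NEUTRALIZE_PATTERN = Chem.MolFromSmarts(
    "[+1!h0!$([*]~[-1,-2,-3,-4]),-1!$([*]~[+1,+2,+3,+4])]"
)


@dataclass(frozen=True)
class ProtonationRule:
    """One ordered entry of the blood-pH rule table."""

    name: str
    pattern: str
    pka: float
    action: str  # {"deprotonate", "protonate", "keep"}
    site: int = 0

    def fires(self, ph: float, margin: float) -> bool:
        if self.action == "deprotonate":
            return self.pka < ph - margin
        if self.action == "protonate":
            return self.pka > ph + margin
        return False


def load_rules(path: str | Path | None = None) -> list[ProtonationRule]:
    """Load a rule table from YAML (default: the packaged blood-pH table).

    Every SMARTS pattern is compiled eagerly; a pattern that fails to compile
    raises :class:`ConfigurationError` naming the rule.
    """
    if path is None:
        raw = resources.files("bbbp").joinpath("rules/blood_ph.yaml").read_text()
    else:
        raw = Path(path).read_text()
    doc = yaml.safe_load(raw)
    rules = []
    for entry in doc["rules"]:
        rule = ProtonationRule(
            name=entry["name"],
            pattern=entry["pattern"],
            pka=float(entry["pka"]),
            action=entry["action"],
            site=int(entry.get("site", 0)),
        )
        if rule.action not in ("deprotonate", "protonate", "keep"):
            raise ConfigurationError(f"rule {rule.name!r}: unknown action {rule.action!r}")
        if Chem.MolFromSmarts(rule.pattern) is None:
            raise ConfigurationError(f"rule {rule.name!r}: invalid SMARTS {rule.pattern!r}")
        rules.append(rule)
    return rules


_DEFAULT_RULES: list[ProtonationRule] | None = None


def default_rules() -> list[ProtonationRule]:
    global _DEFAULT_RULES
    if _DEFAULT_RULES is None:
        _DEFAULT_RULES = load_rules()
    return _DEFAULT_RULES


def _parse(smiles: str) -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise InvalidSmilesError(smiles)
    return mol


def strip_to_parent(smiles: str) -> str:
    """Keep the main fragment of a multi-fragment SMILES.

    The parent is the fragment with the most heavy atoms; ties go to the
    fragment with more carbons, then to the lexicographically smallest
    canonical SMILES.  Single-fragment inputs pass through unchanged (up to
    canonicalization).
    """
    mol = _parse(smiles)
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=False)
    if not frags:
        raise InvalidSmilesError(smiles, "no fragments")

    def key(frag: Chem.Mol):
        n_heavy = frag.GetNumHeavyAtoms()
        n_carbon = sum(1 for a in frag.GetAtoms() if a.GetAtomicNum() == 6)
        return (-n_heavy, -n_carbon, Chem.MolToSmiles(frag))

    best = min(frags, key=key)
    return Chem.MolToSmiles(best)


def neutralize(smiles: str) -> str:
    """Return the free (uncharged) form, keeping permanent cations.

    Protonated amines lose a proton; carboxylate/phenolate/thiolate/alkoxide
    anions gain one.  A quaternary ammonium nitrogen has no proton to remove
    and stays cationic.  If RDKit cannot sanitize the neutralized molecule the
    input is returned unchanged (flagged to the caller by identity).
    """
    mol = _parse(smiles)
    matches = mol.GetSubstructMatches(_NEUTRALIZE_PATTERN)
    if not matches:
        return Chem.MolToSmiles(mol)
    edited = Chem.RWMol(mol)
    for (idx,) in matches:
        atom = edited.GetAtomWithIdx(idx)
        charge = atom.GetFormalCharge()
        h = atom.GetTotalNumHs()
        atom.SetFormalCharge(0)
        atom.SetNumExplicitHs(h - charge)
        atom.UpdatePropertyCache()
    try:
        out = edited.GetMol()
        Chem.SanitizeMol(out)
    except Exception:
        return Chem.MolToSmiles(mol)
    return Chem.MolToSmiles(out)


def _apply_rule_site(mol: Chem.RWMol, idx: int, action: str) -> bool:
    atom = mol.GetAtomWithIdx(idx)
    h = atom.GetTotalNumHs()
    if action == "deprotonate":
        if h < 1:
            return False
        atom.SetFormalCharge(atom.GetFormalCharge() - 1)
        atom.SetNumExplicitHs(h - 1)
    elif action == "protonate":
        atom.SetFormalCharge(atom.GetFormalCharge() + 1)
        atom.SetNumExplicitHs(h + 1)
    else:
        return False
    atom.SetNoImplicit(True)
    return True


def to_blood_form(
    smiles: str,
    ph: float = BLOOD_PH,
    rules: list[ProtonationRule] | None = None,
    margin: float = PH_MARGIN,
) -> str:
    """Dominant protonation state at blood pH from a free-form SMILES.

    Rules are applied in order; each ionizable site is transformed by the
    first rule that matches it (later matches on the same atom are ignored).
    Sites matched only by ``keep`` rules, or whose pKa falls within ``margin``
    of ``ph`` (mixed-species region), stay neutral.
    """
    if rules is None:
        rules = default_rules()
    mol = _parse(smiles)
    edited = Chem.RWMol(mol)
    consumed: set[int] = set()
    for rule in rules:
        patt = Chem.MolFromSmarts(rule.pattern)
        if patt is None:
            raise ConfigurationError(f"rule {rule.name!r}: invalid SMARTS {rule.pattern!r}")
        for match in edited.GetMol().GetSubstructMatches(patt):
            idx = match[rule.site]
            if idx in consumed:
                continue
            consumed.add(idx)
            if rule.fires(ph, margin):
                _apply_rule_site(edited, idx, rule.action)
    out = edited.GetMol()
    try:
        Chem.SanitizeMol(out)
    except Exception:
        return Chem.MolToSmiles(mol)
    return Chem.MolToSmiles(out)
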