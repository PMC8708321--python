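"""Reading, writing and curating BBBP-style datasets.

A BBBP dataset is a CSV with four columns: ``num`` (string identifier),
``name`` (free text), ``p_np`` (binary penetration label, 1 = penetrating)
and ``smiles``.  Curation canonicalizes structures and removes duplicate and
label-inconsistent entries, producing the "independent" dataset the models
are trained on, together with a machine-readable report of every removal.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Sequence

from rdkit import Chem, RDLogger

from .errors import InvalidSmilesError, SchemaError

RDLogger.DisableLog("rdApp.*")

REQUIRED_COLUMNS = ("num", "name", "p_np", "smiles")


@dataclass(frozen=True)
class MoleculeRecord:
    """One dataset row: identifier, compound name, label and structure."""

    num: str
    name: str
    p_np: int
    smiles: str


@dataclass
class CurationReport:
    """Ledger of everything curation removed or rewrote.

    ``removed_duplicates`` holds ``(removed_num, kept_num)`` pairs;
    ``removed_inconsistent`` holds the num-groups whose members shared a
    structure but disagreed on the label (all members removed);
    ``corrected`` holds ``(num, reason)`` pairs for patched or flagged rows.
    """

    removed_duplicates: list[tuple[str, str]] = field(default_factory=list)
    removed_inconsistent: list[list[str]] = field(default_factory=list)
    corrected: list[tuple[str, str]] = field(default_factory=list)
    n_in: int = 0
    n_out: int = 0

    @property
    def removed_nums(self) -> set[str]:
        out = {num for num, _ in self.removed_duplicates}
        for group in self.removed_inconsistent:
            out.update(group)
        return out

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(asdict(self), indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, text_or_path: str | Path) -> "CurationReport":
        if isinstance(text_or_path, Path):
            text = text_or_path.read_text()
        else:
            try:
                json.loads(text_or_path)
                text = text_or_path
            except json.JSONDecodeError:
                text = Path(text_or_path).read_text()
        raw = json.loads(text)
        return cls(
            removed_duplicates=[tuple(x) for x in raw["removed_duplicates"]],
            removed_inconsistent=[list(x) for x in raw["removed_inconsistent"]],
            corrected=[tuple(x) for x in raw["corrected"]],
            n_in=raw["n_in"],
            n_out=raw["n_out"],
        )


def _coerce_label(value: str, num: str) -> int:
    s = str(value).strip()
    try:
        f = float(s)
    except ValueError:
        raise SchemaError(f"row num={num!r}: unparseable p_np value {value!r}") from None
    if f not in (0.0, 1.0):
        raise SchemaError(f"row num={num!r}: p_np must be 0 or 1, got {value!r}")
    return int(f)


def read_bbbp_csv(path: str | Path) -> list[MoleculeRecord]:
    """Read a BBBP-schema CSV into records, preserving file order.

    The header is order-insensitive and quoted fields are allowed. A missing
    required column raises :class:`SchemaError` naming the column; an
    unparseable label raises :class:`SchemaError` naming the row's num.
    """
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        missing = [c for c in REQUIRED_COLUMNS if c not in header]
        if missing:
            raise SchemaError(f"missing required column(s): {', '.join(missing)}")
        records = []
        for row in reader:
            num = (row["num"] or "").strip()
            records.append(
                MoleculeRecord(
                    num=num,
                    name=(row["name"] or "").strip(),
                    p_np=_coerce_label(row["p_np"], num),
                    smiles=(row["smiles"] or "").strip(),
                )
            )
    return records


def write_bbbp_csv(records: Iterable[MoleculeRecord], path: str | Path) -> None:
    """Write records back to the four-column CSV schema (UTF-8, minimal quoting)."""
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, quoting=csv.QUOTE_MINIMAL)
        writer.writerow(REQUIRED_COLUMNS)
        for r in records:
            writer.writerow([r.num, r.name, r.p_np, r.smiles])


def canonical_smiles(smiles: str) -> str:
    """Deterministic canonical SMILES; idempotent by construction."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise InvalidSmilesError(smiles)
    return Chem.MolToSmiles(mol)


def _num_sort_key(num: str):
    try:
        return (0, int(num))
    except ValueError:
        return (1, num)


def deduplicate(
    records: Sequence[MoleculeRecord],
    keys: Sequence[str] | None = None,
) -> tuple[list[MoleculeRecord], CurationReport]:
    """Remove duplicate and label-inconsistent records.

    Records are grouped by ``keys`` (default: canonical SMILES of each
    record's structure; records that fail to parse use their raw string and
    therefore never collide with parseable ones). Within a group of identical
    structures, records agreeing on the label keep exactly one member — the
    numerically smallest ``num`` — while groups with conflicting labels are
    removed entirely.  The kept set is invariant under permutation of the
    input rows; output preserves input order.
    """
    if keys is None:
        keys = []
        for r in records:
            try:
                keys.append(canonical_smiles(r.smiles))
            except InvalidSmilesError:
                keys.append(f"__raw__:{r.smiles}")
    if len(keys) != len(records):
        raise ValueError("keys must align with records")

    groups: dict[str, list[MoleculeRecord]] = {}
    for key, rec in zip(keys, records):
        groups.setdefault(key, []).append(rec)

    report = CurationReport(n_in=len(records))
    drop: set[str] = set()
    for members in groups.values():
        if len(members) == 1:
            continue
        labels = {m.p_np for m in members}
        if len(labels) == 1:
            kept = min(members, key=lambda m: _num_sort_key(m.num))
            for m in members:
                if m.num != kept.num:
                    report.removed_duplicates.append((m.num, kept.num))
                    drop.add(m.num)
        else:
            report.removed_inconsistent.append([m.num for m in members])
            drop.update(m.num for m in members)

    kept_records = [r for r in records if r.num not in drop]
    report.n_out = len(kept_records)
    return kept_records, report


def read_patch_csv(path: str | Path) -> dict[str, str]:
    """Read a two-column (num, smiles) patch table of hand-corrected structures."""
    patches: dict[str, str] = {}
    with Path(path).open(newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        header = next(reader)
        if [h.strip().lower() for h in header[:2]] != ["num", "smiles"]:
            raise SchemaError("patch file must have header: num,smiles")
        for row in reader:
            if row:
                patches[row[0].strip()] = row[1].strip()
    return patches


def apply_patches(
    records: Sequence[MoleculeRecord],
    patches: dict[str, str],
    report: CurationReport | None = None,
) -> list[MoleculeRecord]:
    """Replace SMILES by num from a patch table, logging each correction."""
    out = []
    for r in records:
        if r.num in patches and patches[r.num] != r.smiles:
            out.append(MoleculeRecord(r.num, r.name, r.p_np, patches[r.num]))
            if report is not None:
                report.corrected.append((r.num, "patched"))
        else:
            out.append(r)
    return out


def curate_free_form(
    records: Sequence[MoleculeRecord],
    patches: dict[str, str] | None = None,
) -> tuple[list[MoleculeRecord], CurationReport]:
    """Full free-form curation: patch, strip counterions, neutralize, deduplicate.

    Each structure is reduced to its neutral parent (largest fragment,
    charges removed except permanent cations) so that different salts of one
    drug collide under the canonical-SMILES identity key.  Records whose
    SMILES cannot be parsed are passed through untouched and flagged in the
    report's ``corrected`` list.
    """
    from .form_rules import neutralize, strip_to_parent

    report = CurationReport(n_in=len(records))
    if patches:
        records = apply_patches(records, patches, report)

    curated: list[MoleculeRecord] = []
    keys: list[str] = []
    for r in records:
        try:
            free = canonical_smiles(neutralize(strip_to_parent(r.smiles)))
            curated.append(MoleculeRecord(r.num, r.name, r.p_np, free))
            keys.append(free)
        except InvalidSmilesError:
            report.corrected.append((r.num, "unparseable-smiles: left as-is"))
            curated.append(r)
            keys.append(f"__raw__:{r.smiles}")

    kept, dedup_report = deduplicate(curated, keys=keys)
    report.removed_duplicates = dedup_report.removed_duplicates
    report.removed_inconsistent = dedup_report.removed_inconsistent
    report.n_out = len(kept)
    return kept, report
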