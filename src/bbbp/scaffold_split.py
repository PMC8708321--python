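"""Bemis-Murcko scaffold grouping and the benchmark's fixed 8:1:1 split.

The fixed split assigns whole scaffold groups, ordered from the largest
group to the smallest (ties broken by descending first-member index, the
reference implementation's behaviour), to train, then validation, then test
against 80%/90% cumulative cutoffs.  Because the largest groups fill the
training partition, validation and test end up populated by rare scaffolds —
a deliberately hard, extrapolative evaluation.

For confidence intervals, the split is resampled by holding every
multi-member scaffold group fixed in train and re-partitioning only the
pooled singleton-scaffold molecules, preserving the reference partition
sizes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from rdkit import Chem
from rdkit.Chem.Scaffolds import MurckoScaffold

from .data_io import MoleculeRecord
from .errors import InvalidSmilesError, SplitError


@dataclass(frozen=True)
class ScaffoldGroup:
    """All dataset indices sharing one Murcko scaffold ('' = acyclic)."""

    scaffold: str
    member_indices: tuple[int, ...]


@dataclass
class SplitIndices:
    """Disjoint train/validation/test index lists over one dataset."""

    train: list[int]
    valid: list[int]
    test: list[int]
    ratio: tuple[float, float, float] = (0.8, 0.1, 0.1)

    @property
    def n(self) -> int:
        return len(self.train) + len(self.valid) + len(self.test)

    def validate(self) -> None:
        parts = [set(self.train), set(self.valid), set(self.test)]
        total = len(self.train) + len(self.valid) + len(self.test)
        union = set().union(*parts)
        if len(union) != total:
            raise SplitError("split partitions overlap or contain duplicates")

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps({"train": self.train, "valid": self.valid, "test": self.test})
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, text_or_path: str | Path) -> "SplitIndices":
        if isinstance(text_or_path, Path):
            raw = json.loads(text_or_path.read_text())
        else:
            try:
                raw = json.loads(text_or_path)
            except json.JSONDecodeError:
                raw = json.loads(Path(text_or_path).read_text())
        return cls(train=raw["train"], valid=raw["valid"], test=raw["test"])


def murcko_scaffold(smiles: str) -> str:
    """Canonical SMILES of the Bemis-Murcko framework; '' for acyclic molecules."""
    if Chem.MolFromSmiles(smiles) is None:
        raise InvalidSmilesError(smiles)
    return MurckoScaffold.MurckoScaffoldSmiles(smiles=smiles, includeChirality=False)


def group_by_scaffold(records: Sequence[MoleculeRecord]) -> list[ScaffoldGroup]:
    """Group dataset indices by scaffold; acyclic molecules share the '' group."""
    groups: dict[str, list[int]] = {}
    for i, rec in enumerate(records):
        groups.setdefault(murcko_scaffold(rec.smiles), []).append(i)
    return [ScaffoldGroup(s, tuple(sorted(ix))) for s, ix in groups.items()]


def _ordered_groups(records: Sequence[MoleculeRecord]) -> list[ScaffoldGroup]:
    groups = group_by_scaffold(records)
    # Largest first; equal sizes broken by descending first-member index.
    return sorted(
        groups, key=lambda g: (len(g.member_indices), g.member_indices[0]), reverse=True
    )


def fixed_scaffold_split(
    records: Sequence[MoleculeRecord],
    ratio: tuple[float, float, float] = (0.8, 0.1, 0.1),
) -> SplitIndices:
    """The benchmark's deterministic scaffold split at the given ratio.

    Groups are atomic: each goes wholly to train while train stays within
    ratio[0]*N after the addition, then to validation within
    (ratio[0]+ratio[1])*N, otherwise to test.
    """
    n = len(records)
    if n < 10:
        raise SplitError("need at least 10 records for a meaningful 8:1:1 split")
    train_cutoff = ratio[0] * n
    valid_cutoff = (ratio[0] + ratio[1]) * n
    train: list[int] = []
    valid: list[int] = []
    test: list[int] = []
    for g in _ordered_groups(records):
        members = list(g.member_indices)
        # degenerate guard: a first group larger than the train cutoff still
        # opens the training partition (groups are atomic, train never empty)
        if not train:
            train.extend(members)
        elif len(train) + len(members) > train_cutoff:
            if len(train) + len(valid) + len(members) > valid_cutoff:
                test.extend(members)
            else:
                valid.extend(members)
        else:
            train.extend(members)
    split = SplitIndices(train=train, valid=valid, test=test, ratio=ratio)
    split.validate()
    return split


def random_split(
    n: int,
    ratio: tuple[float, float, float] = (0.8, 0.1, 0.1),
    seed: int = 0,
) -> SplitIndices:
    """Plain seeded random split, as a comparison baseline."""
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_train = int(round(ratio[0] * n))
    n_valid = int(round(ratio[1] * n))
    return SplitIndices(
        train=sorted(int(i) for i in perm[:n_train]),
        valid=sorted(int(i) for i in perm[n_train : n_train + n_valid]),
        test=sorted(int(i) for i in perm[n_train + n_valid :]),
        ratio=ratio,
    )


def singleton_reference_split(
    records: Sequence[MoleculeRecord],
    ratio: tuple[float, float, float] = (0.8, 0.1, 0.1),
) -> SplitIndices:
    """Deterministic reference split satisfying the resampler's precondition.

    All multi-member scaffold groups go to train; validation and test each
    take ``min(round(ratio*N), pool//3)`` singleton-scaffold molecules (in
    index order), the rest of the pool joins train.  Use this on datasets
    where the fixed benchmark split leaves multi-member groups in
    validation/test, which :func:`singleton_pool_resample` rejects.
    """
    groups = group_by_scaffold(records)
    fixed_train = sorted(
        i for g in groups if len(g.member_indices) > 1 for i in g.member_indices
    )
    pool = sorted(g.member_indices[0] for g in groups if len(g.member_indices) == 1)
    n = len(records)
    n_valid = min(int(round(ratio[1] * n)), len(pool) // 3)
    n_test = min(int(round(ratio[2] * n)), len(pool) // 3)
    if n_valid == 0 or n_test == 0:
        raise SplitError("too few singleton scaffolds to form validation/test partitions")
    n_train_s = len(pool) - n_valid - n_test
    split = SplitIndices(
        train=sorted(fixed_train + pool[:n_train_s]),
        valid=pool[n_train_s : n_train_s + n_valid],
        test=pool[n_train_s + n_valid :],
        ratio=ratio,
    )
    split.validate()
    return split


def singleton_pool_resample(
    records: Sequence[MoleculeRecord],
    reference_split: SplitIndices,
    n_resamples: int = 100,
    seed: int = 0,
) -> list[SplitIndices]:
    """Resampled scaffold splits for confidence intervals.

    Members of multi-element scaffold groups stay in train in every resample.
    The pooled singleton-scaffold molecules are randomly re-partitioned to
    reproduce the reference split's partition sizes.  Requires every
    validation/test member of the reference split to belong to a singleton
    group.
    """
    groups = group_by_scaffold(records)
    singleton = {g.member_indices[0] for g in groups if len(g.member_indices) == 1}
    fixed_train = sorted(
        i for g in groups if len(g.member_indices) > 1 for i in g.member_indices
    )

    offenders = [
        g.scaffold
        for g in groups
        if len(g.member_indices) > 1
        and any(i in set(reference_split.valid) | set(reference_split.test) for i in g.member_indices)
    ]
    if offenders:
        raise SplitError(
            "reference split has validation/test members in multi-element scaffold "
            f"groups: {offenders[:5]}{'...' if len(offenders) > 5 else ''}"
        )

    pool = sorted(singleton)
    n_train_s = len(reference_split.train) - len(fixed_train)
    n_valid = len(reference_split.valid)
    n_test = len(reference_split.test)
    if n_train_s < 0 or n_train_s + n_valid + n_test != len(pool):
        raise SplitError("reference split composition inconsistent with scaffold groups")

    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_resamples):
        perm = rng.permutation(pool)
        train_s = perm[:n_train_s]
        valid = perm[n_train_s : n_train_s + n_valid]
        test = perm[n_train_s + n_valid :]
        split = SplitIndices(
            train=sorted(fixed_train + [int(i) for i in train_s]),
            valid=sorted(int(i) for i in valid),
            test=sorted(int(i) for i in test),
            ratio=reference_split.ratio,
        )
        split.validate()
        out.append(split)
    return out
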