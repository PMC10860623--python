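"""Sibling pedigrees: family structure for simulation and heritability fitting.

Only sibships are modelled (no parents, no half-relatives): every pair of
subjects in the same family is a full-sib pair with coefficient of
relationship 0.5, and subjects in different families are unrelated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = ["PedigreeSpec", "Pedigree", "make_pedigree", "STUDY_SPEC"]


@dataclass(frozen=True)
class PedigreeSpec:
    """Requested family structure: one ``(family_id, n_members)`` per family."""

    families: tuple[tuple[str, int], ...]

    def __post_init__(self) -> None:
        ids = [fid for fid, _ in self.families]
        if len(set(ids)) != len(ids):
            raise ValueError("family ids must be unique")
        for fid, n in self.families:
            if n < 1:
                raise ValueError(f"family {fid!r} has non-positive size {n}")

    @property
    def n_subjects(self) -> int:
        return sum(n for _, n in self.families)


def _study_families() -> tuple[tuple[str, int], ...]:
    # 91 two-sib families, 8 three-sib, 1 four-sib: 100 families, 210 subjects.
    sizes = [2] * 91 + [3] * 8 + [4]
    return tuple((f"fam{i + 1:03d}", n) for i, n in enumerate(sizes))


#: The study cohort layout: 100 sibships totalling 210 subjects.
STUDY_SPEC = PedigreeSpec(families=_study_families())


@dataclass(frozen=True)
class Pedigree:
    """Immutable subject <-> family mapping with family-block bookkeeping.

    Subjects are stored grouped by family, in spec order, which lets the
    variance-component code treat the phenotype vector as contiguous family
    blocks.
    """

    subjects: tuple[str, ...]
    family_of: Mapping[str, str]
    families: Mapping[str, tuple[str, ...]] = field(repr=False)

    def __post_init__(self) -> None:
        if len(set(self.subjects)) != len(self.subjects):
            raise ValueError("subject ids must be unique")
        for sid in self.subjects:
            if sid not in self.family_of:
                raise ValueError(f"subject {sid!r} missing family assignment")

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def n_families(self) -> int:
        return len(self.families)

    def family_sizes(self) -> np.ndarray:
        return np.array([len(m) for m in self.families.values()], dtype=int)

    def sib_pairs(self) -> list[tuple[str, str]]:
        """All unordered within-family subject pairs."""
        pairs: list[tuple[str, str]] = []
        for members in self.families.values():
            pairs.extend(combinations(members, 2))
        return pairs

    def block_index(self, subject_ids: Sequence[str] | None = None) -> tuple[np.ndarray, np.ndarray]:
        """Family-block layout over a subject subset.

        Returns ``(order, sizes)``: ``order`` indexes ``subject_ids`` so that
        subjects of the same family are contiguous; ``sizes`` are the block
        lengths in that order. Defaults to all subjects.
        """
        ids = list(self.subjects) if subject_ids is None else list(subject_ids)
        fams: dict[str, list[int]] = {}
        for i, sid in enumerate(ids):
            fams.setdefault(self.family_of[sid], []).append(i)
        order = np.array([i for members in fams.values() for i in members], dtype=int)
        sizes = np.array([len(m) for m in fams.values()], dtype=int)
        return order, sizes

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"subject": list(self.subjects),
             "family": [self.family_of[s] for s in self.subjects]}
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "Pedigree":
        """Build from a table with ``subject`` and ``family`` columns."""
        fams: dict[str, list[str]] = {}
        for sid, fid in zip(df["subject"].astype(str), df["family"].astype(str)):
            fams.setdefault(fid, []).append(sid)
        subjects = tuple(s for members in fams.values() for s in members)
        family_of = {s: f for f, members in fams.items() for s in members}
        return cls(subjects=subjects, family_of=family_of,
                   families={f: tuple(m) for f, m in fams.items()})


def make_pedigree(spec: PedigreeSpec = STUDY_SPEC) -> Pedigree:
    """Materialize a pedigree with deterministic subject ids.

    Subject ids are ``<family_id>_s<k>``; the default spec reproduces the
    study cohort (100 families, 210 siblings).
    """
    families: dict[str, tuple[str, ...]] = {}
    family_of: dict[str, str] = {}
    subjects: list[str] = []
    for fid, n in spec.families:
        members = tuple(f"{fid}_s{k + 1}" for k in range(n))
        families[fid] = members
        subjects.extend(members)
        for sid in members:
            family_of[sid] = fid
    return Pedigree(subjects=tuple(subjects), family_of=family_of, families=families)


def pedigree_from_sizes(sizes: Iterable[int], prefix: str = "fam") -> Pedigree:
    """Convenience: pedigree from a bare list of family sizes."""
    spec = PedigreeSpec(families=tuple(
        (f"{prefix}{i + 1:04d}", int(n)) for i, n in enumerate(sizes)))
    return make_pedigree(spec)
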