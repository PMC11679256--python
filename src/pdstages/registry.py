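"""Registry of subcortical structures and their segmentation label codes.

The analysis operates on the deep grey-matter structures, ventricular CSF
and the cerebellum as delineated by FreeSurfer's automatic subcortical
segmentation (``aseg``).  Each structure is identified by one or more
integer label codes; a few structures pool several codes into a single
voxel cloud (the bilateral thalamus, and cerebellar cortex plus white
matter on each side).  The thalamus is the designated reference structure:
every other structure's volume is normalised by the thalamus volume and
its centroid distances are measured against the thalamus centroid.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterator, List, Tuple


@dataclass(frozen=True)
class StructureRegistry:
    """Ordered mapping from structure name to a set of label codes.

    Parameters
    ----------
    labels :
        Mapping ``name -> frozenset of integer label codes``.  Insertion
        order is meaningful: it fixes the feature-column order downstream.
    reference :
        Name of the reference structure (default ``"Thalamus"``).  Must be
        a key of ``labels``.
    """

    labels: Dict[str, FrozenSet[int]]
    reference: str = "Thalamus"

    def __post_init__(self) -> None:
        if self.reference not in self.labels:
            raise ValueError(f"reference structure {self.reference!r} not in registry")
        seen: set[int] = set()
        for name, codes in self.labels.items():
            if not codes:
                raise ValueError(f"structure {name!r} has no label codes")
            overlap = seen & set(codes)
            if overlap:
                raise ValueError(f"label codes {sorted(overlap)} assigned to more than one structure")
            seen |= set(codes)

    @property
    def names(self) -> List[str]:
        return list(self.labels.keys())

    @property
    def non_reference(self) -> List[str]:
        """All structure names except the reference, in registry order."""
        return [n for n in self.labels if n != self.reference]

    def codes(self, name: str) -> FrozenSet[int]:
        return self.labels[name]

    @property
    def all_codes(self) -> FrozenSet[int]:
        out: set[int] = set()
        for codes in self.labels.values():
            out |= set(codes)
        return frozenset(out)

    def __len__(self) -> int:
        return len(self.labels)

    def __iter__(self) -> Iterator[str]:
        return iter(self.labels)

    def __contains__(self, name: object) -> bool:
        return name in self.labels


def default_registry() -> StructureRegistry:
    """The 19-structure registry used throughout the analysis.

    Label codes follow the FreeSurfer aseg convention.  The bilateral
    thalamus (codes 10 and 49) forms a single reference structure;
    each cerebellar hemisphere pools its white matter and cortex codes.
    """
    entries: List[Tuple[str, FrozenSet[int]]] = [
        ("Thalamus", frozenset({10, 49})),
        ("Left-Hippocampus", frozenset({17})),
        ("Right-Hippocampus", frozenset({53})),
        ("Left-Amygdala", frozenset({18})),
        ("Right-Amygdala", frozenset({54})),
        ("Left-Caudate", frozenset({11})),
        ("Right-Caudate", frozenset({50})),
        ("Left-Putamen", frozenset({12})),
        ("Right-Putamen", frozenset({51})),
        ("Left-Pallidum", frozenset({13})),
        ("Right-Pallidum", frozenset({52})),
        ("Left-Accumbens-area", frozenset({26})),
        ("Right-Accumbens-area", frozenset({58})),
        ("Left-VentralDC", frozenset({28})),
        ("Right-VentralDC", frozenset({60})),
        ("4th-Ventricle", frozenset({15})),
        ("Left-Cerebellum", frozenset({7, 8})),
        ("Right-Cerebellum", frozenset({46, 47})),
        ("CSF", frozenset({24})),
    ]
    return StructureRegistry(labels=dict(entries))


# Canonical cohort group names, in fixed order (used for ensemble tie-breaks).
GROUPS: Tuple[str, str, str] = ("CONTROL", "PRODROMAL", "PARKINSON")


def feature_columns(registry: StructureRegistry | None = None) -> List[str]:
    """Deterministic feature-column order of the cohort table.

    One raw thalamus volume, then (normalised volume, Euclidean distance,
    cosine distance) per non-reference structure in registry order, then
    the demographic covariates.  With the default 19-structure registry
    this yields 1 + 18*3 + 2 = 57 columns.
    """
    reg = registry if registry is not None else default_registry()
    cols = [f"{reg.reference}_vol"]
    for name in reg.non_reference:
        cols.extend([f"{name}_normvol", f"{name}_euclid", f"{name}_cosine"])
    cols.extend(["Sex", "Age"])
    return cols
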