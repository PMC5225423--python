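"""Core in-memory containers shared across the pipeline.

An :class:`ExpressionMatrix` holds log2-scale intensities as a pandas
DataFrame (miRNA probes in rows, samples in columns, ``NaN`` marking missing
cells) together with a case/control label per sample.  Target and pathway
annotations are plain mappings from an identifier to a frozen gene set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property
from typing import Iterable, Mapping

import pandas as pd

CASE = "case"
CONTROL = "control"
VALID_GROUPS = frozenset({CASE, CONTROL})


def _check_unique(labels: Iterable[str], what: str) -> None:
    seen: set[str] = set()
    for lab in labels:
        if lab in seen:
            raise ValueError(f"duplicate {what} identifier: {lab!r}")
        seen.add(lab)


@dataclass
class ExpressionMatrix:
    """miRNA x sample matrix of log2 intensities with group labels.

    Parameters
    ----------
    values
        DataFrame with miRNA ids as index and sample ids as columns.
        ``NaN`` entries are treated as missing throughout the pipeline.
    groups
        Series mapping each sample id to ``"case"`` or ``"control"``.
        May be ``None`` for matrices whose labels are assigned later
        (e.g. straight out of a GEO series-matrix file).
    """

    values: pd.DataFrame
    groups: pd.Series | None = None

    def __post_init__(self) -> None:
        _check_unique(self.values.index, "miRNA")
        _check_unique(self.values.columns, "sample")
        self.values = self.values.astype(float)
        if self.groups is not None:
            self.groups = self.groups.astype(str)
            missing = [s for s in self.values.columns if s not in self.groups.index]
            if missing:
                raise ValueError(
                    "samples missing from the label file: " + ", ".join(map(str, missing))
                )
            self.groups = self.groups.loc[list(self.values.columns)]
            bad = sorted(set(self.groups) - VALID_GROUPS)
            if bad:
                raise ValueError(f"unknown group labels: {bad}; expected {sorted(VALID_GROUPS)}")

    @property
    def mirna_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_missing(self) -> int:
        return int(self.values.isna().to_numpy().sum())

    def _group_samples(self, group: str) -> list[str]:
        if self.groups is None:
            raise ValueError("expression matrix has no group labels")
        return [s for s in self.sample_ids if self.groups[s] == group]

    @property
    def case_samples(self) -> list[str]:
        return self._group_samples(CASE)

    @property
    def control_samples(self) -> list[str]:
        return self._group_samples(CONTROL)

    def subset(self, mirna_ids: Iterable[str]) -> "ExpressionMatrix":
        ids = list(mirna_ids)
        unknown = [m for m in ids if m not in self.values.index]
        if unknown:
            raise KeyError(f"miRNAs absent from matrix: {unknown}")
        return ExpressionMatrix(self.values.loc[ids].copy(), self.groups)

    def with_groups(self, groups: Mapping[str, str] | pd.Series) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.copy(), pd.Series(dict(groups)))


@dataclass
class TargetMap:
    """Per-miRNA target-gene sets; the universe is their union."""

    targets: dict[str, frozenset[str]]

    def __post_init__(self) -> None:
        self.targets = {m: frozenset(g) for m, g in self.targets.items()}

    @cached_property
    def universe(self) -> frozenset[str]:
        out: set[str] = set()
        for genes in self.targets.values():
            out |= genes
        return frozenset(out)

    def __contains__(self, mirna: str) -> bool:
        return mirna in self.targets

    def __getitem__(self, mirna: str) -> frozenset[str]:
        try:
            return self.targets[mirna]
        except KeyError:
            raise KeyError(f"miRNA not in target map: {mirna!r}") from None


@dataclass
class PathwayAnnotation:
    """Named pathway gene sets (GMT semantics)."""

    gene_sets: dict[str, frozenset[str]]
    names: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.gene_sets = {p: frozenset(g) for p, g in self.gene_sets.items()}
        for pid, genes in self.gene_sets.items():
            if not genes:
                raise ValueError(f"pathway {pid!r} has an empty gene set")

    def __len__(self) -> int:
        return len(self.gene_sets)

    def items(self):
        return self.gene_sets.items()
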