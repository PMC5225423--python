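"""Pearson correlation (CE) between miRNA pairs and CE-stratified bins.

Correlations are computed over all samples (cases and controls pooled) on
pairwise-complete observations; pairs are then binned by |CE| and sign into
the strata used as classifier feature sets (0.6-0.7, 0.7-0.8, >0.8 per
sign by default).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix

__all__ = ["MiRNAPair", "pairwise_ce", "stratify_pairs", "DEFAULT_BIN_EDGES"]

DEFAULT_BIN_EDGES = (0.6, 0.7, 0.8)


@dataclass(frozen=True)
class MiRNAPair:
    """Unordered miRNA pair with its Pearson correlation coefficient."""

    mirna_a: str
    mirna_b: str
    ce: float

    def __post_init__(self) -> None:
        if self.mirna_a == self.mirna_b:
            raise ValueError(f"self-pair not allowed: {self.mirna_a!r}")
        if self.mirna_a > self.mirna_b:
            first, second = self.mirna_b, self.mirna_a
            object.__setattr__(self, "mirna_a", first)
            object.__setattr__(self, "mirna_b", second)

    @property
    def sign_class(self) -> str:
        return "positive" if self.ce > 0 else "negative"

    @property
    def key(self) -> tuple[str, str]:
        return (self.mirna_a, self.mirna_b)


def pairwise_ce(matrix: ExpressionMatrix, feature_ids: Iterable[str]) -> list[MiRNAPair]:
    """All unordered Pearson-correlation pairs among ``feature_ids``.

    Samples from both groups are pooled; missing values are handled by
    pairwise-complete observations.  Pairs whose CE is undefined (a
    zero-variance feature) or exactly zero are excluded; undefined ones
    trigger a warning naming the offending feature.
    """
    ids = list(dict.fromkeys(feature_ids))
    if len(matrix.sample_ids) < 3:
        raise ValueError("need at least 3 samples to estimate correlations")
    sub = matrix.subset(ids).values
    corr = sub.T.corr(method="pearson", min_periods=3)
    degenerate = [m for m in ids if sub.loc[m].std(skipna=True) == 0]
    for m in degenerate:
        warnings.warn(f"feature {m!r} has zero variance; its pairs are excluded", stacklevel=2)
    pairs: list[MiRNAPair] = []
    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            ce = corr.at[a, b]
            if not np.isfinite(ce) or ce == 0.0:
                continue
            pairs.append(MiRNAPair(a, b, float(ce)))
    return pairs


def _stratum_label(sign: str, abs_ce: float, edges: Sequence[float]) -> str | None:
    if abs_ce > edges[-1]:
        return f"{sign}, >{edges[-1]:g}"
    for lo, hi in zip(edges[:-1], edges[1:]):
        if lo < abs_ce <= hi:
            return f"{sign}, {lo:g}-{hi:g}"
    return None


def stratify_pairs(
    pairs: Iterable[MiRNAPair], bin_edges: Sequence[float] = DEFAULT_BIN_EDGES
) -> dict[str, list[MiRNAPair]]:
    """Bin pairs by |CE| and sign into feature-set strata.

    With the default edges (0.6, 0.7, 0.8) each sign contributes strata
    (0.6-0.7], (0.7-0.8] and (>0.8); pairs at or below the lowest edge are
    not assigned to any stratum.
    """
    edges = list(bin_edges)
    if edges != sorted(edges) or not all(0 <= e <= 1 for e in edges):
        raise ValueError("bin edges must be sorted and lie in [0, 1]")
    strata: dict[str, list[MiRNAPair]] = {}
    for sign in ("positive", "negative"):
        for lo, hi in zip(edges[:-1], edges[1:]):
            strata[f"{sign}, {lo:g}-{hi:g}"] = []
        strata[f"{sign}, >{edges[-1]:g}"] = []
    for pair in pairs:
        label = _stratum_label(pair.sign_class, abs(pair.ce), edges)
        if label is not None:
            strata[label].append(pair)
    return strata


def pairs_table(pairs: Iterable[MiRNAPair],
                strata: dict[str, list[MiRNAPair]] | None = None) -> pd.DataFrame:
    """Tabulate pairs (mirna_a, mirna_b, ce, sign_class, stratum) for export."""
    stratum_of: dict[tuple[str, str], str] = {}
    if strata:
        for label, members in strata.items():
            for p in members:
                stratum_of[p.key] = label
    rows = [
        {
            "mirna_a": p.mirna_a,
            "mirna_b": p.mirna_b,
            "ce": p.ce,
            "sign_class": p.sign_class,
            "stratum": stratum_of.get(p.key, ""),
        }
        for p in pairs
    ]
    return pd.DataFrame(rows, columns=["mirna_a", "mirna_b", "ce", "sign_class", "stratum"])
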