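"""Symmetric percent-similarity matrices (16S identity, ANI, AAI).

One container serves both the 16S identity matrices used for rank
delineation and the genome-level ANI/AAI matrices used for species/genus
clustering.  Missing pairs are allowed (NaN) and are treated as falling
below every threshold.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd


class SimilarityMatrix:
    """A symmetric matrix of pairwise percent similarities over an id set."""

    def __init__(self, df: pd.DataFrame, kind: str = "identity",
                 validate: bool = True) -> None:
        if validate:
            if list(df.index) != list(df.columns):
                raise ValueError("matrix index and columns must be identical")
            vals = df.to_numpy(dtype=float)
            if vals.size:
                diag = np.diag(vals)
                if not np.allclose(diag, 100.0, atol=1e-6):
                    raise ValueError("matrix diagonal must be 100")
                both = ~np.isnan(vals) & ~np.isnan(vals.T)
                if not np.allclose(vals[both], vals.T[both], atol=1e-6):
                    raise ValueError("matrix is not symmetric")
                finite = vals[~np.isnan(vals)]
                if finite.size and (finite.min() < 0 or finite.max() > 100):
                    raise ValueError("similarities must lie in [0, 100]")
        self.df = df.astype(float)
        self.kind = kind

    @classmethod
    def from_dense(cls, ids: Iterable[str], values: np.ndarray,
                   kind: str = "identity") -> "SimilarityMatrix":
        ids = list(ids)
        return cls(pd.DataFrame(values, index=ids, columns=ids), kind=kind)

    @classmethod
    def from_pairs(cls, ids: Iterable[str],
                   pairs: Mapping[tuple[str, str], float],
                   kind: str = "identity") -> "SimilarityMatrix":
        """Build from a sparse {(a, b): similarity} mapping; missing pairs NaN."""
        ids = list(ids)
        df = pd.DataFrame(np.nan, index=ids, columns=ids)
        np.fill_diagonal(df.values, 100.0)
        for (a, b), v in pairs.items():
            df.loc[a, b] = v
            df.loc[b, a] = v
        return cls(df, kind=kind)

    @property
    def ids(self) -> list[str]:
        return list(self.df.index)

    def value(self, a: str, b: str) -> float:
        return float(self.df.loc[a, b])

    def min_pairwise(self, ids: Iterable[str]) -> tuple[float, tuple[str, str]]:
        """Minimum off-diagonal similarity over an id subset and its arg-pair.

        Missing (NaN) pairs count as -inf, i.e. below every threshold.
        """
        ids = list(ids)
        if len(ids) < 2:
            return 100.0, (ids[0], ids[0]) if ids else ("", "")
        sub = self.df.loc[ids, ids].to_numpy(dtype=float)
        sub = np.where(np.isnan(sub), -np.inf, sub)
        iu = np.triu_indices(len(ids), k=1)
        flat = sub[iu]
        k = int(np.argmin(flat))
        return float(flat[k]), (ids[iu[0][k]], ids[iu[1][k]])

    def to_tsv(self, path: str | Path) -> None:
        self.df.to_csv(path, sep="\t", index_label="id")

    @classmethod
    def read_tsv(cls, path: str | Path, kind: str = "identity") -> "SimilarityMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        df.index = df.index.astype(str)
        df.columns = df.columns.astype(str)
        return cls(df, kind=kind)

    def __contains__(self, item: str) -> bool:
        return item in self.df.index

    def __len__(self) -> int:
        return len(self.df)


def single_linkage_components(ids: list[str],
                              edge: "callable[[str, str], bool]") -> list[frozenset[str]]:
    """Connected components of the graph whose edges satisfy ``edge(a, b)``.

    Deterministic: components are sorted by their lexicographically smallest
    member.  Simple union-find; id sets here are small (tens to hundreds).
    """
    parent = {i: i for i in ids}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            if edge(a, b):
                ra, rb = find(a), find(b)
                if ra != rb:
                    parent[ra] = rb
    groups: dict[str, set[str]] = {}
    for x in ids:
        groups.setdefault(find(x), set()).add(x)
    return sorted((frozenset(g) for g in groups.values()), key=min)
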