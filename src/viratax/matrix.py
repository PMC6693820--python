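"""Symmetric pairwise genome distance matrices (bits), with an infinite
"no-match" sentinel for the gene-alignment matrix.

Matrices are stored dense; ``numpy.inf`` is the open-circuit sentinel for
genome pairs with no gene match. TSV serialization keeps a header row and
an index column of genome ids, with the sentinel written as ``inf``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd


@dataclass
class DistanceMatrix:
    ids: list[str]
    values: np.ndarray
    sentinel_allowed: bool = False
    _pos: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError(f"matrix shape {self.values.shape} != ({n},{n})")
        if not np.array_equal(self.values, self.values.T):
            raise ValueError("matrix not symmetric")
        if np.any(np.diagonal(self.values) != 0):
            raise ValueError("diagonal must be zero")
        finite = np.isfinite(self.values)
        if np.any(self.values[finite] < 0):
            raise ValueError("negative distances")
        if not self.sentinel_allowed and not finite.all():
            raise ValueError("non-finite entries in a sentinel-free matrix")
        self._pos = {gid: i for i, gid in enumerate(self.ids)}

    def __len__(self) -> int:
        return len(self.ids)

    def get(self, id_a: str, id_b: str) -> float:
        return float(self.values[self._pos[id_a], self._pos[id_b]])

    def off_diagonal(self) -> np.ndarray:
        """Upper-triangle off-diagonal entries (including sentinels)."""
        iu = np.triu_indices(len(self.ids), k=1)
        return self.values[iu]

    def max_finite_off_diagonal(self) -> float:
        off = self.off_diagonal()
        off = off[np.isfinite(off)]
        if off.size == 0:
            raise ValueError("no finite off-diagonal entries")
        return float(off.max())

    def to_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame(self.values, index=self.ids, columns=self.ids)
        df.to_csv(path, sep="\t", float_format="%.10g")

    @classmethod
    def from_tsv(cls, path: str | Path, sentinel_allowed: bool | None = None) -> "DistanceMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        ids = [str(c) for c in df.index]
        values = df.to_numpy(dtype=float)
        # symmetrize away round-trip float noise
        values = 0.5 * (values + values.T)
        np.fill_diagonal(values, 0.0)
        if sentinel_allowed is None:
            sentinel_allowed = bool(np.isinf(values).any())
        return cls(ids=ids, values=values, sentinel_allowed=sentinel_allowed)
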