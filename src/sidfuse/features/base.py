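"""FeatureBlock: a per-post feature matrix with column provenance.

Every featurizer in the package returns a :class:`FeatureBlock` whose columns
carry both a unique name and a family tag (BSC, RFS or WEC) so that
downstream combination recipes and the fusion ensemble can reason about which
feature family each column came from.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

FAMILIES = ("BSC", "RFS", "WEC")


@dataclass
class FeatureBlock:
    matrix: np.ndarray
    column_names: list[str]
    column_block: list[str]
    row_ids: list[str]

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2:
            raise ValueError("matrix must be 2-D")
        n, m = self.matrix.shape
        if len(self.column_names) != m or len(self.column_block) != m:
            raise ValueError("column metadata length does not match matrix width")
        if len(self.row_ids) != n:
            raise ValueError("row_ids length does not match matrix height")
        if len(set(self.column_names)) != m:
            raise ValueError("column names must be unique")
        bad = set(self.column_block) - set(FAMILIES)
        if bad:
            raise ValueError(f"unknown column family tags: {sorted(bad)}")
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("matrix contains NaN or infinite values")

    @property
    def shape(self) -> tuple[int, int]:
        return self.matrix.shape

    @property
    def n_features(self) -> int:
        return self.matrix.shape[1]

    def take_columns(self, idx: Sequence[int]) -> "FeatureBlock":
        idx = list(idx)
        return FeatureBlock(
            self.matrix[:, idx],
            [self.column_names[i] for i in idx],
            [self.column_block[i] for i in idx],
            list(self.row_ids),
        )

    @staticmethod
    def hstack(blocks: Sequence["FeatureBlock"]) -> "FeatureBlock":
        if not blocks:
            raise ValueError("no blocks to stack")
        ids = blocks[0].row_ids
        for b in blocks[1:]:
            if b.row_ids != ids:
                raise ValueError("blocks have mismatched row ids")
        return FeatureBlock(
            np.hstack([b.matrix for b in blocks]),
            [c for b in blocks for c in b.column_names],
            [t for b in blocks for t in b.column_block],
            list(ids),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.row_ids, columns=self.column_names)

    def to_csv(self, path: str | Path) -> None:
        """Write the matrix as CSV plus a sidecar JSON of column family tags."""
        path = Path(path)
        df = self.to_frame()
        df.index.name = "id"
        df.to_csv(path)
        sidecar = path.with_suffix(path.suffix + ".meta.json")
        sidecar.write_text(json.dumps({"column_block": self.column_block}, indent=1))

    @staticmethod
    def from_csv(path: str | Path) -> "FeatureBlock":
        path = Path(path)
        df = pd.read_csv(path, index_col="id")
        meta = json.loads(path.with_suffix(path.suffix + ".meta.json").read_text())
        return FeatureBlock(
            df.to_numpy(dtype=float),
            list(df.columns),
            list(meta["column_block"]),
            [str(i) for i in df.index],
        )
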