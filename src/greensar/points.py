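"""Point locations on a road network (projected planar coordinates, meters)."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class PointSet:
    """Road-midpoint locations with integer ids and planar (x, y) coordinates.

    Ids must be unique and coordinates finite; at least two points are
    required for any spatial analysis.
    """

    ids: np.ndarray
    x: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        ids = np.asarray(self.ids, dtype=np.int64)
        x = np.asarray(self.x, dtype=float)
        y = np.asarray(self.y, dtype=float)
        if not (ids.shape == x.shape == y.shape) or ids.ndim != 1:
            raise ValueError("ids, x, y must be 1-D arrays of equal length")
        if ids.size < 2:
            raise ValueError("a PointSet needs at least 2 points")
        if np.unique(ids).size != ids.size:
            raise ValueError("point ids must be unique")
        if not (np.isfinite(x).all() and np.isfinite(y).all()):
            raise ValueError("coordinates must be finite")
        object.__setattr__(self, "ids", ids)
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)

    @property
    def n(self) -> int:
        return self.ids.size

    @property
    def coords(self) -> np.ndarray:
        """(n, 2) coordinate array."""
        return np.column_stack([self.x, self.y])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"id": self.ids, "x": self.x, "y": self.y})

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "PointSet":
        return cls(df["id"].to_numpy(), df["x"].to_numpy(), df["y"].to_numpy())

    @classmethod
    def from_csv(cls, path) -> "PointSet":
        return cls.from_frame(pd.read_csv(path))
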