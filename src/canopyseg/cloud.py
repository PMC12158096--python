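"""Point-cloud container and delimited-text IO.

A :class:`PointCloud` is a thin wrapper around a float ``(N, 3)`` coordinate
array plus optional per-point attribute columns (ground flag, normalized
height, structural part tag, ground-truth tree id, predicted tree id).  All
attributes are plain numpy arrays aligned with ``xyz``; subsetting keeps them
in sync.  Clouds round-trip through CSV (all columns) and whitespace XYZ
(coordinates only).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

# structural part tags for simulated / classified points
PART_GROUND = 0
PART_TRUNK = 1
PART_CROWN = 2
PART_NOISE = 3

PART_NAMES = {
    PART_GROUND: "ground",
    PART_TRUNK: "trunk",
    PART_CROWN: "crown",
    PART_NOISE: "noise",
}

NO_LABEL = -1  # tree id / truth id meaning "none"

_OPTIONAL_COLUMNS = ("ground", "height", "part", "truth_id", "tree_id")


@dataclass
class PointCloud:
    """3D points with aligned per-point attribute columns.

    Parameters
    ----------
    xyz
        ``(N, 3)`` float array of coordinates in a projected metric CRS.
    ground
        Optional boolean ground-return flags.
    height
        Optional normalized (above-ground) heights in metres.
    part
        Optional structural part codes (``PART_*`` constants).
    truth_id
        Optional ground-truth tree labels (simulator output); ``-1`` = noise.
    tree_id
        Optional predicted tree labels; ``-1`` = unassigned.
    extent
        Optional plot extent ``(xmin, ymin, xmax, ymax)`` metadata (the
        planted area, used as the canopy-closure denominator).
    """

    xyz: np.ndarray
    ground: np.ndarray | None = None
    height: np.ndarray | None = None
    part: np.ndarray | None = None
    truth_id: np.ndarray | None = None
    tree_id: np.ndarray | None = None
    extent: tuple[float, float, float, float] | None = field(default=None)

    def __post_init__(self) -> None:
        self.xyz = np.asarray(self.xyz, dtype=np.float64)
        if self.xyz.ndim != 2 or self.xyz.shape[1] != 3:
            raise ValueError(f"xyz must be (N, 3), got {self.xyz.shape}")
        n = len(self.xyz)
        for name in _OPTIONAL_COLUMNS:
            col = getattr(self, name)
            if col is not None:
                col = np.asarray(col)
                if len(col) != n:
                    raise ValueError(f"attribute {name!r} has length {len(col)}, expected {n}")
                setattr(self, name, col)

    # -- basic protocol ----------------------------------------------------

    def __len__(self) -> int:
        return len(self.xyz)

    @property
    def x(self) -> np.ndarray:
        return self.xyz[:, 0]

    @property
    def y(self) -> np.ndarray:
        return self.xyz[:, 1]

    @property
    def z(self) -> np.ndarray:
        return self.xyz[:, 2]

    def subset(self, mask_or_index: np.ndarray) -> "PointCloud":
        """Return a new cloud restricted to a boolean mask or index array."""
        kw = {"xyz": self.xyz[mask_or_index], "extent": self.extent}
        for name in _OPTIONAL_COLUMNS:
            col = getattr(self, name)
            kw[name] = None if col is None else col[mask_or_index]
        return PointCloud(**kw)

    def with_(self, **updates) -> "PointCloud":
        """Copy with some attribute columns replaced."""
        return replace(self, **updates)

    # -- IO ----------------------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        data = {"x": self.x, "y": self.y, "z": self.z}
        for name in _OPTIONAL_COLUMNS:
            col = getattr(self, name)
            if col is not None:
                data[name] = col
        return pd.DataFrame(data)

    @classmethod
    def from_frame(cls, df: pd.DataFrame,
                   extent: tuple[float, float, float, float] | None = None) -> "PointCloud":
        missing = [c for c in ("x", "y", "z") if c not in df.columns]
        if missing:
            raise ValueError(f"missing coordinate columns: {missing}")
        kw = {"xyz": df[["x", "y", "z"]].to_numpy(dtype=np.float64), "extent": extent}
        for name in _OPTIONAL_COLUMNS:
            if name in df.columns:
                col = df[name].to_numpy()
                if name == "ground":
                    col = col.astype(bool)
                elif name in ("part", "truth_id", "tree_id"):
                    col = col.astype(np.int64)
                kw[name] = col
        return cls(**kw)

    def write_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.6f")

    @classmethod
    def read(cls, path: str | Path) -> "PointCloud":
        """Read a cloud from CSV (headered) or whitespace-delimited XYZ."""
        path = Path(path)
        if path.suffix.lower() in (".csv",):
            return cls.from_frame(pd.read_csv(path))
        if path.suffix.lower() in (".xyz", ".txt"):
            arr = np.loadtxt(path, ndmin=2)
            if arr.shape[1] < 3:
                raise ValueError(f"{path}: expected at least 3 columns")
            return cls(xyz=arr[:, :3])
        raise ValueError(f"{path}: unsupported point format "
                         "(supported: .csv with x,y,z header, .xyz/.txt whitespace)")
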