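"""Sensor layouts: a minimal geometric description of an MEG helmet.

The default fixture mimics a 306-channel whole-head system: 102 sites on a
hemispherical shell, each carrying one magnetometer and a pair of planar
gradiometers. Only positions, sensor kinds and gradiometer pairing matter
to the analysis (adjacency graphs, planar combination); field units and
coil geometry do not.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["SensorLayout", "make_sensor_layout", "hemisphere_layout"]

_KINDS = ("mag", "grad")


@dataclass(frozen=True)
class SensorLayout:
    """Sensor ids, 3-D positions (meters), kinds and planar-pair links."""

    sensor_id: tuple[str, ...]
    positions: np.ndarray          # (n, 3) float, meters
    kind: tuple[str, ...]          # "mag" | "grad"
    pair_id: tuple[str | None, ...]

    def __post_init__(self) -> None:
        n = len(self.sensor_id)
        pos = np.asarray(self.positions, dtype=float)
        if pos.shape != (n, 3):
            raise ValueError(f"positions must be ({n}, 3), got {pos.shape}")
        if not np.all(np.isfinite(pos)):
            raise ValueError("non-finite sensor coordinates")
        object.__setattr__(self, "positions", pos)
        if len(set(self.sensor_id)) != n:
            raise ValueError("duplicate sensor ids")
        bad = [k for k in self.kind if k not in _KINDS]
        if bad:
            raise ValueError(f"unknown sensor kinds: {sorted(set(bad))}")
        for pid, members in self.pairs().items():
            if len(members) != 2:
                raise ValueError(
                    f"pair_id {pid!r} links {len(members)} sensors (expected 2)"
                )
            if any(self.kind[m] != "grad" for m in members):
                raise ValueError(f"pair_id {pid!r} links a non-gradiometer")

    def __len__(self) -> int:
        return len(self.sensor_id)

    def pairs(self) -> dict[str, list[int]]:
        """Map pair_id -> indices of its two gradiometers."""
        out: dict[str, list[int]] = {}
        for i, pid in enumerate(self.pair_id):
            if pid is not None:
                out.setdefault(pid, []).append(i)
        return out

    def select(self, kind: str) -> np.ndarray:
        """Indices of all sensors of one kind."""
        return np.array([i for i, k in enumerate(self.kind) if k == kind], dtype=int)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "sensor_id": self.sensor_id,
            "x": self.positions[:, 0],
            "y": self.positions[:, 1],
            "z": self.positions[:, 2],
            "kind": self.kind,
            "pair_id": [p if p is not None else "" for p in self.pair_id],
        })

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def _layout_from_frame(df: pd.DataFrame) -> SensorLayout:
    required = {"sensor_id", "x", "y", "z", "kind", "pair_id"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"layout CSV missing columns: {sorted(missing)}")
    pair = [None if (pd.isna(p) or p == "") else str(p) for p in df["pair_id"]]
    return SensorLayout(
        sensor_id=tuple(str(s) for s in df["sensor_id"]),
        positions=df[["x", "y", "z"]].to_numpy(dtype=float),
        kind=tuple(str(k) for k in df["kind"]),
        pair_id=tuple(pair),
    )


def hemisphere_layout(n_sites: int = 102, radius: float = 0.095,
                      seed: int = 0) -> SensorLayout:
    """Quasi-uniform helmet fixture: per site 1 mag + 2 paired grads.

    Sites are placed on the upper hemisphere of a sphere of the given
    radius (meters) by a Fibonacci lattice, which spaces ``n_sites`` points
    nearly uniformly. All three sensors of a site are co-located; the
    analysis distinguishes them by kind only.
    """
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    i = np.arange(n_sites)
    golden = (1 + np.sqrt(5)) / 2
    z = (i + 0.5) / n_sites            # upper hemisphere: z in (0, 1)
    theta = 2 * np.pi * i / golden
    r_xy = np.sqrt(1 - z**2)
    site_pos = radius * np.column_stack([r_xy * np.cos(theta),
                                         r_xy * np.sin(theta), z])
    ids, kinds, pair, pos = [], [], [], []
    for s in range(n_sites):
        for suffix, kind, pid in ((f"MAG{s:04d}", "mag", None),
                                  (f"GRD{s:04d}a", "grad", f"P{s:04d}"),
                                  (f"GRD{s:04d}b", "grad", f"P{s:04d}")):
            ids.append(suffix)
            kinds.append(kind)
            pair.append(pid)
            pos.append(site_pos[s])
    return SensorLayout(sensor_id=tuple(ids), positions=np.array(pos),
                        kind=tuple(kinds), pair_id=tuple(pair))


def make_sensor_layout(spec=None, **kwargs) -> SensorLayout:
    """Build a layout from a CSV path, a DataFrame, or the default fixture.

    ``spec=None`` returns the 306-sensor hemisphere fixture (102 sites);
    a string/Path is read as CSV with columns
    ``sensor_id,x,y,z,kind,pair_id``; a DataFrame is used directly.
    Extra keyword arguments are forwarded to :func:`hemisphere_layout`.
    """
    if spec is None:
        return hemisphere_layout(**kwargs)
    if isinstance(spec, pd.DataFrame):
        return _layout_from_frame(spec)
    return _layout_from_frame(pd.read_csv(spec, dtype={"pair_id": str}))
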