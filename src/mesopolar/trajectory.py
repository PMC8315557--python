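"""Trajectory containers shared by the RDME and particle engines."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np
import pandas as pd

__all__ = ["Trajectory"]


@dataclass
class Trajectory:
    """Time-stamped snapshots of a simulation.

    For RDME runs ``counts`` holds per-snapshot voxel occupancies with shape
    (T, S, n, n); for particle runs ``positions``/``position_species`` hold
    per-snapshot molecule coordinates.  ``totals`` (T, S) is always present.
    """

    times: np.ndarray
    species_names: tuple[str, ...]
    L: float
    totals: np.ndarray
    kind: str  # "rdme" | "particle"
    h: float | None = None
    counts: np.ndarray | None = None  # (T, S, n, n) voxel occupancies
    positions: list[np.ndarray] | None = None  # per snapshot (N_t, 2)
    position_species: list[np.ndarray] | None = None  # per snapshot (N_t,)
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("snapshot times must be strictly increasing")
        if self.totals.shape != (len(self.times), len(self.species_names)):
            raise ValueError("totals shape does not match times/species")

    # -- accessors -------------------------------------------------------

    def species_index(self, name: str) -> int:
        return self.species_names.index(name)

    def totals_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.totals, columns=list(self.species_names))
        df.insert(0, "time", self.times)
        return df

    def points_at(
        self,
        snapshot: int,
        species: Sequence[str] | None = None,
        rng: np.random.Generator | None = None,
    ) -> np.ndarray:
        """Molecule coordinates for one snapshot, shape (N, 2).

        Particle runs return the stored positions.  RDME runs return
        pseudo-coordinates: one point per molecule sampled uniformly within
        its voxel (presentation/analysis convention letting grid and particle
        output share one code path); pass ``rng`` for reproducibility.
        """
        if species is None:
            wanted = set(range(len(self.species_names)))
        else:
            wanted = {self.species_index(s) for s in species}
        if self.kind == "particle":
            sp = self.position_species[snapshot]
            mask = np.isin(sp, list(wanted))
            return self.positions[snapshot][mask]
        if self.counts is None:
            raise ValueError("RDME trajectory was recorded without voxel counts")
        rng = rng or np.random.default_rng()
        grid = self.counts[snapshot]
        n = grid.shape[-1]
        pts = []
        for s in wanted:
            occ = grid[s]
            iy, ix = np.nonzero(occ)
            reps = occ[iy, ix]
            cx = np.repeat(ix, reps).astype(float)
            cy = np.repeat(iy, reps).astype(float)
            if len(cx):
                jitter = rng.random((len(cx), 2))
                pts.append(
                    np.column_stack([(cx + jitter[:, 0]), (cy + jitter[:, 1])])
                    * self.h
                )
        if not pts:
            return np.empty((0, 2))
        return np.concatenate(pts, axis=0)

    # -- serialization ---------------------------------------------------

    def save(self, path) -> None:
        """Write to a .npz archive (arrays) with a JSON metadata block."""
        payload: dict[str, Any] = {
            "times": self.times,
            "totals": self.totals,
            "meta": np.frombuffer(
                json.dumps(
                    {
                        "species_names": list(self.species_names),
                        "L": self.L,
                        "h": self.h,
                        "kind": self.kind,
                        "metadata": self.metadata,
                    }
                ).encode(),
                dtype=np.uint8,
            ),
        }
        if self.counts is not None:
            payload["counts"] = self.counts
        if self.positions is not None:
            for i, (p, s) in enumerate(zip(self.positions, self.position_species)):
                payload[f"pos_{i}"] = p
                payload[f"psp_{i}"] = s
        np.savez_compressed(path, **payload)

    @classmethod
    def load(cls, path) -> "Trajectory":
        with np.load(path) as data:
            meta = json.loads(bytes(data["meta"].tobytes()).decode())
            positions = None
            position_species = None
            n_snap = len(data["times"])
            if "pos_0" in data:
                positions = [data[f"pos_{i}"] for i in range(n_snap)]
                position_species = [data[f"psp_{i}"] for i in range(n_snap)]
            return cls(
                times=data["times"],
                species_names=tuple(meta["species_names"]),
                L=meta["L"],
                totals=data["totals"],
                kind=meta["kind"],
                h=meta["h"],
                counts=data["counts"] if "counts" in data else None,
                positions=positions,
                position_species=position_species,
                metadata=meta["metadata"],
            )
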