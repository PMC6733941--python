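"""Per-vesicle donor/acceptor time series and their on-disk CSV format."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .fret import apparent_fret

__all__ = ["VesicleTrajectory"]


@dataclass
class VesicleTrajectory:
    """Donor/acceptor intensity time series for one vesicle.

    ``time`` is seconds from acquisition start, strictly increasing;
    channels are counts per frame and equal length. ``t0`` is the detergent
    injection time when known (synthetic data carries the truth value).
    """

    time: np.ndarray
    donor: np.ndarray
    acceptor: np.ndarray
    frame_dt: float
    t0: float | None = None
    vesicle_id: str = "vesicle-0"
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.donor = np.asarray(self.donor, dtype=float)
        self.acceptor = np.asarray(self.acceptor, dtype=float)
        if not (len(self.time) == len(self.donor) == len(self.acceptor)):
            raise ValueError("time/donor/acceptor must have equal length")
        if len(self.time) > 1 and not np.all(np.diff(self.time) > 0):
            raise ValueError("time must be strictly increasing")
        if self.frame_dt <= 0:
            raise ValueError("frame_dt must be positive")

    def __len__(self) -> int:
        return len(self.time)

    @property
    def total(self) -> np.ndarray:
        """Summed donor+acceptor intensity per frame."""
        return self.donor + self.acceptor

    @property
    def efficiency(self) -> np.ndarray:
        """Apparent FRET efficiency per frame (NaN where total <= 0)."""
        return apparent_fret(self.donor, self.acceptor)

    # ---------------------------------------------------------------- I/O
    def to_csv(self, path) -> None:
        """Write ``time_s, donor, acceptor`` CSV plus a JSON metadata sidecar."""
        path = Path(path)
        pd.DataFrame(
            {"time_s": self.time, "donor": self.donor, "acceptor": self.acceptor}
        ).to_csv(path, index=False)
        sidecar = {
            "frame_dt": self.frame_dt,
            "t0": self.t0,
            "vesicle_id": self.vesicle_id,
            "meta": _jsonable(self.meta),
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def from_csv(cls, path) -> "VesicleTrajectory":
        path = Path(path)
        df = pd.read_csv(path)
        sidecar_path = path.with_suffix(".json")
        frame_dt = None
        t0 = None
        vesicle_id = path.stem
        meta: dict = {}
        if sidecar_path.exists():
            sidecar = json.loads(sidecar_path.read_text())
            frame_dt = sidecar.get("frame_dt")
            t0 = sidecar.get("t0")
            vesicle_id = sidecar.get("vesicle_id", vesicle_id)
            meta = sidecar.get("meta", {})
        if frame_dt is None:
            frame_dt = float(np.median(np.diff(df["time_s"].to_numpy())))
        return cls(
            time=df["time_s"].to_numpy(),
            donor=df["donor"].to_numpy(),
            acceptor=df["acceptor"].to_numpy(),
            frame_dt=float(frame_dt),
            t0=t0,
            vesicle_id=vesicle_id,
            meta=meta,
        )


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj
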