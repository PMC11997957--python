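"""Source estimate container shared by the inverse solvers."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["SourceEstimate"]


@dataclass
class SourceEstimate:
    """Per-vertex source amplitudes on the template mesh.

    Parameters
    ----------
    data : (P, T) or (P,) float array
        Amplitudes in A·m.  eLORETA and MWE both emit signed values;
        magnitudes are taken only at evaluation time.
    vertices : (P,) int array
        Template-mesh vertex ids the rows refer to.
    times : (T,) float array or None
        Time axis in ms; ``None`` for single-time estimates.
    signed : bool
        Whether amplitudes carry dipole polarity.
    """

    data: np.ndarray
    vertices: np.ndarray
    times: np.ndarray | None = None
    signed: bool = True

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.vertices = np.asarray(self.vertices, dtype=np.int64)
        if self.data.shape[0] != len(self.vertices):
            raise ValueError("data rows must match vertex count")
        if self.times is not None:
            self.times = np.asarray(self.times, dtype=float)
            if self.data.ndim != 2 or self.data.shape[1] != len(self.times):
                raise ValueError("data columns must match time axis")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    def at_time(self, time_ms: float) -> "SourceEstimate":
        """Single-column estimate at the sample nearest ``time_ms``."""
        if self.times is None:
            raise ValueError("estimate has no time axis")
        idx = int(np.argmin(np.abs(self.times - time_ms)))
        return SourceEstimate(
            self.data[:, idx], self.vertices, times=None, signed=self.signed
        )

    def magnitude(self) -> np.ndarray:
        return np.abs(self.data)

    def to_hdf5(self, group) -> None:
        group.create_dataset("data", data=self.data)
        group.create_dataset("vertices", data=self.vertices)
        if self.times is not None:
            group.create_dataset("times", data=self.times)
        group.attrs["signed"] = self.signed

    @classmethod
    def from_hdf5(cls, group) -> "SourceEstimate":
        times = group["times"][()] if "times" in group else None
        return cls(
            group["data"][()],
            group["vertices"][()],
            times=times,
            signed=bool(group.attrs["signed"]),
        )
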