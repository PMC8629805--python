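"""Observation matrices: the empirical record of a system's microstate.

An :class:`ObservationMatrix` holds T time-samples of D real variates
together with an element map saying which columns belong to which
element (individual).  An element may own several variates, e.g. the
(vx, vy) velocity components of one fish.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

__all__ = ["ObservationMatrix", "rank_gaussianize"]


@dataclass
class ObservationMatrix:
    """T x D data matrix plus the element -> columns partition.

    Parameters
    ----------
    values : (T, D) array
        One row per time-sample, one column per variate.
    element_map : list of lists of int
        ``element_map[i]`` are the column indices owned by element ``i``.
        Every column must belong to exactly one element.
    column_names : optional list of str, length D.
    units : free-form unit string recorded on serialization.
    """

    values: np.ndarray = field(repr=False)
    element_map: list[list[int]]
    column_names: list[str] | None = None
    units: str = "arbitrary"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a T x D matrix")
        T, D = self.values.shape
        if T < 2:
            raise ValueError(f"need at least 2 time-samples, got {T}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("values contain non-finite entries")
        self.element_map = [list(map(int, cols)) for cols in self.element_map]
        claimed = sorted(c for cols in self.element_map for c in cols)
        if claimed != list(range(D)):
            raise ValueError(
                "element_map must assign every column to exactly one element"
            )
        if self.column_names is not None and len(self.column_names) != D:
            raise ValueError("column_names length must equal D")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_variates(self) -> int:
        return self.values.shape[1]

    @property
    def n_elements(self) -> int:
        return len(self.element_map)

    def element_sizes(self) -> list[int]:
        """k_i: number of variates per element."""
        return [len(cols) for cols in self.element_map]

    # ------------------------------------------------------------------
    # CSV + JSON sidecar round trip
    # ------------------------------------------------------------------

    def to_csv(self, path: str | Path) -> None:
        """Write the data as CSV with a ``<path>.meta.json`` sidecar."""
        path = Path(path)
        names = self.column_names or [f"v{c}" for c in range(self.n_variates)]
        pd.DataFrame(self.values, columns=names).to_csv(path, index=False)
        sidecar = {
            "element_map": self.element_map,
            "units": self.units,
            "column_names": names,
        }
        Path(str(path) + ".meta.json").write_text(json.dumps(sidecar, indent=1))

    @classmethod
    def from_csv(cls, path: str | Path) -> "ObservationMatrix":
        path = Path(path)
        meta = json.loads(Path(str(path) + ".meta.json").read_text())
        frame = pd.read_csv(path)
        return cls(
            values=frame.to_numpy(dtype=float),
            element_map=meta["element_map"],
            column_names=meta.get("column_names"),
            units=meta.get("units", "arbitrary"),
        )


def rank_gaussianize(obs: ObservationMatrix) -> ObservationMatrix:
    """Map every column to standard-normal quantiles by rank.

    Each output column is the monotone transform of its input column
    whose empirical distribution matches N(0, 1): value with (average)
    rank k among T maps to ``Phi^{-1}((k - 1/2) / T)``.  The output is
    therefore invariant under any strictly increasing per-column
    transform of the input, which is what makes the Gaussian
    mutual-information term a lower bound for arbitrary continuous
    marginals.

    Raises
    ------
    ValueError
        If a column is constant — its rank transform is undefined.
    """
    T = obs.n_samples
    out = np.empty_like(obs.values)
    for c in range(obs.n_variates):
        col = obs.values[:, c]
        if np.ptp(col) == 0.0:
            name = obs.column_names[c] if obs.column_names else f"column {c}"
            raise ValueError(
                f"{name} is constant; rank-Gaussianization undefined"
            )
        ranks = rankdata(col, method="average")
        out[:, c] = norm.ppf((ranks - 0.5) / T)
    return ObservationMatrix(
        values=out,
        element_map=[list(cols) for cols in obs.element_map],
        column_names=list(obs.column_names) if obs.column_names else None,
        units="standard-normal quantiles",
    )
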