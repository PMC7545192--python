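"""Density scale adjusted metrics (DSAMs).

A DSAM is the residual of one region's log indicator density from the
selected scaling law, z = log10 y - log10 yhat(d).  A positive z means the
region exceeds its scaling expectation for its population density; residuals
are mean-zero per indicator by the OLS property.  Cells excluded from the
fit (zero counts) stay missing in the DSAM matrix and downstream similarity
computations use pairwise-complete observations.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .data_io import DensityMatrix
from .scaling import FitTable


class MissingFitError(KeyError):
    """An indicator in the density matrix has no corresponding fit."""


@dataclass
class DsamMatrix:
    """Regions x indicators matrix of scaling residuals.

    ``z.index`` are regions and ``z.columns`` indicators in the primary
    orientation; :meth:`transpose_view` exchanges the roles (for analyses by
    region instead of by indicator).
    """

    z: pd.DataFrame

    @property
    def regions(self) -> list[str]:
        return list(self.z.index)

    @property
    def indicators(self) -> list[str]:
        return list(self.z.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.z.shape

    def transpose_view(self) -> "DsamMatrix":
        """Exchange the roles of regions and indicators (pure relabelling)."""
        return DsamMatrix(z=self.z.T)

    def write_csv(self, path: str | Path) -> None:
        self.z.to_csv(path)

    @classmethod
    def read_csv(cls, path: str | Path) -> "DsamMatrix":
        return cls(z=pd.read_csv(path, index_col=0))


def compute_dsams(dm: DensityMatrix, fits: FitTable) -> DsamMatrix:
    """Residuals from the *selected* model of each indicator.

    Every indicator present in the density matrix must have a fit; missing
    cells (zero counts, zero density) propagate as NaN.
    """
    missing = [name for name in dm.indicators if name not in fits.fits]
    if missing:
        raise MissingFitError(f"no fit for indicator(s): {missing}")
    cols = {}
    x = dm.log_d.to_numpy()
    for name in dm.indicators:
        y = dm.log_y[name].to_numpy()
        z = np.where(np.isfinite(x) & np.isfinite(y), y - fits[name].predict(x), np.nan)
        cols[name] = z
    return DsamMatrix(z=pd.DataFrame(cols, index=dm.region_id))


def transpose_view(zm: DsamMatrix) -> DsamMatrix:
    """Module-level alias of :meth:`DsamMatrix.transpose_view`."""
    return zm.transpose_view()
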