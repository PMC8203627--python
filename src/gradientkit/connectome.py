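"""Functional connectome construction from parcel time series.

Pearson correlation of regional signals, Fisher r-to-z, group averaging,
and row-wise density thresholding (each region keeps its strongest
connections, the convention of spectral gradient workflows).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "RegionTimeSeries",
    "ConnectivityMatrix",
    "correlation_connectome",
    "group_average_connectome",
    "threshold_by_density",
]

#: |r| is clipped here before atanh so degenerate (perfectly correlated)
#: inputs stay finite.
R_CLIP = 1.0 - 1e-7


@dataclass
class RegionTimeSeries:
    """Parcel x timepoint signal matrix for one subject."""

    values: np.ndarray
    subject_id: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, float)
        if self.values.ndim != 2:
            raise ValueError("time series must be 2-D (parcels x timepoints)")
        if self.values.shape[1] < 2:
            raise ValueError("need at least 2 timepoints")
        if np.isnan(self.values).any():
            raise ValueError("time series contains NaN")


@dataclass
class ConnectivityMatrix:
    """Symmetric parcel x parcel Fisher-z connectome.

    After row-wise thresholding the matrix may be asymmetric;
    ``is_thresholded`` flags that state and ``density`` records the
    retained fraction.
    """

    values: np.ndarray
    density: float = 1.0
    is_thresholded: bool = False
    subject_id: str = ""

    @property
    def n_parcels(self) -> int:
        return self.values.shape[0]


def correlation_connectome(ts: RegionTimeSeries) -> ConnectivityMatrix:
    """Pearson correlation matrix with Fisher r-to-z, zero diagonal.

    Raises if any parcel has zero variance (correlation undefined).
    """
    x = ts.values
    if x.shape[1] < 3:
        raise ValueError("need at least 3 timepoints for a stable correlation")
    sd = x.std(axis=1)
    dead = np.flatnonzero(sd == 0)
    if dead.size:
        raise ValueError(f"zero-variance parcel(s): {dead.tolist()}")
    r = np.corrcoef(x)
    r = np.clip(r, -R_CLIP, R_CLIP)
    z = np.arctanh(r)
    np.fill_diagonal(z, 0.0)
    z = (z + z.T) / 2.0  # enforce exact symmetry against fp noise
    return ConnectivityMatrix(values=z, subject_id=ts.subject_id)


def group_average_connectome(connectomes) -> ConnectivityMatrix:
    """Entrywise mean of unthresholded connectomes."""
    connectomes = list(connectomes)
    if not connectomes:
        raise ValueError("no connectomes given")
    shape = connectomes[0].values.shape
    for c in connectomes:
        if c.values.shape != shape:
            raise ValueError("connectome shape mismatch")
        if c.is_thresholded:
            raise ValueError("group average expects unthresholded connectomes")
    mean = np.mean([c.values for c in connectomes], axis=0)
    np.fill_diagonal(mean, 0.0)
    return ConnectivityMatrix(values=mean, subject_id="group")


def threshold_by_density(C: ConnectivityMatrix, density: float) -> ConnectivityMatrix:
    """Keep each row's top ``ceil(density * (n-1))`` off-diagonal entries.

    Ranking is by signed value (strong negatives are dropped, per the
    gradient-workflow convention); ties at the cut-off are all retained,
    so the rule is deterministic without an ordering assumption. The
    result may be asymmetric and is flagged ``is_thresholded``.
    """
    if not 0.0 < density <= 1.0:
        raise ValueError(f"density must be in (0, 1], got {density}")
    W = C.values.copy()
    n = W.shape[0]
    k = int(np.ceil(density * (n - 1)))
    off = ~np.eye(n, dtype=bool)
    for i in range(n):
        row = W[i]
        vals = row[off[i]]
        cut = np.sort(vals)[-k]  # k-th largest off-diagonal value
        keep = (row >= cut) & off[i]
        row[~keep] = 0.0
    return ConnectivityMatrix(
        values=W, density=density, is_thresholded=True, subject_id=C.subject_id
    )
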