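"""Parcel time series -> Fisher-z functional connectivity.

The recipe is the standard one for resting-state segregation analyses:
average the signal across member units of each parcel, correlate every
pair of parcel series over time (Pearson), Fisher z-transform, and remove
negative z-values.  "Remove" is implemented as exclusion from subsequent
means via a validity mask, not truncation to zero — the two differ in the
denominator of every downstream mean, and exclusion is order-invariant
with respect to the within/between split.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .parcellation import ParcellationMap

__all__ = [
    "ZConnectivity",
    "parcel_average",
    "correlation_matrix",
    "fisher_z",
    "ConnectivityExtractor",
]


@dataclass
class ZConnectivity:
    """Per-subject symmetric Fisher-z connectivity with a validity mask.

    ``valid_mask`` is False wherever an edge was removed (negative z) and
    always False on the diagonal — self-correlation is not an edge.
    """

    subject_id: str
    z: np.ndarray
    valid_mask: np.ndarray

    def __post_init__(self) -> None:
        z = np.asarray(self.z, dtype=float)
        m = np.asarray(self.valid_mask, dtype=bool)
        if z.ndim != 2 or z.shape[0] != z.shape[1]:
            raise ValueError("z must be a square matrix")
        if m.shape != z.shape:
            raise ValueError("valid_mask shape must match z")
        if not np.allclose(z, z.T, equal_nan=True):
            raise ValueError("z must be symmetric")
        if not np.array_equal(m, m.T):
            raise ValueError("valid_mask must be symmetric")
        off = ~np.eye(z.shape[0], dtype=bool)
        if np.any(m & off & (z < 0)):
            raise ValueError("valid_mask must be False wherever z < 0")
        m = m & off  # diagonal never used in any mean
        self.z = z
        self.valid_mask = m

    @property
    def n_parcels(self) -> int:
        return self.z.shape[0]

    def drop_parcels(self, drop: np.ndarray) -> "ZConnectivity":
        """Return a copy with parcels in boolean mask ``drop`` removed."""
        keep = ~np.asarray(drop, dtype=bool)
        return ZConnectivity(
            self.subject_id, self.z[np.ix_(keep, keep)], self.valid_mask[np.ix_(keep, keep)]
        )

    # -- IO ----------------------------------------------------------------
    def to_tsv(self, path) -> None:
        """Square TSV; removed edges (and the diagonal) as the token ``NA``."""
        out = self.z.astype(object)
        out[~self.valid_mask] = "NA"
        pd.DataFrame(out).to_csv(path, sep="\t", index=False, header=False)

    @classmethod
    def from_tsv(cls, path, subject_id: str = "") -> "ZConnectivity":
        raw = pd.read_csv(path, sep="\t", header=None, na_values=["NA"]).to_numpy(float)
        mask = ~np.isnan(raw)
        z = np.where(mask, raw, 0.0)
        z = (z + z.T) / 2.0  # NA entries are symmetric, so this is exact
        return cls(subject_id, z, mask)


def parcel_average(series: np.ndarray, membership: np.ndarray) -> np.ndarray:
    """Average unit (vertex/voxel) rows into parcel rows.

    Parameters
    ----------
    series
        ``(n_units, n_timepoints)`` signal matrix.
    membership
        Parcel index per unit; parcels are ``0..max``.

    Returns
    -------
    ``(n_parcels, n_timepoints)`` matrix whose row ``p`` is the unweighted
    mean of the member rows of parcel ``p``.
    """
    series = np.asarray(series, dtype=float)
    membership = np.asarray(membership, dtype=int)
    if series.ndim != 2 or len(membership) != series.shape[0]:
        raise ValueError("membership length must equal number of unit rows")
    n_parcels = int(membership.max()) + 1
    counts = np.bincount(membership, minlength=n_parcels)
    empty = np.flatnonzero(counts == 0)
    if empty.size:
        raise ValueError(f"parcels with no member units: {empty.tolist()}")
    out = np.zeros((n_parcels, series.shape[1]))
    np.add.at(out, membership, series)
    return out / counts[:, None]


def correlation_matrix(series: np.ndarray) -> np.ndarray:
    """Pearson correlation across time between every pair of parcel rows."""
    series = np.asarray(series, dtype=float)
    if series.ndim != 2 or series.shape[1] < 3:
        raise ValueError("need a parcel x time matrix with >= 3 timepoints")
    sd = series.std(axis=1)
    dead = np.flatnonzero(sd == 0)
    if dead.size:
        raise ValueError(f"zero-variance parcel series: {dead.tolist()}")
    r = np.corrcoef(series)
    return np.clip(r, -1.0, 1.0)


def fisher_z(r: np.ndarray, subject_id: str = "") -> ZConnectivity:
    """Fisher z-transform a correlation matrix and mask negative edges.

    z = atanh(r) off-diagonal; the validity mask retains z >= 0 (a zero
    correlation survives).  Perfect off-diagonal correlation is rejected:
    its z is infinite and would dominate any mean.
    """
    r = np.asarray(r, dtype=float)
    off = ~np.eye(r.shape[0], dtype=bool)
    if np.any(np.abs(r[off]) >= 1.0):
        raise ValueError("off-diagonal |r| >= 1: perfectly correlated parcels")
    z = np.zeros_like(r)
    z[off] = np.arctanh(r[off])
    mask = off & (z >= 0.0)
    return ZConnectivity(subject_id, z, mask)


class ConnectivityExtractor(TransformerMixin, BaseEstimator):
    """Transform parcel time series into Fisher-z connectivity matrices.

    ``transform`` accepts an array ``(n_subjects, n_parcels, n_timepoints)``
    (or a list of per-subject matrices) and returns one
    :class:`ZConnectivity` per subject.  When a parcellation is supplied,
    excluded ("none network") parcels are dropped *before* correlation so
    they cannot leak into between-network means.
    """

    def __init__(self, parcellation: ParcellationMap | None = None):
        self.parcellation = parcellation

    def fit(self, X, y=None):  # noqa: D102 — stateless, sklearn protocol
        self._validate(X)
        self.n_features_in_ = np.asarray(X[0]).shape[0]
        return self

    def transform(self, X) -> list[ZConnectivity]:  # noqa: D102
        self._validate(X)
        excl = None
        if self.parcellation is not None:
            excl = self.parcellation.excluded
        out = []
        for i, series in enumerate(X):
            series = np.asarray(series, dtype=float)
            if excl is not None:
                if series.shape[0] != excl.size:
                    raise ValueError(
                        f"subject {i}: {series.shape[0]} parcels, "
                        f"parcellation has {excl.size}"
                    )
                series = series[~excl]
            out.append(fisher_z(correlation_matrix(series), subject_id=str(i)))
        return out

    @staticmethod
    def _validate(X) -> None:
        if len(X) == 0:
            raise ValueError("no subjects")
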