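"""Parcel-to-network assignment.

A parcellation map assigns each cortical parcel to exactly one named
functional network (or to no network, in which case the parcel is excluded
from all connectivity summaries).  The map defines the within/between edge
classes that the segregation index is built on.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

#: label used for parcels assigned to no functional network
NONE_NETWORK = "none"


@dataclass(frozen=True)
class ParcellationMap:
    """Assignment of parcels ``0..n-1`` to named functional networks.

    Parameters
    ----------
    network_labels
        One label per parcel.  Parcels labelled :data:`NONE_NETWORK` are
        excluded from every connectivity summary.
    """

    network_labels: tuple[str, ...]
    _index: dict[str, np.ndarray] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        labels = np.asarray(self.network_labels, dtype=object)
        idx = {
            str(lab): np.flatnonzero(labels == lab)
            for lab in dict.fromkeys(self.network_labels)  # preserve order
        }
        object.__setattr__(self, "_index", idx)

    # -- basic queries -----------------------------------------------------
    @property
    def n_parcels(self) -> int:
        return len(self.network_labels)

    @property
    def networks(self) -> list[str]:
        """Network names in first-appearance order, excluded label omitted."""
        return [lab for lab in self._index if lab != NONE_NETWORK]

    @property
    def excluded(self) -> np.ndarray:
        """Boolean mask of parcels assigned to no network."""
        return np.asarray([lab == NONE_NETWORK for lab in self.network_labels])

    def parcels_of(self, network: str) -> np.ndarray:
        """Parcel indices belonging to ``network``."""
        try:
            return self._index[network]
        except KeyError:
            raise KeyError(f"unknown network {network!r}") from None

    def network_sizes(self) -> dict[str, int]:
        return {lab: len(self.parcels_of(lab)) for lab in self.networks}

    def labels_array(self) -> np.ndarray:
        return np.asarray(self.network_labels, dtype=object)

    # -- IO ----------------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "parcel_id": np.arange(self.n_parcels),
                "network_label": list(self.network_labels),
            }
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "ParcellationMap":
        df = pd.read_csv(path, sep="\t")
        missing = {"parcel_id", "network_label"} - set(df.columns)
        if missing:
            raise ValueError(f"parcellation TSV missing columns: {sorted(missing)}")
        df = df.sort_values("parcel_id")
        if not np.array_equal(df["parcel_id"].to_numpy(), np.arange(len(df))):
            raise ValueError("parcel_id must be 0..n-1 with no gaps")
        return cls(tuple(str(x) for x in df["network_label"]))


def make_parcellation(
    network_sizes: Sequence[int], labels: Sequence[str]
) -> ParcellationMap:
    """Build a parcellation with ``network_sizes[k]`` contiguous parcels per label.

    Raises
    ------
    ValueError
        If lengths mismatch, labels repeat, or a size is < 1.
    """
    if len(network_sizes) != len(labels):
        raise ValueError(
            f"got {len(network_sizes)} sizes but {len(labels)} labels"
        )
    if len(set(labels)) != len(labels):
        raise ValueError(f"duplicate network labels in {list(labels)}")
    sizes = [int(s) for s in network_sizes]
    if any(s < 1 for s in sizes):
        raise ValueError("every network size must be >= 1")
    out: list[str] = []
    for size, lab in zip(sizes, labels):
        out.extend([str(lab)] * size)
    return ParcellationMap(tuple(out))


def classify_networks(
    networks: Sequence[str], class_map: Mapping[str, str]
) -> dict[str, str]:
    """Validate and return the network -> class assignment for ``networks``."""
    missing = [n for n in networks if n not in class_map]
    if missing:
        raise ValueError(f"networks without class assignment: {missing}")
    return {n: class_map[n] for n in networks}
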