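"""Network segregation index and its gray-matter-partialized variants.

For each functional network the index is

    segregation = (Zw - Zb) / Zw

where Zw is the mean Fisher-z connectivity among parcels of the network
(within-network FC) and Zb the mean from that network to all parcels of
other networks (between-network FC).  A value of 1 means a fully
segregated network (no between-network connectivity); 0 means no
within/between distinction.

Both means are built as the mean over the network's parcels of the
parcel-level means zW_i / zB_i (mean of means).  The parcel-level profile
is what the partialization regression consumes: per subject, zW_i (and
separately zB_i) is regressed on a per-parcel gray-matter covariate R_i
(cortical thickness or a T1w/T2w myelin proxy) pooled across the whole
cortical surface, and the slope-adjusted series
PFC_i = y_i - beta1 * (R_i - mean(R)) replaces y_i before the network
means and the index are recomputed.  This removes the component of
connectivity that is linearly explained by local gray-matter structure
while preserving the grand FC level.

Undefined quantities (a parcel with no retained edges, a network with
Zw = 0) are flagged as NaN in the output tables and logged — never
silently imputed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .connectivity import ZConnectivity
from .parcellation import ParcellationMap

__all__ = [
    "parcel_fc_profile",
    "network_summary",
    "aggregate_class",
    "partialize",
    "PartialFit",
    "NetworkSegregation",
]

logger = logging.getLogger(__name__)

VARIANTS = ("raw", "partial_thickness", "partial_myelin")


def _align_labels(z: ZConnectivity, parcellation: ParcellationMap) -> np.ndarray:
    """Network label per row of ``z``, tolerating pre-dropped excluded parcels."""
    labels = parcellation.labels_array()
    excl = parcellation.excluded
    if z.n_parcels == labels.size:
        if excl.any():
            raise ValueError(
                "z still contains excluded parcels; drop them before profiling"
            )
        return labels
    if z.n_parcels == (~excl).sum():
        return labels[~excl]
    raise ValueError(
        f"z has {z.n_parcels} parcels; parcellation has {labels.size} "
        f"({(~excl).sum()} after exclusion)"
    )


def _masked_row_means(z: np.ndarray, mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    counts = mask.sum(axis=1)
    sums = np.where(mask, z, 0.0).sum(axis=1)
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return means, counts


def parcel_fc_profile(
    z: ZConnectivity, parcellation: ParcellationMap
) -> pd.DataFrame:
    """Per-parcel mean retained z to same-network and other-network parcels.

    Returns a DataFrame with columns ``parcel_id``, ``network_label``,
    ``zW``, ``zB``, ``n_within_edges``, ``n_between_edges``.  A parcel with
    zero retained edges in a class gets NaN there and a log message.
    """
    labels = _align_labels(z, parcellation)
    networks = [lab for lab in dict.fromkeys(labels)]
    if len(networks) < 2:
        raise ValueError("segregation needs >= 2 networks")
    same = labels[:, None] == labels[None, :]
    w_mask = z.valid_mask & same
    b_mask = z.valid_mask & ~same
    zW, nW = _masked_row_means(z.z, w_mask)
    zB, nB = _masked_row_means(z.z, b_mask)
    for i in np.flatnonzero(nW == 0):
        logger.warning(
            "subject %s parcel %d: no retained within-network edges", z.subject_id, i
        )
    for i in np.flatnonzero(nB == 0):
        logger.warning(
            "subject %s parcel %d: no retained between-network edges", z.subject_id, i
        )
    return pd.DataFrame(
        {
            "subject_id": z.subject_id,
            "parcel_id": np.arange(z.n_parcels),
            "network_label": labels,
            "zW": zW,
            "zB": zB,
            "n_within_edges": nW,
            "n_between_edges": nB,
        }
    )


def _segregation(zw: float, zb: float) -> float:
    if not np.isfinite(zw) or not np.isfinite(zb) or zw == 0.0:
        return np.nan
    return (zw - zb) / zw


def network_summary(
    profiles: pd.DataFrame, variant: str = "raw"
) -> pd.DataFrame:
    """Network-level within/between FC and segregation from a parcel profile.

    Zw(network) is the mean of defined zW_i over its parcels; likewise Zb.
    ``segregation = (Zw - Zb)/Zw``, NaN-flagged (and logged) when Zw = 0 or
    a mean is undefined.
    """
    if variant not in VARIANTS:
        raise ValueError(f"variant must be one of {VARIANTS}")
    rows = []
    for (subject, network), grp in profiles.groupby(
        ["subject_id", "network_label"], sort=False
    ):
        zw = float(grp["zW"].mean())  # pandas mean skips NaN parcels
        zb = float(grp["zB"].mean())
        seg = _segregation(zw, zb)
        if np.isnan(seg):
            logger.warning(
                "subject %s network %s: segregation undefined (Zw=%r, Zb=%r)",
                subject, network, zw, zb,
            )
        rows.append(
            {
                "subject_id": subject,
                "network_label": network,
                "variant": variant,
                "Z_within": zw,
                "Z_between": zb,
                "segregation": seg,
            }
        )
    return pd.DataFrame(rows)


def aggregate_class(
    summaries: pd.DataFrame, class_map: Mapping[str, str]
) -> pd.DataFrame:
    """Average network segregation into classes (sensorimotor / associative).

    Unweighted mean over the networks of each class, per subject and
    variant.  A class whose networks are all undefined stays NaN.
    """
    missing = sorted(set(summaries["network_label"]) - set(class_map))
    if missing:
        raise ValueError(f"networks without class assignment: {missing}")
    if not set(class_map.values()):
        raise ValueError("empty class map")
    df = summaries.copy()
    df["network_class"] = df["network_label"].map(class_map)
    out = (
        df.groupby(["subject_id", "variant", "network_class"], sort=False)[
            "segregation"
        ]
        .mean()
        .reset_index()
    )
    for _, row in out[out["segregation"].isna()].iterrows():
        logger.warning(
            "subject %s class %s (%s): aggregate segregation undefined",
            row["subject_id"], row["network_class"], row["variant"],
        )
    return out


@dataclass
class PartialFit:
    """OLS fit of a parcel FC profile on a gray-matter covariate.

    ``pfc`` holds PFC_i = y_i - beta1 * R_i per included parcel (intercept
    retained); ``included`` marks parcels with a defined target value.
    """

    subject_id: str
    covariate: str
    target: str
    beta0: float
    beta1: float
    pfc: np.ndarray
    included: np.ndarray
    y_mean: float

    def residual_mean(self) -> float:
        """Mean of e_i = y_i - beta0 - beta1*R_i over included parcels (~0)."""
        return float(np.mean(self.pfc[self.included] - self.y_mean))


def partialize(
    profiles: pd.DataFrame,
    gm: np.ndarray,
    target: str,
    covariate_name: str = "thickness",
) -> PartialFit:
    """Regress parcel-level FC on a gray-matter covariate, whole surface pooled.

    Parameters
    ----------
    profiles
        One subject's parcel profile (from :func:`parcel_fc_profile`).
    gm
        Per-parcel covariate R_i, aligned with the profile rows.
    target
        ``"within"`` (y_i = zW_i) or ``"between"`` (y_i = zB_i).

    The regression y_i = beta0 + beta1*R_i + e_i is ordinary least squares
    over all parcels with a defined target, pooled across networks.  The
    partialized value removes the slope contribution about the covariate
    mean, PFC_i = y_i - beta1*(R_i - mean(R)), which preserves the grand
    FC level (mean PFC = mean y) while eliminating the per-parcel
    gray-matter dependence; a zero slope reproduces y_i exactly.  Negative
    PFC_i arising from residualization are retained: negative-edge removal
    happened upstream on edges, and residualization defines no second
    removal.
    """
    if target not in ("within", "between"):
        raise ValueError("target must be 'within' or 'between'")
    y = profiles["zW" if target == "within" else "zB"].to_numpy(float)
    gm = np.asarray(gm, dtype=float)
    if gm.shape[0] != y.shape[0]:
        raise ValueError(
            f"gm covariate has {gm.shape[0]} parcels, profile has {y.shape[0]}"
        )
    included = np.isfinite(y)
    if included.sum() < 3:
        raise ValueError("need >= 3 parcels with a defined target value")
    r_inc = gm[included]
    if np.ptp(r_inc) == 0:
        raise ValueError("constant gray-matter covariate: slope unidentifiable")
    X = np.column_stack([np.ones(included.sum()), r_inc])
    beta, *_ = np.linalg.lstsq(X, y[included], rcond=None)
    beta0, beta1 = float(beta[0]), float(beta[1])
    r_mean = float(r_inc.mean())
    pfc = np.where(included, y - beta1 * (gm - r_mean), np.nan)
    subject = str(profiles["subject_id"].iloc[0]) if len(profiles) else ""
    return PartialFit(
        subject, covariate_name, target, beta0, beta1, pfc, included,
        y_mean=float(y[included].mean()),
    )


def partialized_profile(
    profiles: pd.DataFrame, gm: np.ndarray, covariate_name: str = "thickness"
) -> pd.DataFrame:
    """Replace zW/zB by their partialized values (both targets regressed)."""
    out = profiles.copy()
    for target, col in (("within", "zW"), ("between", "zB")):
        fit = partialize(profiles, gm, target, covariate_name)
        out[col] = fit.pfc
    return out


class NetworkSegregation(TransformerMixin, BaseEstimator):
    """Per-subject, per-network segregation from Fisher-z connectivity.

    Parameters
    ----------
    parcellation
        Parcel-to-network map (excluded parcels allowed; connectivity must
        already have them dropped).
    variant
        ``"raw"``, ``"partial_thickness"`` or ``"partial_myelin"``.  The
        partial variants require ``gm`` at transform time.
    class_map
        Optional network -> class map; when given, ``transform`` also
        attaches class-aggregated segregation.

    ``transform`` takes a sequence of :class:`ZConnectivity` (and, for the
    partial variants, a per-subject array of per-parcel covariates) and
    returns the tidy network summary table.
    """

    def __init__(
        self,
        parcellation: ParcellationMap,
        variant: str = "raw",
        class_map: Mapping[str, str] | None = None,
    ):
        self.parcellation = parcellation
        self.variant = variant
        self.class_map = class_map

    def fit(self, X, y=None):  # noqa: D102 — stateless, sklearn protocol
        if self.variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}")
        self.networks_ = self.parcellation.networks
        return self

    def transform(
        self, X: Sequence[ZConnectivity], gm: np.ndarray | None = None
    ) -> pd.DataFrame:  # noqa: D102
        if self.variant != "raw" and gm is None:
            raise ValueError(f"variant {self.variant!r} needs gm covariates")
        covariate = self.variant.removeprefix("partial_")
        tables = []
        for i, z in enumerate(X):
            prof = parcel_fc_profile(z, self.parcellation)
            if self.variant != "raw":
                prof = partialized_profile(prof, np.asarray(gm)[i], covariate)
            tables.append(network_summary(prof, variant=self.variant))
        return pd.concat(tables, ignore_index=True)

    def class_summary(self, summaries: pd.DataFrame) -> pd.DataFrame:
        """Aggregate a transform() result into sensorimotor/associative classes."""
        if self.class_map is None:
            raise ValueError("no class_map configured")
        return aggregate_class(summaries, self.class_map)
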