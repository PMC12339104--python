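"""Synthetic inputs with known ground truth.

Everything the pipeline consumes can be generated here with a planted,
recoverable structure:

* block-modular BOLD-like time series whose population correlation is
  ``r_within`` inside network blocks and ``r_between`` elsewhere,
  optionally AR(1)-filtered in time (the stationary correlation is
  preserved exactly);
* per-parcel gray-matter covariates (cortical-thickness-like and
  T1w/T2w-myelin-like), and an optional planted linear contamination of
  the connectivity matrix by such a covariate — the ground truth against
  which partialization is judged;
* phenotype tables whose marginal scales emulate a late-middle-aged
  metabolic-risk cohort (insulin, glucose, lipids, blood pressure,
  anthropometry, APOE carrier status coded as a binary indicator:
  no epsilon-2 carriers, no epsilon-4 homozygotes);
* trial-level navigation records (drop error per subtask) drawn from a
  linear mixed model on a Box-Cox-transformed scale with a participant
  random intercept, with every planted coefficient returned alongside.

The generators draw from a multivariate normal with the exact block
correlation as covariance; no hemodynamic model is used because the
downstream index only consumes second-order structure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .connectivity import ZConnectivity
from .inference import box_cox_inverse, zscore
from .metabolic import MetabolicScores
from .parcellation import ParcellationMap, make_parcellation

__all__ = [
    "SimConfig",
    "TrialGenConfig",
    "block_correlation",
    "simulate_bold",
    "simulate_gm_covariates",
    "contaminate_fc",
    "simulate_phenotypes",
    "simulate_trials",
    "model_terms",
]

logger = logging.getLogger(__name__)


def block_correlation(
    network_sizes: tuple[int, ...], r_within: float, r_between: float
) -> np.ndarray:
    """Block correlation matrix: r_within inside blocks, r_between elsewhere.

    Raises a constructive error if the matrix is not positive
    semi-definite — silent clipping would corrupt every downstream
    recovery check.
    """
    n = int(sum(network_sizes))
    corr = np.full((n, n), float(r_between))
    start = 0
    for size in network_sizes:
        corr[start : start + size, start : start + size] = float(r_within)
        start += size
    np.fill_diagonal(corr, 1.0)
    min_eig = float(np.linalg.eigvalsh(corr).min())
    if min_eig < -1e-10:
        raise ValueError(
            f"block correlation not PSD (min eigenvalue {min_eig:.3g}) for "
            f"r_within={r_within}, r_between={r_between}, sizes={network_sizes}"
        )
    return corr


@dataclass(frozen=True)
class SimConfig:
    """Configuration of the block-modular BOLD generator.

    ``n_timepoints`` defaults to 250 — a typical single-run resting-state
    acquisition length.  ``ar1`` is the lag-one temporal autocorrelation;
    the innovations are scaled so the stationary spatial correlation still
    equals the block matrix exactly.
    """

    n_subjects: int
    network_sizes: tuple[int, ...]
    n_timepoints: int = 250
    r_within: float = 0.5
    r_between: float = 0.1
    ar1: float = 0.0
    gm_contamination_slope: float = 0.0
    seed: int = 0
    labels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if any(s < 2 for s in self.network_sizes):
            raise ValueError(
                "every network needs >= 2 parcels (a singleton has no within edges)"
            )
        if not (0.0 <= self.r_between < self.r_within < 1.0):
            raise ValueError("need 0 <= r_between < r_within < 1")
        if not (0.0 <= self.ar1 < 1.0):
            raise ValueError("ar1 must be in [0, 1)")
        if self.n_timepoints < 3:
            raise ValueError("n_timepoints must be >= 3")
        block_correlation(self.network_sizes, self.r_within, self.r_between)

    @property
    def n_parcels(self) -> int:
        return int(sum(self.network_sizes))

    def parcellation(self) -> ParcellationMap:
        labels = self.labels or tuple(
            f"N{k}" for k in range(len(self.network_sizes))
        )
        return make_parcellation(self.network_sizes, labels)


def simulate_bold(cfg: SimConfig) -> tuple[np.ndarray, np.ndarray]:
    """Draw per-subject parcel x time series with the configured block structure.

    Returns ``(series, corr)`` where ``series`` has shape
    ``(n_subjects, n_parcels, n_timepoints)`` and ``corr`` is the ground-
    truth population correlation matrix.  Fully reproducible from the seed.
    """
    corr = block_correlation(cfg.network_sizes, cfg.r_within, cfg.r_between)
    L = np.linalg.cholesky(corr + 1e-12 * np.eye(cfg.n_parcels))
    rng = np.random.default_rng(cfg.seed)
    p, T = cfg.n_parcels, cfg.n_timepoints
    e = rng.standard_normal((cfg.n_subjects, T, p)) @ L.T  # (S, T, p), cov=corr
    if cfg.ar1 > 0.0:
        phi = cfg.ar1
        x = np.empty_like(e)
        x[:, 0] = e[:, 0]
        scale = np.sqrt(1.0 - phi * phi)
        for t in range(1, T):
            x[:, t] = phi * x[:, t - 1] + scale * e[:, t]
        e = x
    return np.swapaxes(e, 1, 2), corr  # (S, p, T)


#: per-covariate (center, shared-topography log-SD, subject-noise log-SD).
#: Centers sit at plausible magnitudes (~2.5 mm thickness, ~1.5 T1w/T2w).
#: The dispersions are deliberately modest: the covariates exist to carry a
#: *planted linear* contamination of connectivity, and the perturbation
#: must stay small against the between-network z-level or the negative-
#: edge mask churns and the planted model stops being linear (see
#: docs/methods.md).
GM_PROFILES: dict[str, tuple[float, float, float]] = {
    "thickness": (2.5, 0.03, 0.015),
    "myelin": (1.5, 0.025, 0.012),
}


def simulate_gm_covariates(
    parcellation: ParcellationMap,
    n_subjects: int,
    seed: int = 0,
    profiles: dict[str, tuple[float, float, float]] = GM_PROFILES,
) -> dict[str, np.ndarray]:
    """Thickness-like and myelin-like per-parcel covariates, strictly positive.

    Each covariate is a shared parcel-level topography plus subject-level
    noise on a log scale (so values stay positive).
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    rng = np.random.default_rng(seed)
    p = parcellation.n_parcels
    out = {}
    for name, (center, topo_sd, noise_sd) in profiles.items():
        topography = rng.standard_normal(p) * topo_sd
        noise = rng.standard_normal((n_subjects, p)) * noise_sd
        out[name] = center * np.exp(topography[None, :] + noise)
    return out


def contaminate_fc(z: ZConnectivity, gm: np.ndarray, slope: float) -> ZConnectivity:
    """Plant a linear gray-matter contamination into a connectivity matrix.

    Each edge (i, j) is shifted by ``slope * (g_i + g_j)/2`` with ``g`` the
    mean-centred covariate, so the average perturbation over edges is zero
    and a constant covariate leaves the matrix untouched.  The negative-
    edge mask is re-derived afterwards.
    """
    gm = np.asarray(gm, dtype=float)
    if gm.shape[0] != z.n_parcels:
        raise ValueError(
            f"gm has {gm.shape[0]} parcels, connectivity has {z.n_parcels}"
        )
    g = gm - gm.mean()
    pert = slope * (g[:, None] + g[None, :]) / 2.0
    z_new = z.z + pert
    np.fill_diagonal(z_new, 0.0)
    off = ~np.eye(z.n_parcels, dtype=bool)
    mask = off & (z_new >= 0.0)
    return ZConnectivity(z.subject_id, z_new, mask)


#: marginal distributions emulating a late-middle-aged metabolic-risk cohort
#: (log-normal scale parameters for positive quantities)
_PHENOTYPE_MARGINALS = {
    "insulin": (8.5, 0.55),       # mU/l, right-skewed, mean ~ 9.9
    "glucose": (5.9, 0.14),       # mmol/l
    "waist": (91.0, 0.13),        # cm
    "height": (167.0, 0.055),     # cm
    "triglycerides": (1.05, 0.40),  # mmol/l
    "systolic": (125.0, 0.13),    # mmHg
    "hdl": (1.60, 0.25),          # mmol/l
    "bmi": (27.3, 0.15),          # kg/m^2
}


def simulate_phenotypes(
    n_subjects: int, carrier_fraction: float = 0.3, seed: int = 0
) -> pd.DataFrame:
    """Phenotype table with derived HOMA-IR and MtbS attached.

    APOE is coded as a binary epsilon-4 carrier indicator only (the design
    excludes epsilon-2 carriers and epsilon-4 homozygotes).
    """
    if not (0.0 <= carrier_fraction <= 1.0):
        raise ValueError("carrier_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    cols = {
        name: median * np.exp(rng.standard_normal(n_subjects) * sigma)
        for name, (median, sigma) in _PHENOTYPE_MARGINALS.items()
    }
    df = pd.DataFrame(cols)
    df.insert(0, "subject_id", [f"S{i:03d}" for i in range(n_subjects)])
    df["age"] = rng.uniform(52.0, 75.0, size=n_subjects)
    df["sex"] = np.where(rng.random(n_subjects) < 0.5, "F", "M")
    df["education"] = rng.integers(5, 21, size=n_subjects).astype(float)
    df["apoe_carrier"] = rng.random(n_subjects) < carrier_fraction
    return MetabolicScores().fit(df).transform(df)


@dataclass(frozen=True)
class TrialGenConfig:
    """Generative mixed model for navigation trials.

    All fixed effects act on the Box-Cox(``lam``)-transformed drop-error
    scale; continuous predictors enter Z-scored, APOE as a 0/1 carrier
    indicator, subtasks as treatment dummies against the first configured
    subtask.  Defaults put drop errors in the thousands of virtual units
    with landmark/boundary subtasks easier than the cue-free one,
    matching the scale of the navigation task the generator emulates.
    """

    subtasks: tuple[str, ...] = ("PPI", "LPI")
    n_trials_per_subtask: int = 12
    intercept: float = 8.25
    subtask_offsets: dict = field(default_factory=lambda: {"LPI": -0.17, "BPI": -0.19})
    beta_homa: float = 0.0
    beta_seg: float = 0.0
    beta_homa_x_seg: float = 0.0
    beta_apoe: float = 0.0
    apoe_x_subtask: dict = field(default_factory=dict)
    beta_distance: float = 0.08
    sd_subject_intercept: float = 0.25
    sd_residual: float = 0.45
    incoming_distance_range: tuple[float, float] = (2000.0, 12000.0)
    lam: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        valid = {"PPI", "BPI", "LPI"}
        if not self.subtasks or not set(self.subtasks) <= valid:
            raise ValueError(f"subtasks must be a non-empty subset of {valid}")
        if len(set(self.subtasks)) != len(self.subtasks):
            raise ValueError("duplicate subtasks")
        if self.n_trials_per_subtask < 1:
            raise ValueError("n_trials_per_subtask must be >= 1")
        if self.sd_subject_intercept < 0 or self.sd_residual < 0:
            raise ValueError("standard deviations must be non-negative")
        lo, hi = self.incoming_distance_range
        if not (0 < lo <= hi):
            raise ValueError("incoming_distance_range must be positive and ordered")


def model_terms(subtasks: tuple[str, ...]) -> list[str]:
    """Design-column names of the full three-way interaction family.

    The family is drop error ~ HOMA-IR x APOE x subtask plus the common
    covariates (age, education, sex, BMI, MtbS, incoming distance); these
    names match both the generator's truth dict and the columns of its
    output table, so a fit with this term list is directly comparable with
    the planted coefficients.
    """
    dummies = [f"subtask_{s}" for s in subtasks[1:]]
    terms = ["homa_z", "apoe", *dummies, "homa_z:apoe"]
    terms += [f"homa_z:{d}" for d in dummies]
    terms += [f"apoe:{d}" for d in dummies]
    terms += [f"homa_z:apoe:{d}" for d in dummies]
    terms += ["age_z", "edu_z", "sex_m", "bmi_z", "mtbs_z", "dist_z"]
    return terms


_MAX_REDRAWS = 100


def simulate_trials(
    phenotypes: pd.DataFrame,
    segregation: pd.DataFrame,
    cfg: TrialGenConfig,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Draw trial-level drop errors from the configured mixed model.

    Parameters
    ----------
    phenotypes
        Table with ``subject_id``, ``homa_ir``, ``apoe_carrier`` and the
        common covariates (``age``, ``education``, ``sex``, ``bmi``,
        ``mtbs``).
    segregation
        Table with ``subject_id`` and a ``segregation`` column (one value
        per subject; multiple rows per subject are averaged — e.g. a
        network-level summary collapses to its mean).

    Returns
    -------
    trials, truth
        ``trials`` is a long-format table with one row per trial carrying
        the raw ``drop_error`` plus every Z-scored design column;
        ``truth`` maps design-column names (see :func:`model_terms`) to
        the planted coefficients, including the zeros for unconfigured
        terms, plus ``Intercept`` and the transformation exponent ``lam``.
    """
    seg = (
        segregation.groupby("subject_id", sort=False)["segregation"]
        .mean()
        .rename("seg_value")
    )
    pheno = phenotypes.set_index("subject_id")
    missing = set(pheno.index) ^ set(seg.index)
    if missing:
        raise ValueError(f"subjects not present in both tables: {sorted(missing)}")
    seg = seg.loc[pheno.index]
    unknown = set(cfg.apoe_x_subtask) - set(cfg.subtasks[1:])
    if unknown:
        raise ValueError(f"apoe_x_subtask offsets for unconfigured subtasks: {unknown}")

    rng = np.random.default_rng(cfg.seed)
    n_sub = len(pheno)
    n_trials = cfg.n_trials_per_subtask * len(cfg.subtasks)

    # subject-level design (Z-scored across subjects, repeated per trial)
    subj = pd.DataFrame(
        {
            "subject_id": pheno.index,
            "homa_z": zscore(pheno["homa_ir"].to_numpy(float)),
            "seg_z": zscore(seg.to_numpy(float)),
            "apoe": pheno["apoe_carrier"].to_numpy(bool).astype(float),
            "age_z": zscore(pheno["age"].to_numpy(float)),
            "edu_z": zscore(pheno["education"].to_numpy(float)),
            "sex_m": (pheno["sex"].to_numpy(object) == "M").astype(float),
            "bmi_z": zscore(pheno["bmi"].to_numpy(float)),
            "mtbs_z": zscore(pheno["mtbs"].to_numpy(float)),
        }
    )
    trials = subj.loc[subj.index.repeat(n_trials)].reset_index(drop=True)
    trials["subtask"] = np.tile(
        np.repeat(list(cfg.subtasks), cfg.n_trials_per_subtask), n_sub
    )
    lo, hi = cfg.incoming_distance_range
    trials["incoming_distance"] = rng.uniform(lo, hi, size=len(trials))
    trials["dist_z"] = zscore(trials["incoming_distance"].to_numpy())
    for s in cfg.subtasks[1:]:
        trials[f"subtask_{s}"] = (trials["subtask"] == s).astype(float)

    lp = np.full(len(trials), cfg.intercept)
    lp += cfg.beta_homa * trials["homa_z"].to_numpy()
    lp += cfg.beta_seg * trials["seg_z"].to_numpy()
    lp += cfg.beta_homa_x_seg * (trials["homa_z"] * trials["seg_z"]).to_numpy()
    lp += cfg.beta_apoe * trials["apoe"].to_numpy()
    lp += cfg.beta_distance * trials["dist_z"].to_numpy()
    for s in cfg.subtasks[1:]:
        dummy = trials[f"subtask_{s}"].to_numpy()
        lp += cfg.subtask_offsets.get(s, 0.0) * dummy
        lp += cfg.apoe_x_subtask.get(s, 0.0) * trials["apoe"].to_numpy() * dummy

    u = rng.normal(0.0, cfg.sd_subject_intercept, size=n_sub)
    lp += np.repeat(u, n_trials)
    eps = rng.normal(0.0, cfg.sd_residual, size=len(trials))
    for attempt in range(_MAX_REDRAWS):
        transformed = lp + eps
        if cfg.lam == 0.0:
            break
        bad = 1.0 + cfg.lam * transformed <= 0
        if not bad.any():
            break
        logger.info("redrawing %d noise values outside the Box-Cox domain", bad.sum())
        eps[bad] = rng.normal(0.0, cfg.sd_residual, size=int(bad.sum()))
    else:
        raise RuntimeError(
            "could not draw strictly positive drop errors within the retry budget"
        )
    trials["drop_error"] = box_cox_inverse(transformed, cfg.lam)

    truth = {name: 0.0 for name in model_terms(cfg.subtasks)}
    truth["Intercept"] = cfg.intercept
    truth["homa_z"] = cfg.beta_homa
    truth["apoe"] = cfg.beta_apoe
    truth["dist_z"] = cfg.beta_distance
    for s in cfg.subtasks[1:]:
        truth[f"subtask_{s}"] = cfg.subtask_offsets.get(s, 0.0)
        truth[f"apoe:subtask_{s}"] = cfg.apoe_x_subtask.get(s, 0.0)
    truth["seg_z"] = cfg.beta_seg
    truth["homa_z:seg_z"] = cfg.beta_homa_x_seg
    truth["lam"] = cfg.lam
    return trials, truth
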