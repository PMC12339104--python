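"""End-to-end orchestration: simulate -> connectivity -> segregation ->
metabolic -> mixed-model ladder -> report.

A run is driven by one :class:`RunConfig` (YAML on disk) holding either a
simulation block or paths to real parcel-level input tables — never both.
One mandatory top-level seed is split deterministically into per-stage
substreams, so adding a stage never perturbs earlier streams and reruns
with an identical config are bit-identical for deterministic stages.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Literal, Optional

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field, model_validator

from . import __version__
from .connectivity import ConnectivityExtractor
from .inference import ModelSpec, MixedModelLadder, box_cox, zscore
from .io import read_series, read_table, write_series, write_sidecar, write_table
from .metabolic import MetabolicScores
from .parcellation import ParcellationMap
from .segregation import NetworkSegregation, aggregate_class
from .simulate import (
    SimConfig,
    TrialGenConfig,
    contaminate_fc,
    simulate_bold,
    simulate_gm_covariates,
    simulate_phenotypes,
    simulate_trials,
)

__all__ = [
    "RunConfig",
    "run_pipeline",
    "report",
    "build_ladder",
    "prepare_analysis_table",
]

logger = logging.getLogger(__name__)

COMMON_COVARIATES = ("age_z", "edu_z", "sex_m", "bmi_z", "mtbs_z", "dist_z")


class SimulationBlock(BaseModel):
    n_subjects: int = 40
    network_sizes: list[int] = Field(default_factory=lambda: [15, 15, 15, 15])
    n_timepoints: int = 250
    r_within: float = 0.5
    r_between: float = 0.1
    ar1: float = 0.0
    gm_contamination_slope: float = 0.0
    carrier_fraction: float = 0.3
    subtasks: list[Literal["PPI", "BPI", "LPI"]] = Field(
        default_factory=lambda: ["PPI", "LPI"]
    )
    n_trials_per_subtask: int = 12
    beta_homa: float = 0.0
    beta_seg: float = 0.0
    beta_homa_x_seg: float = 0.0
    beta_apoe: float = 0.0


class InputPaths(BaseModel):
    series_manifest: str
    parcellation: str
    phenotypes: str
    trials: str
    gm_thickness: Optional[str] = None
    gm_myelin: Optional[str] = None


class RunConfig(BaseModel):
    """Validated run configuration (see docs/run_config.schema.json)."""

    seed: int
    simulation: Optional[SimulationBlock] = None
    inputs: Optional[InputPaths] = None
    variants: list[Literal["raw", "partial_thickness", "partial_myelin"]] = Field(
        default_factory=lambda: ["raw"]
    )
    class_map: Optional[dict[str, str]] = None
    ladder: Literal[
        "apoe_homa_subtask", "homa_moderation", "apoe_moderation", "none"
    ] = "homa_moderation"
    log_level: str = "INFO"

    @model_validator(mode="after")
    def _exactly_one_source(self):
        if (self.simulation is None) == (self.inputs is None):
            raise ValueError("exactly one of 'simulation' or 'inputs' is required")
        return self

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.model_validate(yaml.safe_load(Path(path).read_text()))

    def config_hash(self) -> str:
        return hashlib.sha256(self.model_dump_json().encode()).hexdigest()[:16]


def build_ladder(name: str, subtasks: tuple[str, ...]) -> list[ModelSpec]:
    """Nested ModelSpec chains for the supported model families.

    ``apoe_homa_subtask`` is the eight-rung APOE/HOMA-IR x subtask family;
    ``homa_moderation`` and ``apoe_moderation`` are the segregation-
    moderation chains (base model, two-way interaction, three-way with
    subtask).  All rungs share the common covariates and a participant
    random intercept.
    """
    cov = list(COMMON_COVARIATES)
    dummies = [f"subtask_{s}" for s in subtasks[1:]]
    dep = "drop_t"

    def spec(pos: int, terms: list[str]) -> ModelSpec:
        return ModelSpec(
            dependent=dep,
            fixed_terms=tuple(terms),
            covariates=tuple(cov),
            random_intercept_group="subject_id",
            ladder_position=pos,
        )

    if name == "none":
        return []
    if name == "apoe_homa_subtask":
        t: list[list[str]] = [[]]
        t.append(t[-1] + dummies)
        t.append(t[-1] + ["homa_z"])
        t.append(t[-1] + ["apoe"])
        t.append(t[-1] + ["homa_z:apoe"])
        t.append(t[-1] + [f"homa_z:{d}" for d in dummies])
        t.append(t[-1] + [f"apoe:{d}" for d in dummies])
        t.append(t[-1] + [f"homa_z:apoe:{d}" for d in dummies])
        return [spec(i, terms) for i, terms in enumerate(t)]
    base = ["seg_z", "homa_z", "apoe", *dummies]
    if name == "homa_moderation":
        rungs = [
            base,
            base + ["homa_z:seg_z"],
            base
            + ["homa_z:seg_z"]
            + [f"homa_z:{d}" for d in dummies]
            + [f"seg_z:{d}" for d in dummies]
            + [f"homa_z:seg_z:{d}" for d in dummies],
        ]
    elif name == "apoe_moderation":
        rungs = [
            base,
            base + ["apoe:seg_z"],
            base
            + ["apoe:seg_z"]
            + [f"apoe:{d}" for d in dummies]
            + [f"seg_z:{d}" for d in dummies]
            + [f"apoe:seg_z:{d}" for d in dummies],
        ]
    else:
        raise ValueError(f"unknown ladder {name!r}")
    return [spec(i, terms) for i, terms in enumerate(rungs)]


def prepare_analysis_table(
    trials: pd.DataFrame,
    phenotypes: pd.DataFrame | None = None,
    segregation: pd.DataFrame | None = None,
    lam: float | None = None,
) -> tuple[pd.DataFrame, float]:
    """Assemble the modelling table: transformed response + Z-scored design.

    The drop error is Box-Cox transformed with the exponent chosen by
    profile likelihood (or fixed via ``lam``, e.g. when the generative
    exponent is known).  Design columns already present (generator
    output) are kept; otherwise they are derived from the raw
    phenotype/trial columns.  Returns ``(table, lambda)``.
    """
    df = trials.copy()
    if phenotypes is not None and "homa_z" not in df.columns:
        pheno = phenotypes.set_index("subject_id")
        df = df.join(
            pd.DataFrame(
                {
                    "homa_z": zscore(pheno["homa_ir"].to_numpy(float)),
                    "apoe": pheno["apoe_carrier"].astype(float),
                    "age_z": zscore(pheno["age"].to_numpy(float)),
                    "edu_z": zscore(pheno["education"].to_numpy(float)),
                    "sex_m": (pheno["sex"] == "M").astype(float),
                    "bmi_z": zscore(pheno["bmi"].to_numpy(float)),
                    "mtbs_z": zscore(pheno["mtbs"].to_numpy(float)),
                },
                index=pheno.index,
            ),
            on="subject_id",
        )
    if segregation is not None and "seg_z" not in df.columns:
        seg = segregation.groupby("subject_id")["segregation"].mean()
        df = df.join(
            pd.Series(zscore(seg.to_numpy(float)), index=seg.index, name="seg_z"),
            on="subject_id",
        )
    if "dist_z" not in df.columns:
        df["dist_z"] = zscore(df["incoming_distance"].to_numpy(float))
    for s in sorted(df["subtask"].unique()):
        col = f"subtask_{s}"
        if col not in df.columns:
            df[col] = (df["subtask"] == s).astype(float)
    transformed, lam = box_cox(df["drop_error"].to_numpy(float), lam=lam)
    df["drop_t"] = transformed
    return df, lam


def _stage_seeds(seed: int, n: int = 8) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]


def run_pipeline(config: RunConfig, out_dir) -> dict:
    """Execute all stages in dependency order; returns the run manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    seeds = _stage_seeds(config.seed)
    manifest: dict = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "version": __version__,
        "stages": {},
    }

    # -- stage 1: inputs ----------------------------------------------------
    gm: dict[str, np.ndarray] = {}
    truth_sidecar: dict = {}
    if config.simulation is not None:
        sim = config.simulation
        sim_cfg = SimConfig(
            n_subjects=sim.n_subjects,
            network_sizes=tuple(sim.network_sizes),
            n_timepoints=sim.n_timepoints,
            r_within=sim.r_within,
            r_between=sim.r_between,
            ar1=sim.ar1,
            gm_contamination_slope=sim.gm_contamination_slope,
            seed=seeds[0],
        )
        parcellation = sim_cfg.parcellation()
        series, _ = simulate_bold(sim_cfg)
        gm = simulate_gm_covariates(parcellation, sim.n_subjects, seed=seeds[1])
        phenotypes = simulate_phenotypes(
            sim.n_subjects, sim.carrier_fraction, seed=seeds[2]
        )
        subject_ids = list(phenotypes["subject_id"])
        truth_sidecar["block_correlation_r"] = {
            "r_within": sim.r_within,
            "r_between": sim.r_between,
        }
        write_series(series, subject_ids, out / "series")
        parcellation.to_tsv(out / "parcellation.tsv")
        for name, mat in gm.items():
            write_table(
                pd.DataFrame(mat, index=subject_ids).reset_index(names="subject_id"),
                out / f"gm_{name}.tsv",
            )
        write_table(phenotypes, out / "phenotypes.tsv")
    else:
        paths = config.inputs
        for p in [
            paths.series_manifest, paths.parcellation, paths.phenotypes,
            paths.trials, paths.gm_thickness, paths.gm_myelin,
        ]:
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"configured input does not exist: {p}")
        series, subject_ids = read_series(paths.series_manifest)
        parcellation = ParcellationMap.from_tsv(paths.parcellation)
        phenotypes = read_table(paths.phenotypes)
        if "homa_ir" not in phenotypes.columns:
            phenotypes = MetabolicScores().fit(phenotypes).transform(phenotypes)
        for name, p in (("thickness", paths.gm_thickness), ("myelin", paths.gm_myelin)):
            if p is not None:
                gm[name] = read_table(p).drop(columns="subject_id").to_numpy(float)
    manifest["stages"]["inputs"] = {"n_subjects": len(subject_ids)}

    # -- stage 2: connectivity ---------------------------------------------
    extractor = ConnectivityExtractor(parcellation).fit(series)
    z_list = extractor.transform(series)
    if (
        config.simulation is not None
        and config.simulation.gm_contamination_slope != 0.0
    ):
        write_table(
            _tidy_segregation(z_list, parcellation, subject_ids, "raw"),
            out / "segregation_uncontaminated.tsv",
        )
        z_list = [
            contaminate_fc(
                z, gm["thickness"][i], config.simulation.gm_contamination_slope
            )
            for i, z in enumerate(z_list)
        ]
    conn_dir = out / "connectivity"
    conn_dir.mkdir(exist_ok=True)
    for sid, z in zip(subject_ids, z_list):
        z.to_tsv(conn_dir / f"z_{sid}.tsv")
    manifest["stages"]["connectivity"] = {"n_matrices": len(z_list)}

    # -- stage 3: segregation ----------------------------------------------
    seg_tables = []
    for variant in config.variants:
        est = NetworkSegregation(parcellation, variant=variant).fit(z_list)
        covariate = variant.removeprefix("partial_")
        seg_tables.append(
            _with_subjects(
                est.transform(
                    z_list, gm=gm.get(covariate) if variant != "raw" else None
                ),
                subject_ids,
            )
        )
    segregation_tbl = pd.concat(seg_tables, ignore_index=True)
    write_table(segregation_tbl, out / "segregation.tsv")
    if config.class_map is not None:
        write_table(
            aggregate_class(segregation_tbl, config.class_map),
            out / "segregation_classes.tsv",
        )
    manifest["stages"]["segregation"] = {"variants": list(config.variants)}

    # -- stage 4: trials ----------------------------------------------------
    raw_seg = segregation_tbl[segregation_tbl["variant"] == "raw"]
    if config.simulation is not None:
        sim = config.simulation
        trial_cfg = TrialGenConfig(
            subtasks=tuple(sim.subtasks),
            n_trials_per_subtask=sim.n_trials_per_subtask,
            beta_homa=sim.beta_homa,
            beta_seg=sim.beta_seg,
            beta_homa_x_seg=sim.beta_homa_x_seg,
            beta_apoe=sim.beta_apoe,
            seed=seeds[3],
        )
        trials, truth = simulate_trials(phenotypes, raw_seg, trial_cfg)
        truth_sidecar["trial_coefficients"] = truth
        write_table(trials, out / "trials.tsv")
    else:
        trials = read_table(config.inputs.trials)
    if truth_sidecar:
        write_sidecar(truth_sidecar, out / "ground_truth.json")
    manifest["stages"]["trials"] = {"n_trials": len(trials)}

    # -- stage 5: mixed-model ladder -----------------------------------------
    if config.ladder != "none":
        table, lam = prepare_analysis_table(trials, phenotypes, raw_seg)
        subtasks = tuple(dict.fromkeys(trials["subtask"]))  # first-appearance order
        specs = build_ladder(config.ladder, subtasks)
        ladder = MixedModelLadder(specs).fit(table)
        write_table(ladder.summary_table(), out / "ladder_models.tsv")
        write_table(ladder.lrt_, out / "ladder_lrt.tsv")
        manifest["stages"]["ladder"] = {
            "family": config.ladder,
            "box_cox_lambda": lam,
            "n_models": len(specs),
        }
    (out / "run_manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True)
    )
    return manifest


def _with_subjects(table: pd.DataFrame, subject_ids) -> pd.DataFrame:
    mapping = {str(i): sid for i, sid in enumerate(subject_ids)}
    out = table.copy()
    out["subject_id"] = out["subject_id"].map(lambda s: mapping.get(str(s), s))
    return out


def _tidy_segregation(z_list, parcellation, subject_ids, variant) -> pd.DataFrame:
    est = NetworkSegregation(parcellation, variant=variant).fit(z_list)
    return _with_subjects(est.transform(z_list), subject_ids)


def report(run_dir) -> str:
    """Summarize a completed run into report.txt (+ summary tables and plots)."""
    run_dir = Path(run_dir)
    manifest_path = run_dir / "run_manifest.json"
    if not manifest_path.exists():
        raise FileNotFoundError(f"no run manifest in {run_dir}: incomplete run")
    manifest = json.loads(manifest_path.read_text())
    lines = [
        "segnav run report",
        "=================",
        f"config hash : {manifest['config_hash']}",
        f"seed        : {manifest['seed']}",
        "",
    ]
    seg = read_table(run_dir / "segregation.tsv")
    per_net = (
        seg.groupby(["variant", "network_label"])["segregation"]
        .agg(["mean", "std"])
        .reset_index()
    )
    write_table(per_net, run_dir / "report_segregation_summary.tsv")
    lines.append("Per-network segregation (mean +/- SD over subjects):")
    for _, r in per_net.iterrows():
        lines.append(
            f"  {r['variant']:<18} {r['network_label']:<10} "
            f"{r['mean']:.4f} +/- {r['std']:.4f}"
        )
    _plot_segregation(per_net, run_dir)

    ladder_path = run_dir / "ladder_models.tsv"
    if ladder_path.exists():
        models = read_table(ladder_path)
        lrt = read_table(run_dir / "ladder_lrt.tsv")
        lines += ["", "Model ladder (maximum likelihood):"]
        for _, r in models.iterrows():
            lines.append(
                f"  [{int(r['ladder_position'])}] LL={r['log_likelihood']:.2f} "
                f"k={int(r['n_params'])}  {r['formula']}"
            )
        lines += ["", "Likelihood-ratio comparisons (full vs reduced):"]
        for _, r in lrt.iterrows():
            lines.append(
                f"  {int(r['full'])} vs {int(r['reduced'])}: "
                f"chi2({int(r['df'])}) = {r['statistic']:.2f}, p = {r['p_value']:.4g}"
            )
    else:
        lines += ["", "No model ladder was fit (segregation section only)."]
    text = "\n".join(lines) + "\n"
    (run_dir / "report.txt").write_text(text)
    return text


def _plot_segregation(per_net: pd.DataFrame, run_dir: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4))
    for variant, grp in per_net.groupby("variant"):
        ax.errorbar(
            grp["network_label"], grp["mean"], yerr=grp["std"],
            marker="o", linestyle="", capsize=3, label=variant,
        )
    ax.set_xlabel("network")
    ax.set_ylabel("segregation index")
    ax.legend()
    fig.tight_layout()
    fig.savefig(run_dir / "report_segregation.png", dpi=120)
    plt.close(fig)
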