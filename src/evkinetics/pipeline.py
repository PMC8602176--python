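"""End-to-end orchestration: quantify, normalize, fit, evaluate, compare.

Stages run in a fixed order — ddPCR quantification and QC first, then the
structural model ladder (each candidate ranked by AIC), the cell-line
covariate scan on the best structure, predictive-check and bootstrap
evaluation, and rank-based group comparisons of the per-animal secondary
parameters.  Every stage writes tidy CSV/JSON artifacts and the resolved
configuration (with all seeds) so any number in the report is reproducible
from the config alone.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path


import pandas as pd

from . import io as evio
from .ddpcr_quant import (
    BatchQuantRecord,
    copies_to_ev_concentration,
    fit_standard_curve,
    normalize_batch,
    poisson_copies,
    qc_negative_control,
)
from .group_stats import compare_groups, posthoc_secondary
from .model_evaluation import VpcConfig, bootstrap, vpc
from .nlme_engine import (
    FitConfig,
    PopulationModel,
    StudyDataset,
    Subject,
    covariate_scan,
    fit,
    initial_estimates,
)
from .pk_model import ModelSpec
from .synthetic_data import AssayBundle

__all__ = [
    "PipelineConfig",
    "StageError",
    "DEFAULT_MODEL_LADDER",
    "quantify_assay",
    "build_analysis_dataset",
    "run",
]

#: Structural candidates fitted by default, mirroring the model-comparison
#: ladder: 2- and 3-compartment mammillary models with central elimination.
DEFAULT_MODEL_LADDER: tuple[dict, ...] = (
    {"label": "2cpt_central_elim", "n_compartments": 2, "elimination_sites": [1]},
    {"label": "3cpt_central_elim", "n_compartments": 3, "elimination_sites": [1]},
)

#: The cross-sample contamination screen flags an animal whose
#: concentration rises between consecutive late samples (first of the pair
#: at or past this time) by more than the given fraction of the animal's
#: peak concentration.  After an IV bolus no true late-time rise of that
#: size is kinetically possible; assay noise near the quantification floor
#: stays far below it.
CONTAMINATION_TIME_MIN = 240.0
CONTAMINATION_RISE_FRACTION = 0.05


class StageError(RuntimeError):
    """A pipeline stage failed; downstream stages were not run."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Validated configuration for a full pipeline run.

    Either ``dataset_csv`` (already-normalized concentrations) or
    ``assay_csv`` (raw droplet wells) is the input; seeds are explicit so
    reruns are byte-identical.
    """

    out_dir: str = "evkinetics_out"
    dataset_csv: str | None = None
    assay_csv: str | None = None
    seed: int = 0
    model_ladder: tuple[dict, ...] = DEFAULT_MODEL_LADDER
    residual: str = "log_additive"
    omega_init: float = 0.1
    sigma_init: float = 0.3
    iiv_params: tuple[str, ...] = ("v1", "v2", "cl")
    covariate: str | None = "cell_line"
    covariate_subsets: tuple[tuple[str, ...], ...] = ((), ("v2",), ("v2", "v3", "cl", "cl3"))
    vpc_simulations: int = 1000
    vpc_bins: int = 10
    bootstrap_n: int = 1000
    max_iter: int = 1000
    run_scan: bool = True
    run_vpc: bool = True
    run_bootstrap: bool = True
    run_stats: bool = True
    plots: bool = False

    def validate(self) -> None:
        if (self.dataset_csv is None) == (self.assay_csv is None):
            raise ValueError("exactly one of dataset_csv or assay_csv is required")
        if self.residual not in ("proportional", "log_additive"):
            raise ValueError(f"unknown residual model {self.residual!r}")
        if self.vpc_simulations < 1 or self.bootstrap_n < 0 or self.max_iter < 1:
            raise ValueError("counts must be positive")
        for entry in self.model_ladder:
            ModelSpec(
                n_compartments=int(entry["n_compartments"]),
                elimination_sites=tuple(entry.get("elimination_sites", (1,))),
                symmetric_distribution=bool(entry.get("symmetric_distribution", True)),
            )


def quantify_assay(bundle: AssayBundle) -> tuple[pd.DataFrame, dict[str, str]]:
    """Droplet wells -> normalized EV-protein concentrations plus QC flags.

    Per batch: Poisson copy estimates, negative-control QC, two-point
    affine normalization of samples and dose aliquot against the reference
    standard curve, then conversion to ug/mL via the animal's own dose
    aliquot.  Returns a (id, time_min, conc) table and a flag log
    (animal id -> reason) for failed negative controls.
    """
    curve_points = [(f, poisson_copies(w)) for f, w in bundle.curve_wells]
    curve = fit_standard_curve(curve_points)
    flags: dict[str, str] = {}
    rows = []
    aliquot_key = ("__dose_aliquot__", -1.0)
    for batch in bundle.batches:
        neg = poisson_copies(batch.negative_control_well)
        if not qc_negative_control(neg):
            # failing sample sets are reanalyzed from RNA; only a persistent
            # failure excludes the animal
            re_well = batch.negative_control_reanalysis_well
            if re_well is None or not qc_negative_control(poisson_copies(re_well)):
                flags[batch.animal_id] = "qc_failure"
        samples = {k: poisson_copies(w) for k, w in batch.sample_wells.items()}
        samples[aliquot_key] = poisson_copies(batch.dose_aliquot_well)
        record = BatchQuantRecord(
            batch_id=batch.batch_id,
            high_standard_copies=poisson_copies(batch.high_standard_well),
            low_standard_copies=poisson_copies(batch.low_standard_well),
            sample_copies=samples,
            negative_control_copies=neg,
            dose_aliquot_copies_per_ug=1.0,  # set below from the normalized aliquot
            dilution_factors=batch.dilution_factors,
            plasma_volume_ml=batch.plasma_volume_ml,
        )
        normalized = normalize_batch(record, curve)
        aliquot = normalized.pop(aliquot_key)
        record.dose_aliquot_copies_per_ug = aliquot / batch.dose_aliquot_ug
        conc = copies_to_ev_concentration(normalized, record)
        for (sid, t), c in conc.items():
            rows.append({"id": sid, "time_min": t, "conc": max(c, 0.0)})
    table = pd.DataFrame(rows).sort_values(["id", "time_min"]).reset_index(drop=True)
    return table, flags


def _contamination_screen(observations: list[tuple[float, float]]) -> bool:
    """True if a late-time concentration rise is kinetically implausible."""
    cmax = max(c for _, c in observations)
    threshold = CONTAMINATION_RISE_FRACTION * cmax
    for (t1, c1), (t2, c2) in zip(observations, observations[1:]):
        if t1 >= CONTAMINATION_TIME_MIN and c2 - c1 > threshold:
            return True
    return False


def build_analysis_dataset(
    conc_table: pd.DataFrame,
    template: StudyDataset,
    qc_flags: dict[str, str],
) -> StudyDataset:
    """Assemble the analysis set, applying QC and contamination exclusions.

    ``template`` supplies each animal's dose and covariates (the design);
    concentrations come from the quantification stage.  Animals flagged by
    the negative-control rule or the late-rise contamination screen go to
    the exclusion log.
    """
    by_id = {s.id: s for s in template.subjects}
    exclusions = dict(template.exclusions)
    subjects: list[Subject] = []
    for sid, grp in conc_table.groupby("id", sort=False):
        if sid not in by_id:
            raise StageError("qc", f"quantified animal {sid!r} not in the design")
        obs = sorted(zip(grp["time_min"].tolist(), grp["conc"].tolist()))
        if sid in qc_flags:
            exclusions[sid] = qc_flags[sid]
            continue
        if _contamination_screen(obs):
            exclusions[sid] = "contamination"
            continue
        src = by_id[sid]
        subjects.append(
            Subject(id=sid, dose=src.dose, observations=obs, covariates=dict(src.covariates))
        )
    if not subjects:
        raise StageError("qc", "no animals left after exclusions")
    return StudyDataset(subjects=subjects, exclusions=exclusions)


def run(config: PipelineConfig) -> dict:
    """Execute the configured stages; returns the report bundle (also written).

    Raises StageError naming the failing stage; downstream stages are
    aborted.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    resolved = asdict(config)
    (out / "config.json").write_text(json.dumps(resolved, indent=2, default=list))
    report: dict = {"seed": config.seed}

    # ---- stage: input / quantification ----
    if config.assay_csv:
        try:
            bundle = evio.read_assay_bundle(config.assay_csv)
            conc, flags = quantify_assay(bundle)
            conc.to_csv(out / "concentrations.csv", index=False)
            design_path = Path(config.assay_csv).with_suffix(".design.csv")
            if not design_path.exists():
                raise StageError("quantify", f"design dataset {design_path} not found")
            template = evio.read_dataset(design_path)
            data = build_analysis_dataset(conc, template, flags)
        except StageError:
            raise
        except Exception as exc:
            raise StageError("quantify", str(exc)) from exc
    else:
        try:
            data = evio.read_dataset(config.dataset_csv)
        except Exception as exc:
            raise StageError("read", str(exc)) from exc
    report["n_animals"] = len(data.subjects)
    report["exclusions"] = dict(data.exclusions)
    (out / "exclusions.json").write_text(json.dumps(data.exclusions, indent=2))

    # ---- stage: model ladder ----
    fit_cfg = FitConfig(max_iter=config.max_iter)
    ladder_rows = []
    fits = {}
    for entry in config.model_ladder:
        label = entry.get("label", f"{entry['n_compartments']}cpt")
        spec = ModelSpec(
            n_compartments=int(entry["n_compartments"]),
            elimination_sites=tuple(entry.get("elimination_sites", (1,))),
            symmetric_distribution=bool(entry.get("symmetric_distribution", True)),
        )
        try:
            theta0 = initial_estimates(data, spec)
            iiv = {p: config.omega_init for p in config.iiv_params if p in spec.structural_names}
            model0 = PopulationModel(
                spec=spec, theta=theta0, omega=iiv, sigma=config.sigma_init, residual=config.residual
            )
            fr = fit(data, model0, fit_cfg)
            fits[label] = fr
            ladder_rows.append(
                {"model": label, "aic": fr.aic, "minus2ll": fr.minus2ll, "converged": fr.converged}
            )
        except Exception as exc:
            ladder_rows.append(
                {"model": label, "aic": math.inf, "minus2ll": math.nan, "converged": False, "error": str(exc)}
            )
    ladder = pd.DataFrame(ladder_rows).sort_values("aic").reset_index(drop=True)
    ladder.to_csv(out / "model_comparison.csv", index=False)
    report["model_comparison"] = ladder.to_dict(orient="records")
    converged = ladder[ladder["converged"] == True]  # noqa: E712
    if converged.empty:
        raise StageError("fit", "no structural model converged")
    best_label = str(converged.iloc[0]["model"])
    best = fits[best_label]
    report["best_model"] = best_label

    # ---- stage: covariate scan ----
    final = best
    if config.run_scan and config.covariate is not None:
        levels = {str(s.covariates.get(config.covariate)) for s in data.subjects}
        if len(levels) > 1:
            scan = covariate_scan(
                data,
                best.model,
                config.covariate,
                [tuple(s) for s in config.covariate_subsets],
                fit_cfg,
            )
            scan_rows = [
                {
                    "subset": "+".join(r["subset"]) or "(none)",
                    "aic": r["aic"],
                    "error": r.get("error", ""),
                }
                for r in scan
            ]
            pd.DataFrame(scan_rows).to_csv(out / "covariate_scan.csv", index=False)
            report["covariate_scan"] = scan_rows
            top = next((r for r in scan if r["fit"] is not None), None)
            if top is not None:
                final = top["fit"]
                report["covariate_selection"] = "+".join(top["subset"]) or "(none)"
    evio.write_fit_result(final, out, stem="final_fit")
    report["final_estimates"] = final.estimates
    report["final_aic"] = final.aic

    # ---- stage: VPC ----
    if config.run_vpc:
        vpc_cfg = VpcConfig(n_simulations=config.vpc_simulations, n_bins=config.vpc_bins)
        vr = vpc(final, vpc_cfg, seed=config.seed + 1)
        vr.summary.to_csv(out / "vpc_summary.csv", index=False)
        vr.corrected_observations.to_csv(out / "vpc_observations.csv", index=False)
        report["vpc_failed_simulations"] = vr.n_failed
        if config.plots:
            from .model_evaluation import plot_concentration_time, plot_vpc

            plot_vpc(vr, out / "vpc.png")
            plot_concentration_time(data, out / "concentration_time.png")

    # ---- stage: bootstrap ----
    if config.run_bootstrap and config.bootstrap_n > 0:
        br = bootstrap(
            data, final.model, n=config.bootstrap_n, seed=config.seed + 2, config=fit_cfg
        )
        br.summary_table().to_csv(out / "bootstrap_summary.csv", index=False)
        br.replicates.to_csv(out / "bootstrap_replicates.csv", index=False)
        report["bootstrap"] = {
            "n_requested": config.bootstrap_n,
            "n_failed": br.n_failed,
            "mean": br.mean,
            "ci95": {k: list(v) for k, v in br.ci95.items()},
        }

    # ---- stage: group statistics ----
    if config.run_stats and len({s.covariates.get("cell_line") for s in data.subjects}) > 1:
        table = posthoc_secondary(final)
        table.to_csv(out / "secondary_parameters.csv", index=False)
        comparisons = {}
        for column in ("t_half_elim_hr", "t_half_compt2_hr", "t_half_compt3_min", "auc_ug_hr_ml"):
            if table[column].isna().any():
                continue
            groups = {
                line: grp[column].tolist() for line, grp in table.groupby("cell_line")
            }
            comparisons[column] = compare_groups(groups).to_dict()
        (out / "group_comparisons.json").write_text(json.dumps(comparisons, indent=2))
        report["group_comparisons"] = comparisons

    (out / "report.json").write_text(json.dumps(report, indent=2, default=float))
    return report
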