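"""Synthetic EV kinetic studies with a full measurement chain.

Generates complete studies mirroring the three-arm rat experiment: EVs
from clone 9 (liver), RFL-6 (lung fibroblast) and RMC (kidney mesangial)
cell lines, IV bolus dosing, the ten-point 2-1440 min sampling schedule,
log-normal inter-animal variability and multiplicative residual error.
On top of the true kinetics it simulates the ddPCR assay itself — droplet
Poisson partitioning, per-batch high/low standards with batch-to-batch
scale variation, negative-control false-positive background — plus the
two QC pathologies seen in such studies (cross-sample contamination,
negative-control failure), so every stage of the quantification and
modeling pipeline is testable without animal data.

Default arm kinetics are the fitted population estimates of the source
study (volumes in mL, clearances in mL/hr); the central volume and the
compartment-2 distributional clearance are shared across arms, with arm
differences carried by V2, V3, Cl and Cl3.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .ddpcr_quant import DropletWell
from .nlme_engine import StudyDataset, Subject
from .pk_model import DoseEvent, ModelSpec, StructuralParams, predict_concentrations

__all__ = [
    "ArmDesign",
    "StudyDesign",
    "AssayDesign",
    "BatchWellSet",
    "AssayBundle",
    "default_design",
    "DEFAULT_ARM_PARAMS",
    "generate_study",
    "generate_assay_layer",
    "inject_pathologies",
    "SAMPLING_SCHEDULE_MIN",
]

#: Nominal blood-sampling schedule, minutes after the IV bolus.
SAMPLING_SCHEDULE_MIN = (2.0, 7.5, 15.0, 30.0, 60.0, 120.0, 240.0, 480.0, 960.0, 1440.0)

#: Population estimates per cell line used as default simulation truths
#: (3-compartment, central elimination; v1 and cl2 shared across arms).
DEFAULT_ARM_PARAMS: dict[str, StructuralParams] = {
    "clone9": StructuralParams(v1=28.0, v2=3057.0, v3=16.0, cl=(193.0,), cl2=111.0, cl3=21.0),
    "RFL6": StructuralParams(v1=28.0, v2=2982.0, v3=90.0, cl=(119.0,), cl2=111.0, cl3=124.0),
    "RMC": StructuralParams(v1=28.0, v2=752.0, v3=17.0, cl=(166.0,), cl2=111.0, cl3=63.0),
}

#: Variance of a log-normal eta giving ~40% CV: ln(1 + 0.4^2).
_OMEGA_40CV = math.log(1.0 + 0.4**2)


@dataclass(frozen=True)
class ArmDesign:
    """One study arm: group size and the arm's true typical parameters."""

    n_animals: int
    params: StructuralParams

    def __post_init__(self) -> None:
        if self.n_animals < 1:
            raise ValueError("each arm needs >= 1 animal")


@dataclass(frozen=True)
class StudyDesign:
    """Study conditions for the kinetic layer.

    ``omega`` holds diagonal eta variances per structural parameter
    (default ~40% CV on v1, v2 and cl); ``sigma`` is the residual SD
    (default 0.45), applied log-additively by default so simulated
    concentrations stay positive.
    """

    arms: dict[str, ArmDesign]
    dose_amount_ug: float = 2000.0
    schedule_min: tuple[float, ...] = SAMPLING_SCHEDULE_MIN
    omega: dict[str, float] = field(
        default_factory=lambda: {"v1": _OMEGA_40CV, "v2": _OMEGA_40CV, "cl": _OMEGA_40CV}
    )
    sigma: float = 0.45
    residual: str = "log_additive"
    spec: ModelSpec = field(default_factory=ModelSpec)
    weight_mean_g: float = 372.0
    weight_sd_g: float = 20.0

    def __post_init__(self) -> None:
        sched = tuple(float(t) for t in self.schedule_min)
        object.__setattr__(self, "schedule_min", sched)
        if any(t2 <= t1 for t1, t2 in zip(sched, sched[1:])):
            raise ValueError("sampling schedule must be strictly increasing")
        if self.dose_amount_ug <= 0:
            raise ValueError("dose must be > 0")
        if self.residual not in ("proportional", "log_additive"):
            raise ValueError(f"unknown residual model {self.residual!r}")

    def to_dict(self) -> dict:
        """JSON-serializable provenance record of the study conditions."""
        return _design_to_dict(self)


def _design_to_dict(design: "StudyDesign") -> dict:
    return {
        "arms": {
            line: {"n_animals": a.n_animals, "params": a.params.as_dict()}
            for line, a in design.arms.items()
        },
        "dose_amount_ug": design.dose_amount_ug,
        "schedule_min": list(design.schedule_min),
        "omega": dict(design.omega),
        "sigma": design.sigma,
        "residual": design.residual,
        "spec": design.spec.to_dict(),
        "weight_mean_g": design.weight_mean_g,
        "weight_sd_g": design.weight_sd_g,
    }


def default_design(n_per_arm: int | None = None, **overrides) -> StudyDesign:
    """Three-arm design at the study's conditions (10 animals per arm)."""
    n = {"clone9": 10, "RFL6": 10, "RMC": 10}
    if n_per_arm is not None:
        n = {k: n_per_arm for k in n}
    arms = {line: ArmDesign(n[line], DEFAULT_ARM_PARAMS[line]) for line in n}
    return StudyDesign(arms=arms, **overrides)


@dataclass(frozen=True)
class AssayDesign:
    """Conditions for the ddPCR measurement layer.

    The reference high standard targets ~25,000 copies per 20 uL reaction;
    the low standard is its 30-fold dilution.  Batch-to-batch technical
    variation is a log-normal scale factor applied to samples, standards
    and dose aliquot alike (so standard-based normalization can remove
    it).  Negative controls draw a log-normal false-positive background
    (median ~60 copies, CV 110%, spanning roughly 20-266 copies).
    """

    n_droplets: int = 20000
    droplet_volume_nl: float = 0.85
    reaction_volume_ul: float = 20.0
    dilution_factors: tuple[float, ...] = (1.0,)
    reference_high_copies: float = 25000.0
    batch_effect_sd: float = 0.15
    negctrl_median_copies: float = 60.0
    negctrl_cv: float = 1.10
    copies_per_ug: float = 2500.0
    plasma_volume_ml: float = 0.05
    #: ug of EV protein represented in the dose-aliquot reaction after its
    #: own dilution (RNA from a large aliquot diluted to mid-range load).
    dose_aliquot_ug: float = 1.0
    curve_factors: tuple[float, ...] = tuple(5.0 / 2**i for i in range(13))

    def __post_init__(self) -> None:
        if min(
            self.n_droplets,
            self.droplet_volume_nl,
            self.reaction_volume_ul,
            self.reference_high_copies,
            self.copies_per_ug,
            self.plasma_volume_ml,
        ) <= 0:
            raise ValueError("assay design values must be > 0")

    @property
    def reference_low_copies(self) -> float:
        return self.reference_high_copies / 30.0


@dataclass
class BatchWellSet:
    """Raw droplet wells for one batch (one animal's sample set)."""

    batch_id: str
    animal_id: str
    sample_wells: dict[tuple[str, float], DropletWell]
    high_standard_well: DropletWell
    low_standard_well: DropletWell
    negative_control_well: DropletWell
    dose_aliquot_well: DropletWell
    dose_aliquot_ug: float
    dilution_factors: tuple[float, ...]
    plasma_volume_ml: float
    #: Independent re-extraction of the negative control, present when the
    #: first measurement exceeded the QC threshold (failed sample sets are
    #: reanalyzed from RNA rather than excluded outright).
    negative_control_reanalysis_well: DropletWell | None = None


@dataclass
class AssayBundle:
    """Measurement layer of a study: per-batch wells plus the reference curve."""

    batches: list[BatchWellSet]
    curve_wells: list[tuple[float, DropletWell]]  # (concentration factor, well)
    design: AssayDesign


def generate_study(design: StudyDesign, seed: int) -> tuple[StudyDataset, dict]:
    """Simulate one study; returns the dataset and a ground-truth sidecar.

    Per animal: draw eta ~ N(0, omega) for the parameters carrying IIV,
    compute P_i = P_arm * exp(eta), evaluate the model at the schedule and
    apply residual error.  The sidecar maps animal id to its eta, true
    parameters and noise-free concentrations, sufficient for parameter-
    recovery assertions.
    """
    rng = np.random.default_rng(seed)
    eta_names = [n for n in design.spec.structural_names if n in design.omega]
    sds = np.sqrt([design.omega[n] for n in eta_names])
    subjects: list[Subject] = []
    truth: dict[str, dict] = {}
    times = list(design.schedule_min)
    dose = DoseEvent(amount=design.dose_amount_ug)
    for line, arm in design.arms.items():
        base = arm.params.as_dict()
        for a in range(arm.n_animals):
            sid = f"{line}-{a + 1:02d}"
            eta = rng.standard_normal(len(eta_names)) * sds
            vals = dict(base)
            for name, e in zip(eta_names, eta):
                vals[name] = vals[name] * math.exp(e)
            params = StructuralParams(
                v1=vals["v1"],
                v2=vals.get("v2"),
                v3=vals.get("v3"),
                cl=(vals["cl"],),
                cl2=vals.get("cl2"),
                cl3=vals.get("cl3"),
            )
            conc = predict_concentrations(params, design.spec, dose, times)
            if design.sigma > 0:
                eps = rng.standard_normal(len(times)) * design.sigma
                if design.residual == "log_additive":
                    obs = conc * np.exp(eps)
                else:
                    obs = np.maximum(conc * (1.0 + eps), 0.0)
            else:
                obs = conc.copy()
            weight = rng.normal(design.weight_mean_g, design.weight_sd_g)
            subjects.append(
                Subject(
                    id=sid,
                    dose=dose,
                    observations=list(zip(times, obs.tolist())),
                    covariates={"cell_line": line, "weight_g": round(float(weight), 1), "batch": sid},
                )
            )
            truth[sid] = {
                "eta": dict(zip(eta_names, eta.tolist())),
                "params": params,
                "conc_true": conc.tolist(),
            }
    return StudyDataset(subjects=subjects), truth


def _simulate_well(true_copies: float, assay: AssayDesign, rng: np.random.Generator) -> DropletWell:
    """Poisson-partition a known copy load into a droplet well.

    The expected copies per droplet follow from the droplet/reaction
    volume ratio; positives are binomial with p = 1 - exp(-lambda).  A
    load that would saturate every droplet is clipped just below
    saturation (the assay's upper detection limit).
    """
    lam = true_copies * assay.droplet_volume_nl / (assay.reaction_volume_ul * 1000.0)
    p = 1.0 - math.exp(-lam) if lam < 700 else 1.0
    n_pos = int(rng.binomial(assay.n_droplets, p))
    if n_pos == assay.n_droplets:
        n_pos = assay.n_droplets - 1  # upper-limit clip
    return DropletWell(
        n_positive=n_pos,
        n_total=assay.n_droplets,
        droplet_volume_nl=assay.droplet_volume_nl,
        reaction_volume_ul=assay.reaction_volume_ul,
    )


def generate_assay_layer(
    dataset: StudyDataset, assay: AssayDesign, seed: int
) -> AssayBundle:
    """Simulate the ddPCR measurement of every observation in a study.

    Each animal forms one batch carrying its own high/low standards,
    negative control and dose aliquot; a common log-normal batch scale
    factor hits samples, standards and aliquot alike.  True copy loads
    invert the quantification chain: copies = conc * copies_per_ug *
    plasma_volume / dilution.
    """
    rng = np.random.default_rng(seed)
    ln_sd = math.sqrt(math.log(1.0 + assay.negctrl_cv**2))
    ln_mu = math.log(assay.negctrl_median_copies)
    dilution = math.prod(assay.dilution_factors)
    batches: list[BatchWellSet] = []
    for subj in dataset.subjects:
        if any(c < 0 for _, c in subj.observations):
            raise ValueError(f"negative concentration for {subj.id}")
        batch_scale = math.exp(rng.normal(0.0, assay.batch_effect_sd))
        wells: dict[tuple[str, float], DropletWell] = {}
        for t, conc in subj.observations:
            true_copies = conc * assay.copies_per_ug * assay.plasma_volume_ml / dilution
            wells[(subj.id, t)] = _simulate_well(true_copies * batch_scale, assay, rng)
        high = _simulate_well(assay.reference_high_copies * batch_scale, assay, rng)
        low = _simulate_well(assay.reference_low_copies * batch_scale, assay, rng)
        neg_level = math.exp(rng.normal(ln_mu, ln_sd))
        neg = _simulate_well(neg_level, assay, rng)
        reanalysis = None
        if neg_level > 200.0:  # failing sample sets get an independent re-extraction
            reanalysis = _simulate_well(math.exp(rng.normal(ln_mu, ln_sd)), assay, rng)
        aliquot = _simulate_well(
            assay.copies_per_ug * assay.dose_aliquot_ug * batch_scale, assay, rng
        )
        batches.append(
            BatchWellSet(
                batch_id=f"batch-{subj.id}",
                animal_id=subj.id,
                sample_wells=wells,
                high_standard_well=high,
                low_standard_well=low,
                negative_control_well=neg,
                dose_aliquot_well=aliquot,
                dose_aliquot_ug=assay.dose_aliquot_ug,
                dilution_factors=assay.dilution_factors,
                plasma_volume_ml=assay.plasma_volume_ml,
                negative_control_reanalysis_well=reanalysis,
            )
        )
    curve_rng = np.random.default_rng(seed + 1)
    curve_wells = [
        (f, _simulate_well(assay.reference_high_copies * f, assay, curve_rng))
        for f in assay.curve_factors
    ]
    return AssayBundle(batches=batches, curve_wells=curve_wells, design=assay)


def inject_pathologies(
    bundle: AssayBundle, kinds: tuple[str, ...], seed: int
) -> tuple[AssayBundle, dict[str, str]]:
    """Inject QC pathologies into a measured study; returns expected exclusions.

    ``contamination``: a large copy load is added to one animal's last
    sample well, producing the implausible late-time rise the pipeline's
    contamination screen flags.  ``qc_failure``: one animal's negative
    control is forced above the 200-copy threshold.  Targets are the first
    RFL6 and RMC animals by default (matching the excluded-arm pattern of
    the emulated study), falling back to any animal.
    """
    allowed = {"contamination", "qc_failure"}
    if not set(kinds) <= allowed:
        raise ValueError(f"kinds must be a subset of {sorted(allowed)}")
    rng = np.random.default_rng(seed)
    expected: dict[str, str] = {}
    batches = [replace(b, sample_wells=dict(b.sample_wells)) for b in bundle.batches]
    assay = bundle.design

    def pick(prefix: str) -> BatchWellSet:
        for b in batches:
            if b.animal_id.startswith(prefix) and b.animal_id not in expected:
                return b
        return next(b for b in batches if b.animal_id not in expected)

    if "contamination" in kinds:
        b = pick("RFL6")
        key = max(b.sample_wells, key=lambda k: k[1])  # latest sample
        well = b.sample_wells[key]
        p = well.n_positive / well.n_total
        lam = -math.log1p(-p) if p < 1 else 700.0
        copies = lam * assay.reaction_volume_ul * 1000.0 / assay.droplet_volume_nl
        b.sample_wells[key] = _simulate_well(copies * 200.0 + 5000.0, assay, rng)
        expected[b.animal_id] = "contamination"
    if "qc_failure" in kinds:
        # persistent contamination of the animal's negative control: the
        # reanalysis from RNA reads high as well, so the exclusion sticks
        b = pick("RMC")
        idx = batches.index(b)
        batches[idx] = replace(
            b,
            negative_control_well=_simulate_well(2000.0, assay, rng),
            negative_control_reanalysis_well=_simulate_well(2000.0, assay, rng),
        )
        expected[batches[idx].animal_id] = "qc_failure"
    return AssayBundle(batches=batches, curve_wells=bundle.curve_wells, design=assay), expected
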