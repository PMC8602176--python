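"""CSV/JSON readers and writers for study data and results.

The dataset dialect is a long-format CSV with fixed header
``id,time_min,dv,amt,cell_line,weight_g,batch``: one dose row per animal
(time_min 0, amt > 0, dv empty) followed by observation rows (dv present,
amt empty).  Missing values are empty fields; encoding UTF-8.  Round
trips are exact: read(write(x)) == x.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path

import pandas as pd

from .ddpcr_quant import DropletWell
from .nlme_engine import FitResult, StudyDataset, Subject
from .pk_model import DoseEvent
from .synthetic_data import AssayBundle, AssayDesign, BatchWellSet

__all__ = [
    "read_dataset",
    "write_dataset",
    "write_fit_result",
    "write_assay_bundle",
    "read_assay_bundle",
    "write_concentration_table",
]

DATASET_COLUMNS = ["id", "time_min", "dv", "amt", "cell_line", "weight_g", "batch"]


def write_dataset(dataset: StudyDataset, path) -> None:
    path = Path(path)
    with path.open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(DATASET_COLUMNS)
        for s in dataset.subjects:
            cov = s.covariates
            meta = [cov.get("cell_line", ""), cov.get("weight_g", ""), cov.get("batch", "")]
            w.writerow([s.id, 0, "", repr(s.dose.amount), *meta])
            for t, dv in s.observations:
                w.writerow([s.id, repr(t), repr(dv), "", *meta])
    if dataset.exclusions:
        with path.with_suffix(".exclusions.json").open("w") as fh:
            json.dump(dataset.exclusions, fh, indent=2)


def read_dataset(path) -> StudyDataset:
    """Parse the long-format dataset dialect; malformed rows name their line."""
    path = Path(path)
    doses: dict[str, float] = {}
    obs: dict[str, list[tuple[float, float]]] = {}
    covs: dict[str, dict] = {}
    order: list[str] = []
    with path.open(newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None or [h.strip() for h in header] != DATASET_COLUMNS:
            raise ValueError(f"{path}: expected header {','.join(DATASET_COLUMNS)}")
        for lineno, row in enumerate(reader, start=2):
            if not row or all(not f.strip() for f in row):
                continue
            if len(row) != len(DATASET_COLUMNS):
                raise ValueError(f"{path}:{lineno}: expected {len(DATASET_COLUMNS)} fields, got {len(row)}")
            sid, t_s, dv_s, amt_s, line, weight, batch = (f.strip() for f in row)
            if not sid:
                raise ValueError(f"{path}:{lineno}: missing id")
            try:
                t = float(t_s)
            except ValueError:
                raise ValueError(f"{path}:{lineno}: bad time_min {t_s!r}") from None
            if sid not in covs:
                order.append(sid)
                covs[sid] = {}
            if line:
                covs[sid]["cell_line"] = line
            if weight:
                covs[sid]["weight_g"] = float(weight)
            if batch:
                covs[sid]["batch"] = batch
            if amt_s:
                try:
                    amt = float(amt_s)
                except ValueError:
                    raise ValueError(f"{path}:{lineno}: bad amt {amt_s!r}") from None
                if t != 0:
                    raise ValueError(f"{path}:{lineno}: dose rows must have time_min 0")
                doses[sid] = amt
            elif dv_s:
                try:
                    dv = float(dv_s)
                except ValueError:
                    raise ValueError(f"{path}:{lineno}: bad dv {dv_s!r}") from None
                obs.setdefault(sid, []).append((t, dv))
            else:
                raise ValueError(f"{path}:{lineno}: row has neither dv nor amt")
    if not obs:
        raise ValueError(f"{path}: no observations")
    subjects = []
    for sid in order:
        if sid not in doses:
            raise ValueError(f"{path}: subject {sid} has no dose row")
        if sid not in obs:
            raise ValueError(f"{path}: subject {sid} has no observations")
        subjects.append(
            Subject(
                id=sid,
                dose=DoseEvent(amount=doses[sid]),
                observations=sorted(obs[sid]),
                covariates=covs[sid],
            )
        )
    exc_path = path.with_suffix(".exclusions.json")
    exclusions = json.loads(exc_path.read_text()) if exc_path.exists() else {}
    return StudyDataset(subjects=subjects, exclusions=exclusions)


def write_concentration_table(conc: pd.DataFrame, path) -> None:
    """Normalized concentrations keyed (id, time_min), ready for the dataset reader."""
    conc.to_csv(path, index=False)


def write_fit_result(fit_result: FitResult, directory, stem: str = "fit") -> None:
    """JSON fit summary plus a flat parameter CSV (estimate, se, 95% CI)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    payload = {
        "model": fit_result.model.to_dict(),
        "minus2ll": fit_result.minus2ll,
        "aic": fit_result.aic,
        "n_params": fit_result.n_params,
        "converged": fit_result.converged,
        "n_iter": fit_result.n_iter,
        "estimates": fit_result.estimates,
        "se": fit_result.se,
        "ci95": fit_result.ci95,
        "etas": {k: list(map(float, v)) for k, v in fit_result.etas.items()},
        "message": fit_result.message,
    }
    (directory / f"{stem}.json").write_text(json.dumps(payload, indent=2))
    fit_result.parameter_table().to_csv(directory / f"{stem}_parameters.csv", index=False)
    fit_result.predictions.to_csv(directory / f"{stem}_predictions.csv", index=False)


_WELL_COLUMNS = [
    "batch_id", "animal_id", "role", "time_min", "curve_factor",
    "n_positive", "n_total", "droplet_volume_nl", "reaction_volume_ul",
    "dilution_factors", "plasma_volume_ml", "dose_aliquot_ug",
]


def write_assay_bundle(bundle: AssayBundle, path) -> None:
    """Flat well-level CSV: samples, standards, controls and curve wells."""
    rows = []

    def well_row(w: DropletWell, **kw):
        base = {c: "" for c in _WELL_COLUMNS}
        base.update(
            n_positive=w.n_positive,
            n_total=w.n_total,
            droplet_volume_nl=w.droplet_volume_nl,
            reaction_volume_ul=w.reaction_volume_ul,
        )
        base.update(kw)
        rows.append(base)

    for b in bundle.batches:
        meta = dict(
            batch_id=b.batch_id,
            animal_id=b.animal_id,
            dilution_factors="|".join(repr(d) for d in b.dilution_factors),
            plasma_volume_ml=b.plasma_volume_ml,
            dose_aliquot_ug=b.dose_aliquot_ug,
        )
        for (sid, t), w in sorted(b.sample_wells.items(), key=lambda kv: kv[0][1]):
            well_row(w, role="sample", time_min=repr(t), **meta)
        well_row(b.high_standard_well, role="high_standard", **meta)
        well_row(b.low_standard_well, role="low_standard", **meta)
        well_row(b.negative_control_well, role="negative_control", **meta)
        if b.negative_control_reanalysis_well is not None:
            well_row(b.negative_control_reanalysis_well, role="negative_control_reanalysis", **meta)
        well_row(b.dose_aliquot_well, role="dose_aliquot", **meta)
    for f, w in bundle.curve_wells:
        well_row(w, role="curve", curve_factor=repr(f))
    pd.DataFrame(rows, columns=_WELL_COLUMNS).to_csv(path, index=False)


def read_assay_bundle(path, design: AssayDesign | None = None) -> AssayBundle:
    design = design or AssayDesign()
    df = pd.read_csv(path, keep_default_na=False)
    batches: list[BatchWellSet] = []

    def to_well(r) -> DropletWell:
        return DropletWell(
            n_positive=int(r["n_positive"]),
            n_total=int(r["n_total"]),
            droplet_volume_nl=float(r["droplet_volume_nl"]),
            reaction_volume_ul=float(r["reaction_volume_ul"]),
        )

    curve_wells = [
        (float(r["curve_factor"]), to_well(r))
        for _, r in df[df["role"] == "curve"].iterrows()
    ]
    for batch_id, grp in df[df["role"] != "curve"].groupby("batch_id", sort=False):
        first = grp.iloc[0]
        roles = {r["role"]: to_well(r) for _, r in grp.iterrows() if r["role"] != "sample"}
        samples = {
            (str(r["animal_id"]), float(r["time_min"])): to_well(r)
            for _, r in grp[grp["role"] == "sample"].iterrows()
        }
        batches.append(
            BatchWellSet(
                batch_id=str(batch_id),
                animal_id=str(first["animal_id"]),
                sample_wells=samples,
                high_standard_well=roles["high_standard"],
                low_standard_well=roles["low_standard"],
                negative_control_well=roles["negative_control"],
                negative_control_reanalysis_well=roles.get("negative_control_reanalysis"),
                dose_aliquot_well=roles["dose_aliquot"],
                dose_aliquot_ug=float(first["dose_aliquot_ug"]),
                dilution_factors=tuple(
                    float(x) for x in str(first["dilution_factors"]).split("|")
                ),
                plasma_volume_ml=float(first["plasma_volume_ml"]),
            )
        )
    return AssayBundle(batches=batches, curve_wells=curve_wells, design=design)
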