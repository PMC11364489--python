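"""End-to-end experiment orchestration: simulate -> encode -> train ->
predict -> evaluate, with the four-arm comparison report.

Every stage writes a ``manifest.json`` (config snapshot, seeds, input
references) into its output directory so that any number in the final
report can be traced back and recomputed from the manifest chain.
Aggregates are reported as mean +/- SD over test cases.  Undefined
metrics (e.g. a conformity index with an empty denominator) propagate as
nulls and are never replaced by sentinel numbers.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Dict, List, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .grid import StructureRole, VolumeGrid
from .metrics import (
    GammaCriteria,
    dose_difference_report,
    dvh,
    gamma_passing_rate,
    plan_quality,
)
from .model import DoseUNetRegressor, assemble_channels, load_checkpoint, save_checkpoint
from .rtio import load_case_bundle
from .synthetic import make_dataset

logger = logging.getLogger("cyberbeam")

DEFAULT_CRITERIA = ("3mm/3%", "3mm/2%", "2mm/2%")

#: Low-dose gamma cutoff (% of reference max) applied to OARs only.
OAR_THRESHOLD_PCT = 0.5


def _nan_to_none(records):
    """Replace float NaNs by JSON nulls (undefined metrics stay null)."""
    out = []
    for row in records:
        out.append({k: (None if isinstance(v, float) and np.isnan(v) else v)
                    for k, v in row.items()})
    return out


def _manifest(directory: Path, payload: Dict) -> None:
    payload = dict(payload)
    payload["software_version"] = __version__
    directory.mkdir(parents=True, exist_ok=True)
    (directory / "manifest.json").write_text(json.dumps(payload, indent=2, default=str))


def structure_threshold(role: StructureRole) -> float:
    """Gamma low-dose cutoff by role: 0.5 % of max for OARs, none elsewhere."""
    return OAR_THRESHOLD_PCT if role == StructureRole.OAR else 0.0


def evaluate_case(
    ref_dose: VolumeGrid,
    eval_dose: VolumeGrid,
    structures,
    prescription: float,
    criteria: Sequence[str] = DEFAULT_CRITERIA,
    case_id: str = "",
) -> Dict:
    """Full evaluation of one predicted dose against its reference.

    Returns gamma rows (per structure x criteria), plan-quality indices
    of both distributions on the target, and the dose-difference table.
    """
    gamma_rows = []
    for name, mask in structures.masks.items():
        role = structures.roles[name]
        if not np.any(mask):
            continue
        thr = structure_threshold(role)
        for crit in criteria:
            gc = GammaCriteria.parse(crit, threshold_pct=thr)
            res = gamma_passing_rate(ref_dose, eval_dose, mask, gc, structure=name)
            gamma_rows.append(
                {
                    "case": case_id,
                    "structure": name,
                    "role": role.value,
                    "criteria": gc.label,
                    "threshold_pct": thr,
                    "passing_rate": res.passing_rate,
                    "n_evaluated": res.n_evaluated,
                }
            )
    target = structures.target
    quality = {
        "reference": plan_quality(ref_dose, target, prescription).__dict__,
        "predicted": plan_quality(eval_dose, target, prescription).__dict__,
    }
    diff_table, _ = dose_difference_report(ref_dose, eval_dose, structures)
    diff_table.insert(0, "case", case_id)
    return {"gamma": gamma_rows, "quality": quality, "differences": diff_table}


def _dvh_figure(ref_dose, eval_dose, structures, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 5))
    colors = plt.cm.tab10.colors
    for i, (name, mask) in enumerate(structures.masks.items()):
        if structures.roles[name] == StructureRole.RING or not np.any(mask):
            continue
        c = colors[i % len(colors)]
        for dose_grid, style, label in ((ref_dose, "-", "ref"), (eval_dose, "--", "pred")):
            curve = dvh(dose_grid, mask, bin_width=0.1, structure=name)
            ax.plot(curve.dose_edges, 100 * curve.volume_fraction, style, color=c,
                    label=f"{name} ({label})", linewidth=1)
    ax.set_xlabel("Dose (Gy)")
    ax.set_ylabel("Volume (%)")
    ax.legend(fontsize=6, ncol=2)
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)


def load_split(data_dir) -> Dict[str, List[Path]]:
    """Case directories per split label from a dataset manifest."""
    data_dir = Path(data_dir)
    manifest = json.loads((data_dir / "manifest.json").read_text())
    split: Dict[str, List[Path]] = {"train": [], "val": [], "test": [], "extra": []}
    for entry in manifest["cases"]:
        split[entry["split"]].append(data_dir / entry["case"])
    return split


def _assemble(case_dir: Path, arm: str):
    bundle, beam = load_case_bundle(case_dir)
    if beam is None:
        raise FileNotFoundError(f"{case_dir} has no encoded beam matrix")
    return assemble_channels(bundle, beam, arm, case_id=case_dir.name), bundle


def train_arm(
    data_dir,
    arm: str,
    out_dir,
    seed: int = 0,
    **net_overrides,
) -> DoseUNetRegressor:
    """Train one arm on a dataset directory; writes a checkpoint + manifest."""
    out_dir = Path(out_dir)
    split = load_split(data_dir)
    logger.info("train arm=%s seed=%d cases=%d/%d", arm, seed,
                len(split["train"]), len(split["val"]))
    train_cases = [_assemble(d, arm)[0] for d in split["train"]]
    val_cases = [_assemble(d, arm)[0] for d in split["val"]]
    model = DoseUNetRegressor(arm=arm, seed=seed, **net_overrides)
    model.fit(train_cases, val_cases)
    save_checkpoint(model, out_dir)
    _manifest(out_dir, {
        "stage": "train",
        "arm": arm,
        "seed": seed,
        "data": str(data_dir),
        "config": model.get_params(),
        "best_epoch": model.best_epoch_,
        "n_parameters": model.n_parameters_,
    })
    return model


def predict_case_dir(run_dir, case_dir, out_path=None) -> VolumeGrid:
    """Predict the dose for one case directory with a trained run."""
    model = load_checkpoint(run_dir)
    case, bundle = _assemble(Path(case_dir), model.arm)
    pred = model.predict(case)
    if out_path is not None:
        out_path = Path(out_path)
        if out_path.suffix == ".dcm":
            from .rtio import write_dose

            write_dose(pred, out_path)
        else:
            np.savez_compressed(out_path, dose=pred.values.astype(np.float32))
    return pred


def run_experiment(config: Dict, out_dir) -> Dict:
    """Run the full multi-arm comparison defined by ``config``.

    Config keys: ``data`` (existing dataset dir) or ``simulate``
    (kwargs for :func:`~cyberbeam.synthetic.make_dataset`), ``arms``,
    ``criteria``, ``seed``, ``net`` (estimator overrides).  Produces per
    arm: a trained run, per-case gamma/quality/difference tables, DVH
    figures, and aggregated CSV/JSON summaries.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    arms = list(config.get("arms", ["TB", "CT+TB"]))
    criteria = list(config.get("criteria", DEFAULT_CRITERIA))
    net = dict(config.get("net", {}))
    logger.info("experiment start: arms=%s seed=%d criteria=%s", arms, seed, criteria)

    if "data" in config:
        data_dir = Path(config["data"])
    else:
        sim = dict(config.get("simulate", {}))
        sim.setdefault("n_cases", 8)
        sim.setdefault("split", (5, 1, 2))
        sim.setdefault("seed", seed)
        data_dir = out_dir / "data"
        make_dataset(data_dir, **sim)
    split = load_split(data_dir)
    if not split["test"]:
        raise ValueError("dataset has no test cases")

    all_gamma: List[Dict] = []
    all_quality: List[Dict] = []
    diff_frames: List[pd.DataFrame] = []
    for arm in arms:
        arm_dir = out_dir / arm.replace("+", "_")
        model = train_arm(data_dir, arm, arm_dir / "run", seed=seed, **net)
        for case_dir in split["test"]:
            case, bundle = _assemble(case_dir, arm)
            pred = model.predict(case)
            np.savez_compressed(
                arm_dir / f"pred_{case_dir.name}.npz", dose=pred.values.astype(np.float32)
            )
            result = evaluate_case(
                bundle.dose, pred, bundle.structures, case.prescription,
                criteria, case_id=case_dir.name,
            )
            for row in result["gamma"]:
                row["arm"] = arm
                all_gamma.append(row)
            for which in ("reference", "predicted"):
                all_quality.append(
                    {"arm": arm, "case": case_dir.name, "distribution": which,
                     **result["quality"][which]}
                )
            frame = result["differences"]
            frame.insert(0, "arm", arm)
            diff_frames.append(frame)
            _dvh_figure(bundle.dose, pred, bundle.structures,
                        arm_dir / f"dvh_{case_dir.name}.png")
        _manifest(arm_dir, {"stage": "evaluate", "arm": arm, "run": str(arm_dir / "run"),
                            "data": str(data_dir), "criteria": criteria})

    gamma_df = pd.DataFrame(all_gamma)
    quality_df = pd.DataFrame(all_quality)
    diff_df = pd.concat(diff_frames, ignore_index=True) if diff_frames else pd.DataFrame()
    gamma_df.to_csv(out_dir / "gamma.csv", index=False)
    quality_df.to_csv(out_dir / "quality.csv", index=False)
    diff_df.to_csv(out_dir / "differences.csv", index=False)

    summary = (
        gamma_df.dropna(subset=["passing_rate"])
        .groupby(["arm", "structure", "criteria"])["passing_rate"]
        .agg(["mean", "std", "count"])
        .reset_index()
        .to_dict(orient="records")
    )
    summary = _nan_to_none(summary)
    report = {
        "seed": seed,
        "arms": arms,
        "criteria": criteria,
        "data": str(data_dir),
        "gamma_summary": summary,
        "quality": _nan_to_none(quality_df.to_dict(orient="records")),
    }
    (out_dir / "report.json").write_text(json.dumps(report, indent=2, default=str))
    _manifest(out_dir, {"stage": "report", "config": config})
    return report
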