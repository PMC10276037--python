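"""End-to-end orchestration: generate -> solve -> label -> split -> train -> evaluate.

A single run configuration (YAML/JSON-able dict) drives the whole pipeline;
every stage draws its randomness from a named sub-stream of one root seed, so
runs are reproducible and stages are independently perturbable.  Artifacts
are written under ``out_dir``: per-sample geometry files (npz + PNG), a
dataset bundle, a CSV manifest, a training-log CSV and an evaluation report.
"""

from __future__ import annotations

import json
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as pio
from .geometry import (
    GeneratorConfigA,
    GeneratorConfigB,
    PorousSample,
    generate_type_a,
    generate_type_b,
)
from .lbm import BoundarySpec, SolverConfig, effective_diffusion, solve_steady
from .metrics import ArchieFit, SampleRecord, fit_archie
from .models import SurrogateSpec, build_model
from .training import (
    Task,
    TrainConfig,
    augment_hflip,
    evaluate_field,
    evaluate_scalar,
    geometry_image,
    split_dataset,
    train,
)

__all__ = ["default_config", "make_labelled_set", "run_pipeline", "archie_from_samples"]


def default_config(scaled: bool = True) -> dict:
    """Baseline run configuration; ``scaled`` gives the desk-test variant."""
    full = {
        "seed": 0,
        "out_dir": "porediff_run",
        "L": 128,
        "sample_type": "A",
        "n_samples": 2017,
        "phi_range": [0.45, 0.95],
        "n_points": 50,
        "solver": {"tolerance": 1e-13, "max_iterations": 1_000_000},
        "task": "SCALAR",
        "model": {"kind": "CNET", "sn_enabled": True, "dropout_p": 0.1},
        "train": {"epochs": 200, "batch_size": 16, "learning_rate": 1e-3,
                  "split_fraction": 0.7, "augment": True},
        "mc_passes": 20,
    }
    if scaled:
        full.update(
            L=64, n_samples=120, n_points=12,
            solver={"tolerance": 1e-10, "max_iterations": 1_000_000},
        )
        full["train"].update(epochs=30)
        full["model"] = {
            "kind": "UNET_HALF", "sn_enabled": True, "dropout_p": 0.1,
            "n_containers": 3, "blocks_per_container": 2, "channels": 32,
        }
    return full


def _substream(seed: int, name: str) -> np.random.Generator:
    tag = int.from_bytes(name.encode()[:4].ljust(4, b"\0"), "little")
    return np.random.default_rng(np.random.SeedSequence([int(seed), tag]))


def generate_samples(cfg: dict, rng: np.random.Generator) -> list[PorousSample]:
    L = cfg["L"]
    lo, hi = cfg["phi_range"]
    samples = []
    for _ in range(cfg["n_samples"]):
        tgt = float(rng.uniform(lo, hi))
        seed = int(rng.integers(2**31))
        if cfg["sample_type"] == "A":
            samples.append(generate_type_a(L, GeneratorConfigA(target_porosity=tgt), seed))
        else:
            samples.append(
                generate_type_b(
                    L, GeneratorConfigB(n_points=cfg["n_points"], target_porosity=tgt), seed
                )
            )
    return samples


def make_labelled_set(samples, solver_cfg: SolverConfig, bc: BoundarySpec | None = None,
                      progress: bool = False):
    """Solve every sample; return (records, fields)."""
    bc = bc or BoundarySpec()
    records, fields = [], []
    for i, s in enumerate(samples):
        fld = solve_steady(s, bc=bc, cfg=solver_cfg)
        D = max(effective_diffusion(fld, s, bc), 0.0)
        records.append(SampleRecord(f"{s.sample_type.value}{i:05d}", s.porosity, D))
        fields.append(fld)
        if progress and (i + 1) % 25 == 0:
            print(f"  solved {i + 1}/{len(samples)}")
    return records, fields


def archie_from_samples(samples, solver_cfg: SolverConfig | None = None) -> ArchieFit:
    solver_cfg = solver_cfg or SolverConfig(tolerance=1e-10)
    records, _ = make_labelled_set(samples, solver_cfg)
    return fit_archie(records)


def run_pipeline(cfg: dict, force: bool = False) -> Path:
    """Execute the full pipeline; returns the artifact directory.

    Idempotent: if the output manifest already exists the run is skipped
    unless ``force``.
    """
    out = Path(cfg.get("out_dir", "porediff_run"))
    manifest_path = out / "manifest.csv"
    if manifest_path.exists() and not force:
        print(f"[run] outputs exist at {out}; use force to regenerate")
        return out
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg.get("seed", 0))
    log = []

    def stage(name):
        t = time.time()
        log.append({"stage": name, "seed": seed, "t_start": t})
        print(f"[run] {name} ...")
        return t

    task = Task(cfg.get("task", "SCALAR"))
    stage("generate")
    samples = generate_samples(cfg, _substream(seed, "gen"))

    stage("solve")
    solver_cfg = SolverConfig(**cfg.get("solver", {}))
    records, fields = make_labelled_set(samples, solver_cfg, progress=True)

    stage("dataset")
    X = np.stack([geometry_image(s) for s in samples])
    if task is Task.SCALAR:
        Y = np.array([[r.phi, r.D] for r in records], dtype=np.float32)
    else:
        Y = np.stack(
            [np.where(s.fluid_mask, f.values, 0.0)[None].astype(np.float32)
             for s, f in zip(samples, fields)]
        )
    tr_cfg = cfg.get("train", {})
    frac = float(tr_cfg.get("split_fraction", 0.7))
    idx_train, idx_val = split_dataset(list(range(len(samples))), frac,
                                       _substream(seed, "splt").integers(2**31))
    rows = []
    for i, (s, r, f) in enumerate(zip(samples, records, fields)):
        gpath = out / "geometry" / f"{r.sample_id}.npz"
        pio.save_sample(gpath, s)
        pio.sample_to_png(out / "geometry" / f"{r.sample_id}.png", s)
        rows.append(
            {
                "sample_id": r.sample_id, "type": s.sample_type.value,
                "seed": s.seed, "target_phi": s.target_porosity,
                "phi": r.phi, "D": r.D,
                "split": "train" if i in set(idx_train) else "val",
                "geometry_path": str(gpath), "field_path": "",
            }
        )
    np.savez_compressed(out / "dataset.npz", X=X, Y=Y,
                        idx_train=idx_train, idx_val=idx_val)
    pio.write_manifest(manifest_path, rows)

    stage("train")
    Xtr, Ytr = X[idx_train], Y[idx_train]
    if tr_cfg.get("augment", True) and task is Task.SCALAR:
        aug = [augment_hflip(x, y, task) for x, y in zip(Xtr, Ytr)]
        Xtr = np.concatenate([Xtr, np.stack([a[0] for a in aug])])
        Ytr = np.concatenate([Ytr, np.stack([a[1] for a in aug])])
    model_cfg = dict(cfg.get("model", {}))
    model_cfg.setdefault("input_side", cfg["L"])
    spec = SurrogateSpec(**model_cfg)
    model = build_model(spec, rng=_substream(seed, "init"))
    train_config = TrainConfig(
        task=task,
        split_fraction=frac,
        batch_size=int(tr_cfg.get("batch_size", 16)),
        epochs=int(tr_cfg.get("epochs", 30)),
        learning_rate=float(tr_cfg.get("learning_rate", 1e-3)),
        lr_drop_epoch=tr_cfg.get("lr_drop_epoch"),
        seed=int(_substream(seed, "trai").integers(2**31)),
        augment=bool(tr_cfg.get("augment", True)),
    )
    history = train(model, (Xtr, Ytr), (X[idx_val], Y[idx_val]), train_config)
    pd.DataFrame(
        {k: v for k, v in history.items() if isinstance(v, list)}
    ).to_csv(out / "training_log.csv", index_label="epoch")

    stage("evaluate")
    M = int(cfg.get("mc_passes", 20))
    eval_seed = int(_substream(seed, "drop").integers(2**31))
    if task is Task.SCALAR:
        report = evaluate_scalar(model, (X[idx_val], Y[idx_val]), M=M, seed=eval_seed)
        summary = {k: report[k] for k in
                   ("mse", "chibar2", "coverage_1sigma", "coverage_2sigma")}
    else:
        report = evaluate_field(model, (X[idx_val], Y[idx_val]), M=M, seed=eval_seed)
        summary = {"mean_abs_error": report["mean_abs_error"],
                   "mean_uncertainty": report["mean_uncertainty"]}
    fit = None
    try:
        fit = fit_archie(records)
        summary["archie_n"] = fit.n
    except ValueError:
        pass
    summary["manifest_hash"] = pio.manifest_hash(manifest_path)
    (out / "evaluation.json").write_text(json.dumps(summary, indent=2))
    _plot_archie(out, records, fit)
    print(f"[run] done: {json.dumps(summary)}")
    return out


def _plot_archie(out: Path, records, fit: ArchieFit | None) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    phi = np.array([r.phi for r in records])
    D = np.array([r.D for r in records])
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.plot(phi, D, "o", mfc="none", label="LBM")
    if fit is not None:
        xx = np.linspace(max(phi.min(), 1e-3), 1.0, 100)
        ax.plot(xx, xx ** (fit.n - 1.0), "g-", label=f"Archie fit n={fit.n:.2f}")
    ax.set_xlabel(r"porosity $\varphi$")
    ax.set_ylabel(r"effective diffusion $D/D_0$")
    ax.legend()
    fig.tight_layout()
    fig.savefig(out / "archie.png", dpi=120)
    plt.close(fig)
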