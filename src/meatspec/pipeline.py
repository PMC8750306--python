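"""Config-driven end-to-end runs: simulate/load → split → model → report.

A run is described by one mapping (usually a YAML file) with an explicit
master seed.  Stage seeds are fanned out deterministically from the master
seed through ``numpy.random.SeedSequence(master, spawn_key=(stage,))`` so a
single number reproduces every artefact.  Each run writes its numeric tables
as CSV plus a ``manifest.json`` recording the config hash, the derived
seeds and the package version.
"""

from __future__ import annotations

import hashlib
import json
import sys
import time
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .dataset import SpectralDataset, read_spectra_table, write_spectra_table
from .discriminant import EvaluationBlock, evaluate_on_split, leave_class_out
from .errors import ConfigError
from .occ import (
    ScreeningRecord,
    classify_samples,
    correct_classification_rate,
    default_grid,
    fit_screening_ensemble,
    screen_grid,
    screening_table,
    select_triplet,
)
from .preprocess import PreprocessSpec, apply_chain
from .serialize import save_occ_models
from .simulate import SimConfig, generate_dataset
from .splitting import stratified_sample_split

_STAGES = ("simulate", "split", "screen", "model", "evaluate")


def stage_seed(master: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the master seed (< 2^31)."""
    if stage not in _STAGES:
        raise ConfigError(f"unknown stage {stage!r}")
    ss = np.random.SeedSequence(master, spawn_key=(_STAGES.index(stage),))
    return int(ss.generate_state(1)[0] % 2**31)


def _config_hash(cfg: Mapping) -> str:
    return hashlib.sha256(json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest()[:16]


def _log(msg: str, t0: float) -> None:
    print(f"[meatspec +{time.perf_counter() - t0:6.1f}s] {msg}", file=sys.stderr)


def _load_data(cfg: Mapping, seed: int) -> SpectralDataset:
    data = cfg.get("data")
    if not isinstance(data, Mapping) or ("file" not in data) == ("simulate" not in data):
        raise ConfigError("config needs data.file or data.simulate (exactly one)")
    if "file" in data:
        return read_spectra_table(data["file"])
    sim = dict(data["simulate"])
    sim.setdefault("seed", seed)
    return generate_dataset(SimConfig(**sim))


def run_pipeline(cfg: Mapping[str, Any], out_dir: str | Path) -> dict[str, Any]:
    """Execute the configured stages and write all artefacts under ``out_dir``.

    Returns the results bundle (also the input of :func:`report`).  The
    config must set ``seed``; the method block is either ``occ`` (screening →
    triplet → scenario classification) or ``discriminant`` (fixed chain →
    PLS-DA or SVM → train/CV/test metrics, optional leave-class-out).
    """
    if "seed" not in cfg:
        raise ConfigError("config must set an explicit master seed ('seed')")
    master = int(cfg["seed"])
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    t0 = time.perf_counter()
    bundle: dict[str, Any] = {"config": dict(cfg), "out_dir": str(out_dir)}

    ds = _load_data(cfg, stage_seed(master, "simulate"))
    _log(f"data ready: {ds.n_scans} scans × {ds.grid.n_channels} channels", t0)
    if cfg.get("write_data", False):
        write_spectra_table(ds, out_dir / "data.csv")

    split_cfg = dict(cfg.get("split", {}))
    split = stratified_sample_split(
        ds,
        method=split_cfg.get("method", "duplex"),
        train_fraction=float(split_cfg.get("train_fraction", 0.7)),
        seed=stage_seed(master, "split"),
    )
    split.to_frame().to_csv(out_dir / "split.csv", index=False)
    _log(f"split: {len(split.train_groups)} train / {len(split.test_groups)} test samples", t0)

    method = cfg.get("method", {})
    kind = method.get("kind", "occ")
    if kind == "occ":
        bundle.update(_run_occ(ds, split, method, master, out_dir, t0))
    elif kind == "discriminant":
        bundle.update(_run_discriminant(ds, split, method, master, out_dir, t0))
    else:
        raise ConfigError(f"unknown method kind {kind!r}")

    manifest = {
        "package_version": __version__,
        "config_hash": _config_hash(cfg),
        "master_seed": master,
        "stage_seeds": {s: stage_seed(master, s) for s in _STAGES},
        "artifacts": sorted(p.name for p in out_dir.iterdir() if p.is_file()),
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    bundle["manifest"] = manifest
    return bundle


def _parse_grid(method: Mapping) -> list[tuple[PreprocessSpec, str, dict]]:
    raw = method.get("grid", "default")
    if raw == "default":
        return default_grid()
    grid = []
    for entry in raw:
        spec = PreprocessSpec.from_string(entry["chain"])
        grid.append((spec, entry["algorithm"], dict(entry.get("params", {}))))
    return grid


def _run_occ(ds, split, method: Mapping, master: int, out_dir: Path, t0) -> dict:
    records = screen_grid(
        ds,
        _parse_grid(method),
        n_repeats=int(method.get("n_repeats", 80)),
        train_fraction=float(method.get("train_fraction", 0.7)),
        seed=stage_seed(master, "screen"),
    )
    screening_table(records).to_csv(out_dir / "screening.csv", index=False)
    combos = select_triplet(records, override=method.get("combos"))
    _log(f"screened {len(records)} combos; selected {combos}", t0)
    models = fit_screening_ensemble(
        ds, records, combos, split.train_groups, q=float(method.get("scenario2_q", 0.95))
    )
    save_occ_models(models, out_dir / "models.json")
    truth = ds.sample_species()
    decisions_frames = []
    rates: dict[int, dict[str, float]] = {}
    for scenario in (1, 2):
        decisions = classify_samples(models, ds, scenario)
        rates[scenario] = correct_classification_rate(decisions, truth)
        decisions_frames.append(
            pd.DataFrame(
                {
                    "sample_id": [d.sample_id for d in decisions],
                    "species": [truth[d.sample_id] for d in decisions],
                    "scenario": scenario,
                    "flag": [d.flag for d in decisions],
                }
            )
        )
    pd.concat(decisions_frames).to_csv(out_dir / "decisions.csv", index=False)
    pd.DataFrame(rates).rename_axis("species").to_csv(out_dir / "rates.csv")
    _log(f"scenario rates written ({len(decisions_frames[0])} samples)", t0)
    return {"screening": records, "triplet": combos, "rates": rates}


def _run_discriminant(ds, split, method: Mapping, master: int, out_dir: Path, t0) -> dict:
    spec = PreprocessSpec.from_string(method.get("preprocess", "snv"))
    labels = list(ds.species)
    Y = None
    if spec.requires_y:
        from .discriminant import indicator_matrix

        Y = indicator_matrix(
            [labels[i] for i in split.train_rows], sorted(set(labels))
        )
    Xtr, Xte = apply_chain(spec, ds.X[split.train_rows], ds.X[split.test_rows], Y)
    X = np.zeros((ds.n_scans, Xtr.shape[1]))
    X[split.train_rows] = Xtr
    X[split.test_rows] = Xte
    seed = stage_seed(master, "model")
    blocks = evaluate_on_split(
        X,
        labels,
        list(ds.sample_ids),
        split.train_rows,
        split.test_rows,
        method=method.get("model", "plsda"),
        max_lv=int(method.get("max_lv", 10)),
        cv_scheme=method.get("cv_scheme", "venetian_blinds"),
        cv_params=method.get("cv_params"),
        seed=seed,
    )
    frames = []
    for name, block in blocks.items():
        frame = block.metrics.copy()
        frame.insert(0, "block", name)
        frames.append(frame)
        block.confusion.to_frame().to_csv(out_dir / f"confusion_{name}.csv")
    pd.concat(frames).rename_axis("class").to_csv(out_dir / "metrics.csv")
    _log("train/cv/test metric blocks written", t0)
    bundle = {"blocks": blocks}
    if method.get("leave_class_out", False):
        lco = leave_class_out(
            X[split.train_rows],
            [labels[i] for i in split.train_rows],
            groups=[ds.meta[i].sample_id for i in split.train_rows],
            seed=seed,
        )
        lco.to_csv(out_dir / "lco.csv", index=False)
        bundle["lco"] = lco
        _log("leave-class-out table written", t0)
    return bundle


# ---------------------------------------------------------------------------
# human-readable reporting
# ---------------------------------------------------------------------------


def _fmt_pct(v: float) -> str:
    return f"{v:5.1f}"


def report(results: Mapping[str, Any] | None) -> str:
    """Summarise a results bundle as text tables.

    Screening AUROCs, scenario correct-classification rates, train/CV/test
    metric blocks and leave-class-out allocations are rendered when present;
    an empty bundle yields an explicit "no results" stanza.
    """
    if not results:
        return "meatspec report\n===============\n(no results)\n"
    lines = ["meatspec report", "==============="]
    if results.get("screening"):
        lines += ["", "Screening (mean AUROC over CV repeats)", "-" * 40]
        records: Sequence[ScreeningRecord] = results["screening"]
        for r in records:
            if r.failed:
                lines.append(f"{r.combo_id:55s}  FAILED ({r.error})")
            else:
                cells = "  ".join(f"{k}={v:.3f}" for k, v in r.auroc_vs.items())
                lines.append(f"{r.combo_id:55s}  {cells}")
    if results.get("triplet"):
        lines += ["", f"Selected triplet: {', '.join(results['triplet'])}"]
    if results.get("rates"):
        lines += ["", "Correct classification rate (%) per scenario", "-" * 44]
        rates = results["rates"]
        species = sorted({s for r in rates.values() for s in r})
        lines.append("species   " + "  ".join(f"scenario {k}" for k in sorted(rates)))
        for s in species:
            cells = "  ".join(
                f"{_fmt_pct(rates[k].get(s, float('nan'))):>10s}" for k in sorted(rates)
            )
            lines.append(f"{s:8s}  {cells}")
    if results.get("blocks"):
        lines += ["", "Per-class metrics (%) by block", "-" * 32]
        blocks: Mapping[str, EvaluationBlock] = results["blocks"]
        for name, block in blocks.items():
            lines.append(f"[{name}]")
            for cls, row in block.metrics.iterrows():
                lines.append(
                    f"  {cls:8s} sens={_fmt_pct(100 * row.sensitivity)} "
                    f"spec={_fmt_pct(100 * row.specificity)} "
                    f"acc={_fmt_pct(100 * row.accuracy)} err={_fmt_pct(100 * row.error)}"
                )
    if results.get("lco") is not None and len(results.get("lco", [])):
        lines += ["", "Leave-class-out allocations", "-" * 27]
        lines.append(results["lco"].to_string(index=False))
    if len(lines) == 2:
        lines.append("(no results)")
    return "\n".join(lines) + "\n"
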