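"""JSON serialisation of fitted one-class models.

A model file carries, per model: the algorithm id, the canonical
pre-processing chain string, the algorithm parameters, the fitted state of
every stateful chain step and of the algorithm itself, and the calibrated
class limits per scenario.  Everything is plain JSON (arrays as nested
lists), so screened combinations can be audited and reapplied exactly.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any, Sequence

import numpy as np

from .errors import ConfigError
from .occ import (
    KnnDistOCC,
    MahalanobisOCC,
    OCCModel,
    OcsvmOCC,
    PcaResidualOCC,
    SimcaOCC,
    _PCABasis,
)
from .preprocess import FittedChain, PreprocessSpec


def _arr(x: np.ndarray | None) -> list | None:
    return None if x is None else np.asarray(x).tolist()


def _basis_to_dict(b: _PCABasis | None) -> dict | None:
    if b is None:
        return None
    return {"mean": _arr(b.mean), "components": _arr(b.components), "score_var": _arr(b.score_var)}


def _basis_from_dict(d: dict | None) -> _PCABasis | None:
    if d is None:
        return None
    return _PCABasis(
        np.asarray(d["mean"]), np.asarray(d["components"]), np.asarray(d["score_var"])
    )


def _estimator_state(est) -> dict[str, Any]:
    if isinstance(est, SimcaOCC):
        return {
            "basis": _basis_to_dict(est.basis_),
            "q_mean": est.q_mean_,
            "t2_mean": est.t2_mean_,
        }
    if isinstance(est, PcaResidualOCC):
        return {"basis": _basis_to_dict(est.basis_)}
    if isinstance(est, KnnDistOCC):
        return {"basis": _basis_to_dict(est.basis_), "train_scores": _arr(est.train_scores_)}
    if isinstance(est, MahalanobisOCC):
        return {"basis": _basis_to_dict(est.basis_), "cov_inv": _arr(est.cov_inv_)}
    if isinstance(est, OcsvmOCC):
        return {
            "support_vectors": _arr(est.support_vectors_),
            "dual_coef": _arr(est.dual_coef_),
            "intercept": est.intercept_,
            "gamma_value": est.gamma_value_,
            "offset": est.offset_,
        }
    raise ConfigError(f"cannot serialise estimator {type(est).__name__}")


def _restore_estimator(algorithm: str, params: dict, state: dict):
    from .occ import _ALGORITHMS

    est = _ALGORITHMS[algorithm](**params)
    if isinstance(est, SimcaOCC):
        est.basis_ = _basis_from_dict(state["basis"])
        est.q_mean_ = state["q_mean"]
        est.t2_mean_ = state["t2_mean"]
    elif isinstance(est, PcaResidualOCC):
        est.basis_ = _basis_from_dict(state["basis"])
    elif isinstance(est, KnnDistOCC):
        est.basis_ = _basis_from_dict(state["basis"])
        est.train_scores_ = np.asarray(state["train_scores"])
    elif isinstance(est, MahalanobisOCC):
        est.basis_ = _basis_from_dict(state["basis"])
        est.cov_inv_ = np.asarray(state["cov_inv"])
    elif isinstance(est, OcsvmOCC):
        est.support_vectors_ = np.asarray(state["support_vectors"])
        est.dual_coef_ = np.asarray(state["dual_coef"])
        est.intercept_ = state["intercept"]
        est.gamma_value_ = state["gamma_value"]
        est.offset_ = state["offset"]
    return est


def _chain_state(chain: FittedChain | None) -> list[dict] | None:
    if chain is None:
        return None
    states = []
    for step in chain.steps:
        state: dict[str, Any] = {}
        for attr in ("reference_", "stats_"):
            if hasattr(step, attr):
                state[attr] = _arr(getattr(step, attr))
        if hasattr(step, "model_") and getattr(step, "model_") is not None:
            m = step.model_
            state["osc"] = {
                "weights": _arr(m.weights),
                "loadings": _arr(m.loadings),
                "removed_variance": _arr(m.removed_variance),
            }
        states.append(state)
    return states


def _restore_chain(spec: PreprocessSpec, states: list[dict] | None) -> FittedChain | None:
    if states is None:
        return None
    from .preprocess import OSCModel

    steps = spec.build()
    for step, state in zip(steps, states):
        for attr in ("reference_", "stats_"):
            if attr in state and state[attr] is not None:
                setattr(step, attr, np.asarray(state[attr]))
        if "osc" in state:
            o = state["osc"]
            step.model_ = OSCModel(
                np.asarray(o["weights"]),
                np.asarray(o["loadings"]),
                np.asarray(o["removed_variance"]),
            )
    return FittedChain(spec, steps)


def occ_models_to_dict(models: Sequence[OCCModel]) -> dict:
    return {
        "models": [
            {
                "algorithm": m.algorithm,
                "preprocess": m.spec.canonical(),
                "params": m.params,
                "class_limits": {str(k): v for k, v in m.class_limits.items()},
                "chain_state": _chain_state(m.chain),
                "estimator_state": _estimator_state(m.estimator),
            }
            for m in models
        ]
    }


def occ_models_from_dict(payload: dict) -> list[OCCModel]:
    models = []
    for d in payload["models"]:
        spec = PreprocessSpec.from_string(d["preprocess"])
        est = _restore_estimator(d["algorithm"], d["params"], d["estimator_state"])
        models.append(
            OCCModel(
                algorithm=d["algorithm"],
                spec=spec,
                params=d["params"],
                estimator=est,
                chain=_restore_chain(spec, d["chain_state"]),
                class_limits={int(k): float(v) for k, v in d["class_limits"].items()},
            )
        )
    return models


def save_occ_models(models: Sequence[OCCModel], path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(occ_models_to_dict(models)))
    return path


def load_occ_models(path: str | Path) -> list[OCCModel]:
    return occ_models_from_dict(json.loads(Path(path).read_text()))
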