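"""Model-store persistence: JSON manifest plus a joblib container."""

from __future__ import annotations

import json
from pathlib import Path

import joblib

from .estimator import HierarchicalCodeClassifier

__all__ = ["save_model", "load_model"]

_FORMAT_VERSION = 1


def save_model(clf: HierarchicalCodeClassifier, model_dir) -> None:
    """Persist a fitted classifier: manifest.json + model.joblib."""
    out = Path(model_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "format_version": _FORMAT_VERSION,
        "strategy": clf.strategy,
        "learner": clf.learner,
        "learner_params": clf.learner_params or {},
        "mode": clf.mode,
        "adaption": clf.adaption,
        "min_positives": clf.min_positives,
        "random_state": clf.random_state,
        "nodes": sorted(clf.model_.trainable_codes()),
        "skipped": [list(s) for s in clf.model_.skipped],
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    joblib.dump(clf, out / "model.joblib")


def load_model(model_dir) -> HierarchicalCodeClassifier:
    path = Path(model_dir) / "model.joblib"
    if not path.exists():
        raise FileNotFoundError(f"no model container at {path}")
    return joblib.load(path)
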