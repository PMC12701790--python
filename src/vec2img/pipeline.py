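"""End-to-end pipeline: load/generate -> encode -> ensembles -> SVM -> fusion.

``run_pipeline`` executes the full protocol from one flat configuration
dict and returns a manifest capturing every random draw (member seeds,
permutations, window triples), the configuration snapshot and all
metrics, sufficient to re-execute the run bit-compatibly in deterministic
mode.
"""

from __future__ import annotations

import json
import time
from pathlib import Path

import numpy as np

from . import __version__
from .baselines import OptimizedSVC, evaluate
from .encoders import CWTEncoder, DWTEncoder, ReshapeEncoder, WignerEncoder
from .ensemble import EnsembleImageClassifier, SmallNetBackbone
from .fusion import FusionRule, fuse, mean_rule, z_normalize_scores
from .io import read_feature_table, write_scores
from .synthdata import SynthSpec, generate

__all__ = ["DEFAULT_CONFIG", "run_pipeline", "build_encoder"]

DEFAULT_CONFIG = {
    "encoders": ["wigner", "reshape"],   # encoder families to ensemble
    "n_members": 3,                      # reference protocol: 15
    "epochs": 10,                        # reference protocol: 30
    "batch_size": 30,
    "learning_rate": 0.001,
    "trainer": "adam",
    "hidden_layer_sizes": [64],
    "pool": 4,
    "normalize_0_255": True,
    "quadrant_threshold": None,
    "beta": 0.5,
    "run_svm": True,
    "svm_weight": 2.0,                   # the "2xSVM+CNNe" weighting
    "seed": 0,
    # synthetic-data fallback when no input tables are given
    "synth": {"mode": "spectral", "n_per_class": 200, "length": 64,
              "class_freqs": [5, 12], "noise_sd": 0.5},
}

_ENCODERS = {
    "wigner": WignerEncoder,
    "reshape": ReshapeEncoder,
    "cwt": CWTEncoder,
    "dwt": DWTEncoder,
}


def build_encoder(name: str, config: dict):
    try:
        cls = _ENCODERS[name]
    except KeyError:
        raise ValueError(
            f"unknown encoder {name!r}; valid options: {sorted(_ENCODERS)}"
        ) from None
    if cls is WignerEncoder:
        return cls(beta=config.get("beta", 0.5),
                   quadrant_threshold=config.get("quadrant_threshold"))
    return cls()


def _merged(config: dict | None) -> dict:
    merged = json.loads(json.dumps(DEFAULT_CONFIG))
    for k, v in (config or {}).items():
        if k == "synth" and isinstance(v, dict):
            merged["synth"].update(v)
        else:
            merged[k] = v
    return merged


def _load_data(config):
    if config.get("train") and config.get("test"):
        X_tr, y_tr, _ = read_feature_table(config["train"])
        X_te, y_te, _ = read_feature_table(config["test"])
        return X_tr, y_tr, X_te, y_te, {"source": "files",
                                        "train": str(config["train"]),
                                        "test": str(config["test"])}
    s = config["synth"]
    spec = SynthSpec(n_per_class=s["n_per_class"], length=s["length"], mode=s["mode"],
                     class_freqs=tuple(s.get("class_freqs", (5, 12))),
                     noise_sd=s["noise_sd"], seed=config["seed"])
    ds = generate(spec)
    return ds.X_train, ds.y_train, ds.X_test, ds.y_test, {"source": "synth", **s}


def run_pipeline(config: dict | None = None, out_dir=None) -> dict:
    """Run the full protocol; returns the manifest (also written to out_dir)."""
    config = _merged(config)
    seed = int(config["seed"])
    t0 = time.time()
    X_tr, y_tr, X_te, y_te, data_info = _load_data(config)
    classes = np.unique(y_tr)

    manifest = {
        "version": __version__,
        "config": config,
        "data": data_info,
        "seed": seed,
        "stages": {},
        "metrics": {},
    }
    out_dir = Path(out_dir) if out_dir is not None else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)

    backbone = SmallNetBackbone(
        hidden_layer_sizes=tuple(config["hidden_layer_sizes"]),
        trainer=config["trainer"], learning_rate=config["learning_rate"],
        batch_size=config["batch_size"], epochs=config["epochs"],
        pool=config["pool"],
    )
    scores: dict[str, np.ndarray] = {}
    for i, enc_name in enumerate(config["encoders"]):
        stage = f"ensemble_{enc_name}"
        t = time.time()
        model = EnsembleImageClassifier(
            encoder=build_encoder(enc_name, config), backbone=backbone,
            n_members=config["n_members"],
            normalize_0_255=config["normalize_0_255"],
            random_state=seed + i,
        ).fit(X_tr, y_tr)
        S = model.predict_proba(X_te)
        scores[enc_name] = S
        manifest["metrics"][enc_name] = evaluate(S, y_te, classes)
        manifest["stages"][stage] = {
            "seconds": round(time.time() - t, 2),
            "members": [
                {"seed": m["seed"],
                 "permutation": m["permuter"].permutation_.tolist(),
                 "window_sizes": (list(map(list, m["encoder"].window_sizes_))
                                  if np.ndim(getattr(m["encoder"], "window_sizes_", ())) > 1
                                  else list(getattr(m["encoder"], "window_sizes_", ())))
                 if hasattr(m["encoder"], "window_sizes_") else None,
                 "best_epoch": int(m["backbone"].best_epoch_),
                 "trace": m["backbone"].trace_.tolist()}
                for m in model.members_
            ],
            "dropped": model.dropped_members_,
        }
        if out_dir is not None:
            write_scores(out_dir / f"scores_{enc_name}.csv", S, classes)

    if len(scores) > 1:
        fused = mean_rule(list(scores.values()))
        scores["fusion"] = fused
        manifest["metrics"]["fusion"] = evaluate(fused, y_te, classes)
        if out_dir is not None:
            write_scores(out_dir / "scores_fusion.csv", fused, classes)

    if config["run_svm"]:
        t = time.time()
        svm = OptimizedSVC(random_state=seed).fit(X_tr, y_tr)
        S = svm.scores(X_te)
        scores["svm"] = S
        manifest["metrics"]["svm"] = evaluate(S, y_te, classes)
        manifest["stages"]["svm"] = {"seconds": round(time.time() - t, 2),
                                     "best_params": svm.best_params_}
        cnn_like = scores.get("fusion", next(iter(scores.values())))
        rule = FusionRule([("svm", float(config["svm_weight"])), ("cnne", 1.0)],
                          normalize=True)
        weighted = fuse(rule, {"svm": S, "cnne": cnn_like})
        manifest["metrics"]["weighted_svm_cnne"] = evaluate(weighted, y_te, classes)
        if out_dir is not None:
            write_scores(out_dir / "scores_svm.csv", S, classes)
            write_scores(out_dir / "scores_weighted_svm_cnne.csv", weighted, classes)

    manifest["seconds_total"] = round(time.time() - t0, 2)
    if out_dir is not None:
        (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
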