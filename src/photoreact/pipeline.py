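"""Config-driven pipeline orchestration with run manifests.

A run is a YAML/JSON config with a mandatory ``seed``, an ``out_dir`` and an
ordered list of stage blocks (``simulate``, ``curate``, ``label``,
``featurize``, ``train``, ``predict``, ``evaluate``, ``phototox``). The
config is validated before any stage runs; each stage consumes and produces
only its declared files; a manifest recording the stage sequence, config
hash, seeds and file digests is written next to the artifacts, so identical
configs and inputs reproduce identical outputs.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, chem_io, featurize, labeling, models, synth
from .evaluation import evaluate as _evaluate
from .phototox import PhototoxRecord, crosstab

STAGES = ("simulate", "curate", "label", "featurize", "train", "predict", "evaluate", "phototox")

_REQUIRED_KEYS = {
    "simulate": ("n",),
    "curate": ("in",),
    "label": ("peaks", "out"),
    "featurize": ("in", "sets", "out"),
    "train": ("features", "labels", "out"),
    "predict": ("model", "features", "out"),
    "evaluate": ("preds", "truth", "out"),
    "phototox": ("classes", "outcomes", "out"),
}

#: stage keys that name input files which must exist before the run starts
_INPUT_KEYS = {
    "curate": ("in",),
    "label": ("peaks",),
    "featurize": ("in",),
    "phototox": ("outcomes",),
}


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def load_config(path: str | Path) -> dict:
    path = Path(path)
    text = path.read_text()
    return yaml.safe_load(text)


def validate_config(config: dict) -> None:
    """Schema check before any stage runs (fail-fast contract)."""
    if not isinstance(config, dict):
        raise ValueError("config must be a mapping")
    for key in ("seed", "out_dir", "stages"):
        if key not in config:
            raise ValueError(f"config is missing required key {key!r}")
    if not isinstance(config["stages"], list) or not config["stages"]:
        raise ValueError("config 'stages' must be a nonempty list")
    for block in config["stages"]:
        if not isinstance(block, dict) or len(block) != 1:
            raise ValueError("each stage block must be a single-key mapping")
        (name, params), = block.items()
        if name not in STAGES:
            raise ValueError(f"unknown stage {name!r}; expected one of {STAGES}")
        params = params or {}
        missing = [k for k in _REQUIRED_KEYS[name] if k not in params]
        if missing:
            raise ValueError(f"stage {name!r} is missing keys {missing}")
        for key in _INPUT_KEYS.get(name, ()):
            # generated-in-run files (inside out_dir) are allowed to not exist yet
            p = Path(params[key])
            if not p.exists() and not str(p).startswith(str(config["out_dir"])):
                raise ValueError(f"stage {name!r} input does not exist: {p}")


def run_pipeline(config: dict | str | Path) -> dict:
    """Execute the declared stages in order and return the run manifest.

    Any stage failure aborts the run with the failing stage named.
    """
    if not isinstance(config, dict):
        config = load_config(config)
    validate_config(config)
    seed = int(config["seed"])
    out_dir = Path(config["out_dir"])
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": seed,
        "config_sha256": hashlib.sha256(
            json.dumps(config, sort_keys=True, default=str).encode()
        ).hexdigest(),
        "stages": [],
        "files": {},
    }
    for block in config["stages"]:
        (name, params), = block.items()
        params = dict(params or {})
        try:
            outputs = _run_stage(name, params, seed, out_dir)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        manifest["stages"].append({"stage": name, "params": params})
        for f in outputs:
            f = Path(f)
            if f.exists():
                manifest["files"][str(f)] = _sha256(f)
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


def _read_labels(path: str) -> dict[str, str]:
    df = pd.read_csv(path)
    col = "label" if "label" in df.columns else "predicted"
    return dict(zip(df["mol_id"].astype(str), df[col]))


def _run_stage(name: str, params: dict, seed: int, out_dir: Path) -> list[str]:
    if name == "simulate":
        cfg = synth.GeneratorConfig(
            n_molecules=int(params["n"]),
            seed=int(params.get("seed", seed)),
            **{k: v for k, v in params.items() if k not in ("n", "seed", "out")},
        )
        target = Path(params.get("out", out_dir / "fixtures"))
        synth.simulate(cfg, target)
        return [target / f for f in ("curated.smi", "peaks.csv", "tox.csv", "truth.json")]

    if name == "curate":
        rule = chem_io.EligibilityRule(
            mw_min=float(params.get("mw_min", 98.0)), mw_max=float(params.get("mw_max", 1080.0))
        )
        parsed = chem_io.parse_structures(params["in"], params.get("format", "smiles"))
        kept, rejected, _ = chem_io.curate(parsed.records, rule)
        target = Path(params.get("out", out_dir / "curated"))
        chem_io.write_curated(kept, rejected, target)
        return [target / "curated.smi", target / "audit.csv"]

    if name == "label":
        cfg = labeling.LabelConfig(
            window_low=float(params.get("window_low", 290.0)),
            window_high=float(params.get("window_high", 700.0)),
            mec_threshold=float(params.get("mec_threshold", 1000.0)),
        )
        records = labeling.read_peaks_csv(params["peaks"])
        labeling.write_labels_csv(records, params["out"], cfg)
        return [params["out"]]

    if name == "featurize":
        parsed = chem_io.parse_structures(params["in"], "smiles")
        ids = [r.mol_id for r in parsed.records]
        smis = [r.canonical_smiles for r in parsed.records]
        sets = params["sets"] if isinstance(params["sets"], list) else str(params["sets"]).split(",")
        mats = [featurize.featurize_set(ids, smis, s.strip()) for s in sets]
        fm = featurize.combine_sets(mats)
        fm.write(params["out"])
        return [f"{params['out']}.csv", f"{params['out']}.json"]

    if name == "train":
        fm = featurize.FeatureMatrix.read(params["features"])
        labels = _read_labels(params["labels"])
        mask = [i for i in fm.mol_ids if i in labels]
        X = fm.values.loc[mask]
        y = np.array([labels[i] for i in mask])
        algo = params.get("algorithm", "rf")
        if algo == "rf":
            cfg = models.RFConfig(
                n_trees=int(params.get("n_trees", 500)),
                mtry=params.get("mtry", "sqrt"),
                seed=int(params.get("seed", seed)),
            )
            model = models.train_rf(X, y, cfg)
        elif algo == "cart":
            model = models.train_cart(X, y, cp=float(params.get("cp", 0.01)), seed=seed)
        elif algo == "svm":
            model = models.train_svm(X, y, seed=seed)
        elif algo == "mlp":
            model = models.train_mlp(X, y, seed=seed)
        else:
            raise ValueError(f"unknown algorithm {algo!r}")
        model.save(params["out"])
        return [f"{params['out']}.joblib", f"{params['out']}.json"]

    if name == "predict":
        model = models.TrainedModel.load(params["model"])
        fm = featurize.FeatureMatrix.read(params["features"])
        preds = models.predict(model, fm.values)
        pd.DataFrame(
            [{"mol_id": p.mol_id, "predicted": p.predicted, "probability": p.probability} for p in preds]
        ).to_csv(params["out"], index=False)
        return [params["out"]]

    if name == "evaluate":
        preds = pd.read_csv(params["preds"])
        truth = _read_labels(params["truth"])
        merged = preds[preds["mol_id"].astype(str).isin(truth)]
        y_true = [truth[str(i)] for i in merged["mol_id"]]
        scores = [
            p if lab == "POS" else 1.0 - p
            for lab, p in zip(merged["predicted"], merged["probability"])
        ]
        report = _evaluate(y_true, list(merged["predicted"]), pos_scores=scores)
        payload = {
            "counts": vars(report.counts),
            **report.rounded(),
            "auc": report.auc,
            "mcc_undefined": report.mcc_undefined,
        }
        Path(params["out"]).write_text(json.dumps(payload, indent=2))
        if params.get("roc"):
            pd.DataFrame(report.roc, columns=["fpr", "tpr"]).to_csv(params["roc"], index=False)
            return [params["out"], params["roc"]]
        return [params["out"]]

    if name == "phototox":
        classes = _read_labels(params["classes"])
        df = pd.read_csv(params["outcomes"])
        outcomes = [PhototoxRecord(str(r.mol_id), r.outcome) for r in df.itertuples()]
        ct = crosstab(classes, outcomes)
        Path(params["out"]).write_text(json.dumps(ct.summary(), indent=2))
        return [params["out"]]

    raise ValueError(f"unknown stage {name!r}")
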