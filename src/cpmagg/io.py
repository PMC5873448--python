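"""Reading and writing model files and participant-data tables.

Model files are single-document YAML with keys ``model_id``, ``intercept``,
``coefficients`` and ``metadata``.  Participant data are plain CSV with a
header row, one column named ``outcome`` (binary) and optionally one named
``true_risk`` (simulation truth).  The four published TAVI 30-day mortality
models (German Aortic Valve, FRANCE-2, OBSERVANT and the American College of
Cardiology model) ship with the package as model files.
"""

from __future__ import annotations

import csv
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core import FittedRiskModel, IPDataset, PublishedCPM

TAVI_MODEL_IDS = ("german_av", "france2", "observant", "acc")


def read_cpm(path) -> PublishedCPM:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    try:
        model_id = doc["model_id"]
        intercept = float(doc["intercept"])
        raw = doc["coefficients"] or {}
    except (KeyError, TypeError) as exc:
        raise ValueError(f"{path}: not a valid model file ({exc})") from exc
    if len(raw) != len(set(raw)):
        raise ValueError(f"{path}: duplicate covariate names")
    coefs = {str(k): float(v) for k, v in raw.items()}
    return PublishedCPM(model_id, intercept, coefs, doc.get("metadata") or {})


def write_cpm(cpm: PublishedCPM | FittedRiskModel, path) -> None:
    if isinstance(cpm, FittedRiskModel):
        doc = {
            "model_id": cpm.provenance,
            "intercept": float(cpm.intercept),
            "coefficients": {k: float(v) for k, v in cpm.coefficients.items()},
            "metadata": {"provenance": cpm.provenance},
        }
    else:
        doc = {
            "model_id": cpm.model_id,
            "intercept": float(cpm.intercept),
            "coefficients": {k: float(v) for k, v in cpm.coefficients.items()},
            "metadata": dict(cpm.metadata),
        }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def load_tavi_cpms() -> list[PublishedCPM]:
    """The four packaged TAVI clinical prediction models.

    The published sources report coefficients only, so each fixture carries
    intercept 0 and ``metadata["intercept_unknown"] = True``.  Recalibration,
    stacking and the hybrid method are invariant to this choice because a
    free intercept absorbs any offset.
    """
    out = []
    for model_id in TAVI_MODEL_IDS:
        ref = resources.files("cpmagg.data") / f"{model_id}.yaml"
        with resources.as_file(ref) as path:
            out.append(read_cpm(path))
    return out


def _check_header(path) -> None:
    with open(path, newline="") as fh:
        header = next(csv.reader(fh))
    if len(header) != len(set(header)):
        dupes = sorted({h for h in header if header.count(h) > 1})
        raise ValueError(f"{path}: duplicate column names {dupes}")
    if "outcome" not in header:
        raise ValueError(f"{path}: no 'outcome' column")


def read_ipd(path) -> IPDataset:
    _check_header(path)
    df = pd.read_csv(path)
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise ValueError(f"{path}: non-numeric cell ({exc})") from exc
    y = df.pop("outcome").to_numpy()
    if not np.isin(y, (0.0, 1.0)).all():
        bad = sorted(set(y) - {0.0, 1.0})
        raise ValueError(f"{path}: outcome must be 0/1, found {bad}")
    true_risk = df.pop("true_risk").to_numpy() if "true_risk" in df.columns else None
    return IPDataset(df, y, true_risk)


def write_ipd(data: IPDataset, path) -> None:
    df = data.covariates.copy()
    df["outcome"] = data.outcome
    if data.true_risk is not None:
        df["true_risk"] = data.true_risk
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
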