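"""CSV/JSON readers and writers plus run manifests.

All writers emit deterministic byte streams for fixed inputs: stable column
order and repr-stable float formatting at six significant digits, comma
separation, UTF-8, "." decimal, mandatory header.
"""

from __future__ import annotations

import csv
import hashlib
import json
import time
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from . import __version__
from .authenticity import PurityModel
from .peaks import AnchorSeries
from .profiles import META_COLUMNS, ProfileMatrix, SampleMeta, ProfileError


class IOError_(ValueError):
    pass


def _fmt_float(value: float) -> str:
    if value == int(value) and abs(value) < 1e15:
        return str(int(value))
    return format(value, ".6g")


# ---------------------------------------------------------------------------
# ProfileMatrix


def write_profile_matrix(matrix: ProfileMatrix, path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle)
        writer.writerow(META_COLUMNS + list(matrix.columns))
        for meta, row in zip(matrix.metas, matrix.values):
            writer.writerow(
                [meta.sample_id, meta.species, meta.subgroup, meta.cultivar,
                 meta.region, str(meta.harvest_year)]
                + [_fmt_float(v) for v in row]
            )


def read_profile_matrix(path: str | Path) -> ProfileMatrix:
    """Read a profile CSV; "NA" concentrations become 0 (not detected)."""
    path = Path(path)
    with open(path, newline="", encoding="utf-8") as handle:
        reader = csv.reader(handle)
        header = next(reader, None)
        if header is None:
            raise IOError_(f"{path}: empty file")
        if header[: len(META_COLUMNS)] != META_COLUMNS:
            raise IOError_(
                f"{path}: header must start with {META_COLUMNS}, got "
                f"{header[:len(META_COLUMNS)]}"
            )
        columns = header[len(META_COLUMNS):]
        metas: list[SampleMeta] = []
        rows: list[list[float]] = []
        seen: set[str] = set()
        for line_no, row in enumerate(reader, start=2):
            if not row:
                continue
            sample_id = row[0]
            if sample_id in seen:
                raise IOError_(f"{path}:{line_no}: duplicate sample_id "
                               f"{sample_id!r}")
            seen.add(sample_id)
            try:
                metas.append(SampleMeta(
                    sample_id=sample_id, species=row[1], subgroup=row[2],
                    cultivar=row[3], region=row[4], harvest_year=int(row[5]),
                ))
            except (ProfileError, ValueError) as exc:
                raise IOError_(f"{path}:{line_no}: {exc}") from exc
            values = []
            for col, cell in zip(columns, row[len(META_COLUMNS):]):
                if cell in ("NA", ""):
                    values.append(0.0)
                else:
                    try:
                        values.append(float(cell))
                    except ValueError as exc:
                        raise IOError_(
                            f"{path}:{line_no}: bad value {cell!r} in {col}"
                        ) from exc
            rows.append(values)
    return ProfileMatrix(metas=tuple(metas), columns=tuple(columns),
                         values=np.array(rows, dtype=float))


# ---------------------------------------------------------------------------
# Anchor series


def write_anchor_series(anchors: AnchorSeries, path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle)
        writer.writerow(["carbon_number", "rt_min"])
        for carbon, rt in anchors.ketones:
            writer.writerow([str(carbon), _fmt_float(rt)])


def read_anchor_series(path: str | Path) -> AnchorSeries:
    with open(path, newline="", encoding="utf-8") as handle:
        reader = csv.DictReader(handle)
        ketones = tuple(
            (int(row["carbon_number"]), float(row["rt_min"])) for row in reader
        )
    return AnchorSeries(ketones=ketones)


# ---------------------------------------------------------------------------
# Model serialization


def model_to_dict(model: PurityModel) -> dict:
    return {
        "scenario": model.scenario,
        "variables": list(model.variables_),
        "n_components": int(model.n_components_),
        "x_mean": model.x_mean_.tolist(),
        "x_scale": model.x_scale_.tolist(),
        "y_mean": float(model.y_mean_),
        "x_weights": model.x_weights_.tolist(),
        "x_loadings": model.x_loadings_.tolist(),
        "y_loadings": model.y_loadings_.tolist(),
        "coef": model.coef_.tolist(),
        "intercept": float(model.intercept_),
        "r2_train": float(model.r2_train_),
        "rmsecv": float(model.rmsecv_),
        "rmsecv_curve": [float(v) for v in model.rmsecv_curve_],
        "decision_rule": {
            "authentic_min": model.decision_rule_.authentic_min,
            "fraud_max": model.decision_rule_.fraud_max,
        },
    }


def save_model(model: PurityModel, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        json.dump(model_to_dict(model), handle, indent=2, sort_keys=True)
        handle.write("\n")


def load_model(path: str | Path) -> PurityModel:
    with open(path, encoding="utf-8") as handle:
        payload = json.load(handle)
    model = PurityModel(scenario=payload["scenario"])
    model.variables_ = tuple(payload["variables"])
    model.n_components_ = payload["n_components"]
    model.x_mean_ = np.array(payload["x_mean"])
    model.x_scale_ = np.array(payload["x_scale"])
    model.y_mean_ = payload["y_mean"]
    model.x_weights_ = np.array(payload["x_weights"])
    model.x_loadings_ = np.array(payload["x_loadings"])
    model.y_loadings_ = np.array(payload["y_loadings"])
    model.coef_ = np.array(payload["coef"])
    model.intercept_ = payload["intercept"]
    model.r2_train_ = payload["r2_train"]
    model.rmsecv_ = payload["rmsecv"]
    model.rmsecv_curve_ = np.array(payload["rmsecv_curve"])
    model.n_features_in_ = len(model.coef_)
    rule = payload["decision_rule"]
    from .authenticity import DecisionRule

    model.decision_rule_ = DecisionRule(rule["authentic_min"], rule["fraud_max"])
    return model


# ---------------------------------------------------------------------------
# Run manifests


def file_sha256(path: str | Path) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as handle:
        for chunk in iter(lambda: handle.read(65536), b""):
            digest.update(chunk)
    return digest.hexdigest()


def write_manifest(
    path: str | Path,
    command: str,
    config: dict,
    seed: Optional[int],
    inputs: Sequence[str | Path] = (),
    artifacts: Sequence[str | Path] = (),
) -> dict:
    manifest = {
        "command": command,
        "config": config,
        "seed": seed,
        "input_hashes": {str(p): file_sha256(p) for p in inputs},
        "artifacts": [str(p) for p in artifacts],
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S", time.gmtime()),
        "package_version": __version__,
    }
    with open(path, "w", encoding="utf-8") as handle:
        json.dump(manifest, handle, indent=2, sort_keys=True)
        handle.write("\n")
    return manifest
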