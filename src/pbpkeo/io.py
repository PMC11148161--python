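"""Result serialization, run manifests and fixture integrity checks."""

from __future__ import annotations

import hashlib
import json
from datetime import datetime, timezone
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

FIXTURE_FILES = (
    "table1.yaml", "physiology_standard.yaml", "table2_demographics.csv",
    "table3_observed.csv", "table4_ddi_observed.csv", "perpetrators.yaml",
    "calibration_locked.yaml",
)


def _data_path(name: str) -> Path:
    return Path(str(resources.files("pbpkeo").joinpath("data", name)))


def fixture_checksums() -> dict:
    out = {}
    for name in FIXTURE_FILES:
        p = _data_path(name)
        if p.exists():
            out[name] = hashlib.sha256(p.read_bytes()).hexdigest()
    return out


def verify_fixtures() -> bool:
    """Compare live fixture hashes against the shipped manifest."""
    manifest = json.loads(_data_path("checksums.json").read_text())
    return fixture_checksums() == manifest


def result_to_frame(result) -> pd.DataFrame:
    """Tidy per-compartment concentrations: time_h, compartment, conc (nmol/L)."""
    rows = []
    for name, conc_um in result.compartment_concentrations_um().items():
        rows.append(pd.DataFrame({
            "time_h": result.time_h, "compartment": name,
            "concentration_nmol_per_L": conc_um * 1000.0}))
    rows.append(pd.DataFrame({
        "time_h": result.time_h, "compartment": "plasma",
        "concentration_nmol_per_L": result.plasma_nmol_l}))
    rows.append(pd.DataFrame({
        "time_h": result.time_h, "compartment": "brain_interstitial_free",
        "concentration_nmol_per_L": result.brain_interstitial_nmol_l}))
    return pd.concat(rows, ignore_index=True)


def write_result(result, out_dir: str | Path, stem: str = "simulation") -> dict:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    csv_path = out / f"{stem}.csv"
    result_to_frame(result).to_csv(csv_path, index=False, float_format="%.6g")
    summary = {
        "n_times": int(len(result.time_h)),
        "horizon_h": float(result.time_h[-1]),
        "plasma_ctrough_nmol_per_L": float(result.plasma_nmol_l[-1]),
        "brt_ctrough_nmol_per_L": float(result.brain_interstitial_nmol_l[-1]),
        "mass_balance_error": result.mass_balance_error(),
    }
    (out / f"{stem}.json").write_text(json.dumps(summary, indent=2))
    return summary


def write_manifest(out_dir: str | Path, config: dict, seed: int | None = None) -> Path:
    from . import __version__
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    payload = json.dumps(config, sort_keys=True, default=str)
    manifest = {
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "package_version": __version__,
        "seed": seed,
        "config_sha256": hashlib.sha256(payload.encode()).hexdigest(),
        "config": config,
        "fixture_checksums": fixture_checksums(),
    }
    path = out / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, default=str))
    return path


def to_jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, dict):
        return {k: to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [to_jsonable(v) for v in obj]
    return obj
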