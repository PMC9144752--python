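"""Packaged datasets, loaders and provenance helpers."""

from __future__ import annotations

import hashlib
import json
from importlib import resources
from pathlib import Path

import pandas as pd

from .geometry import PlaqueParams

__all__ = ["load_reference", "load_params", "provenance_block", "write_json"]

PLAQUE_NAMES = ("CIA", "CIB", "COB", "COC")

# sha256 of the packaged CSVs; guards against accidental edits of the
# transcribed certificate/parameter tables
_CHECKSUMS = {
    "reference_surface.csv": "f5575b782f2a8fff55f1719b51e368529838fb24a4df4ec2810d71be34ef0619",
    "plaque_params.csv": "20d3dc2f4ea3a40f91134e32294ef7e21dfac6dbcf8063af36b86a0c3a4beed2",
}


def _data_text(name: str, verify: bool = True) -> str:
    text = resources.files("rutheye.data").joinpath(name).read_text()
    if verify:
        digest = hashlib.sha256(text.encode()).hexdigest()
        expected = _CHECKSUMS.get(name)
        if expected is not None and digest != expected:
            raise ValueError(f"packaged file {name} failed its checksum")
    return text


def load_reference(verify: bool = True) -> pd.DataFrame:
    """Packaged certificate-average reference surface-dose table.

    80 rows: 4 plaques x 4 circles x 5 folded angles, columns plaque, circle,
    angle_deg, mean_pct, sd_pct (percent of the CAX dose at 1 mm depth).
    """
    import io as _io

    df = pd.read_csv(_io.StringIO(_data_text("reference_surface.csv", verify)))
    if len(df) != 80:
        raise ValueError(f"reference table has {len(df)} rows, expected 80")
    return df


def load_params(parameter_set: str, verify: bool = True) -> list[PlaqueParams]:
    """Packaged geometric parameters for the four asymmetric plaques.

    ``parameter_set`` is 'official' (vendor user-manual values) or 'modified'
    (values refit to photographs of the physical plaques).
    """
    import io as _io

    if parameter_set not in ("official", "modified"):
        raise ValueError(f"unknown parameter set {parameter_set!r}")
    df = pd.read_csv(_io.StringIO(_data_text("plaque_params.csv", verify)))
    df = df[df["parameter_set"] == parameter_set]
    out = []
    for _, row in df.iterrows():
        p = PlaqueParams(
            name=row["name"], D=float(row["D"]), R=float(row["R"]),
            s=float(row["s"]), a=float(row["a"]), r1=float(row["r1"]),
            r2=float(row["r2"]), parameter_set=parameter_set,
        )
        p.validate()
        out.append(p)
    if len(out) != 4:
        raise ValueError("expected 4 plaques per parameter set")
    return out


def get_params(name: str, parameter_set: str) -> PlaqueParams:
    """Parameters for a single named plaque."""
    for p in load_params(parameter_set):
        if p.name == name:
            return p
    raise ValueError(f"unknown plaque {name!r}")


def provenance_block(config: dict, kernel_provenance: str = "") -> dict:
    """Provenance record written into run outputs."""
    from . import __version__

    blob = json.dumps(config, sort_keys=True, default=str)
    return {
        "package": f"rutheye {__version__}",
        "config_hash": hashlib.sha256(blob.encode()).hexdigest()[:16],
        "config": config,
        "kernel": kernel_provenance,
    }


def write_json(path, payload: dict, config: dict | None = None,
               kernel_provenance: str = "") -> None:
    """Write a JSON output with an attached provenance block."""
    out = dict(payload)
    if config is not None:
        out["provenance"] = provenance_block(config, kernel_provenance)
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text(json.dumps(out, indent=1, default=str))
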