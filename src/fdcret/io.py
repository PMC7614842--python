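"""CSV/YAML readers and writers with reproducibility metadata.

CSV outputs carry ``#``-prefixed metadata header lines (parameters, seed)
so every artifact records how it was produced.  Model parameter sets are
YAML blocks with explicit units in the key names.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
import yaml

from .bond_kinetics import BondKineticsParams

__all__ = [
    "write_csv_with_metadata",
    "read_csv_with_metadata",
    "params_to_yaml",
    "params_from_yaml",
]


def write_csv_with_metadata(path, df: pd.DataFrame, metadata: dict | None = None) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        for key, value in (metadata or {}).items():
            fh.write(f"# {key}: {value}\n")
        df.to_csv(fh, index=False)


def read_csv_with_metadata(path):
    """Returns (DataFrame, metadata dict)."""
    path = Path(path)
    meta = {}
    skip = 0
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            skip += 1
            body = line[1:].strip()
            if ":" in body:
                k, v = body.split(":", 1)
                meta[k.strip()] = v.strip()
    df = pd.read_csv(path, skiprows=skip)
    return df, meta


def params_to_yaml(params: BondKineticsParams, path=None) -> str:
    block = {
        "k_off_per_s": float(params.k_off),
        "k_on_per_s": float(params.k_on),
        "n_L": int(params.n_L),
        "patch_area_um2": float(params.patch_area),
    }
    text = yaml.safe_dump(block, sort_keys=False)
    if path is not None:
        Path(path).write_text(text)
    return text


def params_from_yaml(source) -> BondKineticsParams:
    """Load a parameter block from a YAML string or file path."""
    p = Path(str(source))
    text = p.read_text() if p.exists() else str(source)
    block = yaml.safe_load(text)
    known = {"k_off_per_s", "k_on_per_s", "n_L", "patch_area_um2"}
    unknown = set(block) - known
    if unknown:
        raise ValueError(f"unknown parameter keys: {sorted(unknown)}")
    return BondKineticsParams(
        k_off=block["k_off_per_s"],
        k_on=block["k_on_per_s"],
        n_L=block["n_L"],
        patch_area=block.get("patch_area_um2", BondKineticsParams.patch_area),
    )
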