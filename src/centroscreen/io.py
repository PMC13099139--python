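"""Table/image readers and writers, layout validation, run configuration.

All tables are CSV with a one-line ``#`` comment header naming the
producing stage and configuration hash, so any output file can be traced
back to the run that made it. Images are TIFF.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

LAYOUT_COLUMNS = ("plate", "well", "role", "gene")
VALID_ROLES = ("library", "scrambled", "PLK1", "OR10A5", "NCAPH2")


class SchemaError(ValueError):
    """A table violates its documented schema; message carries row context."""


def write_table(df: pd.DataFrame, path, stage: str = "", config_hash: str = "") -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# centroscreen stage={stage or 'unknown'} config={config_hash or 'n/a'}\n")
        df.to_csv(fh, index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def write_tiff(path, array: np.ndarray) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, array)


def read_tiff(path) -> np.ndarray:
    return tifffile.imread(path)


def validate_layout(layout: pd.DataFrame) -> pd.DataFrame:
    """Check the plate-layout schema; raises SchemaError with row context."""
    missing = set(LAYOUT_COLUMNS) - set(layout.columns)
    if missing:
        raise SchemaError(f"layout missing columns: {sorted(missing)}")
    bad_role = ~layout["role"].isin(VALID_ROLES)
    if bad_role.any():
        i = int(np.flatnonzero(bad_role)[0])
        raise SchemaError(
            f"layout row {i}: unknown role {layout['role'].iloc[i]!r} "
            f"(expected one of {VALID_ROLES})"
        )
    dup = layout.duplicated(subset=["plate", "well"])
    if dup.any():
        i = int(np.flatnonzero(dup)[0])
        row = layout.iloc[i]
        raise SchemaError(
            f"layout row {i}: well {row['well']} on plate {row['plate']} assigned twice"
        )
    return layout


@dataclass
class RunConfig:
    """Everything needed to reproduce a pipeline run.

    Every stochastic stage carries an explicit seed; configs round-trip
    losslessly through YAML.
    """

    pixel_size: float = 0.108
    outdir: str = "centroscreen_run"
    seeds: dict = dc_field(default_factory=dict)
    simulate: dict = dc_field(default_factory=dict)
    gate: dict = dc_field(default_factory=dict)
    screen: dict = dc_field(default_factory=dict)

    REQUIRED_SEEDS = ("simulate",)

    def validate(self) -> "RunConfig":
        for stage in self.REQUIRED_SEEDS:
            if stage not in self.seeds:
                raise ValueError(f"config missing seed for stage {stage!r}")
        return self

    def to_dict(self) -> dict:
        return {
            "pixel_size": self.pixel_size,
            "outdir": self.outdir,
            "seeds": dict(self.seeds),
            "simulate": dict(self.simulate),
            "gate": dict(self.gate),
            "screen": dict(self.screen),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        return cls(
            pixel_size=d.get("pixel_size", 0.108),
            outdir=d.get("outdir", "centroscreen_run"),
            seeds=dict(d.get("seeds", {})),
            simulate=dict(d.get("simulate", {})),
            gate=dict(d.get("gate", {})),
            screen=dict(d.get("screen", {})),
        )

    def config_hash(self) -> str:
        # the output location is not part of the scientific configuration
        payload = {k: v for k, v in self.to_dict().items() if k != "outdir"}
        return hashlib.sha256(
            yaml.safe_dump(payload, sort_keys=True).encode()
        ).hexdigest()[:12]


def load_config(path) -> RunConfig:
    with open(path) as fh:
        return RunConfig.from_dict(yaml.safe_load(fh) or {})


def save_config(config: RunConfig, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)


def file_sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(outdir, config: RunConfig, outputs: list) -> Path:
    """Record versions, seeds, the config hash and output hashes for a run."""
    from . import __version__

    outdir = Path(outdir)
    manifest = {
        "package": "centroscreen",
        "version": __version__,
        "config_hash": config.config_hash(),
        "seeds": dict(config.seeds),
        "outputs": {str(Path(p).name): file_sha256(p) for p in outputs},
    }
    path = outdir / "manifest.json"
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return path
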