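"""File formats: measurement CSVs, kappa config files, chain CSVs.

Measurements use a wide CSV layout (one row per replicate) with header
``sample_id, replicate, I_D, I_A, I_F``; lines starting with ``#`` are
comments.  Kappa tables are YAML key-value grids.  Concentration-valued
inputs accept a units flag (``M`` or ``uM``) and are converted to molar
on read; one canonical internal unit avoids silent 1e-6 errors.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .data import FretDataset
from .mcmc import Chain
from .spectral import KappaTable

__all__ = [
    "read_dataset",
    "write_dataset",
    "read_kappa",
    "write_kappa",
    "write_chain",
    "read_chain",
    "RunConfig",
    "concentration_to_molar",
    "content_hash",
]

_UNIT_FACTORS = {"M": 1.0, "uM": 1e-6}


def concentration_to_molar(value: float, units: str) -> float:
    """Convert a concentration to molar given a units flag (M or uM)."""
    try:
        return float(value) * _UNIT_FACTORS[units]
    except KeyError:
        raise ValueError(f"unknown units {units!r}; expected one of {sorted(_UNIT_FACTORS)}")


def read_dataset(path: str | Path) -> FretDataset:
    """Read a measurements CSV into a :class:`FretDataset`.

    Validates column presence, numeric intensities and equal replicate
    counts across channels per sample; errors name the offending row or
    sample.
    """
    path = Path(path)
    try:
        # round_trip parser: bit-exact write -> read of float64 intensities
        df = pd.read_csv(path, comment="#", float_precision="round_trip")
    except pd.errors.EmptyDataError:
        raise ValueError(f"no samples: {path} is empty")
    return FretDataset.from_frame(df)


def write_dataset(dataset: FretDataset, path: str | Path) -> None:
    """Write a dataset to the wide CSV layout (round-trips bit-exactly)."""
    path = Path(path)
    df = dataset.to_frame()
    with open(path, "w") as fh:
        fh.write("# three-cube FRET measurements: one row per replicate\n")
        df.to_csv(fh, index=False, float_format="%.17g")


def read_kappa(path: str | Path) -> KappaTable:
    """Read a kappa table from a YAML channel-by-species grid."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    try:
        return KappaTable(
            kappa_D=tuple(doc["kappa_D"]),
            kappa_A=tuple(doc["kappa_A"]),
            kappa_F=tuple(doc["kappa_F"]),
        )
    except (KeyError, TypeError) as exc:
        raise ValueError(f"malformed kappa config {path}: {exc}") from exc


def write_kappa(kappa: KappaTable, path: str | Path) -> None:
    doc = {
        "channels": ["donor", "acceptor", "fret"],
        "units": "intensity per molar",
        "kappa_D": list(kappa.kappa_D),
        "kappa_A": list(kappa.kappa_A),
        "kappa_F": list(kappa.kappa_F),
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def write_chain(chain: Chain, path: str | Path) -> None:
    """Write a chain as CSV (step, log10_kd, efr, energy, accepted)."""
    chain.to_frame().to_csv(path, index=False, float_format="%.17g")


def read_chain(path: str | Path, seed: int = -1) -> Chain:
    df = pd.read_csv(path)
    states = df[["log10_kd", "efr"]].to_numpy()
    return Chain(
        states=states,
        energies=df["energy"].to_numpy(),
        accepted=df["accepted"].to_numpy().astype(bool),
        seed=seed,
        init=states[0].copy(),
    )


@dataclass
class RunConfig:
    """Plumbing record for a CLI run; embedded in every output artifact."""

    mode: str
    dataset: Optional[str] = None
    kappa: Optional[str] = None
    units: str = "M"
    chains: int = 3
    steps: int = 20000
    seed: int = 0
    prior_efr: Optional[tuple[float, float]] = None
    kd_bounds: tuple[float, float] = (-12.0, -2.0)
    out_dir: str = "."
    extra: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def write(self, path: str | Path, input_hashes: Optional[dict[str, str]] = None) -> None:
        doc = {"config": self.to_dict(), "input_hashes": input_hashes or {}}
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=2, default=_json_default)


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    raise TypeError(f"not JSON serialisable: {type(obj)}")


def content_hash(path: str | Path) -> str:
    """SHA-256 of a file's bytes, for provenance records."""
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(65536), b""):
            h.update(block)
    return h.hexdigest()
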