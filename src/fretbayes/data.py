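"""In-memory containers for three-cube FRET measurements.

A *sample* is one cell (or region of interest) measured ``n`` times in
each of the three spectral channels; a *dataset* is a collection of
samples, typically spanning different donor/acceptor concentrations.
Datasets round-trip through a wide CSV layout (one row per replicate)
via :mod:`fretbayes.io`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Optional

import numpy as np
import pandas as pd

if TYPE_CHECKING:  # pragma: no cover - import cycle guard
    from .simulate import SimulationConfig

__all__ = ["SampleMeasurements", "FretDataset"]


@dataclass
class SampleMeasurements:
    """Replicate intensity triples for one sample.

    ``intensities`` has shape (n, 3), columns ordered donor, acceptor,
    FRET.  Intensities may be negative (measurement noise on a weak
    signal); the Gaussian noise model is defined on all reals.
    """

    sample_id: str
    intensities: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.intensities, dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 3:
            raise ValueError(
                f"sample {self.sample_id!r}: intensities must have shape (n, 3), "
                f"got {arr.shape}"
            )
        if arr.shape[0] < 1:
            raise ValueError(f"sample {self.sample_id!r}: needs at least one replicate")
        if not np.all(np.isfinite(arr)):
            raise ValueError(f"sample {self.sample_id!r}: non-finite intensity values")
        self.intensities = arr

    @property
    def n(self) -> int:
        """Number of replicate measurements per channel."""
        return self.intensities.shape[0]

    def channel(self, i: int) -> np.ndarray:
        return self.intensities[:, i]


@dataclass
class FretDataset:
    """A set of samples measured under the same instrument settings.

    ``config`` optionally records the generating simulation (ground
    truth) for simulated data.
    """

    samples: list[SampleMeasurements]
    config: Optional["SimulationConfig"] = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if not self.samples:
            raise ValueError("dataset must contain at least one sample")
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            raise ValueError(f"duplicate sample ids: {ids}")

    @property
    def m(self) -> int:
        """Number of samples."""
        return len(self.samples)

    def __iter__(self):
        return iter(self.samples)

    def __len__(self) -> int:
        return len(self.samples)

    def to_frame(self) -> pd.DataFrame:
        """Wide layout: columns sample_id, replicate, I_D, I_A, I_F."""
        rows = []
        for s in self.samples:
            for k in range(s.n):
                rows.append((s.sample_id, k, *s.intensities[k]))
        return pd.DataFrame(rows, columns=["sample_id", "replicate", "I_D", "I_A", "I_F"])

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "FretDataset":
        """Build a dataset from the wide CSV layout.

        Replicate counts must agree across channels within each sample;
        a missing intensity in any channel is reported with the sample
        and row that caused it.
        """
        required = ["sample_id", "replicate", "I_D", "I_A", "I_F"]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise ValueError(f"missing required columns: {missing}")
        if len(df) == 0:
            raise ValueError("no samples: the file contains no measurement rows")
        for col in ("I_D", "I_A", "I_F"):
            vals = pd.to_numeric(df[col], errors="coerce")
            bad = df.index[vals.isna()]
            if len(bad) > 0:
                raise ValueError(
                    f"non-numeric or missing intensity in column {col!r} at row "
                    f"{bad[0]} (sample_id={df.loc[bad[0], 'sample_id']!r})"
                )
        samples = []
        for sid, grp in df.groupby("sample_id", sort=False):
            counts = grp[["I_D", "I_A", "I_F"]].notna().sum()
            if counts.nunique() != 1:
                raise ValueError(
                    f"sample {sid!r}: replicate counts differ across channels "
                    f"({counts.to_dict()})"
                )
            arr = grp[["I_D", "I_A", "I_F"]].to_numpy(dtype=float)
            samples.append(SampleMeasurements(sample_id=str(sid), intensities=arr))
        return cls(samples=samples)
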