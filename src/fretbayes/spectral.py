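"""Forward model for three-cube FRET: binding equilibrium and spectral mixing.

A donor-tagged protein D and an acceptor-tagged protein A form a 1:1
complex DA with dissociation constant ``Kd = [D][A]/[DA]``.  Each
fluorescent species contributes linearly to the intensity recorded in
each of three spectral channels (donor, acceptor, FRET).  The
proportionality constants -- the "kappa" table -- fold together
illumination intensity, molar extinction, quantum yield and detector
sensitivity, so spectral cross-talk (unintended excitation) and
bleed-through (emission into another channel's window) are handled by
the same linear map.  Donors in complex transfer energy to their
acceptor with intrinsic efficiency ``E_fr``, which moves emission from
the donor constants to the FRET-sensitized constants.

All concentrations are in molar (M) internally; intensities are in
arbitrary fluorescence units.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "CHANNELS",
    "ModelParams",
    "KappaTable",
    "ConcentrationState",
    "solve_equilibrium",
    "mixing_matrix",
    "predict_intensities",
]

#: Channel order used everywhere: index 0 = donor, 1 = acceptor, 2 = FRET.
CHANNELS = ("donor", "acceptor", "fret")


@dataclass(frozen=True)
class ModelParams:
    """Interaction parameters of the binding model.

    Parameters
    ----------
    Kd : float
        Dissociation constant in molar; strictly positive.
    E_fr : float
        Intrinsic FRET efficiency: the probability that exciting a donor
        in complex excites its acceptor.  Dimensionless, in [0, 1].
    """

    Kd: float
    E_fr: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.Kd) and self.Kd > 0):
            raise ValueError(f"Kd must be positive and finite, got {self.Kd!r}")
        if not (0.0 <= self.E_fr <= 1.0):
            raise ValueError(f"E_fr must lie in [0, 1], got {self.E_fr!r}")

    @property
    def log10_kd(self) -> float:
        return math.log10(self.Kd)


@dataclass(frozen=True)
class KappaTable:
    """Photophysical constants mapping species concentrations to intensities.

    ``kappa_D[i]``, ``kappa_A[i]`` and ``kappa_F[i]`` give the intensity
    per molar of, respectively, donor emission, acceptor emission and
    FRET-sensitized emission in channel ``i`` (0 = donor channel,
    1 = acceptor channel, 2 = FRET channel).  The underlying
    illumination/extinction/quantum-yield/detection factors are never
    needed individually and are folded into these nine constants.
    """

    kappa_D: tuple[float, float, float]
    kappa_A: tuple[float, float, float]
    kappa_F: tuple[float, float, float]

    def __post_init__(self) -> None:
        for name in ("kappa_D", "kappa_A", "kappa_F"):
            vals = tuple(float(v) for v in getattr(self, name))
            if len(vals) != 3:
                raise ValueError(f"{name} must have exactly 3 entries, got {len(vals)}")
            if any(not math.isfinite(v) or v < 0 for v in vals):
                raise ValueError(f"{name} entries must be finite and >= 0, got {vals}")
            object.__setattr__(self, name, vals)
        if not any(v > 0 for row in (self.kappa_D, self.kappa_A, self.kappa_F) for v in row):
            raise ValueError("at least one kappa constant must be positive")

    def as_array(self) -> np.ndarray:
        """Return a (3 species, 3 channels) array, rows D, A, F."""
        return np.array([self.kappa_D, self.kappa_A, self.kappa_F], dtype=float)


@dataclass(frozen=True)
class ConcentrationState:
    """Equilibrium concentrations (molar) for given totals and Kd."""

    D0: float
    A0: float
    D: float
    A: float
    DA: float

    def as_vector(self) -> np.ndarray:
        """Species vector ([D], [A], [DA]) used by the mixing matrix."""
        return np.array([self.D, self.A, self.DA], dtype=float)


def solve_equilibrium(D0: float, A0: float, Kd: float) -> ConcentrationState:
    """Solve the bimolecular binding equilibrium D + A <=> DA.

    With totals ``[D0] = [D] + [DA]`` and ``[A0] = [A] + [DA]`` and
    ``Kd = [D][A]/[DA]``, the complex concentration is the physically
    valid (smaller) root of

        DA^2 - (D0 + A0 + Kd) DA + D0 A0 = 0.

    The root is evaluated in the cancellation-free form
    ``DA = 2 D0 A0 / (b + sqrt(b^2 - 4 D0 A0))`` with
    ``b = D0 + A0 + Kd``, which stays accurate in the weak-binding
    regime ``Kd >> D0 + A0`` where the textbook formula loses digits.

    Parameters
    ----------
    D0, A0 : float
        Total donor and acceptor concentrations, molar, >= 0.
    Kd : float
        Dissociation constant, molar, > 0.
    """
    if not (math.isfinite(Kd) and Kd > 0):
        raise ValueError(f"Kd must be positive and finite, got {Kd!r}")
    if D0 < 0 or A0 < 0:
        raise ValueError(f"total concentrations must be >= 0, got D0={D0!r}, A0={A0!r}")
    b = D0 + A0 + Kd
    # b > 0 always (Kd > 0); discriminant >= (D0 - A0)^2 + Kd^2 > 0.
    disc = b * b - 4.0 * D0 * A0
    DA = 2.0 * D0 * A0 / (b + math.sqrt(disc))
    D = D0 - DA
    A = A0 - DA
    # Round-off guard: clamp tiny negative free concentrations.
    tol = 1e-15 * max(D0, A0)
    if D < 0:
        if D < -tol:
            raise ArithmeticError(f"equilibrium solver produced D={D!r} < 0")
        D = 0.0
    if A < 0:
        if A < -tol:
            raise ArithmeticError(f"equilibrium solver produced A={A!r} < 0")
        A = 0.0
    return ConcentrationState(D0=D0, A0=A0, D=D, A=A, DA=DA)


def mixing_matrix(kappa: KappaTable, E_fr: float) -> np.ndarray:
    """Spectral mixing matrix M with I = M @ ([D], [A], [DA]).

    Columns correspond to species: free donor (kappa_D), free acceptor
    (kappa_A) and complex.  A complex contributes donor emission scaled
    by (1 - E_fr) (donors not undergoing transfer), full acceptor
    emission, and FRET-sensitized emission scaled by E_fr:

        M[:, DA] = kappa_D (1 - E_fr) + kappa_A + kappa_F E_fr.

    Every entry is nonnegative and linear in E_fr.
    """
    if not (0.0 <= E_fr <= 1.0):
        raise ValueError(f"E_fr must lie in [0, 1], got {E_fr!r}")
    kd = np.asarray(kappa.kappa_D, dtype=float)
    ka = np.asarray(kappa.kappa_A, dtype=float)
    kf = np.asarray(kappa.kappa_F, dtype=float)
    col_da = kd * (1.0 - E_fr) + ka + kf * E_fr
    return np.column_stack([kd, ka, col_da])


def predict_intensities(
    D0: float, A0: float, params: ModelParams, kappa: KappaTable
) -> np.ndarray:
    """Predicted noiseless intensities (donor, acceptor, FRET channels).

    Solves the binding equilibrium for the species concentrations and
    applies the spectral mixing matrix.  Each channel is the sum of the
    free-donor, free-acceptor and complex contributions.
    """
    state = solve_equilibrium(D0, A0, params.Kd)
    return mixing_matrix(kappa, params.E_fr) @ state.as_vector()


def _channel_coefficients(kappa: KappaTable, E_fr: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Coefficients (kd, ka, delta) with I_i = kd_i D0 + ka_i A0 + delta_i DA.

    Algebraic rearrangement of the mixing matrix using mass
    conservation ([D] = [D0] - [DA], [A] = [A0] - [DA]); the complex
    only changes the signal through delta = E_fr (kappa_F - kappa_D).
    Used by the likelihood hot path to avoid rebuilding matrices.
    """
    kd = np.asarray(kappa.kappa_D, dtype=float)
    ka = np.asarray(kappa.kappa_A, dtype=float)
    kf = np.asarray(kappa.kappa_F, dtype=float)
    return kd, ka, E_fr * (kf - kd)
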