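"""Shared helpers for building calibration fixtures in tests."""

import numpy as np

from fretbayes.calibration import CalibrationDataset, _construct_coefficients
from fretbayes.data import SampleMeasurements


def make_block(coeffs, conc, n=10, r=0.0, seed=0, sample_id="b"):
    pred = np.asarray(coeffs, float) * conc
    rng = np.random.default_rng(seed)
    noise = rng.normal(size=(n, 3)) * (r * pred)[None, :]
    return SampleMeasurements(sample_id, pred[None, :] + noise)


def make_calibration_blocks(kappa, concs, efr_construct=0.35, n=10, r=0.0, seed=0):
    a_construct = _construct_coefficients(kappa, efr_construct)
    return CalibrationDataset(
        donor_only=make_block(kappa.kappa_D, concs[0], n, r, seed, "donor_only"),
        acceptor_only=make_block(kappa.kappa_A, concs[1], n, r, seed + 1, "acceptor_only"),
        construct=make_block(a_construct, concs[2], n, r, seed + 2, "construct"),
    )
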