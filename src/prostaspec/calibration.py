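"""Mapping AI likelihood scores to inferred ISUP grades and CsPCa labels.

A trained detector emits, per patient, a probability of clinically
significant cancer in [0, 1].  Pathology reports grades on the ISUP 0–5
scale.  The two are tied together through three anchor points — probability
0 ↔ ISUP 0, probability 0.5 ↔ ISUP 2, probability 1 ↔ ISUP 5 — and two
interpolation rules between them:

* piecewise-linear through the anchors (slope 4 below 0.5, slope 6 above);
* ``ISUP = c · atanh(p)`` with ``c = 2 / atanh(0.5) ≈ 3.6409`` chosen so that
  p = 0.5 maps to grade 2.  Since atanh diverges at p → 1 while ISUP is
  bounded, the output is capped at 5 (reached at p = tanh(5/c) ≈ 0.8808).

Clinical significance (CsPCa) is assigned at ISUP grade ≥ 2.

Inferred grades are kept continuous for regression; rounding to integer
grades would only discard information.
"""

from __future__ import annotations

import math

import numpy as np

__all__ = [
    "ATANH_SCALE",
    "LINEAR_ANCHORS",
    "isup_from_likelihood_linear",
    "isup_from_likelihood_atanh",
    "cspca_label",
]

#: (probability, ISUP) anchor points fixed by the grade scale.
LINEAR_ANCHORS = ((0.0, 0.0), (0.5, 2.0), (1.0, 5.0))

#: Scale constant of the atanh calibration, 2/atanh(0.5) ≈ 3.6409.
ATANH_SCALE = 2.0 / math.atanh(0.5)

_MAX_ISUP = 5.0


def _check_probability(p) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if np.any((p < 0.0) | (p > 1.0)):
        raise ValueError("likelihood must lie in [0, 1]")
    return p


def isup_from_likelihood_linear(p):
    """Continuous ISUP grade by piecewise-linear interpolation of the anchors.

    Accepts a scalar or array probability; returns the same shape.
    """
    p = _check_probability(p)
    xs, ys = zip(*LINEAR_ANCHORS)
    out = np.interp(p, xs, ys)
    return float(out) if out.ndim == 0 else out


def isup_from_likelihood_atanh(p):
    """Continuous ISUP grade via ``c·atanh(p)``, capped at grade 5.

    ``c = 2/atanh(0.5)`` so that probability 0.5 maps exactly to grade 2.
    """
    p = _check_probability(p)
    with np.errstate(divide="ignore"):
        out = np.minimum(ATANH_SCALE * np.arctanh(p), _MAX_ISUP)
    return float(out) if out.ndim == 0 else out


def cspca_label(isup) -> bool:
    """Clinically significant prostate cancer: ISUP grade ≥ 2."""
    if isup < 0:
        raise ValueError(f"ISUP grade must be non-negative, got {isup}")
    return bool(isup >= 2)
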