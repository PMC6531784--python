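"""Closed-form assay computations: AFM volumes, Gaussian peak, ddCT.

Atomic force microscopy renders an adsorbed protein particle as a
spherical cap of height ``h`` and basal radius ``r`` (both nm); its
molecular volume is the cap volume

    Vm = (pi h / 6) (3 r^2 + h^2)            [nm^3]

The volume expected from molecular mass M0 (Da) is

    Vc = (M0 / N0) (V1 + d V2)               [cm^3 -> nm^3]

with Avogadro's number N0, partial specific volumes of protein
V1 = 0.74 cm^3/g and water V2 = 1 cm^3/g, and hydration
d = 0.4 g water / g protein.  Particle-volume histograms are
summarized by a Gaussian fit (peak = ML mean, uncertainty = SEM).
qPCR relative expression uses the standard 2^-ddCT formula.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .synthetic_data import AFMParticle  # noqa: F401  (re-exported container)

AVOGADRO = 6.02214076e23  # 1/mol, exact SI value
CM3_TO_NM3 = 1e21


class BiophysError(ValueError):
    pass


def afm_molecular_volume(h: float, r: float) -> float:
    """Spherical-cap molecular volume Vm = (pi h / 6)(3 r^2 + h^2), nm^3."""
    if h < 0 or r < 0:
        raise BiophysError("height and radius must be non-negative")
    return (math.pi * h / 6.0) * (3.0 * r**2 + h**2)


def predicted_molecular_volume(
    m0: float, d: float = 0.4, v1: float = 0.74, v2: float = 1.0
) -> float:
    """Volume predicted from molecular mass: (M0/N0)(V1 + d V2) in nm^3.

    ``m0`` in Da; V1, V2 in cm^3/g; d in g water per g protein.
    """
    if m0 < 0:
        raise BiophysError("molecular mass must be non-negative")
    return (m0 / AVOGADRO) * (v1 + d * v2) * CM3_TO_NM3


def particle_volumes(particles: Iterable[AFMParticle]) -> np.ndarray:
    return np.array([afm_molecular_volume(p.h, p.r) for p in particles])


@dataclass(frozen=True)
class VolumePeak:
    peak: float  # nm^3, Gaussian mean
    sem: float  # nm^3, sample SD / sqrt(n)
    n: int


def fit_volume_peak(volumes: Sequence[float]) -> VolumePeak:
    """Gaussian summary of a particle-volume distribution.

    The maximum-likelihood normal mean is the sample mean; the quoted
    uncertainty is the standard error of that mean.
    """
    v = np.asarray(volumes, dtype=float)
    if v.size < 2:
        raise BiophysError("need at least 2 volumes")
    return VolumePeak(
        peak=float(v.mean()), sem=float(v.std(ddof=1) / np.sqrt(v.size)), n=int(v.size)
    )


def decorated_fraction(n_decorated: int, n_total: int) -> float:
    """Fraction of particles decorated by a binding partner."""
    if n_total <= 0 or not 0 <= n_decorated <= n_total:
        raise BiophysError("need 0 <= n_decorated <= n_total with n_total > 0")
    return n_decorated / n_total


@dataclass(frozen=True)
class QpcrMeasurement:
    """Cycle thresholds for target and reference genes in two conditions."""

    ct_target_treated: float
    ct_reference_treated: float
    ct_target_control: float
    ct_reference_control: float


def ddct_fold_change(m: QpcrMeasurement) -> float:
    """Relative expression 2^-ddCT of treated vs control."""
    cts = (
        m.ct_target_treated,
        m.ct_reference_treated,
        m.ct_target_control,
        m.ct_reference_control,
    )
    if not all(math.isfinite(c) for c in cts):
        raise BiophysError("cycle thresholds must be finite")
    dct_treated = m.ct_target_treated - m.ct_reference_treated
    dct_control = m.ct_target_control - m.ct_reference_control
    return float(2.0 ** -(dct_treated - dct_control))
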