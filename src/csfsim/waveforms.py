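"""Inlet boundary-condition waveforms.

The simulator drives the craniospinal CSF space with volumetric flow
sources attached to network compartments: constant choroid-plexus
production, two cardiac (1 Hz) sinusoids representing arterial volume
changes at the ventricle walls and in the basilar region, and a
respiratory (0.2 Hz) sinusoid representing venous volume changes in the
occipital cerebral veins.  Every pulsatile source is a pure sine with
zero net volume over a whole period; all flows are in ml/s.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Union

import numpy as np

TWO_PI = 2.0 * np.pi

ArrayLike = Union[float, np.ndarray]


@dataclass(frozen=True)
class InletSource:
    """A constant or sinusoidal volumetric flow source at a network node.

    The signal is ``mean_flow + amplitude * sin(2*pi*frequency*t + phase)``
    in ml/s.  A constant source has ``amplitude == 0``.

    Parameters
    ----------
    name:
        Source identifier (e.g. ``"production"``, ``"arterial1"``).
    node:
        Name of the compartment the source discharges into.
    mean_flow:
        Time-average flow (ml/s).
    amplitude:
        Sinusoid amplitude (ml/s), non-negative.
    frequency:
        Sinusoid frequency (Hz), non-negative.
    phase:
        Phase offset (radians) at ``t = 0``.
    """

    name: str
    node: str
    mean_flow: float = 0.0
    amplitude: float = 0.0
    frequency: float = 0.0
    phase: float = 0.0

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError(f"source {self.name!r}: amplitude must be >= 0")
        if self.frequency < 0:
            raise ValueError(f"source {self.name!r}: frequency must be >= 0")

    def __call__(self, t: ArrayLike) -> ArrayLike:
        return evaluate_source(self, t)


@dataclass(frozen=True)
class MeasurementInputs:
    """Flow-MRI quantities used to size the cardiac inlet sources.

    Parameters
    ----------
    aqueduct_amplitude:
        Pulsatile flow amplitude measured at the third-ventricle /
        cerebral-aqueduct level (ml/s).
    cervical_amplitude:
        Pulsatile flow amplitude measured at the cervical spinal canal
        (ml/s); literature values span roughly 1.5-6 ml/s.
    spinal_compliance_fraction:
        Fraction of total craniospinal compliance carried by the spinal
        compartment, in (0, 1]; about 0.63-0.73 when supine.
    """

    aqueduct_amplitude: float
    cervical_amplitude: float
    spinal_compliance_fraction: float

    def __post_init__(self) -> None:
        if self.aqueduct_amplitude < 0:
            raise ValueError("aqueduct_amplitude must be >= 0")
        if not 0.0 < self.spinal_compliance_fraction <= 1.0:
            raise ValueError(
                "spinal_compliance_fraction must be in (0, 1], got "
                f"{self.spinal_compliance_fraction}"
            )
        if self.cervical_amplitude < self.aqueduct_amplitude:
            raise ValueError(
                "cervical_amplitude must be >= aqueduct_amplitude "
                f"({self.cervical_amplitude} < {self.aqueduct_amplitude})"
            )


def evaluate_source(source: InletSource, t: ArrayLike) -> ArrayLike:
    """Volumetric flow of ``source`` at time ``t`` (s; scalar or array)."""
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("t must be >= 0")
    value = source.mean_flow + source.amplitude * np.sin(
        TWO_PI * source.frequency * t_arr + source.phase
    )
    return float(value) if value.ndim == 0 else value


def arterial1_from_aqueduct(m: MeasurementInputs) -> float:
    """Ventricle-wall pulsation amplitude (ml/s).

    By conservation of mass in the rigid ventricles, the arterial
    pulsation imposed at the ventricle walls equals the pulsatile flow
    amplitude measured at the third ventricle.
    """
    return m.aqueduct_amplitude


def arterial2_from_measurements(m: MeasurementInputs) -> float:
    """Basilar-region pulsation amplitude (ml/s).

    The cervical flow amplitude is the spinal share of the total
    arterial volume pulsation; subtracting the ventricular contribution
    and dividing by the spinal compliance fraction recovers the flow
    amplitude that must be injected in the basilar region:
    ``(Q_c - Q_v3) / c_sp``.
    """
    return (m.cervical_amplitude - m.aqueduct_amplitude) / m.spinal_compliance_fraction


def combined_0d_inflow(sources: Iterable[InletSource], t: ArrayLike) -> ArrayLike:
    """Sum of all source signals at ``t`` — the single-inlet 0D inflow."""
    t_arr = np.asarray(t, dtype=float)
    total = np.zeros_like(t_arr)
    for source in sources:
        total = total + evaluate_source(source, t_arr)
    return float(total) if total.ndim == 0 else total
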