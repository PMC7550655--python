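"""Acquisition protocols and the two forward signal models.

Everything downstream either evaluates or inverts one of the two models
defined here:

* the bi-exponential intravoxel-incoherent-motion (IVIM) decay over
  diffusion weighting b,

  .. math:: S(b) = S_0 \\left[(1-f)\\,e^{-bD} + f\\,e^{-bD^*}\\right]

  with true diffusion coefficient ``D``, pseudo-diffusion coefficient
  ``Dstar`` (capillary blood motion) and perfusion fraction ``f``;

* the mono-exponential multi-echo gradient-echo decay over echo time,

  .. math:: S(TE) = S_0\\, e^{-R_2^* \\cdot TE}.

Units are fixed once and for all: b in s/mm², D and D* in mm²/s, TE in ms,
R2* in 1/s. The ms→s factor lives in :data:`MS_PER_S` and nowhere else.
Display conversions (D in 10⁻³ mm²/s, f in %) are formatting concerns and
never enter the math.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "ValidationError",
    "DiffusionProtocol",
    "RelaxometryProtocol",
    "IVIMParams",
    "MonoexpDecayParams",
    "ivim_signal",
    "gre_signal",
    "default_protocols",
    "write_protocol_sidecar",
    "read_protocol_sidecar",
    "MS_PER_S",
]

#: milliseconds per second — the single TE-unit conversion constant.
MS_PER_S = 1000.0

#: Default diffusion weightings, s/mm² (13 b-values, max 1500).
DEFAULT_BVALUES = (0.0, 25.0, 50.0, 75.0, 100.0, 150.0, 200.0,
                   400.0, 600.0, 800.0, 1000.0, 1200.0, 1500.0)

#: Default echo times, ms (16 echoes), and repetition time, ms.
DEFAULT_ECHO_TIMES_MS = (3.4, 9.3, 15.2, 21.2, 27.1, 33.0, 38.9, 44.8,
                         50.7, 56.6, 62.5, 68.5, 74.4, 80.3, 86.2, 92.1)
DEFAULT_TR_MS = 160.0


class ValidationError(ValueError):
    """Raised when a protocol or parameter invariant is violated."""


def _as_float_tuple(values: Sequence[float]) -> tuple[float, ...]:
    return tuple(float(v) for v in values)


@dataclass(frozen=True)
class DiffusionProtocol:
    """Ordered b-value schedule for a multi-b DWI acquisition.

    Invariants: b-values are non-negative, strictly increasing, include
    b = 0, and there are at least 4 of them (the segmented fit needs two
    points on each side of its boundary).
    """

    bvalues: tuple[float, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "bvalues", _as_float_tuple(self.bvalues))
        b = np.asarray(self.bvalues)
        if b.size < 4:
            raise ValidationError("bvalues: need at least 4 b-values")
        if np.any(b < 0):
            raise ValidationError("bvalues: must be non-negative")
        if np.any(np.diff(b) <= 0):
            raise ValidationError("bvalues: must be strictly increasing")
        if b[0] != 0.0:
            raise ValidationError("bvalues: schedule must contain b = 0")

    def __len__(self) -> int:
        return len(self.bvalues)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.bvalues, dtype=float)


@dataclass(frozen=True)
class RelaxometryProtocol:
    """Ordered echo-time schedule for a multi-echo gradient-echo acquisition.

    ``repetition_time_ms`` is carried as metadata only; it never enters the
    fitting.
    """

    echo_times_ms: tuple[float, ...]
    repetition_time_ms: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "echo_times_ms",
                           _as_float_tuple(self.echo_times_ms))
        te = np.asarray(self.echo_times_ms)
        if te.size < 3:
            raise ValidationError("echo_times_ms: need at least 3 echoes")
        if np.any(te <= 0):
            raise ValidationError("echo_times_ms: must be positive")
        if np.any(np.diff(te) <= 0):
            raise ValidationError("echo_times_ms: must be strictly increasing")

    def __len__(self) -> int:
        return len(self.echo_times_ms)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.echo_times_ms, dtype=float)


@dataclass(frozen=True)
class IVIMParams:
    """Per-voxel IVIM tissue parameters.

    S0 in arbitrary units; D and Dstar in mm²/s with ``Dstar > D``
    (identifiability of the fast compartment); perfusion fraction
    ``f`` in [0, 1].
    """

    S0: float
    D: float
    Dstar: float
    f: float

    def __post_init__(self) -> None:
        if not self.S0 > 0:
            raise ValidationError("S0: must be positive")
        if not self.D > 0:
            raise ValidationError("D: must be positive")
        if not self.Dstar > self.D:
            raise ValidationError("Dstar: must exceed D")
        if not 0.0 <= self.f <= 1.0:
            raise ValidationError("f: must lie in [0, 1]")


@dataclass(frozen=True)
class MonoexpDecayParams:
    """Mono-exponential decay: signal at TE = 0 and relaxation rate R2* (1/s).

    T2* = 1/R2* is derived on demand, never stored.
    """

    S0: float
    R2star: float

    def __post_init__(self) -> None:
        if not self.S0 > 0:
            raise ValidationError("S0: must be positive")
        if self.R2star < 0:
            raise ValidationError("R2star: must be non-negative")

    @property
    def T2star_ms(self) -> float:
        if self.R2star == 0:
            return float("inf")
        return MS_PER_S / self.R2star


def ivim_signal(params: IVIMParams,
                protocol: DiffusionProtocol) -> np.ndarray:
    """Evaluate the bi-exponential IVIM decay on a b-value schedule.

    Returns one strictly positive value per b-value, non-increasing in b.
    At b = 0 the signal equals S0 exactly.
    """
    b = protocol.as_array()
    return params.S0 * ((1.0 - params.f) * np.exp(-b * params.D)
                        + params.f * np.exp(-b * params.Dstar))


def gre_signal(params: MonoexpDecayParams,
               protocol: RelaxometryProtocol) -> np.ndarray:
    """Evaluate the mono-exponential gradient-echo decay on a TE schedule.

    R2* is declared in 1/s and TEs in ms; the conversion happens here.
    """
    te_s = protocol.as_array() / MS_PER_S
    return params.S0 * np.exp(-params.R2star * te_s)


def default_protocols() -> tuple[DiffusionProtocol, RelaxometryProtocol]:
    """The study's acquisition schedules: 13 b-values and 16 echo times."""
    return (DiffusionProtocol(DEFAULT_BVALUES),
            RelaxometryProtocol(DEFAULT_ECHO_TIMES_MS,
                                repetition_time_ms=DEFAULT_TR_MS))


# --------------------------------------------------------------------------
# Protocol sidecar (JSON) — lets a volume travel with its schedule.

def write_protocol_sidecar(path: str | Path,
                           diffusion: DiffusionProtocol | None = None,
                           relaxometry: RelaxometryProtocol | None = None,
                           ) -> None:
    """Write a JSON sidecar ``{bvalues, echo_times_ms, tr_ms}``."""
    payload: dict = {}
    if diffusion is not None:
        payload["bvalues"] = list(diffusion.bvalues)
    if relaxometry is not None:
        payload["echo_times_ms"] = list(relaxometry.echo_times_ms)
        if relaxometry.repetition_time_ms is not None:
            payload["tr_ms"] = relaxometry.repetition_time_ms
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def read_protocol_sidecar(path: str | Path
                          ) -> tuple[DiffusionProtocol | None,
                                     RelaxometryProtocol | None]:
    """Read a protocol sidecar written by :func:`write_protocol_sidecar`."""
    payload = json.loads(Path(path).read_text())
    diffusion = None
    relaxometry = None
    if "bvalues" in payload:
        diffusion = DiffusionProtocol(payload["bvalues"])
    if "echo_times_ms" in payload:
        relaxometry = RelaxometryProtocol(payload["echo_times_ms"],
                                          repetition_time_ms=payload.get("tr_ms"))
    return diffusion, relaxometry
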