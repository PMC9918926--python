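"""Current-injection and voltage-measurement protocols.

A protocol fixes the frame layout: which electrode pairs inject current,
and which single-ended electrode potentials (referenced to the zero-mean
ground) are recorded under each injection.  The frame length m is the
number of recorded potentials.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from ._errors import ProtocolError

__all__ = ["MeasurementProtocol", "default_protocol", "two_row_protocol"]


@dataclass(frozen=True)
class MeasurementProtocol:
    """Ordered injection pairs and measurement definitions.

    Attributes
    ----------
    injection_pairs : tuple of (source, sink, amplitude)
        Electrode indices (0-based) and current amplitude in amperes.
    measurements : tuple of (injection index, electrode index)
        Each entry records the potential of one electrode under one
        injection; their order defines the frame layout.
    """

    injection_pairs: tuple = field(default_factory=tuple)
    measurements: tuple = field(default_factory=tuple)

    def __post_init__(self):
        object.__setattr__(self, "injection_pairs", tuple(map(tuple, self.injection_pairs)))
        object.__setattr__(self, "measurements", tuple(map(tuple, self.measurements)))
        for src, sink, amp in self.injection_pairs:
            if src == sink:
                raise ProtocolError("injection pair must use two distinct electrodes")
            if not amp > 0:
                raise ProtocolError("injection amplitude must be positive")
        for inj, _ in self.measurements:
            if not 0 <= inj < len(self.injection_pairs):
                raise ProtocolError("measurement references a missing injection pair")

    @property
    def frame_length(self) -> int:
        return len(self.measurements)

    def validate_for(self, electrode_count: int) -> None:
        for src, sink, _ in self.injection_pairs:
            if not (0 <= src < electrode_count and 0 <= sink < electrode_count):
                raise ProtocolError(f"electrode index out of range (have {electrode_count})")
        for _, el in self.measurements:
            if not 0 <= el < electrode_count:
                raise ProtocolError(f"electrode index out of range (have {electrode_count})")

    def to_dict(self) -> dict:
        return {
            "injection_pairs": [list(p) for p in self.injection_pairs],
            "measurements": [list(m) for m in self.measurements],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MeasurementProtocol":
        return cls(d["injection_pairs"], d["measurements"])


def default_protocol(electrode_count: int = 8, amplitude: float = 1e-3) -> MeasurementProtocol:
    """Default 8-electrode frame of length 32.

    Four opposite-style injection pairs across the array — (0,4), (1,5),
    (2,6), (3,7) — at 1 mA, with all eight single-ended electrode
    potentials recorded under each injection: m = 4 x 8 = 32.
    """
    if electrode_count != 8:
        raise ProtocolError("the default protocol is defined for 8 electrodes")
    pairs = [(k, k + 4, amplitude) for k in range(4)]
    meas = [(p, e) for p in range(4) for e in range(8)]
    return MeasurementProtocol(pairs, meas)


def two_row_protocol(amplitude: float = 1e-3) -> MeasurementProtocol:
    """Two rows of 8 electrodes, cyclic within-row injections, 16 potentials each.

    8 adjacent-pair injections per row x 2 rows x 16 recorded potentials
    gives a 256-component frame (protocol bookkeeping only; solving a 3D
    two-row model is out of scope).
    """
    pairs = []
    for row in range(2):
        base = 8 * row
        pairs += [(base + k, base + (k + 1) % 8, amplitude) for k in range(8)]
    meas = [(p, e) for p in range(16) for e in range(16)]
    return MeasurementProtocol(pairs, meas)
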