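"""Block-design protocol arithmetic.

Default design: a 30-s baseline rest followed by five cycles of 30-s
alternating answer/rest blocks — 330 s (5:30 min) per question, 22 min for a
four-question session at the 300-ms DTOF framing.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class ProtocolDesign:
    baseline_s: float = 30.0
    n_cycles: int = 5
    answer_s: float = 30.0
    rest_s: float = 30.0
    frame_period_ms: float = 300.0

    @property
    def frame_period_s(self) -> float:
        return self.frame_period_ms / 1000.0

    @property
    def total_run_s(self) -> float:
        return self.baseline_s + self.n_cycles * (self.answer_s + self.rest_s)

    @property
    def frames_per_run(self) -> int:
        return int(round(self.total_run_s / self.frame_period_s))

    @property
    def baseline_frames(self) -> int:
        return int(round(self.baseline_s / self.frame_period_s))

    @property
    def answer_onsets_s(self) -> list[float]:
        return [
            self.baseline_s + k * (self.answer_s + self.rest_s)
            for k in range(self.n_cycles)
        ]

    def session_minutes(self, n_questions: int) -> float:
        return n_questions * self.total_run_s / 60.0


def build_protocol(
    baseline_s: float = 30.0,
    n_cycles: int = 5,
    answer_s: float = 30.0,
    rest_s: float = 30.0,
    frame_period_ms: float = 300.0,
) -> ProtocolDesign:
    """Validate and build a block-design protocol.

    All durations must be positive (answer/rest strictly; a zero-cycle run is
    allowed) and commensurate with the frame period.
    """
    if frame_period_ms <= 0:
        raise ValueError("frame period must be positive")
    if n_cycles < 0:
        raise ValueError("n_cycles must be >= 0")
    dt = frame_period_ms / 1000.0
    for name, dur in [("baseline_s", baseline_s), ("answer_s", answer_s), ("rest_s", rest_s)]:
        if dur <= 0:
            raise ValueError(f"{name} must be positive")
        n = dur / dt
        if abs(n - round(n)) > 1e-9:
            raise ValueError(f"{name}={dur} is not a multiple of the frame period")
    return ProtocolDesign(baseline_s, n_cycles, answer_s, rest_s, frame_period_ms)
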