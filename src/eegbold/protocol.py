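"""Block-design stimulation protocol for the flicker experiment.

The experiment alternates 15.3 s blocks of reversing-checkerboard flicker
with 15.3 s blocks of rest, one functional scan every TR = 3.06 s, so each
block spans exactly 5 scans.  Task blocks draw their reversal frequency from
the canonical set of eight flicker frequencies; the steady-state response is
entrained at the second harmonic (twice the reversal frequency).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Checkerboard reversal frequencies used in the experiment (Hz).
FLICKER_FREQUENCIES: tuple[float, ...] = (2.0, 3.75, 5.0, 6.0, 7.5, 10.0, 15.0, 30.0)

#: Scans per block; together with TR this fixes the 15.3 s block length.
SCANS_PER_BLOCK: int = 5

DEFAULT_TR: float = 3.06
DEFAULT_EEG_RATE: float = 250.0


@dataclass(frozen=True)
class StimulusProtocol:
    """Timing of the alternating task/rest block design.

    Parameters
    ----------
    block_duration
        Duration of every block (task and rest alike), seconds.  Always
        ``SCANS_PER_BLOCK * TR``.
    block_order
        Sequence of ``(condition, frequency)`` tuples in presentation order;
        ``condition`` is ``"task"`` or ``"rest"`` and ``frequency`` is the
        flicker (reversal) frequency in Hz for task blocks, 0 for rest.
    n_scans
        Total number of functional scans covered by the protocol.
    TR
        Scan repetition time, seconds.
    eeg_rate
        EEG sampling rate, Hz.
    """

    block_duration: float
    block_order: tuple[tuple[str, float], ...]
    n_scans: int
    TR: float = DEFAULT_TR
    eeg_rate: float = DEFAULT_EEG_RATE

    def __post_init__(self) -> None:
        if self.TR <= 0:
            raise ValueError("TR must be positive")
        if self.eeg_rate <= 0:
            raise ValueError("eeg_rate must be positive")
        if abs(self.block_duration - SCANS_PER_BLOCK * self.TR) > 1e-9:
            raise ValueError("block_duration must equal 5 scans (5 * TR)")
        if self.n_scans != SCANS_PER_BLOCK * len(self.block_order):
            raise ValueError("n_scans inconsistent with block_order")
        for cond, f in self.block_order:
            if cond == "task" and f not in FLICKER_FREQUENCIES:
                raise ValueError(f"flicker frequency {f} not in the canonical set")

    @property
    def duration(self) -> float:
        """Total protocol duration in seconds (= n_scans * TR)."""
        return self.n_scans * self.TR

    @property
    def n_eeg_samples(self) -> int:
        return int(round(self.duration * self.eeg_rate))

    def block_onsets(self) -> np.ndarray:
        """Onset time (s) of every block, in presentation order."""
        return np.arange(len(self.block_order)) * self.block_duration

    def task_blocks(self) -> list[tuple[float, float, float]]:
        """``(onset, offset, frequency)`` for every task block, seconds/Hz."""
        out = []
        for onset, (cond, f) in zip(self.block_onsets(), self.block_order):
            if cond == "task":
                out.append((float(onset), float(onset + self.block_duration), f))
        return out

    def task_boxcar(self, rate: float) -> np.ndarray:
        """Indicator of task blocks sampled at `rate` Hz over the protocol."""
        n = int(round(self.duration * rate))
        t = np.arange(n) / rate
        box = np.zeros(n)
        for onset, offset, _ in self.task_blocks():
            box[(t >= onset) & (t < offset)] = 1.0
        return box

    def condition_boxcar(self, frequency: float, rate: float) -> np.ndarray:
        """Indicator of task blocks at one flicker frequency."""
        n = int(round(self.duration * rate))
        t = np.arange(n) / rate
        box = np.zeros(n)
        for onset, offset, f in self.task_blocks():
            if f == frequency:
                box[(t >= onset) & (t < offset)] = 1.0
        return box

    def to_dict(self) -> dict:
        return {
            "block_duration": self.block_duration,
            "block_order": [list(b) for b in self.block_order],
            "n_scans": self.n_scans,
            "TR": self.TR,
            "eeg_rate": self.eeg_rate,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "StimulusProtocol":
        return cls(
            block_duration=d["block_duration"],
            block_order=tuple((c, f) for c, f in d["block_order"]),
            n_scans=d["n_scans"],
            TR=d["TR"],
            eeg_rate=d["eeg_rate"],
        )


def generate_protocol(
    n_task_blocks: int,
    TR: float = DEFAULT_TR,
    seed: int = 0,
    eeg_rate: float = DEFAULT_EEG_RATE,
) -> StimulusProtocol:
    """Randomised alternating task/rest protocol.

    Blocks alternate task, rest, task, rest, ...; every block is 5 scans.
    Task frequencies are a seeded random permutation-with-repetition of the
    canonical flicker set: the set is tiled until it covers ``n_task_blocks``
    and then shuffled, so frequencies stay balanced across the session.
    """
    if n_task_blocks < 1:
        raise ValueError("n_task_blocks must be >= 1")
    if TR <= 0:
        raise ValueError("TR must be positive")
    rng = np.random.default_rng(seed)
    n_tiles = -(-n_task_blocks // len(FLICKER_FREQUENCIES))
    pool = np.tile(np.asarray(FLICKER_FREQUENCIES), n_tiles)
    rng.shuffle(pool)
    freqs = pool[:n_task_blocks]
    order: list[tuple[str, float]] = []
    for f in freqs:
        order.append(("task", float(f)))
        order.append(("rest", 0.0))
    n_scans = SCANS_PER_BLOCK * len(order)
    return StimulusProtocol(
        block_duration=SCANS_PER_BLOCK * TR,
        block_order=tuple(order),
        n_scans=n_scans,
        TR=TR,
        eeg_rate=eeg_rate,
    )
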