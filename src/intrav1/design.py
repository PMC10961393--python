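"""Block design of the Navon experiment.

Each 44 s block: a 1 s cue ('Global' or 'Local'), 19 s baseline, 20 s of
letter repetitions, and a 4 s report period.  A run holds 12 blocks, three
per condition (EG, EL, UG, UL), in seed-controlled random order; a session
has 4 or 5 runs.  The fMRI repetition time is 2.5 s.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

CONDITIONS = ("EG", "EL", "UG", "UL")
TR = 2.5
BLOCK_S = 44.0
CUE_S = 1.0
BASELINE_S = 19.0
STIM_S = 20.0
REPORT_S = 4.0
BLOCKS_PER_CONDITION = 3


def condition_level(condition: str) -> str:
    return "Global" if condition[1] == "G" else "Local"


def condition_letter(condition: str) -> str:
    return condition[0]


@dataclass(frozen=True)
class Block:
    condition: str
    onset_s: float  # block (= cue) onset within the run

    @property
    def cue_onset_s(self) -> float:
        return self.onset_s

    @property
    def baseline_onset_s(self) -> float:
        return self.onset_s + CUE_S

    @property
    def stim_onset_s(self) -> float:
        return self.onset_s + CUE_S + BASELINE_S

    @property
    def stim_duration_s(self) -> float:
        return STIM_S

    @property
    def report_onset_s(self) -> float:
        return self.stim_onset_s + STIM_S

    @property
    def duration_s(self) -> float:
        return BLOCK_S


@dataclass(frozen=True)
class BlockSchedule:
    """Per-run ordered blocks for one session."""

    runs: tuple[tuple[Block, ...], ...]
    tr: float = TR

    @property
    def n_runs(self) -> int:
        return len(self.runs)

    @property
    def run_duration_s(self) -> float:
        return len(self.runs[0]) * BLOCK_S

    @property
    def n_samples_per_run(self) -> int:
        return int(np.ceil(self.run_duration_s / self.tr))

    def blocks_of(self, run: int, condition: str) -> list[Block]:
        return [b for b in self.runs[run] if b.condition == condition]

    def to_dict(self) -> dict:
        return {
            "tr": self.tr,
            "runs": [
                [{"condition": b.condition, "onset_s": b.onset_s} for b in run]
                for run in self.runs
            ],
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "BlockSchedule":
        runs = tuple(
            tuple(Block(b["condition"], float(b["onset_s"])) for b in run)
            for run in payload["runs"]
        )
        return cls(runs=runs, tr=float(payload["tr"]))


def make_block_schedule(n_runs: int, seed: int = 0, tr: float = TR) -> BlockSchedule:
    """Randomized block order: 3 blocks per condition per run, 44 s blocks."""
    if n_runs not in (4, 5):
        raise ValueError("sessions have 4 or 5 runs")
    rng = np.random.default_rng(seed)
    runs = []
    base = list(CONDITIONS) * BLOCKS_PER_CONDITION
    for _ in range(n_runs):
        order = list(base)
        rng.shuffle(order)
        runs.append(
            tuple(Block(cond, i * BLOCK_S) for i, cond in enumerate(order))
        )
    return BlockSchedule(runs=tuple(runs), tr=tr)
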