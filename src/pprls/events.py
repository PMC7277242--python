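"""Newline-delimited event log for simulation runs.

Each record is (step, event, agent_id, stage, sex).  Events:

``survive``  an agent alive at the start of the step survived it, at ``stage``;
``death``    an agent alive at the start of the step died, at ``stage``;
``birth``    a female gave birth; the record carries the *mother's* id and
             stage, so per-stage fecundity can be read off directly;
``famine``   step-level marker (agent_id = -1, stage = consecutive famine
             duration T_f).

The log is columnar internally (chunked numpy arrays) and serialises to TSV,
gzip-compressed when the path ends in ``.gz``.
"""

from __future__ import annotations

import gzip
from pathlib import Path

import numpy as np
import pandas as pd

SURVIVE, DEATH, BIRTH, FAMINE = 0, 1, 2, 3
EVENT_NAMES = {SURVIVE: "survive", DEATH: "death", BIRTH: "birth", FAMINE: "famine"}
EVENT_CODES = {v: k for k, v in EVENT_NAMES.items()}


class EventLog:
    """Append-only columnar event log."""

    def __init__(self) -> None:
        self._chunks: list[tuple[np.ndarray, ...]] = []
        self._cache: tuple[np.ndarray, ...] | None = None

    def append(
        self,
        step: int,
        event: int,
        agent_id: np.ndarray,
        stage: np.ndarray,
        sex: np.ndarray,
    ) -> None:
        agent_id = np.atleast_1d(np.asarray(agent_id, dtype=np.int64))
        k = agent_id.size
        if k == 0:
            return
        self._chunks.append(
            (
                np.full(k, step, dtype=np.int64),
                np.full(k, event, dtype=np.int8),
                agent_id,
                np.atleast_1d(np.asarray(stage, dtype=np.int16)),
                np.atleast_1d(np.asarray(sex, dtype=np.int8)),
            )
        )
        self._cache = None

    def _columns(self) -> tuple[np.ndarray, ...]:
        if self._cache is None:
            if not self._chunks:
                empty = (
                    np.empty(0, np.int64), np.empty(0, np.int8),
                    np.empty(0, np.int64), np.empty(0, np.int16),
                    np.empty(0, np.int8),
                )
                self._cache = empty
            else:
                self._cache = tuple(
                    np.concatenate([c[i] for c in self._chunks])
                    for i in range(5)
                )
        return self._cache

    @property
    def step(self) -> np.ndarray:
        return self._columns()[0]

    @property
    def event(self) -> np.ndarray:
        return self._columns()[1]

    @property
    def agent_id(self) -> np.ndarray:
        return self._columns()[2]

    @property
    def stage(self) -> np.ndarray:
        return self._columns()[3]

    @property
    def sex(self) -> np.ndarray:
        return self._columns()[4]

    def __len__(self) -> int:
        return int(self.step.size)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "step": self.step,
                "event": [EVENT_NAMES[e] for e in self.event],
                "agent_id": self.agent_id,
                "stage": self.stage,
                "sex": self.sex,
            }
        )

    def write_tsv(self, path: str | Path) -> None:
        path = Path(path)
        frame = self.to_frame()
        if path.suffix == ".gz":
            with gzip.open(path, "wt") as fh:
                frame.to_csv(fh, sep="\t", index=False)
        else:
            frame.to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path: str | Path) -> "EventLog":
        frame = pd.read_csv(path, sep="\t")
        log = cls()
        codes = frame["event"].map(EVENT_CODES).to_numpy(np.int8)
        for code in np.unique(codes):
            sub = frame[codes == code]
            for step, grp in sub.groupby("step"):
                log.append(
                    int(step), int(code),
                    grp["agent_id"].to_numpy(np.int64),
                    grp["stage"].to_numpy(np.int16),
                    grp["sex"].to_numpy(np.int8),
                )
        return log
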