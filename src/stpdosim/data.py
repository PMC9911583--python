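"""In-memory containers for multi-patient time-activity data.

Times are stored in minutes post injection; activities in % of
administered activity.  Activities must be strictly positive because the
fitting works on log-transformed observations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class Observation:
    patient_id: str
    time: float  # minutes post injection
    activity: float  # % of administered activity

    def __post_init__(self):
        if not self.time > 0:
            raise ValueError(
                f"{self.patient_id}: time must be > 0 min, got {self.time}"
            )
        if not self.activity > 0:
            raise ValueError(
                f"{self.patient_id}: activity must be > 0 "
                f"(log transform), got {self.activity}"
            )


class BiokineticDataset:
    """Ordered collection of observations from one or more patients."""

    def __init__(self, observations: Iterable[Observation]):
        self.observations = list(observations)
        seen: dict = {}
        for obs in self.observations:
            seen.setdefault(obs.patient_id, None)
        self.patients = list(seen)

    @property
    def n_obs(self) -> int:
        return len(self.observations)

    def of_patient(self, patient_id: str):
        return [o for o in self.observations if o.patient_id == patient_id]

    def patient_arrays(self, patient_id: str):
        obs = self.of_patient(patient_id)
        t = np.array([o.time for o in obs], dtype=float)
        y = np.array([o.activity for o in obs], dtype=float)
        return t, y

    def without(self, patient_id: str) -> "BiokineticDataset":
        if patient_id not in self.patients:
            raise KeyError(f"unknown patient {patient_id!r}")
        return BiokineticDataset(
            o for o in self.observations if o.patient_id != patient_id
        )

    def extended(self, extra: Sequence[Observation]) -> "BiokineticDataset":
        return BiokineticDataset(self.observations + list(extra))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "patient_id": [o.patient_id for o in self.observations],
                "time_h": [o.time / 60.0 for o in self.observations],
                "activity_pct": [o.activity for o in self.observations],
            }
        )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "BiokineticDataset":
        return cls(
            Observation(str(r.patient_id), float(r.time_h) * 60.0,
                        float(r.activity_pct))
            for r in df.itertuples()
        )

    def __repr__(self):
        return (
            f"BiokineticDataset({len(self.patients)} patients, "
            f"{self.n_obs} observations)"
        )
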