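"""Sample sheet: sample identifiers with control/case condition labels."""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

CONTROL = "control"
CASE = "case"


@dataclass
class SampleSheet:
    """Ordered sample identifiers with a condition label each."""

    sample_ids: list[str]
    conditions: list[str]

    def __post_init__(self) -> None:
        if len(self.sample_ids) != len(self.conditions):
            raise ValueError("sample_ids and conditions differ in length")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample identifiers")
        bad = sorted(set(self.conditions) - {CONTROL, CASE})
        if bad:
            raise ValueError(f"unknown condition labels: {bad}")

    @property
    def controls(self) -> list[str]:
        return [s for s, c in zip(self.sample_ids, self.conditions) if c == CONTROL]

    @property
    def cases(self) -> list[str]:
        return [s for s, c in zip(self.sample_ids, self.conditions) if c == CASE]

    @property
    def n_controls(self) -> int:
        return len(self.controls)

    @property
    def n_cases(self) -> int:
        return len(self.cases)

    def __len__(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"sample_id": self.sample_ids, "condition": self.conditions}
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "SampleSheet":
        return cls(
            sample_ids=frame["sample_id"].astype(str).tolist(),
            conditions=frame["condition"].astype(str).tolist(),
        )

    def write(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def read(cls, path) -> "SampleSheet":
        return cls.from_frame(pd.read_csv(path, sep="\t"))
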