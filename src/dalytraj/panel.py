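"""Long-format person-wave panel container.

A panel holds one row per person per survey wave, with demographic fields,
socioeconomic status, per-disease onset years (``onset_<disease>`` columns,
NaN while undiagnosed), expenditure controls and follow-up status.  The
container is a thin wrapper over a :class:`pandas.DataFrame` plus a metadata
dictionary recording the conventions (duration convention, cohort boundaries,
centering medians, codebook) applied so far.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .errors import DataError

#: Columns every raw panel must carry (onset/expenditure columns are extra).
REQUIRED_COLUMNS = (
    "person_id",
    "wave_year",
    "birth_year",
    "age",
    "female",
    "urban",
    "education",
    "income_pc",
    "no_spouse",
    "smoking",
    "drinking",
    "exit_type",
)

#: Interview-timing slack allowed between age and wave_year - birth_year.
AGE_SLACK = 1


@dataclass
class PanelDataset:
    """A validated long-format collection of person-wave records."""

    data: pd.DataFrame
    meta: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.data)

    @property
    def n_persons(self) -> int:
        return self.data["person_id"].nunique()

    def onset_columns(self) -> list[str]:
        return [c for c in self.data.columns if c.startswith("onset_")]

    def validate(self) -> "PanelDataset":
        """Check person-wave invariants; raise :class:`DataError` on violation."""
        df = self.data
        missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
        if missing:
            raise DataError(f"panel is missing required columns: {missing}")
        if len(df) == 0:
            return self
        if df.duplicated(["person_id", "wave_year"]).any():
            dupes = df.loc[
                df.duplicated(["person_id", "wave_year"]), "person_id"
            ].unique()[:5]
            raise DataError(f"duplicate person-wave records, e.g. persons {list(dupes)}")
        ordered = df.sort_values(["person_id", "wave_year"]).index
        if not ordered.equals(df.index):
            raise DataError("panel rows must be ordered by person_id, wave_year")
        slack = (df["age"] - (df["wave_year"] - df["birth_year"])).abs()
        if (slack > AGE_SLACK).any():
            bad = df.loc[slack > AGE_SLACK, "person_id"].iloc[0]
            raise DataError(
                f"age inconsistent with wave_year - birth_year beyond ±{AGE_SLACK} "
                f"(first offender: person {bad})"
            )
        for col in self.onset_columns():
            late = df[col].notna() & (df[col] > df["wave_year"])
            if late.any():
                row = df.loc[late].iloc[0]
                raise DataError(
                    f"onset after wave: person {row['person_id']}, "
                    f"disease {col[len('onset_'):]}, onset {row[col]:.0f} "
                    f"> wave {row['wave_year']}"
                )
        return self

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)
        meta_path = Path(path).with_suffix(".meta.json")
        meta_path.write_text(json.dumps(self.meta, indent=2, default=str))

    @classmethod
    def from_csv(cls, path) -> "PanelDataset":
        data = pd.read_csv(path)
        meta_path = Path(path).with_suffix(".meta.json")
        meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
        return cls(data=data, meta=meta)


def as_frame(panel) -> pd.DataFrame:
    """Accept either a PanelDataset or a bare DataFrame."""
    return panel.data if isinstance(panel, PanelDataset) else panel
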