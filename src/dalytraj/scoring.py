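"""Years-lived-with-disability (YLD) scoring for 13 chronic diseases.

Each diagnosed condition j contributes ``W_j * T_j`` healthy years lost,
where ``W_j`` is the condition's disability weight (a severity score in
[0, 1], 0 = full health, 1 = death) and ``T_j`` the years lived with the
condition.  The per-person total is the plain sum over conditions — no
age-weighting, time-discounting or multiplicative comorbidity adjustment.
Because the conditions tracked here are chronic and essentially non-fatal,
the YLD total is used directly as the DALY burden.

Weights are a registry of 13 conditions drawn from GBD 2013 health states
plus China- and WHO-specific estimates for hypertension and diabetes.
Hyperlipidemia, though present in the 14-condition questionnaire, carries no
weight and is excluded.  Four entries are composites averaging two GBD
health states; the hepatic entry averages decompensated liver cirrhosis
(lower limit) and viral hepatitis, (0.123 + 0.006) / 2 = 0.0645.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataError
from .panel import PanelDataset, as_frame

#: The 13 scored chronic conditions, in registry order.
DISEASES = (
    "hypertension",
    "diabetes",
    "cancer",
    "chronic_pulmonary",
    "hepatic",
    "heart_disease",
    "stroke",
    "kidney_disease",
    "gastric",
    "emotional_mental",
    "memory",
    "arthritis",
    "asthma",
)

#: Questionnaire condition excluded from scoring (no disability weight).
EXCLUDED_DISEASES = ("hyperlipidemia",)

DURATION_CONVENTIONS = ("diagnosis_year", "first_report")


@dataclass(frozen=True)
class WeightEntry:
    """One registry entry: weight, provenance, and composite components.

    ``components`` is a tuple of ``(label, value)`` pairs for composite
    entries; a value is ``None`` when the source states only the health-state
    label for the component, not its numeric weight.
    """

    disease_id: str
    weight: float
    source: str
    components: tuple = ()

    @property
    def is_composite(self) -> bool:
        return len(self.components) > 0


@dataclass
class DiseaseWeightTable:
    """Registry mapping disease id -> disability weight."""

    entries: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, disease_id: str) -> bool:
        return disease_id in self.entries

    def weight(self, disease_id: str) -> float:
        try:
            return self.entries[disease_id].weight
        except KeyError:
            raise DataError(f"unknown disease id: {disease_id!r}") from None

    def weights(self) -> dict:
        return {d: e.weight for d, e in self.entries.items()}

    def validate(self) -> "DiseaseWeightTable":
        if len(self.entries) != len(DISEASES):
            raise ConfigurationError(
                f"weight table must have exactly {len(DISEASES)} entries, "
                f"got {len(self.entries)}"
            )
        for excluded in EXCLUDED_DISEASES:
            if excluded in self.entries:
                raise ConfigurationError(f"{excluded} must not carry a weight")
        for d, e in self.entries.items():
            if not 0.0 <= e.weight <= 1.0:
                raise ConfigurationError(f"weight for {d} outside [0, 1]: {e.weight}")
            values = [v for _, v in e.components if v is not None]
            if e.is_composite and len(values) == len(e.components) and values:
                if not math.isclose(e.weight, sum(values) / len(values), abs_tol=1e-9):
                    raise ConfigurationError(
                        f"composite weight for {d} is not the mean of its components"
                    )
        return self

    def to_csv(self, path) -> None:
        rows = []
        for e in self.entries.values():
            rows.append(
                {
                    "disease_id": e.disease_id,
                    "weight": e.weight,
                    "source": e.source,
                    "components": ";".join(
                        f"{lab}={'' if v is None else repr(v)}"
                        for lab, v in e.components
                    ),
                }
            )
        pd.DataFrame(rows).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "DiseaseWeightTable":
        df = pd.read_csv(path, keep_default_na=False)
        entries = {}
        for _, row in df.iterrows():
            components = []
            if row.get("components"):
                for part in str(row["components"]).split(";"):
                    lab, _, val = part.partition("=")
                    components.append((lab, float(val) if val else None))
            entries[row["disease_id"]] = WeightEntry(
                disease_id=row["disease_id"],
                weight=float(row["weight"]),
                source=str(row.get("source", "")),
                components=tuple(components),
            )
        return cls(entries=entries)


def build_weight_table() -> DiseaseWeightTable:
    """Construct the fixed 13-disease disability-weight registry."""

    def entry(d, w, source, components=()):
        return WeightEntry(d, w, source, tuple(components))

    hepatic_components = (
        ("decompensated liver cirrhosis (lower limit)", 0.123),
        ("viral hepatitis", 0.006),
    )
    entries = {
        "hypertension": entry("hypertension", 0.36, "China multi-source study"),
        "diabetes": entry("diabetes", 0.015, "WHO 2004 (95% CI 0.012-0.018)"),
        "cancer": entry("cancer", 0.288, "GBD: cancer diagnosis and primary treatment"),
        "chronic_pulmonary": entry(
            "chronic_pulmonary", 0.225, "GBD: moderate chronic pulmonary disease"
        ),
        "hepatic": entry(
            "hepatic",
            (0.123 + 0.006) / 2,
            "mean of decompensated cirrhosis (lower limit) and viral hepatitis",
            hepatic_components,
        ),
        "heart_disease": entry("heart_disease", 0.008, "GBD: moderate angina pectoris"),
        "stroke": entry("stroke", 0.07, "GBD: moderate stroke"),
        "kidney_disease": entry(
            "kidney_disease", 0.104, "GBD: chronic kidney disease (stage 4)"
        ),
        "gastric": entry("gastric", 0.209, "GBD: gastric bleeding lower limit value"),
        "emotional_mental": entry(
            "emotional_mental",
            0.265,
            "mean of moderate anxiety and moderate depression",
            (("moderate anxiety", None), ("moderate depression", None)),
        ),
        "memory": entry(
            "memory",
            0.322,
            "mean of moderate dementia and Parkinson's disease",
            (("moderate dementia", None), ("Parkinson's disease", None)),
        ),
        "arthritis": entry(
            "arthritis",
            0.080,
            "mean of moderate musculoskeletal disorders",
            (("moderate musculoskeletal disorders (mean)", None),),
        ),
        "asthma": entry("asthma", 0.036, "GBD: partly controlled asthma"),
    }
    return DiseaseWeightTable(entries=entries).validate()


@dataclass
class YldRecord:
    """Per-person-wave YLD decomposition."""

    person_id: object
    wave_year: int
    durations: dict
    per_disease_ylds: dict
    total_ylds: float


def disease_duration(
    onsets: dict,
    wave_year: int,
    convention: str = "diagnosis_year",
    first_reports: dict | None = None,
) -> dict:
    """Years lived with each diagnosed disease at ``wave_year``.

    Under the default ``diagnosis_year`` convention the reference year is the
    recorded onset year; under ``first_report`` it is the wave at which the
    diagnosis first entered the data (``first_reports`` map).  Durations are
    floored at zero; undiagnosed diseases are omitted.
    """
    if convention not in DURATION_CONVENTIONS:
        raise ConfigurationError(f"unknown duration convention: {convention!r}")
    out = {}
    for disease, onset in onsets.items():
        if onset is None or (isinstance(onset, float) and math.isnan(onset)):
            continue
        if onset > wave_year:
            raise DataError(
                f"onset year {onset} after wave {wave_year} for disease {disease}"
            )
        if convention == "first_report":
            ref = (first_reports or {}).get(disease, onset)
        else:
            ref = onset
        out[disease] = max(0.0, float(wave_year - ref))
    return out


def score_person_wave(
    durations: dict, table: DiseaseWeightTable, person_id=None, wave_year=None
) -> YldRecord:
    """Score one person-wave: YLD_j = W_j * T_j, total = sum over j."""
    per_disease = {}
    for disease, t in durations.items():
        if disease not in table:
            raise DataError(f"unknown disease id: {disease!r}")
        if t < 0:
            raise DataError(f"negative duration for {disease}: {t}")
        per_disease[disease] = table.weight(disease) * float(t)
    return YldRecord(
        person_id=person_id,
        wave_year=wave_year,
        durations=dict(durations),
        per_disease_ylds=per_disease,
        total_ylds=float(sum(per_disease.values())),
    )


def score_panel(
    panel,
    table: DiseaseWeightTable | None = None,
    convention: str = "diagnosis_year",
) -> pd.DataFrame:
    """Score every observed person-wave of a panel.

    Returns a frame keyed by (person_id, wave_year) with per-disease duration
    (``dur_<d>``) and YLD (``yld_<d>``) columns plus the ``dalys`` total.
    """
    if convention not in DURATION_CONVENTIONS:
        raise ConfigurationError(f"unknown duration convention: {convention!r}")
    table = table or build_weight_table()
    df = as_frame(panel)
    out = df[["person_id", "wave_year"]].copy()
    total = np.zeros(len(df))
    for disease in DISEASES:
        col = f"onset_{disease}"
        if col not in df.columns:
            continue
        onset = df[col].astype(float)
        late = onset.notna() & (onset > df["wave_year"])
        if late.any():
            row = df.loc[late].iloc[0]
            raise DataError(
                f"onset after wave: person {row['person_id']}, disease {disease}"
            )
        if convention == "first_report":
            reported_wave = df["wave_year"].where(onset.notna())
            ref = reported_wave.groupby(df["person_id"]).transform("min")
            ref = ref.where(onset.notna())
        else:
            ref = onset
        dur = (df["wave_year"] - ref).clip(lower=0.0)
        yld = table.weight(disease) * dur
        out[f"dur_{disease}"] = dur
        out[f"yld_{disease}"] = yld
        total += yld.fillna(0.0).to_numpy()
    out["dalys"] = total
    out.attrs["duration_convention"] = convention
    return out


def attach_scores(panel, scores: pd.DataFrame) -> PanelDataset:
    """Merge the ``dalys`` outcome back onto the panel."""
    df = as_frame(panel).merge(
        scores[["person_id", "wave_year", "dalys"]],
        on=["person_id", "wave_year"],
        how="left",
        validate="one_to_one",
    )
    meta = dict(panel.meta) if isinstance(panel, PanelDataset) else {}
    meta["duration_convention"] = scores.attrs.get("duration_convention")
    return PanelDataset(data=df, meta=meta)
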