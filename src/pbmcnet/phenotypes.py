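"""Subject phenotype table: demographics and vascular-health variables."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

#: Canonical phenotype columns and their units.
PHENOTYPE_UNITS = {
    "age": "years",
    "sex": "F/M",
    "BMI": "kg/m^2",
    "AIx": "%",       # augmentation index, surrogate of arterial stiffness
    "AoPP": "mmHg",   # central aortic pulse pressure
    "AoSP": "mmHg",   # central aortic systolic pressure
    "cohort": "control/hypertensive",
}


@dataclass
class PhenotypeTable:
    """One row per subject; columns as in :data:`PHENOTYPE_UNITS`.

    ``sex`` must be present (values "F"/"M") when female-stratified BMI
    analyses are requested; ``cohort`` is "control" or "hypertensive".
    """

    values: pd.DataFrame

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            raise ValueError("PhenotypeTable: duplicate subject IDs")
        for col in ("age",):
            if col not in self.values.columns:
                raise ValueError(f"PhenotypeTable: missing column {col!r}")
        if "sex" in self.values.columns:
            bad = set(self.values["sex"].dropna()) - {"F", "M"}
            if bad:
                raise ValueError(f"PhenotypeTable: invalid sex values {sorted(bad)}")
        if "cohort" in self.values.columns:
            bad = set(self.values["cohort"].dropna()) - {"control", "hypertensive"}
            if bad:
                raise ValueError(f"PhenotypeTable: invalid cohort labels {sorted(bad)}")

    @property
    def subjects(self) -> tuple[str, ...]:
        return tuple(self.values.index)

    def females(self) -> "PhenotypeTable":
        return PhenotypeTable(self.values[self.values["sex"] == "F"].copy())

    def numeric(self, variable: str) -> pd.Series:
        s = pd.to_numeric(self.values[variable], errors="coerce")
        if not np.isfinite(s.dropna()).all():
            raise ValueError(f"PhenotypeTable: non-finite values in {variable!r}")
        return s
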