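"""Cohort tables for two-arm randomized trials.

A cohort is one row per subject: identifiers, randomized arm, the binary
one-year success endpoint, the time-to-event endpoint, and a set of baseline
covariates declared continuous or categorical by a :class:`CohortSchema`.
Missing covariate values are preserved as missing (``NaN``), never silently
imputed here — imputation is a fitted preprocessing step.

Deterministic dataset splits follow the order of registration (enrollment
sequence), the trial's device for carving training/validation/test sets
without touching the randomization.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

ARM_TREATMENT = "treatment"
ARM_CONTROL = "control"
ARMS = (ARM_TREATMENT, ARM_CONTROL)

#: columns every cohort file must carry besides covariates
MANDATORY_COLUMNS = ("subject_id", "registration_order", "arm", "event_time", "event_indicator")

FOLLOWUP_HORIZON = 12.0  # months


class SchemaError(ValueError):
    """A cohort file does not conform to the declared schema."""


class CohortValidationError(ValueError):
    """A cohort violates a structural invariant (ids, arms, endpoint coding)."""


@dataclass(frozen=True)
class CohortSchema:
    """Declares which covariates exist and whether each is continuous or categorical."""

    continuous: tuple[str, ...]
    categorical: tuple[str, ...]

    def __post_init__(self):
        overlap = set(self.continuous) & set(self.categorical)
        if overlap:
            raise SchemaError(f"features declared both continuous and categorical: {sorted(overlap)}")

    @property
    def features(self) -> tuple[str, ...]:
        return tuple(self.continuous) + tuple(self.categorical)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps({"continuous": list(self.continuous), "categorical": list(self.categorical)}, indent=2)
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "CohortSchema":
        d = json.loads(Path(path).read_text())
        return cls(continuous=tuple(d["continuous"]), categorical=tuple(d["categorical"]))


class CohortTable:
    """An ordered two-arm cohort with a covariate schema.

    Rows are kept sorted by ``registration_order``. The binary endpoint
    ``success`` (1 = no recurrence within follow-up) is derived from
    ``event_indicator`` when absent and must agree with it when present:
    success == 1 exactly when no event was observed.
    """

    def __init__(self, data: pd.DataFrame, schema: CohortSchema, horizon: float = FOLLOWUP_HORIZON):
        df = data.copy()
        for col in MANDATORY_COLUMNS:
            if col not in df.columns:
                raise SchemaError(f"mandatory column missing: {col!r}")
        missing_feats = [f for f in schema.features if f not in df.columns]
        if missing_feats:
            raise SchemaError(f"schema features absent from data: {missing_feats}")

        df["subject_id"] = df["subject_id"].astype(str)
        df["registration_order"] = df["registration_order"].astype(int)
        if (df["registration_order"] <= 0).any():
            raise CohortValidationError("registration_order must be positive")
        if df["registration_order"].duplicated().any():
            dupes = df.loc[df["registration_order"].duplicated(), "registration_order"].tolist()
            raise CohortValidationError(f"duplicate registration_order values: {dupes}")

        bad_arm = set(df["arm"].unique()) - set(ARMS)
        if bad_arm:
            raise CohortValidationError(f"unknown arm labels: {sorted(bad_arm)}")

        df["event_time"] = df["event_time"].astype(float)
        df["event_indicator"] = df["event_indicator"].astype(int)
        if not df["event_indicator"].isin((0, 1)).all():
            raise CohortValidationError("event_indicator must be binary")
        if (df["event_time"] <= 0).any():
            raise CohortValidationError("event_time must be positive")
        if (df["event_time"] > horizon + 1e-9).any():
            raise CohortValidationError(f"event_time exceeds follow-up horizon ({horizon} months)")

        if "success" not in df.columns:
            df["success"] = 1 - df["event_indicator"]
        else:
            df["success"] = df["success"].astype(int)
            if not (df["success"] == 1 - df["event_indicator"]).all():
                raise CohortValidationError("success must equal 1 - event_indicator (same endpoint)")

        for f in schema.continuous:
            df[f] = pd.to_numeric(df[f], errors="raise").astype(float)
        for f in schema.categorical:
            df[f] = df[f].astype(object)
            # normalize pandas NA flavours to np.nan for a single missing marker
            df[f] = df[f].where(pd.notna(df[f]), np.nan)

        order = ["subject_id", "registration_order", "arm", "success", "event_time", "event_indicator"]
        df = df[order + list(schema.features)]
        df = df.sort_values("registration_order", kind="mergesort").reset_index(drop=True)

        self.data = df
        self.schema = schema
        self.horizon = horizon

    # -- basic accessors -------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.data)

    def __len__(self) -> int:
        return self.n

    def arm_counts(self) -> dict[str, int]:
        vc = self.data["arm"].value_counts()
        return {a: int(vc.get(a, 0)) for a in ARMS}

    def features_frame(self) -> pd.DataFrame:
        return self.data[list(self.schema.features)].copy()

    # -- IO ---------------------------------------------------------------
    @classmethod
    def from_csv(cls, path: str | Path, schema: CohortSchema | str | Path, horizon: float = FOLLOWUP_HORIZON) -> "CohortTable":
        """Load a cohort from a UTF-8 comma-separated file with a header row.

        Empty cells are read as missing. ``schema`` may be a
        :class:`CohortSchema` or a path to its JSON sidecar.
        """
        if not isinstance(schema, CohortSchema):
            schema = CohortSchema.from_json(schema)
        df = pd.read_csv(path, dtype={"subject_id": str}, keep_default_na=True, na_values=[""])
        return cls(df, schema, horizon=horizon)

    def to_csv(self, path: str | Path, schema_path: str | Path | None = None) -> None:
        """Write the cohort as CSV (empty string = missing); optionally write the schema sidecar."""
        self.data.to_csv(path, index=False, na_rep="")
        if schema_path is not None:
            self.schema.to_json(schema_path)

    # -- splitting --------------------------------------------------------
    def split_by_registration_order(self, sizes: tuple[int, int] | None = None) -> tuple["CohortTable", "CohortTable"]:
        """Split into (earliest ``sizes[0]``, remaining ``sizes[1]``) by registration order.

        ``sizes`` must sum to the cohort size. When omitted, the convenience
        default is ``(ceil(n/2), floor(n/2))``; reproducing a specific
        published split requires passing its sizes explicitly. The split
        deliberately ignores arm: randomization imbalance within parts is
        whatever the enrollment sequence produced.
        """
        if sizes is None:
            sizes = (math.ceil(self.n / 2), math.floor(self.n / 2))
        a, b = int(sizes[0]), int(sizes[1])
        if a < 0 or b < 0 or a + b != self.n:
            raise ValueError(f"split sizes {sizes} do not partition cohort of n={self.n}")
        first = CohortTable(self.data.iloc[:a], self.schema, horizon=self.horizon)
        second = CohortTable(self.data.iloc[a:], self.schema, horizon=self.horizon)
        return first, second


def load_cohort(path: str | Path, schema: CohortSchema | str | Path) -> CohortTable:
    """Functional alias for :meth:`CohortTable.from_csv`."""
    return CohortTable.from_csv(path, schema)


def write_split_artifacts(cohort: CohortTable, parts: tuple[CohortTable, CohortTable], directory: str | Path) -> dict:
    """Write split parts as CSV plus a provenance JSON (input hash, sizes, timestamp)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, part in enumerate(parts):
        p = directory / f"split_part{i}.csv"
        part.to_csv(p)
        paths.append(str(p))
    payload = cohort.data.to_csv(index=False, na_rep="").encode()
    prov = {
        "input_sha256": hashlib.sha256(payload).hexdigest(),
        "sizes": [parts[0].n, parts[1].n],
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "files": paths,
    }
    (directory / "split_provenance.json").write_text(json.dumps(prov, indent=2))
    return prov
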