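"""Patient-level symptom data: container, CSV round-trip, age dichotomization.

The on-disk dialect is a UTF-8 comma-separated file with a header row and,
per catalog item ``<code>``, the columns ``occ_<code>`` (0/1, empty =
missing), ``sev_<code>`` (1-4) and ``dis_<code>`` (0-4). Severity and
distress are conditional ratings: they are defined only where the symptom
occurred, and a defined rating next to an absent or missing occurrence is a
validation error, not data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .catalog import ItemCatalog, default_catalog

__all__ = [
    "SchemaError",
    "ValidationError",
    "PatientRecord",
    "SymptomDataset",
    "AgeGroupSplit",
    "load_dataset",
    "dichotomize_by_age",
]

logger = logging.getLogger(__name__)


class SchemaError(ValueError):
    """A required column is missing or malformed."""


class ValidationError(ValueError):
    """Cell values violate the instrument's invariants."""


@dataclass(frozen=True)
class PatientRecord:
    """One patient's responses (a read-only view onto the dataset arrays)."""

    patient_id: str
    age: float
    occurrence: np.ndarray  # 0.0 / 1.0 / nan per item
    severity: np.ndarray    # 1-4 where occurrence == 1, else nan
    distress: np.ndarray    # 0-4 where occurrence == 1, else nan


@dataclass
class SymptomDataset:
    """Binary occurrence plus conditional ordinal ratings for one sample.

    Arrays are ``n_patients x n_items`` floats; missing values are NaN.
    """

    catalog: ItemCatalog
    patient_ids: list[str]
    ages: np.ndarray
    occurrence: np.ndarray
    severity: np.ndarray
    distress: np.ndarray
    provenance: str = ""

    def __post_init__(self) -> None:
        n, p = len(self.patient_ids), len(self.catalog)
        self.ages = np.asarray(self.ages, dtype=float)
        for name in ("occurrence", "severity", "distress"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (n, p):
                raise ValidationError(
                    f"{name} has shape {arr.shape}, expected ({n}, {p})"
                )
            setattr(self, name, arr)
        if self.ages.shape != (n,):
            raise ValidationError(f"ages has shape {self.ages.shape}, expected ({n},)")
        self.validate()

    # -- invariants -----------------------------------------------------
    def validate(self) -> None:
        occ, sev, dis = self.occurrence, self.severity, self.distress
        bad_occ = ~(np.isnan(occ) | (occ == 0) | (occ == 1))
        if bad_occ.any():
            raise ValidationError(self._describe_cells("occurrence not in {0,1,missing}", bad_occ))
        present = occ == 1
        orphan = (~present) & (~np.isnan(sev) | ~np.isnan(dis))
        if orphan.any():
            raise ValidationError(
                self._describe_cells("severity/distress defined without occurrence", orphan)
            )
        bad_sev = ~np.isnan(sev) & ~np.isin(sev, [1, 2, 3, 4])
        if bad_sev.any():
            raise ValidationError(self._describe_cells("severity outside 1-4", bad_sev))
        bad_dis = ~np.isnan(dis) & ~np.isin(dis, [0, 1, 2, 3, 4])
        if bad_dis.any():
            raise ValidationError(self._describe_cells("distress outside 0-4", bad_dis))

    def _describe_cells(self, msg: str, mask: np.ndarray, limit: int = 10) -> str:
        rows, cols = np.nonzero(mask)
        cells = [
            f"(row {r}, item {self.catalog.codes[c]})" for r, c in zip(rows[:limit], cols[:limit])
        ]
        more = "" if len(rows) <= limit else f" and {len(rows) - limit} more"
        return f"{msg}: {', '.join(cells)}{more}"

    # -- basic accessors ------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.patient_ids)

    def __len__(self) -> int:
        return self.n

    def record(self, i: int) -> PatientRecord:
        return PatientRecord(
            self.patient_ids[i],
            float(self.ages[i]),
            self.occurrence[i],
            self.severity[i],
            self.distress[i],
        )

    def subset(self, mask: np.ndarray, provenance: str | None = None) -> "SymptomDataset":
        mask = np.asarray(mask)
        return SymptomDataset(
            self.catalog,
            [pid for pid, m in zip(self.patient_ids, mask) if m],
            self.ages[mask],
            self.occurrence[mask],
            self.severity[mask],
            self.distress[mask],
            provenance if provenance is not None else self.provenance,
        )

    # -- frame / CSV round trip -----------------------------------------
    def to_frame(self) -> pd.DataFrame:
        data: dict[str, object] = {"patient_id": self.patient_ids, "age": self.ages}
        for j, code in enumerate(self.catalog.codes):
            data[f"occ_{code}"] = self.occurrence[:, j]
            data[f"sev_{code}"] = self.severity[:, j]
            data[f"dis_{code}"] = self.distress[:, j]
        return pd.DataFrame(data)

    def write_csv(self, path: str | Path) -> None:
        df = self.to_frame()
        # integers where defined, empty string where missing
        for col in df.columns[2:]:
            df[col] = df[col].map(lambda v: "" if pd.isna(v) else str(int(v)))
        df.to_csv(path, index=False)

    @classmethod
    def from_frame(
        cls, df: pd.DataFrame, catalog: ItemCatalog | None = None, provenance: str = ""
    ) -> "SymptomDataset":
        catalog = catalog or default_catalog()
        if "age" not in df.columns:
            raise SchemaError("missing required column 'age'")
        missing = [
            f"{kind}_{code}"
            for code in catalog.codes
            for kind in ("occ", "sev", "dis")
            if f"{kind}_{code}" not in df.columns
        ]
        if missing:
            raise SchemaError(f"missing required columns: {missing[:6]}"
                              + ("..." if len(missing) > 6 else ""))
        ages = pd.to_numeric(df["age"], errors="coerce").to_numpy(dtype=float)
        ok = np.isfinite(ages) & (ages >= 0)
        n_bad = int((~ok).sum())
        if n_bad:
            logger.warning("rejected %d row(s) with unparseable or negative age", n_bad)
        df = df.loc[ok]
        ages = ages[ok]
        if "patient_id" in df.columns:
            pids = df["patient_id"].astype(str).tolist()
        else:
            pids = [f"p{i:05d}" for i in range(len(df))]

        def block(prefix: str) -> np.ndarray:
            cols = [pd.to_numeric(df[f"{prefix}_{c}"], errors="coerce") for c in catalog.codes]
            return pd.concat(cols, axis=1).to_numpy(dtype=float)

        return cls(catalog, pids, ages, block("occ"), block("sev"), block("dis"), provenance)


def load_dataset(path: str | Path, catalog: ItemCatalog | None = None) -> SymptomDataset:
    """Read and validate a patient-level CSV file (see module docstring)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    df = df.replace("", np.nan)
    return SymptomDataset.from_frame(df, catalog, provenance=str(path))


@dataclass
class AgeGroupSplit:
    """Exhaustive, disjoint partition of a sample at an age cutoff.

    The cutoff is inclusive on the older side: age >= cutoff goes to
    ``older`` (the WHO convention of >= 60 years defining the older
    population is the default downstream).
    """

    younger: SymptomDataset
    older: SymptomDataset
    cutoff: float = 60.0

    @property
    def sizes(self) -> tuple[int, int]:
        return self.younger.n, self.older.n


def dichotomize_by_age(
    dataset: SymptomDataset, cutoff: float = 60.0, min_group_factor: int = 5
) -> AgeGroupSplit:
    """Split a dataset into younger (< cutoff) and older (>= cutoff) groups.

    Warns when a group is smaller than ``min_group_factor`` times the item
    count, the usual minimum-sample heuristic for factoring the group.
    """
    if np.isnan(dataset.ages).any():
        raise ValidationError("all records must have a defined age")
    older_mask = dataset.ages >= cutoff
    split = AgeGroupSplit(
        dataset.subset(~older_mask, provenance=f"{dataset.provenance} [age < {cutoff}]"),
        dataset.subset(older_mask, provenance=f"{dataset.provenance} [age >= {cutoff}]"),
        cutoff,
    )
    floor = min_group_factor * len(dataset.catalog)
    for name, grp in (("younger", split.younger), ("older", split.older)):
        if grp.n == 0:
            logger.warning("%s group is empty at cutoff %.1f", name, cutoff)
        elif grp.n < floor:
            logger.warning(
                "%s group has n=%d < %d; factor analysis on it may be unstable",
                name, grp.n, floor,
            )
    logger.info("age split at %.1f: younger n=%d, older n=%d", cutoff, *split.sizes)
    return split
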