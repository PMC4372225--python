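"""Activity-threshold dataset construction.

Builds labelled inhibitor / non-inhibitor datasets from raw activity tables:
IC50 thresholding, removal of compounds with conflicting measurements,
stratified train/validation splitting, and scaffold-class subsetting
(e.g. pyrimidine, quinazoline) via SMARTS substructure matching.

Conventions
-----------
* A compound is an *inhibitor* when every one of its IC50 measurements is
  strictly below the cutoff, a *non-inhibitor* when every measurement is at
  or above it.  A compound measured on both sides of the cutoff is a
  conflict and is removed (and counted).
* IC50 values are in nanomolar throughout.
"""

from __future__ import annotations

import csv
import io
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit import RDLogger

logger = logging.getLogger(__name__)

RDLogger.DisableLog("rdApp.error")

LABEL_ACTIVE = "inhibitor"
LABEL_INACTIVE = "non_inhibitor"


@dataclass(frozen=True)
class MoleculeRecord:
    """One activity measurement: a compound, its SMILES and one IC50 (nM)."""

    compound_id: str
    smiles: str
    ic50_nm: float

    def __post_init__(self) -> None:
        if not self.ic50_nm > 0:
            raise ValueError(
                f"ic50_nm must be positive, got {self.ic50_nm!r} "
                f"for compound {self.compound_id!r}"
            )


@dataclass
class ActivityDataset:
    """Labelled compounds at a stated IC50 cutoff.

    ``compounds`` is a DataFrame with columns ``compound_id``, ``smiles``,
    ``label`` (``inhibitor`` / ``non_inhibitor``); each compound_id appears
    exactly once.
    """

    cutoff_nm: float
    compounds: pd.DataFrame
    n_removed_conflicts: int = 0
    split_tag: str = "full"

    def __post_init__(self) -> None:
        required = {"compound_id", "smiles", "label"}
        missing = required - set(self.compounds.columns)
        if missing:
            raise ValueError(f"compounds frame missing columns: {sorted(missing)}")
        if self.compounds["compound_id"].duplicated().any():
            dups = self.compounds.loc[
                self.compounds["compound_id"].duplicated(), "compound_id"
            ].tolist()
            raise ValueError(f"duplicate compound_ids in dataset: {dups[:5]}")
        bad = set(self.compounds["label"]) - {LABEL_ACTIVE, LABEL_INACTIVE}
        if bad:
            raise ValueError(f"unknown labels: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.compounds)

    @property
    def compound_ids(self) -> list[str]:
        return self.compounds["compound_id"].tolist()

    @property
    def labels(self) -> pd.Series:
        return pd.Series(
            self.compounds["label"].values,
            index=self.compounds["compound_id"].values,
            name="label",
        )

    @property
    def n_active(self) -> int:
        return int((self.compounds["label"] == LABEL_ACTIVE).sum())

    @property
    def n_inactive(self) -> int:
        return int((self.compounds["label"] == LABEL_INACTIVE).sum())

    def summary(self) -> dict:
        return {
            "cutoff_nm": self.cutoff_nm,
            "split_tag": self.split_tag,
            "n_compounds": len(self),
            "n_active": self.n_active,
            "n_inactive": self.n_inactive,
            "n_removed_conflicts": self.n_removed_conflicts,
        }

    def to_csv(self, path: str | Path) -> None:
        self.compounds.to_csv(path, index=False)

    def write_summary(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.summary(), indent=2) + "\n")


@dataclass(frozen=True)
class ClassDefinition:
    """A named structural class defined by a SMARTS pattern.

    Lower ``priority`` wins when several patterns match (every quinazoline
    contains a pyrimidine ring, so quinazoline must outrank pyrimidine).
    """

    class_name: str
    smarts: str
    priority: int

    def pattern(self) -> Chem.Mol:
        patt = Chem.MolFromSmarts(self.smarts)
        if patt is None:
            raise ValueError(
                f"unparseable SMARTS for class {self.class_name!r}: {self.smarts!r}"
            )
        return patt


#: Quinazoline before pyrimidine: the quinazoline bicycle contains a
#: 1,3-diazine ring, so priority decides the overlap.
DEFAULT_CLASS_REGISTRY: list[ClassDefinition] = [
    ClassDefinition("quinazoline", "c1ccc2ncncc2c1", priority=1),
    ClassDefinition("pyrimidine", "c1ccncn1", priority=2),
]


def _validate_registry(registry: list[ClassDefinition]) -> list[ClassDefinition]:
    if not registry:
        raise ValueError("class registry is empty")
    priorities = [c.priority for c in registry]
    if len(set(priorities)) != len(priorities):
        raise ValueError("class registry priorities must be unique")
    return sorted(registry, key=lambda c: c.priority)


def load_activity_table(
    path: str | Path,
    dialect: str | None = None,
    activities: str | Path | None = None,
) -> list[MoleculeRecord]:
    """Read an activity table into validated :class:`MoleculeRecord` rows.

    Parameters
    ----------
    path
        CSV/TSV with columns ``compound_id, smiles, ic50_nm`` (resolved by
        header, else by position), or a ``.smi`` file (SMILES, whitespace,
        compound id) paired with ``activities`` — a CSV mapping
        ``compound_id`` to ``ic50_nm``.
    dialect
        ``"csv"``, ``"tsv"`` or ``"smi"``; inferred from the suffix when None.

    Rows with unparseable SMILES or non-positive/non-numeric IC50 are
    rejected and counted in the log; zero valid records is a hard error.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect is None:
        dialect = {".tsv": "tsv", ".smi": "smi"}.get(path.suffix.lower(), "csv")

    if dialect == "smi":
        if activities is None:
            raise ValueError(".smi input requires an `activities` CSV (compound_id,ic50_nm)")
        rows = _rows_from_smi(path, Path(activities))
    else:
        sep = "\t" if dialect == "tsv" else ","
        rows = _rows_from_table(path, sep)

    records: list[MoleculeRecord] = []
    n_rejected = 0
    for compound_id, smiles, ic50_raw in rows:
        try:
            ic50 = float(ic50_raw)
        except (TypeError, ValueError):
            n_rejected += 1
            logger.warning("rejected %s: unparseable IC50 %r", compound_id, ic50_raw)
            continue
        if not ic50 > 0 or not np.isfinite(ic50):
            n_rejected += 1
            logger.warning("rejected %s: non-positive IC50 %r", compound_id, ic50)
            continue
        if Chem.MolFromSmiles(smiles) is None:
            n_rejected += 1
            logger.warning("rejected %s: invalid SMILES %r", compound_id, smiles)
            continue
        records.append(MoleculeRecord(str(compound_id), smiles, ic50))

    logger.info("loaded %d records from %s (%d rejected)", len(records), path, n_rejected)
    if not records:
        raise ValueError(f"zero valid records in {path} ({n_rejected} rejected)")
    return records


def _rows_from_table(path: Path, sep: str) -> list[tuple[str, str, str]]:
    text = path.read_text()
    if not text.strip():
        raise ValueError(f"zero valid records in {path} (empty file)")
    reader = csv.reader(io.StringIO(text), delimiter=sep)
    table = [row for row in reader if row and any(cell.strip() for cell in row)]
    header = [c.strip().lower() for c in table[0]]
    wanted = ["compound_id", "smiles", "ic50_nm"]
    if set(wanted) <= set(header):
        idx = [header.index(c) for c in wanted]
        body = table[1:]
    elif len(table[0]) >= 3:
        # no resolvable header: take the first three columns positionally
        idx = [0, 1, 2]
        body = table
        if _looks_like_header(table[0]):
            body = table[1:]
    else:
        raise ValueError(
            f"cannot resolve columns compound_id,smiles,ic50_nm in {path} "
            f"(header: {table[0]})"
        )
    return [(row[idx[0]].strip(), row[idx[1]].strip(), row[idx[2]].strip()) for row in body]


def _looks_like_header(row: list[str]) -> bool:
    try:
        float(row[2])
        return False
    except (ValueError, IndexError):
        return True


def _rows_from_smi(smi_path: Path, activities: Path) -> list[tuple[str, str, str]]:
    act = pd.read_csv(activities, dtype={"compound_id": str})
    if not {"compound_id", "ic50_nm"} <= set(act.columns):
        raise ValueError(f"activities file {activities} needs columns compound_id,ic50_nm")
    ic50_by_id = act.groupby("compound_id")["ic50_nm"].apply(list).to_dict()
    rows: list[tuple[str, str, str]] = []
    for line in smi_path.read_text().splitlines():
        parts = line.split()
        if len(parts) < 2:
            continue
        smiles, compound_id = parts[0], parts[1]
        for ic50 in ic50_by_id.get(compound_id, []):
            rows.append((compound_id, smiles, str(ic50)))
    return rows


def build_dataset(records: list[MoleculeRecord], cutoff_nm: float) -> ActivityDataset:
    """Label compounds at ``cutoff_nm`` and drop conflicting ones.

    A compound is an inhibitor iff *every* IC50 < cutoff and a non-inhibitor
    iff every IC50 >= cutoff; compounds with measurements on both sides are
    removed and counted in ``n_removed_conflicts``.  A measurement exactly at
    the cutoff counts as inactive (the active rule is a strict ``<``).
    """
    if not records:
        raise ValueError("no records to build a dataset from")
    if not cutoff_nm > 0:
        raise ValueError(f"cutoff_nm must be positive, got {cutoff_nm}")

    by_compound: dict[str, dict] = {}
    for rec in records:
        entry = by_compound.setdefault(
            rec.compound_id, {"smiles": rec.smiles, "ic50s": []}
        )
        entry["ic50s"].append(rec.ic50_nm)

    rows = []
    n_conflicts = 0
    for compound_id, entry in by_compound.items():
        below = any(v < cutoff_nm for v in entry["ic50s"])
        at_or_above = any(v >= cutoff_nm for v in entry["ic50s"])
        if below and at_or_above:
            n_conflicts += 1
            continue
        label = LABEL_ACTIVE if below else LABEL_INACTIVE
        rows.append((compound_id, entry["smiles"], label))

    if not rows:
        raise ValueError("empty dataset after conflict removal")
    frame = pd.DataFrame(rows, columns=["compound_id", "smiles", "label"])
    return ActivityDataset(cutoff_nm=cutoff_nm, compounds=frame,
                           n_removed_conflicts=n_conflicts, split_tag="full")


def train_validation_split(
    ds: ActivityDataset,
    validation_fraction: float = 0.1,
    seed: int = 0,
) -> tuple[ActivityDataset, ActivityDataset]:
    """Stratified random train/validation split (default 90/10).

    Per label class, round(fraction × class size) compounds go to the
    validation set; the split is deterministic given ``seed``.
    """
    if not 0 < validation_fraction < 1:
        raise ValueError(f"validation_fraction must be in (0,1), got {validation_fraction}")
    rng = np.random.default_rng(seed)
    val_idx: list[int] = []
    for label in (LABEL_ACTIVE, LABEL_INACTIVE):
        cls = np.flatnonzero((ds.compounds["label"] == label).values)
        if len(cls) < 2:
            raise ValueError(f"class {label!r} has {len(cls)} compounds; cannot stratify")
        n_val = int(round(validation_fraction * len(cls)))
        n_val = min(max(n_val, 1), len(cls) - 1)  # keep both parts non-empty per class
        val_idx.extend(rng.permutation(cls)[:n_val].tolist())

    mask = np.zeros(len(ds), dtype=bool)
    mask[val_idx] = True
    train = ActivityDataset(
        cutoff_nm=ds.cutoff_nm,
        compounds=ds.compounds.loc[~mask].reset_index(drop=True),
        n_removed_conflicts=ds.n_removed_conflicts,
        split_tag="train",
    )
    validation = ActivityDataset(
        cutoff_nm=ds.cutoff_nm,
        compounds=ds.compounds.loc[mask].reset_index(drop=True),
        n_removed_conflicts=ds.n_removed_conflicts,
        split_tag="validation",
    )
    return train, validation


def assign_class(
    smiles: str, registry: list[ClassDefinition] = DEFAULT_CLASS_REGISTRY
) -> str:
    """Assign a structural class by highest-priority SMARTS match, else "other"."""
    ordered = _validate_registry(registry)
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"invalid SMILES: {smiles!r}")
    for definition in ordered:
        if mol.HasSubstructMatch(definition.pattern()):
            return definition.class_name
    return "other"


def class_subset(
    ds: ActivityDataset,
    class_name: str,
    registry: list[ClassDefinition] = DEFAULT_CLASS_REGISTRY,
) -> ActivityDataset:
    """Restrict ``ds`` to compounds assigned to ``class_name``."""
    keep = ds.compounds["smiles"].map(lambda s: assign_class(s, registry) == class_name)
    if not keep.any():
        raise ValueError(f"class {class_name!r} has no members in this dataset")
    return ActivityDataset(
        cutoff_nm=ds.cutoff_nm,
        compounds=ds.compounds.loc[keep.values].reset_index(drop=True),
        n_removed_conflicts=0,
        split_tag=ds.split_tag,
    )


def leave_class_out(
    ds: ActivityDataset,
    class_name: str,
    registry: list[ClassDefinition] = DEFAULT_CLASS_REGISTRY,
) -> ActivityDataset:
    """Complement of :func:`class_subset`: every compound *not* in the class.

    Postcondition: no compound in the result is assigned to ``class_name``
    (so a model trained on it has never seen that scaffold class).
    """
    drop = ds.compounds["smiles"].map(lambda s: assign_class(s, registry) == class_name)
    if drop.all():
        raise ValueError(f"leaving out class {class_name!r} empties the dataset")
    return ActivityDataset(
        cutoff_nm=ds.cutoff_nm,
        compounds=ds.compounds.loc[~drop.values].reset_index(drop=True),
        n_removed_conflicts=0,
        split_tag=ds.split_tag,
    )
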