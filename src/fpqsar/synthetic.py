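"""Synthetic activity tables and binary fingerprint matrices.

Emulates the statistical structure the pipeline assumes: class-conditional
Bernoulli fingerprint bits with planted discriminative bits (known expected
frequency difference), near-duplicate redundant columns to exercise the
phi filter, the strong class imbalance of a screening dataset
(508 inhibitors vs 2997 non-inhibitors by default over 881 bits), IC50
values consistent with the labels around a stated cutoff (log-uniform within
two decades on each side), and optional conflicting re-measurements.

Real substructure fingerprints carry chemical correlation structure that
independent Bernoulli draws do not reproduce; see docs/methods.md for what
that does and does not let the tests demonstrate.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .datasets import (
    LABEL_ACTIVE,
    LABEL_INACTIVE,
    ActivityDataset,
    MoleculeRecord,
    build_dataset,
)
from .fingerprints import FingerprintMatrix, load_reference_score_table

#: Simple valid scaffolds cycled through for untagged synthetic compounds.
_PLAIN_SMILES = ["CCO", "CCN", "c1ccccc1", "CC(C)O", "CCCC", "c1ccccc1C", "CCOC", "CC(=O)O"]

#: Substituted 1,3-diazines used for synthetic members of the tagged class,
#: so SMARTS-based class assignment works on the synthetic data too.
_CLASS_SMILES = ["c1ccncn1", "Cc1ccncn1", "CCc1ccncn1", "Oc1ccncn1", "Nc1ccncn1"]


@dataclass(frozen=True)
class PlantedBit:
    """A descriptor with distinct set-probabilities per class.

    Expected fingerprint score is 100 * (p_active - p_inactive).
    """

    index: int
    p_active: float
    p_inactive: float


@dataclass
class SyntheticSpec:
    """Parameters of one synthetic dataset.

    Defaults mirror the EGFR10 benchmark scale: 508 inhibitors, 2997
    non-inhibitors, 881 binary descriptors, activity cutoff 10 nM.
    """

    n_active: int = 508
    n_inactive: int = 2997
    n_descriptors: int = 881
    planted_positive: list[PlantedBit] = field(default_factory=list)
    planted_negative: list[PlantedBit] = field(default_factory=list)
    background_p: float = 0.3
    n_redundant_copies: int = 0
    copy_flip_prob: float = 0.05
    cutoff_nm: float = 10.0
    conflict_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_active <= 0 or self.n_inactive <= 0 or self.n_descriptors <= 0:
            raise ValueError("n_active, n_inactive, n_descriptors must be positive")
        if not 0 < self.background_p < 1:
            raise ValueError("background_p must be in (0, 1)")
        if not 0 <= self.copy_flip_prob < 0.5:
            raise ValueError("copy_flip_prob must be in [0, 0.5)")
        if not 0 <= self.conflict_fraction < 1:
            raise ValueError("conflict_fraction must be in [0, 1)")
        idx = [b.index for b in self.planted_positive + self.planted_negative]
        if len(set(idx)) != len(idx):
            raise ValueError("planted bit indices must be unique")
        if idx and (min(idx) < 0 or max(idx) >= self.n_descriptors):
            raise ValueError("planted bit index out of range")
        for bit in self.planted_positive:
            if not bit.p_active > bit.p_inactive:
                raise ValueError(f"positive planted bit {bit.index}: need p_active > p_inactive")
        for bit in self.planted_negative:
            if not bit.p_active < bit.p_inactive:
                raise ValueError(f"negative planted bit {bit.index}: need p_active < p_inactive")
        for bit in self.planted_positive + self.planted_negative:
            for p in (bit.p_active, bit.p_inactive):
                if not 0 < p < 1:
                    raise ValueError("planted probabilities must be in (0, 1)")


def planted_preset(seed: int = 0, n_active: int = 500, n_inactive: int = 500) -> SyntheticSpec:
    """Balanced planted-signal benchmark: 5 positive bits at 0.7/0.4, 5
    negative bits at 0.4/0.7, background 0.3 in both classes."""
    return SyntheticSpec(
        n_active=n_active,
        n_inactive=n_inactive,
        planted_positive=[PlantedBit(i, 0.7, 0.4) for i in range(0, 5)],
        planted_negative=[PlantedBit(i, 0.4, 0.7) for i in range(5, 10)],
        seed=seed,
    )


def egfr10_like_preset(seed: int = 0, scale: float = 1.0) -> SyntheticSpec:
    """Imbalanced benchmark shaped like the EGFR10 study conditions.

    The 20 published best fingerprints are planted at their published percent
    frequencies (so the expected score table reproduces the published
    frequency differences); everything else is background, plus redundant
    near-copies of the planted columns to exercise the phi filter.
    """
    ref = load_reference_score_table()
    planted_pos, planted_neg = [], []
    for name, row in ref.iterrows():
        index = int(name.removeprefix("FP")) - 1
        bit = PlantedBit(index, row["freq_active"] / 100.0, row["freq_inactive"] / 100.0)
        (planted_pos if row["sign"] == "positive" else planted_neg).append(bit)
    return SyntheticSpec(
        n_active=max(int(round(508 * scale)), 10),
        n_inactive=max(int(round(2997 * scale)), 10),
        planted_positive=planted_pos,
        planted_negative=planted_neg,
        n_redundant_copies=5,
        conflict_fraction=0.006,  # ~23 conflicting compounds of ~3528 at full scale
        seed=seed,
    )


def _bit_probabilities(spec: SyntheticSpec) -> tuple[np.ndarray, np.ndarray]:
    p_a = np.full(spec.n_descriptors, spec.background_p)
    p_i = np.full(spec.n_descriptors, spec.background_p)
    for bit in spec.planted_positive + spec.planted_negative:
        p_a[bit.index] = bit.p_active
        p_i[bit.index] = bit.p_inactive
    return p_a, p_i


def _ic50_values(rng, labels: np.ndarray, cutoff: float) -> np.ndarray:
    """Log-uniform IC50 within [cutoff/100, cutoff) for actives and
    [cutoff, cutoff*100] for inactives."""
    lo = np.where(labels == LABEL_ACTIVE, np.log10(cutoff) - 2, np.log10(cutoff))
    hi = np.where(labels == LABEL_ACTIVE, np.log10(cutoff), np.log10(cutoff) + 2)
    u = rng.uniform(size=len(labels))
    vals = 10 ** (lo + u * (hi - lo))
    # keep actives strictly below the cutoff despite float rounding
    vals = np.where(
        (labels == LABEL_ACTIVE) & (vals >= cutoff), np.nextafter(cutoff, 0), vals
    )
    return vals


def generate_records(spec: SyntheticSpec) -> list[MoleculeRecord]:
    """Raw activity measurements, including conflicting extra compounds.

    ``round(conflict_fraction * (n_active + n_inactive))`` additional
    compounds carry one measurement on each side of the cutoff, so
    :func:`fpqsar.datasets.build_dataset` removes exactly those and the
    surviving dataset has the spec's class sizes.
    """
    rng = np.random.default_rng(spec.seed)
    labels = np.array(
        [LABEL_ACTIVE] * spec.n_active + [LABEL_INACTIVE] * spec.n_inactive
    )
    ic50 = _ic50_values(rng, labels, spec.cutoff_nm)
    records = [
        MoleculeRecord(f"SYN{j:05d}", _PLAIN_SMILES[j % len(_PLAIN_SMILES)], float(v))
        for j, v in enumerate(ic50)
    ]
    n_conflict = int(round(spec.conflict_fraction * (spec.n_active + spec.n_inactive)))
    for c in range(n_conflict):
        cid = f"SYNCONF{c:04d}"
        smiles = _PLAIN_SMILES[c % len(_PLAIN_SMILES)]
        below = float(10 ** (np.log10(spec.cutoff_nm) - 2 * rng.uniform()))
        above = float(10 ** (np.log10(spec.cutoff_nm) + 2 * rng.uniform()))
        records.append(MoleculeRecord(cid, smiles, min(below, np.nextafter(spec.cutoff_nm, 0))))
        records.append(MoleculeRecord(cid, smiles, max(above, spec.cutoff_nm)))
    return records


def generate(spec: SyntheticSpec) -> tuple[ActivityDataset, FingerprintMatrix, dict]:
    """Synthesize a labelled dataset, its fingerprint matrix, and a ground-
    truth manifest (planted indices, redundant copies, expected scores).

    Bit-identical for a given spec (all randomness from ``spec.seed``).
    """
    records = generate_records(spec)
    ds = build_dataset(records, spec.cutoff_nm)

    rng = np.random.default_rng(spec.seed + 1)
    labels = ds.labels.to_numpy()
    active = labels == LABEL_ACTIVE
    p_a, p_i = _bit_probabilities(spec)
    prob = np.where(active[:, None], p_a[None, :], p_i[None, :])
    X = (rng.uniform(size=prob.shape) < prob).astype(np.int8)

    names = [f"FP{i + 1}" for i in range(spec.n_descriptors)]
    planted = spec.planted_positive + spec.planted_negative
    copies: dict[str, str] = {}
    if spec.n_redundant_copies:
        extra_cols = []
        for c in range(spec.n_redundant_copies):
            parent = planted[c % len(planted)] if planted else None
            parent_idx = parent.index if parent else c % spec.n_descriptors
            flips = rng.uniform(size=X.shape[0]) < spec.copy_flip_prob
            col = np.where(flips, 1 - X[:, parent_idx], X[:, parent_idx]).astype(np.int8)
            name = f"FPCOPY{c + 1}"
            copies[name] = names[parent_idx]
            extra_cols.append(col)
        X = np.column_stack([X] + extra_cols)
        names = names + list(copies)

    fm = FingerprintMatrix(
        pd.DataFrame(X, index=ds.compound_ids, columns=names).rename_axis("compound_id")
    )
    manifest = {
        "seed": spec.seed,
        "cutoff_nm": spec.cutoff_nm,
        "n_active": ds.n_active,
        "n_inactive": ds.n_inactive,
        "n_removed_conflicts": ds.n_removed_conflicts,
        "background_p": spec.background_p,
        "planted": [
            {
                "descriptor": names[b.index],
                "p_active": b.p_active,
                "p_inactive": b.p_inactive,
                "expected_score": 100.0 * (b.p_active - b.p_inactive),
            }
            for b in planted
        ],
        "redundant_copies": copies,
    }
    return ds, fm, manifest


def make_class_structure(
    spec: SyntheticSpec,
    class_fraction: float,
    class_marker_index: int,
    class_name: str = "pyrimidine",
) -> tuple[ActivityDataset, FingerprintMatrix, dict]:
    """Generate a dataset where a random fraction of compounds belongs to a
    named structural class.

    Class members get a class-bearing SMILES (so SMARTS class assignment
    recovers the tag) and the marker descriptor column set to 1 for every
    member; non-members keep their background draw for that column.  The
    manifest gains ``class_name``, ``class_members`` and ``class_marker``.
    """
    if not 0 < class_fraction < 1:
        raise ValueError("class_fraction must be in (0, 1)")
    ds, fm, manifest = generate(spec)
    if not 0 <= class_marker_index < fm.shape[1]:
        raise ValueError("class_marker_index out of range")

    rng = np.random.default_rng(spec.seed + 2)
    member = rng.uniform(size=len(ds)) < class_fraction
    if not member.any() or member.all():
        raise ValueError("class_fraction produced a degenerate class; adjust fraction or n")

    compounds = ds.compounds.copy()
    compounds.loc[member, "smiles"] = [
        _CLASS_SMILES[j % len(_CLASS_SMILES)] for j in range(int(member.sum()))
    ]
    tagged = ActivityDataset(
        cutoff_nm=ds.cutoff_nm,
        compounds=compounds,
        n_removed_conflicts=ds.n_removed_conflicts,
        split_tag=ds.split_tag,
    )
    values = fm.values.copy()
    marker = values.columns[class_marker_index]
    values.loc[member, marker] = 1
    manifest = dict(manifest)
    manifest.update(
        {
            "class_name": class_name,
            "class_marker": marker,
            "class_members": compounds.loc[member, "compound_id"].tolist(),
        }
    )
    return tagged, FingerprintMatrix(values), manifest


def write_outputs(
    ds: ActivityDataset, fm: FingerprintMatrix, manifest: dict, out_dir: str | Path
) -> None:
    """Write the formats the rest of the package reads: activity CSV with
    IC50s regenerated from the manifest seed, PaDEL-dialect fingerprint CSV,
    labelled dataset CSV and ground_truth.json."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ds.to_csv(out / "dataset.csv")
    fm.to_padel_csv(out / "fingerprints.csv")
    (out / "ground_truth.json").write_text(json.dumps(manifest, indent=2) + "\n")


def activity_table_csv(spec: SyntheticSpec, path: str | Path) -> None:
    """Write the raw (pre-thresholding) activity table, conflicts included."""
    records = generate_records(spec)
    frame = pd.DataFrame(
        [(r.compound_id, r.smiles, r.ic50_nm) for r in records],
        columns=["compound_id", "smiles", "ic50_nm"],
    )
    frame.to_csv(path, index=False)
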