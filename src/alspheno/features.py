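"""Assembly of the per-subject 121-feature table and subset slicing.

The table concatenates the four feature blocks of each subject in the
fixed schema order (connectome graph metrics, CST DTI metrics, FD/BPF
morphometry, demographics + clinical scores), carries the phenotype
label (0-4) and a missing-value mask, and supports the study's feature
subsets: all features, WM-only (101), GM-only (10),
clinical/demographic (10), and the three published WEKA selections.

Missing values (truncated CST tracts) are imputed with the column mean
of the full dataset, reproducing the study's stated procedure; a
leakage-free per-training-fold variant is available in the
cross-validation stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import schema
from .cohort import CohortBundle, PhenotypeLabel

__all__ = [
    "FeatureTable",
    "assemble_feature_table",
    "impute_missing_with_mean",
    "subset_features",
    "write_feature_csv",
    "read_feature_csv",
    "write_feature_arff",
    "read_feature_arff",
]

SELECTORS = ("all", "wm", "gm", "clinical_demographic",
             "table2", "table3", "table4", "custom")


@dataclass
class FeatureTable:
    """Subjects x features matrix aligned to a (sub)schema, plus labels."""

    data: pd.DataFrame  # float matrix, index = subject IDs
    labels: pd.Series  # int codes 0-4, same index
    feature_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.feature_names:
            self.feature_names = list(self.data.columns)
        if list(self.data.columns) != self.feature_names:
            raise ValueError("data columns must match feature_names")
        if not self.data.index.equals(self.labels.index):
            raise ValueError("labels index must match data index")
        bad = set(self.labels.unique()) - {0, 1, 2, 3, 4}
        if bad:
            raise ValueError(f"labels outside 0..4: {sorted(bad)}")

    @property
    def n_subjects(self) -> int:
        return len(self.data)

    @property
    def missing_mask(self) -> pd.DataFrame:
        return self.data.isna()

    @property
    def X(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def y(self) -> np.ndarray:
        return self.labels.to_numpy(dtype=int)

    def filter_classes(self, classes: list[int]) -> "FeatureTable":
        keep = self.labels.isin(classes)
        return FeatureTable(self.data.loc[keep].copy(),
                            self.labels.loc[keep].copy())

    def equals(self, other: "FeatureTable") -> bool:
        return (self.feature_names == other.feature_names
                and self.labels.equals(other.labels)
                and np.allclose(self.data.to_numpy(), other.data.to_numpy(),
                                equal_nan=True))


def assemble_feature_table(bundle: CohortBundle) -> FeatureTable:
    """Concatenate each subject's blocks into schema order.

    Gender is encoded 0/1; missing CST entries remain NaN (flagged via
    ``missing_mask``) until imputation.
    """
    rows = []
    ids = []
    labels = []
    for rec in bundle.records:
        merged: dict[str, float] = {}
        for block in (rec.graph_block, rec.cst_block,
                      rec.fd_block, rec.clinical_block):
            merged.update(block)
        unknown = set(merged) - set(schema.FEATURE_NAMES)
        if unknown:
            raise ValueError(f"unknown feature name(s): {sorted(unknown)}")
        missing = set(schema.FEATURE_NAMES) - set(merged)
        if missing:
            raise ValueError(f"subject {rec.subject_id} lacks: {sorted(missing)}")
        rows.append([merged[n] for n in schema.FEATURE_NAMES])
        ids.append(rec.subject_id)
        labels.append(rec.label.code)
    data = pd.DataFrame(rows, index=ids, columns=schema.FEATURE_NAMES,
                        dtype=float)
    data.index.name = "subject_id"
    return FeatureTable(data, pd.Series(labels, index=data.index, name="label"))


def impute_missing_with_mean(t: FeatureTable) -> FeatureTable:
    """Replace every missing cell by its column mean over observed cells.

    The mean is taken over the *full* table (the study's procedure);
    see :func:`alspheno.classify.cross_validate` for the per-fold
    leakage-free variant.  Idempotent; errors on a fully missing column.
    """
    fully_missing = t.data.columns[t.data.isna().all()]
    if len(fully_missing):
        raise ValueError(f"fully missing column(s): {list(fully_missing)}")
    if not t.data.isna().any().any():
        return t
    data = t.data.fillna(t.data.mean())
    return FeatureTable(data, t.labels.copy())


def subset_features(t: FeatureTable, selector: str,
                    custom: list[str] | None = None) -> FeatureTable:
    """Column-slice the table to a named feature subset, preserving order."""
    if selector not in SELECTORS:
        raise ValueError(f"unknown selector {selector!r}")
    if selector == "all":
        names = t.feature_names
    elif selector == "wm":
        names = [n for n in t.feature_names if n in set(schema.WM_FEATURES)]
    elif selector == "gm":
        names = [n for n in t.feature_names if n in set(schema.GM_FEATURES)]
    elif selector == "clinical_demographic":
        names = [n for n in t.feature_names
                 if n in set(schema.CLINICAL_DEMOGRAPHIC_FEATURES)]
    elif selector == "custom":
        if custom is None:
            raise ValueError("custom selector requires a feature list")
        unknown = [n for n in custom if n not in t.feature_names]
        if unknown:
            raise ValueError(f"custom name(s) not in schema: {unknown}")
        names = [n for n in t.feature_names if n in set(custom)]
    else:
        sel = set(schema.WEKA_SELECTIONS[selector])
        names = [n for n in t.feature_names if n in sel]
    return FeatureTable(t.data[names].copy(), t.labels.copy())


# ---------------------------------------------------------------------------
# CSV / ARFF round-trip
# ---------------------------------------------------------------------------

def write_feature_csv(t: FeatureTable, path: str | Path) -> Path:
    out = t.data.copy()
    out["label"] = t.labels
    out.to_csv(path)
    return Path(path)


def read_feature_csv(path: str | Path) -> FeatureTable:
    df = pd.read_csv(path, index_col=0)
    if "label" not in df.columns:
        raise ValueError(f"{path}: no 'label' column")
    labels = df.pop("label").astype(int)
    labels.name = "label"
    return FeatureTable(df.astype(float), labels)


def write_feature_arff(t: FeatureTable, path: str | Path,
                       relation: str = "als_phenotypes") -> Path:
    """ARFF export: numeric attributes plus a 5-value nominal class."""
    lines = [f"@RELATION {relation}", ""]
    for name in t.feature_names:
        quoted = f"'{name}'" if any(c in name for c in " ,%") else name
        lines.append(f"@ATTRIBUTE {quoted} NUMERIC")
    lines.append("@ATTRIBUTE class {0,1,2,3,4}")
    lines.append("")
    lines.append("@DATA")
    for sid, row in t.data.iterrows():
        vals = ["?" if pd.isna(v) else repr(float(v)) for v in row]
        vals.append(str(int(t.labels.loc[sid])))
        lines.append(",".join(vals))
    Path(path).write_text("\n".join(lines) + "\n")
    return Path(path)


def read_feature_arff(path: str | Path) -> FeatureTable:
    names: list[str] = []
    rows: list[list[float]] = []
    labels: list[int] = []
    in_data = False
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line or line.startswith("%"):
            continue
        low = line.lower()
        if low.startswith("@attribute"):
            rest = line.split(None, 1)[1]
            if rest.startswith("'"):
                name = rest[1:rest.index("'", 1)]
            else:
                name = rest.split()[0]
            if name != "class":
                names.append(name)
        elif low.startswith("@data"):
            in_data = True
        elif in_data:
            parts = line.split(",")
            rows.append([np.nan if p.strip() == "?" else float(p)
                         for p in parts[:-1]])
            labels.append(int(parts[-1]))
    ids = [f"S{i:03d}" for i in range(len(rows))]
    data = pd.DataFrame(rows, index=ids, columns=names, dtype=float)
    data.index.name = "subject_id"
    return FeatureTable(data, pd.Series(labels, index=data.index, name="label"))
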