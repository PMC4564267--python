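"""Reading and writing of expression matrices, probe annotations, manifests and gene sets.

All tabular inputs are plain TSV: expression matrices carry a header row of
sample identifiers with the feature identifier in the first column; probe
annotations are two-column (probe_id, gene_symbol); gene sets follow the GMT
convention.  The study manifest is a YAML document listing, per study, the
disease, the file paths and the case/control sample identifiers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

CASE = "case"
CONTROL = "control"


@dataclass
class ExpressionDataset:
    """One study's feature x sample log-expression matrix with group labels.

    ``values`` is a features x samples DataFrame (index = probe or gene
    identifiers, columns = sample identifiers); ``groups`` maps every sample
    to ``"case"`` or ``"control"``.
    """

    study_id: str
    disease: str
    values: pd.DataFrame
    groups: pd.Series

    def __post_init__(self) -> None:
        self.groups = pd.Series(self.groups)
        if list(self.groups.index) != list(self.values.columns):
            raise ValueError(
                f"{self.study_id}: group labels do not cover the sample columns"
            )
        bad = set(self.groups.unique()) - {CASE, CONTROL}
        if bad:
            raise ValueError(f"{self.study_id}: unknown group labels {sorted(bad)}")
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique()
            raise ValueError(
                f"{self.study_id}: duplicate feature identifiers: {list(dups[:5])}"
            )

    @property
    def features(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    @property
    def case_ids(self) -> list[str]:
        return list(self.groups.index[self.groups == CASE])

    @property
    def control_ids(self) -> list[str]:
        return list(self.groups.index[self.groups == CONTROL])

    def subset_features(self, features: Sequence[str]) -> "ExpressionDataset":
        return ExpressionDataset(
            self.study_id, self.disease, self.values.loc[list(features)], self.groups
        )

    def to_tsv(self, path: str | Path) -> None:
        out = self.values.copy()
        out.index.name = "feature_id"
        out.to_csv(path, sep="\t")


@dataclass
class StudyEntry:
    study_id: str
    disease: str
    expression_path: Path
    annotation_path: Path | None
    case_ids: list[str]
    control_ids: list[str]
    already_log: bool = True

    def __post_init__(self) -> None:
        if not self.case_ids or not self.control_ids:
            raise ValueError(f"{self.study_id}: case and control lists must be non-empty")
        overlap = set(self.case_ids) & set(self.control_ids)
        if overlap:
            raise ValueError(
                f"{self.study_id}: samples in both groups: {sorted(overlap)[:5]}"
            )


@dataclass
class StudyManifest:
    entries: list[StudyEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [e.study_id for e in self.entries]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate study_id values in manifest")

    @property
    def study_ids(self) -> list[str]:
        return [e.study_id for e in self.entries]

    @property
    def study_to_disease(self) -> dict[str, str]:
        return {e.study_id: e.disease for e in self.entries}

    @property
    def diseases(self) -> list[str]:
        seen: dict[str, None] = {}
        for e in self.entries:
            seen.setdefault(e.disease, None)
        return list(seen)


@dataclass
class GeneSet:
    name: str
    description: str
    genes: list[str]


def load_manifest(path: str | Path) -> StudyManifest:
    """Load a YAML study manifest; relative paths resolve against its directory."""
    path = Path(path)
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or "studies" not in doc:
        raise ValueError(f"{path}: manifest must contain a top-level 'studies' list")
    base = path.parent
    entries = []
    for block in doc["studies"]:
        ann = block.get("annotation")
        entries.append(
            StudyEntry(
                study_id=str(block["study_id"]),
                disease=str(block["disease"]),
                expression_path=base / block["expression"],
                annotation_path=(base / ann) if ann else None,
                case_ids=[str(s) for s in block["cases"]],
                control_ids=[str(s) for s in block["controls"]],
                already_log=bool(block.get("already_log", True)),
            )
        )
    return StudyManifest(entries)


def load_expression_matrix(
    path: str | Path,
    case_ids: Sequence[str],
    control_ids: Sequence[str],
    study_id: str = "",
    disease: str = "",
) -> ExpressionDataset:
    """Read a TSV expression matrix restricted to the requested samples.

    Samples are returned in manifest order (cases first, then controls).
    Missing samples, non-numeric or empty cells and duplicate feature
    identifiers are hard errors.
    """
    path = Path(path)
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    raw.index = raw.index.astype(str)
    if raw.index.has_duplicates:
        dups = raw.index[raw.index.duplicated()].unique()
        raise ValueError(f"{path}: duplicate feature identifiers: {list(dups[:5])}")
    wanted = list(case_ids) + list(control_ids)
    missing = [s for s in wanted if s not in raw.columns]
    if missing:
        raise ValueError(f"{path}: sample(s) not found in header: {missing}")
    sub = raw[wanted]
    values = pd.DataFrame(index=sub.index, columns=sub.columns, dtype=float)
    for col in sub.columns:
        stripped = sub[col].str.strip()
        converted = pd.to_numeric(stripped, errors="coerce")
        bad = converted.index[converted.isna()]
        if len(bad):
            raise ValueError(
                f"{path}: non-numeric or missing value at feature "
                f"{bad[0]!r}, sample {col!r}"
            )
        # astype(float) is correctly rounded (full printed precision),
        # unlike the fast to_numeric parser
        values[col] = stripped.astype(float)
    groups = pd.Series(
        [CASE] * len(case_ids) + [CONTROL] * len(control_ids), index=wanted
    )
    return ExpressionDataset(study_id or path.stem, disease, values, groups)


def load_probe_map(path: str | Path) -> pd.DataFrame:
    """Read a two-column (probe_id, gene_symbol) TSV.

    Gene symbols are upper-cased; an empty symbol marks an unannotated probe.
    """
    path = Path(path)
    df = pd.read_csv(
        path, sep="\t", dtype=str, keep_default_na=False,
        names=["probe_id", "gene_symbol"], header=None, skiprows=_has_header(path),
    )
    df["probe_id"] = df["probe_id"].astype(str)
    df["gene_symbol"] = df["gene_symbol"].str.strip().str.upper()
    if df["probe_id"].duplicated().any():
        dups = df.loc[df["probe_id"].duplicated(), "probe_id"].unique()
        raise ValueError(f"{path}: duplicate probe identifiers: {list(dups[:5])}")
    return df


def _has_header(path: Path) -> int:
    with open(path) as fh:
        first = fh.readline()
    return 1 if first.lower().startswith("probe_id") else 0


def load_gene_sets(path: str | Path) -> list[GeneSet]:
    """Read a GMT gene-set file: name, description, then member symbols.

    Members are upper-cased and de-duplicated preserving first occurrence;
    sets are returned in file order.
    """
    sets: list[GeneSet] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}: line {lineno}: expected >=3 tab-separated fields"
                )
            seen: dict[str, None] = {}
            for g in fields[2:]:
                g = g.strip().upper()
                if g:
                    seen.setdefault(g, None)
            sets.append(GeneSet(fields[0], fields[1], list(seen)))
    return sets


def write_probe_map(probe_map: pd.DataFrame, path: str | Path) -> None:
    probe_map.to_csv(path, sep="\t", index=False)


def write_manifest(manifest: StudyManifest, path: str | Path) -> None:
    path = Path(path)
    base = path.parent

    def rel(p: Path | None) -> str | None:
        if p is None:
            return None
        try:
            return str(Path(p).relative_to(base))
        except ValueError:
            return str(p)

    doc = {
        "studies": [
            {
                "study_id": e.study_id,
                "disease": e.disease,
                "expression": rel(e.expression_path),
                "annotation": rel(e.annotation_path),
                "cases": list(e.case_ids),
                "controls": list(e.control_ids),
                "already_log": e.already_log,
            }
            for e in manifest.entries
        ]
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
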