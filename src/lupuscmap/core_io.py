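"""Data model and readers/writers for the pipeline's on-disk formats.

Canonical formats are all plain text: GCT 1.2 for expression matrices and
drug-profile statistics, GMT for gene sets and signatures, TSV for clinical
tables, annotations and score matrices, JSON for fitted models and
manifests.  Gene and sample identifiers are opaque strings; no probe/symbol
mapping happens here.  Expression values are assumed to be on the log2
scale throughout the package.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

VALID_ROLES = frozenset({"case", "control"})

CLINICAL_COLUMNS = (
    "patient_id",
    "visit_index",
    "sledai",
    "neut_pct",
    "lymph_pct",
    "nephritis",
    "cohort_id",
)


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen = pd.Index(ids)
    if seen.has_duplicates:
        dupes = sorted(seen[seen.duplicated()].unique())
        raise FormatError(f"duplicate {what} ids: {dupes[:10]}")


@dataclass
class ExpressionMatrix:
    """Genes x samples numeric table (log2 scale) with case/control roles.

    ``values`` is indexed by gene id with one column per sample id;
    ``sample_role`` maps every sample id to ``"case"`` or ``"control"``.
    """

    values: pd.DataFrame
    sample_role: Mapping[str, str]

    def __post_init__(self) -> None:
        _check_unique(list(self.values.index), "gene")
        _check_unique(list(self.values.columns), "sample")
        arr = self.values.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise FormatError("expression values must be numeric")
        if not np.all(np.isfinite(arr)):
            raise ValidationError("expression values must be finite")
        missing = set(self.values.columns) - set(self.sample_role)
        if missing:
            raise ValidationError(f"samples without a role: {sorted(missing)[:10]}")
        bad = {s: r for s, r in self.sample_role.items() if r not in VALID_ROLES}
        if bad:
            raise ValidationError(f"unknown role tokens: {bad}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def case_ids(self) -> list[str]:
        return [s for s in self.values.columns if self.sample_role[s] == "case"]

    @property
    def control_ids(self) -> list[str]:
        return [s for s in self.values.columns if self.sample_role[s] == "control"]


@dataclass
class GeneSignature:
    """A disease signature: ordered up- and down-regulated gene sets."""

    up: list[str]
    down: list[str]
    origin: str = ""

    def __post_init__(self) -> None:
        overlap = set(self.up) & set(self.down)
        if overlap:
            raise ValidationError(
                f"signature up/down sets overlap: {sorted(overlap)[:10]}"
            )
        _check_unique(self.up, "signature up gene")
        _check_unique(self.down, "signature down gene")


@dataclass
class RankedProfile:
    """A drug's full gene ranking, most up- to most down-regulated.

    ``genes`` is a permutation of the library universe; ``stats`` holds the
    per-gene differential statistic in ranking order (non-increasing).
    """

    genes: list[str]
    stats: np.ndarray

    def __post_init__(self) -> None:
        self.stats = np.asarray(self.stats, dtype=float)
        if len(self.genes) != len(self.stats):
            raise ValidationError("ranking and statistic lengths differ")
        if np.any(np.diff(self.stats) > 1e-9):
            raise ValidationError("profile statistic must be non-increasing")


@dataclass
class DrugLibrary:
    """Reference library of drug perturbation profiles plus annotations.

    ``profiles`` maps drug id to a :class:`RankedProfile` over a shared gene
    universe.  ``moa`` and ``targets`` are binary drugs x annotation tables
    (0/1 entries, drug ids on the index).
    """

    gene_ids: list[str]
    profiles: dict[str, RankedProfile]
    moa: pd.DataFrame = field(default_factory=pd.DataFrame)
    targets: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        universe = set(self.gene_ids)
        _check_unique(self.gene_ids, "gene")
        for drug, prof in self.profiles.items():
            if set(prof.genes) != universe or len(prof.genes) != len(self.gene_ids):
                raise ValidationError(f"profile for {drug!r} is not a permutation of the universe")
        for name, table in (("moa", self.moa), ("targets", self.targets)):
            if table.size and not table.isin([0, 1]).all().all():
                raise ValidationError(f"{name} table must be binary")

    @property
    def drug_ids(self) -> list[str]:
        return list(self.profiles)


@dataclass
class ClinicalTable:
    """Longitudinal clinical visits, sorted by (patient_id, visit_index)."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = set(CLINICAL_COLUMNS) - set(self.data.columns)
        if missing:
            raise FormatError(f"clinical table missing columns: {sorted(missing)}")
        df = self.data.loc[:, list(CLINICAL_COLUMNS)].copy()
        df["visit_index"] = df["visit_index"].astype(int)
        if (df["visit_index"] < 1).any():
            raise ValidationError("visit_index must be >= 1")
        dup = df.duplicated(subset=["patient_id", "visit_index"])
        if dup.any():
            pairs = df.loc[dup, ["patient_id", "visit_index"]].to_records(index=False)
            raise ValidationError(f"duplicated (patient, visit) pairs: {list(pairs)[:10]}")
        for col in ("sledai", "neut_pct", "lymph_pct"):
            vals = df[col].to_numpy(dtype=float)
            if not np.all(np.isfinite(vals)):
                raise ValidationError(f"non-finite values in column {col}")
        if (df["sledai"] < 0).any():
            raise ValidationError("sledai must be non-negative")
        for col in ("neut_pct", "lymph_pct"):
            if ((df[col] < 0) | (df[col] > 100)).any():
                raise ValidationError(f"{col} must lie in [0, 100]")
        over = df["neut_pct"] + df["lymph_pct"] > 100
        if over.any():
            rows = df.loc[over, ["patient_id", "visit_index"]].to_records(index=False)
            raise ValidationError(
                f"neut_pct + lymph_pct > 100 for rows: {list(rows)[:10]}"
            )
        if not df["nephritis"].isin([0, 1]).all():
            raise ValidationError("nephritis must be 0/1")
        self.data = df.sort_values(["patient_id", "visit_index"]).reset_index(drop=True)

    @property
    def patient_ids(self) -> list[str]:
        return list(dict.fromkeys(self.data["patient_id"]))


@dataclass
class GeneSet:
    name: str
    description: str
    genes: list[str]


# ---------------------------------------------------------------------------
# GCT 1.2


def write_gct(values: pd.DataFrame, path: str | Path) -> None:
    """Write a genes x samples table as GCT 1.2 text."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("#1.2\n")
        fh.write(f"{values.shape[0]}\t{values.shape[1]}\n")
        fh.write("NAME\tDescription\t" + "\t".join(map(str, values.columns)) + "\n")
        for gene, row in values.iterrows():
            cells = "\t".join(repr(float(v)) for v in row)
            fh.write(f"{gene}\tna\t{cells}\n")


def read_gct(path: str | Path) -> pd.DataFrame:
    """Parse GCT 1.2 text (or a plain TSV with a header row) into a DataFrame."""
    path = Path(path)
    with path.open("r", encoding="utf-8") as fh:
        first = fh.readline().rstrip("\n")
        if first.startswith("#1."):
            dims = fh.readline().rstrip("\n").split("\t")
            try:
                n_genes, n_samples = int(dims[0]), int(dims[1])
            except (IndexError, ValueError) as exc:
                raise FormatError(f"{path}: line 2: bad GCT dimension line {dims!r}") from exc
            header = fh.readline().rstrip("\n").split("\t")
            if len(header) < 3 or header[0] != "NAME":
                raise FormatError(f"{path}: line 3: bad GCT header {header[:3]!r}")
            samples = header[2:]
            if len(samples) != n_samples:
                raise FormatError(
                    f"{path}: line 3: header declares {n_samples} samples, found {len(samples)}"
                )
            genes, rows = [], []
            for lineno, line in enumerate(fh, start=4):
                parts = line.rstrip("\n").split("\t")
                if len(parts) != 2 + n_samples:
                    raise FormatError(
                        f"{path}: line {lineno}: expected {2 + n_samples} fields, found {len(parts)}"
                    )
                genes.append(parts[0])
                try:
                    rows.append([float(v) for v in parts[2:]])
                except ValueError as exc:
                    raise FormatError(f"{path}: line {lineno}: non-numeric cell") from exc
            if len(genes) != n_genes:
                raise FormatError(
                    f"{path}: body has {len(genes)} rows but header declares {n_genes}"
                )
            df = pd.DataFrame(rows, index=genes, columns=samples)
        else:
            try:
                df = pd.read_csv(path, sep="\t", index_col=0)
            except ValueError as exc:
                raise FormatError(f"{path}: could not parse as TSV: {exc}") from exc
            if not all(np.issubdtype(d, np.number) for d in df.dtypes):
                raise FormatError(f"{path}: non-numeric cell in TSV body")
            df.index = df.index.map(str)
    _check_unique(list(df.index), "gene")
    _check_unique(list(df.columns), "sample")
    return df


def read_expression(path: str | Path, role_path: str | Path) -> ExpressionMatrix:
    """Read a GCT/TSV expression matrix and attach sample roles.

    ``role_path`` is a two-column TSV (sample_id, role) with role tokens
    ``case`` or ``control``.
    """
    values = read_gct(path)
    roles: dict[str, str] = {}
    with Path(role_path).open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise FormatError(f"{role_path}: line {lineno}: expected 2 fields")
            sample, role = parts
            if sample == "sample_id" and role == "role":
                continue  # optional header
            if role not in VALID_ROLES:
                raise ValidationError(
                    f"{role_path}: line {lineno}: unknown role token {role!r}"
                )
            roles[sample] = role
    return ExpressionMatrix(values=values, sample_role=roles)


def write_expression(
    em: ExpressionMatrix, path: str | Path, role_path: str | Path | None = None
) -> None:
    write_gct(em.values, path)
    if role_path is not None:
        with Path(role_path).open("w", encoding="utf-8") as fh:
            for sample in em.sample_ids:
                fh.write(f"{sample}\t{em.sample_role[sample]}\n")


# ---------------------------------------------------------------------------
# GMT


def read_gmt(path: str | Path) -> list[GeneSet]:
    sets: list[GeneSet] = []
    with Path(path).open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}: line {lineno}: GMT line has < 3 fields")
            sets.append(GeneSet(name=parts[0], description=parts[1], genes=parts[2:]))
    return sets


def write_gmt(sets: Iterable[GeneSet], path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        for gs in sets:
            fh.write("\t".join([gs.name, gs.description or "na", *gs.genes]) + "\n")


def signatures_to_gmt(signatures: Iterable[GeneSignature], path: str | Path) -> None:
    """Serialize signatures as paired ``<origin>_UP`` / ``<origin>_DN`` sets."""
    sets = []
    for sig in signatures:
        sets.append(GeneSet(f"{sig.origin}_UP", "na", list(sig.up)))
        sets.append(GeneSet(f"{sig.origin}_DN", "na", list(sig.down)))
    write_gmt(sets, path)


def gmt_to_signatures(path: str | Path) -> list[GeneSignature]:
    sets = {gs.name: gs for gs in read_gmt(path)}
    out = []
    for name, gs in sets.items():
        if not name.endswith("_UP"):
            continue
        origin = name[: -len("_UP")]
        dn = sets.get(f"{origin}_DN")
        if dn is None:
            raise FormatError(f"{path}: set {name!r} has no matching {origin}_DN")
        out.append(GeneSignature(up=list(gs.genes), down=list(dn.genes), origin=origin))
    return out


# ---------------------------------------------------------------------------
# Clinical TSV


def read_clinical(path: str | Path) -> ClinicalTable:
    try:
        df = pd.read_csv(path, sep="\t", dtype={"patient_id": str, "cohort_id": str})
    except ValueError as exc:
        raise FormatError(f"{path}: could not parse clinical TSV: {exc}") from exc
    return ClinicalTable(df)


def write_clinical(table: ClinicalTable, path: str | Path) -> None:
    table.data.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Score matrices and binary annotation tables (plain TSV)


def read_matrix_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.map(str)
    return df


def write_matrix_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t")


def write_json(obj: object, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def read_json(path: str | Path) -> object:
    return json.loads(Path(path).read_text())
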