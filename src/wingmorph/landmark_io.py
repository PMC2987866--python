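"""Reading, writing and validating 2-D landmark datasets.

Two on-disk dialects are supported: the community-standard TPS record format
(``LM=``, ``ID=``, ``IMAGE=``, ``SCALE=`` lines) and plain coordinate tables
(CSV/TSV) in a *wide* (one specimen per row, ``x1,y1,...,xk,yk``) or *long*
(one landmark per row) layout.  Both carry the metadata the downstream
repeatability and classification stages need: species label for reference
specimens, user id, replicate id, an optional pixel-to-length scale, and
free-form extras (sex, locality, date).

Landmark order is positional: landmark *i* is assumed homologous across all
specimens of a dataset.  Missing landmarks are not supported.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import DatasetConsistencyError, ParseError

__all__ = [
    "LandmarkConfiguration",
    "LandmarkDataset",
    "ValidationReport",
    "read_tps",
    "write_tps",
    "read_table",
    "write_table",
    "validate_dataset",
    "merge_datasets",
]

# Metadata columns recognised in coordinate tables (case-insensitive).
_ID_COLUMNS = ("specimen", "specimen_id", "id")
_META_COLUMNS = {
    "species": "species",
    "user": "user_id",
    "user_id": "user_id",
    "replicate": "replicate_id",
    "replicate_id": "replicate_id",
    "individual": "individual_id",
    "individual_id": "individual_id",
    "scale": "scale_factor",
    "scale_factor": "scale_factor",
}


@dataclass
class LandmarkConfiguration:
    """One specimen's ordered 2-D landmark set plus its metadata.

    Coordinates are in pixel units (x rightward, y upward, origin arbitrary —
    superimposition removes position, scale and orientation, so the
    digitizer's frame is preserved untouched).  ``scale_factor`` is the
    optional length-per-pixel conversion; ``individual_id`` identifies the
    biological individual when the same specimen is digitized repeatedly
    (it defaults to ``specimen_id``).
    """

    specimen_id: str
    coords: np.ndarray
    scale_factor: float | None = None
    species: str | None = None
    user_id: str | None = None
    replicate_id: str | None = None
    individual_id: str | None = None
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 2:
            raise ValueError(
                f"coords of {self.specimen_id!r} must be (k, 2), got {self.coords.shape}"
            )
        if self.coords.shape[0] < 3:
            raise ValueError(
                f"configuration {self.specimen_id!r} has k={self.coords.shape[0]} < 3 landmarks"
            )
        if not np.all(np.isfinite(self.coords)):
            raise ValueError(f"configuration {self.specimen_id!r} has non-finite coordinates")
        if self.scale_factor is not None and self.scale_factor <= 0:
            raise ValueError(f"scale_factor of {self.specimen_id!r} must be positive")
        if self.individual_id is None:
            self.individual_id = self.specimen_id

    @property
    def k(self) -> int:
        return self.coords.shape[0]

    @property
    def centroid(self) -> np.ndarray:
        return self.coords.mean(axis=0)

    def with_coords(self, coords: np.ndarray, **changes) -> "LandmarkConfiguration":
        """Copy of this configuration with new coordinates (and field changes)."""
        return replace(self, coords=np.array(coords, dtype=float), extra=dict(self.extra), **changes)

    def __eq__(self, other) -> bool:  # coords need array comparison
        if not isinstance(other, LandmarkConfiguration):
            return NotImplemented
        return (
            self.specimen_id == other.specimen_id
            and np.array_equal(self.coords, other.coords)
            and self.scale_factor == other.scale_factor
            and self.species == other.species
            and self.user_id == other.user_id
            and self.replicate_id == other.replicate_id
            and self.individual_id == other.individual_id
            and self.extra == other.extra
        )


class LandmarkDataset:
    """An ordered collection of configurations sharing landmark count/order.

    Invariants enforced at construction: non-empty, uniform k, unique
    specimen ids.  The subset of configurations carrying a species label
    forms the reference partition.
    """

    def __init__(
        self,
        configurations: Sequence[LandmarkConfiguration],
        provenance: str = "",
    ) -> None:
        configurations = list(configurations)
        if not configurations:
            raise DatasetConsistencyError("dataset must contain at least one configuration")
        ks = {c.k for c in configurations}
        if len(ks) > 1:
            raise DatasetConsistencyError(f"mixed landmark counts within one dataset: {sorted(ks)}")
        seen: set[str] = set()
        for c in configurations:
            if c.specimen_id in seen:
                raise DatasetConsistencyError(f"duplicate specimen_id {c.specimen_id!r}")
            seen.add(c.specimen_id)
        self.configurations = configurations
        self.landmark_count = configurations[0].k
        self.provenance = provenance

    # -- container protocol -------------------------------------------------
    def __len__(self) -> int:
        return len(self.configurations)

    def __iter__(self) -> Iterator[LandmarkConfiguration]:
        return iter(self.configurations)

    def __getitem__(self, i):
        return self.configurations[i]

    def __eq__(self, other) -> bool:
        if not isinstance(other, LandmarkDataset):
            return NotImplemented
        return self.configurations == other.configurations

    # -- convenience accessors ----------------------------------------------
    @property
    def specimen_ids(self) -> list[str]:
        return [c.specimen_id for c in self.configurations]

    @property
    def species_labels(self) -> list[str | None]:
        return [c.species for c in self.configurations]

    def coords_array(self) -> np.ndarray:
        """All coordinates stacked as an (n, k, 2) array."""
        return np.stack([c.coords for c in self.configurations])

    def subset(self, ids: Iterable[str]) -> "LandmarkDataset":
        wanted = set(ids)
        return LandmarkDataset(
            [c for c in self.configurations if c.specimen_id in wanted],
            provenance=self.provenance,
        )

    def references(self) -> "LandmarkDataset":
        """Configurations carrying a species label (the reference partition)."""
        labeled = [c for c in self.configurations if c.species is not None]
        if not labeled:
            raise DatasetConsistencyError("dataset has no species-labeled configurations")
        return LandmarkDataset(labeled, provenance=self.provenance)

    def by_species(self) -> dict[str, "LandmarkDataset"]:
        groups: dict[str, list[LandmarkConfiguration]] = {}
        for c in self.configurations:
            if c.species is not None:
                groups.setdefault(c.species, []).append(c)
        return {s: LandmarkDataset(cfgs, provenance=self.provenance) for s, cfgs in groups.items()}


@dataclass
class ValidationReport:
    """Outcome of dataset validation: empty ``violations`` means valid."""

    violations: list[tuple[str, str]] = field(default_factory=list)
    warnings: list[tuple[str, str]] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations

    def __str__(self) -> str:
        lines = [f"VIOLATION [{kind}] {msg}" for kind, msg in self.violations]
        lines += [f"warning [{kind}] {msg}" for kind, msg in self.warnings]
        return "\n".join(lines) if lines else "dataset valid"


# ---------------------------------------------------------------------------
# TPS format
# ---------------------------------------------------------------------------

_KEYVAL_RE = re.compile(r"^\s*([A-Za-z_]+)\s*=\s*(.*?)\s*$")


def _split_coords(line: str) -> list[str]:
    return [tok for tok in re.split(r"[,\s]+", line.strip()) if tok]


def read_tps(path: str | Path) -> LandmarkDataset:
    """Read a TPS landmark file.

    Accepts ``LM=`` or ``lm=`` record headers, Windows or Unix line endings,
    and comma or whitespace coordinate separators.  ``SCALE=`` populates the
    scale factor; specimen id comes from ``ID=``, falling back to the
    ``IMAGE=`` basename, else the running record index.  Unrecognised
    ``KEY=value`` lines are preserved in ``extra``.
    """
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    lines = text.replace("\r\n", "\n").replace("\r", "\n").split("\n")

    configs: list[LandmarkConfiguration] = []
    i = 0
    record_index = 0
    while i < len(lines):
        line = lines[i].strip()
        if not line:
            i += 1
            continue
        m = _KEYVAL_RE.match(line)
        if not m or m.group(1).upper() != "LM":
            raise ParseError(f"{path.name}:{i + 1}: expected an LM= record header, got {line!r}")
        try:
            k = int(m.group(2))
        except ValueError:
            raise ParseError(f"{path.name}:{i + 1}: malformed landmark count {m.group(2)!r}") from None
        i += 1
        pts: list[list[float]] = []
        while len(pts) < k and i < len(lines):
            coord_line = lines[i].strip()
            if not coord_line:
                i += 1
                continue
            if _KEYVAL_RE.match(coord_line) and not _looks_numeric(coord_line):
                break  # a metadata line arrived before k coordinate pairs
            toks = _split_coords(coord_line)
            if len(toks) != 2:
                raise ParseError(
                    f"{path.name}:{i + 1}: expected an 'x y' pair in record {record_index + 1}"
                )
            try:
                pts.append([float(toks[0]), float(toks[1])])
            except ValueError:
                raise ParseError(
                    f"{path.name}:{i + 1}: non-numeric coordinate {coord_line!r}"
                ) from None
            i += 1
        if len(pts) != k:
            raise ParseError(
                f"{path.name}: record {record_index + 1} declares LM={k} but has "
                f"{len(pts)} coordinate lines"
            )
        # trailing metadata lines of the record
        meta: dict[str, str] = {}
        while i < len(lines):
            tail = lines[i].strip()
            if not tail:
                i += 1
                continue
            m2 = _KEYVAL_RE.match(tail)
            if not m2 or m2.group(1).upper() == "LM":
                break
            meta[m2.group(1).upper()] = m2.group(2)
            i += 1

        specimen_id = meta.pop("ID", None)
        if specimen_id is None and "IMAGE" in meta:
            specimen_id = Path(meta["IMAGE"]).stem
        if not specimen_id:
            specimen_id = str(record_index)
        scale = None
        if "SCALE" in meta:
            try:
                scale = float(meta.pop("SCALE"))
            except ValueError:
                raise ParseError(
                    f"{path.name}: record {record_index + 1}: non-numeric SCALE value"
                ) from None
        extra = {key.lower(): val for key, val in meta.items() if key != "IMAGE"}
        if "IMAGE" in meta:
            extra["image"] = meta["IMAGE"]
        species = extra.pop("species", None)
        user_id = extra.pop("user", None)
        replicate_id = extra.pop("replicate", None)
        individual_id = extra.pop("individual", None)
        try:
            cfg = LandmarkConfiguration(
                specimen_id=specimen_id,
                coords=np.array(pts),
                scale_factor=scale,
                species=species,
                user_id=user_id,
                replicate_id=replicate_id,
                individual_id=individual_id,
                extra=extra,
            )
        except ValueError as exc:
            raise ParseError(f"{path.name}: record {record_index + 1}: {exc}") from None
        configs.append(cfg)
        record_index += 1

    if not configs:
        raise ParseError(f"{path.name}: no TPS records found")
    ks = {c.k for c in configs}
    if len(ks) > 1:
        raise DatasetConsistencyError(
            f"{path.name}: mixed landmark counts across records: {sorted(ks)}"
        )
    return LandmarkDataset(configs, provenance=str(path))


def _looks_numeric(line: str) -> bool:
    toks = _split_coords(line)
    if len(toks) != 2:
        return False
    try:
        float(toks[0]), float(toks[1])
        return True
    except ValueError:
        return False


def write_tps(dataset: LandmarkDataset, path: str | Path) -> None:
    """Write a dataset as a TPS file; round-trips exactly through read_tps."""
    path = Path(path)
    out: list[str] = []
    for cfg in dataset:
        out.append(f"LM={cfg.k}")
        for x, y in cfg.coords:
            out.append(f"{x:.17g} {y:.17g}")
        if "image" in cfg.extra:
            out.append(f"IMAGE={cfg.extra['image']}")
        out.append(f"ID={cfg.specimen_id}")
        if cfg.scale_factor is not None:
            out.append(f"SCALE={cfg.scale_factor:.17g}")
        if cfg.species is not None:
            out.append(f"SPECIES={cfg.species}")
        if cfg.user_id is not None:
            out.append(f"USER={cfg.user_id}")
        if cfg.replicate_id is not None:
            out.append(f"REPLICATE={cfg.replicate_id}")
        if cfg.individual_id != cfg.specimen_id:
            out.append(f"INDIVIDUAL={cfg.individual_id}")
        for key, val in cfg.extra.items():
            if key != "image":
                out.append(f"{key.upper()}={val}")
    path.write_text("\n".join(out) + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# Plain coordinate tables
# ---------------------------------------------------------------------------


def _find_id_column(columns: Sequence[str]) -> str:
    lower = {c.lower(): c for c in columns}
    for cand in _ID_COLUMNS:
        if cand in lower:
            return lower[cand]
    raise ParseError(f"no specimen-id column found among {list(columns)}")


def read_table(path: str | Path, dialect: str = "wide") -> LandmarkDataset:
    """Read a CSV/TSV coordinate table.

    *wide*: one specimen per row, coordinate columns ``x1,y1,...,xk,yk``
    (names case-insensitive) plus optional metadata columns
    (species/user/replicate/individual/scale).
    *long*: one landmark per row with ``landmark``, ``x``, ``y`` columns.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df = pd.read_csv(path, sep=sep)
    if dialect == "wide":
        return _table_wide(df, str(path))
    if dialect == "long":
        return _table_long(df, str(path))
    raise ValueError(f"unknown table dialect {dialect!r}")


def _meta_kwargs(row: Mapping, meta_cols: Mapping[str, str]) -> dict:
    kw: dict = {}
    extra: dict = {}
    for col, fieldname in meta_cols.items():
        val = row[col]
        if pd.isna(val):
            continue
        if fieldname == "scale_factor":
            kw[fieldname] = float(val)
        else:
            kw[fieldname] = str(val)
    kw["extra"] = extra
    return kw


def _table_wide(df: pd.DataFrame, source: str) -> LandmarkDataset:
    id_col = _find_id_column(df.columns)
    meta_cols = {c: _META_COLUMNS[c.lower()] for c in df.columns if c.lower() in _META_COLUMNS}
    coord_cols = [
        c for c in df.columns if re.fullmatch(r"[xy]\d+", c.lower()) and c not in meta_cols
    ]
    if not coord_cols:
        raise ParseError(f"{source}: no coordinate columns (x1,y1,...) found")
    if len(coord_cols) % 2:
        raise ParseError(f"{source}: odd number of coordinate columns ({len(coord_cols)})")
    k = len(coord_cols) // 2
    ordered = []
    for i in range(1, k + 1):
        for axis in ("x", "y"):
            match = [c for c in coord_cols if c.lower() == f"{axis}{i}"]
            if not match:
                raise ParseError(f"{source}: missing coordinate column {axis}{i}")
            ordered.append(match[0])
    configs = []
    for _, row in df.iterrows():
        coords = np.array([float(row[c]) for c in ordered]).reshape(k, 2)
        configs.append(
            LandmarkConfiguration(
                specimen_id=str(row[id_col]), coords=coords, **_meta_kwargs(row, meta_cols)
            )
        )
    return LandmarkDataset(configs, provenance=source)


def _table_long(df: pd.DataFrame, source: str) -> LandmarkDataset:
    id_col = _find_id_column(df.columns)
    lower = {c.lower(): c for c in df.columns}
    for needed in ("landmark", "x", "y"):
        if needed not in lower:
            raise ParseError(f"{source}: long dialect requires a {needed!r} column")
    lm_col, x_col, y_col = lower["landmark"], lower["x"], lower["y"]
    meta_cols = {c: _META_COLUMNS[c.lower()] for c in df.columns if c.lower() in _META_COLUMNS}

    dup = df.duplicated(subset=[id_col, lm_col])
    if dup.any():
        bad = df.loc[dup, [id_col, lm_col]].iloc[0]
        raise ParseError(
            f"{source}: duplicated (specimen, landmark) pair ({bad[id_col]}, {bad[lm_col]})"
        )
    configs = []
    for sid, grp in df.groupby(id_col, sort=False):
        grp = grp.sort_values(lm_col)
        coords = grp[[x_col, y_col]].to_numpy(dtype=float)
        configs.append(
            LandmarkConfiguration(
                specimen_id=str(sid), coords=coords, **_meta_kwargs(grp.iloc[0], meta_cols)
            )
        )
    return LandmarkDataset(configs, provenance=source)


def write_table(dataset: LandmarkDataset, path: str | Path, dialect: str = "wide") -> None:
    """Write a dataset as a CSV/TSV coordinate table (inverse of read_table)."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    k = dataset.landmark_count
    rows = []
    if dialect == "wide":
        for cfg in dataset:
            row: dict = {"specimen": cfg.specimen_id}
            _put_meta(row, cfg)
            for i in range(k):
                row[f"x{i + 1}"] = cfg.coords[i, 0]
                row[f"y{i + 1}"] = cfg.coords[i, 1]
            rows.append(row)
    elif dialect == "long":
        for cfg in dataset:
            for i in range(k):
                row = {"specimen": cfg.specimen_id, "landmark": i + 1}
                _put_meta(row, cfg)
                row["x"] = cfg.coords[i, 0]
                row["y"] = cfg.coords[i, 1]
                rows.append(row)
    else:
        raise ValueError(f"unknown table dialect {dialect!r}")
    pd.DataFrame(rows).to_csv(path, sep=sep, index=False, float_format="%.17g")


def _put_meta(row: dict, cfg: LandmarkConfiguration) -> None:
    if cfg.species is not None:
        row["species"] = cfg.species
    if cfg.user_id is not None:
        row["user"] = cfg.user_id
    if cfg.replicate_id is not None:
        row["replicate"] = cfg.replicate_id
    if cfg.individual_id != cfg.specimen_id:
        row["individual"] = cfg.individual_id
    if cfg.scale_factor is not None:
        row["scale"] = cfg.scale_factor


# ---------------------------------------------------------------------------
# Validation and merging
# ---------------------------------------------------------------------------


def validate_dataset(
    dataset: LandmarkDataset | Iterable[LandmarkConfiguration],
) -> ValidationReport:
    """Check dataset invariants, returning a report instead of raising.

    Violations: mixed landmark counts, duplicate specimen ids, non-finite
    coordinates, degenerate configurations (< 3 distinct landmark points).
    Warnings: configurations lacking a scale factor — shape analysis is
    scale-free but centroid sizes in pixels are only comparable across
    devices once converted to absolute length units.
    """
    configs = list(dataset)
    report = ValidationReport()
    if not configs:
        report.violations.append(("empty", "dataset contains no configurations"))
        return report
    ks = sorted({c.k for c in configs})
    if len(ks) > 1:
        report.violations.append(
            ("landmark-count", f"mixed landmark counts across configurations: {ks}")
        )
    seen: set[str] = set()
    n_unscaled = 0
    for c in configs:
        if c.specimen_id in seen:
            report.violations.append(("duplicate-id", f"duplicate specimen_id {c.specimen_id!r}"))
        seen.add(c.specimen_id)
        if not np.all(np.isfinite(c.coords)):
            report.violations.append(("non-finite", f"{c.specimen_id!r} has non-finite coordinates"))
            continue
        if len(np.unique(np.round(c.coords, 12), axis=0)) < 3:
            report.violations.append(
                ("degenerate-configuration", f"{c.specimen_id!r} has < 3 distinct landmark points")
            )
        if c.scale_factor is None:
            n_unscaled += 1
    if n_unscaled:
        report.warnings.append(
            (
                "no-scale",
                f"{n_unscaled} configuration(s) lack a scale factor; centroid sizes stay "
                "in device-dependent pixel units",
            )
        )
    return report


def merge_datasets(*datasets: LandmarkDataset, provenance: str = "") -> LandmarkDataset:
    """Concatenate datasets sharing k; raises on id collisions or k mismatch."""
    configs: list[LandmarkConfiguration] = []
    for d in datasets:
        configs.extend(d.configurations)
    return LandmarkDataset(configs, provenance=provenance or "; ".join(d.provenance for d in datasets))
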