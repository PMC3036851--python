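"""File formats: genotype matrices, distance-matrix TSV triples, genome specs.

Genotype matrices are exchanged as plain CSV (rows = individuals, header =
marker names, codes 0/1/2, missing "NA", with an optional ``#group`` comment
line carrying linkage-group assignment) or in a MAPMAKER-raw-style dialect
(``data type f2 intercross``; per-marker lines of A/H/B/- symbols) for
interoperability with classic linkage software.

Distance matrices are written as a TSV triple: ``<base>.tsv`` holds the cM
distances, ``<base>.r.tsv`` and ``<base>.lod.tsv`` the companion
recombination-fraction and LOD matrices in identical layout (marker-name
header row and index column, symmetric numeric body).  Symmetry is validated
on read.

Genome specifications are YAML or JSON: a ``groups`` list whose entries give
either ``{name_prefix, n_markers, spacing_cm}`` for equally spaced groups or
explicit ``{names, positions}``.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core import (
    DataError,
    DistanceMatrix,
    GenomeSpec,
    LinkageGroup,
    ParseError,
)
from .simulate import MISSING, GenotypeMatrix

__all__ = [
    "read_genotypes",
    "write_genotypes",
    "read_distance_matrix",
    "write_distance_matrix",
    "load_genome",
    "dump_genome",
]

_MAPMAKER_SYMBOLS = {"A": 0, "H": 1, "B": 2, "-": MISSING}
_MAPMAKER_CODES = {v: k for k, v in _MAPMAKER_SYMBOLS.items()}


# ---------------------------------------------------------------------------
# Genotypes


def write_genotypes(gm: GenotypeMatrix, path, dialect: str = "csv") -> None:
    """Write a genotype matrix in the ``csv`` or ``mapmaker_raw`` dialect."""
    path = Path(path)
    if dialect == "csv":
        lines = ["#group," + ",".join(str(g) for g in gm.groups)]
        lines.append(",".join(gm.names))
        for row in gm.codes:
            lines.append(
                ",".join("NA" if c == MISSING else str(int(c)) for c in row)
            )
        path.write_text("\n".join(lines) + "\n")
    elif dialect == "mapmaker_raw":
        lines = ["data type f2 intercross", f"{gm.n} {gm.k} 0"]
        for j, name in enumerate(gm.names):
            symbols = "".join(_MAPMAKER_CODES[int(c)] for c in gm.codes[:, j])
            lines.append(f"*{name} {symbols}")
        path.write_text("\n".join(lines) + "\n")
    else:
        raise ParseError(f"unknown genotype dialect {dialect!r}")


def read_genotypes(path, dialect: str = "csv") -> GenotypeMatrix:
    """Read a genotype matrix; inverse of :func:`write_genotypes`."""
    path = Path(path)
    if dialect == "csv":
        return _read_genotypes_csv(path)
    if dialect == "mapmaker_raw":
        return _read_genotypes_mapmaker(path)
    raise ParseError(f"unknown genotype dialect {dialect!r}")


def _read_genotypes_csv(path: Path) -> GenotypeMatrix:
    lines = path.read_text().splitlines()
    groups: tuple[int, ...] | None = None
    if lines and lines[0].startswith("#group,"):
        groups = tuple(int(g) for g in lines[0].split(",")[1:])
        lines = lines[1:]
    if not lines:
        raise ParseError(f"{path}: empty genotype file")
    names = tuple(lines[0].split(","))
    k = len(names)
    rows = []
    for li, line in enumerate(lines[1:], start=2):
        cells = line.split(",")
        if len(cells) != k:
            raise ParseError(f"{path}:{li}: expected {k} columns, got {len(cells)}")
        row = []
        for ci, cell in enumerate(cells, start=1):
            cell = cell.strip()
            if cell == "NA":
                row.append(MISSING)
            elif cell in ("0", "1", "2"):
                row.append(int(cell))
            else:
                raise ParseError(
                    f"{path}:{li}: column {ci}: invalid genotype code {cell!r}"
                )
        rows.append(row)
    codes = np.array(rows, dtype=np.int8).reshape(len(rows), k)
    if groups is None:
        groups = (0,) * k
    return GenotypeMatrix(codes=codes, names=names, groups=groups)


def _read_genotypes_mapmaker(path: Path) -> GenotypeMatrix:
    lines = path.read_text().splitlines()
    if not lines or "f2 intercross" not in lines[0]:
        raise ParseError(f"{path}:1: expected 'data type f2 intercross' header")
    try:
        n, k = (int(x) for x in lines[1].split()[:2])
    except (IndexError, ValueError) as exc:
        raise ParseError(f"{path}:2: malformed count line") from exc
    names: list[str] = []
    columns: list[list[int]] = []
    for li, line in enumerate(lines[2:], start=3):
        if not line.strip():
            continue
        if not line.startswith("*"):
            raise ParseError(f"{path}:{li}: marker line must start with '*'")
        parts = line[1:].split(None, 1)
        if len(parts) != 2:
            raise ParseError(f"{path}:{li}: expected '*name symbols'")
        name, symbols = parts
        symbols = symbols.replace(" ", "")
        if len(symbols) != n:
            raise ParseError(
                f"{path}:{li}: expected {n} genotype symbols, got {len(symbols)}"
            )
        col = []
        for ci, s in enumerate(symbols, start=1):
            if s not in _MAPMAKER_SYMBOLS:
                raise ParseError(
                    f"{path}:{li}: symbol {ci}: invalid genotype symbol {s!r}"
                )
            col.append(_MAPMAKER_SYMBOLS[s])
        names.append(name)
        columns.append(col)
    if len(names) != k:
        raise ParseError(f"{path}: header declares {k} markers, found {len(names)}")
    codes = np.array(columns, dtype=np.int8).T.reshape(n, k)
    return GenotypeMatrix(codes=codes, names=tuple(names), groups=(0,) * k)


# ---------------------------------------------------------------------------
# Distance matrices


def _companion_paths(path) -> tuple[Path, Path, Path]:
    base = Path(path)
    stem = base.name[: -len(".tsv")] if base.name.endswith(".tsv") else base.name
    return base, base.with_name(f"{stem}.r.tsv"), base.with_name(f"{stem}.lod.tsv")


def _write_matrix_tsv(m: np.ndarray, names, path: Path) -> None:
    pd.DataFrame(m, index=list(names), columns=list(names)).to_csv(path, sep="\t")


def _read_matrix_tsv(path: Path) -> tuple[np.ndarray, tuple[str, ...]]:
    df = pd.read_csv(path, sep="\t", index_col=0)
    m = df.to_numpy(dtype=float)
    if m.shape[0] != m.shape[1]:
        raise DataError(f"{path}: matrix is not square")
    if np.any(np.isnan(m)):
        raise DataError(f"{path}: matrix contains NaN cells")
    if not np.allclose(m, m.T, atol=1e-9):
        raise DataError(f"{path}: matrix is not symmetric")
    return m, tuple(str(c) for c in df.columns)


def write_distance_matrix(D: DistanceMatrix, path) -> None:
    """Write the TSV triple ``<base>.tsv`` / ``.r.tsv`` / ``.lod.tsv``."""
    d_path, r_path, lod_path = _companion_paths(path)
    names = D.names if D.names is not None else tuple(
        f"m{i + 1}" for i in range(D.k)
    )
    _write_matrix_tsv(D.d, names, d_path)
    if D.r is not None:
        _write_matrix_tsv(D.r, names, r_path)
    if D.lod is not None:
        _write_matrix_tsv(D.lod, names, lod_path)


def read_distance_matrix(path, units: str = "r") -> DistanceMatrix:
    """Read a distance-matrix TSV triple (companions optional on disk)."""
    d_path, r_path, lod_path = _companion_paths(path)
    d, names = _read_matrix_tsv(d_path)
    r = lod = None
    if r_path.exists():
        r, r_names = _read_matrix_tsv(r_path)
        if r_names != names:
            raise DataError(f"{r_path}: marker names differ from {d_path}")
    if lod_path.exists():
        lod, lod_names = _read_matrix_tsv(lod_path)
        if lod_names != names:
            raise DataError(f"{lod_path}: marker names differ from {d_path}")
    if units == "r" and r is None:
        units = "cM"  # fall back when no companion r matrix is on disk
    return DistanceMatrix(d=d, r=r, lod=lod, names=names, units=units)


# ---------------------------------------------------------------------------
# Genome specs


def _genome_to_dict(genome: GenomeSpec) -> dict:
    return {
        "groups": [
            {"names": list(g.names), "positions": [float(p) for p in g.positions]}
            for g in genome.groups
        ]
    }


def dump_genome(genome: GenomeSpec, path) -> None:
    """Write a genome spec as YAML (or JSON if the suffix is .json)."""
    path = Path(path)
    payload = _genome_to_dict(genome)
    if path.suffix == ".json":
        path.write_text(json.dumps(payload, indent=2) + "\n")
    else:
        path.write_text(yaml.safe_dump(payload, sort_keys=False))


def load_genome(source) -> GenomeSpec:
    """Load a genome spec from a YAML/JSON path or an equivalent dict.

    Each group entry is either ``{name_prefix, n_markers, spacing_cm[,
    start_number]}`` or explicit ``{names, positions}``.
    """
    if isinstance(source, dict):
        payload = source
    else:
        path = Path(source)
        text = path.read_text()
        payload = (
            json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        )
    if not isinstance(payload, dict) or "groups" not in payload:
        raise ParseError("genome spec must be a mapping with a 'groups' list")
    groups = []
    start = 1
    for entry in payload["groups"]:
        if "names" in entry:
            groups.append(
                LinkageGroup(tuple(entry["names"]), tuple(entry["positions"]))
            )
        else:
            n_markers = int(entry["n_markers"])
            groups.append(
                LinkageGroup.equally_spaced(
                    entry.get("name_prefix", "m"),
                    n_markers,
                    float(entry["spacing_cm"]),
                    int(entry.get("start_number", start)),
                )
            )
            start += n_markers
    return GenomeSpec(tuple(groups))
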