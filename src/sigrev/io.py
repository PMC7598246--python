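"""Readers and writers for the pipeline's file formats.

Matrices travel as GCT 1.2 (or plain TSV), signatures as GMT with paired
``<name>_UP`` / ``<name>_DN`` sets, ranked drug profiles as a gene x
perturbation rank matrix plus a metadata TSV, and everything else as TSV.
Readers fail fast on malformed input; writers can prepend a ``#`` comment
line recording the producing stage and parameters.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .connectivity import RankedProfile
from .diffexp import ExpressionMatrix, GeneSignature
from .exceptions import FormatError

__all__ = [
    "read_gct",
    "write_gct",
    "read_gmt",
    "read_signatures_gmt",
    "write_signatures_gmt",
    "read_matrix_tsv",
    "write_matrix_tsv",
    "read_groups_tsv",
    "read_profile_library",
    "write_profile_library",
    "write_tsv",
]


# ---------------------------------------------------------------------------
# GCT
# ---------------------------------------------------------------------------

def read_gct(path: str | Path, scale: str = "log2") -> ExpressionMatrix:
    """Parse a GCT 1.2/1.3 matrix; row descriptions are preserved in
    ``values.attrs['description']``."""
    lines = Path(path).read_text().splitlines()
    if len(lines) < 3:
        raise FormatError(f"{path}: truncated GCT (needs version, dims, header)")
    version = lines[0].strip()
    if version not in ("#1.2", "#1.3"):
        raise FormatError(f"{path}: unsupported GCT version line {version!r}")
    dims = lines[1].split("\t")
    if len(dims) < 2:
        raise FormatError(f"{path}: malformed dimension line")
    n_rows, n_cols = int(dims[0]), int(dims[1])
    header = lines[2].split("\t")
    if len(header) != n_cols + 2:
        raise FormatError(
            f"{path}: header has {len(header) - 2} samples, dimension line says {n_cols}")
    body = [ln.split("\t") for ln in lines[3:] if ln.strip()]
    if len(body) != n_rows:
        raise FormatError(f"{path}: {len(body)} data rows, dimension line says {n_rows}")
    names = [row[0] for row in body]
    desc = [row[1] for row in body]
    try:
        values = np.array([[float(v) for v in row[2:]] for row in body])
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric matrix entry ({exc})") from exc
    if values.shape[1] != n_cols:
        raise FormatError(f"{path}: ragged data rows")
    df = pd.DataFrame(values, index=names, columns=header[2:])
    df.attrs["description"] = dict(zip(names, desc))
    return ExpressionMatrix(df, None, scale)


def write_gct(m: ExpressionMatrix, path: str | Path,
              descriptions: dict | None = None) -> None:
    path = Path(path)
    desc = descriptions or m.values.attrs.get("description", {})
    with path.open("w") as fh:
        fh.write("#1.2\n")
        fh.write(f"{m.values.shape[0]}\t{m.values.shape[1]}\n")
        fh.write("Name\tDescription\t" + "\t".join(map(str, m.values.columns)) + "\n")
        for gene, row in m.values.iterrows():
            d = desc.get(gene, "na")
            fh.write(f"{gene}\t{d}\t" + "\t".join(f"{v:.6g}" for v in row) + "\n")


# ---------------------------------------------------------------------------
# GMT
# ---------------------------------------------------------------------------

def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """GMT -> ordered gene lists keyed by set name; duplicate genes within a
    set are dropped with a warning, empty lines skipped."""
    sets: dict[str, list[str]] = {}
    for ln_no, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) < 3:
            raise FormatError(f"{path}:{ln_no}: GMT line needs name, description, genes")
        name, genes = parts[0], [g for g in parts[2:] if g]
        uniq = list(dict.fromkeys(genes))
        if len(uniq) != len(genes):
            warnings.warn(f"{path}:{ln_no}: duplicate genes in set {name!r} removed",
                          stacklevel=2)
        sets[name] = uniq
    return sets


def read_signatures_gmt(path: str | Path) -> list[GeneSignature]:
    """Reconstruct signatures from paired ``<name>_UP`` / ``<name>_DN`` sets."""
    sets = read_gmt(path)
    names = {}
    for key in sets:
        if key.endswith("_UP"):
            names.setdefault(key[:-3], {})["up"] = sets[key]
        elif key.endswith("_DN"):
            names.setdefault(key[:-3], {})["down"] = sets[key]
    sigs = []
    for name, parts in names.items():
        if "up" not in parts or "down" not in parts:
            raise FormatError(f"{path}: signature {name!r} lacks its UP or DN partner set")
        sigs.append(GeneSignature(name=name, up=parts["up"], down=parts["down"]))
    if not sigs:
        raise FormatError(f"{path}: no paired UP/DN sets found")
    return sigs


def write_signatures_gmt(sigs: Sequence[GeneSignature], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for sig in sigs:
            fh.write("\t".join([f"{sig.name}_UP", sig.provenance or "na", *sig.up]) + "\n")
            fh.write("\t".join([f"{sig.name}_DN", sig.provenance or "na", *sig.down]) + "\n")


# ---------------------------------------------------------------------------
# TSV
# ---------------------------------------------------------------------------

def read_matrix_tsv(path: str | Path, scale: str = "log2") -> ExpressionMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    if df.empty:
        raise FormatError(f"{path}: empty matrix")
    return ExpressionMatrix(df, None, scale)


def write_matrix_tsv(m: ExpressionMatrix, path: str | Path, comment: str = "") -> None:
    with Path(path).open("w") as fh:
        if comment:
            fh.write(f"# {comment}\n")
        m.values.to_csv(fh, sep="\t")


def read_groups_tsv(path: str | Path) -> pd.Series:
    """Two-column TSV (sample_id, group) -> sample->group Series."""
    df = pd.read_csv(path, sep="\t", comment="#")
    if df.shape[1] < 2:
        raise FormatError(f"{path}: need sample_id and group columns")
    return pd.Series(df.iloc[:, 1].to_numpy(), index=df.iloc[:, 0].astype(str))


def write_tsv(df: pd.DataFrame, path: str | Path, comment: str = "",
              index: bool = False) -> None:
    with Path(path).open("w") as fh:
        if comment:
            fh.write(f"# {comment}\n")
        df.to_csv(fh, sep="\t", index=index)


# ---------------------------------------------------------------------------
# ranked profile libraries
# ---------------------------------------------------------------------------

def write_profile_library(profiles: Sequence[RankedProfile], rank_path: str | Path,
                          meta_path: str | Path) -> None:
    """Persist profiles as a gene x perturbation rank matrix + metadata TSV."""
    universe = profiles[0].ranked_genes
    gene_index = sorted(universe)
    data = {}
    meta_rows = []
    for p in profiles:
        ranks = pd.Series({g: i + 1 for i, g in enumerate(p.ranked_genes)})
        data[p.profile_id] = ranks.reindex(gene_index).to_numpy()
        meta_rows.append(
            {"perturbation_id": p.profile_id, "drug_id": p.drug_id,
             "cell_line": p.cell_line, "dose": p.dose, "time": p.time}
        )
    pd.DataFrame(data, index=gene_index).rename_axis("gene").to_csv(rank_path, sep="\t")
    pd.DataFrame(meta_rows).to_csv(meta_path, sep="\t", index=False)


def read_profile_library(rank_path: str | Path, meta_path: str | Path,
                         cell_line: str | None = None) -> list[RankedProfile]:
    ranks = pd.read_csv(rank_path, sep="\t", index_col=0, comment="#")
    meta = pd.read_csv(meta_path, sep="\t", comment="#", dtype=str)
    required = {"perturbation_id", "drug_id", "cell_line", "dose", "time"}
    if not required <= set(meta.columns):
        raise FormatError(f"{meta_path}: needs columns {sorted(required)}")
    profiles = []
    for row in meta.itertuples(index=False):
        if cell_line is not None and row.cell_line != cell_line:
            continue
        if row.perturbation_id not in ranks.columns:
            raise FormatError(f"{meta_path}: {row.perturbation_id} missing from rank matrix")
        col = ranks[row.perturbation_id]
        expected = set(range(1, len(col) + 1))
        if set(col.astype(int)) != expected:
            raise FormatError(
                f"{rank_path}: column {row.perturbation_id} is not a permutation of ranks")
        ordered = list(col.sort_values().index)
        profiles.append(
            RankedProfile(row.perturbation_id, row.drug_id, row.cell_line,
                          row.dose, row.time, ordered)
        )
    if not profiles:
        raise FormatError(f"{meta_path}: no profiles selected")
    return profiles
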