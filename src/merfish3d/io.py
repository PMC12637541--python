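"""Readers and writers for the toolkit's tabular and mesh formats.

All tabular artifacts are plain CSV with documented headers so every
output is language-neutral and diffable; cell-by-gene matrices can also
be written as MatrixMarket triplets with row/column name sidecars.
Meshes round-trip through trimesh (OBJ/PLY).
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
import scipy.io
import scipy.sparse
import trimesh

__all__ = [
    "write_molecules_csv",
    "read_molecules_csv",
    "write_cells_csv",
    "read_cells_csv",
    "write_edge_list_csv",
    "read_edge_list_csv",
    "write_cell_by_gene_mtx",
    "load_mesh",
    "save_mesh",
]


def write_molecules_csv(molecules: pd.DataFrame, path) -> None:
    molecules.to_csv(path, index=False)


def read_molecules_csv(path) -> pd.DataFrame:
    out = pd.read_csv(path)
    if "is_blank" in out.columns:
        out["is_blank"] = out["is_blank"].astype(bool)
    return out


def write_cells_csv(cells: pd.DataFrame, path) -> None:
    cells.to_csv(path, index=False)


def read_cells_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_edge_list_csv(edges: pd.DataFrame, path) -> None:
    edges.to_csv(path, index=False)


def read_edge_list_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_cell_by_gene_mtx(matrix: pd.DataFrame, directory) -> None:
    """MatrixMarket triplet plus cell/gene name sidecars."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    sparse = scipy.sparse.csr_matrix(matrix.to_numpy())
    scipy.io.mmwrite(directory / "matrix.mtx", sparse)
    (directory / "cells.txt").write_text(
        "\n".join(str(i) for i in matrix.index) + "\n"
    )
    (directory / "genes.txt").write_text("\n".join(matrix.columns) + "\n")


def load_mesh(path) -> trimesh.Trimesh:
    mesh = trimesh.load(path, force="mesh")
    if not isinstance(mesh, trimesh.Trimesh):
        raise ValueError(f"{path} did not contain a triangle mesh")
    return mesh


def save_mesh(mesh: trimesh.Trimesh, path) -> None:
    mesh.export(path)
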