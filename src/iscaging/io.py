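"""Containers and file formats shared across the pipeline.

The pipeline's in-memory objects are deliberately plain: a sparse
genes x cells count matrix with two aligned metadata frames, and a handful
of dataclasses for derived results.  On disk everything is plain text:
Matrix Market for counts, tab-separated tables for metadata and results,
GMT for gene sets, JSON for configuration echoes and reports.  Every file
written by the pipeline carries a provenance comment (seed + config hash)
so a run can be identified from any of its artifacts.
"""

from __future__ import annotations

import hashlib
import io as _stdio
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.io import mmread, mmwrite

CONDITIONS = ("Y", "O", "O_met", "O_rap")

PATHWAYS = ("Wnt", "CellCycle", "Ribosome", "Oxphos")

#: cell types along the maturation continuum, in developmental order
MAIN_TYPES = ("Stem", "R", "R-Div", "Div1", "Div2", "EC")

MITO_PREFIX = "mt-"


class FixtureError(ValueError):
    """Raised when an on-disk fixture is malformed or inconsistent."""


@dataclass
class CountMatrix:
    """Sparse genes x cells non-negative integer counts with identifiers.

    ``genes`` and ``cells`` are DataFrames indexed by gene / cell id whose
    rows align with the matrix axes.  ``cells`` doubles as the cohort
    metadata table (mouse id, condition, QC stats, cluster labels...).
    """

    counts: sp.csr_matrix
    genes: pd.DataFrame
    cells: pd.DataFrame

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        if self.counts.shape != (len(self.genes), len(self.cells)):
            raise FixtureError(
                f"count matrix is {self.counts.shape} but metadata describe "
                f"{len(self.genes)} genes x {len(self.cells)} cells"
            )

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    @property
    def gene_ids(self) -> pd.Index:
        return self.genes.index

    @property
    def cell_ids(self) -> pd.Index:
        return self.cells.index

    def subset_cells(self, mask: np.ndarray) -> "CountMatrix":
        return CountMatrix(
            self.counts[:, np.asarray(mask)], self.genes, self.cells.loc[mask].copy()
        )


@dataclass
class NormalizedMatrix:
    """Dense log-normalized expression (genes x cells), natural log of
    1 + 1e4 * count / cell_total."""

    values: np.ndarray
    genes: pd.DataFrame
    cells: pd.DataFrame

    @property
    def gene_ids(self) -> pd.Index:
        return self.genes.index

    @property
    def cell_ids(self) -> pd.Index:
        return self.cells.index

    def row(self, gene: str) -> np.ndarray:
        i = self.genes.index.get_loc(gene)
        return self.values[i]


@dataclass
class TestResult:
    """Uniform record for the statistical battery."""

    name: str
    statistic: float
    df: tuple | float | None
    p: float
    detail: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        df = self.df
        if isinstance(df, tuple):
            df = list(df)
        return {"test": self.name, "statistic": self.statistic, "df": df,
                "p": self.p, **self.detail}


# ---------------------------------------------------------------------------
# provenance headers

def config_hash(obj) -> str:
    """Stable short hash of a JSON-serializable configuration object."""
    payload = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:12]


def provenance_line(seed, cfg_hash: str) -> str:
    return f"seed={seed} config_sha={cfg_hash}"


def write_tsv(df: pd.DataFrame, path, seed=None, cfg_hash: str = "", index=True,
              index_label=None) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        if seed is not None:
            fh.write(f"# {provenance_line(seed, cfg_hash)}\n")
        df.to_csv(fh, sep="\t", index=index, index_label=index_label)


def read_tsv(path, index_col=0) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col, comment="#")


# ---------------------------------------------------------------------------
# Matrix Market

def write_mtx(matrix: sp.spmatrix, path, seed=None, cfg_hash: str = "") -> None:
    """Write integer counts as Matrix Market with a provenance comment."""
    buf = _stdio.BytesIO()
    mmwrite(buf, sp.coo_matrix(matrix), field="integer")
    text = buf.getvalue().decode()
    if seed is not None:
        head, rest = text.split("\n", 1)
        text = f"{head}\n%{provenance_line(seed, cfg_hash)}\n{rest}"
    Path(path).write_text(text)


def read_mtx(path) -> sp.csr_matrix:
    try:
        m = mmread(str(path))
    except Exception as exc:  # malformed header / body
        raise FixtureError(f"malformed Matrix Market file {path}: {exc}") from exc
    return sp.csr_matrix(m)


# ---------------------------------------------------------------------------
# GMT gene sets

def read_gmt(path) -> dict[str, list[str]]:
    """Parse a GMT file: one set per line, name TAB description TAB genes..."""
    sets: dict[str, list[str]] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise FixtureError(
                f"{path}:{lineno}: GMT line has {len(fields)} fields, needs >= 3"
            )
        name = fields[0]
        if name in sets:
            raise FixtureError(f"{path}:{lineno}: duplicate gene set {name!r}")
        sets[name] = [g for g in fields[2:] if g]
    return sets


def write_gmt(sets: dict[str, list[str]], path, description: str = "na") -> None:
    lines = [
        "\t".join([name, description, *genes]) for name, genes in sets.items()
    ]
    Path(path).write_text("\n".join(lines) + "\n")
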