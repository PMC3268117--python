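"""Species-tagged expression matrices and their tab-delimited I/O.

The in-memory container wraps a pandas DataFrame (probes x samples) of
log2, RMA-style normalized intensities, together with a species tag and a
partial probe -> gene-symbol annotation.  Missing values are not supported:
post-RMA array data is complete, and every downstream contract relies on
finite values.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import DegenerateInputError, FormatError, GeneLookupError

SPECIES = ("human", "mouse")


@dataclass
class ProbeAnnotation:
    """Mapping of probe-set identifiers to gene symbols."""

    entries: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for probe, symbol in self.entries.items():
            if not symbol or not str(symbol).strip():
                raise FormatError(f"empty gene symbol for probe {probe!r}")

    @classmethod
    def read(cls, path: str | Path) -> "ProbeAnnotation":
        """Read a two-column ``probe_id<TAB>gene_symbol`` file."""
        df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment=None)
        if df.shape[1] < 2:
            raise FormatError(f"{path}: expected two tab-separated columns")
        if df[0].duplicated().any():
            dup = df[0][df[0].duplicated()].iloc[0]
            raise FormatError(f"{path}: duplicate probe id {dup!r}")
        return cls(dict(zip(df[0], df[1])))

    def write(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            for probe, symbol in self.entries.items():
                fh.write(f"{probe}\t{symbol}\n")
        return path


@dataclass
class ExpressionMatrix:
    """Probe-by-sample log2 expression matrix for one species.

    Parameters
    ----------
    data
        DataFrame with probe ids as index, sample ids as columns.  Row and
        column order is preserved exactly as given.
    species
        ``"human"`` or ``"mouse"``.
    annotation
        Optional probe -> gene-symbol mapping; may cover only part of the
        probes.
    scale
        ``"log2"`` (default, RMA convention) or ``"linear"``; controls
        fold-change arithmetic downstream.
    """

    data: pd.DataFrame
    species: str
    annotation: dict[str, str] = field(default_factory=dict)
    scale: str = "log2"

    def __post_init__(self) -> None:
        if self.species not in SPECIES:
            raise ValueError(f"species must be one of {SPECIES}, got {self.species!r}")
        if self.scale not in ("log2", "linear"):
            raise ValueError(f"scale must be 'log2' or 'linear', got {self.scale!r}")
        if self.data.columns.duplicated().any():
            dup = self.data.columns[self.data.columns.duplicated()][0]
            raise FormatError(f"duplicate sample label {dup!r}")
        if self.data.index.duplicated().any():
            dup = self.data.index[self.data.index.duplicated()][0]
            raise FormatError(f"duplicate probe id {dup!r}")
        if self.data.shape[1] < 2:
            raise ValueError("an expression matrix needs at least 2 samples")
        values = self.data.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise FormatError("matrix contains non-numeric values")
        if not np.all(np.isfinite(values)):
            r, c = np.argwhere(~np.isfinite(values))[0]
            raise FormatError(
                f"non-finite value at probe {self.data.index[r]!r}, "
                f"sample {self.data.columns[c]!r}"
            )

    # ------------------------------------------------------------------
    @property
    def probe_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_probes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def gene_symbols(self) -> set[str]:
        """Uppercased symbols of all annotated probes."""
        return {s.upper() for s in self.annotation.values()}

    def probes_for_gene(self, symbol: str) -> list[str]:
        """All probes annotated to ``symbol`` (case-insensitive); falls back
        to a direct probe-id match so collapsed matrices (index = symbols)
        keep working."""
        want = symbol.upper()
        hits = [p for p, s in self.annotation.items() if s.upper() == want]
        if not hits:
            hits = [p for p in self.data.index if str(p).upper() == want]
        return hits

    def gene_row(self, symbol: str) -> pd.Series:
        """Expression row for a gene symbol.

        When several probes map to the gene, the probe with the highest
        mean intensity is used (the same rule as :func:`collapse_to_genes`).
        """
        hits = self.probes_for_gene(symbol)
        if not hits:
            raise GeneLookupError(f"gene {symbol!r} not found in {self.species} matrix")
        if len(hits) == 1:
            return self.data.loc[hits[0]]
        sub = self.data.loc[hits]
        return sub.loc[sub.mean(axis=1).idxmax()]

    def has_gene(self, symbol: str) -> bool:
        return bool(self.probes_for_gene(symbol))


# ----------------------------------------------------------------------
# Tab-delimited I/O


def read_expression_matrix(
    path: str | Path,
    species: str,
    annotation: ProbeAnnotation | Mapping[str, str] | None = None,
) -> ExpressionMatrix:
    """Read a ``probe_id<TAB>sample...`` matrix, preserving file order.

    Raises :class:`FormatError` on duplicate sample labels, non-numeric
    cells (with the offending position) or an empty file.
    """
    path = Path(path)
    text = path.read_text()
    if not text.strip():
        raise FormatError(f"{path}: empty file")
    header = text.splitlines()[0].rstrip("\n").split("\t")
    samples = header[1:]
    seen: set[str] = set()
    for s in samples:
        if s in seen:
            raise FormatError(f"{path}: duplicate sample label {s!r}")
        seen.add(s)
    raw = pd.read_csv(io.StringIO(text), sep="\t", index_col=0, dtype=str)
    try:
        df = raw.apply(pd.to_numeric)
    except (ValueError, TypeError):
        for j, col in enumerate(raw.columns):
            converted = pd.to_numeric(raw[col], errors="coerce")
            bad = converted.isna() & raw[col].notna()
            if bad.any():
                i = int(np.argmax(bad.to_numpy()))
                raise FormatError(
                    f"{path}: non-numeric cell {raw[col].iloc[i]!r} at "
                    f"probe {raw.index[i]!r} (row {i + 2}), sample {col!r} (column {j + 2})"
                ) from None
        raise
    ann: dict[str, str] = {}
    if annotation is not None:
        entries = annotation.entries if isinstance(annotation, ProbeAnnotation) else dict(annotation)
        ann = {p: g for p, g in entries.items() if p in df.index}
    return ExpressionMatrix(df, species=species, annotation=ann)


def write_expression_matrix(mat: ExpressionMatrix, path: str | Path) -> Path:
    """Write ``mat`` as a tab-delimited file re-readable to equality.

    Values are rendered with 8 significant digits, so round-trips preserve
    log2 intensities well below 1e-6.
    """
    path = Path(path)
    df = mat.data.copy()
    df.index.name = "probe_id"
    df.to_csv(path, sep="\t", float_format="%.8g")
    return path


def read_series_matrix(
    path: str | Path, species: str, annotation: ProbeAnnotation | None = None
) -> ExpressionMatrix:
    """Optional reader for GEO Series-Matrix-style files.

    Comment/metadata lines starting with ``!`` are skipped; the expression
    table is taken between ``!series_matrix_table_begin`` and
    ``!series_matrix_table_end`` when those sentinels are present.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    if any(l.startswith("!series_matrix_table_begin") for l in lines):
        start = next(i for i, l in enumerate(lines) if l.startswith("!series_matrix_table_begin"))
        end = next(
            (i for i, l in enumerate(lines) if l.startswith("!series_matrix_table_end")),
            len(lines),
        )
        table = lines[start + 1 : end]
    else:
        table = [l for l in lines if not l.startswith("!")]
    if not table:
        raise FormatError(f"{path}: no expression table found")
    df = pd.read_csv(io.StringIO("\n".join(table)), sep="\t", index_col=0)
    df.index = [str(p).strip('"') for p in df.index]
    df.columns = [str(c).strip('"') for c in df.columns]
    ann = {}
    if annotation is not None:
        ann = {p: g for p, g in annotation.entries.items() if p in df.index}
    return ExpressionMatrix(df, species=species, annotation=ann)


def collapse_to_genes(
    mat: ExpressionMatrix, rule: str = "max_mean"
) -> tuple[ExpressionMatrix, int]:
    """Collapse probe-level rows to one row per annotated gene symbol.

    Under ``max_mean`` the retained probe for each gene is the one with the
    largest mean intensity across samples.  Unannotated probes are dropped.

    Returns the collapsed matrix (index = gene symbols, original casing of
    the first annotation entry) and the number of dropped probes.
    """
    if rule != "max_mean":
        raise ValueError(f"unknown collapse rule {rule!r}")
    if not mat.annotation:
        raise DegenerateInputError("no annotated probes to collapse")
    means = mat.data.mean(axis=1)
    best: dict[str, tuple[str, str]] = {}  # upper symbol -> (probe, display symbol)
    for probe, symbol in mat.annotation.items():
        if probe not in mat.data.index:
            continue
        key = symbol.upper()
        if key not in best or means[probe] > means[best[key][0]]:
            best[key] = (probe, symbol)
    if not best:
        raise DegenerateInputError("no annotated probes to collapse")
    # keep original row order of the retained probes
    keep_probes = {probe: sym for probe, sym in best.values()}
    rows = [p for p in mat.data.index if p in keep_probes]
    out = mat.data.loc[rows].copy()
    out.index = [keep_probes[p] for p in rows]
    n_dropped = mat.n_probes - len(rows)
    collapsed = ExpressionMatrix(
        out,
        species=mat.species,
        annotation={s: s for s in out.index},
        scale=mat.scale,
    )
    return collapsed, n_dropped
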