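"""The packaged 64-gene mesenchymal-transition signature and companion lists.

The signature is the 64-gene list (one Affymetrix HG-U133A probe set per
gene) of the invasion-associated fibroblastic expression program anchored
by COL11A1/THBS2/INHBA.  Each entry carries an EMT annotation class:

- ``core_overlap``  — one of the 17 genes shared with the 91-gene EMT core
  signature derived from induced EMTs;
- ``obvious_marker`` — SNAI2 (Slug), FN1 (fibronectin), ACTA2 (alpha-SMA);
- ``reported_additional`` — PDGFRB, SPARC, INHBA, COL6A2, reported as
  EMT-related elsewhere;
- ``other`` — the remaining 40 genes.

The class partition is exhaustive and disjoint: 17 + 3 + 4 + 40 = 64.
Gene symbols are kept verbatim as historically printed (e.g. HNT, C7orf10)
and compared case-insensitively, since mouse symbols are conventionally
mixed-case and human ones upper-case.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .errors import ResourceError

EMT_CLASSES = ("core_overlap", "obvious_marker", "reported_additional", "other")

#: Size of the full published EMT core signature (upregulated genes).  The
#: full list is not packaged — only its 17-member overlap with the 64-gene
#: signature — but the size is needed for enrichment arithmetic.
EMT_CORE_SIGNATURE_SIZE = 91

_EXPECTED_CLASS_COUNTS = {
    "core_overlap": 17,
    "obvious_marker": 3,
    "reported_additional": 4,
    "other": 40,
}


@dataclass(frozen=True)
class SignatureEntry:
    rank: int
    probe_set_id: str
    gene_symbol: str
    emt_class: str


@dataclass
class SignatureDefinition:
    """An ordered signature: entries sorted by rank."""

    entries: list[SignatureEntry]
    name: str = "mesenchymal_transition_64"

    def __post_init__(self) -> None:
        symbols = [e.gene_symbol.upper() for e in self.entries]
        if len(set(symbols)) != len(symbols):
            raise ResourceError(f"{self.name}: duplicate gene symbols")
        ranks = [e.rank for e in self.entries]
        if sorted(ranks) != list(range(1, len(self.entries) + 1)):
            raise ResourceError(f"{self.name}: ranks must be 1..{len(self.entries)} each once")
        self.entries = sorted(self.entries, key=lambda e: e.rank)
        for e in self.entries:
            if e.emt_class not in EMT_CLASSES:
                raise ResourceError(f"{self.name}: unknown EMT class {e.emt_class!r}")

    @property
    def gene_symbols(self) -> list[str]:
        return [e.gene_symbol for e in self.entries]

    def entry_for(self, symbol: str) -> SignatureEntry:
        want = symbol.upper()
        for e in self.entries:
            if e.gene_symbol.upper() == want:
                return e
        raise KeyError(symbol)

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)


@dataclass
class NamedGeneList:
    name: str
    symbols: list[str]

    def __post_init__(self) -> None:
        upper = [s.upper() for s in self.symbols]
        if len(set(upper)) != len(upper):
            raise ValueError(f"{self.name}: duplicate symbols")

    def __len__(self) -> int:
        return len(self.symbols)

    def __iter__(self):
        return iter(self.symbols)


# ----------------------------------------------------------------------


def _data_path(filename: str) -> Path:
    return Path(resources.files("xenosig").joinpath("data", filename))


def load_signature(path: str | Path | None = None) -> SignatureDefinition:
    """Load the packaged 64-gene signature (or an alternative from ``path``).

    The file format is ``rank<TAB>probe_set_id<TAB>gene_symbol<TAB>emt_class``
    with a header row.  The packaged resource is additionally checked
    against the published class counts (17/3/4/40).
    """
    packaged = path is None
    path = _data_path("signature64.tsv") if packaged else Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype={"rank": int})
    except (OSError, ValueError) as exc:
        raise ResourceError(f"cannot read signature resource {path}: {exc}") from exc
    required = {"rank", "probe_set_id", "gene_symbol", "emt_class"}
    if not required.issubset(df.columns):
        raise ResourceError(f"{path}: missing columns {sorted(required - set(df.columns))}")
    entries = [
        SignatureEntry(int(r.rank), str(r.probe_set_id), str(r.gene_symbol), str(r.emt_class))
        for r in df.itertuples()
    ]
    sig = SignatureDefinition(entries)
    if packaged:
        if len(sig) != 64:
            raise ResourceError(f"packaged signature has {len(sig)} entries, expected 64")
        counts = {c: count_class(sig, {c}) for c in EMT_CLASSES}
        if counts != _EXPECTED_CLASS_COUNTS:
            raise ResourceError(f"packaged signature class counts {counts} are corrupted")
    return sig


def load_gene_list(name: str, path: str | Path | None = None) -> NamedGeneList:
    """Load one of the packaged named lists (``core_overlap_17``,
    ``validated_up_29``, ``emt_tf_panel``, ``adipocyte_markers``), or a
    list of that name from an alternative two-column TSV."""
    path = _data_path("gene_lists.tsv") if path is None else Path(path)
    try:
        df = pd.read_csv(path, sep="\t")
    except (OSError, ValueError) as exc:
        raise ResourceError(f"cannot read gene lists from {path}: {exc}") from exc
    sub = df[df["list_name"] == name]
    if sub.empty:
        raise ResourceError(f"no gene list named {name!r} in {path}")
    return NamedGeneList(name, [str(s) for s in sub["gene_symbol"]])


def count_class(sig: SignatureDefinition, classes: Iterable[str]) -> int:
    """Number of signature entries whose EMT class is in ``classes``."""
    classes = set(classes)
    if not classes:
        raise ValueError("classes must be a non-empty set")
    unknown = classes - set(EMT_CLASSES)
    if unknown:
        raise ValueError(f"unknown EMT class labels {sorted(unknown)}")
    return sum(1 for e in sig.entries if e.emt_class in classes)


def overlap_with(
    sig: SignatureDefinition, genes: NamedGeneList | Sequence[str]
) -> tuple[int, list[str]]:
    """Overlap of a gene list with the signature.

    Returns the overlap count and the shared symbols (signature casing),
    ordered by signature rank.  Matching is case-insensitive.
    """
    symbols = genes.symbols if isinstance(genes, NamedGeneList) else list(genes)
    query = {s.upper() for s in symbols}
    shared = [e.gene_symbol for e in sig.entries if e.gene_symbol.upper() in query]
    return len(shared), shared
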