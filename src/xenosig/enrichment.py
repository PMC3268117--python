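"""Hypergeometric gene-set overlap statistics and cross-species analyses.

The enrichment question: having drawn ``n`` genes (e.g. the 64-gene
signature) from a universe of ``N``, what is the probability of seeing at
least ``k`` members of a size-``K`` category (e.g. the 91-gene EMT core
signature)?  The upper tail is computed in log space (gammaln +
logsumexp) so probabilities far below 1e-30 keep full relative accuracy.

Note the strong dependence of the tail on the universe size ``N``, which
published P values frequently omit: for (k=17, n=64, K=91) the tail is
8.4e-10 at N=2000 but 8.2e-24 at N=14500.  ``universe_size`` is therefore
a required, explicit argument.

The cross-species operations attribute the signature to the graft: human
SAM up-calls are tested for signature enrichment, the mouse matrix is
scanned for genes downregulated under the *human*-derived partition, and
the adipocyte-marker cluster is correlated against the per-sample human
signature score.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.special import gammaln, logsumexp

from .errors import AlignmentError, GeneLookupError
from .matrix import ExpressionMatrix
from .sam import DEGene, SamConfig, SamplePartition, sam_qvalues, _check_alignment
from .signature import NamedGeneList, SignatureDefinition, overlap_with


@dataclass
class EnrichmentResult:
    k: int  # overlap count
    n: int  # query-list size
    K: int  # category size
    N: int  # universe size
    p_tail: float  # P(X >= k)
    shared: list[str] | None = None


def _log_binom(a: int, b) -> np.ndarray:
    b = np.asarray(b, dtype=float)
    return gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1)


def hypergeom_tail(k: int, n: int, K: int, N: int) -> float:
    """Upper-tail probability P(X >= k) of Hypergeometric(N, K, n).

    Exact conventions: ``k <= 0`` returns 1.0 (whole sample space);
    ``k > min(n, K)`` returns 0.0 (impossible event).  Computed as a
    log-space sum of pmf terms, accurate in a relative sense down to the
    smallest representable magnitudes.
    """
    for name, v in (("k", k), ("n", n), ("K", K), ("N", N)):
        if int(v) != v:
            raise ValueError(f"{name} must be an integer, got {v!r}")
    k, n, K, N = int(k), int(n), int(K), int(N)
    if min(n, K, N) < 0 or n > N or K > N:
        raise ValueError(f"invalid hypergeometric parameters k={k} n={n} K={K} N={N}")
    hi = min(n, K)
    lo_support = max(0, n - (N - K))
    if k > hi:
        return 0.0
    if k <= lo_support:
        return 1.0
    i = np.arange(k, hi + 1)
    logp = _log_binom(K, i) + _log_binom(N - K, n - i) - _log_binom(N, n)
    return float(np.exp(logsumexp(logp)))


def signature_enrichment(
    query: NamedGeneList | Sequence[str],
    category: NamedGeneList | SignatureDefinition | Sequence[str],
    universe_size: int,
) -> EnrichmentResult:
    """Hypergeometric overlap of a query gene list with a category.

    The overlap is computed case-insensitively; when the category is a
    :class:`SignatureDefinition` the shared genes come back in signature
    rank order.
    """
    q_symbols = list(query.symbols) if isinstance(query, NamedGeneList) else list(query)
    if isinstance(category, SignatureDefinition):
        k, shared = overlap_with(category, q_symbols)
        K = len(category)
    else:
        c_symbols = list(category.symbols) if isinstance(category, NamedGeneList) else list(category)
        q_upper = {s.upper() for s in q_symbols}
        shared = [s for s in c_symbols if s.upper() in q_upper]
        k, K = len(shared), len(c_symbols)
    n = len(set(s.upper() for s in q_symbols))
    if universe_size < max(n, K):
        raise ValueError(
            f"universe_size {universe_size} smaller than the lists (n={n}, K={K})"
        )
    return EnrichmentResult(
        k=k, n=n, K=K, N=universe_size, p_tail=hypergeom_tail(k, n, K, universe_size),
        shared=shared,
    )


def signature_score(mat: ExpressionMatrix, sig: SignatureDefinition) -> np.ndarray:
    """Per-sample signature score: unweighted mean of the signature-gene
    rows present in the matrix (matrix sample order)."""
    rows = [mat.gene_row(s).to_numpy() for s in sig.gene_symbols if mat.has_gene(s)]
    if not rows:
        raise GeneLookupError("no signature genes present in the matrix")
    return np.mean(rows, axis=0)


def mouse_down_analysis(
    mouse: ExpressionMatrix,
    human_partition: SamplePartition,
    config: SamConfig | None = None,
    direction: str = "down",
) -> list[DEGene]:
    """SAM on the mouse matrix under the human-derived partition.

    Returns the significantly downregulated mouse genes (the paper-facing
    direction; pass ``direction="up"`` for the symmetric analysis),
    sorted by descending fold-change magnitude, i.e. ascending FC for the
    down direction.
    """
    config = config or SamConfig()
    _check_alignment(mouse, human_partition)  # AlignmentError lists unshared samples
    de = sam_qvalues(mouse, human_partition, config)
    if direction == "down":
        hits = [g for g in de if g.significant_down]
        return sorted(hits, key=lambda g: (g.fold_change, g.gene))
    if direction == "up":
        hits = [g for g in de if g.significant_up]
        return sorted(hits, key=lambda g: (-g.fold_change, g.gene))
    raise ValueError(f"direction must be 'down' or 'up', got {direction!r}")


def adipocyte_association(
    mouse: ExpressionMatrix,
    markers: NamedGeneList | Sequence[str],
    human_score: np.ndarray,
) -> float:
    """Pearson correlation between the per-sample mean of the mouse
    adipocyte-marker rows and the per-sample human signature score.

    Degenerate inputs (constant marker mean or constant score) are
    reported as 0.0 with a warning rather than NaN.
    """
    symbols = list(markers.symbols) if isinstance(markers, NamedGeneList) else list(markers)
    if not symbols:
        raise GeneLookupError("empty adipocyte marker list")
    rows = [mouse.gene_row(s).to_numpy() for s in symbols if mouse.has_gene(s)]
    if not rows:
        raise GeneLookupError(f"none of the markers {symbols} present in the mouse matrix")
    marker_mean = np.mean(rows, axis=0)
    score = np.asarray(human_score, dtype=float)
    if score.shape != marker_mean.shape:
        raise AlignmentError("human score length does not match the mouse sample count")
    if np.ptp(marker_mean) == 0 or np.ptp(score) == 0:
        warnings.warn("degenerate (constant) input; association reported as 0", stacklevel=2)
        return 0.0
    return float(np.corrcoef(marker_mean, score)[0, 1])
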