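"""Two-class unpaired SAM (significance analysis of microarrays).

Implements the permutation-based differential-expression procedure from
first principles: the regularized relative difference

    d = (mean_high - mean_low) / (s + s0)

with pooled scatter

    s = sqrt[(1/n1 + 1/n2) * (SS_high + SS_low) / (n1 + n2 - 2)],

a fudge factor ``s0`` chosen to decouple the spread of ``d`` from ``s``,
a permutation null over group labelings (exhaustive when the number of
distinct labelings is small enough — C(18, 7) = 31824 qualifies, making
the 7-vs-11 analysis fully deterministic), and per-gene q-values from the
median number of null exceedances.  A gene is called significant when its
q-value is below 0.05 AND its linear fold change exceeds 2 (up) or falls
below 1/2 (down).

Sample partitioning by proxy-gene expression (the largest-gap rule, with
a fixed-group-size override to reproduce a 7/11 split) lives here too.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from math import comb
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .errors import AlignmentError, DegenerateInputError
from .matrix import ExpressionMatrix
from .signature import NamedGeneList

__all__ = [
    "SamplePartition",
    "SamConfig",
    "DEGene",
    "SAMTwoClass",
    "partition_by_proxy",
    "sam_d",
    "choose_s0",
    "sam_qvalues",
    "fold_change",
    "tf_panel_report",
]


# ----------------------------------------------------------------------
# Sample partitioning


@dataclass
class SamplePartition:
    proxy_gene: str
    labels: dict[str, str]  # sample -> "high" | "low"
    proxy_values: dict[str, float]
    method: str

    def __post_init__(self) -> None:
        groups = set(self.labels.values())
        if not {"high", "low"} >= groups or len(groups) != 2:
            raise ValueError("partition must contain both 'high' and 'low' samples")

    @property
    def high(self) -> list[str]:
        return [s for s, g in self.labels.items() if g == "high"]

    @property
    def low(self) -> list[str]:
        return [s for s, g in self.labels.items() if g == "low"]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": list(self.labels),
                "group": [self.labels[s] for s in self.labels],
                "proxy_value": [self.proxy_values[s] for s in self.labels],
            }
        )


def partition_by_proxy(
    mat: ExpressionMatrix,
    proxy: str = "COL11A1",
    method: str = "largest_gap",
    fixed_n_high: int | None = None,
) -> SamplePartition:
    """Split samples into high/low groups by the proxy gene's expression.

    ``largest_gap`` sorts the proxy values in descending order and splits
    at the largest difference between consecutive values, considering only
    interior split points that leave at least two samples in each group.
    ``fixed_n_high`` overrides the rule: the top ``fixed_n_high`` samples
    become the high group (the 7/11 replication mode).
    """
    row = mat.gene_row(proxy)
    if mat.n_samples < 4:
        raise ValueError("partitioning needs at least 4 samples")
    values = {s: float(row[s]) for s in mat.sample_ids}
    if len(set(values.values())) == 1:
        raise DegenerateInputError(f"proxy gene {proxy!r} has constant expression")
    # descending value, ties by sample id (stable, deterministic)
    ordered = sorted(mat.sample_ids, key=lambda s: (-values[s], s))
    v = np.array([values[s] for s in ordered])
    n = len(ordered)
    if fixed_n_high is not None:
        if not 1 <= fixed_n_high <= n - 1:
            raise ValueError(f"fixed_n_high must be in [1, {n - 1}]")
        split = fixed_n_high
        if v[split - 1] == v[split]:
            warnings.warn(
                f"tie at the fixed split boundary (value {v[split]:g}); "
                "resolved by sample-id order",
                stacklevel=2,
            )
        method_used = f"fixed_n_high={fixed_n_high}"
    else:
        gaps = v[:-1] - v[1:]  # gap[j] between positions j and j+1
        candidates = np.arange(1, n - 2)  # split after position j keeps >=2 per side
        best = candidates[np.argmax(gaps[candidates])]
        ties = candidates[gaps[candidates] == gaps[best]]
        if len(ties) > 1:
            warnings.warn(
                "multiple equally large gaps; split at the highest-expression "
                "gap (sample-id order breaks value ties)",
                stacklevel=2,
            )
        split = int(best) + 1
        method_used = method
    labels = {s: ("high" if i < split else "low") for i, s in enumerate(ordered)}
    return SamplePartition(proxy_gene=proxy, labels=labels, proxy_values=values, method=method_used)


# ----------------------------------------------------------------------
# Core statistics


def sam_d(high_values, low_values, s0: float = 0.0) -> tuple[float, float]:
    """Relative difference ``d`` and pooled scatter ``s`` for one gene."""
    x1 = np.asarray(high_values, dtype=float)
    x2 = np.asarray(low_values, dtype=float)
    n1, n2 = len(x1), len(x2)
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least 2 values")
    if s0 < 0:
        raise ValueError("s0 must be non-negative")
    ss = ((x1 - x1.mean()) ** 2).sum() + ((x2 - x2.mean()) ** 2).sum()
    s = float(np.sqrt((1.0 / n1 + 1.0 / n2) * ss / (n1 + n2 - 2)))
    if s + s0 == 0:
        raise DegenerateInputError("zero within-group scatter with s0 = 0")
    return float((x1.mean() - x2.mean()) / (s + s0)), s


def fold_change(mean_high: float, mean_low: float, scale: str = "log2") -> float:
    """Linear fold change between group means.

    On log2 data this is ``2 ** (mean_high - mean_low)`` — the ratio of
    geometric means.  On linear-scale data it is the plain ratio.
    """
    if scale == "log2":
        return float(2.0 ** (mean_high - mean_low))
    if scale == "linear":
        return float(mean_high / mean_low)
    raise ValueError(f"scale must be 'log2' or 'linear', got {scale!r}")


def _mad(x: np.ndarray) -> float:
    return float(np.median(np.abs(x - np.median(x))))


def choose_s0(
    numerators, s, grid: Sequence[float] = tuple(range(0, 101, 5))
) -> float:
    """Pick the fudge factor stabilizing the spread of ``d`` across ``s``.

    Candidates are the given percentiles of ``s``.  For each candidate the
    genes are binned into quartiles of ``s`` and the median absolute
    deviation of ``d = numerator / (s + s0)`` is computed per bin; the
    candidate minimizing the coefficient of variation of these MADs wins
    (ties: the smallest candidate).  Deterministic for fixed input.
    """
    numerators = np.asarray(numerators, dtype=float)
    s = np.asarray(s, dtype=float)
    if len(s) < 10:
        warnings.warn("fewer than 10 genes: falling back to s0 = median(s)", stacklevel=2)
        return float(np.median(s))
    candidates = np.percentile(s, np.asarray(grid, dtype=float))
    edges = np.percentile(s, [25, 50, 75])
    bins = np.digitize(s, edges)
    best_cv, best_s0 = np.inf, float(candidates[0])
    for cand in candidates:
        with np.errstate(divide="ignore", invalid="ignore"):
            d = numerators / (s + cand)
        mads = np.array([_mad(d[bins == b]) for b in range(4) if np.any(bins == b)])
        mean = mads.mean()
        cv = 0.0 if np.allclose(mads, mads[0]) else (mads.std() / mean if mean > 0 else np.inf)
        if cv < best_cv - 1e-15:
            best_cv, best_s0 = cv, float(cand)
    return best_s0


# ----------------------------------------------------------------------
# Configuration and result containers


@dataclass(frozen=True)
class SamConfig:
    """Knobs of the SAM permutation engine and calling rule."""

    n_permutations: int = 1000
    exhaustive_threshold: int = 50000
    seed: int = 0
    s0_percentiles: tuple[float, ...] = tuple(range(0, 101, 5))
    q_threshold: float = 0.05
    fc_threshold: float = 2.0
    s0: float | None = None  # None -> choose automatically

    def __post_init__(self) -> None:
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        if self.q_threshold <= 0 or self.fc_threshold <= 0:
            raise ValueError("thresholds must be positive")


@dataclass
class DEGene:
    gene: str
    d: float
    mean_high: float
    mean_low: float
    fold_change: float
    q_value: float
    significant_up: bool
    significant_down: bool
    degenerate: bool = False


# ----------------------------------------------------------------------
# The estimator


class SAMTwoClass(BaseEstimator):
    """Two-class unpaired SAM as a scikit-learn-style estimator.

    ``fit(X, y)`` expects ``X`` of shape ``(n_samples, n_genes)`` (log2
    intensities by default) and binary labels ``y`` (1/"high" = high
    group).  Fitted attributes follow sklearn conventions:

    - ``d_``, ``s_``, ``s0_`` — relative differences, pooled scatters and
      the selected fudge factor;
    - ``mean_high_``, ``mean_low_``, ``fold_change_``;
    - ``q_values_`` — permutation q-values, monotone non-increasing in
      ``|d|`` and capped at 1;
    - ``significant_up_`` / ``significant_down_`` — the q/FC calling rule;
    - ``degenerate_`` — boolean mask of genes with ``s + s0 = 0``
      (excluded from the null, reported rather than silently ranked);
    - ``exhaustive_``, ``n_permutations_`` — what the null actually was.

    Exhaustive nulls enumerate all distinct high-group labelings in
    lexicographic order and are seed-independent; sampled nulls draw
    ``n_permutations`` uniform labelings from ``random_state``.
    """

    def __init__(
        self,
        n_permutations: int = 1000,
        exhaustive_threshold: int = 50000,
        s0: float | None = None,
        s0_percentiles: tuple[float, ...] = tuple(range(0, 101, 5)),
        q_threshold: float = 0.05,
        fc_threshold: float = 2.0,
        scale: str = "log2",
        random_state: int = 0,
    ):
        self.n_permutations = n_permutations
        self.exhaustive_threshold = exhaustive_threshold
        self.s0 = s0
        self.s0_percentiles = s0_percentiles
        self.q_threshold = q_threshold
        self.fc_threshold = fc_threshold
        self.scale = scale
        self.random_state = random_state

    # -- internals ------------------------------------------------------

    @staticmethod
    def _group_stats(X: np.ndarray, high_mask: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-gene (mean_high, mean_low, pooled scatter s); X is genes x samples."""
        n1 = int(high_mask.sum())
        n2 = high_mask.size - n1
        m1 = X[:, high_mask].mean(axis=1)
        m2 = X[:, ~high_mask].mean(axis=1)
        ss1 = ((X[:, high_mask] - m1[:, None]) ** 2).sum(axis=1)
        ss2 = ((X[:, ~high_mask] - m2[:, None]) ** 2).sum(axis=1)
        s = np.sqrt((1.0 / n1 + 1.0 / n2) * (ss1 + ss2) / (n1 + n2 - 2))
        return m1, m2, s

    def _permuted_counts(
        self,
        X: np.ndarray,
        obs_abs_sorted: np.ndarray,
        n_high: int,
        s0: float,
        valid: np.ndarray,
    ) -> tuple[np.ndarray, bool, int]:
        """For each permutation, count null |d| values >= each observed |d|.

        Returns (counts with shape (n_valid_genes, n_perms), exhaustive
        flag, number of permutations).  Vectorized over permutation chunks
        via sums/sums-of-squares against a 0/1 labeling matrix.
        """
        G, n = X.shape
        n_total = comb(n, n_high)
        exhaustive = n_total <= self.exhaustive_threshold
        if exhaustive:
            def labelings():
                for combo in itertools.combinations(range(n), n_high):
                    yield combo
            n_perms = n_total
        else:
            rng = np.random.default_rng(self.random_state)
            def labelings():
                for _ in range(self.n_permutations):
                    yield tuple(rng.permutation(n)[:n_high])
            n_perms = self.n_permutations
        if n_perms < 10:
            raise ValueError(f"only {n_perms} permutations available; at least 10 required")

        Xv = X[valid]
        Gv = Xv.shape[0]
        Xsq = Xv**2
        tot = Xv.sum(axis=1, keepdims=True)
        tot_sq = Xsq.sum(axis=1, keepdims=True)
        n1, n2 = n_high, n - n_high
        coef = (1.0 / n1 + 1.0 / n2) / (n - 2)

        # keep the per-chunk working set small; large blocks thrash memory
        chunk = int(np.clip(2_000_000 // max(Gv, 1), 64, 8192))
        counts = np.empty((Gv, n_perms), dtype=np.int32)
        queries = obs_abs_sorted  # ascending observed |d|
        it = labelings()
        done = 0
        while done < n_perms:
            block = list(itertools.islice(it, chunk))
            if not block:
                break
            B = len(block)
            idx = np.asarray(block, dtype=np.intp)  # (B, n_high)
            Z = np.zeros((n, B))
            Z[idx.T, np.arange(B)[None, :]] = 1.0
            S1 = Xv @ Z
            Q1 = Xsq @ Z
            M1 = S1 / n1
            M2 = (tot - S1) / n2
            SS = (Q1 - n1 * M1**2) + ((tot_sq - Q1) - n2 * M2**2)
            np.maximum(SS, 0.0, out=SS)
            dstar = np.abs((M1 - M2) / (np.sqrt(coef * SS) + s0))
            dstar.sort(axis=0)  # ascending per permutation
            for b in range(B):
                counts[:, done + b] = Gv - np.searchsorted(dstar[:, b], queries, side="left")
            done += B
        return counts, exhaustive, n_perms

    # -- API ------------------------------------------------------------

    def fit(self, X, y, *, gene_names: Sequence[str] | None = None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-D (n_samples, n_genes)")
        y = np.asarray(y)
        if y.shape[0] != X.shape[0]:
            raise ValueError("y length must match the number of samples")
        if y.dtype.kind in "biuf":
            high_mask = y.astype(float) == 1.0
        else:
            high_mask = np.isin(np.char.lower(y.astype(str)), ["1", "high", "true"])
        n_high = int(high_mask.sum())
        n_low = int((~high_mask).sum())
        if n_high < 2 or n_low < 2:
            raise ValueError("each group needs at least 2 samples")
        Xg = X.T  # genes x samples
        G = Xg.shape[0]
        if gene_names is None:
            gene_names = [f"g{i}" for i in range(G)]
        if len(gene_names) != G:
            raise ValueError("gene_names length must match X's gene axis")

        m1, m2, s = self._group_stats(Xg, high_mask)
        numerators = m1 - m2
        if self.s0 is not None:
            s0 = float(self.s0)
        else:
            s0 = choose_s0(numerators, s, self.s0_percentiles)
        valid = (s + s0) > 0
        d = np.full(G, np.nan)
        with np.errstate(divide="ignore", invalid="ignore"):
            d[valid] = numerators[valid] / (s[valid] + s0)

        obs_abs = np.abs(d[valid])
        order = np.argsort(obs_abs, kind="stable")
        counts_sorted, exhaustive, n_perms = self._permuted_counts(
            Xg, obs_abs[order], n_high, s0, valid
        )
        med_sorted = np.median(counts_sorted, axis=1)
        med = np.empty_like(med_sorted)
        med[order] = med_sorted
        Gv = int(valid.sum())
        # rank: number of observed |d| >= each gene's |d| (1 = most extreme)
        rank = Gv - np.searchsorted(obs_abs[order], obs_abs, side="left")
        q_raw = np.minimum(med / rank, 1.0)
        # monotonize: larger |d| never gets a larger q
        desc = np.argsort(-obs_abs, kind="stable")
        q_mono = np.maximum.accumulate(q_raw[desc])
        q_valid = np.empty_like(q_raw)
        q_valid[desc] = q_mono
        q = np.full(G, np.nan)
        q[valid] = np.minimum(q_valid, 1.0)
        # degenerate genes: infinite-|d| semantics, flagged not ranked
        q[~valid] = 0.0

        fc = np.array([fold_change(a, b, self.scale) for a, b in zip(m1, m2)])
        self.gene_names_ = list(gene_names)
        self.d_ = d
        self.s_ = s
        self.s0_ = s0
        self.mean_high_ = m1
        self.mean_low_ = m2
        self.fold_change_ = fc
        self.q_values_ = q
        self.degenerate_ = ~valid
        self.significant_up_ = valid & (q < self.q_threshold) & (fc > self.fc_threshold)
        self.significant_down_ = valid & (q < self.q_threshold) & (fc < 1.0 / self.fc_threshold)
        self.exhaustive_ = exhaustive
        self.n_permutations_ = n_perms
        self.n_high_ = n_high
        self.n_low_ = n_low
        return self

    def results_(self) -> list[DEGene]:
        """Fitted results as one :class:`DEGene` per gene, input order."""
        return [
            DEGene(
                gene=self.gene_names_[i],
                d=float(self.d_[i]) if not self.degenerate_[i] else float("nan"),
                mean_high=float(self.mean_high_[i]),
                mean_low=float(self.mean_low_[i]),
                fold_change=float(self.fold_change_[i]),
                q_value=float(self.q_values_[i]),
                significant_up=bool(self.significant_up_[i]),
                significant_down=bool(self.significant_down_[i]),
                degenerate=bool(self.degenerate_[i]),
            )
            for i in range(len(self.gene_names_))
        ]


# ----------------------------------------------------------------------
# Matrix-level wrappers


def _check_alignment(mat: ExpressionMatrix, partition: SamplePartition) -> None:
    mat_samples = set(mat.sample_ids)
    part_samples = set(partition.labels)
    if mat_samples != part_samples:
        missing = sorted(part_samples - mat_samples)
        extra = sorted(mat_samples - part_samples)
        raise AlignmentError(
            f"partition/matrix sample mismatch: partition-only {missing}, matrix-only {extra}"
        )


def sam_qvalues(
    mat: ExpressionMatrix, partition: SamplePartition, config: SamConfig | None = None
) -> list[DEGene]:
    """Run SAM on ``mat`` under ``partition``; one DEGene per probe row.

    Rows are labelled by their annotated gene symbol where available,
    falling back to the probe id (probe-set-level analysis is the
    default; collapse first for gene-level results).
    """
    config = config or SamConfig()
    _check_alignment(mat, partition)
    y = np.array([1 if partition.labels[s] == "high" else 0 for s in mat.sample_ids])
    names = [mat.annotation.get(p, p) for p in mat.data.index]
    est = SAMTwoClass(
        n_permutations=config.n_permutations,
        exhaustive_threshold=config.exhaustive_threshold,
        s0=config.s0,
        s0_percentiles=config.s0_percentiles,
        q_threshold=config.q_threshold,
        fc_threshold=config.fc_threshold,
        scale=mat.scale,
        random_state=config.seed,
    ).fit(mat.data.to_numpy().T, y, gene_names=names)
    return est.results_()


def de_to_frame(de: list[DEGene]) -> pd.DataFrame:
    def call(g: DEGene) -> str:
        if g.significant_up:
            return "up"
        if g.significant_down:
            return "down"
        return "ns"

    return pd.DataFrame(
        {
            "gene": [g.gene for g in de],
            "d": [g.d for g in de],
            "mean_high": [g.mean_high for g in de],
            "mean_low": [g.mean_low for g in de],
            "fold_change": [g.fold_change for g in de],
            "q_value": [g.q_value for g in de],
            "call": [call(g) for g in de],
        }
    )


def tf_panel_report(de: list[DEGene], panel: NamedGeneList) -> pd.DataFrame:
    """Fold change / q-value / call for each EMT transcription factor in
    ``panel``; absent genes are flagged missing."""
    by_gene = {g.gene.upper(): g for g in de}
    rows = []
    for symbol in panel:
        hit = by_gene.get(symbol.upper())
        if hit is None:
            rows.append(
                {"gene": symbol, "fold_change": np.nan, "q_value": np.nan,
                 "significant_up": False, "missing": True}
            )
        else:
            rows.append(
                {"gene": symbol, "fold_change": hit.fold_change, "q_value": hit.q_value,
                 "significant_up": hit.significant_up, "missing": False}
            )
    return pd.DataFrame(rows)
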