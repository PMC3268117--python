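"""Synthetic paired human/mouse xenograft expression matrices.

The generator emulates the statistical structure of an 18-tumor xenograft
experiment profiled with species-specific arrays: a single continuous
latent mesenchymal-activity gradient ``a_s`` drives (i) coordinated
overexpression of the 64 planted human signature genes and (ii)
downregulation of a mouse adipocyte-marker cluster, while transfection
labels (INHBA / FST / control) shift only the transfected human gene.

All quantities live in log2 space:

    human signature gene g:   x_gs = beta_g + lambda_g * a_s + eps
    human background gene:    x_gs = beta_g + eps
    mouse adipocyte gene:     y_gs = beta_g - slope_g * a_s + eps
    mouse background:         y_gs = beta_g + eps

with ``eps ~ Normal(0, noise_sd)``, baselines ``beta_g ~ Uniform(baseline
range)`` and loadings ``lambda_g ~ Normal(loading mean, loading sd)``
truncated at zero.  Activities are drawn with a deliberate gap —
high samples ~ Uniform(0.7, 1.0), low ~ Uniform(0.0, 0.45) — so the
largest-gap partition rule is well defined at low noise while expression
still covers a continuous range within each group.

Default effect sizes are anchored to the fold changes such an experiment
reports: a loading of 3.0 gives a typical planted between-group fold
change of 2^(3.0 * 0.625) ~ 3.7 (the observed SNAI2 fold change of 5.22
corresponds to lambda ~ 3.8), and the adipocyte slope of 4.0 gives ~ 5.7x
downregulation (the top observed adipocyte fold changes, 12.3 and 11.8,
correspond to slopes ~ 5.8).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import GeneLookupError
from .matrix import ExpressionMatrix
from .signature import SignatureDefinition, load_signature

#: Expected difference between mean high-group and mean low-group activity:
#: E[U(0.7, 1.0)] - E[U(0.0, 0.45)] = 0.85 - 0.225.
EXPECTED_ACTIVITY_GAP = 0.625

#: Activity interval for high/intermediate samples and for low samples.
HIGH_ACTIVITY_RANGE = (0.7, 1.0)
LOW_ACTIVITY_RANGE = (0.0, 0.45)

#: Mouse adipocyte markers planted by default (mouse-cased symbols).
DEFAULT_ADIPOCYTE_GENES = ("Adipoq", "Cfd", "Fabp4")

#: EMT transcription factors planted as inert background rows so panel
#: reports have something to look at (SNAI2 itself is a signature gene).
_TF_BACKGROUND = ("SNAI1", "TWIST1", "ZEB1", "ZEB2", "FOXC2")


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the generative model; defaults are the stated world."""

    n_samples: int = 18
    n_human_genes: int = 5000
    n_mouse_genes: int = 5000
    n_high: int = 7
    n_low: int = 11
    signature_loading_mean: float = 3.0  # log2 units per unit activity
    loading_sd: float = 0.3
    noise_sd: float = 0.5  # log2 units
    adipocyte_slope: float = 4.0  # log2 downregulation per unit activity
    baseline_range: tuple[float, float] = (4.0, 12.0)
    transfection_counts: tuple[tuple[str, int], ...] = (
        ("INHBA", 7),
        ("FST", 6),
        ("control", 5),
    )
    transfection_boost: float = 3.0  # log2 shift on the transfected gene
    adipocyte_extra_genes: tuple[str, ...] = ()
    loading_overrides: tuple[tuple[str, float], ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_high <= 0 or self.n_low <= 0:
            raise ValueError("n_high and n_low must both be positive")
        if self.n_high + self.n_low != self.n_samples:
            raise ValueError("n_high + n_low must equal n_samples")
        if self.noise_sd < 0 or self.loading_sd < 0:
            raise ValueError("standard deviations must be non-negative")
        if sum(n for _, n in self.transfection_counts) != self.n_samples:
            raise ValueError("transfection counts must sum to n_samples")
        if self.n_human_genes < 64 + 1 + len(_TF_BACKGROUND):
            raise ValueError("n_human_genes too small to host the planted genes")
        if self.n_mouse_genes < 3 + len(self.adipocyte_extra_genes):
            raise ValueError("n_mouse_genes too small to host the adipocyte cluster")

    def override_for(self, symbol: str) -> float | None:
        for g, v in self.loading_overrides:
            if g.upper() == symbol.upper():
                return v
        return None


@dataclass
class SyntheticTruth:
    """Everything the generator drew, for downstream recovery checks."""

    activity: dict[str, float]
    group: dict[str, str]  # sample -> high/low
    planted_signature_genes: list[str]
    loadings: dict[str, float]  # gene -> lambda (human) or slope (mouse)
    planted_adipocyte_genes: list[str]
    planted_fold_changes: dict[str, float]  # gene -> intended linear FC (high/low)
    realized_fold_changes: dict[str, float]  # gene -> FC implied by the drawn activities
    transfection: dict[str, str]


def plant_fold_change(config: SimulationConfig, gene: str, fc: float) -> SimulationConfig:
    """Return a config whose loading for ``gene`` yields the target linear
    fold change between the planted groups (in expectation).

    For a human signature gene the planted loading is ``log2(fc) /
    E[a_high - a_low]``; for a mouse adipocyte gene ``fc`` is the
    downregulation magnitude and sets the slope the same way.
    """
    if not fc > 0:
        raise ValueError(f"fold change must be positive, got {fc}")
    sig_symbols = {s.upper() for s in load_signature().gene_symbols}
    adipo = {s.upper() for s in DEFAULT_ADIPOCYTE_GENES + config.adipocyte_extra_genes}
    if gene.upper() not in sig_symbols | adipo:
        raise GeneLookupError(f"gene {gene!r} is not a planted gene of either species")
    loading = float(np.log2(fc) / EXPECTED_ACTIVITY_GAP)
    overrides = tuple((g, v) for g, v in config.loading_overrides if g.upper() != gene.upper())
    return dataclasses.replace(config, loading_overrides=overrides + ((gene, loading),))


def generate_xenograft(
    config: SimulationConfig | None = None,
    signature: SignatureDefinition | None = None,
) -> tuple[ExpressionMatrix, ExpressionMatrix, SyntheticTruth]:
    """Draw one synthetic experiment.

    Returns the human matrix, the mouse matrix (shared sample ids) and the
    truth table.  All randomness flows from ``config.seed``; the same seed
    reproduces the same experiment bit for bit.
    """
    config = config or SimulationConfig()
    signature = signature or load_signature()
    rng = np.random.default_rng(config.seed)
    n = config.n_samples
    width = max(2, len(str(n)))
    samples = [f"S{i + 1:0{width}d}" for i in range(n)]

    # latent activity with a planted gap
    group_labels = np.array(["low"] * n, dtype=object)
    high_idx = rng.choice(n, size=config.n_high, replace=False)
    group_labels[high_idx] = "high"
    activity = np.where(
        group_labels == "high",
        rng.uniform(*HIGH_ACTIVITY_RANGE, size=n),
        rng.uniform(*LOW_ACTIVITY_RANGE, size=n),
    )

    # transfection labels, independent of activity
    tf_pool = [label for label, count in config.transfection_counts for _ in range(count)]
    transfection = list(np.array(tf_pool, dtype=object)[rng.permutation(n)])

    sig_symbols = list(signature.gene_symbols)
    loadings_sig = np.maximum(
        rng.normal(config.signature_loading_mean, config.loading_sd, size=len(sig_symbols)), 0.0
    )
    for i, s in enumerate(sig_symbols):
        override = config.override_for(s)
        if override is not None:
            loadings_sig[i] = override

    # human matrix: signature genes, FST, TF-panel backgrounds, filler
    n_named = len(sig_symbols) + 1 + len(_TF_BACKGROUND)
    n_filler_h = config.n_human_genes - n_named
    human_genes = sig_symbols + ["FST"] + list(_TF_BACKGROUND) + [
        f"HSBG{i + 1:05d}" for i in range(n_filler_h)
    ]
    lam = np.zeros(len(human_genes))
    lam[: len(sig_symbols)] = loadings_sig
    beta_h = rng.uniform(*config.baseline_range, size=len(human_genes))
    x = beta_h[:, None] + lam[:, None] * activity[None, :]
    x += rng.normal(0.0, config.noise_sd, size=x.shape)
    # transfections touch only the transfected gene's human row
    tf_arr = np.asarray(transfection, dtype=object)
    x[human_genes.index("INHBA"), tf_arr == "INHBA"] += config.transfection_boost
    x[human_genes.index("FST"), tf_arr == "FST"] += config.transfection_boost

    # mouse matrix: adipocyte cluster + filler
    adipo_genes = list(DEFAULT_ADIPOCYTE_GENES) + list(config.adipocyte_extra_genes)
    n_filler_m = config.n_mouse_genes - len(adipo_genes)
    mouse_genes = adipo_genes + [f"MmBg{i + 1:05d}" for i in range(n_filler_m)]
    slope = np.zeros(len(mouse_genes))
    for i, g in enumerate(adipo_genes):
        override = config.override_for(g)
        slope[i] = config.adipocyte_slope if override is None else override
    beta_m = rng.uniform(*config.baseline_range, size=len(mouse_genes))
    y = beta_m[:, None] - slope[:, None] * activity[None, :]
    y += rng.normal(0.0, config.noise_sd, size=y.shape)

    human = ExpressionMatrix(
        pd.DataFrame(x, index=[f"HS_{g}" for g in human_genes], columns=samples),
        species="human",
        annotation={f"HS_{g}": g for g in human_genes},
    )
    mouse = ExpressionMatrix(
        pd.DataFrame(y, index=[f"MM_{g}" for g in mouse_genes], columns=samples),
        species="mouse",
        annotation={f"MM_{g}": g for g in mouse_genes},
    )

    loadings = {g: float(l) for g, l in zip(sig_symbols, loadings_sig)}
    loadings.update({g: float(s) for g, s in zip(adipo_genes, slope)})
    fc = {g: float(2.0 ** (l * EXPECTED_ACTIVITY_GAP)) for g, l in zip(sig_symbols, loadings_sig)}
    fc.update(
        {g: float(2.0 ** (-s * EXPECTED_ACTIVITY_GAP)) for g, s in zip(adipo_genes, slope)}
    )
    # the fold change actually planted in this draw: the intended one scaled
    # by the realized (not expected) between-group activity gap
    realized_gap = float(
        activity[group_labels == "high"].mean() - activity[group_labels == "low"].mean()
    )
    rfc = {g: float(2.0 ** (l * realized_gap)) for g, l in zip(sig_symbols, loadings_sig)}
    rfc.update({g: float(2.0 ** (-s * realized_gap)) for g, s in zip(adipo_genes, slope)})
    truth = SyntheticTruth(
        activity={s: float(a) for s, a in zip(samples, activity)},
        group={s: str(g) for s, g in zip(samples, group_labels)},
        planted_signature_genes=sig_symbols,
        loadings=loadings,
        planted_adipocyte_genes=adipo_genes,
        planted_fold_changes=fc,
        realized_fold_changes=rfc,
        transfection={s: str(t) for s, t in zip(samples, transfection)},
    )
    return human, mouse, truth


def export_truth(truth: SyntheticTruth, out_dir: str | Path) -> tuple[Path, Path]:
    """Write per-sample and per-gene truth tables; returns the two paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    samples_path = out_dir / "truth_samples.tsv"
    genes_path = out_dir / "truth_genes.tsv"
    pd.DataFrame(
        {
            "sample_id": list(truth.activity),
            "activity": [repr(truth.activity[s]) for s in truth.activity],
            "group": [truth.group[s] for s in truth.activity],
            "transfection": [truth.transfection[s] for s in truth.activity],
        }
    ).to_csv(samples_path, sep="\t", index=False)
    genes = truth.planted_signature_genes + truth.planted_adipocyte_genes
    pd.DataFrame(
        {
            "gene": genes,
            "species": ["human"] * len(truth.planted_signature_genes)
            + ["mouse"] * len(truth.planted_adipocyte_genes),
            "loading": [repr(truth.loadings[g]) for g in genes],
            "planted_fold_change": [repr(truth.planted_fold_changes[g]) for g in genes],
            "realized_fold_change": [repr(truth.realized_fold_changes[g]) for g in genes],
        }
    ).to_csv(genes_path, sep="\t", index=False)
    return samples_path, genes_path


def load_truth(out_dir: str | Path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read back the two truth tables written by :func:`export_truth`."""
    out_dir = Path(out_dir)
    per_sample = pd.read_csv(out_dir / "truth_samples.tsv", sep="\t")
    per_gene = pd.read_csv(out_dir / "truth_genes.tsv", sep="\t")
    return per_sample, per_gene
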