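"""End-to-end orchestration: ranking, partitioning, two-species SAM,
enrichment, association and the combined heat-map-style report."""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .coexpression import AssociationRanking, pearson_with_proxy
from .enrichment import (
    EnrichmentResult,
    adipocyte_association,
    mouse_down_analysis,
    signature_enrichment,
    signature_score,
)
from .errors import AlignmentError, XenosigError
from .matrix import ExpressionMatrix
from .sam import DEGene, SamConfig, SamplePartition, de_to_frame, partition_by_proxy, sam_qvalues
from .signature import NamedGeneList, SignatureDefinition, load_gene_list, load_signature


@dataclass
class CrossSpeciesReport:
    """Everything the combined human/mouse analysis produces."""

    ranking: AssociationRanking
    partition: SamplePartition
    human_de: list[DEGene]
    mouse_de: list[DEGene]  # significant_down, sorted by ascending FC
    signature_overlap: EnrichmentResult
    adipocyte_association: float
    human_score: dict[str, float]
    heatmap_sample_order: list[str]
    heatmap_human_genes: list[str]
    heatmap_mouse_genes: list[str]

    @property
    def human_up(self) -> list[DEGene]:
        return [g for g in self.human_de if g.significant_up]


class PipelineStageError(XenosigError):
    """Wraps a failure with the pipeline stage it occurred in."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"[stage {stage}] {cause}")
        self.stage = stage
        self.cause = cause


def run_pipeline(
    human: ExpressionMatrix,
    mouse: ExpressionMatrix,
    sig: SignatureDefinition | None = None,
    config: SamConfig | None = None,
    proxy: str = "COL11A1",
    fixed_n_high: int | None = None,
    universe_size: int | None = None,
    adipocyte_markers: NamedGeneList | None = None,
    out_dir: str | Path | None = None,
) -> CrossSpeciesReport:
    """Run the whole cross-species analysis.

    Stages: Pearson ranking against the proxy -> sample partition by proxy
    expression -> human SAM up-calls -> hypergeometric enrichment of the
    up-calls against the signature (universe defaults to the number of
    human genes analyzed) -> mouse downregulation under the human
    partition -> adipocyte-marker association -> heat-map ordering
    (samples by descending human signature score; human gene block by
    signature rank, mouse block by ascending fold change).

    When ``out_dir`` is given, all artifact tables plus a JSON run log are
    written there.
    """
    sig = sig or load_signature()
    config = config or SamConfig()
    markers = adipocyte_markers or load_gene_list("adipocyte_markers")

    if set(human.sample_ids) != set(mouse.sample_ids):
        raise AlignmentError(
            "human and mouse matrices must share sample ids; "
            f"human-only {sorted(set(human.sample_ids) - set(mouse.sample_ids))}, "
            f"mouse-only {sorted(set(mouse.sample_ids) - set(human.sample_ids))}"
        )

    def stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:  # tag errors with the stage they came from
            raise PipelineStageError(name, exc) from exc

    ranking = stage("rank", pearson_with_proxy, human, proxy)
    partition = stage(
        "partition", partition_by_proxy, human, proxy, fixed_n_high=fixed_n_high
    )
    human_de = stage("human_de", sam_qvalues, human, partition, config)
    up_genes = [g.gene for g in human_de if g.significant_up]
    N = universe_size if universe_size is not None else len(human_de)
    overlap = stage("enrichment", signature_enrichment, up_genes, sig, N)
    mouse_ordered = ExpressionMatrix(
        mouse.data[human.sample_ids], species=mouse.species,
        annotation=mouse.annotation, scale=mouse.scale,
    )
    mouse_down = stage("mouse_de", mouse_down_analysis, mouse_ordered, partition, config)
    score = stage("score", signature_score, human, sig)
    assoc = stage("association", adipocyte_association, mouse_ordered, markers, score)

    score_by_sample = dict(zip(human.sample_ids, map(float, score)))
    sample_order = sorted(
        human.sample_ids, key=lambda s: (-score_by_sample[s], s)
    )
    sig_in_matrix = [s for s in sig.gene_symbols if human.has_gene(s)]
    heat_mouse = [g.gene for g in mouse_down]

    report = CrossSpeciesReport(
        ranking=ranking,
        partition=partition,
        human_de=human_de,
        mouse_de=mouse_down,
        signature_overlap=overlap,
        adipocyte_association=assoc,
        human_score=score_by_sample,
        heatmap_sample_order=sample_order,
        heatmap_human_genes=sig_in_matrix,
        heatmap_mouse_genes=heat_mouse,
    )
    if out_dir is not None:
        write_report(report, out_dir, config)
    return report


def write_report(report: CrossSpeciesReport, out_dir: str | Path, config: SamConfig) -> Path:
    """Write the artifact bundle: DE tables for both species, enrichment,
    association, heat-map ordering and a run log."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    de_to_frame(report.human_de).to_csv(out_dir / "de_human.tsv", sep="\t", index=False)
    de_to_frame(report.mouse_de).to_csv(out_dir / "de_mouse.tsv", sep="\t", index=False)
    ov = report.signature_overlap
    pd.DataFrame(
        [{"k": ov.k, "n": ov.n, "K": ov.K, "N": ov.N, "p_tail": ov.p_tail}]
    ).to_csv(out_dir / "enrichment.tsv", sep="\t", index=False)
    pd.DataFrame(
        [{"adipocyte_association": report.adipocyte_association}]
    ).to_csv(out_dir / "association.tsv", sep="\t", index=False)
    report.partition.to_frame().to_csv(out_dir / "partition.tsv", sep="\t", index=False)
    order_rows = (
        [{"block": "sample", "name": s, "position": i}
         for i, s in enumerate(report.heatmap_sample_order)]
        + [{"block": "human_gene", "name": g, "position": i}
           for i, g in enumerate(report.heatmap_human_genes)]
        + [{"block": "mouse_gene", "name": g, "position": i}
           for i, g in enumerate(report.heatmap_mouse_genes)]
    )
    pd.DataFrame(order_rows).to_csv(out_dir / "heatmap_order.tsv", sep="\t", index=False)
    log = {
        "proxy": report.partition.proxy_gene,
        "partition_method": report.partition.method,
        "n_high": len(report.partition.high),
        "n_low": len(report.partition.low),
        "n_human_up": len(report.human_up),
        "n_mouse_down": len(report.mouse_de),
        "enrichment": {"k": ov.k, "n": ov.n, "K": ov.K, "N": ov.N, "p_tail": ov.p_tail},
        "adipocyte_association": report.adipocyte_association,
        "sam_config": {
            "n_permutations": config.n_permutations,
            "exhaustive_threshold": config.exhaustive_threshold,
            "seed": config.seed,
            "q_threshold": config.q_threshold,
            "fc_threshold": config.fc_threshold,
        },
    }
    (out_dir / "run_log.json").write_text(json.dumps(log, indent=2))
    return out_dir
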