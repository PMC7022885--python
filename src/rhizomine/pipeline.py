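"""End-to-end pipeline: alignment hits to community statistics.

Stage order mirrors the analysis the package implements: per-sample
read assignment, contaminant-lineage removal, low-abundance filtering,
rank aggregation, median-of-ratios normalization, then the multivariate
layer (Bray-Curtis, PERMANOVA, NMDS).  Every table is written with a
provenance header carrying the config hash and seed, and the whole run
is deterministic: re-running with identical inputs and config yields
byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Union

import pandas as pd

from . import __version__
from .community_stats import bray_curtis, nmds, permanova
from .io import (
    PathLike,
    provenance_header,
    read_alignment_tsv,
    read_count_table,
    read_metadata,
    write_count_table,
)
from .read_assignment import profile_sample
from .tables import (
    CountTable,
    aggregate_at_rank,
    low_abundance_filter,
    normalize,
    remove_contaminant_lineages,
    size_factors,
)
from .taxonomy import (
    METAZOA_TAXID,
    VIRIDIPLANTAE_TAXID,
    TaxonomyTree,
    load_taxonomy,
    load_taxonomy_tsv,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All tunables of the pipeline, serialized alongside every output.

    Defaults are the thresholds the analysis is defined by: 97% identity
    for read assignment, the >=5-reads-in->=3-libraries abundance rule,
    family-level aggregation, 999 permutations at alpha 0.05, pathway
    enrichment at p < 0.1.
    """

    min_identity: float = 97.0
    score_margin: float = 0.0
    flank: int = 50
    min_count: int = 5
    min_samples: int = 3
    exclude_root_taxids: tuple[int, ...] = (VIRIDIPLANTAE_TAXID, METAZOA_TAXID)
    rank: str = "family"
    n_perm: int = 999
    alpha: float = 0.05
    enrichment_p: float = 0.1
    seed: int = 0
    size_factor_pseudocount: float = 0.0

    def __post_init__(self):
        if not 0 <= self.min_identity <= 100:
            raise ValueError("min_identity outside [0, 100]")
        if self.flank < 0 or self.min_count < 0 or self.min_samples < 1:
            raise ValueError("negative threshold in config")
        if self.n_perm < 0:
            raise ValueError("n_perm must be non-negative")
        if not 0 < self.alpha < 1 or not 0 < self.enrichment_p <= 1:
            raise ValueError("alpha and enrichment_p must be in (0, 1)")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["exclude_root_taxids"] = list(self.exclude_root_taxids)
        return d


@dataclass
class PipelineInputs:
    """File locations; ``alignments`` maps sample id to its hit TSV."""

    alignments: Mapping[str, PathLike]
    metadata: PathLike
    taxonomy_tsv: Optional[PathLike] = None
    taxonomy_nodes: Optional[PathLike] = None
    taxonomy_names: Optional[PathLike] = None


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the cause."""


def _load_tree(inputs: PipelineInputs) -> TaxonomyTree:
    if inputs.taxonomy_tsv is not None:
        return load_taxonomy_tsv(inputs.taxonomy_tsv)
    if inputs.taxonomy_nodes is not None:
        return load_taxonomy(inputs.taxonomy_nodes, inputs.taxonomy_names)
    raise FileNotFoundError("no taxonomy source given (taxonomy_tsv or taxonomy_nodes)")


def run_pipeline(
    inputs: PipelineInputs,
    config: PipelineConfig,
    outdir: PathLike,
) -> Path:
    """Execute every stage and write all artifacts under ``outdir``.

    Returns the output directory.  Any stage failure is re-raised as
    :class:`PipelineError` naming the stage.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg_dict = config.to_dict()
    stage_log: list[str] = []

    def run_stage(name: str, fn):
        stage_log.append(name)
        logger.info("stage: %s", name)
        try:
            return fn()
        except Exception as exc:
            raise PipelineError(f"stage {name!r} failed: {exc}") from exc

    for sample, path in inputs.alignments.items():
        if not Path(path).exists():
            raise FileNotFoundError(f"alignment file for sample {sample!r}: {path}")
    meta_path = Path(inputs.metadata)
    if not meta_path.exists():
        raise FileNotFoundError(f"metadata file not found: {meta_path}")
    tax_source = inputs.taxonomy_tsv or inputs.taxonomy_nodes
    if tax_source is None:
        raise FileNotFoundError(
            "no taxonomy source given (taxonomy_tsv or taxonomy_nodes)"
        )
    if not Path(tax_source).exists():
        raise FileNotFoundError(f"taxonomy file not found: {tax_source}")

    tree = run_stage("load_taxonomy", lambda: _load_tree(inputs))
    meta = run_stage("load_metadata", lambda: read_metadata(inputs.metadata))

    def assign_all() -> tuple[pd.DataFrame, dict[str, int]]:
        columns = {}
        unassigned = {}
        for sample in sorted(inputs.alignments):
            hits = read_alignment_tsv(inputs.alignments[sample])
            hits = sorted(hits, key=lambda h: h.read_id)
            counts, n_un = profile_sample(
                hits,
                tree,
                min_identity=config.min_identity,
                score_margin=config.score_margin,
            )
            columns[sample] = counts
            unassigned[sample] = n_un
        frame = pd.DataFrame(columns).fillna(0).astype(int)
        frame = frame.sort_index()
        return frame, unassigned

    raw_frame, unassigned = run_stage("assign", assign_all)
    raw = CountTable(raw_frame, meta)

    decontaminated = run_stage(
        "contaminant_filter",
        lambda: remove_contaminant_lineages(raw, tree, config.exclude_root_taxids),
    )
    abundant = run_stage(
        "low_abundance_filter",
        lambda: low_abundance_filter(
            decontaminated, min_count=config.min_count, min_samples=config.min_samples
        ),
    )
    aggregated = run_stage(
        "aggregate", lambda: aggregate_at_rank(abundant, tree, rank=config.rank)
    )

    def normalize_stage():
        table = aggregated
        if config.size_factor_pseudocount > 0:
            padded = CountTable(
                table.counts + int(config.size_factor_pseudocount), table.sample_meta
            )
            factors = size_factors(padded)
        else:
            factors = size_factors(table)
        return factors, normalize(table, factors)

    factors, normalized = run_stage("normalize", normalize_stage)

    distances = run_stage("bray_curtis", lambda: bray_curtis(normalized))
    permanova_table = run_stage(
        "permanova",
        lambda: permanova(
            distances,
            meta,
            terms=("genotype", "soil", "genotype:soil"),
            n_perm=config.n_perm,
            seed=config.seed,
        ),
    )
    ordination = run_stage(
        "nmds", lambda: nmds(distances, k=2, n_starts=8, seed=config.seed)
    )

    def write_all():
        write_count_table(raw.counts, outdir / "raw_counts.tsv", cfg_dict, config.seed)
        write_count_table(
            abundant.counts, outdir / "filtered_counts.tsv", cfg_dict, config.seed
        )
        write_count_table(
            aggregated.counts,
            outdir / f"{config.rank}_counts.tsv",
            cfg_dict,
            config.seed,
        )
        write_count_table(
            factors.to_frame(),
            outdir / "size_factors.tsv",
            cfg_dict,
            config.seed,
            index_label="sample",
        )
        write_count_table(
            normalized, outdir / "normalized_counts.tsv", cfg_dict, config.seed
        )
        write_count_table(
            distances.to_frame(),
            outdir / "bray_curtis.tsv",
            cfg_dict,
            config.seed,
            index_label="sample",
        )
        write_count_table(
            permanova_table, outdir / "permanova.tsv", cfg_dict, config.seed,
            index_label="term",
        )
        with open(outdir / "nmds.tsv", "w") as handle:
            handle.write(provenance_header(cfg_dict, config.seed))
            handle.write(f"# stress={ordination.stress!r}\n")
            ordination.coordinates.to_csv(
                handle, sep="\t", index_label="sample", lineterminator="\n"
            )
        summary = {
            "version": __version__,
            "stages": stage_log,
            "n_samples": raw.n_samples,
            "n_taxa_raw": raw.n_features,
            "n_taxa_filtered": abundant.n_features,
            "n_features_aggregated": aggregated.n_features,
            "unassigned_reads": unassigned,
            "assigned_reads": {
                s: int(raw.counts[s].sum()) for s in raw.samples
            },
            "nmds_stress": ordination.stress,
        }
        (outdir / "summary.json").write_text(
            json.dumps(summary, indent=2, sort_keys=True) + "\n"
        )
        (outdir / "config.json").write_text(
            json.dumps(cfg_dict, indent=2, sort_keys=True) + "\n"
        )
        (outdir / "stages.log").write_text("\n".join(stage_log) + "\n")

    run_stage("write_outputs", write_all)
    return outdir
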