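"""End-to-end drivers: de novo library construction and its evaluation.

The de novo phase is the three-step approach (self-alignment, clustering,
consensus) run with the three clustering strategies in parallel, followed
by classification and classification-aware redundancy removal.  The
evaluation phase rebuilds a knowledge-based library from reference
ancestors and compares the two.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

from .classify import (
    Classification,
    LengthRanges,
    classify_consensus,
    compute_features,
    remove_redundancy,
)
from .clustering import (
    GrouperParams,
    PilerParams,
    ReconParams,
    chain_matches,
    filter_clusters,
    grouper_cluster,
    piler_cluster,
    recon_like_cluster,
)
from .consensus import MsaParams, build_library
from .core_io import GenomeSet
from .selfalign import SelfAlignParams, filter_long_matches, self_align

log = logging.getLogger("teforge")

METHODS = ("grouper", "recon", "piler")


@dataclass
class PipelineConfig:
    selfalign: SelfAlignParams = field(default_factory=SelfAlignParams)
    grouper: GrouperParams = field(default_factory=GrouperParams)
    recon: ReconParams = field(default_factory=ReconParams)
    piler: PilerParams = field(default_factory=PilerParams)
    msa: MsaParams = field(default_factory=MsaParams)
    ranges: LengthRanges = field(default_factory=LengthRanges)


def cluster_genome(
    genome: GenomeSet,
    methods=METHODS,
    config: Optional[PipelineConfig] = None,
    matches=None,
):
    """Self-align (unless precomputed matches are given) and cluster with
    the requested methods; returns (matches, {method: clusters})."""
    if config is None:
        config = PipelineConfig()
    if matches is None:
        matches = self_align(genome, config.selfalign)
        matches = filter_long_matches(matches, config.selfalign)
    clusterings = {}
    chains = None
    for method in methods:
        if method == "grouper":
            chains = chain_matches(matches, config.grouper) if chains is None else chains
            clusters = grouper_cluster(chains, config.grouper)
        elif method == "recon":
            chains = chain_matches(matches, config.grouper) if chains is None else chains
            clusters = recon_like_cluster(chains, config.recon)
        elif method == "piler":
            clusters = piler_cluster(matches, config.piler)
        else:
            raise ValueError(f"unknown clustering method {method!r}")
        clusterings[method] = filter_clusters(clusters)
        log.info("%s: %d clusters after filters", method, len(clusterings[method]))
    return matches, clusterings


def denovo_libraries(
    genome: GenomeSet,
    methods=METHODS,
    config: Optional[PipelineConfig] = None,
    matches=None,
) -> dict:
    """Per-method consensus libraries (lists of ConsensusRecord)."""
    if config is None:
        config = PipelineConfig()
    _, clusterings = cluster_genome(genome, methods, config, matches)
    return {
        method: build_library(clusters, genome, config.msa)
        for method, clusters in clusterings.items()
    }


def classify_library(
    records,
    te_databank: Optional[dict] = None,
    host_genes: Optional[dict] = None,
    ranges: Optional[LengthRanges] = None,
) -> list:
    """Classify each consensus; returns (ConsensusRecord, Classification)
    pairs."""
    if ranges is None:
        ranges = LengthRanges()
    out = []
    for rec in records:
        features = compute_features(rec.sequence, te_databank, host_genes)
        cls = classify_consensus(features, len(rec.sequence), ranges)
        out.append((rec, cls))
    return out


def run_tedenovo(
    genome: GenomeSet,
    te_databank: Optional[dict] = None,
    host_genes: Optional[dict] = None,
    methods=METHODS,
    config: Optional[PipelineConfig] = None,
) -> dict:
    """Full de novo phase.

    Returns a dict with the per-method libraries, the combined classified
    library before and after redundancy removal, and the final records.
    """
    if config is None:
        config = PipelineConfig()
    libraries = denovo_libraries(genome, methods, config)
    combined = [r for m in methods for r in libraries[m]]
    classified = classify_library(combined, te_databank, host_genes, config.ranges)
    final = remove_redundancy(classified)
    log.info(
        "de novo library: %d consensus (%d before redundancy removal)",
        len(final),
        len(classified),
    )
    return {
        "per_method": libraries,
        "classified": classified,
        "final": final,
    }


def library_fasta_records(final) -> dict:
    """Classified FASTA dict: headers encode label and completeness."""
    out = {}
    for rec, cls in final:
        out[f"{rec.id}#{cls.label}|{cls.completeness}"] = rec.sequence
    return out
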