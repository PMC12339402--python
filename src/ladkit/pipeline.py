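"""End-to-end orchestration of the synthetic CUT&RUN analysis.

simulate -> spike-in normalize -> HMM segment -> consensus -> annotate ->
TE enrichment -> imaging, with a manifest recording config, seed and
outputs. Each stage draws from its own seed substream (keyed by stage
name), so adding a stage does not perturb the randomness of earlier ones.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .config import Config
from .core import BinnedSignalTrack, DomainSet, jaccard_bp
from .domains import (
    assign_classes,
    classify_degs,
    deg_class_enrichment,
    expressed_proportion,
    generic_scheme,
    mes_scheme,
    overlap_accounting,
)
from .hmm import HMMModel, consensus_domains, decode, fit_hmm
from .simulate import MARKS, CutRunReplicate, SimParams, SimTruth, \
    simulate_cutrun, simulate_expression, simulate_genome, simulate_te_table
from .spikein import average_tracks, compute_scale_factor, normalize_track, \
    rpkm_from_counts
from .te import build_te_table, flag_enriched

logger = logging.getLogger(__name__)


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage substream of the global seed (< 2^31)."""
    ss = np.random.SeedSequence([seed, zlib.crc32(stage.encode())])
    return int(ss.generate_state(1)[0] % (2**31))


def sha256_file(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


@dataclass
class RunManifest:
    """What a run saw and produced; identical manifests -> identical outputs."""

    seed: int
    config: dict
    inputs: Dict[str, str] = field(default_factory=dict)   # path -> sha256
    outputs: Dict[str, str] = field(default_factory=dict)  # stage -> path
    version: str = __version__

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2) + "\n")


def replicate_tracks(
    replicates: Sequence[CutRunReplicate],
    truth: SimTruth,
    mark: str,
    config: Config,
) -> List[BinnedSignalTrack]:
    """Raw counts -> RPKM -> spike-in-normalized tracks, one per replicate."""
    tracks = []
    for rep in replicates:
        rpkm = rpkm_from_counts(
            rep.counts, truth.genome, truth.bin_size, rep.total_mapped)
        s = compute_scale_factor(mark, rep.n_spikein, config)
        tracks.append(normalize_track(rpkm, s))
    return tracks


def segment_mark(
    tracks: Sequence[BinnedSignalTrack],
    mark: str,
    seed: int,
    model: Optional[HMMModel] = None,
) -> tuple:
    """Fit one K=2 model jointly on all replicates, decode each, intersect.

    Training treats each replicate's per-chromosome valid runs as
    independent sequences. Returns (model, per-replicate DomainSets,
    consensus DomainSet).
    """
    sequences = [run for t in tracks for c in t.genome for run in t.valid_runs(c)]
    if model is None:
        model = fit_hmm(sequences, K=2, seed=seed)
    rep_domains = [
        decode(model, t, mark=mark, sample=f"rep{i + 1}")
        for i, t in enumerate(tracks)
    ]
    return model, rep_domains, consensus_domains(rep_domains)


@dataclass
class PipelineResult:
    truth: SimTruth
    models: Dict[str, HMMModel]
    consensus: Dict[str, DomainSet]
    replicate_domains: Dict[str, List[DomainSet]]
    gene_table: pd.DataFrame
    overlap_table: pd.DataFrame
    enrichment: list
    te_table: pd.DataFrame
    jaccard_vs_truth: Dict[str, float]
    manifest: RunManifest


def run_pipeline(
    params: Optional[SimParams] = None,
    config: Optional[Config] = None,
    seed: int = 0,
    marks: Sequence[str] = MARKS,
    outdir: Optional[str | Path] = None,
) -> PipelineResult:
    """Full synthetic run: every stage on generated data with known truth."""
    params = params or SimParams()
    config = config or Config(bin_size=params.bin_size)
    manifest = RunManifest(seed=seed, config=dataclasses.asdict(config))

    truth = simulate_genome(params, seed=stage_seed(seed, "simulate"))
    models, consensus, rep_domains, jac = {}, {}, {}, {}
    for mark in marks:
        reps = simulate_cutrun(
            truth, params, mark=mark, genotype="WT",
            seed=stage_seed(seed, f"cutrun:{mark}"))
        tracks = replicate_tracks(reps, truth, mark, config)
        model, rds, cons = segment_mark(
            tracks, mark, seed=stage_seed(seed, f"hmm:{mark}"))
        models[mark], rep_domains[mark], consensus[mark] = model, rds, cons
        jac[mark] = jaccard_bp(cons.intervals, truth.domains[mark].intervals)
        logger.info("run_pipeline: %s consensus %d domains, Jaccard vs truth %.3f",
                    mark, len(cons), jac[mark])

    scheme = mes_scheme() if set(marks) == set(MARKS) else generic_scheme(marks)
    gene_table = assign_classes(truth.genes, consensus, scheme, config)
    tpm_table, de_table, _ = simulate_expression(
        truth, params, seed=stage_seed(seed, "expression"))
    gene_table = gene_table.merge(tpm_table, on="gene_id")
    gene_table = gene_table.merge(de_table, on="gene_id")
    gene_table["expressed"] = gene_table["tpm"] > config.tpm_expressed
    gene_table["de_status"] = classify_degs(
        gene_table, config.deg_fc, config.deg_alpha)
    overlap_table = overlap_accounting(consensus)
    enrichment = [
        deg_class_enrichment(gene_table, cls, "up")
        for cls in ("LAD", "KOD", "non-LAD")
        if (gene_table["domain_class"] == cls).any()
    ]

    family_rpkm, te_truth, te_classes = simulate_te_table(
        params, seed=stage_seed(seed, "te"))
    te_table = flag_enriched(
        build_te_table(family_rpkm, te_classes),
        marks=list(family_rpkm), threshold=config.te_z_threshold)
    te_table["truth_enriched"] = te_table.index.isin(te_truth)

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        from .io import write_domains
        for mark in marks:
            p = outdir / f"consensus_{mark}.bed"
            write_domains(consensus[mark], p)
            manifest.outputs[f"consensus:{mark}"] = str(p)
        gene_table.to_csv(outdir / "gene_domain_table.tsv", sep="\t", index=False)
        overlap_table.to_csv(outdir / "overlap_accounting.tsv", sep="\t", index=False)
        te_table.to_csv(outdir / "te_table.tsv", sep="\t")
        manifest.outputs["gene_table"] = str(outdir / "gene_domain_table.tsv")
        manifest.to_json(outdir / "manifest.json")

    return PipelineResult(
        truth=truth, models=models, consensus=consensus,
        replicate_domains=rep_domains, gene_table=gene_table,
        overlap_table=overlap_table, enrichment=enrichment,
        te_table=te_table, jaccard_vs_truth=jac, manifest=manifest,
    )
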