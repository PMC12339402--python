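"""Synthetic data with known ground truth for every pipeline stage.

The generator emulates the statistical structure the analysis assumes:
Mb-scale two-state domain signal in 10 kb bins across replicates
(negative-binomial counts, Poisson spike-ins), genotype-dependent loss of
lamina contact, domain-class-dependent gene expression, a small set of
genuinely lamina-enriched TE families among a large null, and nuclei whose
marker is peripherally or internally distributed. Everything is
deterministic given (params, seed).

Truth construction: a "lamina" first-order Markov chain over
{background, domain} defines LADs (carrying LB1, LAP2B and H3K9me2
together); an independent sparser chain adds H3K9me2-only regions (KODs).
Emission levels are free parameters of the simulation, not measured
quantities.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .core import DomainSet, Genome, GenomicInterval, merge_intervals
from .domains import mes_scheme
from .imaging import NucleusImage

MARKS = ("LB1", "LAP2B", "H3K9me2")


@dataclass
class SimParams:
    """Desk-scale defaults: 2 x 50 Mb chromosomes = 10,000 bins of 10 kb."""

    n_chromosomes: int = 2
    chrom_length: int = 50_000_000
    bin_size: int = 10_000
    n_replicates: int = 3
    spikein_expected: float = 3000.0
    # negative-binomial emission (per-bin counts)
    background_mean: float = 20.0
    domain_mean: float = 80.0
    nb_dispersion: float = 10.0  # size parameter; variance = m + m^2/size
    # lamina (LAD) chain
    stay_background: float = 0.995
    stay_domain: float = 0.995
    # extra H3K9me2-only (KOD) chain
    kod_stay_background: float = 0.998
    kod_stay_domain: float = 0.99
    # genes
    n_genes: int = 2000
    gene_min_length: int = 2_000
    gene_max_length: int = 200_000
    # expression (free parameters, not measured values)
    expressed_prob: Dict[str, float] = field(
        default_factory=lambda: {"non-LAD": 0.6, "KOD": 0.35, "LAD": 0.1}
    )
    derepressed_fraction: float = 0.2
    # genotype contact-loss multipliers
    genotype_factors: Dict[str, float] = field(
        default_factory=lambda: {"WT": 1.0, "KO": 0.3}
    )
    # TE table
    n_te_families: int = 1200
    n_te_enriched: int = 40
    te_shift_mads: float = 10.0
    te_null_shape: float = 50.0
    te_null_scale: float = 0.2
    te_mark_cv: float = 0.02  # mark-specific noise around the family abundance
    # nucleus images
    image_size: int = 160
    pixel_size_um: float = 0.1
    nucleus_radii: Tuple[int, int] = (60, 45)
    ring_width_px: float = 2.0
    ring_amplitude: float = 100.0
    image_background: float = 0.0
    image_noise_sd: float = 0.0
    n_foci: int = 12
    focus_sigma_px: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_chromosomes", "chrom_length", "bin_size", "n_replicates",
                     "n_genes", "n_te_families", "image_size"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for p in (self.stay_background, self.stay_domain,
                  self.kod_stay_background, self.kod_stay_domain):
            if not (0 < p <= 1):
                raise ValueError("stay-probabilities must be in (0, 1]")
        for frac in (*self.expressed_prob.values(), self.derepressed_fraction):
            if not (0 <= frac <= 1):
                raise ValueError("fractions must be in [0, 1]")
        if self.chrom_length < self.bin_size:
            raise ValueError("chromosome shorter than one bin")
        if self.background_mean >= self.domain_mean:
            raise ValueError("background mean must be below domain mean")

    def genome(self) -> Genome:
        return Genome(
            {f"chr{i + 1}": self.chrom_length for i in range(self.n_chromosomes)}
        )


@dataclass
class SimTruth:
    """Ground truth against which every downstream call is evaluated."""

    genome: Genome
    bin_size: int
    domains: Dict[str, DomainSet]               # per mark
    domain_bins: Dict[str, Dict[str, np.ndarray]]  # mark -> chrom -> bool array
    genes: List[GenomicInterval]
    gene_classes: Dict[str, str]
    emission_means: Tuple[float, float]         # (background, domain)
    emission_sds: Tuple[float, float]
    stay_probs: Tuple[float, float]
    genotype_factors: Dict[str, float]


def _markov_states(n_bins: int, stay_bg: float, stay_dom: float,
                   rng: np.random.Generator, start_background: bool = True
                   ) -> np.ndarray:
    """First-order two-state chain; True marks domain bins."""
    states = np.empty(n_bins, dtype=bool)
    u = rng.random(n_bins)
    state = False if start_background else bool(u[0] < 0.5)
    for i in range(n_bins):
        states[i] = state
        stay = stay_dom if state else stay_bg
        if u[i] >= stay:
            state = not state
    return states


def _states_to_intervals(states: np.ndarray, chrom: str, bin_size: int,
                         chrom_length: int, label: str = "domain"
                         ) -> List[GenomicInterval]:
    out = []
    i = 0
    n = len(states)
    while i < n:
        if states[i]:
            j = i
            while j < n and states[j]:
                j += 1
            out.append(GenomicInterval(
                chrom, i * bin_size, min(j * bin_size, chrom_length), label))
            i = j
        else:
            i += 1
    return out


def simulate_genome(params: SimParams, seed: Optional[int] = None) -> SimTruth:
    """Draw the true domain landscape, gene placement and gene classes."""
    rng = np.random.default_rng(params.seed if seed is None else seed)
    genome = params.genome()
    lad_bins: Dict[str, np.ndarray] = {}
    kod_bins: Dict[str, np.ndarray] = {}
    for chrom in genome:
        n = genome.n_bins(chrom, params.bin_size)
        lad = _markov_states(n, params.stay_background, params.stay_domain, rng)
        extra = _markov_states(
            n, params.kod_stay_background, params.kod_stay_domain, rng)
        lad_bins[chrom] = lad
        kod_bins[chrom] = extra & ~lad
    k9_bins = {c: lad_bins[c] | kod_bins[c] for c in genome}

    def domainset(mark: str, bins: Dict[str, np.ndarray]) -> DomainSet:
        ivs = []
        for chrom in genome:
            ivs.extend(_states_to_intervals(
                bins[chrom], chrom, params.bin_size, genome[chrom]))
        return DomainSet(mark=mark, sample="truth", intervals=ivs)

    domain_bins = {"LB1": lad_bins, "LAP2B": lad_bins, "H3K9me2": k9_bins}
    domains = {m: domainset(m, domain_bins[m]) for m in MARKS}

    # genes: uniform placement, log-uniform lengths 2-200 kb
    genes: List[GenomicInterval] = []
    chroms = genome.chroms
    lengths = np.exp(rng.uniform(
        np.log(params.gene_min_length), np.log(params.gene_max_length),
        size=params.n_genes)).astype(int)
    for i in range(params.n_genes):
        chrom = chroms[rng.integers(len(chroms))]
        length = min(int(lengths[i]), genome[chrom] - 1)
        start = int(rng.integers(0, genome[chrom] - length))
        genes.append(GenomicInterval(chrom, start, start + length, f"gene_{i:05d}"))

    scheme = mes_scheme()
    gene_classes: Dict[str, str] = {}
    for gene in genes:
        membership = {}
        for mark in MARKS:
            bins = domain_bins[mark][gene.chrom]
            first = gene.start // params.bin_size
            last = (gene.end - 1) // params.bin_size
            covered = 0
            for b in range(first, last + 1):
                if bins[b]:
                    s = max(gene.start, b * params.bin_size)
                    e = min(gene.end, (b + 1) * params.bin_size)
                    covered += e - s
            membership[mark] = covered / len(gene) >= 0.90
        gene_classes[gene.label] = scheme.classify(membership)

    def nb_sd(mean: float) -> float:
        return float(np.sqrt(mean + mean**2 / params.nb_dispersion))

    return SimTruth(
        genome=genome,
        bin_size=params.bin_size,
        domains=domains,
        domain_bins=domain_bins,
        genes=genes,
        gene_classes=gene_classes,
        emission_means=(params.background_mean, params.domain_mean),
        emission_sds=(nb_sd(params.background_mean), nb_sd(params.domain_mean)),
        stay_probs=(params.stay_background, params.stay_domain),
        genotype_factors=dict(params.genotype_factors),
    )


def simulate_gaussian_sequences(
    n_bins: int,
    n_sequences: int = 1,
    means: Tuple[float, float] = (0.0, 6.0),
    sds: Tuple[float, float] = (1.0, 1.0),
    stay_probs: Tuple[float, float] = (0.99, 0.99),
    seed: int = 0,
) -> Tuple[List[np.ndarray], List[np.ndarray]]:
    """Two-state Gaussian-emission HMM draws (the segmentation model's own
    generative assumptions). Returns (observation sequences, state paths);
    d' = (means[1] - means[0]) / sd controls separability."""
    rng = np.random.default_rng(seed)
    obs, paths = [], []
    for _ in range(n_sequences):
        states = _markov_states(n_bins, stay_probs[0], stay_probs[1], rng)
        x = np.where(
            states,
            rng.normal(means[1], sds[1], n_bins),
            rng.normal(means[0], sds[0], n_bins),
        )
        obs.append(x)
        paths.append(states.astype(int))
    return obs, paths


@dataclass
class CutRunReplicate:
    """Raw per-bin counts plus per-sample sequencing totals."""

    counts: Dict[str, np.ndarray]
    n_spikein: int

    @property
    def total_mapped(self) -> int:
        return int(sum(c.sum() for c in self.counts.values()))


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, size_param: float
             ) -> np.ndarray:
    p = size_param / (size_param + mean)
    return rng.negative_binomial(size_param, p)


def simulate_cutrun(
    truth: SimTruth,
    params: SimParams,
    mark: str = "H3K9me2",
    genotype: str = "WT",
    seed: Optional[int] = None,
    scope: str = "domain",
) -> List[CutRunReplicate]:
    """Negative-binomial bin counts per replicate, Poisson spike-ins.

    scope="domain": the contact-loss factor f interpolates the domain mean
    toward background (mean = bg + f * (dom - bg)) in that mark's true
    domain bins only, so f = 0 makes domains indistinguishable from
    background. scope="genome": every bin's mean is multiplied by f,
    emulating a global loss of recovered material (the spike-in expectation
    is untouched).
    """
    if mark not in truth.domain_bins:
        raise KeyError(f"unknown mark {mark!r}")
    if genotype not in truth.genotype_factors:
        raise KeyError(f"unknown genotype {genotype!r}; "
                       f"known: {sorted(truth.genotype_factors)}")
    if scope not in ("domain", "genome"):
        raise ValueError("scope must be 'domain' or 'genome'")
    f = truth.genotype_factors[genotype]
    rng = np.random.default_rng(params.seed if seed is None else seed)
    bg, dom = params.background_mean, params.domain_mean
    replicates = []
    for _ in range(params.n_replicates):
        counts = {}
        for chrom in truth.genome:
            in_domain = truth.domain_bins[mark][chrom]
            mean = np.where(in_domain, bg + f * (dom - bg), bg) \
                if scope == "domain" else \
                np.where(in_domain, dom, bg) * f
            counts[chrom] = _nb_draw(rng, mean, params.nb_dispersion)
        n_spikein = int(rng.poisson(params.spikein_expected))
        replicates.append(CutRunReplicate(counts=counts, n_spikein=n_spikein))
    return replicates


def simulate_expression(
    truth: SimTruth, params: SimParams, seed: Optional[int] = None
) -> Tuple[pd.DataFrame, pd.DataFrame, set]:
    """Per-gene TPM and differential-expression tables.

    Each gene is expressed (TPM drawn above 5) with a class-specific
    probability; a random subset of repressed domain genes (LAD or KOD) is
    "derepressed" in the mutant genotype with log2FC > 1 and adjusted
    p < 0.05. Returns (tpm_table, de_table, truth_derepressed_ids).
    """
    rng = np.random.default_rng(params.seed if seed is None else seed)
    gene_ids = [g.label for g in truth.genes]
    classes = []
    for gid in gene_ids:
        cls = truth.gene_classes[gid]
        if cls not in params.expressed_prob:
            raise KeyError(f"no expression probability for gene class {cls!r}")
        classes.append(cls)
    probs = np.array([params.expressed_prob[c] for c in classes])
    expressed = rng.random(len(gene_ids)) < probs
    # expressed genes draw strictly above the 5-TPM threshold
    tpm = np.where(
        expressed,
        5.0 + rng.lognormal(2.0, 1.0, len(gene_ids)),
        rng.uniform(0.0, 5.0, len(gene_ids)),
    )
    tpm_table = pd.DataFrame({"gene_id": gene_ids, "tpm": tpm})

    repressed_domain = [
        gid for gid, cls, ex in zip(gene_ids, classes, expressed)
        if cls in ("LAD", "KOD") and not ex
    ]
    n_dep = int(round(params.derepressed_fraction * len(repressed_domain)))
    derepressed = set(
        rng.choice(repressed_domain, size=n_dep, replace=False)
    ) if n_dep else set()
    log2fc = rng.normal(0.0, 0.3, len(gene_ids))
    padj = rng.uniform(0.05, 1.0, len(gene_ids))
    for i, gid in enumerate(gene_ids):
        if gid in derepressed:
            log2fc[i] = rng.uniform(1.5, 5.0)
            padj[i] = rng.uniform(1e-8, 0.01)
    de_table = pd.DataFrame({"gene_id": gene_ids, "log2fc": log2fc, "padj": padj})
    return tpm_table, de_table, derepressed


def simulate_te_table(
    params: SimParams,
    seed: Optional[int] = None,
    marks: Sequence[str] = ("H3K9me2", "LAP2B"),
    degenerate: bool = False,
) -> Tuple[Dict[str, pd.Series], set, Dict[str, str]]:
    """TE-family RPKM per mark: gamma null plus a shifted enriched subset.

    The designated enriched families are shifted upward by
    te_shift_mads x MAD (of the null draw) in every given mark, so their
    modified z clears the threshold. With ``degenerate=True`` all families
    get identical RPKM (MAD = 0) to exercise the error path. Returns
    (mark -> family RPKM series, truth-enriched ids, family -> TE class).
    """
    rng = np.random.default_rng(params.seed if seed is None else seed)
    families = [f"TEfam_{i:04d}" for i in range(params.n_te_families)]
    te_classes = {
        fam: rng.choice(["LINE", "LTR", "SINE", "other"], p=[0.3, 0.4, 0.2, 0.1])
        for fam in families
    }
    if params.n_te_enriched > params.n_te_families:
        raise ValueError("more enriched families than families")
    enriched = set(rng.choice(families, size=params.n_te_enriched, replace=False))
    is_enriched = np.array([fam in enriched for fam in families])
    # one latent abundance per family, shared across marks: a family's copy
    # number drives its RPKM under every antibody
    base = rng.gamma(params.te_null_shape, params.te_null_scale, len(families))
    out: Dict[str, pd.Series] = {}
    for mark in marks:
        if degenerate:
            values = np.full(len(families), 10.0)
        else:
            noise = rng.normal(1.0, params.te_mark_cv, len(families))
            values = base * np.clip(noise, 0.1, None)
            med = np.median(values)
            mad = np.median(np.abs(values - med))
            values = values + is_enriched * params.te_shift_mads * mad
        out[mark] = pd.Series(values, index=pd.Index(families, name="family"),
                              name=f"rpkm_{mark}")
    return out, enriched, te_classes


def simulate_nucleus(
    params: SimParams, mode: str = "peripheral", seed: Optional[int] = None
) -> NucleusImage:
    """A single-nucleus image: elliptical mask and one marker channel.

    peripheral: amplitude in a ring of ring_width_px at the mask boundary
    (EDT <= width), emulating lamina-tethered heterochromatin; internal:
    Gaussian foci in the interior, emulating nucleoplasmic aggregates;
    uniform: amplitude everywhere in the mask. Additive Gaussian noise is
    clipped at zero.
    """
    if mode not in ("peripheral", "internal", "uniform"):
        raise ValueError("mode must be peripheral|internal|uniform")
    rng = np.random.default_rng(params.seed if seed is None else seed)
    size = params.image_size
    a, b = params.nucleus_radii
    cy, cx = size / 2.0, size / 2.0
    yy, xx = np.mgrid[0:size, 0:size]
    mask = ((xx - cx) / a) ** 2 + ((yy - cy) / b) ** 2 <= 1.0

    from scipy import ndimage
    edt = ndimage.distance_transform_edt(mask)
    signal = np.zeros((size, size))
    if mode == "uniform":
        signal[mask] = params.ring_amplitude
    elif mode == "peripheral":
        ring = mask & (edt <= params.ring_width_px)
        signal[ring] = params.ring_amplitude
    else:
        interior = np.argwhere(mask & (edt > 0.5 * edt.max()))
        for _ in range(params.n_foci):
            py, px = interior[rng.integers(len(interior))]
            signal += params.ring_amplitude * np.exp(
                -((yy - py) ** 2 + (xx - px) ** 2)
                / (2 * params.focus_sigma_px**2)
            )
        signal[~mask] = 0.0
    channel = params.image_background + signal
    if params.image_noise_sd > 0:
        channel = channel + rng.normal(0, params.image_noise_sd, channel.shape)
    channel = np.clip(channel, 0, None)
    channel[~mask] = 0.0
    return NucleusImage(
        channels={"marker": channel}, mask=mask, pixel_size=params.pixel_size_um
    )

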