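"""Synthetic mitochondrial-like datasets with known constraint truth.

The generator is a deliberate caricature, not a coalescent: sites are
independent, the number of segregating mutations per site is Poisson, and
derived-allele sample counts follow the neutral 1/k frequency spectrum.
Real mtDNA sites share a single non-recombining genealogy, but the analyses
under test treat sites marginally, so independent sites give clean,
assertable statistics.  Purifying constraint c in [0, 1] acts twice, as in
the real signal: it thins the mutation rate (depressing SNP density) and it
caps derived-allele frequencies (depressing the MAF of surviving variants).
A replication-asymmetry gradient (D_ssH) modulates the mutation rate so the
bias-correction stage has something real to remove, and the divergence
tracks are coupled to the same constraint truth so polymorphism and
divergence correlate only through selection.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .core_io import (
    AnnotationSet,
    ElementSet,
    GeneRecord,
    ScoreTrack,
    SiteTable,
    write_annotations,
    write_elements,
    write_fasta,
    write_score_track,
    write_snp_table,
)
from .mutbias import ReplicationModel, dssh_track

__all__ = [
    "SyntheticConfig",
    "SyntheticTruth",
    "generate_layout",
    "simulate_site_alleles",
    "simulate_divergence",
    "emit_dataset",
    "power_study_config",
]


# Gene mosaic emulating the human mtDNA map (name, class, length, strand).
# The control region is handled separately (it wraps the coordinate origin).
_MT_TEMPLATE: list[tuple[str, str, int, str]] = [
    ("TF", "tRNA", 71, "+"),
    ("RNR1", "rRNA", 954, "+"),
    ("TV", "tRNA", 69, "+"),
    ("RNR2", "rRNA", 1558, "+"),
    ("TL1", "tRNA", 75, "+"),
    ("ND1", "protein", 957, "+"),
    ("TI", "tRNA", 69, "+"),
    ("TQ", "tRNA", 72, "-"),
    ("TM", "tRNA", 68, "+"),
    ("ND2", "protein", 1041, "+"),
    ("TW", "tRNA", 68, "+"),
    ("TA", "tRNA", 69, "-"),
    ("TN", "tRNA", 73, "-"),
    ("TC", "tRNA", 66, "-"),
    ("TY", "tRNA", 66, "-"),
    ("CO1", "protein", 1542, "+"),
    ("TS1", "tRNA", 69, "-"),
    ("TD", "tRNA", 68, "+"),
    ("CO2", "protein", 684, "+"),
    ("TK", "tRNA", 70, "+"),
    ("ATP8", "protein", 207, "+"),
    ("ATP6", "protein", 681, "+"),
    ("CO3", "protein", 783, "+"),
    ("TG", "tRNA", 68, "+"),
    ("ND3", "protein", 345, "+"),
    ("TR", "tRNA", 65, "+"),
    ("ND4L", "protein", 297, "+"),
    ("ND4", "protein", 1377, "+"),
    ("TH", "tRNA", 69, "+"),
    ("TS2", "tRNA", 59, "+"),
    ("TL2", "tRNA", 71, "+"),
    ("ND5", "protein", 1812, "+"),
    ("ND6", "protein", 525, "-"),
    ("TE", "tRNA", 69, "-"),
    ("CYB", "protein", 1140, "+"),
    ("TT", "tRNA", 66, "+"),
    ("TP", "tRNA", 68, "-"),
]
_CR_TAIL = 545  # control-region bp before the origin (wraps to _CR_HEAD after it)
_CR_HEAD = 577
_REF_LENGTH = 16569


@dataclass
class SyntheticConfig:
    """Study conditions for one synthetic dataset.

    ``theta_neutral`` is the expected number of segregating mutations per
    neutral site: 1.8 reproduces the ultradense regime of roughly one
    segregating mutation on every other base pair genome-wide once the
    constraint mosaic thins the functional sites.  Constraint is essentially
    two-level by default — strong (0.9) at tRNA/rRNA and nonsynonymous
    protein sites, weak at 4-fold degenerate (0.1), control (0.2) and
    intergenic (0) sites — because the segmentation under test is itself a
    two-state method; intermediate levels are configurable.
    ``dssh_effect`` is the log-rate slope per unit of D_ssH / genome_length.
    """

    genome_length: int = 16569
    circular: bool = True
    seed: int = 0
    n_samples: int = 16411
    origin_h: int = 191
    origin_l: int = 5721
    leading_direction: int = -1
    theta_neutral: float = 1.8
    dssh_effect: float = 0.3
    divergence_scale: float = 2.0
    divergence_noise_sd: float = 0.5
    prob_slope: float = 8.0
    sfs_truncation: int | None = None  # default: n_samples - 1
    maf_cap_quantile: float = 0.9  # top decile of spectrum mass excluded when c > 0.5
    functional_threshold: float = 0.05
    class_constraint: dict = field(
        default_factory=lambda: {"tRNA": 0.9, "rRNA": 0.9, "control": 0.2, "other": 0.2}
    )
    protein_constraint: dict = field(
        default_factory=lambda: {
            "first_position": 0.9,
            "second_position": 0.9,
            "fourfold_third": 0.1,
            "other_third": 0.9,
        }
    )
    layout: list | None = None  # explicit [(name, class, length, strand), ...]
    constraint_layout: list | None = None  # [(start, end, c), ...] overrides

    def __post_init__(self) -> None:
        if self.genome_length < 10:
            raise ValueError("genome too short")
        if self.theta_neutral <= 0:
            raise ValueError("theta_neutral must be positive")
        if self.n_samples < 2:
            raise ValueError("need at least 2 sampled chromosomes")
        if self.constraint_layout is not None:
            for s, e, c in self.constraint_layout:
                if not (0 <= s < e <= self.genome_length):
                    raise ValueError("constraint interval outside genome")
                if not 0 <= c <= 1:
                    raise ValueError("constraint must lie in [0, 1]")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, payload: dict) -> "SyntheticConfig":
        known = set(cls.__dataclass_fields__)
        unknown = set(payload) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        payload = dict(payload)
        if payload.get("layout") is not None:
            payload["layout"] = [tuple(b) for b in payload["layout"]]
        if payload.get("constraint_layout") is not None:
            payload["constraint_layout"] = [tuple(b) for b in payload["constraint_layout"]]
        return cls(**payload)

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()


@dataclass
class SyntheticTruth:
    """Ground truth behind one synthetic dataset."""

    constraint: np.ndarray  # c_i in [0, 1]
    mu: np.ndarray  # per-site expected mutation count
    elements: ElementSet  # maximal runs with c above the functional threshold
    dssh: np.ndarray  # per-site single-strandedness used for mu
    sequence: str  # reference sequence


def _default_layout(config: SyntheticConfig) -> list[tuple[str, str, int, str]]:
    """mtDNA-like mosaic, scaled to the configured genome length."""
    f = config.genome_length / _REF_LENGTH
    blocks: list[tuple[str, str, int, str]] = []
    head = max(int(round(_CR_HEAD * f)), 1)
    tail = max(int(round(_CR_TAIL * f)), 1)
    blocks.append(("CR", "control", head, "+"))
    for name, cls, length, strand in _MT_TEMPLATE:
        scaled = max(int(round(length * f)), 3)
        if cls == "protein":
            scaled = max(3 * (scaled // 3), 3)
        blocks.append((name, cls, scaled, strand))
    used = sum(b[2] for b in blocks) + tail
    pad = config.genome_length - used
    if pad < 0:
        raise ValueError("scaled layout exceeds genome; use an explicit layout")
    if pad > 0:
        blocks.append(("IG", "intergenic", pad, "+"))
    blocks.append(("CR", "control", tail, "+"))
    return blocks


def generate_layout(config: SyntheticConfig) -> tuple[AnnotationSet, SyntheticTruth]:
    """Tile the genome with gene blocks and derive per-site constraint truth.

    Protein-gene constraint is codon-structured (positions read on the coding
    strand): second positions are strongly constrained, 4-fold degenerate
    third positions nearly neutral.  4-fold status requires the reference
    sequence, which is generated here (uniform random nucleotides, seeded).
    """
    from .constraint_stats import fourfold_degenerate_prefixes

    rng = np.random.default_rng(config.seed)
    L = config.genome_length
    blocks = list(config.layout) if config.layout is not None else _default_layout(config)
    total = sum(b[2] for b in blocks)
    if total != L:
        raise ValueError(f"layout lengths sum to {total}, expected {L}")

    sequence = "".join(rng.choice(list("ACGT"), size=L))
    fourfold = fourfold_degenerate_prefixes()
    complement = str.maketrans("ACGT", "TGCA")

    records: list[GeneRecord] = []
    constraint = np.zeros(L)
    cursor = 0
    pc = config.protein_constraint
    for name, cls, length, strand in blocks:
        start, end = cursor, cursor + length
        cursor = end
        if cls == "intergenic":
            continue
        records.append(GeneRecord(name, start, end, strand, cls, description=cls))
        if cls == "protein":
            gene_seq = sequence[start:end]
            positions = np.arange(start, end)
            if strand == "-":
                gene_seq = gene_seq.translate(complement)[::-1]
                positions = positions[::-1]
            for ci in range(len(gene_seq) // 3):
                codon = gene_seq[3 * ci : 3 * ci + 3]
                p1, p2, p3 = positions[3 * ci : 3 * ci + 3]
                constraint[p1] = pc["first_position"]
                constraint[p2] = pc["second_position"]
                constraint[p3] = (
                    pc["fourfold_third"] if codon[:2] in fourfold else pc["other_third"]
                )
            leftover = positions[3 * (len(gene_seq) // 3) :]
            constraint[leftover] = pc["first_position"]
        else:
            constraint[start:end] = config.class_constraint.get(cls, 0.0)

    if config.constraint_layout is not None:
        for s, e, c in config.constraint_layout:
            constraint[s:e] = c

    model = ReplicationModel(
        L,
        config.origin_h % L,
        config.origin_l % L,
        config.leading_direction,
        control_region=[],  # mutation process runs everywhere
    )
    dssh = dssh_track(model)
    mu = config.theta_neutral * (1.0 - constraint) * np.exp(config.dssh_effect * dssh / L)

    above = constraint > config.functional_threshold
    diff = np.diff(np.concatenate(([0], above.astype(np.int8), [0])))
    starts = np.flatnonzero(diff == 1)
    ends = np.flatnonzero(diff == -1)
    elements = ElementSet(
        L, starts, ends, [f"truth_{i + 1}" for i in range(len(starts))], source="truth"
    )
    annotations = AnnotationSet(L, records, circular=config.circular)
    return annotations, SyntheticTruth(constraint, mu, elements, dssh, sequence)


def power_study_config(seed: int) -> SyntheticConfig:
    """Study conditions for the sample-size power analysis.

    The dense default regime saturates — even 100 chromosomes recover
    essentially everything — so the power question is posed where detection
    is sample-limited: sparse polymorphism (theta = 0.12) and ~58 scattered
    fully constrained elements (c = 1) separated by 200-bp neutral gaps,
    with the 1,864-chromosome sample that is the downsampling grid's full
    size.  Element lengths cycle over 50..120 bp: each length crosses its
    Viterbi detection threshold at a different sample size, so aggregate
    recall climbs across the whole grid instead of switching at one point.
    Full constraint keeps element evidence a clean monomorphic run at every
    sample size; only the neutral-side information grows with n.
    """
    lengths = (50, 60, 70, 80, 90, 100, 110, 120)
    blocks, elements, pos, i = [], [], 0, 0
    while True:
        elen = lengths[i % len(lengths)]
        if pos + 200 + elen > 16_569:
            break
        blocks.append((f"ig{i}", "intergenic", 200, "+"))
        blocks.append((f"E{i}", "tRNA", elen, "+"))
        elements.append((pos + 200, pos + 200 + elen, 1.0))
        pos += 200 + elen
        i += 1
    blocks.append(("tail", "intergenic", 16_569 - pos, "+"))
    return SyntheticConfig(
        seed=seed,
        n_samples=1864,
        theta_neutral=0.12,
        layout=blocks,
        constraint_layout=elements,
    )


def _sfs_weights(k_max: int) -> np.ndarray:
    k = np.arange(1, k_max + 1, dtype=float)
    w = 1.0 / k
    return w / w.sum()


def _sfs_cap(k_max: int, quantile: float) -> int:
    """Largest derived count kept when the spectrum's top mass is excluded.

    The cut is at ``quantile`` of the 1/k probability mass, not of the count
    range: for the neutral spectrum this lands near k_max**quantile, well
    below half the sample, so capping removes the high-frequency (and
    high-MAF) tail — selection holding deleterious variants rare.
    """
    cdf = np.cumsum(_sfs_weights(k_max))
    return int(np.searchsorted(cdf, quantile) + 1)


def simulate_site_alleles(
    config: SyntheticConfig, truth: SyntheticTruth, seed: int | None = None
) -> SiteTable:
    """Draw per-site segregating mutations and sample-level allele counts.

    Per site, the number of mutations m_i is Poisson(mu_i).  Each mutation's
    derived sample count k follows the neutral spectrum P(k) proportional to
    1/k over 1..sfs_truncation; under strong constraint (c > 0.5) the top
    decile of counts is excluded, mimicking selection holding deleterious
    variants at low frequency.  Mutations land on distinct non-reference
    nucleotides (recurring onto them past three), so the number of distinct
    alleles is min(1 + m_i, 4).
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    L = config.genome_length
    n = config.n_samples
    k_max = min(config.sfs_truncation or (n - 1), n - 1)
    k_max_capped = max(_sfs_cap(k_max, config.maf_cap_quantile), 1)

    ref_idx = np.array([("ACGT".index(b)) for b in truth.sequence], dtype=np.int64)
    m = rng.poisson(truth.mu)
    counts = np.zeros((L, 4), dtype=np.int64)
    counts[np.arange(L), ref_idx] = n

    poly = np.flatnonzero(m > 0)
    capped_site = truth.constraint > 0.5
    n_mut = m[poly]
    # draw derived counts for all mutations in two vectorized batches
    site_of_mut = np.repeat(poly, n_mut)
    capped_mut = capped_site[site_of_mut]
    ks = np.empty(site_of_mut.size, dtype=np.int64)
    free = ~capped_mut
    if free.any():
        ks[free] = rng.choice(np.arange(1, k_max + 1), size=int(free.sum()), p=_sfs_weights(k_max))
    if capped_mut.any():
        ks[capped_mut] = rng.choice(
            np.arange(1, k_max_capped + 1), size=int(capped_mut.sum()), p=_sfs_weights(k_max_capped)
        )

    offset = 0
    for site, m_i in zip(poly, n_mut):
        k_site = ks[offset : offset + m_i]
        offset += m_i
        r = ref_idx[site]
        alt_classes = [a for a in range(4) if a != r]
        budget = n - 1  # the reference allele is never fully replaced
        for j, k in enumerate(k_site):
            k = min(int(k), budget)
            if k <= 0:
                break  # sample exhausted; drop the remaining recurrent mutations
            alt = alt_classes[j % 3]
            counts[site, alt] += k
            counts[site, r] -= k
            budget -= k

    allele_count = (counts > 0).sum(axis=1)
    return SiteTable(L, allele_count, circular=config.circular, sample_counts=counts)


def simulate_divergence(
    config: SyntheticConfig, truth: SyntheticTruth, seed: int | None = None
) -> tuple[ScoreTrack, ScoreTrack]:
    """Divergence tracks coupled to the constraint truth.

    Returns a negated-phyloP-like track, scale * (1 - c) + Gaussian noise
    (larger = more divergent), and a phastCons-style probability of
    conservation, logistic(slope * (c - 0.5)).
    """
    rng = np.random.default_rng((config.seed if seed is None else seed))
    c = truth.constraint
    neg = config.divergence_scale * (1.0 - c)
    if config.divergence_noise_sd > 0:
        neg = neg + rng.normal(0.0, config.divergence_noise_sd, size=len(c))
    prob = 1.0 / (1.0 + np.exp(-config.prob_slope * (c - 0.5)))
    prob = np.clip(prob, 0.0, 1.0)
    return (
        ScoreTrack(len(c), neg, "negated_phylop"),
        ScoreTrack(len(c), prob, "conservation_probability"),
    )


def emit_dataset(config: SyntheticConfig, out_dir) -> dict:
    """Write a complete dataset to disk; same seed => byte-identical files.

    Files: reference FASTA, SNP table (with sample counts), phyloP-style
    wiggle (sign-flipped back to conservation polarity), conservation
    probability wiggle, annotation BED, truth-element BED, truth-constraint
    wiggle, and a manifest with the seed and config hash.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    annotations, truth = generate_layout(config)
    sites = simulate_site_alleles(config, truth, seed=config.seed + 1)
    neg_track, prob_track = simulate_divergence(config, truth, seed=config.seed + 2)

    paths = {
        "reference": out / "reference.fa",
        "snps": out / "snps.tsv",
        "phylop": out / "phylop.wig",
        "phastcons": out / "phastcons_prob.wig",
        "annotations": out / "annotations.bed",
        "truth_elements": out / "truth_elements.bed",
        "truth_constraint": out / "truth_constraint.wig",
        "manifest": out / "manifest.json",
    }
    write_fasta(truth.sequence, paths["reference"])
    write_snp_table(sites, paths["snps"], reference=truth.sequence)
    phylop = ScoreTrack(neg_track.length, -neg_track.values, "phylop", neg_track.missing)
    write_score_track(phylop, paths["phylop"])
    write_score_track(prob_track, paths["phastcons"])
    write_annotations(annotations, paths["annotations"])
    write_elements(truth.elements, paths["truth_elements"])
    write_score_track(
        ScoreTrack(config.genome_length, truth.constraint, "conservation_probability"),
        paths["truth_constraint"],
    )
    manifest = {
        "seed": config.seed,
        "config": config.to_dict(),
        "config_sha256": config.digest(),
        "files": {k: v.name for k, v in paths.items() if k != "manifest"},
    }
    with open(paths["manifest"], "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return {k: str(v) for k, v in paths.items()}
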