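"""Element evaluation: overlap permutation test, summaries, and power analysis.

The permutation test asks whether polymorphism-called elements share more
base pairs with divergence-called elements than expected by chance, by
re-placing the polymorphism elements at random positions on the circular
genome.  The power analysis downsamples the per-site allele counts to
smaller sample sizes (hypergeometric draws without replacement), retrains
the HMM, and measures how much of the reference constrained sequence the
calls still recover.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .core_io import AnnotationSet, ElementSet, ScoreTrack, SiteTable
from .popcons_hmm import baum_welch_train, call_elements, viterbi_decode

DEFAULT_SIZE_GRID = tuple(range(100, 1801, 100)) + (1864,)

__all__ = [
    "OverlapTestResult",
    "PowerCurve",
    "overlap_bp",
    "permutation_overlap_test",
    "summarize_elements",
    "threshold_elements",
    "downsample_alleles",
    "power_curve",
    "element_recovery",
    "DEFAULT_SIZE_GRID",
]


def overlap_bp(a: ElementSet, b: ElementSet) -> int:
    """Base pairs covered by both interval sets."""
    if a.genome_length != b.genome_length:
        raise ValueError("element sets live on different genome lengths")
    if len(a) == 0 or len(b) == 0:
        return 0
    total = 0
    i = j = 0
    while i < len(a) and j < len(b):
        lo = max(a.starts[i], b.starts[j])
        hi = min(a.ends[i], b.ends[j])
        if hi > lo:
            total += hi - lo
        if a.ends[i] <= b.ends[j]:
            i += 1
        else:
            j += 1
    return int(total)


@dataclass
class OverlapTestResult:
    observed_bp: int
    permuted_bp: np.ndarray
    n_permutations: int
    scheme: str
    seed: int

    @property
    def p_value(self) -> float:
        """Empirical p with the +1 correction; never exactly zero."""
        exceed = int((self.permuted_bp >= self.observed_bp).sum())
        return (1 + exceed) / (1 + self.n_permutations)

    @property
    def p_report(self) -> str:
        p = self.p_value
        bound = 1.0 / (1 + self.n_permutations)
        return f"< {bound:g}" if p <= bound else f"= {p:g}"


def _placed_overlap(prefix: np.ndarray, L: int, starts: np.ndarray, lengths: np.ndarray) -> int:
    """Overlap of wrapped intervals [start, start+len) with a fixed bitmap."""
    total = 0
    for s, ln in zip(starts, lengths):
        e = s + ln
        if e <= L:
            total += prefix[e] - prefix[s]
        else:
            total += (prefix[L] - prefix[s]) + prefix[e - L]
    return int(total)


def permutation_overlap_test(
    a: ElementSet,
    b: ElementSet,
    n_perm: int = 10000,
    scheme: str = "independent_uniform_circular",
    seed: int = 0,
) -> OverlapTestResult:
    """Permutation test of the bp overlap between two element sets.

    The elements of ``a`` are randomly re-placed on the circular genome
    (``b`` stays fixed) and the overlap recomputed ``n_perm`` times.
    ``independent_uniform_circular`` places each element of ``a`` at an
    independent uniform start, preserving lengths (placed elements may
    overlap one another); ``rotation`` applies one uniform circular offset
    to all of ``a``, preserving spacing.
    """
    if scheme not in ("independent_uniform_circular", "rotation"):
        raise ValueError(f"unknown permutation scheme {scheme!r}")
    if a.genome_length != b.genome_length:
        raise ValueError("element sets live on different genome lengths")
    L = a.genome_length
    observed = overlap_bp(a, b)
    rng = np.random.default_rng(seed)
    if len(a) == 0:
        warnings.warn("empty element set: overlap test is vacuous (p = 1)", stacklevel=2)
        return OverlapTestResult(observed, np.zeros(n_perm, dtype=np.int64), n_perm, scheme, seed)

    bitmap = b.coverage_mask()
    prefix = np.concatenate(([0], np.cumsum(bitmap)))
    lengths = a.lengths
    permuted = np.empty(n_perm, dtype=np.int64)
    for p in range(n_perm):
        if scheme == "independent_uniform_circular":
            starts = rng.integers(0, L, size=len(a))
        else:
            starts = (a.starts + rng.integers(0, L)) % L
        permuted[p] = _placed_overlap(prefix, L, starts, lengths)
    return OverlapTestResult(observed, permuted, n_perm, scheme, seed)


def threshold_elements(track: ScoreTrack, threshold: float = 0.5, above: bool = True) -> ElementSet:
    """Call elements as maximal runs where the track is above (or below) a cut.

    With a conservation-probability track and the default cut this produces
    phastCons-style conserved elements from the divergence side.
    """
    values = track.values.copy()
    values[track.missing] = np.nan
    with np.errstate(invalid="ignore"):
        hit = values > threshold if above else values < threshold
    hit &= ~track.missing
    diff = np.diff(np.concatenate(([0], hit.astype(np.int8), [0])))
    starts = np.flatnonzero(diff == 1)
    ends = np.flatnonzero(diff == -1)
    return ElementSet(
        track.length,
        starts,
        ends,
        [f"divergence_{i + 1}" for i in range(len(starts))],
        source="divergence-threshold",
    )


def summarize_elements(
    elements: ElementSet, annotations: AnnotationSet, include_control: bool = False
) -> dict:
    """Count/length summary plus genic-vs-intergenic composition.

    Genic = union of gene-class spans (protein/tRNA/rRNA, plus the control
    region if ``include_control``); everything else is intergenic.
    """
    classes: tuple[str, ...] = ("protein", "tRNA", "rRNA")
    if include_control:
        classes = classes + ("control",)
    genic = annotations.class_mask(classes)
    cover = elements.coverage_mask()
    element_bp = int(cover.sum())
    genic_bp = int(genic.sum())
    intergenic_element_bp = int((cover & ~genic).sum())
    recovered_genic_bp = int((cover & genic).sum())
    return {
        "n_elements": len(elements),
        "mean_length_bp": elements.mean_length,
        "element_bp": element_bp,
        "genic_bp": genic_bp,
        "frac_element_bp_intergenic": (intergenic_element_bp / element_bp) if element_bp else 0.0,
        "frac_genic_bp_recovered": (recovered_genic_bp / genic_bp) if genic_bp else 0.0,
    }


def downsample_alleles(sites: SiteTable, n: int, seed: int = 0) -> SiteTable:
    """Redraw ``n`` chromosomes per site without replacement and recount alleles.

    A multivariate hypergeometric draw from each site's allele counts; the
    new distinct-allele count is the number of allele classes with at least
    one drawn copy.  Requires sample counts; sparse rare alleles vanish at
    small ``n``, which is exactly the power loss under study.
    """
    if sites.sample_counts is None:
        raise ValueError("downsampling requires a site table with sample counts")
    sizes = sites.sample_sizes
    too_small = np.flatnonzero(sizes < n)
    if too_small.size:
        raise ValueError(
            f"sample size {n} exceeds the {sizes[too_small[0]]} chromosomes "
            f"at site {int(too_small[0])}"
        )
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    counts = np.empty_like(sites.sample_counts)
    full = sites.sample_counts
    for i in range(sites.length):
        if sizes[i] == n:
            counts[i] = full[i]
        else:
            counts[i] = rng.multivariate_hypergeometric(full[i], n)
    allele_count = (counts > 0).sum(axis=1)
    return SiteTable(sites.length, allele_count, sites.circular, counts)


def element_recovery(called: ElementSet, reference: ElementSet) -> dict:
    """Base-level recall/precision/F1 of called elements against a reference."""
    ref = reference.coverage_mask()
    got = called.coverage_mask()
    tp = int((ref & got).sum())
    recall = tp / ref.sum() if ref.sum() else 0.0
    precision = tp / got.sum() if got.sum() else 0.0
    f1 = 2 * precision * recall / (precision + recall) if (precision + recall) else 0.0
    return {"recall": recall, "precision": precision, "f1": f1, "overlap_bp": tp}


@dataclass
class PowerCurve:
    sizes: np.ndarray
    power: np.ndarray  # base-level recall of reference-constrained bp
    precision: np.ndarray
    f1: np.ndarray
    metric: str
    seed: int
    replicates: int
    per_replicate: np.ndarray = field(default=None)  # (n_sizes, replicates) recall

    def __post_init__(self) -> None:
        self.sizes = np.asarray(self.sizes, dtype=np.int64)
        if (np.diff(self.sizes) <= 0).any():
            raise ValueError("sizes must be strictly increasing")


def power_curve(
    sites: SiteTable,
    reference_elements: ElementSet,
    sizes=DEFAULT_SIZE_GRID,
    hmm_config: dict | None = None,
    seed: int = 0,
    replicates: int = 3,
    nested: bool = True,
) -> PowerCurve:
    """Detection power versus sample size by allele downsampling.

    For each sample size: downsample, retrain the HMM on the recounted
    alleles (same fixed transitions and restart protocol), call elements by
    Viterbi, and score base-level recall of the reference-constrained bp
    (precision and F1 reported alongside).  Replicate draws are averaged.

    With ``nested`` (default), each replicate draws one chain of nested
    subsamples — the draw at size n is taken from the draw at the next
    larger size, so within a replicate the alleles observed at n are a
    subset of those at n' > n.  This common-random-numbers design removes
    the between-size sampling noise that would otherwise mask the power
    trend; ``nested=False`` draws each size independently.
    """
    hmm_config = dict(hmm_config or {})
    sizes = np.asarray(sorted(sizes), dtype=np.int64)
    recalls = np.zeros((len(sizes), replicates))
    precisions = np.zeros_like(recalls)
    f1s = np.zeros_like(recalls)
    for rep in range(replicates):
        current = sites
        for si in range(len(sizes) - 1, -1, -1):
            n = int(sizes[si])
            sub_seed = int(seed + 1000 * si + rep) % (2**31 - 1)
            source = current if nested else sites
            sub = downsample_alleles(source, n, seed=sub_seed)
            if nested:
                current = sub
            result = baum_welch_train(sub.allele_count, seed=sub_seed, **hmm_config)
            path = viterbi_decode(result.params, sub.allele_count)
            called = call_elements(path, result.functional_state, sub.length)
            scores = element_recovery(called, reference_elements)
            recalls[si, rep] = scores["recall"]
            precisions[si, rep] = scores["precision"]
            f1s[si, rep] = scores["f1"]
    return PowerCurve(
        sizes,
        recalls.mean(axis=1),
        precisions.mean(axis=1),
        f1s.mean(axis=1),
        metric="base_level_recall",
        seed=seed,
        replicates=replicates,
        per_replicate=recalls,
    )
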