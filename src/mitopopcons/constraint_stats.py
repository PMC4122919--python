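"""Polymorphism–divergence correlation analyses.

Sign convention: allele counts are always correlated against the *negated*
phyloP-like score (larger = more divergent), so purifying selection shows up
as a positive rho — sites free to diverge between species are also the sites
free to vary within the species.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from Bio.Data import CodonTable

from .core_io import AnnotationSet, ScoreTrack, SiteTable

P_FLOOR = 2.2e-16  # conventional reporting floor for vanishing p-values

SITE_CLASSES = (
    "second_codon_position",
    "fourfold_degenerate",
    "other_coding",
    "rna_gene",
    "noncoding_control",
    "noncoding_other",
)

__all__ = [
    "CorrelationResult",
    "SiteClassMask",
    "spearman",
    "window_average",
    "per_gene_correlations",
    "classify_sites",
    "maf_divergence_correlation",
    "fourfold_degenerate_prefixes",
]


@dataclass
class CorrelationResult:
    rho: float | None
    p_value: float | None
    n: int
    method: str = "spearman"
    tie_corrected: bool = True

    @property
    def p_reported(self) -> float | None:
        """p floored at 2.2e-16, the conventional smallest reportable value."""
        if self.p_value is None:
            return None
        return max(self.p_value, P_FLOOR)

    def __repr__(self) -> str:  # compact, for report printing
        if self.rho is None:
            return f"CorrelationResult(rho=undefined, n={self.n})"
        p = "< 2.2e-16" if self.p_value < P_FLOOR else f"= {self.p_value:.3g}"
        return f"CorrelationResult(rho={self.rho:.3f}, P {p}, n={self.n})"


def spearman(x, y) -> CorrelationResult:
    """Spearman rank correlation with midranks and a t-approximation p-value.

    Midranks are essential here: allele counts take only four values, so ties
    dominate.  p is two-sided from the t distribution with n - 2 df; a raw
    value below 2.2e-16 is kept but reported at the floor.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 observations")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("inputs must be finite")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("zero variance: correlation undefined", stacklevel=2)
        return CorrelationResult(None, None, n)
    rx = stats.rankdata(x, method="average")
    ry = stats.rankdata(y, method="average")
    rx = (rx - rx.mean()) / rx.std()
    ry = (ry - ry.mean()) / ry.std()
    rho = float(np.clip(np.mean(rx * ry), -1.0, 1.0))
    if abs(rho) == 1.0:
        p = 0.0
    else:
        t = rho * np.sqrt((n - 2) / (1.0 - rho * rho))
        p = float(2.0 * stats.t.sf(abs(t), df=n - 2))
    return CorrelationResult(rho, p, n)


def window_average(
    values,
    width: int,
    step: int | None = None,
    circular: bool = False,
    mask=None,
) -> np.ndarray:
    """Mean of ``values`` in genomic windows.

    ``step == width`` gives adjacent windows, ``step == 1`` sliding windows.
    Masked (missing) sites are excluded from each mean; a window with no
    usable site is NaN.  In linear mode a trailing partial window is kept
    only if it spans at least half a width; in circular mode windows wrap.
    """
    values = np.asarray(values, dtype=float)
    n = len(values)
    if width < 1 or width > n:
        raise ValueError(f"width must lie in 1..{n}")
    step = width if step is None else step
    if step < 1:
        raise ValueError("step must be >= 1")
    usable = np.isfinite(values)
    if mask is not None:
        usable &= ~np.asarray(mask, dtype=bool)

    starts = range(0, n, step) if circular else range(0, max(n - width, 0) + 1, step)
    means = []
    for s in starts:
        if circular:
            idx = np.arange(s, s + width) % n
        else:
            idx = np.arange(s, min(s + width, n))
        ok = usable[idx]
        means.append(values[idx][ok].mean() if ok.any() else np.nan)
    if not circular:
        covered = (len(means) - 1) * step + width if means else 0
        tail_start = len(means) * step
        tail = n - tail_start
        if covered < n and tail >= width / 2:
            idx = np.arange(tail_start, n)
            ok = usable[idx]
            means.append(values[idx][ok].mean() if ok.any() else np.nan)
    return np.asarray(means)


# ---------------------------------------------------------------------------
# per-gene table
# ---------------------------------------------------------------------------


def _negated_values(scores: ScoreTrack) -> np.ndarray:
    if scores.kind == "phylop":
        scores = scores.negated()
    values = scores.values.astype(float).copy()
    values[scores.missing] = np.nan
    return values


def per_gene_correlations(
    sites: SiteTable,
    scores: ScoreTrack,
    annotations: AnnotationSet,
    residuals: np.ndarray | None = None,
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, dict]:
    """Per-gene Spearman correlations between polymorphism and divergence.

    One row per gene name (records sharing a name — origin-spanning genes —
    are pooled): rho/p of allele count vs negated score inside the span, and
    a corrected column using D_ssH-adjusted GLM residuals in place of raw
    counts where ``residuals`` (genome-length, NaN outside the fitted sites)
    is given.  A Benjamini–Hochberg column is added as an extension beyond
    the raw per-gene p convention.  Returns the table and a significance
    tally at ``alpha``.
    """
    neg = _negated_values(scores)
    by_name: dict[str, list] = {}
    for rec in annotations.records:
        by_name.setdefault(rec.name, []).append(rec)

    rows = []
    for name, recs in by_name.items():
        idx = np.concatenate([np.arange(r.start, r.end) for r in recs])
        start = min(r.start for r in recs)
        end = max(r.end for r in recs)
        description = recs[0].description
        row = {
            "gene": name,
            "description": description,
            "start": start,
            "end": end,
            "rho": np.nan,
            "p": np.nan,
            "rho_corrected": np.nan,
            "p_corrected": np.nan,
        }
        ok = np.isfinite(neg[idx])
        if ok.sum() >= 3:
            x = sites.allele_count[idx][ok].astype(float)
            y = neg[idx][ok]
            if np.ptp(x) > 0 and np.ptp(y) > 0:
                res = spearman(x, y)
                row["rho"], row["p"] = res.rho, res.p_value
        if residuals is not None:
            okc = ok & np.isfinite(residuals[idx])
            if okc.sum() >= 3:
                x = residuals[idx][okc]
                y = neg[idx][okc]
                if np.ptp(x) > 0 and np.ptp(y) > 0:
                    res = spearman(x, y)
                    row["rho_corrected"], row["p_corrected"] = res.rho, res.p_value
        rows.append(row)

    table = pd.DataFrame(rows).sort_values("start", ignore_index=True)
    # BH-adjusted p as a clearly-marked extension column
    table["p_bh_extension"] = _benjamini_hochberg(table["p"].to_numpy())
    n_genes = len(table)
    tally = {
        "n_genes": n_genes,
        "n_significant": int((table["p"] < alpha).sum()),
        "n_significant_corrected": int((table["p_corrected"] < alpha).sum()),
        "alpha": alpha,
    }
    return table, tally


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    q = np.full_like(p, np.nan, dtype=float)
    ok = np.isfinite(p)
    pv = p[ok]
    m = len(pv)
    if m == 0:
        return q
    order = np.argsort(pv)
    adj = pv[order] * m / (np.arange(m) + 1)
    adj = np.minimum.accumulate(adj[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    q[ok] = out
    return q


# ---------------------------------------------------------------------------
# codon-class site labels
# ---------------------------------------------------------------------------


def fourfold_degenerate_prefixes(table_id: int = 2) -> set[str]:
    """Codon prefixes whose four third-base completions encode one amino acid.

    Uses the vertebrate mitochondrial code (translation table 2) by default.
    """
    table = CodonTable.unambiguous_dna_by_id[table_id]
    prefixes = set()
    for first in "ACGT":
        for second in "ACGT":
            aas = set()
            for third in "ACGT":
                codon = first + second + third
                aas.add("*" if codon in table.stop_codons else table.forward_table[codon])
            if len(aas) == 1 and "*" not in aas:
                prefixes.add(first + second)
    return prefixes


_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@dataclass
class SiteClassMask:
    """Per-site functional-class label over the genome."""

    labels: np.ndarray  # dtype object/str, one of SITE_CLASSES or "" (unlabeled)

    def positions(self, label: str) -> np.ndarray:
        return np.flatnonzero(self.labels == label)


def classify_sites(annotations: AnnotationSet, reference_sequence: str) -> SiteClassMask:
    """Label each site by codon class / gene class.

    Protein codons are read 5'->3' on the coding strand (minus-strand genes
    use the reverse complement).  Codon position 2 -> second_codon_position;
    position 3 -> fourfold_degenerate iff the codon prefix is 4-fold
    degenerate under the vertebrate mitochondrial code, else other_coding;
    position 1 -> other_coding.  tRNA/rRNA spans -> rna_gene; control ->
    noncoding_control; everything else -> noncoding_other.  A trailing
    partial codon is skipped with a warning; overlaps resolve by annotation
    order (first record wins) with a warning.
    """
    L = annotations.genome_length
    if len(reference_sequence) != L:
        raise ValueError("reference sequence length must match genome length")
    seq = reference_sequence.upper()
    labels = np.array([""] * L, dtype=object)
    fourfold = fourfold_degenerate_prefixes()

    for rec in annotations.records:
        span = np.arange(rec.start, rec.end)
        if rec.gene_class == "protein":
            if (labels[span] != "").any():
                warnings.warn(
                    f"gene {rec.name} overlaps previously labeled sites; "
                    "keeping earlier labels",
                    stacklevel=2,
                )
                span = span[labels[span] == ""]
                if span.size == 0:
                    continue
            gene_seq = seq[rec.start : rec.end]
            positions = np.arange(rec.start, rec.end)
            if rec.strand == "-":
                gene_seq = gene_seq.translate(_COMPLEMENT)[::-1]
                positions = positions[::-1]
            n_codons, remainder = divmod(len(gene_seq), 3)
            if remainder:
                warnings.warn(
                    f"gene {rec.name}: span not divisible by 3, "
                    f"skipping trailing partial codon ({remainder} bp)",
                    stacklevel=2,
                )
            for c in range(n_codons):
                codon = gene_seq[3 * c : 3 * c + 3]
                p1, p2, p3 = positions[3 * c : 3 * c + 3]
                if labels[p1] == "":
                    labels[p1] = "other_coding"
                if labels[p2] == "":
                    labels[p2] = "second_codon_position"
                if labels[p3] == "":
                    labels[p3] = (
                        "fourfold_degenerate" if codon[:2] in fourfold else "other_coding"
                    )
        elif rec.gene_class in ("tRNA", "rRNA"):
            sel = labels[span] == ""
            labels[span[sel]] = "rna_gene"
        elif rec.gene_class == "control":
            sel = labels[span] == ""
            labels[span[sel]] = "noncoding_control"

    labels[labels == ""] = "noncoding_other"
    return SiteClassMask(labels)


def maf_divergence_correlation(sites: SiteTable, scores: ScoreTrack) -> CorrelationResult:
    """Spearman correlation of minor allele frequency with divergence.

    Restricted to biallelic sites with sample counts; mutation-rate variation
    does not shift allele frequencies, so a positive correlation here is a
    selection signal untouched by the D_ssH gradient.
    """
    maf = sites.minor_allele_freq()
    neg = _negated_values(scores)
    ok = np.isfinite(maf) & np.isfinite(neg)
    if ok.sum() < 3:
        warnings.warn("fewer than 3 biallelic sites with scores", stacklevel=2)
        return CorrelationResult(None, None, int(ok.sum()))
    if np.ptp(maf[ok]) == 0 or np.ptp(neg[ok]) == 0:
        warnings.warn("zero variance among qualifying sites", stacklevel=2)
        return CorrelationResult(None, None, int(ok.sum()))
    return spearman(maf[ok], neg[ok])
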