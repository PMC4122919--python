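"""Readers, writers and coordinate liftover for the formats the pipeline touches.

All in-memory coordinates are 0-based, half-open.  File formats keep their
native conventions (SNP tables and fixedStep wiggle are 1-based; BED and
bedGraph are 0-based half-open) and are converted at the boundary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from Bio import Align, SeqIO
from Bio.Align import substitution_matrices

NUCLEOTIDES = "ACGT"
_NUC_INDEX = {b: i for i, b in enumerate(NUCLEOTIDES)}

GENE_CLASSES = ("protein", "tRNA", "rRNA", "control", "other")

__all__ = [
    "SiteTable",
    "ScoreTrack",
    "AnnotationSet",
    "GeneRecord",
    "ElementSet",
    "CoordinateMap",
    "read_fasta",
    "write_fasta",
    "read_snp_table",
    "write_snp_table",
    "read_score_track",
    "write_score_track",
    "read_annotations",
    "write_annotations",
    "read_elements",
    "write_elements",
    "build_coordinate_map",
    "lift_position",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class SiteTable:
    """Per-site polymorphism summary over a whole (usually circular) genome.

    ``allele_count[i]`` is the number of distinct nucleotide alleles observed
    at site ``i`` (1 = monomorphic, at most 4).  ``sample_counts`` optionally
    records, per site, how many sampled chromosomes carry each of the four
    nucleotides (A, C, G, T columns); its row sums are the per-site sample
    sizes.
    """

    length: int
    allele_count: np.ndarray
    circular: bool = True
    sample_counts: np.ndarray | None = None  # shape (length, 4), int64

    def __post_init__(self) -> None:
        self.allele_count = np.asarray(self.allele_count, dtype=np.int64)
        if self.allele_count.shape != (self.length,):
            raise ValueError("allele_count length does not match genome length")
        if self.allele_count.min(initial=1) < 1 or self.allele_count.max(initial=1) > 4:
            raise ValueError("allele counts must lie in 1..4")
        if self.sample_counts is not None:
            self.sample_counts = np.asarray(self.sample_counts, dtype=np.int64)
            if self.sample_counts.shape != (self.length, 4):
                raise ValueError("sample_counts must have shape (length, 4)")
            observed = (self.sample_counts > 0).sum(axis=1)
            if not np.array_equal(observed, self.allele_count):
                raise ValueError("allele_count inconsistent with sample_counts")

    @property
    def sample_sizes(self) -> np.ndarray:
        if self.sample_counts is None:
            raise ValueError("site table carries no sample counts")
        return self.sample_counts.sum(axis=1)

    def minor_allele_freq(self) -> np.ndarray:
        """MAF per site; NaN where the site is not biallelic or counts absent."""
        maf = np.full(self.length, np.nan)
        if self.sample_counts is None:
            return maf
        biallelic = self.allele_count == 2
        counts = self.sample_counts[biallelic]
        n = counts.sum(axis=1)
        minor = np.sort(counts, axis=1)[:, -2]  # second largest = minor allele
        maf[biallelic] = minor / n
        return maf


@dataclass
class ScoreTrack:
    """Per-site real-valued divergence/conservation measure."""

    length: int
    values: np.ndarray
    kind: str  # phylop | negated_phylop | conservation_probability
    missing: np.ndarray | None = None  # True where no value was observed

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.length,):
            raise ValueError("track values length mismatch")
        if self.missing is None:
            self.missing = np.zeros(self.length, dtype=bool)
        else:
            self.missing = np.asarray(self.missing, dtype=bool)
            if self.missing.shape != (self.length,):
                raise ValueError("mask length must equal track length")
        if self.kind == "conservation_probability":
            ok = self.values[~self.missing]
            if ok.size and (ok.min() < 0 or ok.max() > 1):
                raise ValueError("conservation probabilities must lie in [0, 1]")

    def negated(self) -> "ScoreTrack":
        """Sign-flip a phyloP-style track so that larger = more divergent."""
        if self.kind == "negated_phylop":
            return self
        if self.kind != "phylop":
            raise ValueError(f"cannot negate a track of kind {self.kind!r}")
        return ScoreTrack(self.length, -self.values, "negated_phylop", self.missing.copy())


@dataclass
class GeneRecord:
    name: str
    start: int
    end: int
    strand: str
    gene_class: str
    description: str = ""


@dataclass
class AnnotationSet:
    """Gene intervals with class and strand on one (circular) genome.

    An interval crossing the origin is stored as two records sharing a name.
    """

    genome_length: int
    records: list[GeneRecord] = field(default_factory=list)
    circular: bool = True

    def __post_init__(self) -> None:
        for rec in self.records:
            if not (0 <= rec.start < rec.end <= self.genome_length):
                raise ValueError(f"record {rec.name}: interval out of range")
            if rec.strand not in "+-":
                raise ValueError(f"record {rec.name}: bad strand {rec.strand!r}")
            if rec.gene_class not in GENE_CLASSES:
                raise ValueError(f"record {rec.name}: unknown class {rec.gene_class!r}")

    def by_class(self, gene_class: str) -> list[GeneRecord]:
        return [r for r in self.records if r.gene_class == gene_class]

    def class_mask(self, classes: tuple[str, ...]) -> np.ndarray:
        mask = np.zeros(self.genome_length, dtype=bool)
        for rec in self.records:
            if rec.gene_class in classes:
                mask[rec.start : rec.end] = True
        return mask


@dataclass
class ElementSet:
    """Called constrained intervals: half-open, sorted, non-overlapping."""

    genome_length: int
    starts: np.ndarray
    ends: np.ndarray
    labels: list[str] | None = None
    source: str = ""

    def __post_init__(self) -> None:
        self.starts = np.asarray(self.starts, dtype=np.int64)
        self.ends = np.asarray(self.ends, dtype=np.int64)
        if self.starts.shape != self.ends.shape:
            raise ValueError("starts/ends length mismatch")
        if self.labels is None:
            self.labels = [f"element_{i}" for i in range(len(self.starts))]
        if self.starts.size:
            if (self.starts >= self.ends).any():
                raise ValueError("empty or inverted interval")
            if self.starts.min() < 0 or self.ends.max() > self.genome_length:
                raise ValueError("interval outside genome")
            if (np.diff(self.starts) <= 0).any() or (self.starts[1:] < self.ends[:-1]).any():
                raise ValueError("intervals must be sorted and non-overlapping")

    def __len__(self) -> int:
        return len(self.starts)

    @property
    def lengths(self) -> np.ndarray:
        return self.ends - self.starts

    @property
    def total_bp(self) -> int:
        return int(self.lengths.sum()) if len(self) else 0

    @property
    def mean_length(self) -> float:
        return float(self.lengths.mean()) if len(self) else 0.0

    def coverage_mask(self) -> np.ndarray:
        mask = np.zeros(self.genome_length, dtype=bool)
        for s, e in zip(self.starts, self.ends):
            mask[s:e] = True
        return mask


@dataclass
class CoordinateMap:
    """Position map between two reference dialects from one global alignment.

    ``mapping[i]`` is the aligned target position of source position ``i`` or
    -1 where the source base has no counterpart in the target.
    """

    source_length: int
    target_length: int
    mapping: np.ndarray

    NONE = -1

    def __post_init__(self) -> None:
        self.mapping = np.asarray(self.mapping, dtype=np.int64)
        if self.mapping.shape != (self.source_length,):
            raise ValueError("map length must equal source length")
        defined = self.mapping[self.mapping >= 0]
        if defined.size and (np.diff(defined) <= 0).any():
            raise ValueError("defined target positions must be strictly increasing")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta(path) -> str:
    record = next(SeqIO.parse(str(path), "fasta"))
    return str(record.seq).upper()


def write_fasta(seq: str, path, name: str = "chrM") -> None:
    with open(path, "w") as fh:
        fh.write(f">{name}\n")
        for i in range(0, len(seq), 70):
            fh.write(seq[i : i + 70] + "\n")


# ---------------------------------------------------------------------------
# SNP tables
# ---------------------------------------------------------------------------


def read_snp_table(
    path,
    dialect: str = "positions_with_alleles",
    genome_length: int | None = None,
    n_samples: int | None = None,
) -> SiteTable:
    """Read a tab-separated SNP table into a full-length :class:`SiteTable`.

    Rows are ``position<TAB>ref<TAB>alt[<TAB>count]`` with 1-based positions,
    one row per alternate allele.  Positions absent from the file are filled
    as monomorphic.  Insertion/deletion alleles (multi-base or ``-`` symbols)
    are skipped with a warning; only SNPs are analyzed.

    With ``dialect="positions_with_counts"`` the fourth column gives the
    number of sampled chromosomes carrying the alternate allele, and the
    reference allele receives the remainder of ``n_samples`` (taken from the
    ``#n_samples=`` header if not passed explicitly).
    """
    if dialect not in ("positions_with_alleles", "positions_with_counts"):
        raise ValueError(f"unknown SNP table dialect {dialect!r}")
    rows: list[tuple[int, str, str, int]] = []
    header_n = None
    header_len = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                if line.startswith("#n_samples="):
                    header_n = int(line.split("=", 1)[1])
                elif line.startswith("#genome_length="):
                    header_len = int(line.split("=", 1)[1])
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"line {lineno}: expected at least 3 columns")
            pos = int(parts[0])
            ref, alt = parts[1].upper(), parts[2].upper()
            if len(ref) != 1 or len(alt) != 1 or ref == "-" or alt == "-":
                warnings.warn(
                    f"line {lineno}: skipping non-SNP variant {ref}>{alt}", stacklevel=2
                )
                continue
            for sym in (ref, alt):
                if sym not in _NUC_INDEX:
                    raise ValueError(f"line {lineno}: non-ACGT allele symbol {sym!r}")
            count = int(parts[3]) if dialect == "positions_with_counts" else 0
            rows.append((pos, ref, alt, count))

    if genome_length is None:
        genome_length = header_len
    if genome_length is None:
        raise ValueError("genome_length required (no #genome_length= header found)")
    if n_samples is None:
        n_samples = header_n

    for pos, _, _, _ in rows:
        if not (1 <= pos <= genome_length):
            raise ValueError(f"position {pos} out of range 1..{genome_length}")

    if dialect == "positions_with_alleles":
        seen: list[set[str]] = [set() for _ in range(genome_length)]
        for pos, ref, alt, _ in rows:
            seen[pos - 1].update((ref, alt))
        allele_count = np.array([max(1, len(s)) for s in seen], dtype=np.int64)
        return SiteTable(genome_length, np.minimum(allele_count, 4))

    if n_samples is None:
        raise ValueError("positions_with_counts dialect requires n_samples")
    counts = np.zeros((genome_length, 4), dtype=np.int64)
    refs: dict[int, str] = {}
    for pos, ref, alt, count in rows:
        counts[pos - 1, _NUC_INDEX[alt]] += count
        refs[pos - 1] = ref
    # reference allele carries the remaining chromosomes
    for i in range(genome_length):
        ref_idx = _NUC_INDEX[refs[i]] if i in refs else 0
        remainder = n_samples - counts[i].sum()
        if remainder < 0:
            raise ValueError(f"position {i + 1}: allele counts exceed n_samples")
        counts[i, ref_idx] += remainder
    allele_count = (counts > 0).sum(axis=1)
    return SiteTable(genome_length, allele_count, sample_counts=counts)


def write_snp_table(sites: SiteTable, path, reference: str | None = None) -> None:
    """Write a SiteTable with sample counts as a ``positions_with_counts`` TSV."""
    if sites.sample_counts is None:
        raise ValueError("writing requires sample counts")
    n = int(sites.sample_sizes.max()) if sites.length else 0
    with open(path, "w") as fh:
        fh.write("#position\tref\talt\tcount\n")
        fh.write(f"#genome_length={sites.length}\n")
        fh.write(f"#n_samples={n}\n")
        for i in range(sites.length):
            row = sites.sample_counts[i]
            if (row > 0).sum() <= 1:
                continue
            ref_idx = int(np.argmax(row)) if reference is None else _NUC_INDEX[reference[i]]
            for j in np.flatnonzero(row):
                if j == ref_idx:
                    continue
                fh.write(f"{i + 1}\t{NUCLEOTIDES[ref_idx]}\t{NUCLEOTIDES[j]}\t{row[j]}\n")


# ---------------------------------------------------------------------------
# score tracks (fixedStep wiggle / bedGraph)
# ---------------------------------------------------------------------------


def read_score_track(path, format: str = "wiggle", kind: str = "phylop", length: int | None = None) -> ScoreTrack:
    """Read a per-site score track from fixedStep wiggle or bedGraph."""
    if format not in ("wiggle", "bedGraph"):
        raise ValueError(f"unknown track format {format!r}")
    entries: list[tuple[int, int, float]] = []  # 0-based half-open
    if format == "wiggle":
        pos = step = None
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith(("#", "track")):
                    continue
                if line.startswith("fixedStep"):
                    fields = dict(kv.split("=") for kv in line.split()[1:])
                    pos = int(fields["start"]) - 1
                    step = int(fields.get("step", 1))
                    span = int(fields.get("span", 1))
                    continue
                if pos is None:
                    raise ValueError("wiggle data before fixedStep header")
                entries.append((pos, pos + span, float(line)))
                pos += step
    else:
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith(("#", "track")):
                    continue
                _, start, end, value = line.split()[:4]
                entries.append((int(start), int(end), float(value)))

    if length is None:
        length = max(e for _, e, _ in entries) if entries else 0
    values = np.zeros(length)
    missing = np.ones(length, dtype=bool)
    for start, end, value in entries:
        if end > length:
            raise ValueError(f"interval [{start}, {end}) beyond track length {length}")
        if not missing[start:end].all():
            raise ValueError(f"overlapping intervals at [{start}, {end})")
        values[start:end] = value
        missing[start:end] = False
    return ScoreTrack(length, values, kind, missing)


def write_score_track(track: ScoreTrack, path, chrom: str = "chrM") -> None:
    """Write as fixedStep wiggle (one value per covered site)."""
    with open(path, "w") as fh:
        pos = 0
        while pos < track.length:
            if track.missing[pos]:
                pos += 1
                continue
            fh.write(f"fixedStep chrom={chrom} start={pos + 1} step=1\n")
            while pos < track.length and not track.missing[pos]:
                fh.write(f"{track.values[pos]:.6g}\n")
                pos += 1


# ---------------------------------------------------------------------------
# annotations and elements (BED dialects)
# ---------------------------------------------------------------------------


def read_annotations(path, genome_length: int | None = None) -> AnnotationSet:
    """Read BED6 annotations; gene class rides in column 4 as ``name|class``.

    An optional ``description`` is a third ``|``-separated field.
    """
    records = []
    max_end = 0
    header_len = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                if line.startswith("#genome_length="):
                    header_len = int(line.split("=", 1)[1])
                continue
            if line.startswith(("track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise ValueError(f"line {lineno}: BED6 requires 6 columns")
            start, end = int(parts[1]), int(parts[2])
            name_field = parts[3].split("|")
            if len(name_field) < 2:
                raise ValueError(f"line {lineno}: column 4 must be name|class[|description]")
            name, gene_class = name_field[0], name_field[1]
            description = name_field[2] if len(name_field) > 2 else ""
            if gene_class not in GENE_CLASSES:
                raise ValueError(f"line {lineno}: unknown class token {gene_class!r}")
            records.append(GeneRecord(name, start, end, parts[5], gene_class, description))
            max_end = max(max_end, end)
    if genome_length is None:
        genome_length = header_len if header_len is not None else max_end
    return AnnotationSet(genome_length, records)


def write_annotations(annotations: AnnotationSet, path, chrom: str = "chrM") -> None:
    with open(path, "w") as fh:
        fh.write(f"#genome_length={annotations.genome_length}\n")
        for rec in sorted(annotations.records, key=lambda r: r.start):
            name = f"{rec.name}|{rec.gene_class}"
            if rec.description:
                name += f"|{rec.description}"
            fh.write(f"{chrom}\t{rec.start}\t{rec.end}\t{name}\t0\t{rec.strand}\n")


def read_elements(path, genome_length: int | None = None, source: str = "") -> ElementSet:
    starts, ends, labels = [], [], []
    header_len = None
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                if line.startswith("#genome_length="):
                    header_len = int(line.split("=", 1)[1])
                continue
            if line.startswith(("track", "browser")):
                continue
            parts = line.split("\t")
            starts.append(int(parts[1]))
            ends.append(int(parts[2]))
            labels.append(parts[3] if len(parts) > 3 else f"element_{len(starts)}")
    if genome_length is None:
        genome_length = header_len if header_len is not None else (max(ends) if ends else 0)
    order = np.argsort(starts) if starts else []
    return ElementSet(
        genome_length,
        np.asarray(starts)[order] if starts else np.array([], dtype=np.int64),
        np.asarray(ends)[order] if ends else np.array([], dtype=np.int64),
        [labels[i] for i in order] if starts else [],
        source=source,
    )


def write_elements(elements: ElementSet, path, chrom: str = "chrM") -> None:
    with open(path, "w") as fh:
        fh.write(f"#genome_length={elements.genome_length}\n")
        for s, e, lab in zip(elements.starts, elements.ends, elements.labels):
            fh.write(f"{chrom}\t{s}\t{e}\t{lab}\n")


# ---------------------------------------------------------------------------
# coordinate liftover
# ---------------------------------------------------------------------------


def _substitution_matrix(match: float, mismatch: float):
    """ACGTN matrix; N is scored as a mismatch against everything, itself included."""
    alphabet = "ACGTN"
    mat = substitution_matrices.Array(alphabet, dims=2)
    for a in alphabet:
        for b in alphabet:
            mat[a, b] = match if (a == b and a != "N") else mismatch
    return mat


def build_coordinate_map(
    seq_source: str,
    seq_target: str,
    match: float = 1.0,
    mismatch: float = -2.0,
    gap_open: float = -5.0,
    gap_extend: float = -1.0,
) -> CoordinateMap:
    """Globally align two reference dialects and derive a position map.

    Affine gap costs: a gap of length L scores ``gap_open + L * gap_extend``.
    Source positions aligned to a target gap map to ``CoordinateMap.NONE``.
    """
    seq_source, seq_target = seq_source.upper(), seq_target.upper()
    if not seq_source or not seq_target:
        raise ValueError("empty sequence")
    for seq in (seq_source, seq_target):
        bad = set(seq) - set("ACGTN")
        if bad:
            raise ValueError(f"sequence contains non-ACGTN symbols: {sorted(bad)}")
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = _substitution_matrix(match, mismatch)
    aligner.open_gap_score = gap_open + gap_extend
    aligner.extend_gap_score = gap_extend
    alignment = aligner.align(seq_source, seq_target)[0]
    mapping = np.full(len(seq_source), CoordinateMap.NONE, dtype=np.int64)
    src_blocks, tgt_blocks = alignment.aligned
    for (s0, s1), (t0, t1) in zip(src_blocks, tgt_blocks):
        mapping[s0:s1] = np.arange(t0, t1)
    cmap = CoordinateMap(len(seq_source), len(seq_target), mapping)
    cmap.score = float(alignment.score)  # kept for diagnostics
    return cmap


def lift_position(cmap: CoordinateMap, pos: int) -> int | None:
    """Lift a 0-based source position; None where the base was deleted."""
    if not (0 <= pos < cmap.source_length):
        raise ValueError(f"position {pos} outside source 0..{cmap.source_length - 1}")
    target = int(cmap.mapping[pos])
    return None if target == CoordinateMap.NONE else target
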