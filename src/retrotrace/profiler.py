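"""Read assignment and truncation-aware tRNA profiling.

Assigns small-RNA reads uniquely to tRNA genes, infers how many 3'
nucleotides each read is missing relative to the CCA-mature transcript
(k=0 intact, k=1 missing the terminal A, k=3 missing the whole CCA, ...),
and aggregates assignments into per-(gene, missing_3p) count matrices,
3'-end truncation spectra and per-position transcript coverage.

Two input routes exist:

* a built-in exact matcher against the truncation reference, intended for
  synthetic or error-free reads (reads are looked up as full-length
  truncated transcript variants; ties between genes are discarded as
  non-unique, matching a uniquely-mapped-reads-only counting rule);
* SAM/BAM alignments produced by any external aligner, either against the
  truncation reference (``gene::missK`` names) or against the mature
  reference (gene names; missing_3p is then inferred from the alignment
  end, with soft-clipped 3' bases not counting as evidence).

Coordinates are 1-based inclusive transcript coordinates internally.
"""

from __future__ import annotations

import gzip
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
import pysam
from Bio import SeqIO

from .reference import TruncationReference

FRACTIONS = ("nucleus", "cytosol")
CONDITIONS = ("control", "treated")

#: Reads shorter than this are discarded (tRNA-fragment biology is out of scope).
MIN_READ_LENGTH = 15


class ProfilerError(ValueError):
    pass


@dataclass(frozen=True)
class SampleDesign:
    """One sequencing sample: subcellular fraction x condition x replicate."""

    sample_id: str
    fraction: str
    condition: str
    replicate: int
    path: Optional[str] = None

    def __post_init__(self) -> None:
        if self.fraction not in FRACTIONS:
            raise ProfilerError(f"fraction must be one of {FRACTIONS}, got {self.fraction!r}")
        if self.condition not in CONDITIONS:
            raise ProfilerError(f"condition must be one of {CONDITIONS}, got {self.condition!r}")
        if self.replicate < 1:
            raise ProfilerError("replicate must be a positive integer")


def validate_design(design: Sequence[SampleDesign]) -> None:
    """Check sample ids and (fraction, condition, replicate) triples are unique."""
    ids = [d.sample_id for d in design]
    if len(set(ids)) != len(ids):
        raise ProfilerError("duplicate sample_id in design")
    triples = [(d.fraction, d.condition, d.replicate) for d in design]
    if len(set(triples)) != len(triples):
        raise ProfilerError("duplicate (fraction, condition, replicate) triple in design")


def load_design(path: Union[str, Path]) -> list[SampleDesign]:
    """Read a design table TSV: sample_id, fraction, condition, replicate[, path]."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "fraction", "condition", "replicate"}
    missing = required - set(df.columns)
    if missing:
        raise ProfilerError(f"design table missing columns: {sorted(missing)}")
    design = [
        SampleDesign(
            r["sample_id"], r["fraction"], r["condition"], int(r["replicate"]),
            r.get("path") if isinstance(r.get("path"), str) else None,
        )
        for r in df.to_dict("records")
    ]
    validate_design(design)
    return design


@dataclass(frozen=True)
class ReadAssignment:
    """A read's unique gene assignment with its inferred 3' truncation."""

    read_id: str
    gene_id: Optional[str]
    missing_3p: int
    unique: bool
    start: int = 1  # 1-based transcript start of the aligned interval


def infer_missing_3p(alignment_end: int, gene_mature_length: int, max_missing: int = 13) -> int:
    """Missing 3' nucleotides from a 1-based inclusive alignment end.

    Reads ending more than ``max_missing`` nt short of the mature 3'
    terminus are binned at ``max_missing``.
    """
    if alignment_end <= 0:
        raise ProfilerError(f"alignment_end must be positive, got {alignment_end}")
    if alignment_end > gene_mature_length:
        raise ProfilerError(
            f"alignment end {alignment_end} beyond mature length {gene_mature_length}"
        )
    return min(gene_mature_length - alignment_end, max_missing)


class ExactMatcher:
    """Exact full-sequence lookup against the truncation reference.

    A read is unique when exactly one gene's variant matches it; reads
    matching variants of more than one gene are flagged non-unique and
    excluded from counting.  Decoy hits are treated as unassigned.
    """

    def __init__(self, ref: TruncationReference):
        self.ref = ref
        index: dict[str, list[tuple[str, int]]] = {}
        for gid, k, seq in ref.entries:
            index.setdefault(seq, []).append((gid, k))
        self._index = index
        self._decoys = {seq for _, seq in ref.decoys}

    def assign(self, read_id: str, seq: str) -> Optional[ReadAssignment]:
        seq = seq.upper().replace("U", "T")
        if len(seq) < MIN_READ_LENGTH:
            return None
        if seq in self._decoys:
            return None
        hits = self._index.get(seq)
        if hits is None:
            return None
        genes = {g for g, _ in hits}
        if len(genes) > 1:
            return ReadAssignment(read_id, None, 0, unique=False)
        gid, k = min(hits, key=lambda t: t[1])  # deepest-3' evidence wins ties
        return ReadAssignment(read_id, gid, k, unique=True)


def _iter_reads(reads: Union[str, Path, Iterable[tuple[str, str]]]):
    if isinstance(reads, (str, Path)):
        path = Path(reads)
        opener = gzip.open if path.suffix == ".gz" else open
        with opener(path, "rt") as fh:
            for rec in SeqIO.parse(fh, "fastq"):
                yield rec.id, str(rec.seq)
    else:
        yield from reads


def assign_reads(
    reads: Union[str, Path, Iterable[tuple[str, str]]],
    ref: TruncationReference,
) -> list[ReadAssignment]:
    """Assign reads (FASTQ path or (id, seq) pairs) with the exact matcher.

    The result is independent of input order: each read is scored on its
    own sequence only.
    """
    matcher = ExactMatcher(ref)
    out: list[ReadAssignment] = []
    n = 0
    for read_id, seq in _iter_reads(reads):
        n += 1
        a = matcher.assign(read_id, seq)
        if a is not None:
            out.append(a)
    if n == 0:
        warnings.warn("no reads in input", stacklevel=2)
    return out


def assign_alignments(
    path: Union[str, Path],
    ref: TruncationReference,
    max_missing: Optional[int] = None,
) -> list[ReadAssignment]:
    """Convert SAM/BAM alignments into read assignments.

    Reference names may be truncation-reference entries (``gene::missK``)
    or mature gene ids; in the latter case missing_3p is inferred from the
    alignment end (``reference_end`` excludes soft clips, so clipped 3'
    bases are absence of evidence).  Secondary/supplementary records are
    skipped; multimapped primaries (MAPQ 0 or NH>1) are flagged non-unique.
    """
    if max_missing is None:
        max_missing = ref.max_missing
    known = {TruncationReference.entry_name(g, k) for g, k, _ in ref.entries}
    known |= set(ref.genes)
    out: list[ReadAssignment] = []
    mode = "rb" if str(path).endswith(".bam") else "r"
    with pysam.AlignmentFile(str(path), mode, check_sq=False) as fh:
        for aln in fh:
            if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                continue
            rname = aln.reference_name
            if rname not in known and not rname.startswith("decoy::"):
                raise ProfilerError(f"alignment reference {rname!r} not in manifest")
            if rname.startswith("decoy::"):
                continue
            multi = aln.mapping_quality == 0 or (
                aln.has_tag("NH") and aln.get_tag("NH") > 1
            )
            if "::miss" in rname:
                gid, k = rname.split("::miss")
                k = int(k)
            else:
                gid = rname
                k = infer_missing_3p(
                    aln.reference_end, ref.mature_length(gid), max_missing
                )
            out.append(
                ReadAssignment(
                    aln.query_name, None if multi else gid, k,
                    unique=not multi, start=aln.reference_start + 1,
                )
            )
    return out


def count_matrix(
    assignments_by_sample: Mapping[str, Sequence[ReadAssignment]],
    design: Sequence[SampleDesign],
    ref: TruncationReference,
) -> pd.DataFrame:
    """Per-(gene, missing_3p) x sample integer counts from unique assignments.

    All (gene, k) rows of the reference are retained, including all-zero
    ones, so downstream filters see every gene.
    """
    validate_design(design)
    sample_ids = [d.sample_id for d in design]
    for sid in assignments_by_sample:
        if sid not in sample_ids:
            raise ProfilerError(f"unknown sample label {sid!r}")
    index = pd.MultiIndex.from_tuples(
        [(g, k) for g, k, _ in ref.entries], names=["gene_id", "missing_3p"]
    )
    mat = pd.DataFrame(0, index=index, columns=sample_ids, dtype=np.int64)
    pos = {key: i for i, key in enumerate(index)}
    for sid, assignments in assignments_by_sample.items():
        col = np.zeros(len(index), dtype=np.int64)
        for a in assignments:
            if a.unique and a.gene_id is not None:
                col[pos[(a.gene_id, a.missing_3p)]] += 1
        mat[sid] = col
    return mat


def truncation_spectrum(
    counts: pd.DataFrame, samples: Optional[Sequence[str]] = None
) -> pd.Series:
    """Pooled fraction of reads at each missing_3p value across a sample group."""
    cols = list(samples) if samples is not None else list(counts.columns)
    if not cols:
        raise ProfilerError("empty sample group")
    by_k = counts[cols].sum(axis=1).groupby(level="missing_3p").sum()
    total = by_k.sum()
    if total == 0:
        raise ProfilerError("all-zero counts in sample group")
    return by_k / total


def gene_spectra(
    counts: pd.DataFrame, samples: Optional[Sequence[str]] = None
) -> pd.DataFrame:
    """Per-gene truncation spectra (rows: gene_id, columns: missing_3p).

    Genes with zero reads in the group get NaN rows rather than dividing
    by zero.
    """
    cols = list(samples) if samples is not None else list(counts.columns)
    pooled = counts[cols].sum(axis=1).unstack("missing_3p", fill_value=0)
    totals = pooled.sum(axis=1)
    return pooled.div(totals.where(totals > 0), axis=0)


def positional_coverage(
    assignments: Sequence[ReadAssignment], gene_id: str, ref: TruncationReference
) -> np.ndarray:
    """Unique-read depth at each 1-based transcript position of one gene."""
    if gene_id not in ref.genes:
        raise ProfilerError(f"unknown gene {gene_id!r}")
    length = ref.mature_length(gene_id)
    cov = np.zeros(length, dtype=np.int64)
    for a in assignments:
        if not a.unique or a.gene_id != gene_id:
            continue
        end = length - a.missing_3p
        cov[a.start - 1 : end] += 1
    return cov
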