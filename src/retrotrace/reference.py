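"""Truncation-aware tRNA reference construction.

Mature tRNAs universally end in the trinucleotide CCA, added
post-transcriptionally by tRNA nucleotidyl transferase.  Reads that stop
short of the mature 3' terminus mark "defective" tRNAs (missing >= 1 nt),
and the number of missing 3' nucleotides is the central read-level
observable of this package.  To assign reads at single-nucleotide 3'
resolution, the reference holds, for every tRNA gene, the mature
(CCA-ending) transcript plus every 3'-truncated variant missing up to
``max_missing`` nucleotides (default 13).

Gene sets are loaded from FASTA.  Two header dialects are understood:

* native: ``>gene_id|amino_acid|anticodon|pseudo={0,1}``
* gtRNAdb-style names embedded in the header, e.g.
  ``Homo_sapiens_tRNA-Ala-AGC-1-1`` (isotype "Und" is treated as a
  pseudogene; no explicit pseudo flag exists in this dialect).

All sequences are normalized to the DNA alphabet (U -> T, uppercase) on
load, because sequencing reads live in DNA space.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

#: The 20 standard isotypes plus selenocysteine (Sec).
AMINO_ACIDS = frozenset(
    [
        "Ala", "Arg", "Asn", "Asp", "Cys", "Gln", "Glu", "Gly", "His",
        "Ile", "Leu", "Lys", "Met", "Phe", "Pro", "Ser", "Thr", "Trp",
        "Tyr", "Val", "Sec",
    ]
)

_AA_ALIASES = {"SeC": "Sec", "SEC": "Sec", "iMet": "Met", "fMet": "Met"}

_GTRNADB_RE = re.compile(
    r"tRNA-(?P<aa>[A-Za-z]{2,4})-(?P<ac>[A-Za-z]{3})(?:-\d+)*", re.IGNORECASE
)

_VALID_SEQ_RE = re.compile(r"^[ACGT]+$")


class ReferenceError(ValueError):
    """Raised for malformed gene inputs or inconsistent reference builds."""


def normalize_sequence(seq: str) -> str:
    """Uppercase and convert RNA (U) to DNA (T); reject other symbols."""
    s = str(seq).strip().upper().replace("U", "T")
    if not s:
        raise ReferenceError("empty sequence")
    if not _VALID_SEQ_RE.match(s):
        bad = sorted(set(s) - set("ACGT"))
        raise ReferenceError(f"sequence contains non-ACGT symbols: {bad}")
    return s


@dataclass(frozen=True)
class TRNAGene:
    """A single tRNA gene with its genomic sequence and annotation.

    ``mature_seq`` is derived from ``genomic_seq`` by appending CCA when it
    is not genomically encoded; genomically encoded CCA is treated
    identically to an enzymatically added one.
    """

    gene_id: str
    amino_acid: str
    anticodon: str
    genomic_seq: str
    is_pseudogene: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "genomic_seq", normalize_sequence(self.genomic_seq))
        object.__setattr__(self, "anticodon", normalize_sequence(self.anticodon))
        if len(self.anticodon) != 3:
            raise ReferenceError(
                f"{self.gene_id}: anticodon must be a triplet, got {self.anticodon!r}"
            )
        aa = _AA_ALIASES.get(self.amino_acid, self.amino_acid)
        object.__setattr__(self, "amino_acid", aa)
        if aa not in AMINO_ACIDS and not self.is_pseudogene:
            raise ReferenceError(f"{self.gene_id}: unknown isotype {aa!r}")

    @property
    def mature_seq(self) -> str:
        return mature_sequence(self)


def mature_sequence(gene: Union[TRNAGene, str]) -> str:
    """Return the CCA-mature transcript for a gene (or raw sequence).

    If the input already ends in CCA it is returned unchanged, so the
    operation is idempotent; otherwise CCA is appended.
    """
    seq = gene.genomic_seq if isinstance(gene, TRNAGene) else normalize_sequence(gene)
    if len(seq) < 10:
        raise ReferenceError(f"degenerate gene sequence of length {len(seq)} (< 10 nt)")
    return seq if seq.endswith("CCA") else seq + "CCA"


def _parse_header(header: str) -> Optional[tuple[str, str, str, bool]]:
    """Parse a FASTA header into (gene_id, amino_acid, anticodon, pseudo).

    Returns None when neither dialect matches.
    """
    name = header.split()[0]
    if "|" in name:
        parts = name.split("|")
        if len(parts) == 4 and parts[3].startswith("pseudo="):
            flag = parts[3].split("=", 1)[1]
            if flag not in ("0", "1"):
                return None
            return parts[0], parts[1], parts[2], flag == "1"
        return None
    m = _GTRNADB_RE.search(name)
    if m is None:
        return None
    aa = m.group("aa")
    aa = _AA_ALIASES.get(aa, aa.capitalize() if aa.islower() or aa.isupper() else aa)
    pseudo = aa.lower() == "und"
    return name, aa, m.group("ac"), pseudo


def load_trna_genes(fasta_path: Union[str, Path], drop_pseudogenes: bool = True,
                    min_length: int = 60, max_length: int = 120) -> list[TRNAGene]:
    """Load tRNA genes from FASTA, optionally excluding pseudogenes.

    Mirrors the construction of a gtRNAdb-derived gene set with pseudogenes
    removed.  Mature lengths outside ``[min_length, max_length]`` are
    rejected as implausible for cytoplasmic-type tRNAs.
    """
    fasta_path = Path(fasta_path)
    genes: list[TRNAGene] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        parsed = _parse_header(rec.description)
        if parsed is None:
            raise ReferenceError(
                f"unparseable FASTA header for record {rec.id!r} in {fasta_path}"
            )
        gene_id, aa, anticodon, pseudo = parsed
        if gene_id in seen:
            raise ReferenceError(f"duplicate gene_id {gene_id!r} in {fasta_path}")
        seen.add(gene_id)
        if pseudo and drop_pseudogenes:
            continue
        if pseudo and aa not in AMINO_ACIDS and aa not in _AA_ALIASES:
            aa = "Und"  # retained pseudogene with unknown isotype
        gene = TRNAGene(gene_id, aa, anticodon, str(rec.seq), is_pseudogene=pseudo)
        n = len(gene.mature_seq)
        if not (min_length <= n <= max_length):
            raise ReferenceError(
                f"{gene_id}: mature length {n} outside [{min_length}, {max_length}]"
            )
        genes.append(gene)
    if not seen:
        raise ReferenceError(f"no FASTA records found in {fasta_path}")
    return genes


@dataclass
class TruncationReference:
    """Mature transcripts plus all 3'-truncated variants (0..K missing nt).

    ``entries`` holds (gene_id, missing_3p, sequence) triples ordered by
    gene_id then missing_3p ascending; entry k is the mature sequence with
    its last k nucleotides removed, so k=3 lacks the whole CCA.
    """

    genes: dict[str, TRNAGene]
    max_missing: int
    entries: list[tuple[str, int, str]]
    decoys: list[tuple[str, str]] = field(default_factory=list)

    @staticmethod
    def entry_name(gene_id: str, missing_3p: int) -> str:
        return f"{gene_id}::miss{missing_3p}"

    def mature_length(self, gene_id: str) -> int:
        return len(self.genes[gene_id].mature_seq)

    @property
    def gene_ids(self) -> list[str]:
        return sorted(self.genes)

    def write(self, outdir: Union[str, Path]) -> tuple[Path, Path]:
        """Serialize to ``reference.fa`` + ``manifest.tsv`` under *outdir*."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        fasta = outdir / "reference.fa"
        manifest = outdir / "manifest.tsv"
        records = [
            SeqRecord(Seq(seq), id=self.entry_name(g, k), description="")
            for g, k, seq in self.entries
        ]
        records += [
            SeqRecord(Seq(seq), id=f"decoy::{d}", description="")
            for d, seq in self.decoys
        ]
        SeqIO.write(records, str(fasta), "fasta")
        with open(manifest, "w") as fh:
            fh.write("gene_id\tmissing_3p\tlength\tamino_acid\tanticodon\n")
            for g, k, seq in self.entries:
                gene = self.genes[g]
                fh.write(f"{g}\t{k}\t{len(seq)}\t{gene.amino_acid}\t{gene.anticodon}\n")
        return fasta, manifest


def build_truncation_set(
    genes: Sequence[TRNAGene],
    max_missing: int = 13,
    decoys: Optional[Iterable[tuple[str, str]]] = None,
) -> TruncationReference:
    """Enumerate mature + 3'-truncated transcript variants for every gene.

    Produces ``max_missing + 1`` entries per gene in deterministic order.
    The truncation depth must leave at least 20 nt of every gene intact;
    genes too short for the requested depth are reported by id.
    """
    if max_missing < 1:
        raise ReferenceError("max_missing must be >= 1")
    gene_map: dict[str, TRNAGene] = {}
    for g in genes:
        if g.gene_id in gene_map:
            raise ReferenceError(f"duplicate gene_id {g.gene_id!r}")
        gene_map[g.gene_id] = g
    if not gene_map:
        raise ReferenceError("no genes provided")
    too_short = [
        g.gene_id for g in genes if max_missing >= len(g.mature_seq) - 20
    ]
    if too_short:
        raise ReferenceError(
            f"max_missing={max_missing} too deep for genes: {', '.join(sorted(too_short))}"
        )
    entries: list[tuple[str, int, str]] = []
    for gid in sorted(gene_map):
        mat = gene_map[gid].mature_seq
        for k in range(max_missing + 1):
            entries.append((gid, k, mat[: len(mat) - k] if k else mat))
    kept_decoys: list[tuple[str, str]] = []
    if decoys:
        trna_seqs = {seq for _, _, seq in entries}
        for did, dseq in decoys:
            dseq = normalize_sequence(dseq)
            if dseq in trna_seqs:
                warnings.warn(
                    f"decoy {did!r} is identical to a tRNA entry; dropped",
                    stacklevel=2,
                )
                continue
            kept_decoys.append((did, dseq))
    return TruncationReference(gene_map, max_missing, entries, kept_decoys)


def read_reference(refdir: Union[str, Path]) -> TruncationReference:
    """Reload a reference previously serialized with :meth:`TruncationReference.write`."""
    refdir = Path(refdir)
    manifest = refdir / "manifest.tsv"
    fasta = refdir / "reference.fa"
    seqs = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(fasta), "fasta")}
    genes: dict[str, TRNAGene] = {}
    max_missing = 0
    rows: list[tuple[str, int]] = []
    with open(manifest) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {c: i for i, c in enumerate(header)}
        for line in fh:
            f = line.rstrip("\n").split("\t")
            gid, k = f[idx["gene_id"]], int(f[idx["missing_3p"]])
            rows.append((gid, k))
            max_missing = max(max_missing, k)
            if k == 0 and gid not in genes:
                genes[gid] = TRNAGene(
                    gid,
                    f[idx["amino_acid"]],
                    f[idx["anticodon"]],
                    seqs[TruncationReference.entry_name(gid, 0)],
                )
    entries = [
        (gid, k, seqs[TruncationReference.entry_name(gid, k)])
        for gid, k in sorted(rows)
    ]
    decoys = [
        (name.split("::", 1)[1], seq)
        for name, seq in seqs.items()
        if name.startswith("decoy::")
    ]
    return TruncationReference(genes, max_missing, entries, decoys)
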