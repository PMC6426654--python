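"""Synthetic data with machine-readable ground truth.

Generates the three kinds of input the analysis consumes, with the
statistical structure the method assumes, so every downstream check can
compare against a truth table rather than hard-coded numbers:

* tRNA gene sets: random mature-length sequences ending in CCA, isotypes
  drawn over the 21 amino acids with anticodons back-translated from the
  standard genetic code (323 genes by default, the size of a typical
  pseudogene-free human gtRNAdb-derived set);
* per-sample read sets over a nucleus/cytosol x control/treated x
  replicate design: gene counts are negative-binomial around a log-normal
  baseline, treated samples shifted by per-gene log2 fold changes, and
  each gene's reads are split across 3'-truncation depths k=0..13 by a
  per-compartment-and-condition spectrum (defaults echo the qualitative
  picture of stressed cells: ~50% intact reads in the cytosol throughout,
  nuclear intact fraction dropping from ~60% to ~30% under treatment with
  extra mass at k=5..8, and one "Sec-like" gene with a strong nuclear
  gain and cytosolic loss).  A noise-free mode emits expected counts
  (largest-remainder rounded) for exact pipeline-identity checks;
* two-channel microscopy fields of non-overlapping elliptical cells with
  known per-cell nuclear:cytoplasmic probe intensity ratios and Gaussian
  noise.

Sequencing depth defaults to 1e5 reads per sample -- a desk-scale stand-in
for the millions of reads of a real run.  All generators are deterministic
per seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from Bio.Data import CodonTable
from Bio.Seq import Seq
from Bio.SeqUtils import seq3

from .profiler import SampleDesign
from .reference import AMINO_ACIDS, TRNAGene


class SimulateError(ValueError):
    pass


# ---------------------------------------------------------------------------
# genes

def _anticodon_table() -> dict[str, list[str]]:
    table: dict[str, list[str]] = {}
    fwd = CodonTable.unambiguous_dna_by_name["Standard"].forward_table
    for codon, aa1 in fwd.items():
        aa = seq3(aa1)
        table.setdefault(aa, []).append(str(Seq(codon).reverse_complement()))
    table["Sec"] = ["TCA"]  # UGA recoding
    return {aa: sorted(acs) for aa, acs in table.items()}


ANTICODONS = _anticodon_table()


def simulate_genes(
    n: int = 323,
    seed: int = 0,
    isotype_weights: Optional[dict[str, float]] = None,
    pseudo_fraction: float = 0.0,
    length_range: tuple[int, int] = (62, 90),
) -> list[TRNAGene]:
    """Random tRNA genes with CCA-mature 3' ends and unique ids.

    Body lengths are uniform in ``length_range`` (before the CCA), so
    mature lengths resemble real cytoplasmic tRNAs.  ``pseudo_fraction``
    of genes are flagged as pseudogenes.
    """
    if n < 1:
        raise SimulateError("n must be >= 1")
    rng = np.random.default_rng(seed)
    isotypes = sorted(AMINO_ACIDS)
    if isotype_weights:
        w = np.array([isotype_weights.get(a, 0.0) for a in isotypes], dtype=float)
        if w.sum() <= 0:
            raise SimulateError("isotype weights sum to zero")
        w = w / w.sum()
    else:
        w = np.full(len(isotypes), 1.0 / len(isotypes))
    genes = []
    for i in range(n):
        aa = isotypes[rng.choice(len(isotypes), p=w)]
        anticodon = ANTICODONS[aa][rng.integers(len(ANTICODONS[aa]))]
        length = int(rng.integers(length_range[0], length_range[1] + 1))
        body = "".join(rng.choice(list("ACGT"), size=length))
        genes.append(
            TRNAGene(
                gene_id=f"chr{rng.integers(1, 23)}-tr{i:03d}",
                amino_acid=aa,
                anticodon=anticodon,
                genomic_seq=body + "CCA",
                is_pseudogene=bool(rng.random() < pseudo_fraction),
            )
        )
    return genes


def write_genes(
    genes: Sequence[TRNAGene], fasta_path: Union[str, Path],
    annotation_path: Optional[Union[str, Path]] = None,
) -> None:
    """Write genes as native-dialect FASTA plus an annotation TSV."""
    with open(fasta_path, "w") as fh:
        for g in genes:
            fh.write(
                f">{g.gene_id}|{g.amino_acid}|{g.anticodon}|"
                f"pseudo={int(g.is_pseudogene)}\n{g.genomic_seq}\n"
            )
    if annotation_path is not None:
        with open(annotation_path, "w") as fh:
            fh.write("gene_id\tamino_acid\tanticodon\tis_pseudogene\n")
            for g in genes:
                fh.write(
                    f"{g.gene_id}\t{g.amino_acid}\t{g.anticodon}\t"
                    f"{int(g.is_pseudogene)}\n"
                )


# ---------------------------------------------------------------------------
# reads

def default_spectra(max_missing: int = 13) -> dict[tuple[str, str], np.ndarray]:
    """Per-(fraction, condition) 3'-truncation spectra over k=0..max_missing."""
    raw = {
        ("cytosol", "control"): [0.50, 0.14, 0.10, 0.08, 0.07, 0.06, 0.05],
        ("cytosol", "treated"): [0.48, 0.14, 0.10, 0.09, 0.07, 0.07, 0.05],
        ("nucleus", "control"): [0.60, 0.08, 0.07, 0.06, 0.06, 0.05, 0.04, 0.04],
        ("nucleus", "treated"): [0.30, 0.05, 0.05, 0.06, 0.08, 0.12, 0.12, 0.11, 0.11],
    }
    out = {}
    for key, vals in raw.items():
        spec = np.zeros(max_missing + 1)
        spec[: len(vals)] = vals
        out[key] = spec / spec.sum()
    return out


@dataclass
class SimDesign:
    """Complete specification of a read simulation.

    ``baseline`` is the relative abundance of each gene (shared across
    samples); treated samples scale gene g by ``2**lfc_<fraction>[g]``.
    ``spectra`` maps (fraction, condition) to a length-(max_missing+1)
    distribution over missing 3' nucleotides.
    """

    baseline: np.ndarray
    lfc_nucleus: np.ndarray
    lfc_cytosol: np.ndarray
    dispersion: float = 0.1
    replicates: int = 2
    depth: int = 100_000
    max_missing: int = 13
    error_rate: float = 0.0
    seed: int = 0
    spectra: dict[tuple[str, str], np.ndarray] = field(default_factory=default_spectra)

    def __post_init__(self) -> None:
        n = len(self.baseline)
        for name in ("lfc_nucleus", "lfc_cytosol"):
            if len(getattr(self, name)) != n:
                raise SimulateError(f"{name} length != number of genes")
        if self.dispersion <= 0:
            raise SimulateError("dispersion must be > 0")
        for key, spec in self.spectra.items():
            if len(spec) != self.max_missing + 1:
                raise SimulateError(f"spectrum {key} has wrong length")
            if abs(float(np.sum(spec)) - 1.0) > 1e-9:
                raise SimulateError(f"spectrum {key} does not sum to 1")

    def samples(self) -> list[SampleDesign]:
        out = []
        for frac, tag in (("nucleus", "nuc"), ("cytosol", "cyt")):
            for cond, ctag in (("control", "ctrl"), ("treated", "trt")):
                for rep in range(1, self.replicates + 1):
                    out.append(
                        SampleDesign(f"{tag}_{ctag}_r{rep}", frac, cond, rep)
                    )
        return out


def default_design(
    genes: Sequence[TRNAGene],
    seed: int = 0,
    depth: int = 100_000,
    replicates: int = 2,
    dispersion: float = 0.1,
    abundance_sigma: float = 1.0,
    sec_nuclear_fold: float = 8.6,
    sec_cytosolic_fold: float = 2.7,
) -> SimDesign:
    """Study-shaped default design: most genes null, one Sec-like responder.

    The Sec-like gene (the first selenocysteine gene, else gene 0) gains
    ``sec_nuclear_fold`` in the nucleus and loses ``sec_cytosolic_fold``
    in the cytosol under treatment.
    """
    rng = np.random.default_rng(seed)
    n = len(genes)
    baseline = rng.lognormal(mean=0.0, sigma=abundance_sigma, size=n)
    lfc_nuc = np.zeros(n)
    lfc_cyt = np.zeros(n)
    sec_idx = next(
        (i for i, g in enumerate(genes) if g.amino_acid == "Sec"), 0
    )
    lfc_nuc[sec_idx] = np.log2(sec_nuclear_fold)
    lfc_cyt[sec_idx] = -np.log2(sec_cytosolic_fold)
    return SimDesign(
        baseline=baseline, lfc_nucleus=lfc_nuc, lfc_cytosol=lfc_cyt,
        dispersion=dispersion, replicates=replicates, depth=depth, seed=seed,
    )


def _integerize(weights: np.ndarray, total: int) -> np.ndarray:
    """Largest-remainder rounding of ``total * weights / sum`` to integers."""
    w = np.asarray(weights, dtype=float)
    if w.sum() <= 0:
        return np.zeros(len(w), dtype=np.int64)
    exact = total * w / w.sum()
    base = np.floor(exact).astype(np.int64)
    short = total - int(base.sum())
    if short > 0:
        frac = exact - base
        top = np.argsort(-frac, kind="stable")[:short]
        base[top] += 1
    return base


@dataclass
class ReadSim:
    """Result of a read simulation: reads, truth table and sample design."""

    reads_by_sample: dict[str, list[tuple[str, str]]]
    truth: pd.DataFrame  # columns: gene_id, missing_3p, sample_id, count
    samples: list[SampleDesign]
    design: SimDesign

    def truth_matrix(self) -> pd.DataFrame:
        """Truth counts as a (gene, missing_3p) x sample matrix."""
        return (
            self.truth.pivot_table(
                index=["gene_id", "missing_3p"], columns="sample_id",
                values="count", fill_value=0, aggfunc="sum",
            )[[d.sample_id for d in self.samples]]
            .astype(np.int64)
            .rename_axis(columns=None)
        )


def simulate_reads(
    genes: Sequence[TRNAGene],
    design: SimDesign,
    mode: str = "sampled",
) -> ReadSim:
    """Draw per-sample read sets with a complete per-(gene, k) truth table.

    ``mode="sampled"``: NB gene counts around the expected depth share,
    multinomial split across truncation depths.  ``mode="noise_free"``:
    expected counts, largest-remainder rounded so each sample sums to the
    design depth exactly.
    """
    if mode not in ("sampled", "noise_free"):
        raise SimulateError(f"unknown mode {mode!r}")
    rng = np.random.default_rng(design.seed)
    n = len(genes)
    if n != len(design.baseline):
        raise SimulateError("design gene count != genes provided")
    matures = [g.mature_seq for g in genes]
    lfc = {"nucleus": design.lfc_nucleus, "cytosol": design.lfc_cytosol}
    reads_by_sample: dict[str, list[tuple[str, str]]] = {}
    records = []
    samples = design.samples()
    for d in samples:
        eff = design.baseline * (
            np.power(2.0, lfc[d.fraction]) if d.condition == "treated" else 1.0
        )
        mu = design.depth * eff / eff.sum()
        if mode == "noise_free":
            gene_counts = _integerize(mu, design.depth)
        else:
            r = 1.0 / design.dispersion
            gene_counts = rng.negative_binomial(r, r / (r + mu))
        spec = design.spectra[(d.fraction, d.condition)]
        reads: list[tuple[str, str]] = []
        ridx = 0
        for gi in range(n):
            c = int(gene_counts[gi])
            if mode == "noise_free":
                k_counts = _integerize(spec, c)
            else:
                k_counts = rng.multinomial(c, spec)
            for k, ck in enumerate(k_counts):
                if ck:
                    seq = matures[gi][: len(matures[gi]) - k] if k else matures[gi]
                    for _ in range(ck):
                        s = seq
                        if design.error_rate > 0 and rng.random() < design.error_rate * len(s):
                            pos = int(rng.integers(len(s)))
                            alt = rng.choice([b for b in "ACGT" if b != s[pos]])
                            s = s[:pos] + alt + s[pos + 1 :]
                        reads.append((f"{d.sample_id}:read{ridx:07d}", s))
                        ridx += 1
                records.append(
                    (genes[gi].gene_id, k, d.sample_id, int(ck))
                )
        reads_by_sample[d.sample_id] = reads
    truth = pd.DataFrame(
        records, columns=["gene_id", "missing_3p", "sample_id", "count"]
    )
    return ReadSim(reads_by_sample, truth, samples, design)


def write_reads(sim: ReadSim, outdir: Union[str, Path]) -> None:
    """Write per-sample FASTQ files plus truth and design TSVs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for sid, reads in sim.reads_by_sample.items():
        with open(outdir / f"{sid}.fastq", "w") as fh:
            for rid, seq in reads:
                fh.write(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n")
    sim.truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
    with open(outdir / "design.tsv", "w") as fh:
        fh.write("sample_id\tfraction\tcondition\treplicate\tpath\n")
        for d in sim.samples:
            fh.write(
                f"{d.sample_id}\t{d.fraction}\t{d.condition}\t{d.replicate}\t"
                f"{outdir / (d.sample_id + '.fastq')}\n"
            )


def simulate_gene_counts(
    n_genes: int,
    lfc: np.ndarray,
    mean_depth: float = 500.0,
    dispersion: float = 0.1,
    replicates: int = 2,
    compartment: str = "nucleus",
    seed: int = 0,
) -> tuple[pd.DataFrame, list[SampleDesign]]:
    """Gene-level NB count matrix for one compartment, for calibration work.

    Control samples have NB(mean_depth) counts per gene; treated samples
    are shifted by per-gene ``2**lfc``.  Unlike :func:`simulate_reads`
    this draws counts directly (no compositional renormalization), which
    is what fold-change recovery and type-I calibration assume.
    """
    lfc = np.asarray(lfc, dtype=float)
    if len(lfc) != n_genes:
        raise SimulateError("lfc length != n_genes")
    rng = np.random.default_rng(seed)
    r = 1.0 / dispersion
    tag = "nuc" if compartment == "nucleus" else "cyt"
    cols, design = {}, []
    for cond, ctag, mult in (
        ("control", "ctrl", np.ones(n_genes)),
        ("treated", "trt", np.power(2.0, lfc)),
    ):
        for rep in range(1, replicates + 1):
            mu = mean_depth * mult
            sid = f"{tag}_{ctag}_r{rep}"
            cols[sid] = rng.negative_binomial(r, r / (r + mu))
            design.append(SampleDesign(sid, compartment, cond, rep))
    index = pd.Index([f"g{i:04d}" for i in range(n_genes)], name="gene_id")
    return pd.DataFrame(cols, index=index, dtype=np.int64), design


# ---------------------------------------------------------------------------
# images

@dataclass
class ImageSim:
    """A simulated two-channel field with per-cell geometry and truth."""

    dapi: np.ndarray
    probe: np.ndarray
    truth: pd.DataFrame


def _ellipse_mask(
    shape: tuple[int, int], cy: float, cx: float, a: float, b: float, angle: float
) -> np.ndarray:
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    dy, dx = yy - cy, xx - cx
    c, s = np.cos(angle), np.sin(angle)
    u = c * dx + s * dy
    v = -s * dx + c * dy
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def simulate_images(
    n_cells: int = 20,
    ratios: Union[float, Sequence[float]] = 2.0,
    noise_sd: float = 5.0,
    seed: int = 0,
    shape: tuple[int, int] = (896, 896),
    nucleus_axes: tuple[float, float] = (20.0, 28.0),
    cyto_scale: tuple[float, float] = (1.55, 1.95),
    cyt_mean: float = 40.0,
    background: float = 5.0,
    dapi_level: float = 180.0,
    max_tries: int = 50_000,
) -> ImageSim:
    """Place non-overlapping elliptical cells with known N/C probe ratios.

    DAPI is bright inside nuclei only; the probe channel has per-cell
    nuclear mean ``ratio * cyt_mean`` over a cytoplasmic mean of
    ``cyt_mean``, both over a dim background, with additive Gaussian
    noise of ``noise_sd`` (so SNR = cyt_mean / noise_sd).  Cells are kept
    clear of the image border (border-touching particles are excluded by
    the segmentation anyway).
    """
    rng = np.random.default_rng(seed)
    ratio_list = (
        [float(ratios)] * n_cells
        if np.isscalar(ratios)
        else [float(ratios[i % len(ratios)]) for i in range(n_cells)]
    )
    h, w = shape
    placed: list[tuple[float, float, float]] = []  # cy, cx, clearance radius
    rows = []
    dapi = np.full(shape, background, dtype=float)
    probe = np.full(shape, background, dtype=float)
    tries = 0
    for i in range(n_cells):
        while True:
            tries += 1
            if tries > max_tries:
                raise SimulateError(
                    "could not place cells without overlap; use a larger frame"
                )
            na = rng.uniform(*nucleus_axes)
            nb = rng.uniform(*nucleus_axes)
            scale = rng.uniform(*cyto_scale)
            ca, cb = na * scale, nb * scale
            r = max(ca, cb)
            margin = r + 4
            cy = rng.uniform(margin, h - margin)
            cx = rng.uniform(margin, w - margin)
            if all(
                np.hypot(cy - py, cx - px) > r + pr + 4 for py, px, pr in placed
            ):
                break
        placed.append((cy, cx, r))
        angle = rng.uniform(0, np.pi)
        nuc = _ellipse_mask(shape, cy, cx, na, nb, angle)
        cell = _ellipse_mask(shape, cy, cx, ca, cb, angle)
        ratio = ratio_list[i]
        dapi[nuc] = dapi_level
        probe[cell & ~nuc] = cyt_mean
        probe[nuc] = ratio * cyt_mean
        rows.append(
            dict(
                cell_id=i + 1, cy=cy, cx=cx, nuc_a=na, nuc_b=nb, angle=angle,
                cyt_a=ca, cyt_b=cb, true_ratio=ratio,
                nuc_area=int(nuc.sum()), noise_sd=noise_sd,
            )
        )
    if noise_sd > 0:
        dapi = np.clip(dapi + rng.normal(0, noise_sd, shape), 0, None)
        probe = np.clip(probe + rng.normal(0, noise_sd, shape), 0, None)
    return ImageSim(
        dapi.astype(np.float32), probe.astype(np.float32), pd.DataFrame(rows)
    )


def write_images(sim: ImageSim, outdir: Union[str, Path]) -> None:
    """Write DAPI/probe TIFFs and the truth TSV."""
    import tifffile

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(outdir / "dapi.tif", sim.dapi)
    tifffile.imwrite(outdir / "probe.tif", sim.probe)
    sim.truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
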