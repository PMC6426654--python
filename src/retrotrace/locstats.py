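"""Differential nucleo-cytoplasmic localization statistics.

Implements the counting-statistics layer of the pipeline: median-of-ratios
size factors, base means, the two depth filters used to select analyzable
genes (strict base-mean > threshold across all samples, or a minimum read
depth in the cytosolic control samples), per-compartment log2 fold changes
of treated vs control, a simplified negative-binomial Wald test with
method-of-moments dispersion, Benjamini-Hochberg adjustment, the
replicate-consistency call (|log2FC| > 0.75 with one sign in every
replicate), amino-acid-level aggregation, and hierarchical row ordering.

The NB test is a deliberately transparent simplification of a full GLM
framework: dispersions are estimated by the method of moments and, by
default, pooled across genes (median of per-gene estimates) because
per-gene moment estimates from two replicates per condition are far too
noisy to calibrate.  A permutation option exists for designs where the
normal approximation is in doubt.
"""

from __future__ import annotations

import warnings
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .profiler import SampleDesign

DEFAULT_LFC_THRESHOLD = 0.75
DEFAULT_DEPTH_THRESHOLD = 20
DISPERSION_FLOOR = 1e-8


class LocStatsError(ValueError):
    pass


# ---------------------------------------------------------------------------
# normalization

def size_factors(matrix: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors (one positive float per sample).

    factor_j = median over genes of count_gj / geometric-mean_g, where the
    geometric mean runs across samples and genes with a zero anywhere are
    excluded from the median.
    """
    counts = matrix.to_numpy(dtype=float)
    all_pos = (counts > 0).all(axis=1)
    if not all_pos.any():
        raise LocStatsError(
            "no gene has nonzero counts in every sample; median-of-ratios "
            "normalization needs at least one (consider a pseudo-reference)"
        )
    log_counts = np.log(counts[all_pos])
    log_geomean = log_counts.mean(axis=1, keepdims=True)
    factors = np.exp(np.median(log_counts - log_geomean, axis=0))
    return pd.Series(factors, index=matrix.columns, name="size_factor")


def normalized_counts(matrix: pd.DataFrame, factors: pd.Series) -> pd.DataFrame:
    return matrix / factors


def base_mean(matrix: pd.DataFrame, factors: pd.Series) -> pd.Series:
    """Mean of normalized counts across all samples, per gene."""
    return normalized_counts(matrix, factors).mean(axis=1).rename("base_mean")


# ---------------------------------------------------------------------------
# filters

def depth_filter(
    matrix: pd.DataFrame,
    mode: str,
    threshold: float = DEFAULT_DEPTH_THRESHOLD,
    factors: Optional[pd.Series] = None,
    design: Optional[Sequence[SampleDesign]] = None,
    cyto_rule: str = "per_sample",
) -> pd.Series:
    """Boolean per-gene depth filter.

    mode="base_mean_gt": base mean of normalized counts strictly greater
    than *threshold* (a gene at exactly the threshold fails).
    mode="cyto_control_ge": raw counts in the cytosolic control samples at
    least *threshold*; ``cyto_rule`` selects whether every such sample
    (default) or their mean must reach it.
    """
    if mode == "base_mean_gt":
        f = size_factors(matrix) if factors is None else factors
        return (base_mean(matrix, f) > threshold).rename("passes_depth_filter")
    if mode == "cyto_control_ge":
        if design is None:
            raise LocStatsError("cyto_control_ge mode requires a design")
        cols = [
            d.sample_id for d in design
            if d.fraction == "cytosol" and d.condition == "control"
        ]
        if not cols:
            raise LocStatsError("design has no cytosol/control samples")
        sub = matrix[cols]
        if cyto_rule == "per_sample":
            ok = (sub >= threshold).all(axis=1)
        elif cyto_rule == "mean":
            ok = sub.mean(axis=1) >= threshold
        else:
            raise LocStatsError(f"unknown cyto_rule {cyto_rule!r}")
        return ok.rename("passes_depth_filter")
    raise LocStatsError(f"unknown depth filter mode {mode!r}")


# ---------------------------------------------------------------------------
# fold changes

def _compartment_samples(
    design: Sequence[SampleDesign], compartment: str
) -> tuple[list[SampleDesign], list[SampleDesign]]:
    treated = [d for d in design if d.fraction == compartment and d.condition == "treated"]
    control = [d for d in design if d.fraction == compartment and d.condition == "control"]
    if not treated or not control:
        missing = "treated" if not treated else "control"
        raise LocStatsError(f"no {missing} samples in compartment {compartment!r}")
    return treated, control


def log2fc_by_compartment(
    matrix: pd.DataFrame,
    factors: pd.Series,
    design: Sequence[SampleDesign],
    compartment: str,
    pseudocount: float = 0.5,
) -> tuple[pd.Series, pd.DataFrame]:
    """Treated-vs-control log2 fold change within one compartment.

    Returns (overall LFC per gene, per-replicate LFCs).  The overall value
    is log2((mean normalized treated + c) / (mean normalized control + c));
    per-replicate values pair replicate i treated with replicate i control.
    """
    treated, control = _compartment_samples(design, compartment)
    norm = normalized_counts(matrix, factors)
    mt = norm[[d.sample_id for d in treated]].mean(axis=1)
    mc = norm[[d.sample_id for d in control]].mean(axis=1)
    overall = np.log2((mt + pseudocount) / (mc + pseudocount)).rename(
        f"log2fc_{compartment}"
    )
    t_by_rep = {d.replicate: d.sample_id for d in treated}
    c_by_rep = {d.replicate: d.sample_id for d in control}
    per_rep = {}
    for rep in sorted(set(t_by_rep) & set(c_by_rep)):
        per_rep[rep] = np.log2(
            (norm[t_by_rep[rep]] + pseudocount) / (norm[c_by_rep[rep]] + pseudocount)
        )
    return overall, pd.DataFrame(per_rep)


# ---------------------------------------------------------------------------
# negative-binomial test

def nb_test(
    matrix: pd.DataFrame,
    factors: pd.Series,
    design: Sequence[SampleDesign],
    compartment: str,
    dispersion: str = "pooled",
    floor: float = DISPERSION_FLOOR,
    method: str = "wald",
    n_permutations: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-gene treated-vs-control test within a compartment.

    Wald test on the log ratio of mean normalized counts under a
    negative-binomial variance model Var = mu + alpha*mu^2.  Dispersion
    alpha is estimated by the method of moments and either pooled across
    genes (median of per-gene estimates, default) or used per gene; both
    are floored.  With a single sample in a condition the model degrades
    to Poisson (alpha=0) with a warning.  ``method="permutation"`` instead
    permutes condition labels within the compartment.
    """
    treated, control = _compartment_samples(design, compartment)
    norm = normalized_counts(matrix, factors)
    xt = norm[[d.sample_id for d in treated]].to_numpy(dtype=float)
    xc = norm[[d.sample_id for d in control]].to_numpy(dtype=float)
    nt, nc = xt.shape[1], xc.shape[1]
    mu_t, mu_c = xt.mean(axis=1), xc.mean(axis=1)

    if nt < 2 or nc < 2:
        warnings.warn(
            "fewer than 2 samples in a condition: falling back to Poisson "
            "(dispersion 0)", stacklevel=2,
        )
        alpha = np.zeros(len(matrix))
    else:
        var_t = xt.var(axis=1, ddof=1)
        var_c = xc.var(axis=1, ddof=1)
        if dispersion == "pooled":
            # aggregate moment identity E[s^2 - mu] = alpha * mu^2 summed
            # over genes and conditions; far less biased at tiny n than a
            # median of per-gene ratios.  mu^2 is estimated unbiasedly as
            # mean^2 - s^2/n (plain mean^2 would bias alpha downward).
            num = (var_t - mu_t).sum() + (var_c - mu_c).sum()
            den = (
                np.maximum(np.square(mu_t) - var_t / nt, 0.0).sum()
                + np.maximum(np.square(mu_c) - var_c / nc, 0.0).sum()
            )
            pooled = num / den if den > 0 else 0.0
            alpha = np.full(len(matrix), max(pooled, floor))
        elif dispersion == "per_gene":
            with np.errstate(divide="ignore", invalid="ignore"):
                a_t = (var_t - mu_t) / np.square(mu_t)
                a_c = (var_c - mu_c) / np.square(mu_c)
            a_g = np.nanmean(np.stack([a_t, a_c]), axis=0)
            alpha = np.where(np.isfinite(a_g), np.maximum(a_g, floor), floor)
        else:
            raise LocStatsError(f"unknown dispersion mode {dispersion!r}")

    eps = 0.5  # pseudocount keeps zero-count genes finite
    log_ratio = np.log(mu_t + eps) - np.log(mu_c + eps)
    # score-type SE: variance of the log ratio evaluated at the pooled
    # mean, which avoids the type-I inflation of plugging tiny-n
    # per-condition means into their own variances; the quadratic terms
    # are the second-order delta-method contribution to Var(log mean)
    mu0 = (nt * mu_t + nc * mu_c) / (nt + nc)
    g = 1.0 / (mu0 + eps) + alpha
    se2 = g / nt + g / nc + ((g / nt) ** 2 + (g / nc) ** 2) / 2.0
    with np.errstate(divide="ignore", invalid="ignore"):
        z = log_ratio / np.sqrt(se2)
    z = np.where(np.isfinite(z), z, 0.0)

    if method == "wald":
        p = 2.0 * stats.norm.sf(np.abs(z))
    elif method == "permutation":
        rng = np.random.default_rng(seed)
        pooled_x = np.concatenate([xt, xc], axis=1)
        obs = np.abs(log_ratio)
        exceed = np.ones(len(matrix))
        for _ in range(n_permutations):
            perm = rng.permutation(nt + nc)
            pt = pooled_x[:, perm[:nt]].mean(axis=1)
            pc = pooled_x[:, perm[nt:]].mean(axis=1)
            stat = np.abs(np.log(pt + eps) - np.log(pc + eps))
            exceed += stat >= obs - 1e-12
        p = exceed / (n_permutations + 1)
    else:
        raise LocStatsError(f"unknown method {method!r}")
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    return pd.DataFrame({"statistic": z, "p_value": p}, index=matrix.index)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise LocStatsError("p_values must be one-dimensional")
    if np.isnan(p).any():
        raise LocStatsError("NaN in p-values")
    if ((p < 0) | (p > 1)).any():
        raise LocStatsError("p-values must lie in [0, 1]")
    n = len(p)
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / np.arange(1, n + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(adj, 1.0)
    return out


def consistency_call(
    per_replicate_lfc: Sequence[float], threshold: float = DEFAULT_LFC_THRESHOLD
) -> str:
    """"up"/"down" when every replicate LFC clears +/-threshold with one sign."""
    lfcs = np.asarray(list(per_replicate_lfc), dtype=float)
    if len(lfcs) < 2:
        raise LocStatsError("consistency call needs >= 2 replicate LFCs")
    if (lfcs > threshold).all():
        return "up"
    if (lfcs < -threshold).all():
        return "down"
    return "none"


def consistency_calls(
    per_replicate_lfc: pd.DataFrame, threshold: float = DEFAULT_LFC_THRESHOLD
) -> pd.Series:
    """Vectorized :func:`consistency_call` over a genes x replicates frame."""
    if per_replicate_lfc.shape[1] < 2:
        raise LocStatsError("consistency call needs >= 2 replicate LFCs")
    vals = per_replicate_lfc.to_numpy(dtype=float)
    up = (vals > threshold).all(axis=1)
    down = (vals < -threshold).all(axis=1)
    out = np.where(up, "up", np.where(down, "down", "none"))
    return pd.Series(out, index=per_replicate_lfc.index, name="consistent_call")


# ---------------------------------------------------------------------------
# aggregation / ordering

def aa_aggregate(
    matrix: pd.DataFrame, gene_annotations: Mapping[str, str]
) -> pd.DataFrame:
    """Per-isotype read fractions per sample (columns sum to 1)."""
    from .reference import AMINO_ACIDS

    iso = pd.Series(
        {g: gene_annotations.get(g) for g in matrix.index}, name="amino_acid"
    )
    if iso.isna().any():
        missing = iso[iso.isna()].index.tolist()[:5]
        raise LocStatsError(f"genes without isotype annotation, e.g. {missing}")
    bad = sorted(set(iso) - AMINO_ACIDS)
    if bad:
        raise LocStatsError(f"unknown isotype labels: {bad}")
    sums = matrix.groupby(iso).sum()
    totals = sums.sum(axis=0)
    if (totals == 0).any():
        raise LocStatsError("sample with zero tRNA-mapped reads")
    return sums / totals


def cluster_rows(lfc_table: pd.DataFrame) -> list:
    """Deterministic hierarchical row ordering (Euclidean, complete linkage)."""
    if len(lfc_table) < 2:
        raise LocStatsError("need >= 2 rows to cluster")
    vals = lfc_table.to_numpy(dtype=float)
    if not np.isfinite(vals).all():
        raise LocStatsError("non-finite values in table")
    link = hierarchy.linkage(pdist(vals, metric="euclidean"), method="complete")
    return [lfc_table.index[i] for i in hierarchy.leaves_list(link)]


# ---------------------------------------------------------------------------
# pipeline glue

def collapse_variants(variant_counts: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Collapse a (gene, missing_3p) x sample matrix into analysis classes.

    Returns gene x sample matrices for "total" (all k), "intact" (k == 0)
    and "defective" (k >= 1 pooled).
    """
    k = variant_counts.index.get_level_values("missing_3p")
    by_gene = lambda df: df.groupby(level="gene_id").sum()
    return {
        "total": by_gene(variant_counts),
        "intact": by_gene(variant_counts[k == 0]),
        "defective": by_gene(variant_counts[k >= 1]),
    }


def localization_table(
    variant_counts: pd.DataFrame,
    design: Sequence[SampleDesign],
    lfc_threshold: float = DEFAULT_LFC_THRESHOLD,
    depth_mode: str = "cyto_control_ge",
    depth_threshold: float = DEFAULT_DEPTH_THRESHOLD,
    pseudocount: float = 0.5,
    test_compartment: str = "nucleus",
) -> pd.DataFrame:
    """Full differential-localization table for intact and defective classes.

    Size factors come from gene-level total counts (library-wide
    normalization); each class then gets base means, nuclear and cytosolic
    LFCs with per-replicate values, the NB test in ``test_compartment``
    (nuclear by default, where localization changes concentrate), BH
    adjustment, depth-filter flags and per-compartment consistency calls.
    """
    classes = collapse_variants(variant_counts)
    factors = size_factors(classes["total"])
    rows = []
    for cls in ("intact", "defective"):
        mat = classes[cls]
        bm = base_mean(mat, factors)
        flt = depth_filter(
            mat, depth_mode, depth_threshold, factors=factors, design=design
        )
        res = nb_test(mat, factors, design, test_compartment)
        adj = bh_adjust(res["p_value"].to_numpy())
        block = pd.DataFrame(
            {
                "variant_class": cls,
                "base_mean": bm,
                "p_value": res["p_value"],
                "adj_p": adj,
                "passes_depth_filter": flt,
            }
        )
        for comp, tag in (("nucleus", "nuc"), ("cytosol", "cyt")):
            lfc, per_rep = log2fc_by_compartment(
                mat, factors, design, comp, pseudocount
            )
            block[f"log2fc_{tag}"] = lfc
            for rep in per_rep.columns:
                block[f"log2fc_{tag}_rep{rep}"] = per_rep[rep]
            block[f"call_{tag}"] = consistency_calls(per_rep, lfc_threshold)
        rows.append(block)
    out = pd.concat(rows)
    out.index.name = "gene_id"
    return out.reset_index().set_index(["gene_id", "variant_class"]).sort_index()
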