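"""Negative-binomial differential expression for two-group contrasts.

This module implements the standard bulk RNA-seq testing stack from first
principles: median-of-ratios size factors, gene-wise method-of-moments
dispersion estimation with shrinkage toward a robust central value, a
two-group negative-binomial Wald test on the log2 scale, Benjamini-Hochberg
FDR adjustment, and FPKM quantification.

The NB model is ``Var(K) = mu + alpha * mu**2`` with per-gene dispersion
``alpha``.  For a two-group contrast the log2 fold change is the log2 ratio
of normalized group means; its standard error follows from the delta method
under the NB variance function, and ``log2FC / SE`` is referred to a
standard normal (Wald test, two-sided).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

DISPERSION_FLOOR = 1e-8
#: default log2 fold-change threshold for DEG calling (1.5-fold)
DEFAULT_LFC_MIN = float(np.log2(1.5))
DEFAULT_ALPHA = 0.05

LN2 = float(np.log(2.0))


@dataclass
class CountMatrix:
    """Integer gene x sample read counts with sample metadata.

    Parameters
    ----------
    counts
        DataFrame indexed by gene_id with one integer column per sample.
    samples
        DataFrame indexed by sample_id with columns ``cell_type``,
        ``genotype``, ``condition``, ``passage``, ``replicate``.
    gene_lengths
        Optional per-gene transcript length in nt (for FPKM).
    """

    counts: pd.DataFrame
    samples: pd.DataFrame
    gene_lengths: pd.Series | None = None

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.counts.index.duplicated().any():
            dups = self.counts.index[self.counts.index.duplicated()].unique()
            raise ValueError(f"duplicated gene_ids: {list(dups[:5])}")
        if not self.counts.columns.equals(self.samples.index):
            missing = set(self.counts.columns) ^ set(self.samples.index)
            raise ValueError(
                "count columns and sample sheet ids disagree: "
                f"{sorted(missing)[:10]}"
            )
        arr = self.counts.to_numpy()
        if (arr < 0).any():
            raise ValueError("negative counts")
        if not np.allclose(arr, np.round(arr)):
            bad = np.argwhere(arr != np.round(arr))[0]
            raise ValueError(
                "non-integer count at gene "
                f"{self.counts.index[bad[0]]!r}, sample "
                f"{self.counts.columns[bad[1]]!r}"
            )
        if self.gene_lengths is not None and not self.gene_lengths.index.equals(
            self.counts.index
        ):
            raise ValueError("gene_lengths index must match counts index")

    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns


@dataclass(frozen=True)
class Contrast:
    """Two-group contrast defined by sample-metadata selectors.

    ``numerator`` / ``denominator`` are dicts of metadata column -> value;
    a sample belongs to a side if it matches every selector entry.  The
    reported log2FC is log2(numerator mean / denominator mean).
    """

    name: str
    numerator: dict = field(default_factory=dict)
    denominator: dict = field(default_factory=dict)

    def _mask(self, samples: pd.DataFrame, selector: dict) -> np.ndarray:
        mask = np.ones(len(samples), dtype=bool)
        for col, val in selector.items():
            mask &= (samples[col] == val).to_numpy()
        return mask

    def split(self, samples: pd.DataFrame) -> tuple[pd.Index, pd.Index]:
        a = self._mask(samples, self.numerator)
        b = self._mask(samples, self.denominator)
        if not a.any() or not b.any():
            raise ValueError(f"contrast {self.name!r}: empty group")
        if (a & b).any():
            raise ValueError(f"contrast {self.name!r}: groups overlap")
        return samples.index[a], samples.index[b]


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors, rescaled to geometric mean 1.

    Reference genes are those with strictly positive counts in every
    sample.  The per-sample median of count/geometric-mean ratios uses
    lower interpolation for ties.
    """
    if counts.shape[1] == 1:
        return pd.Series([1.0], index=counts.columns, name="size_factor")
    arr = counts.to_numpy(dtype=float)
    allpos = (arr > 0).all(axis=1)
    if not allpos.any():
        raise ValueError(
            "no gene has positive counts in every sample; "
            "pseudo-reference fallback is disabled"
        )
    ref = arr[allpos]
    log_geomean = np.log(ref).mean(axis=1)
    ratios = ref / np.exp(log_geomean)[:, None]
    sf = np.quantile(ratios, 0.5, axis=0, method="lower")
    sf = sf / np.exp(np.mean(np.log(sf)))
    return pd.Series(sf, index=counts.columns, name="size_factor")


def _replicate_groups(
    counts: pd.DataFrame, groups: pd.Series
) -> list[np.ndarray]:
    """Column-index lists for replicate groups with >= 2 samples."""
    out = []
    for g in pd.unique(groups):
        cols = np.flatnonzero((groups == g).reindex(counts.columns).fillna(False))
        if len(cols) >= 2:
            out.append(cols)
    if not out:
        raise ValueError("no replicate group with >= 2 samples")
    return out


def common_dispersion(
    counts: pd.DataFrame,
    sf: pd.Series,
    groups: pd.Series,
    floor: float = DISPERSION_FLOOR,
) -> float:
    """Single shared NB dispersion by Cox-Reid adjusted profile likelihood.

    Group means are profiled out at their normalized sample means and the
    adjustment term ``0.5 * log sum_j w_j`` (w the NB GLM weights) per
    gene and group corrects the downward bias that plain profiling incurs
    with few replicates.  This is the standard pooled estimator used by
    count-based DE packages.
    """
    glists = _replicate_groups(counts, groups)
    s = sf.reindex(counts.columns).to_numpy()
    k = counts.to_numpy(dtype=float)
    cols_used = np.concatenate(glists)
    mus = np.zeros((k.shape[0], len(cols_used)))
    spans = []
    pos = 0
    for cols in glists:
        q = (k[:, cols] / s[cols]).mean(axis=1)
        mus[:, pos : pos + len(cols)] = q[:, None] * s[cols][None, :]
        spans.append(slice(pos, pos + len(cols)))
        pos += len(cols)
    kk = k[:, cols_used]
    keep = mus.sum(axis=1) > 0  # all-zero genes carry no information
    kk, mus = kk[keep], np.maximum(mus[keep], 1e-10)

    def nll(log_a: float) -> float:
        a = np.exp(log_a)
        r = 1.0 / a
        ll = (
            special.gammaln(kk + r)
            - special.gammaln(r)
            + r * np.log(r / (r + mus))
            + kk * np.log(mus / (r + mus))
        ).sum()
        w = mus / (1.0 + a * mus)
        cr = sum(np.log(w[:, sp].sum(axis=1)).sum() for sp in spans)
        return -(ll - 0.5 * cr)

    res = optimize.minimize_scalar(
        nll, bounds=(np.log(floor), np.log(10.0)), method="bounded"
    )
    return float(max(np.exp(res.x), floor))


def estimate_dispersions(
    counts: pd.DataFrame,
    sf: pd.Series,
    groups: pd.Series,
    shrink_weight: float = 0.9,
    floor: float = DISPERSION_FLOOR,
) -> pd.Series:
    """Gene-wise NB dispersions with shrinkage toward a common value.

    Per replicate group, the method-of-moments estimate on normalized
    counts is ``(s2 - m) / m**2``; groups are pooled weighted by their
    degrees of freedom and the result clipped at zero (genes at or below
    zero are set to the floor, so on Poisson-like data the estimates
    concentrate near the floor).  Gene estimates are then shrunk in log
    space toward the Cox-Reid common dispersion, which is close to
    unbiased where the raw method-of-moments values are not.

    Parameters
    ----------
    groups
        Series over sample ids naming each sample's replicate group.
    shrink_weight
        Weight of the common value in the log-space average (0 = raw
        gene-wise estimates, 1 = a single shared dispersion).  The
        default is high because with 2-4 residual degrees of freedom
        the gene-wise estimates carry little information and plugging
        them into a Wald test unshrunk inflates the type-I error.
    """
    norm = counts.to_numpy(dtype=float) / sf.reindex(counts.columns).to_numpy()
    glists = _replicate_groups(counts, groups)
    num = np.zeros(counts.shape[0])
    den = 0.0
    for cols in glists:
        n = len(cols)
        sub = norm[:, cols]
        m = sub.mean(axis=1)
        v = sub.var(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            contrib = (v - m) / m**2
        num += (n - 1) * np.nan_to_num(contrib, nan=0.0, posinf=0.0, neginf=0.0)
        den += n - 1
    raw = np.maximum(num / den, 0.0)
    target = np.log(common_dispersion(counts, sf, groups, floor=floor))
    log_a = np.log(np.maximum(raw, floor))
    shrunk = np.exp((1.0 - shrink_weight) * log_a + shrink_weight * target)
    return pd.Series(np.maximum(shrunk, floor), index=counts.index, name="dispersion")


def nb_wald_contrast(
    cm: CountMatrix,
    contrast: Contrast,
    sf: pd.Series | None = None,
    dispersions: pd.Series | None = None,
) -> pd.DataFrame:
    """Two-group NB Wald test.

    Group means are averages of size-factor-normalized counts; the
    log2FC is the log2 ratio of group means and its SE comes from the
    delta method under ``Var(K) = mu + alpha * mu**2``.  Genes with a
    zero total in either group are flagged untested (NaN statistics)
    and excluded from the BH adjustment.

    Returns a DataFrame indexed by gene with columns ``baseMean``,
    ``log2FoldChange``, ``lfcSE``, ``pvalue``, ``padj``, ``tested``.
    """
    if sf is None:
        sf = size_factors(cm.counts)
    a_ids, b_ids = contrast.split(cm.samples)
    if dispersions is None:
        grp = pd.Series("", index=cm.samples.index, dtype=object)
        grp.loc[a_ids] = "A"
        grp.loc[b_ids] = "B"
        keep = grp != ""
        dispersions = estimate_dispersions(
            cm.counts.loc[:, keep], sf[keep], grp[keep]
        )
    alpha = dispersions.reindex(cm.gene_ids).to_numpy()

    def _group(ids: pd.Index) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        k = cm.counts[list(ids)].to_numpy(dtype=float)
        s = sf[list(ids)].to_numpy()
        q = (k / s).mean(axis=1)
        n = len(ids)
        # Var(ln q_hat) = (1/n^2) * sum_j (1/(q s_j) + alpha)
        with np.errstate(divide="ignore", invalid="ignore"):
            var_ln = ((1.0 / (q[:, None] * s[None, :])).sum(axis=1) + n * alpha) / n**2
        return q, var_ln, k

    qa, var_a, ka = _group(a_ids)
    qb, var_b, kb = _group(b_ids)
    tested = (ka.sum(axis=1) > 0) & (kb.sum(axis=1) > 0)

    with np.errstate(divide="ignore", invalid="ignore"):
        lfc = np.log2(qa / qb)
        se_ln = np.sqrt(var_a + var_b)
        z = np.log(qa / qb) / se_ln
    pvalue = 2.0 * stats.norm.sf(np.abs(z))
    # identical group means give z = 0/0 -> NaN; that is a true null
    pvalue = np.where(tested & np.isnan(z) & (qa == qb), 1.0, pvalue)
    lfc = np.where(tested & (qa == qb), 0.0, lfc)

    base_mean = (
        cm.counts[list(a_ids) + list(b_ids)].to_numpy(dtype=float)
        / sf[list(a_ids) + list(b_ids)].to_numpy()
    ).mean(axis=1)

    res = pd.DataFrame(
        {
            "baseMean": base_mean,
            "log2FoldChange": np.where(tested, lfc, np.nan),
            "lfcSE": np.where(tested, se_ln / LN2, np.nan),
            "pvalue": np.where(tested, pvalue, np.nan),
            "tested": tested,
        },
        index=cm.gene_ids,
    )
    res["padj"] = adjust_bh(res["pvalue"].to_numpy())
    return res[["baseMean", "log2FoldChange", "lfcSE", "pvalue", "padj", "tested"]]


def adjust_bh(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values.

    NaN entries are excluded from the number of tests m and propagate
    as NaN.  Output is clipped to [0, 1] and monotone in sorted-p order.
    """
    p = np.asarray(pvalues, dtype=float)
    q = np.full_like(p, np.nan)
    mask = ~np.isnan(p)
    m = int(mask.sum())
    if m == 0:
        return q
    pm = p[mask]
    if ((pm < 0) | (pm > 1)).any():
        raise ValueError("p-values outside [0, 1]")
    order = np.argsort(pm, kind="stable")
    ranked = pm[order] * m / np.arange(1, m + 1)
    qs = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(qs, 1.0)
    q[mask] = out
    return q


def call_degs(
    de: pd.DataFrame,
    alpha: float = DEFAULT_ALPHA,
    lfc_min: float = DEFAULT_LFC_MIN,
) -> tuple[set, set]:
    """DEG calls: (up, down) gene-id sets at padj < alpha and |log2FC| >= lfc_min."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if lfc_min < 0:
        raise ValueError("lfc_min must be >= 0")
    sig = (de["padj"] < alpha) & de["tested"].astype(bool)
    up = set(de.index[sig & (de["log2FoldChange"] >= lfc_min)])
    down = set(de.index[sig & (de["log2FoldChange"] <= -lfc_min)])
    return up, down


def fpkm(counts: pd.DataFrame, gene_lengths: pd.Series) -> pd.DataFrame:
    """Fragments per kilobase per million mapped reads.

    FPKM_gj = count_gj * 1e9 / (length_g * total_count_j).
    """
    lengths = gene_lengths.reindex(counts.index).to_numpy(dtype=float)
    if (lengths <= 0).any() or np.isnan(lengths).any():
        raise ValueError("gene lengths must be positive for all genes")
    totals = counts.sum(axis=0).to_numpy(dtype=float)
    if (totals <= 0).any():
        bad = counts.columns[totals <= 0]
        raise ValueError(f"zero library total in samples: {list(bad)}")
    vals = counts.to_numpy(dtype=float) * 1e9 / (lengths[:, None] * totals[None, :])
    return pd.DataFrame(vals, index=counts.index, columns=counts.columns)
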