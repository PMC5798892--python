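"""Input-subtracted ChIP density normalization and promoter-signal summaries.

A density track is a set of sorted, non-overlapping genomic intervals
with non-negative values (bedGraph semantics, 0-based half-open).  A
treat/control pair is combined on the common union grid as

    normalized_i = treat_i / sum(treat) * 1e6  -  control_i / sum(control) * 1e6

i.e. each track is scaled to parts-per-million of its summed interval
density before subtraction; negative values are retained by default.
Promoter signal is the length-weighted mean of the normalized track over
a TSS-centered window, binned and strand-oriented for metagene profiles.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

TRACK_COLUMNS = ["chrom", "start", "end", "value"]


def validate_track(track: pd.DataFrame, name: str = "track") -> None:
    """Check bedGraph invariants: sorted, non-overlapping, values >= 0."""
    for col in TRACK_COLUMNS:
        if col not in track.columns:
            raise ValueError(f"{name}: missing column {col!r}")
    if (track["value"] < 0).any():
        raise ValueError(f"{name}: negative density values")
    if (track["end"] <= track["start"]).any():
        raise ValueError(f"{name}: empty or inverted intervals")
    for chrom, sub in track.groupby("chrom", sort=False):
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        if not (starts[1:] >= ends[:-1]).all():
            raise ValueError(f"{name}: overlapping or unsorted intervals on {chrom}")


def _union_grid(treat: pd.DataFrame, control: pd.DataFrame, chrom: str):
    """Breakpoint grid covering both tracks on one chromosome, with each
    track's value resampled onto it (0 where uncovered)."""
    t = treat[treat["chrom"] == chrom]
    c = control[control["chrom"] == chrom]
    edges = np.unique(
        np.concatenate(
            [t["start"], t["end"], c["start"], c["end"]]
        )
    )
    starts, ends = edges[:-1], edges[1:]

    def resample(sub: pd.DataFrame) -> np.ndarray:
        vals = np.zeros(len(starts))
        if len(sub):
            s = sub["start"].to_numpy()
            e = sub["end"].to_numpy()
            v = sub["value"].to_numpy(dtype=float)
            idx = np.searchsorted(s, starts, side="right") - 1
            ok = (idx >= 0) & (starts < e[np.clip(idx, 0, None)])
            vals[ok] = v[idx[ok]]
        return vals

    return starts, ends, resample(t), resample(c)


def normalize_density(treat: pd.DataFrame, control: pd.DataFrame) -> pd.DataFrame:
    """Control-subtracted per-million normalization on the union grid.

    Both tracks must share a chromosome namespace and have positive
    total density.  Totals are sums of per-interval density values on
    the union grid, so the per-million treat terms sum to exactly 1e6.
    """
    validate_track(treat, "treat")
    validate_track(control, "control")
    t_chroms = set(treat["chrom"])
    c_chroms = set(control["chrom"])
    if t_chroms != c_chroms:
        offenders = sorted(t_chroms ^ c_chroms)
        raise ValueError(f"chromosome namespaces differ: {offenders}")

    pieces = []
    grids = {}
    for chrom in sorted(t_chroms):
        starts, ends, tv, cv = _union_grid(treat, control, chrom)
        grids[chrom] = (starts, ends, tv, cv)
    total_t = sum(g[2].sum() for g in grids.values())
    total_c = sum(g[3].sum() for g in grids.values())
    if total_t <= 0 or total_c <= 0:
        raise ValueError("zero total density mass")
    for chrom in sorted(t_chroms):
        starts, ends, tv, cv = grids[chrom]
        val = tv / total_t * 1e6 - cv / total_c * 1e6
        pieces.append(
            pd.DataFrame({"chrom": chrom, "start": starts, "end": ends, "value": val})
        )
    return pd.concat(pieces, ignore_index=True)


def promoter_signal(
    track: pd.DataFrame,
    tss: pd.DataFrame,
    half_window: int = 2_000,
    bin_width: int = 100,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-gene mean normalized density over a TSS-centered window.

    Bins are length-weighted means of overlapping interval values with
    uncovered bases counted as 0; profiles are strand-oriented (most
    upstream bin first).  Returns ``(summary, profiles)``: summary has
    columns signal (window mean), n_covered_bases and no_coverage flag;
    profiles is genes x bins.
    """
    if half_window % bin_width != 0:
        raise ValueError("half_window must be a multiple of bin_width")
    nbins = 2 * half_window // bin_width
    by_chrom = {
        chrom: (
            sub["start"].to_numpy(),
            sub["end"].to_numpy(),
            sub["value"].to_numpy(dtype=float),
        )
        for chrom, sub in track.groupby("chrom", sort=False)
    }
    sig_rows = []
    prof = np.zeros((len(tss), nbins))
    for gi, (_, row) in enumerate(tss.iterrows()):
        strand = row["strand"]
        pos = int(row["start"]) if strand == "+" else int(row["end"]) - 1
        w0 = pos - half_window
        bins = np.zeros(nbins)
        covered = 0
        if row["chrom"] in by_chrom:
            s, e, v = by_chrom[row["chrom"]]
            lo = np.searchsorted(e, w0, side="right")
            hi = np.searchsorted(s, pos + half_window, side="left")
            for i in range(lo, hi):
                a = max(s[i], w0)
                b = min(e[i], pos + half_window)
                if b <= a:
                    continue
                covered += b - a
                first = (a - w0) // bin_width
                last = (b - 1 - w0) // bin_width
                for bidx in range(first, last + 1):
                    ba = max(a, w0 + bidx * bin_width)
                    bb = min(b, w0 + (bidx + 1) * bin_width)
                    bins[bidx] += v[i] * (bb - ba)
        bins /= bin_width
        if strand == "-":
            bins = bins[::-1]
        prof[gi] = bins
        sig_rows.append(
            {
                "gene_id": row["name"],
                "signal": bins.mean(),
                "n_covered_bases": covered,
                "no_coverage": covered == 0,
            }
        )
    summary = pd.DataFrame(sig_rows).set_index("gene_id")
    profiles = pd.DataFrame(prof, index=summary.index, columns=range(nbins))
    return summary, profiles


def group_signal_summary(
    signals: pd.DataFrame,
    gene_sets: dict,
    sample_groups: pd.Series,
    compare: tuple[str, str] = ("WT", "KO"),
) -> pd.DataFrame:
    """Per-set, per-group promoter-signal summary with a direction test.

    ``signals`` is genes x samples (per-sample promoter signal);
    ``sample_groups`` maps sample id -> group label (e.g. genotype).
    Samples within a group are averaged per gene, then per set the mean
    and SE across member genes are reported for each compared group,
    together with a paired t-test across genes for the direction
    ``compare[0] > compare[1]``.  Empty sets yield a missing row with a
    warning; singleton sets have missing SE and p.
    """
    import warnings

    missing = {
        name for name, genes in gene_sets.items() if not set(genes) & set(signals.index)
    }
    group_means = {}
    for grp in compare:
        cols = sample_groups.index[sample_groups == grp]
        if len(cols) == 0:
            raise ValueError(f"no samples in group {grp!r}")
        group_means[grp] = signals[list(cols)].mean(axis=1)

    rows = []
    for name, genes in gene_sets.items():
        genes = sorted(set(genes) & set(signals.index))
        if not genes:
            warnings.warn(f"gene set {name!r} is empty; row reported as missing")
            rows.append({"gene_set": name, "n_genes": 0})
            continue
        row = {"gene_set": name, "n_genes": len(genes)}
        vals = {}
        for grp in compare:
            x = group_means[grp].loc[genes].to_numpy()
            vals[grp] = x
            row[f"mean_{grp}"] = float(x.mean())
            row[f"se_{grp}"] = (
                float(x.std(ddof=1) / np.sqrt(len(x))) if len(x) > 1 else np.nan
            )
        a, b = vals[compare[0]], vals[compare[1]]
        row["mean_diff"] = float((a - b).mean())
        row[f"{compare[0]}_gt_{compare[1]}"] = bool(row["mean_diff"] > 0)
        if len(a) > 1:
            t, p = stats.ttest_rel(a, b)
            row["t_stat"], row["pvalue"] = float(t), float(p)
        else:
            row["t_stat"], row["pvalue"] = np.nan, np.nan
        rows.append(row)
    return pd.DataFrame(rows).set_index("gene_set")
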