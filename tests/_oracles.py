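"""Independent brute-force oracles used by the test suite.

These deliberately avoid the vectorized code paths of the package:
plain Python loops over definitions, so that agreement is meaningful.
"""

from __future__ import annotations

import numpy as np

from atf6rg.motifs import IUPAC, MotifPattern, revcomp


def brute_force_hits(seq: str, patterns: list[MotifPattern], origin: int = 0):
    """Position-by-position motif matching; returns a sorted list of
    (pattern_id, strand, offset, matched_sequence, mismatches)."""
    seq = seq.upper()
    out = []
    for pat in patterns:
        L = pat.length
        budget = pat.max_mismatch_per_half_site
        n5 = len(pat.half_site_5p)
        off3 = n5 + pat.spacer_length
        for start in range(len(seq) - L + 1):
            window = seq[start : start + L]
            for strand in ("+", "-"):
                probe = window if strand == "+" else revcomp(window)
                mm5 = sum(
                    b not in IUPAC[p]
                    for b, p in zip(probe[:n5], pat.half_site_5p)
                )
                mm3 = sum(
                    b not in IUPAC[p]
                    for b, p in zip(probe[off3:], pat.half_site_3p)
                )
                if mm5 <= budget and mm3 <= budget:
                    out.append(
                        (pat.pattern_id, strand, start + origin, probe, mm5 + mm3)
                    )
    return sorted(out)


def brute_force_bh(pvalues):
    """Definitional BH q-values: q_i = min over candidate thresholds
    t >= p_i of m * t / #{p_k <= t}, computed by exhaustive search."""
    p = np.asarray(pvalues, dtype=float)
    q = np.full_like(p, np.nan)
    valid = ~np.isnan(p)
    pv = p[valid]
    m = len(pv)
    out = np.empty(m)
    for i, pi in enumerate(pv):
        cands = [
            m * t / np.sum(pv <= t) for t in pv if t >= pi
        ]
        out[i] = min(1.0, min(cands))
    q[valid] = out
    return q


def brute_force_venn(a, b, c):
    """Membership-pattern enumeration over the union of three sets."""
    regions = {k: set() for k in ("A", "B", "C", "AB", "AC", "BC", "ABC")}
    for x in set(a) | set(b) | set(c):
        key = ""
        if x in a:
            key += "A"
        if x in b:
            key += "B"
        if x in c:
            key += "C"
        regions[key].add(x)
    return regions


def brute_force_promoter_bins(track_rows, chrom, tss, strand, half_window, bin_width):
    """Per-base accumulation of track values into strand-oriented bins."""
    nbins = 2 * half_window // bin_width

    def value_at(pos):
        for (c, s, e, v) in track_rows:
            if c == chrom and s <= pos < e:
                return v
        return 0.0

    bins = []
    for b in range(nbins):
        vals = [
            value_at(tss - half_window + b * bin_width + k) for k in range(bin_width)
        ]
        bins.append(sum(vals) / bin_width)
    if strand == "-":
        bins = bins[::-1]
    return np.array(bins)


COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def brute_force_promoter_seq(genome, chrom, tss, strand, upstream, downstream):
    """Per-base promoter extraction in gene orientation."""
    contig = genome[chrom]
    out = []
    for o in range(-upstream, downstream):
        pos = tss + o if strand == "+" else tss - o
        if 0 <= pos < len(contig):
            base = contig[pos]
            out.append(base if strand == "+" else COMP[base])
    return "".join(out)
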