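"""Strand-aware scanner for bipartite ERSE promoter motifs.

ATF6 binds ER stress response elements: two half-sites separated by a
fixed-length spacer of arbitrary sequence,

* ERSE I:  ``CCAAT`` - N9 - ``CCACR`` (R = A/G), 19 nt total
* ERSE II: ``ATTGG`` - N1 - ``CCACG``, 11 nt total

The scanner tests every position of a promoter window against each
pattern, on both orientations by default, with an optional per-half-site
mismatch budget for non-canonical elements.  ``N`` bases never match.
Offsets are TSS-relative: 0 is the TSS base, negative is upstream, and a
hit's offset is the leftmost position of the full match on the forward
(gene-oriented) reading regardless of strand.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

IUPAC = {
    "A": {"A"},
    "C": {"C"},
    "G": {"G"},
    "T": {"T"},
    "R": {"A", "G"},
    "Y": {"C", "T"},
    "S": {"C", "G"},
    "W": {"A", "T"},
    "K": {"G", "T"},
    "M": {"A", "C"},
    "B": {"C", "G", "T"},
    "D": {"A", "G", "T"},
    "H": {"A", "C", "T"},
    "V": {"A", "C", "G"},
    "N": {"A", "C", "G", "T"},
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")

MAX_RELAXED_MISMATCH = 2


def revcomp(seq: str) -> str:
    """Reverse complement (IUPAC-aware)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class MotifPattern:
    """Bipartite motif: 5' half-site, fixed spacer, 3' half-site."""

    pattern_id: str
    half_site_5p: str
    spacer_length: int
    half_site_3p: str
    max_mismatch_per_half_site: int = 0

    @property
    def length(self) -> int:
        return len(self.half_site_5p) + self.spacer_length + len(self.half_site_3p)

    def positions(self) -> list[tuple[int, frozenset, int]]:
        """(window index, allowed bases, half-site id 0/1) for specified positions."""
        out = []
        for i, ch in enumerate(self.half_site_5p):
            out.append((i, frozenset(IUPAC[ch]), 0))
        off = len(self.half_site_5p) + self.spacer_length
        for i, ch in enumerate(self.half_site_3p):
            out.append((off + i, frozenset(IUPAC[ch]), 1))
        return out


ERSE_I = MotifPattern("ERSE_I", "CCAAT", 9, "CCACR")
ERSE_II = MotifPattern("ERSE_II", "ATTGG", 1, "CCACG")


@dataclass(frozen=True)
class MotifHit:
    """One match in a promoter window (offset TSS-relative, see module doc)."""

    gene_id: str
    pattern_id: str
    strand: str
    offset: int
    matched_sequence: str
    mismatches: int


def compile_patterns(mode: str = "canonical", max_mm: int = 1) -> list[MotifPattern]:
    """The ERSE pattern set.

    ``canonical`` returns the two exact consensus patterns; ``relaxed``
    returns the same half-sites with a per-half-site mismatch budget of
    ``max_mm`` (spacer lengths unchanged).  ``relaxed`` with budget 0 is
    hit-for-hit equivalent to ``canonical``.
    """
    if mode == "canonical":
        return [ERSE_I, ERSE_II]
    if mode == "relaxed":
        if not 0 <= max_mm <= MAX_RELAXED_MISMATCH:
            raise ValueError(
                f"max_mm must be in [0, {MAX_RELAXED_MISMATCH}]: beyond that the "
                "5-nt half-sites lose all specificity"
            )
        suffix = f"_mm{max_mm}" if max_mm else ""
        return [
            MotifPattern(
                p.pattern_id + suffix,
                p.half_site_5p,
                p.spacer_length,
                p.half_site_3p,
                max_mm,
            )
            for p in (ERSE_I, ERSE_II)
        ]
    raise ValueError(f"unknown mode {mode!r}")


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.upper().encode(), dtype=np.uint8)


def _match_tables(pattern: MotifPattern, strand: str):
    """Per-specified-position (window index, byte lookup, half-site id).

    For the minus strand the pattern is reverse-complemented so matches
    are found on the forward reading; half-site ids are preserved so the
    mismatch budget still applies per original half-site.
    """
    specs = []
    if strand == "+":
        pos = pattern.positions()
    else:
        plen = pattern.length
        pos = []
        for i, allowed, hs in pattern.positions():
            rc_allowed = frozenset(a.translate(_COMPLEMENT) for a in allowed)
            pos.append((plen - 1 - i, rc_allowed, hs))
    for i, allowed, hs in pos:
        tab = np.zeros(256, dtype=bool)
        for b in allowed:
            tab[ord(b)] = True
        specs.append((i, tab, hs))
    return specs


def scan_sequence(
    seq: str,
    patterns: list[MotifPattern],
    both_strands: bool = True,
    origin: int = 0,
) -> list[MotifHit]:
    """All pattern matches in one sequence.

    ``origin`` is the TSS-relative coordinate of the first base of
    ``seq``; reported offsets are sequence index + origin.  Hits are
    sorted by offset, then pattern id, then strand; overlapping hits are
    all reported.  The ``gene_id`` field is left empty (filled by
    :func:`scan_promoters`).
    """
    codes = _encode(seq)
    hits: list[MotifHit] = []
    strands = ("+", "-") if both_strands else ("+",)
    for pattern in patterns:
        plen = pattern.length
        nstart = len(codes) - plen + 1
        if nstart <= 0:
            continue
        for strand in strands:
            mm = np.zeros((2, nstart), dtype=np.int16)
            for i, tab, hs in _match_tables(pattern, strand):
                mm[hs] += ~tab[codes[i : i + nstart]]
            budget = pattern.max_mismatch_per_half_site
            ok = np.flatnonzero((mm[0] <= budget) & (mm[1] <= budget))
            for start in ok:
                window = seq[start : start + plen].upper()
                matched = window if strand == "+" else revcomp(window)
                hits.append(
                    MotifHit(
                        gene_id="",
                        pattern_id=pattern.pattern_id,
                        strand=strand,
                        offset=int(start) + origin,
                        matched_sequence=matched,
                        mismatches=int(mm[0, start] + mm[1, start]),
                    )
                )
    hits.sort(key=lambda h: (h.offset, h.pattern_id, h.strand))
    return hits


@dataclass
class PromoterSet:
    """Gene-oriented promoter windows with their TSS-relative origin.

    ``sequences`` maps gene_id -> sequence; every sequence spans the
    window [-upstream, +downstream) in gene orientation.  ``truncated``
    flags genes whose window ran off a contig edge (their sequences are
    shorter and start at ``origins[gene]``).
    """

    sequences: pd.Series
    upstream: int
    downstream: int
    origins: dict | None = None
    truncated: frozenset = frozenset()

    def origin(self, gene: str) -> int:
        if self.origins and gene in self.origins:
            return self.origins[gene]
        return -self.upstream


def extract_promoters(
    genome,
    tss: pd.DataFrame,
    upstream: int = 10_000,
    downstream: int = 2_000,
) -> PromoterSet:
    """Gene-oriented promoter windows around annotated TSSs.

    ``genome`` is a mapping chrom -> sequence (e.g. a ``pyfaidx.Fasta``
    or a plain dict); ``tss`` is BED6-like (0-based half-open, strand in
    the sixth column) with the TSS at ``start`` for + genes and at
    ``end - 1`` for - genes.  For a + gene the window is the genomic
    slice ``[tss - upstream, tss + downstream)``; for a - gene, upstream
    lies at higher genomic coordinates, so the window is the reverse
    complement of ``[tss - downstream + 1, tss + upstream + 1)``.
    Windows truncated at contig edges are flagged; records naming a
    missing chromosome are skipped with a log entry.
    """
    seqs = {}
    origins = {}
    truncated = set()
    for _, row in tss.iterrows():
        gene, chrom, strand = row["name"], row["chrom"], row["strand"]
        try:
            contig = genome[chrom]
        except KeyError:
            logger.warning("chromosome %s missing from genome; skipping %s", chrom, gene)
            continue
        clen = len(contig)
        pos = int(row["start"]) if strand == "+" else int(row["end"]) - 1
        if strand == "+":
            g0, g1 = pos - upstream, pos + downstream
        else:
            g0, g1 = pos - downstream + 1, pos + upstream + 1
        c0, c1 = max(g0, 0), min(g1, clen)
        if c0 != g0 or c1 != g1:
            truncated.add(gene)
        piece = str(contig[c0:c1])
        if strand == "-":
            piece = revcomp(piece)
            origins[gene] = -upstream + (g1 - c1)
        else:
            origins[gene] = -upstream + (c0 - g0)
        seqs[gene] = piece
    return PromoterSet(
        sequences=pd.Series(seqs, name="sequence"),
        upstream=upstream,
        downstream=downstream,
        origins=origins,
        truncated=frozenset(truncated),
    )


def scan_promoters(
    promoters: PromoterSet, patterns: list[MotifPattern]
) -> tuple[pd.DataFrame, pd.Series]:
    """Scan every promoter; returns (hit table, per-gene has_canonical_erse).

    Promoters with more than 50% ``N`` are skipped with a log entry.
    The hit table has columns gene_id, pattern_id, strand, offset,
    matched_sequence, mismatches.
    """
    if promoters.sequences.index.duplicated().any():
        raise ValueError("duplicate gene_id in promoter set")
    canonical_ids = {p.pattern_id for p in (ERSE_I, ERSE_II)}
    rows = []
    flags = {}
    for gene, seq in promoters.sequences.items():
        if seq and seq.upper().count("N") / len(seq) > 0.5:
            logger.warning("promoter of %s is >50%% N; skipped", gene)
            flags[gene] = False
            continue
        hits = scan_sequence(seq, patterns, origin=promoters.origin(gene))
        flags[gene] = any(
            h.pattern_id in canonical_ids and h.mismatches == 0 for h in hits
        )
        for h in hits:
            rows.append(
                (gene, h.pattern_id, h.strand, h.offset, h.matched_sequence, h.mismatches)
            )
    table = pd.DataFrame(
        rows,
        columns=["gene_id", "pattern_id", "strand", "offset", "matched_sequence", "mismatches"],
    )
    return table, pd.Series(flags, name="has_canonical_erse", dtype=bool)


def _halfsite_match_prob(half_site: str, max_mm: int, probs: dict[str, float]) -> float:
    """P(<= max_mm mismatches) for one half-site under i.i.d. base draws."""
    # Poisson-binomial over positions via DP
    dp = np.zeros(max_mm + 2)
    dp[0] = 1.0
    for ch in half_site:
        p_match = sum(probs[b] for b in IUPAC[ch])
        new = np.zeros_like(dp)
        new[: max_mm + 1] += dp[: max_mm + 1] * p_match
        new[1 : max_mm + 2] += dp[: max_mm + 1] * (1.0 - p_match)
        new[max_mm + 1] += dp[max_mm + 1]
        dp = new
    return float(dp[: max_mm + 1].sum())


def expected_background_hits(
    pattern: MotifPattern, window_length: int, gc: float = 0.5
) -> float:
    """Closed-form expected hit count per window, both strands, i.i.d. bases.

    ``2 * (L - l + 1) * P(5' half matches) * P(3' half matches)`` with
    per-base probabilities implied by the GC fraction.
    """
    if not 0 < gc < 1:
        raise ValueError("gc must lie in (0, 1)")
    probs = {"A": (1 - gc) / 2, "T": (1 - gc) / 2, "C": gc / 2, "G": gc / 2}
    nstart = window_length - pattern.length + 1
    if nstart <= 0:
        return 0.0
    mm = pattern.max_mismatch_per_half_site
    p = _halfsite_match_prob(pattern.half_site_5p, mm, probs) * _halfsite_match_prob(
        pattern.half_site_3p, mm, probs
    )
    return 2.0 * nstart * p
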