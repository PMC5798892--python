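"""CARG/IARG classification and cross-cell-type overlap partitioning.

CARGs (constitutive ATF6-responsive genes) are genes significantly
downregulated in the ATF6 knockout versus wild type at BOTH early and
late passage without a stressor; the mirrored constitutively-up set is
kept alongside.  IARGs (induced ATF6-responsive genes) are genes
upregulated by tunicamycin in wild-type cells AND downregulated in the
knockout versus wild type under tunicamycin.  Both definitions are
literal intersections of per-contrast DEG calls, matching how the sets
were derived from separate per-contrast tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd


@dataclass
class ResponsiveGeneSets:
    """Named responsive-gene sets for one cell type."""

    cell_type: str
    carg_down: set = field(default_factory=set)
    const_up: set = field(default_factory=set)
    iarg: set = field(default_factory=set)
    contrasts: dict = field(default_factory=dict)
    thresholds: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.carg_down & self.const_up:
            raise ValueError("carg_down and const_up must be disjoint")


#: region keys of a 3-set Venn, by membership pattern (A, B, C)
VENN_REGIONS = ("A", "B", "C", "AB", "AC", "BC", "ABC")


@dataclass
class OverlapPartition:
    """Disjoint 7-region Venn partition of three gene sets."""

    set_names: tuple[str, str, str]
    regions: dict

    def counts(self) -> dict:
        return {k: len(v) for k, v in self.regions.items()}

    def region_for(self, *names: str) -> set:
        key = "".join(
            letter
            for letter, nm in zip("ABC", self.set_names)
            if nm in names
        )
        return self.regions[key]


def derive_cargs(
    deg_ep: tuple[set, set], deg_lp: tuple[set, set]
) -> tuple[set, set]:
    """Constitutive responsive genes from KO-vs-WT DEGs at both passages.

    ``deg_ep`` / ``deg_lp`` are (up, down) DEG sets from the early- and
    late-passage knockout-versus-wild-type contrasts.  Returns
    ``(carg_down, const_up)``: genes significant in the same direction
    at both passages.
    """
    up_ep, down_ep = deg_ep
    up_lp, down_lp = deg_lp
    return set(down_ep) & set(down_lp), set(up_ep) & set(up_lp)


def derive_iargs(tm_up_wt: set, ko_down_tm: set) -> set:
    """Induced responsive genes: TM-upregulated in WT and blunted in the KO.

    ``tm_up_wt`` is the up set of the TM-versus-vehicle contrast within
    wild type; ``ko_down_tm`` the down set of the KO-versus-WT contrast
    under TM.
    """
    return set(tm_up_wt) & set(ko_down_tm)


def carg_iarg_overlap(cargs: set, iargs: set) -> dict:
    """Intersection of the two responsive classes, with exclusive counts."""
    shared = set(cargs) & set(iargs)
    return {
        "shared": shared,
        "n_carg_only": len(set(cargs) - shared),
        "n_iarg_only": len(set(iargs) - shared),
    }


def cross_celltype_partition(sets_by_celltype: dict) -> OverlapPartition:
    """7-region Venn partition of gene sets from exactly three cell types."""
    if len(sets_by_celltype) != 3:
        raise ValueError("cross-cell-type partition requires exactly 3 sets")
    names = tuple(sets_by_celltype)
    a, b, c = (set(sets_by_celltype[n]) for n in names)
    universe = a | b | c
    regions = {k: set() for k in VENN_REGIONS}
    for gene in universe:
        key = "".join(
            letter for letter, s in zip("ABC", (a, b, c)) if gene in s
        )
        regions[key].add(gene)
    return OverlapPartition(set_names=names, regions=regions)


def evaluate_recovery(called: set, planted: set, universe: set | None = None) -> dict:
    """Sensitivity / precision / empirical FDR of a called set vs. truth.

    Undefined ratios (empty planted or empty called set) are reported as
    ``None``.
    """
    called, planted = set(called), set(planted)
    if universe is not None:
        stray = called - set(universe)
        if stray:
            raise ValueError(f"called genes outside the universe: {sorted(stray)[:5]}")
    tp = len(called & planted)
    sensitivity = tp / len(planted) if planted else None
    precision = tp / len(called) if called else None
    return {
        "n_called": len(called),
        "n_planted": len(planted),
        "n_true_positive": tp,
        "sensitivity": sensitivity,
        "precision": precision,
        "fdr": None if precision is None else 1.0 - precision,
    }
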