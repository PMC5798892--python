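"""Truth-labelled synthetic data emulating the ATF6 knockout study design.

The generators produce (i) a factorial sample design over cell type
(hMSC/hESC/hWAPC), genotype (WT / ATF6 knockout), ER-stress condition
(vehicle / 12-h tunicamycin) and, for hMSCs, culture passage (early/late);
(ii) an NB count matrix with planted effects for the two responsive-gene
classes — CARGs (constitutively down in the knockout at both passages) and
IARGs (tunicamycin-induced in WT, blunted in the knockout) — plus a small
"both" class mirroring the CARG/IARG overlap; (iii) promoter sequences with
planted ERSE motifs; and (iv) H3K4me3-like ChIP density tracks whose
promoter enrichment follows the planted transcriptional activity.

Every generator is a pure function of its arguments including the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .de import CountMatrix
from .motifs import MotifPattern, compile_patterns, revcomp

CELL_TYPES = ("hMSC", "hESC", "hWAPC")
GENOTYPES = ("WT", "KO")
CONDITIONS = ("vehicle", "TM")
PASSAGES = ("EP", "LP")
DUMMY_PASSAGE = "NA"

LABELS = ("null", "carg_down", "const_up", "iarg", "both")

#: contrasts of the study, in the order the gene-set logic consumes them
CONTRAST_NAMES = (
    "KO_vs_WT.vehicle.EP",
    "KO_vs_WT.vehicle.LP",
    "TM_vs_vehicle.WT",
    "KO_vs_WT.TM",
)

BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass(frozen=True)
class SampleDesign:
    """Factorial sample layout; ``samples`` is indexed by sample_id."""

    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if self.samples.index.duplicated().any():
            raise ValueError("duplicate sample ids")
        counts = self.samples.groupby(
            ["cell_type", "genotype", "condition", "passage"], observed=True
        ).size()
        if (counts < 2).any():
            raise ValueError("every design cell needs >= 2 replicates")

    @property
    def cell_types(self) -> list[str]:
        return list(pd.unique(self.samples["cell_type"]))


@dataclass
class SimParams:
    """Parameters of the count simulation.

    Baseline means are log-normal (location/scale on the natural-log
    scale), dispersions log-normal around a typical bulk RNA-seq value,
    and library-size multipliers log-normal with geometric mean 1.
    Effect sizes are log2 fold changes; fractions give the share of the
    gene universe in each truth class (remainder is null).
    """

    n_genes: int = 5000
    mean_log_loc: float = float(np.log(100.0))
    mean_log_scale: float = 1.2
    disp_log_loc: float = float(np.log(0.05))
    disp_log_scale: float = 0.3
    libsize_log_scale: float = 0.15
    carg_lfc: float = -1.5
    const_up_lfc: float = 1.5
    tm_lfc: float = 1.5
    ko_blunt_lfc: float = -1.5
    frac_carg: float = 0.04
    frac_const_up: float = 0.02
    frac_iarg: float = 0.03
    frac_both: float = 0.002
    gene_length_range: tuple[int, int] = (500, 5000)
    seed: int = 0

    def validate(self) -> None:
        fracs = (self.frac_carg, self.frac_const_up, self.frac_iarg, self.frac_both)
        if any(f < 0 for f in fracs) or sum(fracs) > 1:
            raise ValueError("truth-class fractions must be >= 0 and sum <= 1")
        if self.disp_log_scale < 0 or self.mean_log_scale < 0:
            raise ValueError("scale parameters must be >= 0")
        if self.carg_lfc > 0 or self.ko_blunt_lfc > 0:
            raise ValueError("carg_lfc and ko_blunt_lfc must be <= 0")
        if self.n_genes < 1:
            raise ValueError("n_genes must be positive")

    def with_overrides(self, **kwargs) -> "SimParams":
        return replace(self, **kwargs)


@dataclass
class TruthLabels:
    """Planted ground truth accompanying a simulated count matrix."""

    labels: pd.Series  # gene -> label
    lfc_by_contrast: pd.DataFrame  # genes x CONTRAST_NAMES
    motif_plants: pd.DataFrame  # gene_id, pattern_id, offset, strand
    promoter_enriched: pd.DataFrame  # genes x genotypes, bool

    def genes_with(self, *labels: str) -> set:
        return set(self.labels.index[self.labels.isin(labels)])


def build_design(
    cell_types,
    n_reps: int = 3,
    include_passages=None,
    include_tm: bool = True,
    seed: int | None = None,
) -> SampleDesign:
    """Full factorial design over the requested factors.

    With passages, vehicle samples exist at both early (EP) and late (LP)
    passage while the tunicamycin arm is paired at EP only; without a
    passage axis each genotype carries vehicle (and optionally TM)
    samples at a single dummy passage level.  Deterministic given its
    arguments; ``seed`` is accepted for interface symmetry with the
    other generators.
    """
    if n_reps < 2:
        raise ValueError("n_reps must be >= 2 (variance inestimable otherwise)")
    cell_types = list(cell_types)
    if not cell_types:
        raise ValueError("cell_types must be non-empty")
    rows = []
    for ct in cell_types:
        cells = []
        for g in GENOTYPES:
            if include_passages:
                cells += [(g, "vehicle", "EP"), (g, "vehicle", "LP")]
                if include_tm:
                    cells.append((g, "TM", "EP"))
            else:
                cells.append((g, "vehicle", DUMMY_PASSAGE))
                if include_tm:
                    cells.append((g, "TM", DUMMY_PASSAGE))
        for g, cond, passage in cells:
            for r in range(1, n_reps + 1):
                sid = f"{ct}_{g}_{cond}_{passage}_r{r}"
                rows.append((sid, ct, g, cond, passage, r))
    df = pd.DataFrame(
        rows,
        columns=["sample_id", "cell_type", "genotype", "condition", "passage", "replicate"],
    ).set_index("sample_id")
    return SampleDesign(samples=df)


def assign_labels(n_genes: int, params: SimParams, rng: np.random.Generator) -> pd.Series:
    """Partition the gene universe into truth classes.

    Class sizes are round(fraction * n_genes), exactly reproducible;
    membership is a seeded permutation.
    """
    sizes = {
        "carg_down": round(params.frac_carg * n_genes),
        "const_up": round(params.frac_const_up * n_genes),
        "iarg": round(params.frac_iarg * n_genes),
        "both": round(params.frac_both * n_genes),
    }
    if sum(sizes.values()) > n_genes:
        raise ValueError("truth-class fractions exceed the gene universe")
    gene_ids = [f"G{i:05d}" for i in range(n_genes)]
    perm = rng.permutation(n_genes)
    labels = pd.Series("null", index=pd.Index(gene_ids, name="gene_id"))
    pos = 0
    for lab, k in sizes.items():
        labels.iloc[perm[pos : pos + k]] = lab
        pos += k
    return labels


def _planted_lfc(label: str, genotype: str, condition: str, p: SimParams) -> float:
    """Sum of planted log2 effects active in one design cell."""
    lfc = 0.0
    if genotype == "KO" and label in ("carg_down", "both"):
        lfc += p.carg_lfc
    if genotype == "KO" and label == "const_up":
        lfc += p.const_up_lfc
    if condition == "TM" and label in ("iarg", "both"):
        lfc += p.tm_lfc
        if genotype == "KO":
            lfc += p.ko_blunt_lfc
    return lfc


def simulate_counts(
    design: SampleDesign, params: SimParams
) -> tuple[CountMatrix, TruthLabels]:
    """NB counts with planted CARG/IARG effects and full truth bookkeeping.

    Per gene g and sample j the mean is
    ``baseline_g * libsize_j * 2**(sum of planted log2FCs active in j)``
    and counts are drawn NB with the gene's dispersion.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    n = params.n_genes
    labels = assign_labels(n, params, rng)
    gene_ids = labels.index

    baseline = rng.lognormal(params.mean_log_loc, params.mean_log_scale, n)
    disp = rng.lognormal(params.disp_log_loc, params.disp_log_scale, n)
    lengths = rng.integers(*params.gene_length_range, size=n)
    meta = design.samples
    lib = rng.lognormal(0.0, params.libsize_log_scale, len(meta))

    lfc_cell = {}  # (label, genotype, condition) -> lfc
    for lab in LABELS:
        for g in GENOTYPES:
            for c in CONDITIONS:
                lfc_cell[(lab, g, c)] = _planted_lfc(lab, g, c, params)
    geno = meta["genotype"].to_numpy()
    cond = meta["condition"].to_numpy()
    cell_table = np.array(
        [[lfc_cell[(lab, g, c)] for g, c in zip(geno, cond)] for lab in LABELS]
    )
    lab_idx = labels.map({lab: i for i, lab in enumerate(LABELS)}).to_numpy()
    lfc_mat = cell_table[lab_idx]
    mu = baseline[:, None] * lib[None, :] * 2.0**lfc_mat
    counts = rng.negative_binomial(1.0 / disp[:, None], 1.0 / (1.0 + disp[:, None] * mu))

    cm = CountMatrix(
        counts=pd.DataFrame(counts, index=gene_ids, columns=meta.index),
        samples=meta.copy(),
        gene_lengths=pd.Series(lengths, index=gene_ids, name="length"),
    )

    # truth log2FC per contrast (numerator minus denominator cell)
    contrast_cells = {
        "KO_vs_WT.vehicle.EP": (("KO", "vehicle"), ("WT", "vehicle")),
        "KO_vs_WT.vehicle.LP": (("KO", "vehicle"), ("WT", "vehicle")),
        "TM_vs_vehicle.WT": (("WT", "TM"), ("WT", "vehicle")),
        "KO_vs_WT.TM": (("KO", "TM"), ("WT", "TM")),
    }
    lfc_by_contrast = pd.DataFrame(0.0, index=gene_ids, columns=list(CONTRAST_NAMES))
    for cname, ((gn, cn), (gd, cd)) in contrast_cells.items():
        lfc_by_contrast[cname] = [
            lfc_cell[(lab, gn, cn)] - lfc_cell[(lab, gd, cd)] for lab in labels
        ]

    motif_plants = _plant_motifs(labels, rng)
    enriched = pd.DataFrame(False, index=gene_ids, columns=list(GENOTYPES))
    active_wt = labels.isin(["carg_down", "iarg", "both"])
    enriched.loc[active_wt, "WT"] = True
    enriched.loc[labels == "const_up", "KO"] = True

    truth = TruthLabels(
        labels=labels,
        lfc_by_contrast=lfc_by_contrast,
        motif_plants=motif_plants,
        promoter_enriched=enriched,
    )
    return cm, truth


def _plant_motifs(
    labels: pd.Series,
    rng: np.random.Generator,
    upstream: int = 10_000,
    downstream: int = 2_000,
) -> pd.DataFrame:
    """One canonical ERSE plant per responsive gene, at a random offset/strand."""
    pat_i, pat_ii = compile_patterns("canonical")
    rows = []
    for gene, lab in labels.items():
        if lab == "null":
            continue
        pat = pat_i if rng.random() < 0.7 else pat_ii
        offset = int(rng.integers(-upstream, downstream - pat.length + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        rows.append((gene, pat.pattern_id, offset, strand))
    return pd.DataFrame(rows, columns=["gene_id", "pattern_id", "offset", "strand"])


def realize_motif(pattern: MotifPattern, rng: np.random.Generator, gc: float = 0.5) -> str:
    """A concrete sequence matching the pattern; degenerate positions and
    spacer bases are drawn at random (spacer at the background GC)."""
    from .motifs import IUPAC

    probs = _base_probs(gc)
    out = []
    for ch in pattern.half_site_5p:
        out.append(rng.choice(sorted(IUPAC[ch])))
    for _ in range(pattern.spacer_length):
        out.append(str(rng.choice(["A", "C", "G", "T"], p=probs)))
    for ch in pattern.half_site_3p:
        out.append(rng.choice(sorted(IUPAC[ch])))
    return "".join(out)


def _base_probs(gc: float) -> np.ndarray:
    if not 0 < gc < 1:
        raise ValueError("gc must lie in (0, 1)")
    at = (1.0 - gc) / 2.0
    g = gc / 2.0
    return np.array([at, g, g, at])  # A C G T


def simulate_promoters(
    gene_ids,
    plant_spec: pd.DataFrame | None = None,
    gc: float = 0.5,
    upstream: int = 10_000,
    downstream: int = 2_000,
    seed: int = 0,
) -> tuple[pd.Series, pd.DataFrame, pd.DataFrame]:
    """Promoter sequences with planted ERSE motifs, plus a TSS table.

    Each promoter is an i.i.d. background sequence of length
    ``upstream + downstream`` (gene-oriented, the TSS-relative window
    [-upstream, +downstream)); plants overwrite the background at the
    stated TSS-relative offsets (reverse-strand plants are written as the
    reverse complement).  The TSS table is BED6-like with synthetic
    coordinates on one chromosome, alternating gene strand.

    Returns ``(promoters, tss, motif_truth)`` where promoters is a
    Series gene_id -> sequence and motif_truth records every plant.
    """
    rng = np.random.default_rng(seed)
    gene_ids = list(gene_ids)
    if len(set(gene_ids)) != len(gene_ids):
        raise ValueError("duplicate gene ids")
    length = upstream + downstream
    patterns = {p.pattern_id: p for p in compile_patterns("canonical")}

    plants: dict[str, list[tuple[str, int, str]]] = {g: [] for g in gene_ids}
    if plant_spec is not None and len(plant_spec):
        for _, row in plant_spec.iterrows():
            g = row["gene_id"]
            if g not in plants:
                continue
            pat = patterns[row["pattern_id"]]
            off = int(row["offset"])
            if off < -upstream or off > downstream - pat.length:
                raise ValueError(
                    f"plant offset {off} for {g} outside "
                    f"[-{upstream}, {downstream - pat.length}]"
                )
            plants[g].append((row["pattern_id"], off, row["strand"]))

    probs = _base_probs(gc)
    seqs = {}
    truth_rows = []
    for g in gene_ids:
        arr = rng.choice(BASES, size=length, p=probs)
        occupied: list[tuple[int, int]] = []
        for pid, off, strand in plants[g]:
            pat = patterns[pid]
            i0, i1 = off + upstream, off + upstream + pat.length
            for a, b in occupied:
                if i0 < b and a < i1:
                    raise ValueError(f"overlapping plants in {g}")
            occupied.append((i0, i1))
            inst = realize_motif(pat, rng, gc)
            if strand == "-":
                inst = revcomp(inst)
            arr[i0:i1] = np.frombuffer(inst.encode(), dtype="S1")
            truth_rows.append((g, pid, off, strand, inst))
        seqs[g] = arr.tobytes().decode()

    spacing = length + 1000
    rows = []
    for i, g in enumerate(gene_ids):
        strand = "+" if i % 2 == 0 else "-"
        win_start = i * spacing
        # gene-oriented window [-upstream, +downstream) maps to genomic
        # [tss-upstream, tss+downstream) on +, [tss-downstream+1, tss+upstream+1) on -
        tss = win_start + upstream if strand == "+" else win_start + downstream - 1
        rows.append(("chrS", tss, tss + 1, g, 0, strand))
    tss_df = pd.DataFrame(
        rows, columns=["chrom", "start", "end", "name", "score", "strand"]
    )
    motif_truth = pd.DataFrame(
        truth_rows, columns=["gene_id", "pattern_id", "offset", "strand", "sequence"]
    )
    return pd.Series(seqs, name="sequence"), tss_df, motif_truth


def build_genome(
    promoters: pd.Series,
    tss: pd.DataFrame,
    upstream: int = 10_000,
    downstream: int = 2_000,
) -> dict[str, str]:
    """Assemble the synthetic chromosome implied by a simulated TSS table.

    Gene-oriented promoter sequences are written into genomic coordinates
    (reverse-complemented for minus-strand genes) so that
    ``motifs.extract_promoters`` recovers them exactly.  Gaps between
    promoter windows are filled with ``N``.
    """
    pieces: dict[str, list[tuple[int, str]]] = {}
    for _, row in tss.iterrows():
        seq = promoters[row["name"]]
        if row["strand"] == "+":
            win_start = row["start"] - upstream
            genomic = seq
        else:
            win_start = row["start"] - downstream + 1
            genomic = revcomp(seq)
        pieces.setdefault(row["chrom"], []).append((win_start, genomic))
    genome = {}
    for chrom, parts in pieces.items():
        end = max(start + len(s) for start, s in parts)
        arr = np.full(end, b"N", dtype="S1")
        for start, s in parts:
            arr[start : start + len(s)] = np.frombuffer(s.encode(), dtype="S1")
        genome[chrom] = arr.tobytes().decode()
    return genome


def simulate_chip_tracks(
    design: SampleDesign,
    truth: TruthLabels,
    tss: pd.DataFrame,
    bin_width: int = 100,
    half_window: int = 2_000,
    noise_shape: float = 1.0,
    noise_scale: float = 1.0,
    amplitude: float = 4.0,
    bump_sigma: float = 500.0,
    n_background_bins: int = 100_000,
    background_mean: float = 30.0,
    seed: int = 0,
) -> dict[str, tuple[pd.DataFrame, pd.DataFrame]]:
    """Per-sample (treat, control) bedGraph-style H3K4me3 density tracks.

    The control is flat gamma noise; the treat track adds a Gaussian
    promoter bump (sd ``bump_sigma`` bp, peak ``amplitude``) at genes
    flagged promoter-enriched for the sample's genotype, mirroring
    H3K4me3 tracking transcriptional activity (enriched in WT at
    CARG/IARG promoters, reduced or absent in the knockout).

    Besides the studied promoter windows, both tracks carry a
    rest-of-genome background compartment (``n_background_bins`` bins on
    ``chrBG`` at mean density ``background_mean``, identical in
    distribution across genotypes).  In a genome-wide library the
    handful of genotype-differential promoters is a sub-percent share of
    total mass; without this compartment, per-million scaling would
    transfer the planted differential mass onto every other window and
    fabricate genotype differences at unrelated genes.

    Returns ``{sample_id: (treat, control)}``, each a DataFrame with
    columns chrom, start, end, value covering ``[tss - half_window,
    tss + half_window)`` in ``bin_width`` bins plus the background.
    """
    if 2 * half_window % bin_width != 0:
        raise ValueError("bin width must divide the window length")
    rng = np.random.default_rng(seed)
    nbins = 2 * half_window // bin_width
    genes = tss["name"].to_numpy()
    tss_pos = tss["start"].to_numpy()
    chroms = tss["chrom"].to_numpy()
    strands = tss["strand"].to_numpy()
    win_tss = np.where(strands == "+", tss_pos, tss["end"].to_numpy() - 1)
    starts = np.concatenate(
        [t - half_window + bin_width * np.arange(nbins) for t in win_tss]
    )
    centers_rel = -half_window + bin_width * (np.arange(nbins) + 0.5)
    bump = amplitude * np.exp(-(centers_rel**2) / (2.0 * bump_sigma**2))
    bg_starts = bin_width * np.arange(n_background_bins)

    out = {}
    for sid, row in design.samples.iterrows():
        flags = (
            truth.promoter_enriched[row["genotype"]].reindex(genes).to_numpy()
        )
        noise_c = rng.gamma(noise_shape, noise_scale, (len(genes), nbins))
        noise_t = rng.gamma(noise_shape, noise_scale, (len(genes), nbins))
        enrich = np.where(flags[:, None], bump[None, :], 0.0)
        bg_scale = background_mean / noise_shape
        bg_t = rng.gamma(noise_shape, bg_scale, n_background_bins)
        bg_c = rng.gamma(noise_shape, bg_scale, n_background_bins)
        base = {
            "chrom": np.concatenate(
                [np.repeat(chroms, nbins), np.repeat("chrBG", n_background_bins)]
            ),
            "start": np.concatenate([starts, bg_starts]),
            "end": np.concatenate([starts + bin_width, bg_starts + bin_width]),
        }
        treat = pd.DataFrame(
            {**base, "value": np.concatenate([(noise_t + enrich).ravel(), bg_t])}
        )
        control = pd.DataFrame(
            {**base, "value": np.concatenate([noise_c.ravel(), bg_c])}
        )
        out[sid] = (treat, control)
    return out
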