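"""Readers and writers for the pipeline's text formats.

Counts and sample sheets are TSV, promoters FASTA (one record per gene),
TSS tables BED6 (0-based half-open, strand in column 6), ChIP tracks
bedGraph, gene sets one-per-line TXT plus a combined JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .de import CountMatrix

SAMPLE_COLUMNS = ["cell_type", "genotype", "condition", "passage", "replicate"]
BED6_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


def load_counts(counts_path, sample_sheet_path) -> CountMatrix:
    """Validated CountMatrix from a counts TSV and a sample sheet TSV.

    The counts file has gene_id in the first column and one column per
    sample; the sample sheet is indexed by sample_id and must cover
    exactly the count columns.  Non-integer or negative entries and
    duplicated gene ids are rejected with the offending record named.
    """
    try:
        counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    except pd.errors.EmptyDataError:
        raise ValueError(f"counts file {counts_path} is empty") from None
    if counts.empty or counts.shape[1] == 0:
        raise ValueError(f"counts file {counts_path} has no data")
    try:
        samples = pd.read_csv(sample_sheet_path, sep="\t", index_col=0)
    except pd.errors.EmptyDataError:
        raise ValueError(f"sample sheet {sample_sheet_path} is empty") from None
    missing = [c for c in SAMPLE_COLUMNS if c not in samples.columns]
    if missing:
        raise ValueError(f"sample sheet lacks columns: {missing}")
    non_numeric = [c for c in counts.columns if not pd.api.types.is_numeric_dtype(counts[c])]
    if non_numeric:
        raise ValueError(f"non-numeric count columns: {non_numeric[:5]}")
    if set(counts.columns) != set(samples.index):
        diff = sorted(set(counts.columns) ^ set(samples.index))
        raise ValueError(f"sample ids disagree between counts and sheet: {diff[:10]}")
    samples = samples.loc[counts.columns]
    return CountMatrix(counts=counts, samples=samples)


def write_counts(cm: CountMatrix, counts_path, sample_sheet_path) -> None:
    cm.counts.to_csv(counts_path, sep="\t", index_label="gene_id")
    cm.samples.to_csv(sample_sheet_path, sep="\t", index_label="sample_id")


def read_genome(path):
    """Random-access genome handle (pyfaidx) usable by extract_promoters."""
    from pyfaidx import Fasta

    return Fasta(str(path), sequence_always_upper=True)


def write_fasta(sequences: pd.Series, path) -> None:
    records = [
        SeqRecord(Seq(seq), id=str(gene), description="")
        for gene, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> pd.Series:
    return pd.Series(
        {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")},
        name="sequence",
    )


def write_bed6(df: pd.DataFrame, path) -> None:
    df[BED6_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


def read_bed6(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, names=BED6_COLUMNS)
    if df["strand"].isna().any() or not df["strand"].isin(["+", "-"]).all():
        raise ValueError(f"{path}: TSS entries must carry strand +/-")
    return df


def write_bedgraph(track: pd.DataFrame, path) -> None:
    track[["chrom", "start", "end", "value"]].to_csv(
        path, sep="\t", header=False, index=False
    )


def read_bedgraph(path) -> pd.DataFrame:
    return pd.read_csv(
        path, sep="\t", header=None, names=["chrom", "start", "end", "value"]
    )


def write_gene_sets(sets_by_name: dict, outdir, region_counts: dict | None = None) -> None:
    """One TXT per set (one gene per line) plus a combined JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    combined = {}
    for name, genes in sets_by_name.items():
        genes = sorted(genes)
        (outdir / f"{name}.txt").write_text("\n".join(genes) + ("\n" if genes else ""))
        combined[name] = genes
    payload = {"sets": combined}
    if region_counts is not None:
        payload["region_counts"] = region_counts
    (outdir / "gene_sets.json").write_text(json.dumps(payload, indent=2, sort_keys=True))


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, default=_jsonify))


def _jsonify(x):
    import numpy as np

    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, (set, frozenset)):
        return sorted(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    raise TypeError(f"not JSON serializable: {type(x)}")
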