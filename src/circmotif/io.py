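"""Readers and writers for the package's file formats.

FASTA for sequences (via Biopython), tab-delimited tables for DE results,
miRNA seeds, qPCR wells and densitometry, BED6+2 for CLIP peaks (the two
extra columns are log2 fold-enrichment over the size-matched input and
-log10 p), and BED6 for motif matches.  Sequences are normalised (U->T,
uppercase) on read.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .clip import BindingSite
from .seqkmer import MotifMatch, normalize_sequence
from .sponge import SeedSite

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_peaks_bed",
    "write_peaks_bed",
    "read_features_bed",
    "write_features_bed",
    "read_seed_tsv",
    "write_seed_tsv",
    "write_matches_bed",
    "read_qpcr_tsv",
    "read_densitometry_tsv",
]

PEAK_COLUMNS = ["chrom", "start", "end", "name", "score", "strand",
                "log2_fold_enrichment", "neg_log10_p"]
FEATURE_COLUMNS = ["chrom", "start", "end", "gene_id", "score", "strand"]


def read_fasta(path: str | Path) -> dict[str, str]:
    """id -> normalised sequence (uppercase DNA, U mapped to T)."""
    return {
        rec.id: normalize_sequence(str(rec.seq))
        for rec in SeqIO.parse(str(path), "fasta")
    }


def write_fasta(path: str | Path, sequences: dict[str, str]) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def read_peaks_bed(path: str | Path, cell_line: str = "") -> list[BindingSite]:
    """BED6+2 peaks; column 4 (name) is the RBP."""
    df = pd.read_csv(path, sep="\t", header=None, names=PEAK_COLUMNS, comment="#")
    return [
        BindingSite(
            chrom=str(r.chrom), start=int(r.start), end=int(r.end), strand=str(r.strand),
            rbp=str(r.name), log2_fold_enrichment=float(r.log2_fold_enrichment),
            neg_log10_p=float(r.neg_log10_p), cell_line=cell_line,
        )
        for r in df.itertuples(index=False)
    ]


def write_peaks_bed(path: str | Path, peaks: list[BindingSite]) -> None:
    rows = [
        (p.chrom, p.start, p.end, p.rbp, 0, p.strand,
         f"{p.log2_fold_enrichment:.4f}", f"{p.neg_log10_p:.4f}")
        for p in peaks
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)


def read_features_bed(path: str | Path) -> pd.DataFrame:
    """BED6 feature intervals; column 4 is the owning gene_id."""
    df = pd.read_csv(path, sep="\t", header=None, names=FEATURE_COLUMNS, comment="#")
    bad = df.index[df["end"] <= df["start"]]
    if len(bad):
        raise ValueError(f"{path}: malformed interval (end <= start) at line {bad[0] + 1}")
    return df


def write_features_bed(path: str | Path, features: pd.DataFrame) -> None:
    features[FEATURE_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


def read_seed_tsv(path: str | Path) -> list[SeedSite]:
    df = pd.read_csv(path, sep="\t")
    for col in ("mirna_id", "site"):
        if col not in df.columns:
            raise ValueError(f"seed table {path} missing column {col!r}")
    conserved = df["conserved"] if "conserved" in df.columns else [False] * len(df)
    return [
        SeedSite(mirna_id=str(m), site_7mer=str(s), conserved=bool(c))
        for m, s, c in zip(df["mirna_id"], df["site"], conserved)
    ]


def write_seed_tsv(path: str | Path, seeds: list[SeedSite]) -> None:
    pd.DataFrame(
        {
            "mirna_id": [s.mirna_id for s in seeds],
            "site": [s.site_7mer for s in seeds],
            "conserved": [s.conserved for s in seeds],
        }
    ).to_csv(path, sep="\t", index=False)


def write_matches_bed(path: str | Path, matches: list[MotifMatch], motif_name: str) -> None:
    """Matches as BED6: name = motif, score = mismatch count."""
    rows = [(m.sequence_id, m.start, m.end, motif_name, m.mismatches, "+") for m in matches]
    pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)


def read_qpcr_tsv(path: str | Path) -> pd.DataFrame:
    """Well table: sample_id, role (standard|sample), copies (standards), ct, replicate."""
    df = pd.read_csv(path, sep="\t")
    for col in ("sample_id", "role", "ct"):
        if col not in df.columns:
            raise ValueError(f"qPCR table {path} missing column {col!r}")
    roles = set(df["role"])
    if not roles <= {"standard", "sample"}:
        raise ValueError(f"unknown qPCR roles: {sorted(roles - {'standard', 'sample'})}")
    return df


def read_densitometry_tsv(path: str | Path) -> pd.DataFrame:
    """Band table: sample_id, role (standard|sample), mass_ng (standards), intensity."""
    df = pd.read_csv(path, sep="\t")
    for col in ("sample_id", "role", "intensity"):
        if col not in df.columns:
            raise ValueError(f"densitometry table {path} missing column {col!r}")
    return df
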