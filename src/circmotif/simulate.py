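"""Ground-truthed synthetic inputs for every stage of the pipeline.

The generator emulates a two-knockdown study of a circular RNA that binds an
RNA-binding protein (RBP) through a degenerate 11-mer: a circRNA sequence
carrying both variants of the planted motif, per-gene 3'UTRs a fraction of
which carry planted instances, two differential-expression tables (experiment
A: circRNA knockdown, motif genes pushed down; experiment B: RBP knockdown,
the same genes pushed up), CLIP peaks that cover planted instances for the
true RBP plus uniformly placed decoy peaks, a miRNA seed list with no planted
association, and qPCR / densitometry calibration panels with known
copies-per-cell.  Truth (planted positions, per-gene motif status, true
effects, true copies) is written to a JSON sidecar, never inferred from
filenames.  Identical config + seed reproduces byte-identical files.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import io as cio
from .clip import BindingSite
from .seqkmer import IUPAC, normalize_sequence
from .sponge import SeedSite

__all__ = ["SyntheticConfig", "SyntheticDataset", "generate_dataset",
           "generate_qpcr_panel", "generate_densitometry_panel"]

BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for the synthetic knockdown experiment.

    Effect sizes and noise are on the log2 fold-change scale; p-values follow
    p = 2*Phi(-|log2FC| / per_gene_se), a smooth stand-in for Wald p-values
    whose ranking is all downstream stages consume.
    """

    n_genes: int = 10_000
    utr_length_mean: float = 500.0   # nt, log-normal across genes
    utr_length_sd: float = 300.0
    utr_length_min: int = 50
    gc_fraction: float = 0.45        # typical of human 3'UTRs
    circ_length: int = 1100
    planted_motif: str = "AGGCCCCCWGC"
    motif_gene_fraction: float = 0.08
    effect_size_delta: float = 0.8   # mean |log2FC| of motif genes; down in A, up in B
    noise_sd: float = 0.3            # per-gene log2FC noise
    per_gene_se: float = 0.25        # SE feeding the p-value model
    clip_capture_prob: float = 0.75  # chance a planted instance receives an RBP peak
    clip_log2fe_min: float = 3.0     # support lower bound of the fold-enrichment law
    clip_log2fe_scale: float = 1.0   # exponential scale above the bound
    n_decoy_peaks: int = 800
    rbp_name: str = "IGF2BP2"
    decoy_rbp_name: str = "DECOY_RBP"
    n_mirna_seeds: int = 20
    circ_copies_per_cell_true: float = 45.0
    amplification_efficiency_true: float = 1.95
    ct_noise_sd: float = 0.15
    qpcr_n_cells: float = 0.8e6
    qpcr_assay_fraction: float = 3.3e-4
    protein_copies_per_cell_true: float = 216_000.0
    protein_mw: float = 66_000.0     # g/mol; synthetic stand-in for a ~66 kDa RBP
    densitometry_n_cells: float = 1.0e6
    seed: int = 1

    def __post_init__(self) -> None:
        for name in ("gc_fraction", "motif_gene_fraction", "clip_capture_prob",
                     "qpcr_assay_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} must lie in [0, 1]")
        if self.n_genes < 100:
            raise ValueError("n_genes must be >= 100")
        if not (1.0 < self.amplification_efficiency_true <= 2.0):
            raise ValueError("amplification_efficiency_true must be in (1, 2]")
        if self.n_decoy_peaks < 0 or self.circ_length < len(self.planted_motif):
            raise ValueError("invalid sizes")
        normalize_sequence(self.planted_motif, allow_iupac=True)


@dataclass
class SyntheticDataset:
    """File layout of one generated dataset plus the parsed truth sidecar."""

    directory: Path
    circ_fasta: Path
    utr_fasta: Path
    de_table_a: Path
    de_table_b: Path
    clip_bed: Path
    utr_features_bed: Path
    mirna_seed_tsv: Path
    qpcr_tsv: Path
    densitometry_tsv: Path
    truth_json: Path
    truth: dict = field(default_factory=dict)


def _random_seq(rng: np.random.Generator, length: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(BASES[rng.choice(4, size=length, p=p)])


def _concrete_motif(rng: np.random.Generator, motif: str) -> str:
    """Sample one concrete instance of an IUPAC motif (degenerate letters per-instance)."""
    return "".join(b if len(IUPAC[b]) == 1 else sorted(IUPAC[b])[rng.integers(len(IUPAC[b]))]
                   for b in motif)


def _de_table(rng, genes, is_motif, delta, noise_sd, se):
    lfc = rng.normal(0.0, noise_sd, size=len(genes))
    lfc[is_motif] += delta
    p = 2.0 * stats.norm.sf(np.abs(lfc) / se)
    from .detables import bh_adjust

    return pd.DataFrame(
        {
            "gene_id": genes,
            "log2_fold_change": np.round(lfc, 6),
            "p_value": p,
            "adjusted_p_value": bh_adjust(p),
        }
    ), lfc


def generate_dataset(config: SyntheticConfig, out_dir: str | Path) -> SyntheticDataset:
    """Write the full synthetic dataset into *out_dir* and return its layout."""
    rng = np.random.default_rng(config.seed)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    motif = normalize_sequence(config.planted_motif, allow_iupac=True)
    W = len(motif)

    # --- circRNA: random background carrying every variant of the motif ---
    circ = list(_random_seq(rng, config.circ_length, config.gc_fraction))
    variants = _expand_iupac(motif)
    slots = np.sort(rng.choice(
        np.arange(0, config.circ_length - W, 2 * W), size=len(variants), replace=False))
    circ_positions = []
    for var, pos in zip(variants, slots):
        circ[pos : pos + W] = list(var)
        circ_positions.append({"start": int(pos), "end": int(pos + W), "instance": var})
    circ_seq = "".join(circ)

    # --- genes, UTRs, planted instances ---
    genes = [f"G{i:05d}" for i in range(config.n_genes)]
    sigma2 = np.log(1.0 + (config.utr_length_sd / config.utr_length_mean) ** 2)
    mu = np.log(config.utr_length_mean) - sigma2 / 2.0
    lengths = np.maximum(
        config.utr_length_min,
        np.round(rng.lognormal(mu, np.sqrt(sigma2), size=config.n_genes)).astype(int),
    )
    n_motif = int(round(config.motif_gene_fraction * config.n_genes))
    motif_idx = np.sort(rng.choice(config.n_genes, size=n_motif, replace=False))
    is_motif = np.zeros(config.n_genes, dtype=bool)
    is_motif[motif_idx] = True

    utrs: dict[str, str] = {}
    planted: dict[str, list[dict]] = {}
    for i, (g, L) in enumerate(zip(genes, lengths)):
        seq = list(_random_seq(rng, int(L), config.gc_fraction))
        if is_motif[i]:
            inst = _concrete_motif(rng, motif)
            pos = int(rng.integers(0, L - W + 1))
            seq[pos : pos + W] = list(inst)
            planted[g] = [{"start": pos, "end": pos + W, "instance": inst}]
        utrs[g] = "".join(seq)

    # --- DE tables: A pushes motif genes down, B pushes them up ---
    de_a, lfc_a = _de_table(rng, genes, is_motif, -config.effect_size_delta,
                            config.noise_sd, config.per_gene_se)
    de_b, lfc_b = _de_table(rng, genes, is_motif, +config.effect_size_delta,
                            config.noise_sd, config.per_gene_se)

    # --- CLIP peaks: true RBP over planted instances, decoys uniform ---
    peaks: list[BindingSite] = []
    for g in genes:
        for inst in planted.get(g, ()):
            if rng.random() >= config.clip_capture_prob:
                continue
            L = len(utrs[g])
            pad_l = int(rng.integers(0, 15))
            pad_r = int(rng.integers(0, 15))
            start = max(0, inst["start"] - pad_l)
            end = min(L, inst["end"] + pad_r)
            peaks.append(BindingSite(
                chrom=g, start=start, end=end, strand="+", rbp=config.rbp_name,
                log2_fold_enrichment=float(config.clip_log2fe_min
                                           + rng.exponential(config.clip_log2fe_scale)),
                neg_log10_p=float(rng.uniform(3, 10)),
            ))
    for _ in range(config.n_decoy_peaks):
        gi = int(rng.integers(config.n_genes))
        g = genes[gi]
        L = len(utrs[g])
        width = int(rng.integers(20, 41))
        start = int(rng.integers(0, max(1, L - width)))
        peaks.append(BindingSite(
            chrom=g, start=start, end=min(L, start + width), strand="+",
            rbp=config.decoy_rbp_name,
            log2_fold_enrichment=float(config.clip_log2fe_min
                                       + rng.exponential(config.clip_log2fe_scale)),
            neg_log10_p=float(rng.uniform(3, 10)),
        ))

    # --- miRNA seed list: no planted association; avoid motif substrings.
    # Half the seeds are drawn from the circRNA's own 7-mers, mirroring that a
    # fraction of circRNA k-mers coincide with real miRNA target sites.
    motif_variant_subs = {v[i : i + 7] for v in variants for i in range(W - 6)}
    circ_ext = circ_seq + circ_seq[:6]
    circ_7mers = sorted({circ_ext[i : i + 7] for i in range(len(circ_seq))} - motif_variant_subs)
    seeds = [SeedSite("miR-148-3p", "CAGTGCA", conserved=True)]
    n_from_circ = config.n_mirna_seeds // 2
    for j in rng.choice(len(circ_7mers), size=min(n_from_circ, len(circ_7mers)), replace=False):
        seeds.append(SeedSite(f"miR-sim-{len(seeds)}", circ_7mers[int(j)]))
    while len(seeds) < config.n_mirna_seeds:
        cand = _random_seq(rng, 7, 0.5)
        if cand in motif_variant_subs or any(s.site_7mer == cand for s in seeds):
            continue
        seeds.append(SeedSite(f"miR-sim-{len(seeds)}", cand))

    # --- calibration panels ---
    qpcr = generate_qpcr_panel(
        true_copies_per_cell=config.circ_copies_per_cell_true,
        efficiency=config.amplification_efficiency_true,
        n_cells=config.qpcr_n_cells,
        assay_fraction=config.qpcr_assay_fraction,
        ct_noise_sd=config.ct_noise_sd,
        seed=int(rng.integers(2**31)),
    )
    densito = generate_densitometry_panel(
        true_copies_per_cell=config.protein_copies_per_cell_true,
        molecular_weight=config.protein_mw,
        n_cells=config.densitometry_n_cells,
        seed=int(rng.integers(2**31)),
    )

    # --- write everything ---
    ds = SyntheticDataset(
        directory=out,
        circ_fasta=out / "circ.fa",
        utr_fasta=out / "utrs.fa",
        de_table_a=out / "de_table_A.tsv",
        de_table_b=out / "de_table_B.tsv",
        clip_bed=out / "clip_peaks.bed",
        utr_features_bed=out / "utr_features.bed",
        mirna_seed_tsv=out / "mirna_seeds.tsv",
        qpcr_tsv=out / "qpcr.tsv",
        densitometry_tsv=out / "densitometry.tsv",
        truth_json=out / "truth.json",
    )
    cio.write_fasta(ds.circ_fasta, {"circ_synthetic": circ_seq})
    cio.write_fasta(ds.utr_fasta, utrs)
    de_a.to_csv(ds.de_table_a, sep="\t", index=False)
    de_b.to_csv(ds.de_table_b, sep="\t", index=False)
    cio.write_peaks_bed(ds.clip_bed, peaks)
    features = pd.DataFrame(
        {"chrom": genes, "start": 0, "end": [len(utrs[g]) for g in genes],
         "gene_id": genes, "score": 0, "strand": "+"}
    )
    cio.write_features_bed(ds.utr_features_bed, features)
    cio.write_seed_tsv(ds.mirna_seed_tsv, seeds)
    qpcr.to_csv(ds.qpcr_tsv, sep="\t", index=False)
    densito.to_csv(ds.densitometry_tsv, sep="\t", index=False)

    motif_genes = [genes[i] for i in motif_idx]
    truth = {
        "config": asdict(config),
        "planted_motif": motif,
        "circ_motif_positions": circ_positions,
        "motif_genes": motif_genes,
        "planted_utr_instances": planted,
        "true_effect_a": {g: float(np.round(lfc_a[i], 6)) for i, g in enumerate(genes) if is_motif[i]},
        "true_effect_b": {g: float(np.round(lfc_b[i], 6)) for i, g in enumerate(genes) if is_motif[i]},
        "fraction_motif_genes_with_negative_true_effect_a": float(
            np.mean([lfc_a[i] < 0 for i in motif_idx])) if n_motif else None,
        "rbp_name": config.rbp_name,
        "decoy_rbp_name": config.decoy_rbp_name,
        "circ_copies_per_cell_true": config.circ_copies_per_cell_true,
        "protein_copies_per_cell_true": config.protein_copies_per_cell_true,
        "amplification_efficiency_true": config.amplification_efficiency_true,
    }
    with open(ds.truth_json, "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)
    ds.truth = truth
    return ds


def _expand_iupac(motif: str) -> list[str]:
    """All concrete sequences of an IUPAC motif (the planted default has two)."""
    outs = [""]
    for letter in motif:
        outs = [o + b for o in outs for b in sorted(IUPAC[letter])]
    return outs


def generate_qpcr_panel(
    true_copies_per_cell: float,
    efficiency: float,
    n_cells: float,
    assay_fraction: float,
    dilution_points=None,
    ct_noise_sd: float = 0.15,
    n_replicates: int = 3,
    intercept: float = 38.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Standard-curve and sample wells with known ground truth.

    Ct follows intercept + slope*log10(copies) with slope = -1/log10(E), so a
    perfect doubling gives Ct = intercept - log2(copies).  The default
    dilution series starts at 2.5e7 molecules per reaction and falls
    tenfold per step.  Gaussian Ct noise; ct_noise_sd = 0 is exact.
    """
    if not (1.0 < efficiency <= 2.0):
        raise ValueError("efficiency must be in (1, 2]")
    if dilution_points is None:
        dilution_points = [2.5e7 / 10**i for i in range(6)]
    dilution_points = [float(d) for d in dilution_points]
    if any(d <= 0 for d in dilution_points):
        raise ValueError("dilution points must be strictly positive")
    rng = np.random.default_rng(seed)
    slope = -1.0 / np.log10(efficiency)
    rows = []
    for d in dilution_points:
        for rep in range(1, n_replicates + 1):
            ct = intercept + slope * np.log10(d) + rng.normal(0, ct_noise_sd)
            rows.append(("standard_curve", "standard", d, round(float(ct), 6), rep))
    copies_in_reaction = true_copies_per_cell * n_cells * assay_fraction
    for rep in range(1, n_replicates + 1):
        ct = intercept + slope * np.log10(copies_in_reaction) + rng.normal(0, ct_noise_sd)
        rows.append(("circ_sample", "sample", "", round(float(ct), 6), rep))
    return pd.DataFrame(rows, columns=["sample_id", "role", "copies", "ct", "replicate"])


def generate_densitometry_panel(
    true_copies_per_cell: float,
    molecular_weight: float,
    n_cells: float,
    standard_masses_ng=(5.0, 10.0, 25.0, 50.0, 100.0),
    slope_au_per_ng: float = 1000.0,
    intercept_au: float = 100.0,
    intensity_noise_sd: float = 200.0,
    n_replicates: int = 3,
    seed: int = 0,
) -> pd.DataFrame:
    """Calibrated western-blot band intensities with known copies per cell."""
    from .stoich import AVOGADRO

    rng = np.random.default_rng(seed)
    rows = []
    for m in standard_masses_ng:
        for rep in range(1, n_replicates + 1):
            inten = intercept_au + slope_au_per_ng * m + rng.normal(0, intensity_noise_sd)
            rows.append(("bsa_ladder", "standard", float(m), round(float(inten), 3), rep))
    sample_ng = true_copies_per_cell * n_cells / AVOGADRO * molecular_weight * 1e9
    for rep in range(1, n_replicates + 1):
        inten = intercept_au + slope_au_per_ng * sample_ng + rng.normal(0, intensity_noise_sd)
        rows.append(("rbp_lysate", "sample", "", round(float(inten), 3), rep))
    return pd.DataFrame(rows, columns=["sample_id", "role", "mass_ng", "intensity", "replicate"])
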