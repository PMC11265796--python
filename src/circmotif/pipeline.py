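"""End-to-end orchestration: classify -> score -> assemble -> scan -> enrich
-> concordance -> sponge control -> stoichiometry, with a machine-readable
report.

The report is a plain dict (JSON-serialisable) regenerable bit-identically
from the same inputs, parameters and seed.  Every statistical step logs the
gene universe it used.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .clip import (PeakFilterParams, annotate_gene_binding, contingency_enrichment,
                   cross_concordance, filter_peaks, peak_motif_overlap, set_overlap_fisher)
from .detables import DOWN, NOT_DE, UP, ClassifyParams, class_counts, classify_genes, read_de_table
from .io import (read_densitometry_tsv, read_fasta, read_features_bed, read_peaks_bed,
                 read_qpcr_tsv, read_seed_tsv)
from .scoring import score_all_kmers, scores_to_frame
from .seqkmer import (BipartitePattern, CircularSequence, ScanParams, assemble_consensus,
                      scan_bipartite, scan_motif)
from .sponge import compare_score_groups, sponge_report
from .stoich import (copies_per_cell, fit_protein_calibration, fit_standard_curve,
                     molar_ratio_report, protein_copies_per_cell)

log = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "write_report"]


@dataclass
class RunConfig:
    """Inputs and parameters for one pipeline run."""

    circ_fasta: str
    utr_fasta: str
    de_table_a: str
    de_table_b: str | None = None
    clip_bed: str | None = None
    utr_features_bed: str | None = None
    mirna_seed_tsv: str | None = None
    qpcr_tsv: str | None = None
    densitometry_tsv: str | None = None
    k: int = 7
    top_n_kmers: int = 10
    scan_max_mismatches: int = 2
    fdr_threshold: float = 0.1
    min_fold_enrichment: float = 8.0
    min_peak_length: int = 4
    min_feature_overlap: int = 4
    min_genes: int = 10
    qpcr_n_cells: float = 0.8e6
    qpcr_assay_fraction: float = 3.3e-4
    protein_mw: float | None = None
    densitometry_n_cells: float | None = None
    ratio_threshold: float = 100.0
    seed: int = 1

    @classmethod
    def from_dataset(cls, ds, **overrides) -> "RunConfig":
        """Point a config at a SyntheticDataset's files."""
        cfg = ds.truth.get("config", {})
        kw = dict(
            circ_fasta=str(ds.circ_fasta),
            utr_fasta=str(ds.utr_fasta),
            de_table_a=str(ds.de_table_a),
            de_table_b=str(ds.de_table_b),
            clip_bed=str(ds.clip_bed),
            utr_features_bed=str(ds.utr_features_bed),
            mirna_seed_tsv=str(ds.mirna_seed_tsv),
            qpcr_tsv=str(ds.qpcr_tsv),
            densitometry_tsv=str(ds.densitometry_tsv),
            qpcr_n_cells=cfg.get("qpcr_n_cells", 0.8e6),
            qpcr_assay_fraction=cfg.get("qpcr_assay_fraction", 3.3e-4),
            protein_mw=cfg.get("protein_mw"),
            densitometry_n_cells=cfg.get("densitometry_n_cells"),
            seed=cfg.get("seed", 1),
        )
        kw.update(overrides)
        return cls(**kw)

    def validate(self) -> None:
        required = {"circ_fasta": self.circ_fasta, "utr_fasta": self.utr_fasta,
                    "de_table_a": self.de_table_a}
        optional = {"de_table_b": self.de_table_b, "clip_bed": self.clip_bed,
                    "utr_features_bed": self.utr_features_bed,
                    "mirna_seed_tsv": self.mirna_seed_tsv, "qpcr_tsv": self.qpcr_tsv,
                    "densitometry_tsv": self.densitometry_tsv}
        for name, path in required.items():
            if path is None or not Path(path).exists():
                raise FileNotFoundError(f"required input {name} missing: {path}")
        for name, path in optional.items():
            if path is not None and not Path(path).exists():
                raise FileNotFoundError(f"configured input {name} does not exist: {path}")
        if min(self.k, self.top_n_kmers, self.min_peak_length, self.min_feature_overlap) < 1:
            raise ValueError("thresholds must be positive")


def _enrichment_to_dict(res) -> dict:
    return {
        "contingency": np.asarray(res.contingency).astype(int).tolist(),
        "statistic": None if np.isnan(res.statistic) else round(float(res.statistic), 6),
        "p_value": float(res.p_value),
        "test": res.test,
        "correction": res.correction,
        "group_percent": {k: round(v, 4) for k, v in res.group_percent.items()},
        "odds_ratio": None if res.odds_ratio is None else round(float(res.odds_ratio), 6),
    }


def run_pipeline(config: RunConfig, out_dir: str | Path | None = None) -> dict:
    """Run every stage and return the report dict (optionally persisted)."""
    config.validate()  # all schemas/paths checked before any computation
    if out_dir is not None:
        Path(out_dir).mkdir(parents=True, exist_ok=True)
    report: dict = {"version": __version__, "config": asdict(config), "seed": config.seed}

    circ_seqs = read_fasta(config.circ_fasta)
    circ_id, circ_seq = next(iter(circ_seqs.items()))
    circ = CircularSequence(circ_id, circ_seq, circular=True)
    utrs = read_fasta(config.utr_fasta)

    cls_params = ClassifyParams(fdr_threshold=config.fdr_threshold)
    de_a = classify_genes(read_de_table(config.de_table_a), cls_params)
    report["experiment_a"] = {"n_genes": len(de_a), "class_counts": class_counts(de_a)}
    log.info("experiment A universe: %d genes", len(de_a))

    # --- k-mer scoring against the ranked list of experiment A ---
    scores = score_all_kmers(circ, config.k, utrs, de_a, min_genes=config.min_genes)
    scored = [s for s in scores if not s.is_na]
    report["kmer_scoring"] = {
        "n_unique_kmers": len(scores),
        "n_scored": len(scored),
        "universe": len([g for g in de_a["gene_id"] if g in utrs]),
        "most_negative": [
            {"kmer": s.kmer, "score": round(s.score, 4), "n_genes": s.n_genes_with_motif}
            for s in scored[: config.top_n_kmers]
        ],
    }

    # --- consensus assembly from the top-N most negative k-mers ---
    top = [s.kmer for s in scored[: config.top_n_kmers]]
    consensus = assemble_consensus(top)
    report["consensus"] = {
        "consensus": consensus.consensus,
        "members": [{"kmer": km, "offset": off} for km, off in consensus.members],
        "unplaced": consensus.unplaced,
    }

    # --- mismatch-tolerant UTR scan and class enrichment ---
    scan_params = ScanParams(max_mismatches=config.scan_max_mismatches)
    matches = []
    for g, seq in utrs.items():
        matches.extend(scan_motif(seq, consensus, scan_params, sequence_id=g))
    has_motif = {g: False for g in utrs}
    for m in matches:
        has_motif[m.sequence_id] = True
    groups = {c: set(de_a.loc[de_a["de_class"] == c, "gene_id"]) for c in (DOWN, UP, NOT_DE)}
    enr_down_up = contingency_enrichment(groups[DOWN], groups[UP], has_motif, labels=(DOWN, UP))
    enr_down_not = contingency_enrichment(groups[DOWN], groups[NOT_DE], has_motif,
                                          labels=(DOWN, NOT_DE))
    report["motif_enrichment"] = {
        "n_matches": len(matches),
        "n_genes_with_motif": sum(has_motif.values()),
        "down_vs_up": _enrichment_to_dict(enr_down_up),
        "down_vs_notDE": _enrichment_to_dict(enr_down_not),
    }

    # --- bipartite recognition-element scan and overlap with the consensus genes ---
    bip = BipartitePattern()
    bip_genes = {g for g, seq in utrs.items() if scan_bipartite(seq, bip, sequence_id=g)}
    motif_genes = {g for g, v in has_motif.items() if v}
    universe = set(utrs)
    report["bipartite_element"] = {
        "pattern": f"{bip.five_prime}-(N{bip.spacer_min}-{bip.spacer_max})-{bip.three_prime}",
        "n_genes_with_element": len(bip_genes),
        "overlap_with_consensus_genes": _enrichment_to_dict(
            set_overlap_fisher(motif_genes, bip_genes, universe)),
        "circ_matches": len(scan_bipartite(circ.sequence, bip, sequence_id=circ.id)),
    }

    # --- CLIP peaks: filter, annotate, per-RBP enrichment, motif overlap ---
    if config.clip_bed and config.utr_features_bed:
        peaks = read_peaks_bed(config.clip_bed)
        params = PeakFilterParams(
            min_fold_enrichment=config.min_fold_enrichment,
            min_peak_length=config.min_peak_length,
            min_feature_overlap=config.min_feature_overlap,
        )
        kept = filter_peaks(peaks, params)
        features = read_features_bed(config.utr_features_bed)
        bound = annotate_gene_binding(kept, features, params)
        rbps = sorted({p.rbp for p in kept})
        frac, _co = peak_motif_overlap(kept, matches)
        clip_rep = {"n_peaks_in": len(peaks), "n_peaks_kept": len(kept), "per_rbp": {}}
        for rbp in rbps:
            has_rbp = {g: (rbp in bound.get(g, ())) for g in utrs}
            res = contingency_enrichment(groups[DOWN], groups[UP], has_rbp, labels=(DOWN, UP))
            clip_rep["per_rbp"][rbp] = {
                "n_bound_genes": sum(has_rbp.values()),
                "down_vs_up": _enrichment_to_dict(res),
                "peak_motif_overlap_fraction": round(frac.get(rbp, 0.0), 6),
            }
        report["clip"] = clip_rep

    # --- cross-knockdown concordance ---
    if config.de_table_b:
        de_b = classify_genes(read_de_table(config.de_table_b), cls_params)
        conc = cross_concordance(de_a, de_b)
        report["concordance"] = {
            "n_shared": conc.n_shared,
            "counts": {r: {c: int(conc.counts.at[r, c]) for c in conc.counts.columns}
                       for r in conc.counts.index},
            "fractions": {r: {c: round(float(conc.fractions.at[r, c]), 6)
                              for c in conc.fractions.columns}
                          for r in conc.fractions.index},
        }

    # --- miRNA sponge control ---
    if config.mirna_seed_tsv:
        seeds = read_seed_tsv(config.mirna_seed_tsv)
        sp = sponge_report(de_a, utrs, seeds, fdr_threshold=config.fdr_threshold)
        seed_7mers = {s.site_7mer for s in seeds}
        rep = {"verdict": sp["verdict"], "n_mirnas": len(seeds)}
        mirna_scored = [s for s in scored if s.kmer in seed_7mers]
        if mirna_scored and len(mirna_scored) < len(scored):
            cmpres = compare_score_groups(scored, seed_7mers)
            rep["mirna_vs_other_kmers"] = {
                "p_value": float(cmpres.p_value),
                "effect_size": round(cmpres.effect_size, 6),
                "median_mirna": round(cmpres.median_a, 4),
                "median_other": round(cmpres.median_b, 4),
            }
        report["sponge"] = rep
        if out_dir is not None:
            sp["per_mirna"].to_csv(Path(out_dir) / "sponge_per_mirna.tsv", sep="\t", index=False)

    # --- stoichiometry ---
    if config.qpcr_tsv:
        wells = read_qpcr_tsv(config.qpcr_tsv)
        std = wells[wells["role"] == "standard"]
        curve = fit_standard_curve(std["copies"].astype(float), std["ct"].astype(float))
        sample_ct = wells.loc[wells["role"] == "sample", "ct"].astype(float).to_numpy()
        rna = copies_per_cell(sample_ct, curve, n_cells=config.qpcr_n_cells,
                              assay_fraction=config.qpcr_assay_fraction)
        report["stoichiometry"] = {
            "standard_curve": {"slope": round(curve.slope, 4),
                               "intercept": round(curve.intercept, 4),
                               "efficiency": round(curve.efficiency, 4),
                               "r_squared": round(curve.r_squared, 6)},
            "rna_copies_per_cell": round(float(rna.molecules_per_cell), 3),
            "rna_ci": [round(float(rna.ci_low), 3), round(float(rna.ci_high), 3)],
        }
        if config.densitometry_tsv and config.protein_mw and config.densitometry_n_cells:
            bands = read_densitometry_tsv(config.densitometry_tsv)
            bstd = bands[bands["role"] == "standard"]
            cal = fit_protein_calibration(bstd["mass_ng"].astype(float),
                                          bstd["intensity"].astype(float),
                                          molecular_weight=config.protein_mw)
            sample_int = bands.loc[bands["role"] == "sample", "intensity"].astype(float).to_numpy()
            prot = protein_copies_per_cell(sample_int, cal, n_cells=config.densitometry_n_cells)
            ratio = molar_ratio_report(rna, prot, implausibility_threshold=config.ratio_threshold)
            report["stoichiometry"]["protein_copies_per_cell"] = round(float(prot.molecules_per_cell), 1)
            report["stoichiometry"]["protein_ci"] = [round(float(prot.ci_low), 1),
                                                     round(float(prot.ci_high), 1)]
            report["stoichiometry"]["molar_ratio"] = {
                k: (v if isinstance(v, bool) else round(v, 6) if np.isfinite(v) else "inf")
                for k, v in ratio.items()
            }

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        scores_to_frame(scores).to_csv(out / "kmer_scores.tsv", sep="\t", index=False)
        write_report(report, out / "report.json")
    return report


def write_report(report: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
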