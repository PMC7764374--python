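"""Truth-annotated synthetic inputs for the whole pipeline.

The generator emulates the design of a nodulation RNA-seq study: three
tissues (nodule N, stripped root SR, uninoculated root UR) with three
biological replicates each; a small organellar genome carrying a
minus-strand single-exon maturase-like gene, a plus-strand four-exon
NADH-dehydrogenase-like gene with labelled group-II introns, and a panel
of single-exon genes for the expression screen.  Planted truth covers
per-site editing degrees per tissue (binomially sampled at
negative-binomial coverage), homozygous germline SNPs for filter testing,
negative-binomial expression counts with planted fold changes, and a
comparative-Ct qPCR model with per-intron spliced fractions.

Everything is deterministic given ``SimulationConfig.seed`` (NumPy PCG64;
each stage derives its own child stream so stages can be re-run
independently).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .gene_models import GeneModel, Intron, sense_transcript_sequence

__all__ = [
    "SimulationConfig",
    "GenomeTruth",
    "SimulatedStudy",
    "MATR_PLANTED_CODONS",
    "matr_like_transcript",
    "matr_like_model",
    "simulate_genome",
    "simulate_pileups",
    "simulate_expression_and_qpcr",
    "simulate_study",
]

BASES = np.array(list("ACGT"))

#: codon index -> reference codon planted in the maturase-like transcript,
#: matching the codon contexts of the published matR editing sites.
MATR_PLANTED_CODONS: Dict[int, str] = {
    11: "TCC", 49: "TTC", 65: "CCA", 79: "TCC", 109: "CCA", 135: "TCG",
    304: "GCC", 354: "CCC", 514: "CCC", 559: "TCT", 566: "CCT",
    573: "CGC", 577: "TAC", 585: "CAC", 608: "CCC", 614: "TCA", 617: "GTC",
}

#: first transcript base of the anchored maturase model on the published
#: genome, chosen so that genome_pos + tpos = 340,037 at every site.
MATR_FIRST_BASE_GENOME = 340_036
MATR_N_CODONS = 620


def matr_like_transcript(n_codons: int = MATR_N_CODONS, filler: str = "GCA") -> str:
    """Sense-strand transcript with the published matR codon contexts
    planted at their codon indices and a fixed filler codon elsewhere.

    The filler carries a cytidine so the gene offers a realistic density
    of editable positions to the simulator; the planted codons are the
    only positions whose annotation is pinned."""
    codons = [MATR_PLANTED_CODONS.get(i, filler) for i in range(1, n_codons + 1)]
    return "".join(codons)


def matr_like_model(chrom: str = "mito", first_base_genome: int = MATR_FIRST_BASE_GENOME) -> GeneModel:
    """Single-exon minus-strand maturase gene anchored so that
    ``genome_pos + tpos == first_base_genome + 1`` for every exonic site."""
    length = 3 * MATR_N_CODONS
    return GeneModel(
        gene_id="matR_like",
        chrom=chrom,
        strand="-",
        exons=((first_base_genome - length + 1, first_base_genome),),
        cds_start_tpos=1,
    )


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the generator.

    Defaults mirror the emulated design: 3 tissues x 3 replicates, mean
    informative depth 200 with negative-binomial overdispersion, true
    editing degrees drawn from {0, 0.2, 0.5, 0.8, 0.95}, homozygous
    germline SNPs, NB expression counts, and Ct noise of 0.2 cycles.
    """

    seed: int = 0
    tissues: Tuple[str, ...] = ("N", "SR", "UR")
    n_replicates: int = 3
    chrom: str = "mito_synth"
    spacer_length: int = 100
    n_expression_genes: int = 10
    expression_gene_length: int = 900
    nad4_exon_length: int = 300
    nad4_intron_length: int = 400
    n_editing_sites: int = 50
    degree_choices: Tuple[float, ...] = (0.0, 0.2, 0.5, 0.8, 0.95)
    differential_fraction: float = 0.3
    n_germline_snps: int = 8
    mean_depth: float = 200.0
    depth_dispersion: float = 10.0
    error_rate: float = 0.005
    library_read_pairs: int = 2_000_000
    expression_base_mean: float = 2000.0
    expression_dispersion: float = 100.0
    planted_fold_changes: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {"gene01": {"N": 2.0}}
    )
    base_ct: float = 24.0
    reference_ct: float = 20.0
    ct_noise_sd: float = 0.2
    spliced_fractions: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {
            "nad4 intron 1": {"N": 0.8, "UR": 0.6, "SR": 0.4},
            "nad4 intron 2": {"N": 0.7, "SR": 0.7, "UR": 0.5},
            "nad4 intron 3": {"N": 0.5, "SR": 0.5, "UR": 0.5},
        }
    )

    def sample_table(self) -> pd.DataFrame:
        rows = [
            {
                "sample_id": f"{t}{r}",
                "tissue": t,
                "replicate": r,
                "library_read_pairs": self.library_read_pairs,
            }
            for t in self.tissues
            for r in range(1, self.n_replicates + 1)
        ]
        return pd.DataFrame(rows)


@dataclass
class GenomeTruth:
    """Genome, gene models, transcripts and the planted truth tables."""

    genome: str
    chrom: str
    genes: List[GeneModel]
    transcripts: Dict[str, str]
    truth_sites: pd.DataFrame
    germline: pd.DataFrame  # chrom, pos, ref, alt


def _rng(config: SimulationConfig, stage: int) -> np.random.Generator:
    return np.random.default_rng([int(config.seed) % (2**31), stage])


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(BASES, size=n))


def simulate_genome(config: SimulationConfig) -> GenomeTruth:
    """Assemble the synthetic genome, plant editing sites and germline SNPs.

    Deterministic given the seed.  Every planted editing site falls on a
    sense-strand cytidine of its gene; germline SNPs are placed on distinct
    sense-C positions so that, unfiltered, they mimic C-to-U candidates.
    """
    rng = _rng(config, 0)
    pieces: List[str] = []
    cursor = 1  # next genome coordinate (1-based)
    genes: List[GeneModel] = []
    transcripts: Dict[str, str] = {}

    def emit(seq: str) -> Tuple[int, int]:
        nonlocal cursor
        pieces.append(seq)
        start = cursor
        cursor += len(seq)
        return start, cursor - 1

    emit(_random_seq(rng, config.spacer_length))

    # maturase-like gene, minus strand, single exon
    matr_t = matr_like_transcript()
    from Bio.Seq import reverse_complement

    s, e = emit(reverse_complement(matr_t))
    matr = GeneModel("matR_like", config.chrom, "-", ((s, e),), cds_start_tpos=1)
    genes.append(matr)
    transcripts["matR_like"] = matr_t
    emit(_random_seq(rng, config.spacer_length))

    # nad4-like gene, plus strand, 4 exons / 3 labelled introns
    exons: List[Tuple[int, int]] = []
    introns: List[Intron] = []
    for i in range(4):
        exons.append(emit(_random_seq(rng, config.nad4_exon_length)))
        if i < 3:
            s_i, e_i = emit(_random_seq(rng, config.nad4_intron_length))
            introns.append(Intron(s_i, e_i, f"nad4 intron {i + 1}"))
    nad4 = GeneModel(
        "nad4_like", config.chrom, "+", tuple(exons), tuple(introns), cds_start_tpos=1
    )
    genes.append(nad4)
    emit(_random_seq(rng, config.spacer_length))

    for i in range(1, config.n_expression_genes + 1):
        s, e = emit(_random_seq(rng, config.expression_gene_length))
        genes.append(
            GeneModel(f"gene{i:02d}", config.chrom, "+", ((s, e),), cds_start_tpos=1)
        )
        emit(_random_seq(rng, config.spacer_length))

    genome = "".join(pieces)
    for g in genes:
        transcripts[g.gene_id] = sense_transcript_sequence(genome, g)

    # candidate sense-C genome positions per gene (exonic and intronic)
    candidates: List[Tuple[int, str, str, str, object]] = []  # pos, gene, strand, region, where
    for g in genes:
        tseq = transcripts[g.gene_id]
        for tpos, base in enumerate(tseq, start=1):
            if base == "C":
                candidates.append(
                    (g.transcript_to_genome(tpos), g.gene_id, g.strand, "exonic", tpos)
                )
        for intron in g.introns:
            for pos in range(intron.start, intron.end + 1):
                # sense C in a plus-strand intron is a plus-strand C
                ref = genome[pos - 1]
                sense = ref if g.strand == "+" else {"A": "T", "C": "G", "G": "C", "T": "A"}[ref]
                if sense == "C":
                    candidates.append((pos, g.gene_id, g.strand, "intronic", intron.label))

    n_needed = config.n_editing_sites + config.n_germline_snps
    if n_needed > len(candidates):
        raise ValueError(
            f"requested {n_needed} sites but only {len(candidates)} sense-C positions available"
        )
    order = rng.permutation(len(candidates))
    chosen = [candidates[i] for i in order[:n_needed]]
    edit_sites = chosen[: config.n_editing_sites]
    germ_sites = chosen[config.n_editing_sites :]

    site_rows = []
    for pos, gene_id, strand, region, where in sorted(edit_sites):
        base_degree = float(rng.choice(config.degree_choices))
        degrees = {t: base_degree for t in config.tissues}
        if rng.random() < config.differential_fraction:
            degrees = {t: float(rng.choice(config.degree_choices)) for t in config.tissues}
        row = {
            "chrom": config.chrom,
            "pos": pos,
            "gene_id": gene_id,
            "strand": strand,
            "region": region,
            "tpos": where if region == "exonic" else pd.NA,
            "intron_label": where if region == "intronic" else pd.NA,
        }
        for t in config.tissues:
            row[f"degree_{t}"] = degrees[t]
        row["expected_called"] = max(degrees.values()) >= 0.15
        site_rows.append(row)
    truth_sites = pd.DataFrame(site_rows)

    germ_rows = []
    for pos, gene_id, strand, region, _ in sorted(germ_sites):
        ref = genome[pos - 1]
        alt = "T" if strand == "+" else "A"
        germ_rows.append(
            {"chrom": config.chrom, "pos": pos, "ref": ref, "alt": alt,
             "gene_id": gene_id, "strand": strand}
        )
    germline = pd.DataFrame(germ_rows)

    return GenomeTruth(genome, config.chrom, genes, transcripts, truth_sites, germline)


def _nb_depth(rng, mean: float, dispersion: float, size: int) -> np.ndarray:
    p = dispersion / (dispersion + mean)
    return rng.negative_binomial(dispersion, p, size=size)


def _base_counts(rng, ref_plus: str, edited_plus: str, depth: int, degree: float, error_rate: float) -> Dict[str, int]:
    """Plus-strand base tallies for one replicate at one site."""
    counts = {b: 0 for b in "ACGT"}
    edited = rng.binomial(depth, degree) if depth > 0 else 0
    counts[edited_plus] += edited
    counts[ref_plus] += depth - edited
    if error_rate > 0 and depth > 0:
        for b in "ACGT":
            n = counts[b]
            if n == 0:
                continue
            n_err = rng.binomial(n, error_rate)
            if n_err:
                counts[b] -= n_err
                others = [o for o in "ACGT" if o != b]
                for o, k in zip(others, rng.multinomial(n_err, [1 / 3] * 3)):
                    counts[o] += k
    return counts


def simulate_pileups(config: SimulationConfig, truth: GenomeTruth) -> pd.DataFrame:
    """Per-sample base counts at every planted editing site and germline SNP.

    Edited reads are Binomial(depth, true degree) with NB-distributed
    depth; sequencing errors move reads to a uniform random other base;
    germline SNPs are homozygous (alternate fraction ~1) in all samples.
    """
    rng = _rng(config, 1)
    samples = config.sample_table()
    rows = []
    for _, site in truth.truth_sites.iterrows():
        ref_plus = truth.genome[site["pos"] - 1]
        edited_plus = "T" if site["strand"] == "+" else "A"
        for _, smp in samples.iterrows():
            depth = int(_nb_depth(rng, config.mean_depth, config.depth_dispersion, 1)[0])
            counts = _base_counts(
                rng, ref_plus, edited_plus, depth, float(site[f"degree_{smp['tissue']}"]), config.error_rate
            )
            rows.append(_pileup_row(smp, config.chrom, site["pos"], ref_plus, counts))
    for _, snp in truth.germline.iterrows():
        for _, smp in samples.iterrows():
            depth = int(_nb_depth(rng, config.mean_depth, config.depth_dispersion, 1)[0])
            counts = _base_counts(rng, snp["ref"], snp["alt"], depth, 1.0, config.error_rate)
            rows.append(_pileup_row(smp, config.chrom, snp["pos"], snp["ref"], counts))
    return (
        pd.DataFrame(rows)
        .sort_values(["chrom", "pos", "tissue", "replicate"], kind="mergesort")
        .reset_index(drop=True)
    )


def _pileup_row(smp, chrom, pos, ref, counts):
    return {
        "sample_id": smp["sample_id"],
        "tissue": smp["tissue"],
        "replicate": int(smp["replicate"]),
        "chrom": chrom,
        "pos": int(pos),
        "ref": ref,
        "na": counts["A"],
        "nc": counts["C"],
        "ng": counts["G"],
        "nt": counts["T"],
    }


def simulate_expression_and_qpcr(
    config: SimulationConfig, truth: GenomeTruth
) -> Tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """NB gene counts with planted fold changes, and a comparative-Ct
    qPCR table with planted per-intron spliced fractions.

    Returns ``(counts, ct_table, truth_expression, truth_splicing)``.
    Ct values follow ``Ct = base_ct - log2(quantity) + Normal(0, sigma)``.
    """
    rng = _rng(config, 2)
    samples = config.sample_table()

    count_rows, expr_truth = [], []
    for g in truth.genes:
        folds = config.planted_fold_changes.get(g.gene_id, {})
        for t in config.tissues:
            mu = config.expression_base_mean * float(folds.get(t, 1.0))
            expr_truth.append({"gene_id": g.gene_id, "tissue": t, "true_mean": mu})
        for _, smp in samples.iterrows():
            mu = config.expression_base_mean * float(folds.get(smp["tissue"], 1.0))
            k = config.expression_dispersion
            n = int(rng.negative_binomial(k, k / (k + mu)))
            count_rows.append(
                {"gene_id": g.gene_id, "sample_id": smp["sample_id"], "read_pairs": n}
            )
    counts = pd.DataFrame(count_rows)

    ct_rows, spl_truth = [], []
    for _, smp in samples.iterrows():
        ct_rows.append(
            {
                "tissue": smp["tissue"],
                "replicate": int(smp["replicate"]),
                "intron_label": "",
                "amplicon": "reference",
                "ct": config.reference_ct + rng.normal(0.0, config.ct_noise_sd),
            }
        )
    for intron, fractions in config.spliced_fractions.items():
        for t in config.tissues:
            f = float(fractions[t])
            spl_truth.append(
                {
                    "intron_label": intron,
                    "tissue": t,
                    "spliced_fraction": f,
                    "true_efficiency": f / (1.0 - f),
                }
            )
        for _, smp in samples.iterrows():
            f = float(fractions[smp["tissue"]])
            for amplicon, q in (("spliced", f), ("unspliced", 1.0 - f)):
                ct_rows.append(
                    {
                        "tissue": smp["tissue"],
                        "replicate": int(smp["replicate"]),
                        "intron_label": intron,
                        "amplicon": amplicon,
                        "ct": config.base_ct - math.log2(q) + rng.normal(0.0, config.ct_noise_sd),
                    }
                )
    return counts, pd.DataFrame(ct_rows), pd.DataFrame(expr_truth), pd.DataFrame(spl_truth)


@dataclass
class SimulatedStudy:
    """All synthetic inputs plus truth, with file emission."""

    config: SimulationConfig
    genome_truth: GenomeTruth
    design: pd.DataFrame
    pileups: pd.DataFrame
    counts: pd.DataFrame
    ct_table: pd.DataFrame
    truth_expression: pd.DataFrame
    truth_splicing: pd.DataFrame

    @property
    def genes(self) -> List[GeneModel]:
        return self.genome_truth.genes

    @property
    def truth_sites(self) -> pd.DataFrame:
        return self.genome_truth.truth_sites

    @property
    def germline(self) -> pd.DataFrame:
        return self.genome_truth.germline

    def write(self, outdir) -> Dict[str, Path]:
        """Emit FASTA, GFF3, VCF, pileup/count/Ct tables and truth TSVs."""
        from . import io as mio

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "genome": outdir / "genome.fasta",
            "gff3": outdir / "genes.gff3",
            "vcf": outdir / "germline.vcf",
            "pileups": outdir / "pileups.tsv",
            "design": outdir / "design.csv",
            "counts": outdir / "counts.tsv",
            "ct": outdir / "qpcr_ct.csv",
            "truth_sites": outdir / "truth_sites.tsv",
            "truth_expression": outdir / "truth_expression.tsv",
            "truth_splicing": outdir / "truth_splicing.tsv",
        }
        mio.write_fasta({self.genome_truth.chrom: self.genome_truth.genome}, paths["genome"])
        mio.write_gff3(self.genes, paths["gff3"])
        mio.write_vcf(self.germline, paths["vcf"])
        self.pileups.to_csv(paths["pileups"], sep="\t", index=False)
        self.design.to_csv(paths["design"], index=False)
        self.counts.to_csv(paths["counts"], sep="\t", index=False)
        self.ct_table.to_csv(paths["ct"], index=False)
        self.truth_sites.to_csv(paths["truth_sites"], sep="\t", index=False)
        self.truth_expression.to_csv(paths["truth_expression"], sep="\t", index=False)
        self.truth_splicing.to_csv(paths["truth_splicing"], sep="\t", index=False)
        return paths


def simulate_study(config: Optional[SimulationConfig] = None, seed: Optional[int] = None) -> SimulatedStudy:
    """Run every generator stage under one config (or just a seed)."""
    if config is None:
        config = SimulationConfig(seed=0 if seed is None else int(seed))
    elif seed is not None:
        config = replace(config, seed=int(seed))
    truth = simulate_genome(config)
    pileups = simulate_pileups(config, truth)
    counts, ct, expr_truth, spl_truth = simulate_expression_and_qpcr(config, truth)
    return SimulatedStudy(
        config=config,
        genome_truth=truth,
        design=config.sample_table(),
        pileups=pileups,
        counts=counts,
        ct_table=ct,
        truth_expression=expr_truth,
        truth_splicing=spl_truth,
    )
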