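"""Calling C-to-U editing sites from per-site base counts.

The pipeline starts from pileup-style tallies (one row per sample and
genomic position with A/C/G/T counts), already aligned and deduplicated
upstream.  A site is an editing *candidate* when its sense-strand
reference base is a cytidine: on a plus-strand gene the edited reads carry
T, on a minus-strand gene the plus-strand pileup shows G (unedited) and A
(edited).  The editing degree of a replicate is the edited fraction of the
two informative bases, in percent; bases other than the informative pair
are sequencing noise and are ignored.

Positions matching a germline variant with the same alternate allele are
DNA-level polymorphisms, not editing, and are removed.  A site is retained
("called") when at least one tissue has *every* biological replicate at or
above the degree threshold (default 15%).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .gene_models import GeneModel

__all__ = [
    "NotACandidateError",
    "editing_degree",
    "compute_observations",
    "read_germline_vcf",
    "filter_germline",
    "call_sites",
    "EditingModel",
    "EditingResults",
]

#: plus-strand (unedited, edited) base pair for a sense-strand C, by strand
INFORMATIVE = {"+": ("C", "T"), "-": ("G", "A")}

DEFAULT_MIN_DEPTH = 10
DEFAULT_MIN_DEGREE = 15.0


class NotACandidateError(ValueError):
    """The sense-strand reference base is not a cytidine."""


def editing_degree(
    counts: Mapping[str, int],
    ref_base: str,
    strand: str,
    min_depth: int = DEFAULT_MIN_DEPTH,
) -> Optional[float]:
    """Editing degree (percent) of one replicate at one site.

    ``counts`` are plus-strand base tallies.  Returns ``None`` when the
    informative depth (unedited + edited reads) is below ``min_depth`` —
    a fraction of almost nothing is noise, not a measurement.
    """
    unedited_base, edited_base = _informative_pair(ref_base, strand)
    unedited = int(counts.get(unedited_base, 0))
    edited = int(counts.get(edited_base, 0))
    informative = unedited + edited
    if informative < min_depth:
        return None
    return 100.0 * edited / informative


def _informative_pair(ref_base: str, strand: str) -> Tuple[str, str]:
    if strand not in INFORMATIVE:
        raise ValueError(f"strand must be '+' or '-', got {strand!r}")
    expected_ref = INFORMATIVE[strand][0]
    if ref_base.upper() != expected_ref:
        raise NotACandidateError(
            f"sense-strand reference is not C (plus-strand ref {ref_base!r} on strand {strand})"
        )
    return INFORMATIVE[strand]


def compute_observations(
    pileups: pd.DataFrame,
    genes: Sequence[GeneModel],
    min_depth: int = DEFAULT_MIN_DEPTH,
) -> pd.DataFrame:
    """Per-replicate editing degrees for every candidate position.

    ``pileups`` needs columns ``sample_id, tissue, replicate, chrom, pos,
    ref, na, nc, ng, nt``.  Each position is assigned to the gene whose
    genomic span contains it; positions outside any gene, or whose
    sense-strand base is not C, are dropped (tallied in the
    ``diagnostics`` attribute of :class:`EditingResults`).

    Returns a tidy frame with one row per (site, replicate):
    ``chrom, pos, gene_id, strand, sample_id, tissue, replicate, degree,
    informative_depth`` where ``degree`` is NaN below ``min_depth``.
    """
    required = {"sample_id", "tissue", "replicate", "chrom", "pos", "ref", "na", "nc", "ng", "nt"}
    missing = required - set(pileups.columns)
    if missing:
        raise ValueError(f"pileup table missing columns: {sorted(missing)}")

    df = pileups.copy()
    gene_id, strand = _assign_genes(df["chrom"].to_numpy(), df["pos"].to_numpy(), genes)
    df["gene_id"] = gene_id
    df["strand"] = strand

    ref = df["ref"].str.upper().to_numpy()
    in_gene = df["gene_id"].notna().to_numpy()
    plus = (df["strand"] == "+").to_numpy() & (ref == "C")
    minus = (df["strand"] == "-").to_numpy() & (ref == "G")
    candidate = in_gene & (plus | minus)

    unedited = np.where(plus, df["nc"].to_numpy(), df["ng"].to_numpy())
    edited = np.where(plus, df["nt"].to_numpy(), df["na"].to_numpy())
    informative = unedited + edited
    with np.errstate(invalid="ignore", divide="ignore"):
        degree = np.where(informative > 0, 100.0 * edited / np.maximum(informative, 1), np.nan)
    degree = np.where(informative >= min_depth, degree, np.nan)

    obs = df.loc[candidate, ["chrom", "pos", "gene_id", "strand", "sample_id", "tissue", "replicate"]].copy()
    obs["degree"] = degree[candidate]
    obs["informative_depth"] = informative[candidate]
    obs = obs.sort_values(["chrom", "pos", "tissue", "replicate"], kind="mergesort").reset_index(drop=True)

    n_rows = len(df)
    obs.attrs["diagnostics"] = {
        "rows_total": int(n_rows),
        "rows_outside_genes": int((~in_gene).sum()),
        "rows_not_sense_c": int((in_gene & ~candidate).sum()),
    }
    return obs


def _assign_genes(chrom: np.ndarray, pos: np.ndarray, genes: Sequence[GeneModel]):
    gene_id = np.full(len(pos), None, dtype=object)
    strand = np.full(len(pos), None, dtype=object)
    for gene in genes:
        lo, hi = gene.span
        mask = (chrom == gene.chrom) & (pos >= lo) & (pos <= hi)
        gene_id[mask] = gene.gene_id
        strand[mask] = gene.strand
    return gene_id, strand


def read_germline_vcf(path) -> Set[Tuple[str, int, str]]:
    """Read a germline variant set as ``{(chrom, pos, alt), ...}``.

    Multi-allelic records contribute one key per alternate allele.  A
    record cyvcf2 cannot parse is a hard error naming the offending line.
    """
    from cyvcf2 import VCF

    keys: Set[Tuple[str, int, str]] = set()
    try:
        vcf = VCF(str(path))
    except Exception as exc:  # unreadable header / not a VCF
        raise ValueError(f"cannot read VCF {path}: {exc}") from exc
    line_no = _count_header_lines(path)
    try:
        for rec in vcf:
            line_no += 1
            for alt in rec.ALT:
                keys.add((rec.CHROM, rec.POS, alt.upper()))
    except Exception as exc:
        raise ValueError(f"malformed VCF record at {path} line {line_no + 1}: {exc}") from exc
    finally:
        vcf.close()
    return keys


def _count_header_lines(path) -> int:
    n = 0
    with open(path, "rt") as fh:
        for line in fh:
            if line.startswith("#"):
                n += 1
            else:
                break
    return n


def filter_germline(
    candidates: pd.DataFrame,
    germline: Iterable[Tuple[str, int, str]],
) -> pd.DataFrame:
    """Drop candidate sites that coincide with a germline variant carrying
    the same alternate allele.

    The alternate allele of a C-to-U candidate on the plus strand of the
    reference is T for a plus-strand gene and A for a minus-strand gene.
    The output is always a subset of the input.
    """
    germline = set(germline)
    if not germline:
        return candidates.copy()
    alt = candidates["strand"].map({"+": "T", "-": "A"})
    keys = list(zip(candidates["chrom"], candidates["pos"].astype(int), alt))
    keep = [k not in germline for k in keys]
    return candidates.loc[keep].copy()


def call_sites(
    observations: pd.DataFrame,
    design: pd.DataFrame,
    min_degree: float = DEFAULT_MIN_DEGREE,
) -> pd.DataFrame:
    """Apply the replicate retention rule and summarise called sites.

    A site is retained iff there exists a tissue in which *all* replicates
    have a defined degree >= ``min_degree`` (a replicate with insufficient
    informative depth fails the clause).  Returns one row per called site
    with per-tissue ``mean_<t>`` / ``sd_<t>`` (percent, sample SD over
    replicates) plus per-replicate degree columns.  The result is
    independent of the row order of ``observations``.
    """
    tissues = _check_design(design)
    obs = observations
    wide = obs.pivot_table(
        index=["chrom", "pos", "gene_id", "strand"],
        columns=["tissue", "replicate"],
        values="degree",
        aggfunc="first",
        dropna=False,
    )
    n_reps = {t: design.loc[design["tissue"] == t, "replicate"].nunique() for t in tissues}

    retained_mask = pd.Series(False, index=wide.index)
    for t in tissues:
        sub = wide[t] if t in wide.columns.get_level_values(0) else None
        if sub is None:
            continue
        ok = sub.notna().sum(axis=1).eq(n_reps[t]) & (sub >= min_degree).sum(axis=1).eq(n_reps[t])
        retained_mask |= ok

    called = wide.loc[retained_mask]
    out = called.index.to_frame(index=False)
    for t in tissues:
        if t in called.columns.get_level_values(0):
            sub = called[t]
            out[f"mean_{t}"] = sub.mean(axis=1, skipna=True).to_numpy()
            out[f"sd_{t}"] = sub.std(axis=1, ddof=1, skipna=True).to_numpy()
            for rep in sorted(sub.columns):
                out[f"degree_{t}_{rep}"] = sub[rep].to_numpy()
        else:
            out[f"mean_{t}"] = np.nan
            out[f"sd_{t}"] = np.nan
    return out.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)


def _check_design(design: pd.DataFrame) -> Sequence[str]:
    required = {"sample_id", "tissue", "replicate"}
    if missing := required - set(design.columns):
        raise ValueError(f"design table missing columns: {sorted(missing)}")
    tissues = list(dict.fromkeys(design["tissue"]))
    for t in tissues:
        if design.loc[design["tissue"] == t, "replicate"].nunique() == 0:
            raise ValueError(f"tissue {t!r} has zero replicates")
    if not tissues:
        raise ValueError("design table is empty")
    return tissues


class EditingModel:
    """Editing-site caller, statsmodels-style.

    Parameters
    ----------
    pileups
        Per-sample, per-position base counts (see
        :func:`compute_observations` for the schema).
    design
        Replicate design with ``sample_id, tissue, replicate``.
    genes
        Gene models assigning strand (hence candidate status) to positions.
    germline
        Optional germline variant keys ``(chrom, pos, alt)`` or a VCF path;
        matching candidates are excluded before calling.
    min_depth
        Minimum informative reads for a replicate degree to count.
    """

    def __init__(
        self,
        pileups: pd.DataFrame,
        design: pd.DataFrame,
        genes: Sequence[GeneModel],
        germline=None,
        min_depth: int = DEFAULT_MIN_DEPTH,
    ):
        self.pileups = pileups
        self.design = design.copy()
        self.genes = list(genes)
        if germline is None:
            self.germline = set()
        elif isinstance(germline, (str, bytes)) or hasattr(germline, "__fspath__"):
            self.germline = read_germline_vcf(germline)
        else:
            self.germline = set(germline)
        self.min_depth = int(min_depth)
        _check_design(self.design)

    def fit(self, min_degree: float = DEFAULT_MIN_DEGREE) -> "EditingResults":
        obs = compute_observations(self.pileups, self.genes, min_depth=self.min_depth)
        diagnostics = dict(obs.attrs.get("diagnostics", {}))
        obs = filter_germline(obs, self.germline)
        sites = call_sites(obs, self.design, min_degree=min_degree)
        return EditingResults(self, obs, sites, min_degree, diagnostics)


class EditingResults:
    """Called editing sites with per-replicate degrees and per-tissue
    mean +/- SD, plus the pre-call observation table."""

    def __init__(self, model, observations, sites, min_degree, diagnostics):
        self.model = model
        self.observations = observations
        self.sites = sites
        self.min_degree = float(min_degree)
        self.diagnostics = diagnostics

    @property
    def tissues(self) -> Sequence[str]:
        return list(dict.fromkeys(self.model.design["tissue"]))

    def summary(self) -> pd.DataFrame:
        """Report-style table: degrees rounded to whole percent as
        ``mean ± sd`` strings, one row per called site."""
        out = self.sites[["chrom", "pos", "gene_id", "strand"]].copy()
        for t in self.tissues:
            mean = self.sites[f"mean_{t}"]
            sd = self.sites[f"sd_{t}"]
            out[t] = [
                "" if pd.isna(m) else f"{m:.0f} ± {0.0 if pd.isna(s) else s:.0f}"
                for m, s in zip(mean, sd)
            ]
        return out

    def __repr__(self) -> str:
        return (
            f"<EditingResults: {len(self.sites)} sites called at "
            f">={self.min_degree:g}% in all replicates of some tissue>"
        )
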