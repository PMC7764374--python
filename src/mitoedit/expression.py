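"""FPKM-based differential expression screen for mitochondrial genes.

Expression is summarised as FPKM (fragments per kilobase of transcript per
million mapped read pairs); tissues are compared by the ratio of mean
FPKMs with a per-gene two-sample Student t-test on the replicate FPKMs.
A comparison is flagged differentially expressed when the fold change
exceeds 1.5 in either direction (ratio > 1.5 or < 1/1.5) at p < 0.05.
This is a plain ratio + t-test screen, not a dispersion-modelling DE
framework — with three replicates of a 14-gene organellar panel that is
the appropriate tool.
"""

from __future__ import annotations

from typing import Dict, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .differential_editing import student_t_p

__all__ = [
    "fpkm",
    "fold_change_table",
    "de_flags",
    "ExpressionModel",
    "ExpressionResults",
]

DEFAULT_FC = 1.5
DEFAULT_ALPHA = 0.05


def fpkm(count, length, total):
    """FPKM = count / (length/1000) / (total/1e6).

    ``count`` is properly-mapped read pairs assigned to the gene,
    ``length`` the transcript length in bp, ``total`` the library's mapped
    read pairs.  Accepts scalars or arrays; ratios of FPKMs are invariant
    to jointly rescaling counts and totals.
    """
    length = np.asarray(length, dtype=float)
    total = np.asarray(total, dtype=float)
    if np.any(length <= 0):
        raise ValueError("transcript length must be positive")
    if np.any(total <= 0):
        raise ValueError("library total must be positive")
    out = np.asarray(count, dtype=float) / (length / 1e3) / (total / 1e6)
    return float(out) if out.ndim == 0 else out


def fold_change_table(
    means: Mapping[str, float],
    pairs: Sequence[Tuple[str, str]],
    decimals: int = 2,
) -> Dict[Tuple[str, str], float]:
    """Ratios of tissue mean FPKMs, rounded to ``decimals`` for reporting."""
    out = {}
    for a, b in pairs:
        if means[b] <= 0:
            raise ValueError(f"mean FPKM for {b!r} must be positive to form a ratio")
        out[(a, b)] = round(float(means[a]) / float(means[b]), decimals)
    return out


def de_flags(
    ratios: Mapping,
    p_values: Mapping,
    fc: float = DEFAULT_FC,
    alpha: float = DEFAULT_ALPHA,
) -> Dict:
    """Differential-expression flags: |log fold change| beyond ``fc``
    (ratio > fc or ratio < 1/fc) *and* p < alpha."""
    return {
        k: bool((r > fc or r < 1.0 / fc) and p_values[k] < alpha)
        for k, r in ratios.items()
    }


class ExpressionModel:
    """Per-gene FPKM screen across a replicated tissue design.

    Parameters
    ----------
    counts
        Long frame ``gene_id, sample_id, read_pairs``.
    lengths
        Mapping gene_id -> transcript length (bp), e.g. from gene models.
    design
        ``sample_id, tissue, replicate`` plus ``library_read_pairs`` (total
        properly mapped read pairs per library; configurable to
        mitochondria-only totals by supplying those instead).
    """

    def __init__(
        self,
        counts: pd.DataFrame,
        lengths: Mapping[str, int],
        design: pd.DataFrame,
        tissues: Optional[Sequence[str]] = None,
    ):
        required = {"gene_id", "sample_id", "read_pairs"}
        if missing := required - set(counts.columns):
            raise ValueError(f"counts table missing columns: {sorted(missing)}")
        if "library_read_pairs" not in design.columns:
            raise ValueError("design table needs a library_read_pairs column")
        self.counts = counts.copy()
        self.lengths = dict(lengths)
        self.design = design.copy()
        self.tissues = list(tissues) if tissues else list(dict.fromkeys(design["tissue"]))
        self.pairs = [
            (a, b) for i, a in enumerate(self.tissues) for b in self.tissues[i + 1 :]
        ]
        if self.tissues == ["N", "SR", "UR"]:
            self.pairs = [("N", "UR"), ("N", "SR"), ("SR", "UR")]

    def fit(self, fc: float = DEFAULT_FC, alpha: float = DEFAULT_ALPHA) -> "ExpressionResults":
        df = self.counts.merge(self.design, on="sample_id", validate="many_to_one")
        unknown = set(df["gene_id"]) - set(self.lengths)
        if unknown:
            raise ValueError(f"no transcript length for genes: {sorted(unknown)}")
        df["length"] = df["gene_id"].map(self.lengths)
        df["fpkm"] = fpkm(df["read_pairs"], df["length"], df["library_read_pairs"])

        per_rep = df.pivot_table(index="gene_id", columns=["tissue", "replicate"], values="fpkm")
        rows = []
        for gene_id, row in per_rep.iterrows():
            reps = {t: row[t].dropna().to_numpy() for t in self.tissues}
            means = {t: float(np.mean(reps[t])) for t in self.tissues}
            ratios = fold_change_table(means, self.pairs)
            pvals = {
                (a, b): student_t_p(reps[a], reps[b]) if min(len(reps[a]), len(reps[b])) >= 2 else np.nan
                for a, b in self.pairs
            }
            flags = de_flags(ratios, pvals, fc=fc, alpha=alpha)
            rec = {"gene_id": gene_id, "length": self.lengths[gene_id]}
            for t in self.tissues:
                rec[f"fpkm_{t}"] = means[t]
            for a, b in self.pairs:
                rec[f"ratio_{a}_{b}"] = ratios[(a, b)]
                rec[f"p_{a}_{b}"] = pvals[(a, b)]
                rec[f"de_{a}_{b}"] = flags[(a, b)]
            rows.append(rec)
        table = pd.DataFrame(rows).sort_values("gene_id").reset_index(drop=True)
        return ExpressionResults(self, table, fc, alpha)


class ExpressionResults:
    """Per-gene FPKM means, fold changes, t-test p-values and DE flags."""

    def __init__(self, model, table, fc, alpha):
        self.model = model
        self.table = table
        self.fc = float(fc)
        self.alpha = float(alpha)

    @property
    def de_genes(self) -> pd.DataFrame:
        de_cols = [c for c in self.table.columns if c.startswith("de_")]
        return self.table[self.table[de_cols].any(axis=1)]

    def summary(self) -> pd.DataFrame:
        t = self.table
        out = t[["gene_id"]].copy()
        for tissue in self.model.tissues:
            out[f"{tissue} FPKM"] = t[f"fpkm_{tissue}"].round(0).astype(int)
        for a, b in self.model.pairs:
            out[f"{a}/{b}"] = t[f"ratio_{a}_{b}"]
            out[f"p ({a}/{b})"] = t[f"p_{a}_{b}"].round(3)
            out[f"DE ({a}/{b})"] = t[f"de_{a}_{b}"]
        return out

    def __repr__(self) -> str:
        return f"<ExpressionResults: {len(self.de_genes)}/{len(self.table)} genes DE at fc>{self.fc:g}, p<{self.alpha:g}>"
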