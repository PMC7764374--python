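"""Group-II intron splicing efficiency from comparative-Ct qPCR.

For each intron, one amplicon spans an exon–exon junction (spliced
transcript) and one spans an intron–exon junction (unspliced precursor);
a housekeeping gene provides the reference.  Relative abundance of an
amplicon in a replicate is ``2^-(Ct_amplicon - Ct_reference)`` (perfect
doubling assumed), and the splicing efficiency of an intron is the ratio
spliced/unspliced.  Because both amplicons share a replicate's reference
Ct, the efficiency is algebraically independent of the housekeeping gene —
shifting all Ct values of a replicate by a constant changes nothing.

Cross-tissue comparison divides each tissue's efficiency by the baseline
tissue's (uninoculated root by default), so the baseline maps to exactly 1.
Replicates are aggregated in the log2 domain (geometric means), where Ct
noise is additive; SDs are computed over biological replicates in log2
and reported both ways.
"""

from __future__ import annotations

import warnings
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "relative_expression",
    "splicing_efficiency",
    "tissue_ratio",
    "SplicingModel",
    "SplicingResults",
]

SPLICED, UNSPLICED, REFERENCE = "spliced", "unspliced", "reference"


def relative_expression(ct_target, ct_reference):
    """Comparative-Ct relative quantity: ``2**-(Ct_target - Ct_reference)``."""
    return 2.0 ** -(np.asarray(ct_target, dtype=float) - np.asarray(ct_reference, dtype=float))


def splicing_efficiency(rel_spliced, rel_unspliced):
    """Spliced/unspliced abundance ratio; requires ``rel_unspliced > 0``."""
    rel_unspliced = np.asarray(rel_unspliced, dtype=float)
    if np.any(rel_unspliced <= 0):
        raise ValueError("unspliced relative abundance must be positive")
    return np.asarray(rel_spliced, dtype=float) / rel_unspliced


def tissue_ratio(
    efficiencies: Mapping[str, float],
    baseline: str = "UR",
) -> dict:
    """Per-tissue splicing-efficiency fold relative to the baseline tissue.

    The baseline maps to exactly 1.0.
    """
    if baseline not in efficiencies:
        raise ValueError(f"baseline tissue {baseline!r} missing")
    base = float(efficiencies[baseline])
    if base <= 0:
        raise ValueError("baseline efficiency must be positive")
    return {t: float(e) / base for t, e in efficiencies.items()}


class SplicingModel:
    """Per-intron splicing-efficiency analysis of a Ct table.

    Parameters
    ----------
    ct_table
        Long frame ``tissue, replicate, intron_label, amplicon, ct`` with
        ``amplicon`` in {spliced, unspliced, reference}; reference rows
        need no intron label (one housekeeping Ct per tissue x replicate;
        technical replicates should be averaged to a single Ct upstream).
    baseline
        Tissue whose efficiency normalises the others.
    """

    def __init__(self, ct_table: pd.DataFrame, baseline: str = "UR"):
        required = {"tissue", "replicate", "amplicon", "ct"}
        if missing := required - set(ct_table.columns):
            raise ValueError(f"Ct table missing columns: {sorted(missing)}")
        df = ct_table.copy()
        if (df["ct"] <= 0).any() or not np.isfinite(df["ct"]).all():
            raise ValueError("Ct values must be finite and positive")
        self.ct_table = df
        self.baseline = baseline
        self.tissues = list(dict.fromkeys(df["tissue"]))
        if baseline not in self.tissues:
            raise ValueError(f"baseline tissue {baseline!r} not present")

    def _reference_ct(self) -> pd.DataFrame:
        ref = self.ct_table[self.ct_table["amplicon"] == REFERENCE]
        return ref.groupby(["tissue", "replicate"], as_index=False)["ct"].mean().rename(columns={"ct": "ct_ref"})

    def fit(self) -> "SplicingResults":
        df = self.ct_table[self.ct_table["amplicon"].isin([SPLICED, UNSPLICED])].copy()
        ref = self._reference_ct()
        df = df.merge(ref, on=["tissue", "replicate"], how="left")
        dropped = df["ct_ref"].isna()
        if dropped.any():
            bad = df.loc[dropped, ["tissue", "replicate"]].drop_duplicates()
            warnings.warn(
                "dropping replicates with no housekeeping Ct: "
                + ", ".join(f"{t}/{r}" for t, r in bad.itertuples(index=False)),
                stacklevel=2,
            )
            df = df[~dropped]
        df["rel"] = relative_expression(df["ct"], df["ct_ref"])
        wide = df.pivot_table(
            index=["intron_label", "tissue", "replicate"], columns="amplicon", values="rel"
        ).dropna(subset=[SPLICED, UNSPLICED])
        wide["efficiency"] = splicing_efficiency(wide[SPLICED], wide[UNSPLICED])
        wide["log2_eff"] = np.log2(wide["efficiency"])
        wide["log2_spliced"] = np.log2(wide[SPLICED])

        per_tissue = (
            wide.reset_index()
            .groupby(["intron_label", "tissue"])
            .agg(
                efficiency=("log2_eff", lambda v: 2.0 ** np.mean(v)),
                log2_eff_mean=("log2_eff", "mean"),
                log2_eff_sd=("log2_eff", lambda v: np.std(v, ddof=1) if len(v) > 1 else 0.0),
                log2_spliced_mean=("log2_spliced", "mean"),
                log2_spliced_sd=("log2_spliced", lambda v: np.std(v, ddof=1) if len(v) > 1 else 0.0),
                n_replicates=("log2_eff", "size"),
            )
            .reset_index()
        )

        rows = []
        for intron, sub in per_tissue.groupby("intron_label"):
            effs = dict(zip(sub["tissue"], sub["efficiency"]))
            if self.baseline not in effs:
                warnings.warn(f"intron {intron!r} lacks baseline tissue data; skipped", stacklevel=2)
                continue
            ratios = tissue_ratio(effs, baseline=self.baseline)
            base_log2_spliced = float(
                sub.loc[sub["tissue"] == self.baseline, "log2_spliced_mean"].iloc[0]
            )
            for _, r in sub.iterrows():
                rows.append(
                    {
                        "intron_label": intron,
                        "tissue": r["tissue"],
                        "efficiency": r["efficiency"],
                        "efficiency_ratio": ratios[r["tissue"]],
                        # multiplicative (back-transformed log2-domain) SD
                        "ratio_sd_factor": 2.0 ** r["log2_eff_sd"],
                        "log2_spliced_ratio": r["log2_spliced_mean"] - base_log2_spliced,
                        "log2_spliced_sd": r["log2_spliced_sd"],
                        "n_replicates": int(r["n_replicates"]),
                    }
                )
        table = pd.DataFrame(rows)
        return SplicingResults(self, table, wide.reset_index())


class SplicingResults:
    """Per-intron, per-tissue splicing efficiencies and baseline-relative
    ratios, with replicate-level detail in ``per_replicate``."""

    def __init__(self, model, table: pd.DataFrame, per_replicate: pd.DataFrame):
        self.model = model
        self.table = table
        self.per_replicate = per_replicate

    def summary(self) -> pd.DataFrame:
        out = self.table.copy()
        for col in ("efficiency", "efficiency_ratio", "ratio_sd_factor", "log2_spliced_ratio", "log2_spliced_sd"):
            out[col] = out[col].round(3)
        return out

    def plot(self, ax=None):
        """Grouped bars of efficiency ratios vs baseline, one group per intron."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(8, 4))
        introns = list(dict.fromkeys(self.table["intron_label"]))
        tissues = [t for t in self.model.tissues]
        x = np.arange(len(introns))
        width = 0.8 / len(tissues)
        for i, t in enumerate(tissues):
            sub = self.table[self.table["tissue"] == t].set_index("intron_label")
            vals = [sub["efficiency_ratio"].get(intron, np.nan) for intron in introns]
            ax.bar(x + i * width, vals, width, label=t)
        ax.axhline(1.0, color="grey", lw=0.8, ls="--")
        ax.set_xticks(x + width)
        ax.set_xticklabels(introns, rotation=45, ha="right")
        ax.set_ylabel(f"splicing efficiency vs {self.model.baseline}")
        ax.legend()
        return ax

    def __repr__(self) -> str:
        n = self.table["intron_label"].nunique() if len(self.table) else 0
        return f"<SplicingResults: {n} introns, baseline {self.model.baseline}>"
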