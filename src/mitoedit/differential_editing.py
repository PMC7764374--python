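"""Differential editing between tissues.

Two devices from the tissue-comparison literature are combined: a plain
effect-size screen (a site is differential when any pairwise difference in
mean editing degree reaches a threshold, default 15 percentage points) and
a compact letter display from pairwise two-sample Student t-tests, so that
tissues sharing a letter are not significantly different.  No
multiple-testing correction is applied — the screen is deliberately the
simple rule practitioners print next to per-site tables.
"""

from __future__ import annotations

import itertools
import string
from typing import Dict, Mapping, Optional, Sequence, Tuple

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "pairwise_differences",
    "flag_differential",
    "student_t_p",
    "letter_groups",
    "DifferentialEditingModel",
    "DifferentialEditingResults",
]

DEFAULT_DELTA = 15.0
DEFAULT_ALPHA = 0.05


def pairwise_differences(
    means: Mapping[str, float],
    pairs: Sequence[Tuple[str, str]],
) -> Dict[Tuple[str, str], Optional[float]]:
    """Signed differences of unrounded tissue means, in percentage points.

    A pair with a missing mean yields ``None`` (the site is then excluded
    from differential testing).  Rounding to whole points is a reporting
    concern only.
    """
    out: Dict[Tuple[str, str], Optional[float]] = {}
    for a, b in pairs:
        ma, mb = means.get(a), means.get(b)
        if ma is None or mb is None or np.isnan(ma) or np.isnan(mb):
            out[(a, b)] = None
        else:
            out[(a, b)] = float(ma) - float(mb)
    return out


def flag_differential(differences, delta_threshold: float = DEFAULT_DELTA) -> bool:
    """True iff any defined pairwise difference has |d| >= threshold
    (boundary inclusive)."""
    vals = differences.values() if isinstance(differences, Mapping) else differences
    return any(d is not None and not np.isnan(d) and abs(d) >= delta_threshold for d in vals)


def student_t_p(x: Sequence[float], y: Sequence[float]) -> float:
    """Two-sided equal-variance two-sample t-test p-value.

    Degenerate zero-variance data are handled explicitly: identical means
    give p = 1 (no evidence of difference), distinct means with zero
    pooled variance give p = 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.var(ddof=1) == 0 and y.var(ddof=1) == 0:
        return 1.0 if x.mean() == y.mean() else 0.0
    return float(stats.ttest_ind(x, y, equal_var=True).pvalue)


def letter_groups(
    replicates: Mapping[str, Sequence[float]],
    alpha: float = DEFAULT_ALPHA,
) -> Dict[str, str]:
    """Compact letter display over pairwise Student t-tests.

    Groups (tissues) that are *not* significantly different at ``alpha``
    share a letter.  Letters label the maximal cliques of the
    not-significantly-different graph; cliques are ordered by the input
    order of their member tissues (the column-order convention used in
    per-site editing tables), so with tissues N, SR, UR three mutually
    distinct groups come out (a, b, c) in that column order.  A tissue in
    several cliques carries several letters (e.g. "ab").  Deterministic
    given the input.
    """
    tissues = list(replicates)
    rank = {t: i for i, t in enumerate(tissues)}
    g = nx.Graph()
    g.add_nodes_from(tissues)
    for a, b in itertools.combinations(tissues, 2):
        if student_t_p(replicates[a], replicates[b]) >= alpha:
            g.add_edge(a, b)
    cliques = [sorted(c, key=rank.__getitem__) for c in nx.find_cliques(g)]
    cliques.sort(key=lambda c: tuple(rank[t] for t in c))
    letters: Dict[str, list] = {t: [] for t in tissues}
    for letter, clique in zip(string.ascii_lowercase, cliques):
        for t in clique:
            letters[t].append(letter)
    return {t: "".join(sorted(ls)) for t, ls in letters.items()}


class DifferentialEditingModel:
    """Differential-editing screen over the replicate degrees of called
    sites.

    Parameters
    ----------
    sites
        Output of :class:`~mitoedit.editing_quant.EditingModel` (an
        ``EditingResults``) or its ``sites`` frame, carrying
        ``degree_<tissue>_<rep>`` columns.
    tissues
        Tissue order; pairwise comparisons are all ordered pairs
        ``(earlier, later)`` in this order, matching the usual
        N-UR / N-SR / SR-UR report layout for ``("N", "SR", "UR")``.
    """

    def __init__(self, sites, tissues: Sequence[str] = ("N", "SR", "UR")):
        if hasattr(sites, "sites"):
            sites = sites.sites
        self.sites = sites.copy()
        self.tissues = list(tissues)
        self.pairs = [
            (a, b)
            for i, a in enumerate(self.tissues)
            for b in self.tissues[i + 1 :]
        ]
        # N-SR-UR convention: N-UR, N-SR, SR-UR
        if self.tissues == ["N", "SR", "UR"]:
            self.pairs = [("N", "UR"), ("N", "SR"), ("SR", "UR")]

    def _replicates(self, row) -> Dict[str, np.ndarray]:
        reps = {}
        for t in self.tissues:
            cols = [c for c in self.sites.columns if c.startswith(f"degree_{t}_")]
            vals = np.array([row[c] for c in cols], dtype=float)
            reps[t] = vals[~np.isnan(vals)]
        return reps

    def fit(
        self,
        delta_threshold: float = DEFAULT_DELTA,
        alpha: float = DEFAULT_ALPHA,
    ) -> "DifferentialEditingResults":
        rows = []
        for _, row in self.sites.iterrows():
            means = {t: row.get(f"mean_{t}", np.nan) for t in self.tissues}
            diffs = pairwise_differences(means, self.pairs)
            complete = all(d is not None for d in diffs.values())
            reps = self._replicates(row)
            rec = {
                "chrom": row["chrom"],
                "pos": row["pos"],
                "gene_id": row.get("gene_id"),
                "strand": row.get("strand"),
            }
            for t in self.tissues:
                rec[f"mean_{t}"] = means[t]
                rec[f"sd_{t}"] = row.get(f"sd_{t}", np.nan)
            for (a, b), d in diffs.items():
                rec[f"diff_{a}_{b}"] = np.nan if d is None else d
            if complete:
                for a, b in self.pairs:
                    if len(reps[a]) >= 2 and len(reps[b]) >= 2:
                        rec[f"p_{a}_{b}"] = student_t_p(reps[a], reps[b])
                    else:
                        rec[f"p_{a}_{b}"] = np.nan
                usable = {t: r for t, r in reps.items() if len(r) >= 2}
                if len(usable) == len(self.tissues):
                    rec.update(
                        {f"letter_{t}": l for t, l in letter_groups(usable, alpha=alpha).items()}
                    )
                rec["differential"] = flag_differential(diffs, delta_threshold)
            else:
                rec["differential"] = False
            rows.append(rec)
        table = pd.DataFrame(rows)
        return DifferentialEditingResults(self, table, delta_threshold, alpha)


class DifferentialEditingResults:
    """Per-site differential table: tissue means +/- SD, pairwise
    differences and p-values, letter labels and the differential flag."""

    def __init__(self, model, table: pd.DataFrame, delta_threshold: float, alpha: float):
        self.model = model
        self.table = table
        self.delta_threshold = float(delta_threshold)
        self.alpha = float(alpha)

    @property
    def differential_sites(self) -> pd.DataFrame:
        return self.table[self.table["differential"].fillna(False)]

    def summary(self) -> pd.DataFrame:
        """Publication-shaped table: whole-percent means with SD and
        letters, whole-point difference columns."""
        t = self.table
        out = t[["chrom", "pos", "gene_id", "strand"]].copy()
        for tissue in self.model.tissues:
            out[tissue] = [
                ""
                if pd.isna(m)
                else f"{m:.0f} ± {0.0 if pd.isna(s) else s:.0f} {l}".rstrip()
                for m, s, l in zip(
                    t[f"mean_{tissue}"],
                    t[f"sd_{tissue}"],
                    t.get(f"letter_{tissue}", [""] * len(t)),
                )
            ]
        for a, b in self.model.pairs:
            col = f"diff_{a}_{b}"
            if col in t:
                out[f"{a}-{b} (%)"] = t[col].round(0).astype("Int64", errors="ignore")
        out["differential"] = t["differential"]
        return out

    def plot(self, ax=None):
        """Bar chart of per-tissue mean degrees for differential sites."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(8, 4))
        d = self.differential_sites
        x = np.arange(len(d))
        width = 0.8 / max(len(self.model.tissues), 1)
        for i, t in enumerate(self.model.tissues):
            ax.bar(
                x + i * width,
                d[f"mean_{t}"],
                width,
                yerr=d[f"sd_{t}"],
                label=t,
                capsize=2,
            )
        ax.set_xticks(x + width)
        ax.set_xticklabels(d["pos"].astype(str), rotation=90)
        ax.set_ylabel("editing degree (%)")
        ax.legend()
        return ax

    def __repr__(self) -> str:
        n = int(self.table["differential"].fillna(False).sum())
        return (
            f"<DifferentialEditingResults: {n}/{len(self.table)} sites with "
            f"|Δ| ≥ {self.delta_threshold:g} points>"
        )
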