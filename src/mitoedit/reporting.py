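"""Joining called sites with annotation into publication-shaped tables."""

from __future__ import annotations

from typing import Dict, Iterable, Mapping, Sequence

import pandas as pd

from .gene_models import GeneModel, annotate_genome_site, genome_to_transcript

__all__ = ["annotate_sites", "editing_report"]


def annotate_sites(
    sites: pd.DataFrame,
    genes: Sequence[GeneModel],
    transcripts: Mapping[str, str],
    co_edits: str = "called",
) -> pd.DataFrame:
    """Attach transcript coordinates and codon-effect annotation to called
    sites.

    ``co_edits='called'`` uses, for each gene, all of its called sites as
    the co-edited set (so two edits in one codon combine, e.g. TCC→TTT);
    ``co_edits='none'`` annotates each site in isolation.
    """
    by_id = {g.gene_id: g for g in genes}
    co_sets: Dict[str, set] = {g_id: set() for g_id in by_id}
    if co_edits == "called":
        for _, row in sites.iterrows():
            g = by_id.get(row["gene_id"])
            if g is None:
                continue
            loc = genome_to_transcript(int(row["pos"]), g)
            if loc.is_exonic:
                co_sets[g.gene_id].add(loc.tpos)

    records = []
    for _, row in sites.iterrows():
        g = by_id.get(row["gene_id"])
        rec = dict(row)
        if g is None:
            rec.update(region="outside", category="noncoding")
            records.append(rec)
            continue
        loc = genome_to_transcript(int(row["pos"]), g)
        ann = annotate_genome_site(
            int(row["pos"]), g, transcripts[g.gene_id], co_sets.get(g.gene_id, ())
        )
        rec.update(
            tpos=loc.tpos,
            region=ann.region,
            category=ann.category,
            aa_position=ann.aa_position,
            codon_position=ann.codon_position,
            ref_codon=ann.ref_codon,
            edited_codon=ann.edited_codon,
            ref_aa=ann.ref_aa,
            edited_aa=ann.edited_aa,
            intron_label=ann.intron_label,
        )
        records.append(rec)
    return pd.DataFrame(records)


def editing_report(annotated: pd.DataFrame, differential: pd.DataFrame, tissues: Sequence[str]) -> pd.DataFrame:
    """Join annotation and differential results into a per-site table with
    genome/transcript/codon coordinates, codon and amino-acid changes,
    per-tissue mean ± SD with letters, and pairwise change columns."""
    ann_cols = [
        "chrom", "pos", "gene_id", "strand", "tpos", "aa_position",
        "ref_codon", "edited_codon", "ref_aa", "edited_aa", "category", "intron_label",
    ]
    ann = annotated[[c for c in ann_cols if c in annotated.columns]]
    diff_cols = [c for c in differential.columns if c not in ("gene_id", "strand")]
    merged = ann.merge(differential[diff_cols], on=["chrom", "pos"], how="left")

    out = merged[["pos", "tpos", "aa_position"]].rename(
        columns={"pos": "genome_position", "tpos": "transcript_position", "aa_position": "aa_position"}
    ).copy()
    out.insert(0, "gene_id", merged["gene_id"])
    out["codon_change"] = [
        f"{r}>{e}" if isinstance(r, str) and isinstance(e, str) else ""
        for r, e in zip(merged.get("ref_codon"), merged.get("edited_codon"))
    ]
    out["aa_change"] = [
        ""
        if not isinstance(ra, str)
        else (f"No ({ra})" if ra == ea else f"{ra}>{ea}")
        for ra, ea in zip(merged.get("ref_aa"), merged.get("edited_aa"))
    ]
    out["category"] = merged["category"]
    for t in tissues:
        mcol, scol, lcol = f"mean_{t}", f"sd_{t}", f"letter_{t}"
        if mcol in merged:
            out[t] = [
                ""
                if pd.isna(m)
                else f"{m:.0f} ± {0 if pd.isna(s) else s:.0f} {l if isinstance(l, str) else ''}".rstrip()
                for m, s, l in zip(merged[mcol], merged[scol], merged.get(lcol, [None] * len(merged)))
            ]
    for col in merged.columns:
        if col.startswith("diff_"):
            a, b = col.split("_")[1:3]
            out[f"{a}-{b} (%)"] = merged[col].round(0)
    if "differential" in merged:
        out["differential"] = merged["differential"]
    return out
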