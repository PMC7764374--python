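"""Reference datasets shipped with the package.

Two published summary tables from a soybean nodulation study are included
as plain TSV: the differential-expression table of mitochondrial
transcripts (FPKM means per tissue with fold changes, t-test p-values and
the significance marks as printed) and the maturase (matR) editing-site
table (genome/transcript coordinates, codon changes, per-tissue editing
degrees with letter groups, and cross-species flags).  They serve as
worked examples and as desk-check inputs for the arithmetic the package
implements.

Tissue labels: N = nodule, SR = stripped root (root after nodule
removal), UR = uninoculated root.
"""

from importlib import resources

import pandas as pd

__all__ = ["load_mito_expression", "load_matr_editing_sites", "MATR_ANCHOR_SUM"]

#: genome_pos + tpos is constant for every site of the single-exon,
#: minus-strand matR gene; this is that constant, fixed by the published
#: coordinate pairs (e.g. genome 340,005 <-> transcript 32).
MATR_ANCHOR_SUM = 340_037


def _read(name: str, **kwargs) -> pd.DataFrame:
    with resources.files(__package__).joinpath(name).open("r") as fh:
        return pd.read_csv(fh, sep="\t", **kwargs)


def load_mito_expression() -> pd.DataFrame:
    """Differential-expression table: per-gene FPKM means for UR/SR/N,
    printed fold-change ratios, t-test p-values, and the printed
    significance (bold) marks for each comparison."""
    return _read("mito_expression.tsv")


def load_matr_editing_sites() -> pd.DataFrame:
    """matR editing-site table: 17 C-to-U sites with genome and transcript
    coordinates, codon/amino-acid changes, per-tissue mean ± SD editing
    degrees with compact-letter labels, pairwise difference columns, and
    flags for sites known in Arabidopsis or previously reported in soybean.

    The row at genome 338,976 prints an incomplete amino-acid change
    (``P>``); translation of its codon change CCC→CTC gives P→L.
    """
    df = _read(
        "matr_editing_sites.tsv",
        dtype={"in_arabidopsis": str, "in_soybean_prior": str},
    )
    return df
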