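"""mitoedit — C-to-U RNA editing, expression and intron-splicing analysis
for plant mitochondrial transcriptomes.

The package is organised statsmodels-style: each analysis stage is a model
class built from tidy input tables whose ``fit()`` returns a results
object carrying estimates, uncertainties and a ``summary()`` table.

* :class:`EditingModel` — call C-to-U editing sites from per-site base
  counts, with germline filtering and the all-replicates degree threshold.
* :class:`DifferentialEditingModel` — pairwise tissue differences,
  Student t-tests and compact letter displays per site.
* :class:`ExpressionModel` — FPKM, fold changes and the ratio + t-test
  differential-expression screen.
* :class:`SplicingModel` — comparative-Ct splicing efficiencies and
  baseline-relative ratios per group-II intron.
* :mod:`mitoedit.synthetic_data` — truth-annotated synthetic studies for
  end-to-end testing.
"""

from .gene_models import (
    CoordinateError,
    EffectAnnotation,
    GeneModel,
    Intron,
    NotEditableError,
    TranscriptLocation,
    annotate_genome_site,
    classify_effect,
    codon_index,
    genome_to_transcript,
    sense_transcript_sequence,
    transcript_to_genome,
)
from .editing_quant import (
    EditingModel,
    EditingResults,
    NotACandidateError,
    call_sites,
    compute_observations,
    editing_degree,
    filter_germline,
    read_germline_vcf,
)
from .differential_editing import (
    DifferentialEditingModel,
    DifferentialEditingResults,
    flag_differential,
    letter_groups,
    pairwise_differences,
    student_t_p,
)
from .expression import ExpressionModel, ExpressionResults, de_flags, fold_change_table, fpkm
from .splicing_qpcr import (
    SplicingModel,
    SplicingResults,
    relative_expression,
    splicing_efficiency,
    tissue_ratio,
)
from .synthetic_data import SimulationConfig, SimulatedStudy, simulate_study
from .reporting import annotate_sites, editing_report
from .datasets import load_matr_editing_sites, load_mito_expression

__version__ = "0.1.0"
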