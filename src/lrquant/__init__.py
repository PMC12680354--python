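"""lrquant: long-read RNA-seq isoform quantification by pseudoalignment.

The pipeline indexes a reference transcriptome as a compacted de Bruijn
graph at long k (default 63), assigns each read a transcript compatibility
class through an error-tolerant decision cascade, and apportions class
counts into transcript abundances with an EM variant suited to long reads.
A profile-parameterized read simulator and a set of agreement metrics
(Lin's CCC, Pearson/Spearman, NRMSE, MRD, PET) support end-to-end
evaluation on synthetic data.
"""

__version__ = "0.1.0"

from .metrics import MetricReport, ccc, evaluate, mrd, nrmse, pet
from .pseudoalign import (
    ReadClassification,
    TCCCounts,
    classify_read,
    pseudoalign_batch,
)
from .quantify import (
    EffectiveLengths,
    EMResult,
    QuantResult,
    compute_tpm,
    estimate_effective_lengths,
    make_abundance_table,
    quantify,
    read_abundance,
    run_em,
    write_abundance,
)
from .simulate import (
    ErrorProfile,
    SimTruth,
    generate_reads,
    generate_transcriptome,
    inject_errors,
    sample_expression,
    write_truth,
)
from .tdbg import (
    DEFAULT_K,
    GraphStats,
    KmerHit,
    TDBGIndex,
    TranscriptSet,
    Unitig,
    build_dlist,
    build_index,
    canonical,
    graph_stats,
    load_index,
    lookup_kmer,
    reverse_complement,
    save_index,
)

__all__ = [
    "__version__",
    "TranscriptSet",
    "TDBGIndex",
    "Unitig",
    "GraphStats",
    "KmerHit",
    "DEFAULT_K",
    "build_index",
    "lookup_kmer",
    "build_dlist",
    "graph_stats",
    "save_index",
    "load_index",
    "canonical",
    "reverse_complement",
    "ReadClassification",
    "TCCCounts",
    "classify_read",
    "pseudoalign_batch",
    "EffectiveLengths",
    "EMResult",
    "QuantResult",
    "estimate_effective_lengths",
    "run_em",
    "compute_tpm",
    "make_abundance_table",
    "write_abundance",
    "read_abundance",
    "quantify",
    "ErrorProfile",
    "SimTruth",
    "generate_transcriptome",
    "sample_expression",
    "generate_reads",
    "inject_errors",
    "write_truth",
    "MetricReport",
    "ccc",
    "nrmse",
    "mrd",
    "pet",
    "evaluate",
]
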