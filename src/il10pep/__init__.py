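"""il10pep: descriptor-based classification of IL-10-inducing peptides.

A toolkit for predicting which MHC-II-binding peptides induce the
anti-inflammatory cytokine interleukin-10, built from six amino-acid
descriptor families (AAC, DPC, CTD, QSO, SOC, autocorrelation), SMOTE
class balancing, permutation-importance feature selection, tree-ensemble
classifiers with stratified cross-validation, and two-sample sequence
statistics — all exercisable on benchmark-shaped synthetic data.
"""

from ._version import __version__
from .descriptors import (DescriptorConfig, DistanceMatrix, GroupScheme,
                          PropertyTable, aac, autocorrelation, column_names,
                          ctd, dpc, encode, qso, soc)
from .io import (ALPHABET, LabeledDataset, Peptide, SyntheticSpec,
                 generate_synthetic, read_fasta, read_table, write_fasta)
from .metrics import (ConfusionCounts, EvaluationReport, confusion,
                      evaluate_scores, pr_ap, roc_auc, scalar_metrics)
from .pipeline import (PeptideClassifier, PeptideClassifierResults,
                       PipelineConfig, TrainedModel, cross_validate,
                       evaluate_holdout, fit_final, predict, stratified_split)
from .resampling import ResampledData, SmoteConfig, smote
from .selection import SelectionResult, select_features, top_k_report
from .seqstats import composition_comparison, position_enrichment

__all__ = [
    "__version__", "ALPHABET",
    "Peptide", "LabeledDataset", "SyntheticSpec",
    "read_fasta", "read_table", "write_fasta", "generate_synthetic",
    "DescriptorConfig", "PropertyTable", "DistanceMatrix", "GroupScheme",
    "aac", "dpc", "ctd", "qso", "soc", "autocorrelation", "encode",
    "column_names",
    "SmoteConfig", "ResampledData", "smote",
    "SelectionResult", "select_features", "top_k_report",
    "ConfusionCounts", "EvaluationReport", "confusion", "scalar_metrics",
    "roc_auc", "pr_ap", "evaluate_scores",
    "PipelineConfig", "TrainedModel", "PeptideClassifier",
    "PeptideClassifierResults", "stratified_split", "cross_validate",
    "fit_final", "evaluate_holdout", "predict",
    "composition_comparison", "position_enrichment",
]
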