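"""Published run-level summary numbers for the sorghum ABA/osmotic-stress
RNA-seq study (2 tissues x 4 treatments x 3 pooled biological runs).

These are inputs, not results: the per-sample read-category totals
(millions of reads, runs combined) feed :func:`droughtseq.qc.qc_summary`,
and the annotation/expression tallies feed the percentage arithmetic in
:func:`expressed_percentages`.  Raw sequence data for the study are
deposited under GEO accession GSE30249.
"""

from __future__ import annotations

import pandas as pd

#: Per-sample read totals in millions, three runs combined.  Columns are
#: the read categories consumed by qc_summary; rows are tissue/treatment
#: samples.
STUDY_LANE_SUMMARY = pd.DataFrame(
    {
        "total_reads": [87.9, 90.2, 80.5, 84.2, 88.7, 88.8, 87.0, 82.2],
        "purity_filtered": [70.7, 68.0, 64.5, 65.3, 66.3, 67.7, 67.2, 66.2],
        "repeat_masked": [5.4, 4.9, 4.6, 5.0, 4.9, 4.7, 5.3, 4.8],
        "unmatched": [4.4, 4.4, 2.3, 3.5, 6.3, 6.6, 1.2, 2.4],
        "uniquely_mapped": [60.7, 58.6, 57.5, 56.5, 54.7, 56.3, 59.7, 58.9],
        "mapped_to_genes": [55.59, 51.78, 52.31, 50.32, 49.59, 49.74, 53.89,
                            52.38],
    },
    index=[
        "NaOH_shoot", "NaOH_root", "ABA_shoot", "ABA_root",
        "H2O_shoot", "H2O_root", "PEG_shoot", "PEG_root",
    ],
)

#: Annotation and transcriptional-activity tallies reported by the study.
STUDY_GENE_TALLIES = {
    "annotated_gene_models": 34496,
    "resolved_gene_models": 34144,
    "high_confidence_models": 27640,
    "expressed_total": 28335,
    "expressed_high_confidence": 25568,
    "expressed_low_confidence": 2649,
    "silent_models": 5809,
    "silent_low_confidence": 3915,
    "detected_nonzero_median": 26466,
    "low_depth_detected": 2971,  # median depth in (0.5X, 2X)
    "de_unique_genes": 5156,
}


def expressed_percentages(tallies: dict | None = None) -> dict[str, float]:
    """Derived percentages of the activity tallies, rounded to one decimal.

    - pct_high_confidence_expressed: expressed high-confidence models /
      all high-confidence models
    - pct_models_silent: silent / resolved models
    - pct_silent_low_confidence: low-confidence silent / silent
    - pct_low_depth_of_detected: genes at median depth in (0.5X, 2X) /
      genes detected with nonzero median depth
    """
    t = STUDY_GENE_TALLIES if tallies is None else tallies
    return {
        "pct_high_confidence_expressed": round(
            100.0 * t["expressed_high_confidence"] / t["high_confidence_models"], 1
        ),
        "pct_models_silent": round(
            100.0 * t["silent_models"] / t["resolved_gene_models"], 1
        ),
        "pct_silent_low_confidence": round(
            100.0 * t["silent_low_confidence"] / t["silent_models"], 1
        ),
        "pct_low_depth_of_detected": round(
            100.0 * t["low_depth_detected"] / t["detected_nonzero_median"], 1
        ),
    }
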