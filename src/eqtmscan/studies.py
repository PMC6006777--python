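"""Reference cohort dimensions used for power and scan-size arithmetic.

Two published blood-tissue cohorts frame the analysis: a whole-blood cohort
(n = 333; 472,199 methylation probes × 13,933 expression probes passing QC)
and a purified-monocyte cohort (n = 1202; 422,016 × 19,445). Their probe
counts set the all-pairs comparison totals, and their sample sizes the
detectable effect-size floors.
"""

from __future__ import annotations

REFERENCE_STUDIES: dict = {
    "whole_blood": {
        "n_samples": 333,
        "n_methylation_probes": 472_199,
        "n_expression_probes": 13_933,
    },
    "monocyte": {
        "n_samples": 1202,
        "n_methylation_probes": 422_016,
        "n_expression_probes": 19_445,
    },
}


def n_comparisons(study: str) -> int:
    """Total CpG × transcript tests in an all-pairs scan of the study."""
    s = REFERENCE_STUDIES[study]
    return s["n_methylation_probes"] * s["n_expression_probes"]
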