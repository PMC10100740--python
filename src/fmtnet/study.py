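"""Reference constants of the emulated FMT study design.

These are the published design figures the pipeline and the synthetic
scenario are anchored to: the sequencing summary (raw-read total over all
faecal samples) and the even rarefaction depth applied before diversity
analyses.
"""

TOTAL_RAW_READS = 6_337_424
N_SAMPLES = 107
RAREFACTION_DEPTH = 14_419


def mean_raw_reads_per_sample(total: int = TOTAL_RAW_READS,
                              n_samples: int = N_SAMPLES) -> int:
    """Average raw reads per sample, rounded to the nearest integer."""
    return round(total / n_samples)
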