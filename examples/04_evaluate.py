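"""Score estimated abundances against simulation ground truth.

CCC measures agreement with the identity line y = x; Pearson/Spearman
measure (rank) correlation; NRMSE is truth-scaled error; MRD is the median
relative difference over expressed transcripts; PET is the percentage of
expressed transcripts detected at all.
"""

from lrquant import (
    ErrorProfile,
    build_index,
    evaluate,
    generate_reads,
    generate_transcriptome,
    inject_errors,
    quantify,
    sample_expression,
)

transcripts = generate_transcriptome(100, length_range=(500, 2000), seed=9)
index = build_index(transcripts, k=63)
truth = sample_expression(transcripts, 3000, model="lognormal", seed=10)
reads, _ = generate_reads(transcripts, truth, seed=11)

for rate in (0.0, 0.03, 0.10):
    noisy = reads
    if rate:
        noisy, _ = inject_errors(noisy, ErrorProfile.preset("ont", rate), seed=12)
    result = quantify(index, noisy)
    report = evaluate(truth.to_frame(), result.table, unit="counts")
    print(
        f"error {100 * rate:4.0f}%: ccc={report.ccc:.3f} "
        f"spearman={report.spearman:.3f} nrmse={report.nrmse:.3f} "
        f"mrd={report.mrd:.3f} pet={report.pet:.1f}%"
    )
# Accuracy is stable through a few percent error and visibly degrades at
# 10%, where few 63-mers survive uncorrupted.
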