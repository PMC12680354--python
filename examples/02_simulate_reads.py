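"""Simulate full-length long reads with a platform error profile.

The simulator draws per-read error-event counts from Binomial(length,
rate), then types each event by the profile's deletion/substitution/
insertion mix at a uniform position.  The realized mix converges on the
preset fractions.
"""

from lrquant import (
    ErrorProfile,
    generate_reads,
    generate_transcriptome,
    inject_errors,
    sample_expression,
)

transcripts = generate_transcriptome(10, length_range=(1000, 1000), seed=2)
truth = sample_expression(transcripts, 2000, model="uniform", seed=2)
reads, _ = generate_reads(transcripts, truth, seed=3)

profile = ErrorProfile.preset("ont", error_rate=0.05)
noisy, tallies = inject_errors(reads, profile, seed=4)

totals = {k: sum(t[k] for t in tallies) for k in ("del", "sub", "ins")}
n = sum(totals.values())
print(f"{len(noisy)} reads, {n} error events at 5% per-base error")
for kind, target in zip(("del", "sub", "ins"), (38.5, 38.5, 23.0)):
    print(f"  {kind}: {100 * totals[kind] / n:5.2f}%  (ONT preset: {target}%)")
# Realized shares should sit within sampling noise of the preset mix.
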