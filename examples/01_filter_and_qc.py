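"""Filter a simulated nanopore 16S batch and print its QC statistics.

Generates 300 full-length 16S-like reads, applies the amplicon preset
(keep 1-2 kb reads at mean quality Q10 or better), and summarizes what
survived.
"""

from nanomon import AMPLICON_16S_PRESET, filter_reads, qc_summary
from nanomon.simulate import SimSpec, make_reference_set, simulate_reads

spec = SimSpec(seed=42, n_reads=300)
refs = make_reference_set(spec)
profile = {taxid: 1 / len(refs.species_taxids) for taxid in refs.species_taxids}
reads, _ = simulate_reads(profile, refs, spec)

kept, report = filter_reads(reads, AMPLICON_16S_PRESET)
qc = qc_summary(reads)

print(f"input reads:      {report.n_input}")
print(f"kept:             {report.n_kept}")
print(f"removed short:    {report.n_removed_short}")
print(f"removed long:     {report.n_removed_long}")
print(f"removed quality:  {report.n_removed_quality}")
print(f"total bases:      {qc.total_bases}")
print(f"N50:              {qc.n50} bp")
print(f"mean quality:     Q{qc.mean_quality:.1f}")
# The N50 is the read length at which half the sequenced bases sit in
# reads at least that long; mean quality is the PHRED transform of the
# average per-base error probability, so low-quality tails drag it down.
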