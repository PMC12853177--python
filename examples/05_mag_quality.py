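"""Apply MAG quality-retention rules to a recovered-bin table.

Uses the completeness/contamination values of seven high-quality bins
recovered from a nanopore WGS run, plus two deliberately failing bins, and
applies both retention rules: the assembly pipeline's (> 80% complete,
< 10% contaminated) and the stricter MIMAG high-quality draft standard
(>= 90% complete, < 5% contaminated).
"""

from nanomon import MAGQualityRecord, filter_mags_mimag, filter_mags_pipeline

bins = [
    MAGQualityRecord("bin.2", 94.63, 0.13, 801_950, "Pseudoclavibacter_A caeni"),
    MAGQualityRecord("bin.5", 95.15, 1.04, 2_551_952, "Methanobacterium_C congolense"),
    MAGQualityRecord("bin.6", 95.58, 0.05, 6_495_533, "Dysosmobacter sp."),
    MAGQualityRecord("bin.11", 96.77, 0.53, 2_816_210, "Bulleidia sp."),
    MAGQualityRecord("bin.12", 91.25, 0.30, 1_765_253, "JAEXAI01 sp."),
    MAGQualityRecord("bin.13", 99.96, 1.05, 3_110_456, "Acetobacter sp."),
    MAGQualityRecord("bin.17", 91.03, 2.30, 4_688_061, "JAUZPN01 sp."),
    MAGQualityRecord("bin.99", 85.00, 3.00, 1_500_000, "medium-quality bin"),
    MAGQualityRecord("bin.100", 95.00, 12.00, 2_000_000, "contaminated bin"),
]

pipeline = filter_mags_pipeline(bins)
mimag = filter_mags_mimag(bins)
print(f"pipeline retention (>80% complete, <10% contaminated): {len(pipeline)}/9")
print(f"MIMAG high-quality (>=90% complete, <5% contaminated): {len(mimag)}/9")
for rec in mimag:
    print(f"  {rec.mag_id:<8} {rec.completeness:6.2f}% complete, "
          f"{rec.contamination:5.2f}% contaminated  {rec.classification}")
# All seven real bins clear the MIMAG bar; bin.99 passes only the looser
# pipeline rule and bin.100 fails both on contamination.
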