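"""The minimum-expected-score (MES) filter for fragmented cfRNA reads.

MAPQ-based filtering discards short reads wholesale; cfRNA is highly
fragmented, so short reads matter.  The MES line accepts an alignment when
its score reaches a threshold that scales with aligned length:
MES = slope*(AL-35) + 64, slope = (277-64)/(150-35).
"""

from nulloscan.detection import AlignmentRecord, FilterConfig, alignment_score, compute_mes, passes_neoepitope_filters

cfg = FilterConfig()
print(f"slope = {cfg.mes_slope} = {float(cfg.mes_slope):.4f} (printed as 1.85)")
for al in (35, 50, 100, 150):
    print(f"  AL={al:<4} MES={compute_mes(al, cfg):.1f}")

print(f"\n35-nt alignment, 1 medium mismatch: AS = {alignment_score(35, [4])} (= MES at 35, accepted)")
print(f"150-nt alignment, penalty 15:       AS = {alignment_score(150, [4, 4, 4, 3])} (= MES at 150, accepted)")

rec = AlignmentRecord(read_id="r", mate=1, target_id="t", target_start=0, target_end=35,
                      aligned_length=35, alignment_score=64, mapq=0,
                      softclip_left=0, softclip_right=0, read_length=35)
ok, _ = passes_neoepitope_filters(rec, cfg)
print(f"\n35-nt read at the anchor passes: {ok}")

# A read either clears MAPQ (>10 for coding targets, >30 for fused targets)
# or the score line; reads with more than a third of their bases
# soft-clipped are removed regardless.
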