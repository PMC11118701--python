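"""Telomere content and relative telomere length on simulated reads.

Simulates a tumor read set with half the telomeric fraction of its
matched normal, estimates telomere content for both, and prints the RTL.
"""

from cinprecursor import relative_telomere_length, telomere_content
from cinprecursor.synthetic_data import simulate_telomere_reads

tumor_reads, _ = simulate_telomere_reads(100_000, 0.005, seed=1, sample_id="tumor")
normal_reads, _ = simulate_telomere_reads(100_000, 0.010, seed=2, sample_id="normal")

tumor = telomere_content((s for _, s in tumor_reads), "tumor")
normal = telomere_content((s for _, s in normal_reads), "normal")
rtl = relative_telomere_length(tumor, normal)

print(f"tumor : {tumor.telomeric_reads} telomeric / {tumor.total_reads} reads "
      f"-> content {tumor.content:.1f} per million")
print(f"normal: {normal.telomeric_reads} telomeric / {normal.total_reads} reads "
      f"-> content {normal.content:.1f} per million")
print(f"RTL (log2 tumor/normal): {rtl:.3f}")

# A read is telomeric when it carries >= 6 telomere repeats (TTAGGG or
# any of the 10 variant hexamers, either strand) per 100 bp. RTL near -1
# means the tumor's telomere content is half its matched normal's —
# telomere shortening, an early event in lung adenocarcinoma precursors.
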