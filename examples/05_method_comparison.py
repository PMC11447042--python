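"""Compare each ratio-spectra method against the reference assay's results.

Uses the published summary statistics (n = 5 determinations per method) of
the bisoprolol/telmisartan assay: a pooled-variance t test on the means and
a variance-ratio F test, both at alpha = 0.05. Estimated statistics below
the critical values (t = 2.306 at df 8, F = 6.388 at df 4,4) indicate no
significant difference in accuracy or precision.
"""

from ratiospec import f_ratio, two_sample_t
from ratiospec import reference as ref

for analyte in ("BPL", "TST"):
    block = ref.METHOD_COMPARISON[analyte]
    reference = block["reference"]
    print(f"{analyte} vs reference method "
          f"(mean {reference['mean']}, SD {reference['sd']}, n {reference['n']}):")
    for method, m in block["methods"].items():
        t = two_sample_t(m["mean"], m["sd"], m["n"],
                         reference["mean"], reference["sd"], reference["n"])
        f = f_ratio(m["variance"], reference["variance"], m["n"], reference["n"])
        verdict = ("ok" if not (t.t_significant or f.f_significant)
                   else "SIGNIFICANT DIFFERENCE")
        note = " (published t is inconsistent with its inputs)" \
            if m.get("t_inconsistent") else ""
        print(f"  {method:4s} t = {t.t_stat:5.3f} (crit {t.t_critical:.3f})  "
              f"F = {f.f_stat:5.3f} (crit {f.f_critical:.3f})  {verdict}{note}")
    print()
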