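"""Bundled worked-example data: a published-style SMA target-gene summary.

Two small reference tables used by the README example, the test suite
and the acceptance script:

* the candidate hub-gene lists of the two severity contrasts (type I SMA
  vs control, and type I vs type III SMA) whose deduplicated union gives
  the eight candidate SMA target genes, and
* the spinal-cord qPCR summary (mean fold change and two-sided P for the
  eight genes at the severe-symptomatic and mild-symptomatic stages)
  together with the regulation symbols of the corresponding summary
  table. The Ptgs2 entry at 6 months is reported only as P < 0.001 and
  is stored at that upper bound; the call is identical for any smaller
  value.
"""
from __future__ import annotations

SI_C_CANDIDATES = ["TNFa", "Bmp4", "Serpine1", "Ptgs2", "Bcl2", "IL6"]
SI_SIII_CANDIDATES = ["TNFa", "Bmp4", "Serpine1", "Gata6", "Ptgs2", "Bcl2", "Cntn1"]

# condition -> list of (gene, mean fold change, two-sided P, expected call)
SPINAL_CORD_QPCR = {
    "type I SMA, postnatal day 8": [
        ("TNFa", 1.65, 0.069, "up_trend"),
        ("Bmp4", 0.46, 0.024, "down_sig"),
        ("Serpine1", 1.42, 0.021, "up_sig"),
        ("Gata6", 1.65, 0.024, "up_sig"),
        ("Ptgs2", 1.68, 0.006, "up_sig"),
        ("Bcl2", 1.58, 0.042, "up_sig"),
        ("IL6", 1.57, 0.033, "up_sig"),
        ("Cntn1", 1.45, 0.046, "up_sig"),
    ],
    "type III SMA, 6 months": [
        ("TNFa", 2.59, 0.078, "up_trend"),
        ("Bmp4", 1.36, 0.174, "unchanged"),
        ("Serpine1", 1.54, 0.043, "up_sig"),
        ("Gata6", 1.85, 0.054, "up_trend"),
        ("Ptgs2", 3.17, 0.001, "up_sig"),
        ("Bcl2", 1.10, 0.196, "unchanged"),
        ("IL6", 1.25, 0.315, "unchanged"),
        ("Cntn1", 1.68, 0.092, "up_trend"),
    ],
}
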