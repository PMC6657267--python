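"""Exact combinatorics of a driver-specific drug.

A drug that kills every circulating tumour cell carrying the CD47 mutation
hits a different share of the viable driver combinations depending on
whether the driver mutations act in a fixed order (EPCAM before CD47/CD44
before MET) or order-free.  The fractions are exact rationals obtained by
enumerating the driver hypercube.
"""

from metastasim import combinatorics_report, load_packaged

scenario = load_packaged("case3")
report = combinatorics_report(scenario)
print(report.to_string(index=False))
print(
    "\nReading: under ordered dynamics the drug cannot touch one-driver CTCs"
    " (they can only be EPCAM-mutated), while order-free dynamics exposes a"
    " quarter of them; with more drivers the targeted share grows in both"
    " modes but stays smaller when the order constrains which combinations"
    " can have entered the circulation."
)
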