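"""Mass-fraction bookkeeping for sieved size classes.

Sieving splits a ground sample into nominal size classes; the mass
retained on each screen, normalized by total mass, is the classical
particle size distribution by weight.  The cumulative fraction below a
mesh is read off by summing the finer classes.
"""

from grainmorph import mass_fraction_table

# masses retained per nominal class after shaking, in grams
class_masses = [
    (">1000 um", 2.09),
    ("500-1000 um", 6.65),
    ("250-500 um", 9.385),
    ("75-250 um", 18.955),
    ("<75 um", 12.92),
]

table = mass_fraction_table(class_masses)
for label, pct in table:
    print(f"{label:>12}: {pct:6.2f} %")
sub250 = sum(pct for label, pct in table if label in ("75-250 um", "<75 um"))
print(f"cumulative < 250 um: {sub250:.2f} %")
# Percentages sum to 100; the sub-250 um fines dominate this knife-milled
# sample, which is why those classes need SEM rather than a flatbed scan.
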