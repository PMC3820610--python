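"""Forward and reverse m/z queries against the sum-composition lipid database.

Computes the ion m/z of an internal standard and a background ion, then shows
how a lock-mass calibration offset changes a reverse search: the measured
value 734.56872 matches protonated PC 32:0 at 0.4 ppm once the -0.0010 Da
offset is applied, versus ~1 ppm without it.
"""

from lipidframe import OffsetSpec, candidates_for, default_database, species_mz

db = default_database()

for name, adduct in (("TAG 17:1/17:1/17:1", "+NH4"), ("PC 32:0", "+H")):
    r = species_mz(db, name, adduct, OffsetSpec(-0.0010))
    print(f"{name:>20s} [{adduct}]  theoretical m/z {r.theoretical_mz:.5f}  "
          f"adjusted (offset -0.0010) {r.adjusted_mz:.5f}")

measured = 734.56872
for offset in (-0.0010, 0.0):
    hits = candidates_for(db, measured, tolerance=0.0020, offset=OffsetSpec(offset), polarity="positive")
    best = next(h for h in hits if h.species_name == "PC 32:0")
    print(f"measured {measured} with offset {offset:+.4f}: {best.species_name} {best.adduct} "
          f"delta {best.delta_mz:+.5f} Da = {best.delta_ppm:+.1f} ppm")
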