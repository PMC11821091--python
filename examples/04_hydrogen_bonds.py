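"""Geometric hydrogen-bond criterion and the species-pair table.

Constructs donor-H-acceptor triplets at chosen (distance, angle) geometry
and classifies them with the 0.35 nm / 30 degree criterion (inclusive
boundaries), then aggregates a table by species pair.
"""

from micellekit import hbond_table, make_hbond_fixture

cases = [
    (0.30, 10.0, ("Surf", "HBD")),   # well inside both cutoffs -> bond
    (0.36, 0.0, ("HBD", "HBD")),     # distance fails -> no bond
    (0.30, 45.0, ("Ch", "HBD")),     # angle fails -> no bond
    (0.35, 30.0, ("Cl", "HBD")),     # exactly on both boundaries -> bond
    (0.32, 20.0, ("HBD", "HBD")),
]
traj, expected = make_hbond_fixture(cases)
table = hbond_table(traj)

for (d, a, pair), exp in zip(cases, expected):
    print(f"d = {d:.2f} nm, angle = {a:4.0f} deg, {pair[0]}-{pair[1]:3s}"
          f" -> expected bond: {exp}")

print("\nper-category mean counts:")
for cat, n in table.counts_by_category().items():
    if n:
        print(f"  {cat:10s} {n:.0f}")
print(f"surfactant-involving share: {table.surfactant_share:.1f}%"
      f"   DES-only share: {table.des_share:.1f}%")
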