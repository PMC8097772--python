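"""Affinity transform and binder classification.

IC50 values (nM) from competition binding assays are mapped onto [0, 1] with
BA = 1 - log(IC50)/log(50000), so that 1 nM -> 1.0, 50000 nM -> 0.0 and the
conventional 500 nM binder cutoff lands at BA = 0.426.
"""

from netbim import classify_binder, inverse_transform_affinity, transform_affinity

for ic50 in (1.0, 50.0, 500.0, 5000.0, 50000.0):
    ba = transform_affinity(ic50)
    call = "binder" if classify_binder(ic50) else "non-binder"
    print(f"IC50 {ic50:>8.0f} nM -> BA {ba:.3f}  ({call})")

print()
print("round trip BA 0.426 ->", f"{inverse_transform_affinity(0.426):.1f} nM")
print("Higher BA means stronger binding; 0.426 is the 500 nM binder threshold.")
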