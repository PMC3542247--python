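"""Double reduction along a chromosome under quadrivalent meiosis.

Double reduction (DR) — a gamete receiving two copies of part of the same
parental homolog — can only arise through quadrivalents. Its frequency is
zero at the centromere and rises with distance towards the theoretical
limit of 1/7 under random centromere partition.
"""

from polymeiosis import (
    ChiasmaProcessConfig,
    ChromosomeSpec,
    estimate_double_reduction,
    run_test_meioses,
)

N = 20_000
LOCI = [0.0, 40.0, 80.0, 120.0, 200.0, 300.0, 400.0]
cfg = ChiasmaProcessConfig()

print(f"DR frequency per locus, 400 cM chromosome, centromere at 80 cM, {N} meioses:")
print(f"{'locus':>8} {'cross-type':>11} {'parallel':>11}")
profiles = {}
for name, parallel in [("cross-type", 0.0), ("parallel", 1.0)]:
    spec = ChromosomeSpec(
        "1", length=400.0, centromere_pos=80.0,
        quadrivalent_fraction=1.0, parallel_fraction=parallel,
    )
    stats = run_test_meioses(spec, cfg, N, LOCI, seed=23)
    profiles[name] = [estimate_double_reduction(stats, pos)[0] for pos in LOCI]

for i, pos in enumerate(LOCI):
    print(f"{pos:>6.0f}cM {profiles['cross-type'][i]:>11.4f} {profiles['parallel'][i]:>11.4f}")

print(
    "\nDR is exactly 0 at the centromere (80 cM) in both configurations and"
    "\napproaches 1/7 = 0.1429 far from it; with bivalents only (not shown)"
    "\nit would be 0 everywhere."
)
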