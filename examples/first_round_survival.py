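"""Why the first selection round is run at low stringency.

A functional sequence enters round 1 with only c = N_RNA/N_DNA copies;
each survives with probability R = Q*A*(1 - exp(-tau)).  The recovered
count is binomial(N, R): at small tau its *mode* is zero — losing the
sequence outright is the single most likely outcome — even though the
mean stays well above zero.
"""

from selexdyn import (
    FirstRoundSetup,
    ReactionParams,
    min_copies_for_confidence,
    recovery_count_mode,
    recovery_probability,
    survival_probability,
)

QA = 0.2 * 0.5  # recovery probability Q = 0.2, amplitude A = 0.5
print(f"copies needed for 95% survival at QA={QA}: {min_copies_for_confidence(0.95, QA)}")
print(f"  (amplification only, QA=1: {min_copies_for_confidence(0.95, 1.0)})")
print(f"survival with c=30: {survival_probability(30, QA):.4f}")

cat = ReactionParams("catalyst", A=0.5, k=1.0)
print("\nN=30 copies entering round 1:")
print("tau     R        mean Nrec  mode Nrec")
for tau in [5.0, 1.0, 0.3, 0.1]:
    R = recovery_probability(cat, 0.2, tau)
    print(f"{tau:<7g} {R:<8.4f} {30 * R:<10.2f} {recovery_count_mode(30, R)}")
print("-> below tau ~ 0.3 the most likely outcome is total loss of the sequence")
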