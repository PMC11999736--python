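"""Who wins a 20-round selection depends on the stringency schedule.

Four catalysts start at frequency 1e-14 each.  At constant tau = 5 the
reaction saturates, so the largest amplitude (seq3, A = 0.7) wins.
If tau is dropped 5-fold per round from round 6, recovery becomes
proportional to A*k and seq1 (A*k = 0.55) overtakes — the frequency
curves cross.  Adding a separation artefact (recovered at Rart = 0.02
regardless of tau) shows why stringency cannot be pushed arbitrarily:
below some tau the artefact out-recovers every catalyst.
"""

from selexdyn import detect_crossings, detect_dominant, presets, run_selection

for title, pool, schedule in [
    ("constant tau = 5", presets.example_pool(), presets.constant_schedule(5.0)),
    ("tau / 5 per round from round 6", presets.example_pool(), presets.stepped_schedule()),
    ("same, with artefact", presets.example_pool(artefact=True), presets.stepped_schedule()),
]:
    traj = run_selection(pool, schedule, 20)
    print(f"\n--- {title} ---")
    print("round  " + "  ".join(f"{l:>9}" for l in traj.labels))
    for n in (0, 5, 10, 15, 20):
        print(f"{n:>5}  " + "  ".join(f"{f:9.2e}" for f in traj.freqs[n]))
    print(f"dominant at round 20: {detect_dominant(traj, 20)}; "
          f"crossings: {len(detect_crossings(traj))}")
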