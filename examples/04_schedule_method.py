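"""Design a scheduled PRM method from protein sequences.

Digests proteins in silico (trypsin, no cleavage before proline), filters
to proteotypic candidates (unique, fully cleaved, no ragged ends), and
greedily schedules 2-min retention-time windows so that no more than 3
heavy/light precursor pairs are ever monitored concurrently — keeping the
slow high-resolution duty cycle compatible with enough points per peak.
"""

from prmquant import (AcquisitionSettings, concurrency_profile, estimate_cycle,
                      select_targets, tryptic_digest)

entries = [
    ("PROT_A", "MGGFGVVFEAKLLDSNQVLLGTKAAARVDPSSLTTGEYRK"),
    ("PROT_B", "MSGEYFDLVPTKQVEPLSDFSLRGGGKELSDSFNQLAKR"),
    ("PROT_C", "MTPDSEVLQGLRVSDGLTPEFNKAEPQPLSPASSSYSVSSPRK"),
]
candidates = tryptic_digest(entries)
print(f"{len(candidates)} digest candidates; "
      f"{sum(c.unique_in_proteome and c.missed_cleavages == 0 and not c.ragged_end for c in candidates)} proteotypic")

method = select_targets(candidates, rt_window=2.0, max_concurrent=3,
                        per_protein_min=2)
for cand, start, end in method.targets:
    print(f"  {cand.sequence:24s} {cand.protein}  window "
          f"{start:5.2f}-{end:5.2f} min")

max_pairs, _ = concurrency_profile(method)
settings = AcquisitionSettings(resolution=240_000, injection_time=500)
cycle_ms, points = estimate_cycle(settings, n_concurrent_precursors=2 * max_pairs)
print(f"\nmax concurrency {max_pairs} pairs -> cycle {cycle_ms:.0f} ms, "
      f"~{points:.1f} points per peak. Each pair costs two scans per cycle "
      "(light + heavy); the 512 ms orbitrap transient at 240k bounds the "
      "scan time, so capping concurrency preserves peak sampling.")
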