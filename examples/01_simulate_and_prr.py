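"""Simulate a spontaneous-reporting corpus and rank PRR signals.

Generates 10,000 VAERS-like reports with one planted female-specific
association (MMR → Rash, risk multiplier 5), computes stratified
proportional reporting ratios, and prints the strongest overall signals.
"""

from vaersnet import (
    PlantedSignal,
    SyntheticConfig,
    compute_prrs,
    count_pairs,
    generate_reports,
    significant_associations,
)

cfg = SyntheticConfig(
    n_reports=10_000,
    seed=42,
    planted_signals=[PlantedSignal("MMR", "Rash", sex="F", multiplier=5.0)],
)
reports, truth = generate_reports(cfg)
records, ctx = count_pairs(reports)
compute_prrs(records, ctx)

sig = significant_associations(records, "overall")
print(f"{len(reports)} reports, {len(records)} distinct vaccine-AE pairs, "
      f"{len(sig)} with overall PRR > 1")

top = sorted(sig, key=lambda r: r.prr_overall, reverse=True)[:5]
print("\nstrongest overall signals (PRR > 1 means the AE is reported "
      "disproportionately often with that vaccine):")
for rec in top:
    print(f"  {rec.vaccine:8s} {rec.symptom:30s} n={rec.n_pair_total:5d} "
          f"PRR={rec.prr_overall:.2f}  (F: {rec.prr_by_sex['F']:.2f}, "
          f"M: {rec.prr_by_sex['M']:.2f})")

planted = next(r for r in records if r.pair == ("MMR", "Rash"))
print(f"\nplanted pair (MMR, Rash): female PRR {planted.prr_by_sex['F']:.2f} "
      f"vs male PRR {planted.prr_by_sex['M']:.2f} — the female-only multiplier "
      "shows up only in the female stratum, as intended.")
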