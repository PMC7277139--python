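"""The packaged full-scale scenario, end to end.

40 t of benzyl chloride over one hour at midnight from the centre of a
16 km x 12 km grid (100 m cells, 10 m surface layer), 100-day horizon,
synthetic north-westerly wind.  The pipeline chains simulation,
endpoint determination, per-age-group risk assessment, and writes the
report bundle (ASCII-grid rasters, summary.csv, wind rose, manifest).

Runs in well under a minute on one CPU.
"""

from pathlib import Path

from chemrisk import load_config, run_pipeline

config_path = Path(__file__).parent / "ulsan_benzyl_chloride.yaml"
result = run_pipeline(
    load_config(config_path),
    out_dir="chemrisk_out/ulsan",
    write_daily_rasters=False,   # flip on to export 200 daily rasters
)

ep = result["endpoint"]
print(f"extinction endpoint: day {ep.endpoint_day} "
      f"(background {ep.background_mg_m3:.3e} mg/m3)\n")
print(result["summary"].to_string(index=False))

ledger = result["history"].ledger
print(f"\nmass budget: {ledger.deposited:.0f} kg deposited, "
      f"{ledger.exported:.0f} kg exported, {ledger.decayed_air:.0f} kg decayed")
print("Every age group shows a red (ECR >= 1e-6) zone south-east of the "
      "source; the 0-9 group has the largest red share and the highest "
      "maximum and mean, as its intake-to-body-weight ratio dominates.")
print(f"report bundle written to {result['out_dir']}")
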