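"""Compare reconstruction methods over a seeded simulation ensemble.

Runs the full pipeline for every method over 20 seeds and prints the mean
SNR and RMSE per method, plus how often each method wins outright.  The
CSV of all runs is written under scratch/ for further analysis.
"""

from pathlib import Path

from mtsr.pipeline import PipelineConfig, run_ensemble

out = Path("scratch")
out.mkdir(exist_ok=True)

df = run_ensemble(PipelineConfig(), seeds=range(20))
summary = df.groupby("method")[["snr_db", "rmse"]].agg(["mean", "std"]).round(3)
print(summary.to_string())

wins = df.loc[df.groupby("seed")["snr_db"].idxmax(), "method"].value_counts()
print("\nper-seed SNR wins:")
print(wins.to_string())

df.to_csv(out / "ensemble.csv", index=False)
print(f"\nwrote {out / 'ensemble.csv'}")
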