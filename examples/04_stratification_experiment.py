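"""Measure type-I-error inflation from mismatched controls, and its
correction.

Runs a small H0 scenario grid at migration rate 0.001: controls drawn 0%
or 75% from deme B, the latter with and without the PCA model correction
(two leading ancestry PCs from a pool of background genes).  Rejection
rates at alpha = 0.05 are printed with the binomial null-consistency
band; the stratified, uncorrected SKAT rate shows clear inflation that
the correction removes.  Replicate counts are kept small so the script
finishes in about two minutes; widths of the reported bands scale
accordingly.
"""

from rarestrat import BackgroundPanel, DemographyConfig, Scenario, run_scenario, summarize

demography = DemographyConfig(migration_rate=0.001)
REPS = 100

print("building background-gene pool for the ancestry PCs ...")
background = BackgroundPanel.from_demography(demography, n_genes=300, seed=9)

runs = []
for pct_b, corrections in ((0.0, ("none",)), (0.75, ("none", "pca_model"))):
    sc = Scenario(migration_rate=0.001, pct_controls_b=pct_b, hypothesis="H0",
                  methods=("sum", "skat"), corrections=corrections,
                  n_pcs=2, replicates=REPS)
    df = run_scenario(sc, demography, master_seed=31, background=background)
    runs.append(summarize(df, alpha=0.05))

for s in runs:
    for _, row in s.iterrows():
        print(f"pctB={row['pct_controls_b']:<5} {row['method']:<5} "
              f"corr={row['correction']:<9} rate={row['rejection_rate']:.3f} "
              f"(null band [{row['null_band_low']:.3f}, {row['null_band_high']:.3f}])")
print("\nRates above the band indicate stratification-driven false positives; "
      "the PCA model correction pulls the 75%-B scenario back toward nominal.")
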