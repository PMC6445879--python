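#!/usr/bin/env python
"""Step 4 — estimator calibration on synthetic two-sample GWAS data.

Runs two seeded Monte-Carlo experiments on 50-instrument panels generated by
the summary-level causal model (500 replicates each) and writes the summary
to results/simulation_summary.tsv:

* null model (theta = 0, no pleiotropy): IVW type-I error at alpha = 0.05
  and CI coverage;
* directional pleiotropy under InSIDE (theta = 0.2, mean direct effect
  0.05): bias of IVW versus MR-Egger.

Finding: IVW rejects near its nominal 5% level under the null, and under
directional pleiotropy the MR-Egger slope is approximately unbiased while
IVW absorbs the average direct effect into its estimate.
"""

from pathlib import Path

from selmr.synthetic_gwas import SimulationConfig, recovery_experiment

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    rows = []
    null = recovery_experiment(
        SimulationConfig(n_instruments=50, theta=0.0, pleiotropy_sd=0.0, seed=0),
        n_reps=500, alpha=0.05, methods=("ivw",))
    rows.append(("null_theta0", null["ivw"]))
    print(f"null model: IVW type-I error = {null['ivw'].rejection_rate:.3f} "
          f"(nominal 0.05), coverage = {null['ivw'].coverage:.3f}")

    directional = recovery_experiment(
        SimulationConfig(n_instruments=50, theta=0.2, pleiotropy_mean=0.05,
                         pleiotropy_sd=0.01, seed=0),
        n_reps=500, methods=("ivw", "egger"))
    for m in ("ivw", "egger"):
        rows.append(("directional_theta0.2", directional[m]))
        print(f"directional pleiotropy: {m} bias = {directional[m].mean_bias:+.3f} "
              f"(empirical SD {directional[m].empirical_sd:.3f})")

    RESULTS.mkdir(exist_ok=True)
    out = RESULTS / "simulation_summary.tsv"
    header = "scenario\tmethod\tmean_bias\tempirical_sd\trejection_rate\tcoverage\tn_reps"
    lines = [header] + [
        f"{scenario}\t{s.method}\t{s.mean_bias:.4f}\t{s.empirical_sd:.4f}"
        f"\t{s.rejection_rate:.3f}\t{s.coverage:.3f}\t{s.n_reps}"
        for scenario, s in rows
    ]
    out.write_text("\n".join(lines) + "\n")
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
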