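"""Fit and score the four calibration variants on one simulated dataset.

Variants mirror the study's comparison: NIR-only PLS (8 LVs), MIR-only PLS
(10 LVs), fused MIR+NIR PLS (10 LVs) and fused PCR (10 PCs), after the
shared preprocessing chain (SG 2nd derivative, SNV, Kennard-Stone 26/13
sample split, calibration-mean centering). Writes the tidy report with
RMSEC / RMSECV / RMSEP / R^2 and predicted-value LoB/LoD per variant.
"""

from pathlib import Path

import specfuse as sf

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    config = sf.ExperimentConfig(seeds=(0,))
    report, manifest = sf.run_experiment(config)
    out = ROOT / "results" / "calibration_variants"
    sf.write_report(report, manifest, out)

    cols = ["variant", "n_components", "rmsec", "rmsecv", "rmsep",
            "r2_pred", "lob", "lod"]
    print(report[cols].to_string(index=False,
                                 float_format=lambda v: f"{v:.3f}"))
    fused = report.set_index("variant")
    print(
        f"\nfused PLS RMSEP {fused.loc['Fused PLS','rmsep']:.3f} mg/mL vs "
        f"single blocks {fused.loc['NIR PLS','rmsep']:.3f} (NIR) / "
        f"{fused.loc['MIR PLS','rmsep']:.3f} (MIR); "
        f"LoD improves to {fused.loc['Fused PLS','lod']:.3f} mg/mL from "
        f"{min(fused.loc['NIR PLS','lod'], fused.loc['MIR PLS','lod']):.3f}"
    )
    print(f"report -> {out}/report.csv")


if __name__ == "__main__":
    main()
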