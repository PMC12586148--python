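#!/usr/bin/env python
"""Run the full photometry correction chain on a synthetic dual-channel
recording and report how well each planted contaminant was removed.

Writes the per-stage series and a provenance report under results/photometry/.
"""

import argparse
import json
from pathlib import Path

import numpy as np
import pandas as pd

from calzone.photometry import preprocess
from calzone.synthgen import PhotometrySpec, SimConfig, ZoneSpec, simulate_behavior, simulate_photometry


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=Path("results/photometry"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    cfg = SimConfig(
        session_duration=600.0,
        zones=(ZoneSpec("arena", 30.0),),
        photometry=PhotometrySpec(
            motion_amplitude=0.3,
            motion_rate=0.5,
            packet_loss_rate=0.001,
            noise_sd=0.01,
            signal_rate=0.1,
            signal_amplitude=0.3,
        ),
        seed=args.seed,
    )
    occ, _ = simulate_behavior(cfg)
    session, gt = simulate_photometry(occ, cfg)
    proc = preprocess(session)

    n_trim = int(5 * session.rate)
    motion = gt.motion[n_trim:]
    raw = session.primary[n_trim:] - gt.bleach_primary[n_trim:]
    corr_before = float(np.corrcoef(raw, motion)[0, 1])
    corr_after = float(np.corrcoef(proc.stage_outputs["motion_corrected"], motion)[0, 1])
    planted_flags = int(gt.artifact_mask.sum())
    recovered = int((proc.artifact_mask & gt.artifact_mask[n_trim:]).sum())

    stages = pd.DataFrame(
        {k: v for k, v in proc.stage_outputs.items() if v.ndim == 1}
    )
    stages.to_csv(args.out / "stages.csv", index=False)
    report = {
        "provenance": proc.provenance,
        "baseline_params": {k: list(v) for k, v in proc.baseline_params.items()},
        "motion_corr_before": corr_before,
        "motion_corr_after": corr_after,
        "packet_loss_planted": planted_flags,
        "packet_loss_flagged": int(proc.artifact_mask.sum()),
        "z_mean": float(proc.zscored.mean()),
        "z_sd": float(proc.zscored.std(ddof=1)),
    }
    (args.out / "report.json").write_text(json.dumps(report, indent=1))

    print(f"session: {session.duration:.0f}s at {session.rate:.0f} Hz")
    print(f"packet-loss spikes planted {planted_flags}, flagged after trim {recovered}")
    print(f"motion-artifact correlation: {corr_before:.3f} raw -> {corr_after:.3f} corrected")
    print(f"final z-scored trace: mean {report['z_mean']:.2e}, s.d. {report['z_sd']:.6f}")


if __name__ == "__main__":
    main()
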