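#!/usr/bin/env python
"""Classify zone-responsive cells in the simulated sessions and compare
responsive proportions, mirroring the in-vivo analysis on extracted traces.

Reads the CSVs written by 01_simulate_sessions.py, z-scores and bins each
cell, fits the per-cell linear model, applies Benjamini-Hochberg within each
zone predictor, and writes the ResponseTable plus a proportions report.
"""

import argparse
import json
from pathlib import Path

import numpy as np

from calzone import cellclass, perievent
from calzone.session_io import read_trace_table, read_tracking_table


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)  # kept for interface symmetry
    ap.add_argument("--sessions", type=Path, default=Path("results/sessions"))
    ap.add_argument("--out", type=Path, default=Path("results/classification"))
    ap.add_argument("--alpha", type=float, default=0.05)
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    for name, gate, pair in (("epm", 0.0, ("open", "closed")), ("aba", 0.1, ("rw", "food"))):
        traces = read_trace_table(args.sessions / f"{name}_traces.csv", rate=10.0)
        occ = read_tracking_table(args.sessions / f"{name}_tracking.csv")
        truth = json.loads((args.sessions / f"{name}_truth.json").read_text())

        z = traces.zscored()
        binned = np.vstack(
            [perievent.bin_signal(z.values[i], z.rate) for i in range(z.n_cells)]
        )
        design = cellclass.build_design(occ)
        table = cellclass.classify_cells(
            binned, design, cell_ids=traces.cell_ids, alpha=args.alpha, effect_gate=gate
        )
        table.to_csv(args.out / f"{name}_responses.csv", index=False)

        rep = cellclass.proportion_report(table, pair[0], pair[1])
        (args.out / f"{name}_proportions.json").write_text(json.dumps(rep.to_dict(), indent=1))

        # agreement with the planted truth on the gated zone labels
        agree = 0
        planted = 0
        for i, labels in enumerate(truth["cell_labels"]):
            for zone, lab in labels.items():
                if lab != "null":
                    planted += 1
                    row = table[(table.cell_id == traces.cell_ids[i]) & (table.predictor == zone)]
                    if row.iloc[0]["label"] == lab:
                        agree += 1
        print(
            f"{name}: excited {rep.counts[0]}/{rep.totals[0]} ({pair[0]}) vs "
            f"{rep.counts[1]}/{rep.totals[1]} ({pair[1]}), z = {rep.z:.2f}, "
            f"p = {rep.p_value:.2e}; planted-label agreement {agree}/{planted}"
        )


if __name__ == "__main__":
    main()
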