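#!/usr/bin/env python
"""Generate the reference synthetic sessions used by the downstream steps.

Writes an EPM-like session (open / closed / center zones) and an ABA-like
session (food / running-wheel / neutral zones) as trace + tracking CSVs,
with the planted ground truth as JSON, under results/sessions/.
"""

import argparse
import json
from pathlib import Path

from calzone.session_io import write_trace_table, write_tracking_table
from calzone.synthgen import CellSpec, SimConfig, ZoneSpec, simulate_behavior, simulate_traces


def epm_config(seed: int) -> SimConfig:
    cells = []
    for i in range(60):
        if i < 15:
            cells.append(CellSpec(0.5, {"open": 0.6}))  # open-arm excited
        elif i < 22:
            cells.append(CellSpec(0.5, {"closed": 0.5}))
        elif i < 30:
            cells.append(CellSpec(0.5, {"open": -0.4}))
        else:
            cells.append(CellSpec(0.5))
    return SimConfig(
        session_duration=900.0,
        zones=(ZoneSpec("open", 8.0), ZoneSpec("closed", 20.0), ZoneSpec("center", 3.0)),
        n_cells=60,
        cell_specs=tuple(cells),
        transit_s=1.0,
        seed=seed,
    )


def aba_config(seed: int) -> SimConfig:
    cells = []
    for i in range(60):
        if i < 12:
            cells.append(CellSpec(0.5, {"rw": 0.5}))  # running-wheel excited
        elif i < 20:
            cells.append(CellSpec(0.5, {"food": 0.5}))
        else:
            cells.append(CellSpec(0.5))
    return SimConfig(
        session_duration=900.0,
        zones=(ZoneSpec("food", 10.0), ZoneSpec("rw", 10.0), ZoneSpec("neutral", 15.0)),
        n_cells=60,
        cell_specs=tuple(cells),
        transit_s=2.0,
        seed=seed,
    )


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=Path("results/sessions"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    for name, cfg in (("epm", epm_config(args.seed)), ("aba", aba_config(args.seed + 1))):
        occ, events = simulate_behavior(cfg)
        traces, gt = simulate_traces(occ, cfg)
        write_trace_table(traces, args.out / f"{name}_traces.csv")
        write_tracking_table(occ, args.out / f"{name}_tracking.csv")
        (args.out / f"{name}_truth.json").write_text(
            json.dumps(
                {"cell_labels": gt.cell_labels, "cell_effects": gt.cell_effects},
                indent=1,
            )
        )
        n_mod = sum(
            any(lab != "null" for lab in labels.values()) for labels in gt.cell_labels
        )
        visits = {z: events.n_visits(z) for z in occ.zones}
        print(
            f"{name}: {traces.n_cells} cells x {traces.n_frames} frames, "
            f"{n_mod} truly modulated cells, visits per zone {visits}"
        )


if __name__ == "__main__":
    main()
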