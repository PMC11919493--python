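#!/usr/bin/env python
"""Estimate the plateau, tcrit50/tcrit90 and the steady-state distribution.

Reads the trajectory simulated by 03_simulate_divergence.py, locates the
steady-state plateau, the critical times at which divergence reaches 50%
and 90% of it, and the post-tcrit90 divergence distribution whose
stationarity is what makes phylogenetic time unreadable from divergence
past that point.

Writes results/critical_times.json and results/steady_state.tsv.
"""

import json
from pathlib import Path

from polyspace import (
    DivergenceTrajectory,
    critical_times,
    steady_state_distribution,
)
from polyspace.constrained_space import encode_sequence, read_fasta_alignment
import numpy as np

RESULTS = Path(__file__).resolve().parents[1] / "results"
SNAPSHOTS = (4000, 6000)


def main() -> None:
    traj = DivergenceTrajectory.from_tsv(RESULTS / "trajectory.tsv")
    ancestor = (RESULTS / "ancestor.txt").read_text().strip()

    crit = critical_times(traj)
    crit.to_json(RESULTS / "critical_times.json")
    print(
        f"plateau D_inf = {crit.plateau:.4f} (SD {crit.plateau_sd:.4f}); "
        f"tcrit50 = {crit.tcrit50:.0f} generations, tcrit90 = {crit.tcrit90:.0f}"
    )

    snapshots = {
        g: np.stack([encode_sequence(s) for s in
                     read_fasta_alignment(RESULTS / f"snapshot_gen{g}.fasta")])
        for g in SNAPSHOTS
        if g > crit.tcrit90
    }
    dist = steady_state_distribution(snapshots, ancestor, crit.tcrit90)
    dist.to_tsv(RESULTS / "steady_state.tsv")
    print(
        f"steady-state distribution over {dist.n_samples} copies "
        f"(generations {dist.window[0]}..{dist.window[1]}), "
        f"max TV between snapshots {dist.max_tv_distance:.3f}"
    )
    payload = json.loads((RESULTS / "critical_times.json").read_text())
    payload["steady_state_max_tv"] = dist.max_tv_distance
    (RESULTS / "critical_times.json").write_text(json.dumps(payload, indent=2) + "\n")


if __name__ == "__main__":
    main()
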