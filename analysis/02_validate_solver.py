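#!/usr/bin/env python
"""Validate the channel flow solver against closed-form laminar solutions.

Three checks: (1) steady straight-channel wall shear vs plane Poiseuille
(6*eta*U/h); (2) pulsatile straight-channel wall shear vs the plane-channel
Womersley solution at alpha = 3.48 under the 1000-steps-per-cycle, 3-cycle
protocol; (3) grid convergence of the pulsatile wall shear across 32/64/128
transverse cells.
"""

import json
from pathlib import Path

import pandas as pd

from aortashear.validation import (
    grid_convergence_study,
    steady_poiseuille_validation,
    womersley_channel_validation,
)

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)


def main() -> None:
    steady = steady_poiseuille_validation(ny=64)
    print(f"steady Poiseuille, 64 cells: wall-shear error "
          f"{100 * steady['rel_error']:.2e} % (tolerance 2%)")

    wom = womersley_channel_validation(ny=64, steps_per_cycle=1000)
    print(f"Womersley channel, alpha={wom['alpha']:.2f}: RMS error "
          f"{100 * wom['rms_rel_error']:.3f} % (tolerance 3%), "
          f"cycle-to-cycle change {100 * wom['cycle_rms_change']:.2e} %")

    conv = grid_convergence_study(nys=(32, 64, 128))
    rows = [{"transverse_cells": ny, "rms_rel_error": err}
            for ny, err in conv["errors"].items()]
    table = pd.DataFrame(rows)
    print(table.to_string(index=False))
    print(f"observed convergence order: {conv['observed_order']:.2f} (>= 1.8 expected)")

    summary = {
        "steady_rel_error": steady["rel_error"],
        "womersley_rms_rel_error": wom["rms_rel_error"],
        "womersley_alpha": wom["alpha"],
        "cycle_rms_change": wom["cycle_rms_change"],
        "convergence_errors": {str(k): v for k, v in conv["errors"].items()},
        "observed_order": conv["observed_order"],
        "max_divergence": wom["max_divergence"],
        "max_mass_error": wom["max_mass_error"],
    }
    with open(OUT / "solver_validation.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    print(f"\nwrote {OUT / 'solver_validation.json'}")


if __name__ == "__main__":
    main()
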