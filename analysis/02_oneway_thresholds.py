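"""One-way sensitivity and threshold analysis.

Scans the two most uncertain natural-history inputs, holding all else at
base case:

* p(PE | untreated DVT) — bisection finds the value above which BOTH
  prophylaxis strategies are dominant (cost-saving and life-saving).  The
  binding strategy is UFH, whose adverse-event mortality outweighs its VTE
  prevention below the threshold (~14%).
* p(death | untreated PE) from 0 to its base value 0.26 — the death-rate
  reduction versus no prophylaxis spans ~0.1–0.5% (LMWH) and ~0–0.3% (UFH);
  LMWH stays dominant over the entire range.

Writes results/oneway_*.csv and results/thresholds.json.
"""

import json
from pathlib import Path

import numpy as np

from vte_cea.parameters import load_parameters
from vte_cea.sensitivity import find_threshold, one_way_scan

OUT = Path(__file__).resolve().parents[1] / "results"
PPEU = "shared.p_pe_given_untreated_dvt"
PDEATH = "shared.p_death_given_untreated_pe"


def main() -> dict:
    bundle = load_parameters()
    OUT.mkdir(exist_ok=True)

    threshold = find_threshold(PPEU, "both_dominant", (1e-6, 0.511), bundle, tol=1e-5)
    print(
        f"Both strategies dominant once p(PE | untreated DVT) exceeds "
        f"{100 * threshold.value:.1f}% (base value 51.1%)."
    )

    scan_ppeu = one_way_scan(PPEU, np.linspace(1e-6, 0.511, 41), bundle)
    scan_ppeu.to_frame().to_csv(OUT / "oneway_p_pe_untreated_dvt.csv", index=False)

    scan_fatal = one_way_scan(PDEATH, np.linspace(1e-9, 0.26, 27), bundle)
    scan_fatal.to_frame().to_csv(OUT / "oneway_p_death_untreated_pe.csv", index=False)
    for sid in ("LMWH", "UFH"):
        reductions = [100 * r.death_rate_reduction for r in scan_fatal.cea[sid]]
        dominant = all(r.dominance == "dominant" for r in scan_fatal.cea[sid])
        print(
            f"  {sid}: death-rate reduction spans {reductions[0]:.2f}% -> {reductions[-1]:.2f}% "
            f"as the untreated-PE fatality runs 0 -> 0.26"
            + ("; dominant throughout" if dominant else "")
        )

    payload = {
        "parameter": PPEU,
        "criterion": "both_dominant",
        "threshold": threshold.value,
        "status": threshold.status,
    }
    (OUT / "thresholds.json").write_text(json.dumps(payload, indent=2) + "\n")
    return payload


if __name__ == "__main__":
    main()
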